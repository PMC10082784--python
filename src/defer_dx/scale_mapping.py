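"""Conversions between the ordinal 1-8 assessment scale, binary decisions,
confidence levels, and AI probabilities.

The assessment scale encodes both a diagnosis and its confidence: 1 is a
maximally confident negative, 8 a maximally confident positive, and 4/5 an
equivocal read.  AI probabilities in [0, 1] are placed on the same scale by
the linear map ``rating = 1 + 7 p``, so probability 0.5 lands exactly on the
4.5 decision boundary.

Two different "uncertain" definitions coexist and are deliberately kept as
separate functions: a *reader* is uncertain when the integer rating is 4 or
5; the *AI* is uncertain when its continuous rating-equivalent falls in the
half-open band [3.5, 5.5) (probabilities in [2.5/7, 4.5/7), i.e. roughly
0.357-0.643).  The edge semantics differ, so they are never unified.
"""

from __future__ import annotations

import numpy as np

#: Rating-scale value at or above which a score counts as a positive call.
DECISION_THRESHOLD = 4.5

#: Continuous rating band in which the AI is treated as uncertain.
AI_BAND_LOW = 3.5
AI_BAND_HIGH = 5.5

#: The same band expressed in probability space (exact, not rounded).
AI_BAND_LOW_PROB = 2.5 / 7.0
AI_BAND_HIGH_PROB = 4.5 / 7.0

__all__ = [
    "DECISION_THRESHOLD",
    "AI_BAND_LOW",
    "AI_BAND_HIGH",
    "AI_BAND_LOW_PROB",
    "AI_BAND_HIGH_PROB",
    "prob_to_rating",
    "rating_to_prob",
    "rating_to_binary",
    "reader_is_uncertain",
    "ai_is_uncertain",
    "confidence_level",
]


def _as_array(x, lo, hi, what):
    arr = np.asarray(x, dtype=float)
    bad = ~np.isfinite(arr) | (arr < lo) | (arr > hi)
    if np.any(bad):
        raise ValueError(f"{what} must lie in [{lo}, {hi}]; got {np.asarray(x)[bad][:5]}")
    return arr


def _maybe_scalar(result, template):
    return result.item() if np.ndim(template) == 0 else result


def prob_to_rating(p):
    """Map a probability in [0, 1] onto the 1-8 rating scale: ``1 + 7 p``."""
    arr = _as_array(p, 0.0, 1.0, "probability")
    return _maybe_scalar(1.0 + 7.0 * arr, p)


def rating_to_prob(r):
    """Inverse of :func:`prob_to_rating`: ``(r - 1) / 7`` for r in [1, 8]."""
    arr = _as_array(r, 1.0, 8.0, "rating")
    return _maybe_scalar((arr - 1.0) / 7.0, r)


def rating_to_binary(r):
    """Binary decision on the rating scale: positive iff ``r >= 4.5``.

    The threshold is inclusive, so a blended or tied score of exactly 4.5
    is a positive call.
    """
    arr = _as_array(r, 1.0, 8.0, "rating")
    return _maybe_scalar(arr >= DECISION_THRESHOLD, r)


def _as_integer_rating(r):
    arr = _as_array(r, 1.0, 8.0, "rating")
    if np.any(arr != np.floor(arr)):
        raise ValueError(f"integer rating expected; got {np.asarray(r)}")
    return arr


def reader_is_uncertain(r):
    """True iff an integer reader rating is equivocal (4 or 5)."""
    arr = _as_integer_rating(r)
    return _maybe_scalar((arr == 4) | (arr == 5), r)


def ai_is_uncertain(r):
    """True iff a continuous rating-equivalent falls in [3.5, 5.5).

    The band is half-open: 3.5 is uncertain, 5.5 is not.
    """
    arr = _as_array(r, 1.0, 8.0, "rating")
    return _maybe_scalar((arr >= AI_BAND_LOW) & (arr < AI_BAND_HIGH), r)


def confidence_level(r):
    """Confidence level 1-4 of an integer rating, symmetric about 4.5.

    {4,5} -> 1 (equivocal), {3,6} -> 2, {2,7} -> 3, {1,8} -> 4.
    """
    arr = _as_integer_rating(r)
    level = np.abs(arr - DECISION_THRESHOLD) + 0.5
    return _maybe_scalar(level.astype(int), r)
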