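"""Collaboration strategies for combining one physician's reads with AI scores.

Seven per-image decision policies share a common output shape: the two solo
baselines (physician alone, AI alone), two uncertainty-based deferral
strategies (AI-aided physician: the physician reads first and defers to the
AI when equivocal; physician-aided AI: the AI scores first and defers to
the physician inside its uncertainty band), two score blends (plain and
weighted average on the 1-8 scale), and an audit strategy in which a
randomly chosen second reader adjudicates physician-AI disagreements.

Every strategy reports a *review burden*: the percentage of images needing
any physician read (0 for AI alone, 100 whenever the physician reads
everything, 100 x AI-uncertain fraction for physician-aided AI, and
100 + 100 x disagreement fraction for the audit strategy, which can exceed
100).  Blended scores are binarized at the same inclusive 4.5 threshold
used everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import AdjudicationError, AlignmentError, ConfigurationError
from .reference_labels import LabelSet
from .scale_mapping import DECISION_THRESHOLD, ai_is_uncertain, reader_is_uncertain

__all__ = [
    "StrategyOutput",
    "WeightedAverageParams",
    "default_weight_grid",
    "physician_alone",
    "ai_alone",
    "ai_aided_physician",
    "physician_aided_ai",
    "average_blend",
    "weighted_blend",
    "select_weight",
    "audit_strategy",
    "run_all_strategies",
    "STRATEGY_NAMES",
]

STRATEGY_NAMES = (
    "physician",
    "ai",
    "ai_aided_physician",
    "physician_aided_ai",
    "average",
    "weighted_average",
    "audit",
)


@dataclass(frozen=True)
class StrategyOutput:
    """Per-image decisions and aggregate burden of one strategy run.

    ``decisions`` has columns ``image_id, final_score, decision, source``
    where source is one of reader / ai / second_reader / blend.
    """

    name: str
    decisions: pd.DataFrame
    review_burden: float


@dataclass(frozen=True)
class WeightedAverageParams:
    """Physician weight for the weighted blend; the AI weight is its complement."""

    w_physician: float
    grid: tuple = field(default_factory=lambda: tuple(default_weight_grid()))

    def __post_init__(self):
        if not 0.0 <= self.w_physician <= 1.0:
            raise ConfigurationError("w_physician must lie in [0, 1]")

    @property
    def w_ai(self) -> float:
        return 1.0 - self.w_physician


def default_weight_grid() -> np.ndarray:
    """The 21-point physician-weight grid {0, 0.05, ..., 1}."""
    return np.round(np.linspace(0.0, 1.0, 21), 2)


# ---------------------------------------------------------------------------
# alignment helpers


def _one_reader_table(ratings_one: pd.DataFrame) -> pd.DataFrame:
    if ratings_one["image_id"].duplicated().any():
        dups = ratings_one.loc[ratings_one["image_id"].duplicated(), "image_id"].tolist()
        raise ValueError(f"duplicate image(s) in single-reader ratings: {dups[:10]}")
    return ratings_one


def _scores_table(scores: pd.DataFrame) -> pd.DataFrame:
    if scores["image_id"].duplicated().any():
        dups = scores.loc[scores["image_id"].duplicated(), "image_id"].tolist()
        raise ValueError(f"duplicate image(s) in score table: {dups[:10]}")
    if "rating_equiv" not in scores.columns:
        scores = scores.assign(rating_equiv=1.0 + 7.0 * scores["probability"])
    return scores


def _align(ratings_one: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    ratings_one = _one_reader_table(ratings_one)
    scores = _scores_table(scores)
    r_ids = set(ratings_one["image_id"])
    s_ids = set(scores["image_id"])
    if r_ids != s_ids:
        raise AlignmentError(
            "ratings and scores cover different images", r_ids.symmetric_difference(s_ids)
        )
    merged = ratings_one.merge(scores[["image_id", "rating_equiv"]], on="image_id")
    return merged.sort_values("image_id", kind="stable").reset_index(drop=True)


def _output(name, image_ids, final_score, source, burden) -> StrategyOutput:
    final_score = np.asarray(final_score, dtype=float)
    decisions = pd.DataFrame(
        {
            "image_id": np.asarray(image_ids),
            "final_score": final_score,
            "decision": (final_score >= DECISION_THRESHOLD).astype(int),
            "source": source,
        }
    )
    return StrategyOutput(name=name, decisions=decisions, review_burden=float(burden))


# ---------------------------------------------------------------------------
# strategies


def physician_alone(ratings_one: pd.DataFrame) -> StrategyOutput:
    """The physician's own rating decides every image; burden 100."""
    df = _one_reader_table(ratings_one).sort_values("image_id", kind="stable")
    return _output("physician", df["image_id"], df["rating"], "reader", 100.0)


def ai_alone(scores: pd.DataFrame) -> StrategyOutput:
    """The AI's rating-equivalent decides every image; burden 0."""
    df = _scores_table(scores).sort_values("image_id", kind="stable")
    return _output("ai", df["image_id"], df["rating_equiv"], "ai", 0.0)


def ai_aided_physician(ratings_one: pd.DataFrame, scores: pd.DataFrame) -> StrategyOutput:
    """Physician reads first; equivocal (4/5) reads defer to the AI.

    The physician still reviews every image, so the burden stays 100.  A
    deferred image carries the AI's continuous rating-equivalent as its
    final score.
    """
    df = _align(ratings_one, scores)
    defer = reader_is_uncertain(df["rating"].to_numpy())
    final = np.where(defer, df["rating_equiv"], df["rating"])
    source = np.where(defer, "ai", "reader")
    return _output("ai_aided_physician", df["image_id"], final, source, 100.0)


def physician_aided_ai(scores: pd.DataFrame, ratings_one: pd.DataFrame) -> StrategyOutput:
    """AI scores first; images inside [3.5, 5.5) defer to the physician.

    Burden is the percentage of images the AI deferred, i.e. the share of
    scores inside the uncertainty band.
    """
    df = _align(ratings_one, scores)
    defer = ai_is_uncertain(df["rating_equiv"].to_numpy())
    final = np.where(defer, df["rating"], df["rating_equiv"])
    source = np.where(defer, "reader", "ai")
    burden = 100.0 * float(np.mean(defer))
    return _output("physician_aided_ai", df["image_id"], final, source, burden)


def average_blend(ratings_one: pd.DataFrame, scores: pd.DataFrame) -> StrategyOutput:
    """Plain average of the physician rating and the AI rating-equivalent."""
    df = _align(ratings_one, scores)
    final = (df["rating"].to_numpy() + df["rating_equiv"].to_numpy()) / 2.0
    return _output("average", df["image_id"], final, "blend", 100.0)


def weighted_blend(
    ratings_one: pd.DataFrame, scores: pd.DataFrame, params: WeightedAverageParams
) -> StrategyOutput:
    """Convex blend ``w * rating + (1 - w) * rating_equiv`` on the 1-8 scale."""
    df = _align(ratings_one, scores)
    w = params.w_physician
    final = w * df["rating"].to_numpy(dtype=float) + params.w_ai * df["rating_equiv"].to_numpy()
    return _output("weighted_average", df["image_id"], final, "blend", 100.0)


def select_weight(
    ratings: pd.DataFrame,
    scores: pd.DataFrame,
    loo_label_sets: dict[str, LabelSet],
    grid=None,
    test_reader: str | None = None,
    label_mode: str = "loo",
) -> WeightedAverageParams:
    """Pick the physician weight maximizing mean validation accuracy.

    For each candidate weight, every reader other than ``test_reader`` is
    scored with the weighted blend on their own reviewed subset against
    their own leave-one-out labels (or the all-reader labels when
    ``label_mode="all"``); the weight with the highest across-reader mean
    accuracy wins, ties breaking toward the smallest physician weight
    (i.e. more AI influence).
    """
    grid = default_weight_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("weight grid must be non-empty")
    if not np.all(np.diff(grid) > 0):
        grid = np.unique(grid)
    if label_mode not in ("loo", "all"):
        raise ConfigurationError("label_mode must be 'loo' or 'all'")

    scores = _scores_table(scores)
    validation_readers = sorted(set(ratings["reader_id"]) - {test_reader})
    if len(validation_readers) < 2:
        raise ConfigurationError(
            "select_weight needs at least 2 readers besides the test reader"
        )

    req = scores.set_index("image_id")["rating_equiv"]
    accs = np.zeros((len(validation_readers), grid.size))
    for i, reader in enumerate(validation_readers):
        own = ratings[ratings["reader_id"] == reader]
        label_set = loo_label_sets[reader] if label_mode == "loo" else loo_label_sets[None]
        r = own["rating"].to_numpy(dtype=float)
        q = own["image_id"].map(req).to_numpy(dtype=float)
        y = own["image_id"].map(label_set.labels).to_numpy(dtype=float)
        blended = r[:, None] * grid[None, :] + q[:, None] * (1.0 - grid[None, :])
        decisions = blended >= DECISION_THRESHOLD
        accs[i] = (decisions == (y[:, None] == 1)).mean(axis=0)
    mean_acc = accs.mean(axis=0)
    best = int(np.argmax(mean_acc))  # first max -> smallest weight on ties
    return WeightedAverageParams(w_physician=float(grid[best]), grid=tuple(grid))


def audit_strategy(
    ratings_one: pd.DataFrame,
    scores: pd.DataFrame,
    other_ratings: pd.DataFrame,
    seed: int = 0,
    test_reader: str | None = None,
) -> StrategyOutput:
    """AI as an auditing tool: disagreements go to a random second reader.

    Where the physician's binary read matches the AI's, the physician's
    rating stands.  Where they disagree, a second reader is drawn
    seeded-uniformly from the other reviewers of that image and that
    reader's rating is used unconditionally.  Burden is 100 plus the
    disagreement percentage.
    """
    df = _align(ratings_one, scores)
    if test_reader is None and len(ratings_one):
        test_reader = str(ratings_one["reader_id"].iloc[0]) if "reader_id" in ratings_one else ""
    disagree = (df["rating"].to_numpy() >= DECISION_THRESHOLD) != (
        df["rating_equiv"].to_numpy() >= DECISION_THRESHOLD
    )

    others = other_ratings
    if "reader_id" in ratings_one.columns:
        own_ids = set(ratings_one["reader_id"].unique())
        others = other_ratings[~other_ratings["reader_id"].isin(own_ids)]
    pool = {img: grp for img, grp in others.groupby("image_id")}

    disputed = df.loc[disagree, "image_id"]
    missing = [img for img in disputed if img not in pool or len(pool[img]) == 0]
    if missing:
        raise AdjudicationError(missing)

    rng = substream(seed, f"audit/{test_reader}")
    final = df["rating"].to_numpy(dtype=float)
    source = np.full(len(df), "reader", dtype=object)
    for pos in np.flatnonzero(disagree):
        grp = pool[df["image_id"].iloc[pos]]
        pick = int(rng.integers(0, len(grp)))
        final[pos] = float(grp["rating"].iloc[pick])
        source[pos] = "second_reader"
    burden = 100.0 + 100.0 * float(np.mean(disagree)) if len(df) else 100.0
    return _output("audit", df["image_id"], final, source, burden)


# ---------------------------------------------------------------------------
# orchestration helper


def run_all_strategies(
    ratings: pd.DataFrame,
    scores: pd.DataFrame,
    test_reader: str,
    loo_label_sets: dict[str, LabelSet] | None = None,
    weight_grid=None,
    seed: int = 0,
    which=STRATEGY_NAMES,
    label_mode: str = "loo",
) -> dict[str, StrategyOutput]:
    """Run the requested strategies around one test reader.

    ``ratings`` is the full long-format table; the test reader's own rows
    become the single-reader input, the rest feed weight selection and
    audit adjudication.  Returns a dict keyed by strategy name.
    """
    own = ratings[ratings["reader_id"] == test_reader]
    own_images = set(own["image_id"])
    scores_sub = _scores_table(scores)
    scores_sub = scores_sub[scores_sub["image_id"].isin(own_images)]

    out: dict[str, StrategyOutput] = {}
    for name in which:
        if name == "physician":
            out[name] = physician_alone(own)
        elif name == "ai":
            out[name] = ai_alone(scores_sub)
        elif name == "ai_aided_physician":
            out[name] = ai_aided_physician(own, scores_sub)
        elif name == "physician_aided_ai":
            out[name] = physician_aided_ai(scores_sub, own)
        elif name == "average":
            out[name] = average_blend(own, scores_sub)
        elif name == "weighted_average":
            if loo_label_sets is None:
                raise ConfigurationError("weighted_average requires loo_label_sets")
            params = select_weight(
                ratings, scores, loo_label_sets, weight_grid, test_reader, label_mode
            )
            out[name] = weighted_blend(own, scores_sub, params)
        elif name == "audit":
            out[name] = audit_strategy(own, scores_sub, ratings, seed, test_reader)
        else:
            raise ConfigurationError(f"unknown strategy {name!r}")
    return out
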