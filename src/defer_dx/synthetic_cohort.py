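"""Synthetic multi-reader chest X-ray cohorts with panel ratings and AI scores.

The generator emulates a reader study of ICU patients imaged repeatedly
during acute hypoxic respiratory failure: ~115 patients contributing ~400
chest X-rays (median 3 per patient), a ~26% patient-level ARDS prevalence
with a fraction of "late-onset" patients whose earliest films are still
negative, panels of 6-9 physician readers per image, and a convolutional
model emitting one probability per image.  Every marginal statistic a
downstream stage consumes — reader accuracy by difficulty, the ~5.6% rate
of equivocal reads, the ~20.8% AI uncertainty-band rate — is a configured,
recoverable target, so the full pipeline is testable without any image data.

Generative mechanism (latent-signal model)
------------------------------------------
Each image carries a difficulty ``d`` in [0, 1].  A reader or model with
accuracy curve ``acc(d) = base_accuracy - difficulty_slope * d`` (floored at
chance) reads an image of true label ``y`` by drawing a latent signal

    t = (2 y - 1) * Phi^{-1}(acc(d)) + z,   z ~ N(0, 1)

whose sign gives the binary call, so P(correct) = acc(d) exactly.  Reader
confidence is a second signal ``v = calibration * |t| + noise`` bucketed
into four confidence levels; the level-1 (equivocal) bucket boundary is set
at the empirical ``uncertain_rate_target`` quantile of v, so the realized
rate of 4/5 ratings matches its target by construction.  With
``calibration = 0`` the confidence signal is pure noise and stated
confidence carries no information about correctness.  The AI's signed
latent magnitude is pushed through a tempered logistic to give a
probability; its ``score_noise`` and ``calibration_temperature`` jointly
control how much probability mass lands in the uncertainty band.

Difficulties are drawn by stratified (shuffled quantile-grid) sampling by
default, so the realized difficulty distribution — and with it the AI
uncertainty-band rate and the difficult-image fraction — is stable across
cohorts of the study's modest size rather than fluctuating binomially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import nbinom, norm

from ._rng import substream
from .errors import ConfigurationError

__all__ = [
    "CohortConfig",
    "ReaderModel",
    "AIModel",
    "SyntheticCohort",
    "generate_cohort",
    "generate_ratings",
    "generate_ai_scores",
    "default_cohort_config",
    "default_reader_models",
    "default_ai_model",
]

# Fraction of non-equivocal confidence mass assigned to levels 2 and 2+3.
# Readers use high-confidence ratings often; the split below leaves half of
# all confident reads at the maximal level.
_LEVEL2_SHARE = 0.2
_LEVEL3_SHARE = 0.3


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class CohortConfig:
    """Patient/image-level structure of a synthetic cohort.

    Defaults reproduce the motivating study's marginals: 115 patients at
    26.1% prevalence (30/115), a zero-truncated negative binomial number of
    images per patient (median 3, IQR ~2-4.5), and 40% of positive patients
    (12/30) developing findings only after their earliest images.
    """

    n_patients: int = 115
    patient_prevalence: float = 30 / 115
    images_per_patient_dist: dict = field(
        default_factory=lambda: {"name": "zt_nbinom", "r": 3.0, "p": 0.5}
    )
    late_onset_fraction: float = 12 / 30
    difficulty_dist: dict = field(
        default_factory=lambda: {"name": "beta", "a": 0.5, "b": 1.6, "stratified": True}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in ("patient_prevalence", "late_onset_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        _validate_count_dist(self.images_per_patient_dist, "images_per_patient_dist")
        _validate_difficulty_dist(self.difficulty_dist, "difficulty_dist")


@dataclass(frozen=True)
class ReaderModel:
    """One physician reader's accuracy and confidence behaviour.

    ``base_accuracy`` is the probability of a correct binary call on a
    difficulty-0 image; accuracy declines by ``difficulty_slope`` per unit
    difficulty (floored at 0.5).  ``calibration`` >= 0 scales how strongly
    stated confidence tracks the correctness signal (0 = uninformative
    confidence).  ``uncertain_rate_target`` is the fraction of this
    reader's reads emitted as an equivocal 4/5 rating.
    """

    reader_id: str
    base_accuracy: float
    difficulty_slope: float = 0.0
    calibration: float = 1.0
    uncertain_rate_target: float = 0.056

    def __post_init__(self):
        if not 0.5 < self.base_accuracy <= 1.0:
            raise ConfigurationError("base_accuracy must lie in (0.5, 1]")
        if not 0.0 <= self.uncertain_rate_target < 1.0:
            raise ConfigurationError("uncertain_rate_target must lie in [0, 1)")
        if self.calibration < 0:
            raise ConfigurationError("calibration must be >= 0")


@dataclass(frozen=True)
class AIModel:
    """The AI scorer's accuracy curve and probability dispersion.

    ``score_noise`` is the standard deviation of the latent-magnitude
    noise; ``calibration_temperature`` divides the latent score before the
    logistic transform, so larger temperatures pull probabilities toward
    0.5 and widen the share of scores in the uncertainty band.
    """

    base_accuracy: float
    difficulty_slope: float = 0.0
    score_noise: float = 1.0
    calibration_temperature: float = 1.0

    def __post_init__(self):
        if not 0.5 < self.base_accuracy <= 1.0:
            raise ConfigurationError("base_accuracy must lie in (0.5, 1]")
        if self.calibration_temperature <= 0:
            raise ConfigurationError("calibration_temperature must be > 0")
        if self.score_noise < 0:
            raise ConfigurationError("score_noise must be >= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """Patients, images and provenance of one generated cohort."""

    patients: pd.DataFrame  # patient_id, status
    images: pd.DataFrame  # image_id, patient_id, true_label, difficulty
    config: CohortConfig


# ---------------------------------------------------------------------------
# distribution specs


def _validate_count_dist(spec, fieldname):
    if not isinstance(spec, dict) or "name" not in spec:
        raise ConfigurationError(f"{fieldname}: expected a dict with a 'name' key")
    name = spec["name"]
    if name == "zt_nbinom":
        r, p = spec.get("r"), spec.get("p")
        if r is None or p is None or r <= 0 or not 0 < p < 1:
            raise ConfigurationError(f"{fieldname}: zt_nbinom needs r > 0 and p in (0, 1)")
    elif name == "fixed":
        k = spec.get("k")
        if k is None or int(k) < 1:
            raise ConfigurationError(f"{fieldname}: fixed needs k >= 1")
    elif name == "uniform_int":
        lo, hi = spec.get("low"), spec.get("high")
        if lo is None or hi is None or lo < 1 or hi < lo:
            raise ConfigurationError(f"{fieldname}: uniform_int needs 1 <= low <= high")
    else:
        raise ConfigurationError(f"{fieldname}: unknown distribution {name!r}")


def _sample_counts(spec, n, rng):
    name = spec["name"]
    if name == "fixed":
        return np.full(n, int(spec["k"]))
    if name == "uniform_int":
        return rng.integers(int(spec["low"]), int(spec["high"]) + 1, size=n)
    # zero-truncated negative binomial via inverse CDF restricted to x >= 1
    r, p = float(spec["r"]), float(spec["p"])
    p0 = nbinom.pmf(0, r, p)
    u = rng.uniform(p0, 1.0, size=n)
    return np.maximum(nbinom.ppf(u, r, p).astype(int), 1)


def _validate_difficulty_dist(spec, fieldname):
    if not isinstance(spec, dict) or "name" not in spec:
        raise ConfigurationError(f"{fieldname}: expected a dict with a 'name' key")
    name = spec["name"]
    if name == "beta":
        a, b = spec.get("a"), spec.get("b")
        if a is None or b is None or a <= 0 or b <= 0:
            raise ConfigurationError(f"{fieldname}: beta needs a > 0 and b > 0")
    elif name == "uniform":
        pass
    elif name == "constant":
        v = spec.get("value")
        if v is None or not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{fieldname}: constant needs value in [0, 1]")
    else:
        raise ConfigurationError(f"{fieldname}: unknown distribution {name!r}")


def _sample_difficulty(spec, n, rng):
    name = spec["name"]
    if name == "constant":
        return np.full(n, float(spec["value"]))
    stratified = bool(spec.get("stratified", True))
    if stratified:
        u = rng.permutation((np.arange(n) + 0.5) / n)
    else:
        u = rng.uniform(size=n)
    if name == "uniform":
        return u
    return beta_dist.ppf(u, float(spec["a"]), float(spec["b"]))


# ---------------------------------------------------------------------------
# generators


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw patients, their images, true labels and difficulties.

    Positive patients flagged as late-onset (probability
    ``late_onset_fraction``) have their first ``ceil(k/2)`` of ``k`` images
    set to a negative true label, emulating patients whose earliest films
    predate radiographic findings.  All draws come from the ``cohort``
    substream of ``config.seed``.
    """
    rng = substream(config.seed, "cohort")
    n = config.n_patients
    status = rng.random(n) < config.patient_prevalence
    counts = _sample_counts(config.images_per_patient_dist, n, rng)
    late = status & (rng.random(n) < config.late_onset_fraction)

    total = int(counts.sum())
    difficulty = _sample_difficulty(config.difficulty_dist, total, rng)

    pat_ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    img_patient = np.repeat(np.arange(n), counts)
    # per-image index within its patient (0-based, in temporal order)
    within = np.concatenate([np.arange(k) for k in counts])
    n_neg_leading = np.where(late, np.ceil(counts / 2).astype(int), 0)
    true_label = np.where(
        status[img_patient], (within >= n_neg_leading[img_patient]).astype(int), 0
    )

    patients = pd.DataFrame({"patient_id": pat_ids, "status": status.astype(int)})
    images = pd.DataFrame(
        {
            "image_id": [f"X{i + 1:05d}" for i in range(total)],
            "patient_id": pat_ids[img_patient],
            "true_label": true_label,
            "difficulty": difficulty,
        }
    )
    return SyntheticCohort(patients=patients, images=images, config=config)


def _accuracy_curve(base, slope, difficulty):
    return np.clip(base - slope * difficulty, 0.5, 1.0)


def _confidence_levels(v, uncertain_rate):
    """Bucket a confidence signal into levels 1-4 by empirical quantiles.

    The level-1 boundary sits at the ``uncertain_rate`` quantile, making the
    realized equivocal-read rate match its target; the remaining mass is
    split 20/30/50 across levels 2/3/4.
    """
    u = float(uncertain_rate)
    qs = np.quantile(
        v, [u, u + _LEVEL2_SHARE * (1 - u), u + (_LEVEL2_SHARE + _LEVEL3_SHARE) * (1 - u)]
    )
    return 1 + (v >= qs[0]).astype(int) + (v >= qs[1]).astype(int) + (v >= qs[2]).astype(int)


def generate_ratings(
    cohort: SyntheticCohort,
    readers: Sequence[ReaderModel],
    panel_size_range: tuple[int, int] = (6, 9),
    seed: int = 0,
    assignment: str = "patient",
) -> pd.DataFrame:
    """Assign reader panels and draw one 1-8 rating per (reader, image).

    Panels are uniform random reader subsets of a size drawn uniformly from
    ``panel_size_range``; with ``assignment="patient"`` (the default) a
    reader assigned to a patient reads all of that patient's images, with
    ``"image"`` panels are drawn per image.  Returns a long-format table
    with columns ``reader_id, patient_id, image_id, rating``.
    """
    lo, hi = panel_size_range
    if lo < 2:
        raise ConfigurationError("panel_size_range: minimum panel size must be >= 2")
    if hi < lo:
        raise ConfigurationError("panel_size_range: max must be >= min")
    if hi > len(readers):
        raise ConfigurationError(
            f"panel_size_range: max panel size {hi} exceeds reader pool of {len(readers)}"
        )
    ids = [r.reader_id for r in readers]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("readers: reader_id values must be unique")
    if assignment not in ("patient", "image"):
        raise ConfigurationError("assignment must be 'patient' or 'image'")

    rng = substream(seed, "ratings/panels")
    images = cohort.images
    if assignment == "patient":
        units = cohort.patients["patient_id"].to_numpy()
        unit_of_image = images["patient_id"].to_numpy()
    else:
        units = images["image_id"].to_numpy()
        unit_of_image = units

    panel_of_unit: dict[str, np.ndarray] = {}
    for u in units:
        size = int(rng.integers(lo, hi + 1))
        panel_of_unit[u] = rng.choice(len(readers), size=size, replace=False)

    # membership matrix: reader k reads image i
    member = np.zeros((len(readers), len(images)), dtype=bool)
    for i, u in enumerate(unit_of_image):
        member[panel_of_unit[u], i] = True

    d = images["difficulty"].to_numpy()
    y = images["true_label"].to_numpy()
    frames = []
    for k, reader in enumerate(readers):
        sel = np.flatnonzero(member[k])
        if sel.size == 0:
            continue
        r_rng = substream(seed, f"ratings/reader/{reader.reader_id}")
        acc = _accuracy_curve(reader.base_accuracy, reader.difficulty_slope, d[sel])
        # acc == 1 is kept finite (z-score ~7) so the confidence signal and
        # its quantile thresholds stay well defined; in practice the binary
        # read still always matches the true label
        mu = norm.ppf(np.minimum(acc, 1.0 - 1e-12))
        t = np.where(y[sel] == 1, mu, -mu) + r_rng.standard_normal(sel.size)
        positive = t > 0
        v = reader.calibration * np.abs(t) + r_rng.standard_normal(sel.size)
        level = _confidence_levels(v, reader.uncertain_rate_target)
        rating = np.where(positive, 4 + level, 5 - level)
        frames.append(
            pd.DataFrame(
                {
                    "reader_id": reader.reader_id,
                    "patient_id": images["patient_id"].to_numpy()[sel],
                    "image_id": images["image_id"].to_numpy()[sel],
                    "rating": rating.astype(int),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["image_id", "reader_id"], kind="stable").reset_index(drop=True)


def generate_ai_scores(cohort: SyntheticCohort, ai: AIModel, seed: int = 0) -> pd.DataFrame:
    """Draw one AI probability per image from a shared latent score.

    The latent ``t = (2y - 1) * Phi^{-1}(acc(d)) + score_noise * z`` drives
    both the probability (``expit(t / calibration_temperature)``) and,
    through its sign, the implied binary call — so probabilities near 0.5
    are genuinely near-chance, and the model's confidence is intrinsically
    calibrated.  With ``score_noise = 1`` the accuracy at threshold 0.5 is
    exactly ``acc(d)``; smaller noise sharpens it, and ``score_noise = 0``
    with ``base_accuracy = 1`` degenerates to probabilities in {0, 1}.
    Returns columns ``image_id, probability, rating_equiv``.
    """
    rng = substream(seed, "scores")
    d = cohort.images["difficulty"].to_numpy()
    y = cohort.images["true_label"].to_numpy()
    acc = _accuracy_curve(ai.base_accuracy, ai.difficulty_slope, d)
    mu = norm.ppf(acc)  # +inf when acc == 1
    t = np.where(y == 1, mu, -mu) + ai.score_noise * rng.standard_normal(d.size)
    p = expit(t / ai.calibration_temperature)
    return pd.DataFrame(
        {
            "image_id": cohort.images["image_id"],
            "probability": p,
            "rating_equiv": 1.0 + 7.0 * p,
        }
    )


# ---------------------------------------------------------------------------
# study-calibrated defaults


def default_cohort_config(seed: int = 0, n_patients: int = 115) -> CohortConfig:
    """Cohort configuration emulating the motivating reader study."""
    return CohortConfig(n_patients=n_patients, seed=seed)


def default_reader_models(n_readers: int = 9) -> list[ReaderModel]:
    """A nine-physician panel with mildly heterogeneous skill.

    Base accuracies are spread over ~0.915-0.975 with a common difficulty
    slope; together with the default difficulty distribution this lands the
    panel near the emulated study's observed marginals (mean accuracy
    ~0.81 against leave-one-out consensus labels, 5.6% equivocal reads,
    ~0.70 accuracy on images inside the AI's uncertainty band).
    Calibration varies across readers: most track their own correctness
    only moderately, mirroring the finding that physician confidence is
    imperfectly calibrated.
    """
    base = np.linspace(0.915, 0.975, n_readers)
    calib = np.tile([0.5, 0.9, 1.3], math.ceil(n_readers / 3))[:n_readers]
    return [
        ReaderModel(
            reader_id=f"R{k + 1}",
            base_accuracy=float(base[k]),
            difficulty_slope=0.50,
            calibration=float(calib[k]),
            uncertain_rate_target=0.056,
        )
        for k in range(n_readers)
    ]


def default_ai_model() -> AIModel:
    """AI scorer calibrated to the emulated study's observed margins.

    Targets: ~0.85 accuracy against leave-one-out consensus labels (~0.68
    on difficult images, ~0.60 inside its own uncertainty band) and ~20.8%
    of probabilities inside the [3.5, 5.5) rating-equivalent band.
    """
    return AIModel(
        base_accuracy=0.999,
        difficulty_slope=0.90,
        score_noise=0.65,
        calibration_temperature=0.74,
    )


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
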