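"""Metrics, the per-reader evaluation protocol, and the patient cluster bootstrap.

The evaluation convention throughout: each reader (and each strategy built
around that reader, and the AI baseline) is scored only on the subset of
images that reader reviewed, against reference labels rebuilt without that
reader's reads.  Cohort-level summaries are the across-reader mean of
those per-reader metrics — never the metric of pooled reads.

Uncertainty is quantified with a patient-level cluster bootstrap: each of
B replicates resamples patients with replacement (a patient drawn k times
contributes its images k times), recomputes every per-reader metric inside
the replicate, averages across readers, and the 95% CI is the 2.5th/97.5th
percentile of the B averaged values (linear-interpolation percentiles).
Metrics with an empty denominator are undefined (NaN), and replicates where
that happens are dropped for that metric with an explicit count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import AlignmentError
from .reference_labels import DifficultyFlags, LabelSet
from .scale_mapping import (
    ai_is_uncertain,
    confidence_level,
    prob_to_rating,
    reader_is_uncertain,
)
from .strategies import STRATEGY_NAMES, run_all_strategies

__all__ = [
    "MetricSet",
    "BootstrapSummary",
    "METRIC_NAMES",
    "binary_metrics",
    "per_reader_evaluation",
    "make_replicate_closure",
    "cluster_bootstrap",
    "one_sided_bootstrap_test",
    "stratified_report",
]

METRIC_NAMES = ("accuracy", "f1", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class MetricSet:
    """Confusion-matrix metrics; NaN marks an undefined (0/0) metric."""

    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    review_burden: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        if self.review_burden is not None:
            d["review_burden"] = self.review_burden
        return d


@dataclass(frozen=True)
class BootstrapSummary:
    """Point estimate and percentile CI for one metric of one strategy."""

    metric: str
    strategy: str | None
    point_estimate: float
    replicate_mean: float
    ci_low: float
    ci_high: float
    n_replicates_used: int
    n_replicates_undefined: int
    seed: int


def _safe_div(num, den):
    return num / den if den > 0 else float("nan")


def binary_metrics(decisions, labels, review_burden: float | None = None) -> MetricSet:
    """Standard confusion-matrix metrics from aligned binary arrays.

    ``decisions`` and ``labels`` must have equal length >= 1; zero
    denominators yield NaN, never 0.
    """
    d = np.asarray(decisions).astype(bool)
    y = np.asarray(labels).astype(bool)
    if d.shape != y.shape or d.size == 0:
        raise AlignmentError("decisions and labels must be aligned and non-empty")
    tp = int(np.sum(d & y))
    fp = int(np.sum(d & ~y))
    fn = int(np.sum(~d & y))
    tn = int(np.sum(~d & ~y))
    return MetricSet(
        accuracy=_safe_div(tp + tn, tp + fp + fn + tn),
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        review_burden=review_burden,
    )


# ---------------------------------------------------------------------------
# per-reader protocol


def per_reader_evaluation(
    ratings: pd.DataFrame,
    scores: pd.DataFrame,
    loo_label_sets: dict[str, LabelSet],
    strategies=STRATEGY_NAMES,
    weight_grid=None,
    seed: int = 0,
    label_mode: str = "loo",
) -> dict[tuple[str, str], MetricSet]:
    """Score every (reader, strategy) pair on the reader's reviewed subset.

    Returns a dict keyed by (reader_id, strategy_name).  Readers with an
    empty reviewed subset are skipped.
    """
    out: dict[tuple[str, str], MetricSet] = {}
    for reader in sorted(loo_label_sets):
        own = ratings[ratings["reader_id"] == reader]
        if own.empty:
            continue
        outputs = run_all_strategies(
            ratings, scores, reader, loo_label_sets, weight_grid, seed, strategies, label_mode
        )
        labels = loo_label_sets[reader].labels
        for name, so in outputs.items():
            y = so.decisions["image_id"].map(labels).to_numpy()
            out[(reader, name)] = binary_metrics(
                so.decisions["decision"].to_numpy(), y, so.review_burden
            )
    return out


# ---------------------------------------------------------------------------
# cluster bootstrap


def make_replicate_closure(
    images: pd.DataFrame,
    ratings: pd.DataFrame,
    scores: pd.DataFrame,
    loo_label_sets: dict[str, LabelSet],
    strategies=STRATEGY_NAMES,
    weight_grid=None,
    seed: int = 0,
    label_mode: str = "loo",
) -> Callable[[np.ndarray], dict[str, float]]:
    """Build a closure evaluating across-reader mean metrics on an image resample.

    Strategy decisions and LOO labels are computed once on the full data;
    a replicate (an integer index array into ``images``, with multiplicity)
    then only re-tallies confusion counts.  The closure returns a flat dict
    keyed ``"strategy/metric"``; a reader whose resampled subset is empty
    (or has an undefined metric) renders the across-reader mean undefined
    for that metric.
    """
    image_ids = images["image_id"].to_numpy()
    pos_of_image = {img: i for i, img in enumerate(image_ids)}
    n_images = len(image_ids)

    per_reader = {}
    for reader in sorted(loo_label_sets):
        own = ratings[ratings["reader_id"] == reader]
        if own.empty:
            continue
        outputs = run_all_strategies(
            ratings, scores, reader, loo_label_sets, weight_grid, seed, strategies, label_mode
        )
        labels = loo_label_sets[reader].labels
        entry = {}
        for name, so in outputs.items():
            dec_full = np.full(n_images, np.nan)
            lab_full = np.full(n_images, np.nan)
            bur_full = np.full(n_images, np.nan)
            idx = [pos_of_image[i] for i in so.decisions["image_id"]]
            dec_full[idx] = so.decisions["decision"].to_numpy(dtype=float)
            lab_full[idx] = so.decisions["image_id"].map(labels).to_numpy(dtype=float)
            # per-image physician reads, so replicate burdens re-aggregate
            # under resampling: 1 read wherever a reader was the source or
            # had to look anyway, plus the second read under audit
            source = so.decisions["source"].to_numpy()
            if name == "ai":
                reads = np.zeros(len(source))
            elif name == "physician_aided_ai":
                reads = (source == "reader").astype(float)
            elif name == "audit":
                reads = 1.0 + (source == "second_reader")
            else:
                reads = np.ones(len(source))
            bur_full[idx] = reads
            entry[name] = (dec_full, lab_full, bur_full)
        per_reader[reader] = entry

    names = list(strategies)

    def closure(idx: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        for name in names:
            sums = {m: [] for m in METRIC_NAMES}
            burdens = []
            for reader, entry in per_reader.items():
                dec_full, lab_full, bur_full = entry[name]
                d = dec_full[idx]
                mask = ~np.isnan(d)
                if not mask.any():
                    for m in METRIC_NAMES:
                        sums[m].append(np.nan)
                    continue
                d = d[mask].astype(bool)
                y = lab_full[idx][mask].astype(bool)
                burden = 100.0 * float(np.mean(bur_full[idx][mask]))
                tp = np.sum(d & y)
                fp = np.sum(d & ~y)
                fn = np.sum(~d & y)
                tn = np.sum(~d & ~y)
                sums["accuracy"].append(_safe_div(tp + tn, tp + fp + fn + tn))
                sums["f1"].append(_safe_div(2 * tp, 2 * tp + fp + fn))
                sums["sensitivity"].append(_safe_div(tp, tp + fn))
                sums["specificity"].append(_safe_div(tn, tn + fp))
                sums["ppv"].append(_safe_div(tp, tp + fp))
                sums["npv"].append(_safe_div(tn, tn + fn))
                burdens.append(burden)
            for m in METRIC_NAMES:
                out[f"{name}/{m}"] = float(np.mean(sums[m]))
            out[f"{name}/review_burden"] = float(np.mean(burdens)) if burdens else np.nan
        return out

    return closure


def _patient_groups(image_patients) -> list[np.ndarray]:
    arr = np.asarray(image_patients)
    uniq, inv = np.unique(arr, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    bounds = np.searchsorted(inv[order], np.arange(len(uniq) + 1))
    return [order[bounds[k] : bounds[k + 1]] for k in range(len(uniq))]


def cluster_bootstrap(
    closure: Callable[[np.ndarray], dict[str, float]],
    image_patients,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapSummary]:
    """Patient-level cluster bootstrap of any per-image-indexed statistic.

    ``closure`` maps an integer image-index array (with multiplicity) to a
    dict of metric values; ``image_patients`` gives each image's patient
    id, aligned with the closure's index space.  The reported point
    estimate is the observed (non-bootstrap) value on the full data; the
    CI is the 2.5/97.5 percentile of the B replicate values, computed over
    defined replicates only.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    groups = _patient_groups(image_patients)
    n_pat = len(groups)
    rng = substream(seed, "bootstrap")

    point = closure(np.arange(len(np.asarray(image_patients))))
    reps = {k: np.empty(B) for k in point}
    for b in range(B):
        draw = rng.integers(0, n_pat, size=n_pat)
        idx = np.concatenate([groups[j] for j in draw])
        res = closure(idx)
        for k in point:
            reps[k][b] = res[k]

    out = {}
    for k, vals in reps.items():
        defined = vals[~np.isnan(vals)]
        n_undef = int(B - defined.size)
        if defined.size:
            lo, hi = np.percentile(defined, [2.5, 97.5], method="linear")
        else:
            lo = hi = float("nan")
        strategy, _, metric = k.rpartition("/")
        out[k] = BootstrapSummary(
            metric=metric or k,
            strategy=strategy or None,
            point_estimate=point[k],
            replicate_mean=float(defined.mean()) if defined.size else float("nan"),
            ci_low=float(lo),
            ci_high=float(hi),
            n_replicates_used=int(defined.size),
            n_replicates_undefined=n_undef,
            seed=seed,
        )
    return out


def one_sided_bootstrap_test(
    closure_a: Callable[[np.ndarray], float],
    closure_b: Callable[[np.ndarray], float],
    image_patients,
    B: int = 1000,
    seed: int = 0,
    paired: bool = True,
) -> dict[str, float]:
    """One-sided bootstrapped two-sample test of H1: A's metric > B's.

    Paired construction (default): both closures are evaluated on the same
    patient resample; p is the proportion of replicates where A <= B (ties
    count against A, a conservative choice).  ``paired=False`` resamples
    the two groups independently.  Replicates where either value is
    undefined are dropped and counted.
    """
    groups = _patient_groups(image_patients)
    n_pat = len(groups)
    rng_a = substream(seed, "test/a")
    rng_b = rng_a if paired else substream(seed, "test/b")

    a_vals = np.empty(B)
    b_vals = np.empty(B)
    for b in range(B):
        draw_a = rng_a.integers(0, n_pat, size=n_pat)
        idx_a = np.concatenate([groups[j] for j in draw_a])
        if paired:
            idx_b = idx_a
        else:
            draw_b = rng_b.integers(0, n_pat, size=n_pat)
            idx_b = np.concatenate([groups[j] for j in draw_b])
        a_vals[b] = closure_a(idx_a)
        b_vals[b] = closure_b(idx_b)

    ok = ~(np.isnan(a_vals) | np.isnan(b_vals))
    n_used = int(ok.sum())
    p = float(np.mean(a_vals[ok] <= b_vals[ok])) if n_used else float("nan")
    return {"p_value": p, "n_replicates_used": n_used, "n_replicates_dropped": B - n_used}


# ---------------------------------------------------------------------------
# stratified (difficulty / uncertainty / confidence) analyses


def _acc(mask_correct):
    return float(np.mean(mask_correct)) if len(mask_correct) else float("nan")


def stratified_report(
    ratings: pd.DataFrame,
    scores: pd.DataFrame,
    label_sets: dict[str, LabelSet],
    difficulty: dict[str, DifficultyFlags],
) -> pd.DataFrame:
    """Reader-vs-AI accuracy within difficulty, uncertainty and confidence strata.

    For each reader the strata are evaluated on that reader's reviewed
    subset against that reader's labels (sharing the exclusion used for
    ``difficulty``).  Returns a tidy frame with columns
    ``reader, stratum_type, stratum, evaluator, n, accuracy``; empty strata
    appear with n = 0 and NaN accuracy.
    """
    scores = scores.copy()
    if "rating_equiv" not in scores.columns:
        scores["rating_equiv"] = prob_to_rating(scores["probability"].to_numpy())
    score_req = scores.set_index("image_id")["rating_equiv"]
    score_p = scores.set_index("image_id")["probability"]

    rows = []
    for reader in sorted(label_sets):
        own = ratings[ratings["reader_id"] == reader].sort_values("image_id")
        if own.empty:
            continue
        labels = label_sets[reader].labels
        y = own["image_id"].map(labels).to_numpy() == 1
        r = own["rating"].to_numpy()
        req = own["image_id"].map(score_req).to_numpy()
        p = own["image_id"].map(score_p).to_numpy()
        reader_dec = r >= 4.5
        ai_dec = req >= 4.5
        reader_ok = reader_dec == y
        ai_ok = ai_dec == y

        diff = own["image_id"].map(difficulty[reader].flags).to_numpy().astype(bool)
        r_unc = reader_is_uncertain(r)
        a_unc = ai_is_uncertain(req)
        level = confidence_level(r)
        ai_level = np.minimum((np.abs(p - 0.5) // 0.125).astype(int) + 1, 4)

        strata = [
            ("difficulty", "difficult", diff),
            ("difficulty", "non_difficult", ~diff),
            ("reader_uncertain", "uncertain", r_unc),
            ("reader_uncertain", "certain", ~r_unc),
            ("ai_uncertain", "uncertain", a_unc),
            ("ai_uncertain", "certain", ~a_unc),
        ]
        for lv in (1, 2, 3, 4):
            strata.append(("reader_confidence", str(lv), level == lv))
        for lv in (1, 2, 3, 4):
            strata.append(("ai_confidence", str(lv), ai_level == lv))

        for stype, sname, mask in strata:
            for evaluator, ok in (("physician", reader_ok), ("ai", ai_ok)):
                if stype == "ai_confidence" and evaluator == "physician":
                    continue
                rows.append(
                    {
                        "reader": reader,
                        "stratum_type": stype,
                        "stratum": sname,
                        "evaluator": evaluator,
                        "n": int(mask.sum()),
                        "accuracy": _acc(ok[mask]),
                    }
                )
    return pd.DataFrame(rows)
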