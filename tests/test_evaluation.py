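"""Tests of metrics, the per-reader protocol, and the cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from defer_dx.errors import AlignmentError
from defer_dx.evaluation import (
    METRIC_NAMES,
    binary_metrics,
    cluster_bootstrap,
    make_replicate_closure,
    one_sided_bootstrap_test,
    per_reader_evaluation,
    stratified_report,
)
from defer_dx.reference_labels import difficulty_flags, loo_label_sets
from defer_dx.synthetic_cohort import (
    AIModel,
    CohortConfig,
    default_reader_models,
    generate_ai_scores,
    generate_cohort,
    generate_ratings,
)

from _oracles import confusion_oracle


def test_binary_metrics_hand_computed_table():
    # TP=3, FP=1, FN=2, TN=4
    decisions = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    labels = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
    m = binary_metrics(decisions, labels)
    assert m.accuracy == pytest.approx(0.7)
    assert m.sensitivity == pytest.approx(0.6)
    assert m.specificity == pytest.approx(0.8)
    assert m.ppv == pytest.approx(0.75)
    assert m.npv == pytest.approx(2 / 3)
    assert m.f1 == pytest.approx(2 / 3)


def test_binary_metrics_all_correct_and_undefined():
    m = binary_metrics([1, 0, 1], [1, 0, 1])
    assert m.accuracy == 1.0 and m.f1 == 1.0
    m = binary_metrics([0, 0], [0, 0])  # no positive labels, no positive calls
    assert np.isnan(m.sensitivity)
    assert np.isnan(m.ppv)
    assert m.specificity == 1.0
    with pytest.raises(AlignmentError):
        binary_metrics([], [])


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
def test_metric_identities_against_brute_force_tally(pairs):
    decisions = [d for d, _ in pairs]
    labels = [y for _, y in pairs]
    tp, fp, fn, tn = confusion_oracle(decisions, labels)
    m = binary_metrics(decisions, labels)
    n = len(pairs)
    assert m.accuracy == pytest.approx((tp + tn) / n)
    if tp + fn:
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
    if not np.isnan(m.ppv) and not np.isnan(m.sensitivity) and (m.ppv + m.sensitivity):
        assert m.f1 == pytest.approx(
            2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity)
        )


def test_per_reader_evaluation_identity_cases(small_study):
    ratings, scores = small_study["ratings"], small_study["scores"]
    loo = loo_label_sets(ratings)
    out = per_reader_evaluation(
        ratings, scores, loo, strategies=("physician", "ai", "ai_aided_physician")
    )
    readers = sorted(loo)
    # AI baseline is deterministic: same labels -> identical MetricSet
    out2 = per_reader_evaluation(ratings, scores, loo, strategies=("ai",))
    for r in readers:
        assert out[(r, "ai")].accuracy == out2[(r, "ai")].accuracy
    # a reader with no equivocal reads collapses ai_aided to physician
    for r in readers:
        own = ratings[ratings["reader_id"] == r]
        if not own["rating"].isin([4, 5]).any():
            assert out[(r, "ai_aided_physician")].accuracy == out[(r, "physician")].accuracy


# ---------------------------------------------------------------------------
# cluster bootstrap


def test_cluster_bootstrap_degenerate_all_correct():
    patients = np.repeat([f"P{i}" for i in range(10)], 3)
    correct = np.ones(30)
    summaries = cluster_bootstrap(
        lambda idx: {"accuracy": float(correct[idx].mean())}, patients, B=200, seed=0
    )
    s = summaries["accuracy"]
    assert (s.ci_low, s.ci_high) == (1.0, 1.0)
    assert s.point_estimate == 1.0
    assert s.n_replicates_used == 200 and s.n_replicates_undefined == 0


def test_cluster_bootstrap_seeded_determinism():
    rng = np.random.default_rng(1)
    patients = np.repeat([f"P{i}" for i in range(20)], 2)
    x = rng.random(40)
    closure = lambda idx: {"m": float(x[idx].mean())}
    a = cluster_bootstrap(closure, patients, B=300, seed=9)["m"]
    b = cluster_bootstrap(closure, patients, B=300, seed=9)["m"]
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    assert a.ci_low <= a.point_estimate <= a.ci_high


def test_cluster_bootstrap_counts_undefined_replicates():
    # sensitivity is undefined whenever the single positive patient is not drawn
    patients = np.array([f"P{i}" for i in range(12)])
    labels = np.zeros(12, dtype=bool)
    labels[0] = True
    decisions = labels.copy()

    def closure(idx):
        y = labels[idx]
        d = decisions[idx]
        tp = np.sum(d & y)
        fn = np.sum(~d & y)
        return {"sensitivity": tp / (tp + fn) if tp + fn else float("nan")}

    s = cluster_bootstrap(closure, patients, B=400, seed=2)["sensitivity"]
    assert s.n_replicates_undefined > 0
    assert s.n_replicates_used + s.n_replicates_undefined == 400


def test_cluster_ci_wider_than_naive_under_within_patient_correlation():
    # correctness is a patient-level coin: images within a patient all agree
    rng = np.random.default_rng(4)
    n_pat, per = 40, 8
    patient_ok = rng.random(n_pat) < 0.7
    correct = np.repeat(patient_ok, per).astype(float)
    patients = np.repeat([f"P{i}" for i in range(n_pat)], per)
    closure = lambda idx: {"acc": float(correct[idx].mean())}
    clustered = cluster_bootstrap(closure, patients, B=500, seed=3)["acc"]
    naive = cluster_bootstrap(closure, np.arange(len(correct)), B=500, seed=3)["acc"]
    assert (clustered.ci_high - clustered.ci_low) > (naive.ci_high - naive.ci_low)


def test_replicate_statistic_is_mean_of_per_reader_metrics_not_pooled():
    # reader A: 1 image, correct; reader B: 3 images, 1 correct.
    # across-reader mean accuracy = (1 + 1/3)/2 = 2/3; pooled accuracy = 2/4.
    images = pd.DataFrame(
        {
            "image_id": ["X0", "X1", "X2", "X3"],
            "patient_id": ["P0", "P1", "P2", "P3"],
            "true_label": [1, 1, 0, 0],
            "difficulty": 0.1,
        }
    )
    rows = [("A", "P0", "X0", 7)] + [
        ("B", p, x, r)
        for p, x, r in [("P1", "X1", 2), ("P2", "X2", 7), ("P3", "X3", 2)]
    ]
    ratings = pd.DataFrame(rows, columns=["reader_id", "patient_id", "image_id", "rating"])
    from defer_dx.reference_labels import LabelSet

    lab = pd.DataFrame(
        {"label": [1, 1, 0, 0], "panel_size": 2, "n_agree": 2, "mean_rating": 4.0},
        index=pd.Index(["X0", "X1", "X2", "X3"], name="image_id"),
    )
    loo = {"A": LabelSet(lab, "A"), "B": LabelSet(lab, "B")}
    closure = make_replicate_closure(
        images, ratings, pd.DataFrame({"image_id": images["image_id"], "probability": 0.9}),
        loo, strategies=("physician",),
    )
    out = closure(np.arange(4))
    assert out["physician/accuracy"] == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# one-sided bootstrap test


def test_one_sided_test_null_case_unpaired():
    rng = np.random.default_rng(7)
    patients = np.repeat([f"P{i}" for i in range(60)], 2)
    a = rng.random(120)
    b = rng.random(120)
    res = one_sided_bootstrap_test(
        lambda idx: float(a[idx].mean()),
        lambda idx: float(b[idx].mean()),
        patients,
        B=400,
        seed=5,
        paired=False,
    )
    assert 0.3 < res["p_value"] < 0.7
    assert res["n_replicates_used"] == 400


def test_one_sided_test_perfect_separation():
    patients = np.repeat([f"P{i}" for i in range(30)], 2)
    good = np.ones(60)
    bad = np.zeros(60)
    res = one_sided_bootstrap_test(
        lambda idx: float(good[idx].mean()),
        lambda idx: float(bad[idx].mean()),
        patients,
        B=200,
        seed=6,
    )
    assert res["p_value"] == 0.0


def test_one_sided_test_better_strategy_on_study_cohort(study_cohort, study_loo):
    """AI-alone beats physician-alone on the calibrated cohort (p < 0.05)."""
    tables = study_cohort
    closure = make_replicate_closure(
        tables["cohort"].images, tables["ratings"], tables["scores"], study_loo,
        strategies=("physician", "ai"),
    )
    res = one_sided_bootstrap_test(
        lambda idx: closure(idx)["ai/accuracy"],
        lambda idx: closure(idx)["physician/accuracy"],
        tables["cohort"].images["patient_id"].to_numpy(),
        B=300,
        seed=8,
    )
    assert res["p_value"] < 0.05


# ---------------------------------------------------------------------------
# stratified report


def test_stratified_report_partitions_and_matches_unstratified(small_study):
    ratings, scores = small_study["ratings"], small_study["scores"]
    loo = loo_label_sets(ratings)
    diffs = {r: difficulty_flags(ratings, ls) for r, ls in loo.items()}
    report = stratified_report(ratings, scores, loo, diffs)
    reader = sorted(loo)[0]
    own = ratings[ratings["reader_id"] == reader]
    sub = report[(report.reader == reader) & (report.stratum_type == "difficulty")
                 & (report.evaluator == "physician")]
    assert sub["n"].sum() == len(own)
    # pooled accuracy over the two difficulty strata equals the plain accuracy
    labels = loo[reader].labels
    correct = ((own["rating"] >= 4.5).to_numpy()
               == (own["image_id"].map(labels).to_numpy() == 1))
    pooled = (sub["n"] * sub["accuracy"]).sum() / sub["n"].sum()
    assert pooled == pytest.approx(correct.mean())


def test_stratified_report_flat_ai_when_no_difficulty_effect():
    config = CohortConfig(n_patients=800, seed=17)
    cohort = generate_cohort(config)
    readers = default_reader_models(6)
    ratings = generate_ratings(cohort, readers, (4, 6), seed=17)
    flat_ai = AIModel(base_accuracy=0.85, difficulty_slope=0.0, score_noise=1.0,
                      calibration_temperature=1.0)
    scores = generate_ai_scores(cohort, flat_ai, seed=17)
    loo = loo_label_sets(ratings)
    # against the true labels a difficulty-flat AI is equally accurate on
    # reader-difficult and easy images (consensus labels would differ:
    # label noise concentrates on difficult panels)
    flags = difficulty_flags(ratings, loo[sorted(loo)[0]]).flags
    truth = cohort.images.set_index("image_id")["true_label"]
    correct = pd.Series(
        (scores["probability"].to_numpy() >= 0.5).astype(int)
        == scores["image_id"].map(truth).to_numpy(),
        index=pd.Index(scores["image_id"], name="image_id"),
    )
    hard = correct[flags.reindex(correct.index)].mean()
    easy = correct[~flags.reindex(correct.index)].mean()
    assert abs(hard - easy) < 0.05


def test_stratified_report_empty_stratum_is_reported_not_error():
    ratings = pd.DataFrame(
        {
            "reader_id": ["A", "A", "B", "B", "C", "C"],
            "patient_id": "P1",
            "image_id": ["X0", "X1", "X0", "X1", "X0", "X1"],
            "rating": [7, 7, 7, 7, 6, 6],  # never uncertain
        }
    )
    scores = pd.DataFrame({"image_id": ["X0", "X1"], "probability": [0.9, 0.8]})
    loo = loo_label_sets(ratings)
    diffs = {r: difficulty_flags(ratings, ls) for r, ls in loo.items()}
    report = stratified_report(ratings, scores, loo, diffs)
    unc = report[(report.stratum_type == "reader_uncertain") & (report.stratum == "uncertain")]
    assert (unc["n"] == 0).all()
    assert unc["accuracy"].isna().all()
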