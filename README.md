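# defer-dx

Evaluation of human–AI collaboration strategies for binary imaging
diagnoses, built around the motivating case of detecting acute respiratory
distress syndrome (ARDS) findings on chest X-rays.

In a multi-reader study, each image is reviewed by a panel of physicians
who grade it on an ordinal 1–8 scale (1 = confident negative, 8 = confident
positive, 4/5 = equivocal), while an AI model emits a probability
`p ∈ [0, 1]` that is placed on the same scale by the linear map
`y_AI = 1 + 7p`. Both readings carry a diagnosis *and* a confidence, which
makes uncertainty-based **deferral** possible: route each case to whichever
agent is confident about it. `defer-dx` implements the full analysis
pipeline for such studies — reference-standard construction, the deferral
strategies, and clustered uncertainty quantification — plus a calibrated
synthetic reader-study generator so the whole pipeline runs and is tested
end to end without any image data.

This is intended for biostatisticians and ML researchers designing or
re-analyzing multi-reader multi-case studies of AI deployment policies.

## What it computes

**Reference standard.** Each image's binary consensus label is the
majority vote of its panel's binarized reads (rating ≥ 4.5 is a positive
read); exact ties fall back to the mean raw rating, positive iff ≥ 4.5.
When a reader is evaluated, the labels are rebuilt *without that reader's
own reads* (leave-one-reader-out, LOO), so no reader influences their own
ground truth. An image is *difficult* when ≥ 2 retained panel reads
disagree with the consensus.

**Strategies.** For each test reader, seven per-image decision policies:

| strategy | rule | review burden |
|---|---|---|
| physician | reader's rating decides | 100% |
| ai | AI rating-equivalent decides | 0% |
| ai_aided_physician | reader first; rating ∈ {4, 5} defers to AI | 100% |
| physician_aided_ai | AI first; score ∈ [3.5, 5.5) defers to reader | ≈ band rate |
| average | (y_physician + y_AI) / 2 | 100% |
| weighted_average | w·y_physician + (1 − w)·y_AI | 100% |
| audit | reader decides; AI disagreement triggers a random second reader | 100% + disagree% |

The weight `w` is selected per test reader from the grid
{0, 0.05, …, 1} by maximizing the mean validation accuracy of the other
readers against their own LOO labels. All continuous scores binarize at
the inclusive 4.5 threshold; the AI uncertainty band [3.5, 5.5) maps back
to probabilities [0.357, 0.643).

**Evaluation.** Accuracy, F1, sensitivity, specificity, PPV and NPV are
computed per reader on that reader's reviewed subset against their LOO
labels, then averaged across readers. 95% CIs come from a patient-level
cluster bootstrap (default B = 1000): patients are resampled with
replacement so correlated images enter or leave together, per-reader
metrics are recomputed inside each replicate, averaged across readers, and
the CI is the 2.5th/97.5th percentile of the B averages. A paired
one-sided bootstrap test compares two strategies' metrics across
replicates. Stratified reports break reader-vs-AI accuracy down by
difficulty, by each side's uncertainty flags, and by confidence level.

## Worked example

Run the full pipeline on the default synthetic cohort (115 patients,
~400 images, 9 readers, panels of 6–9, B = 1000):

```python
from defer_dx.io_cli import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(seed=1, out_dir="demo_out"))
print(bundle["report"])
```

which prints (abridged):

| Metric | physician | ai | physician_aided_ai | weighted_average |
|---|---|---|---|---|
| accuracy | 0.806 (0.783, 0.829) | 0.857 (0.823, 0.89) | 0.865 (0.839, 0.891) | 0.877 (0.851, 0.904) |
| sensitivity | 0.722 (0.649, 0.778) | 0.731 (0.619, 0.826) | 0.742 (0.649, 0.818) | 0.753 (0.651, 0.833) |
| specificity | 0.834 (0.814, 0.851) | 0.898 (0.86, 0.931) | 0.905 (0.88, 0.926) | 0.916 (0.89, 0.939) |
| review_burden | 100 (100, 100) | 0 (0, 0) | 21.9 (17.7, 26.4) | 100 (100, 100) |

Reading it: the AI alone is more accurate than the average physician
(0.857 vs 0.806), but deferral does better than either — letting the AI
score first and handing only its uncertain band to a physician reaches
0.865 accuracy while requiring physicians to review only ~22% of images.
The weighted blend is marginally more accurate still, but needs a
physician read of every image. `demo_out/` also receives the per-reader
results, per-image decisions with their decision source, labels,
difficulty flags, strata, a JSON manifest and this Markdown report.

The same pipeline is scriptable from the shell:

```bash
defer-dx simulate --seed 1 --out-dir data/
defer-dx evaluate --data-dir data/ --seed 1 --out-dir out/
defer-dx all --config run.yaml
```

Real study data can be supplied as four CSVs (`patients.csv`,
`images.csv`, `ratings.csv`, `scores.csv`; schemas in
`defer_dx.io_cli.load_tables`) via `RunConfig(data_dir=...)`.

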