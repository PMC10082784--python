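# Methods

This note documents the statistical machinery in `defer-dx`: the scale
conventions, the consensus and deferral rules, the cluster bootstrap, and
— in most detail — the synthetic reader-study generator, since its design
determines what the package's tests do and do not demonstrate.

## Scales, thresholds and uncertainty bands

Physician reads are integers 1–8 encoding diagnosis and confidence
jointly; AI probabilities are mapped to the same scale by
`y = 1 + 7p`. Binary decisions use the inclusive threshold `y ≥ 4.5`
(equivalently `p ≥ 0.5`); a blended or tied score of exactly 4.5 is a
positive call. Two uncertainty definitions coexist deliberately:

- a **reader** is uncertain iff the integer rating is 4 or 5 (confidence
  level 1 of 4, where level = ⌈|y − 4.5|⌉);
- the **AI** is uncertain iff its continuous rating-equivalent lies in the
  half-open band [3.5, 5.5), i.e. `p ∈ [2.5/7, 4.5/7)` ≈ [0.357, 0.643).

They are kept as distinct operations because their edge semantics differ
(integer membership vs a half-open interval). The band bounds are carried
exactly as rationals of 7; the three-decimal values are display-only.

## Consensus labels and difficulty

A panel's consensus label is the strict majority of binarized reads
(rating ≥ 5 on integers); an exact tie (even panels only) falls to the
mean raw rating with the same inclusive 4.5 threshold. Leave-one-reader-out
(LOO) label sets rebuild the consensus once per reader with that reader's
rows deleted; an image left with fewer than two reads raises an error
rather than being dropped silently, because silent drops would
desynchronize the per-reader evaluation subsets. Panels smaller than the
six-reader study design are legal but logged (small fixtures would
otherwise be untestable); the warning is suppressed for LOO exclusions,
which legitimately reduce six-reader panels to five. An image is
*difficult* under a given exclusion iff at least two retained binary reads
disagree with the consensus label.

## Strategies

All seven strategies share one output contract: a per-image final score on
the 1–8 scale, the binary decision at 4.5, the decision source
(reader / ai / second_reader / blend), and a review burden in percent.
Design choices where the rules leave room:

- Deferred decisions in `ai_aided_physician` carry the AI's *continuous*
  rating-equivalent (not a snapped integer); binary decisions are
  unaffected and downstream blends keep full information.
- Blends binarize at 4.5 — the only threshold the framework defines.
- `select_weight` evaluates every grid weight (default {0, 0.05, …, 1},
  21 candidates) by the mean accuracy of the non-test readers, each scored
  on their own reviewed subset against their own LOO labels (an
  `label_mode="all"` switch scores against all-reader labels instead).
  Ties break toward the smaller physician weight, i.e. more AI influence;
  a deterministic rule is required and the AI side is the better-performing
  one in the motivating setting. Note that exact ties are structural, not
  exceptional: with integer reader ratings the decision margin is at least
  0.5 while one 0.05 grid step perturbs a blend by at most 0.35, so
  neighbouring weights often produce identical decisions.
- The audit strategy's second reader is drawn seeded-uniformly from the
  image's other reviewers, via a dedicated substream per test reader so
  per-reader results are independently reproducible. The second reader's
  read is used unconditionally, even if it is itself equivocal.

## Per-reader evaluation and the cluster bootstrap

Every reader (and every strategy built around that reader, and the AI
baseline) is evaluated only on the images that reader reviewed, against
that reader's LOO labels. Cohort summaries are the across-reader mean of
per-reader metrics — never the metric of pooled reads; the two orders
genuinely differ and a regression test pins the distinction.

The bootstrap resamples *patients* with replacement (B = 1000 by default);
a patient drawn k times contributes its images k times. Within each
replicate all per-reader metrics — including review burdens, which are
re-aggregated from per-image physician-read counts — are recomputed and
averaged across readers; the 95% CI is the 2.5th/97.5th percentile of the
B averages, using numpy's inclusive linear-interpolation percentile so CIs
are bit-reproducible. The reported point estimate is the observed
(non-bootstrap) value; the replicate mean is logged alongside. A metric
with an empty denominator is undefined (NaN, never 0 — zero-imputation
would bias sensitivity in low-prevalence resamples); replicates where a
metric is undefined are dropped for that metric and counted explicitly.

The one-sided two-sample test is paired by default: both statistics are
evaluated on the same patient resample, and `p` is the fraction of
replicates where the putatively better statistic fails to exceed the other
(ties count as failures — conservative and deterministic). An unpaired
variant (independent resamples) is available behind a flag without
endorsement.

## The synthetic cohort generator

The generator emulates the structure of a single-center ICU reader study:
115 patients at 30/115 patient-level prevalence, a zero-truncated negative
binomial number of images per patient (r = 3, p = 0.5: median 3,
IQR ≈ 2–4.5, ≈ 3.4 images/patient), and 12/30 of positive patients
"late-onset" — their first ⌈k/2⌉ of k images are negative, so image-level
prevalence lands near 0.21. Panels of 6–9 readers are assigned at the
patient level by default (a reader reads all of an assigned patient's
images; per-image assignment is an option — the underlying study design is
ambiguous between the two and neither is asserted).

### Latent-signal reads

Each image has a difficulty `d ∈ [0, 1]`. An agent with accuracy curve
`acc(d) = clip(base − slope·d, 0.5, 1)` reads an image of true label `y`
through a latent signal

    t = (2y − 1) · Φ⁻¹(acc(d)) + σ·z,  z ~ N(0, 1)

whose sign is the binary call. For readers σ = 1, so
P(correct) = acc(d) exactly. Reader confidence is a second signal
`v = κ·|t| + noise` bucketed into confidence levels 1–4 at the empirical
quantiles of v, with the level-1 (equivocal) boundary at the
`uncertain_rate_target` quantile — the realized 4/5-rating rate therefore
matches its target by construction rather than merely in expectation.
κ = 0 makes stated confidence pure noise; the default panel mixes
κ ∈ {0.5, 0.9, 1.3}, reproducing imperfectly calibrated physician
confidence. The non-equivocal mass is split 20/30/50 over levels 2/3/4.

The AI shares the same latent form with `σ = score_noise` and exposes the
probability `p = expit(t / τ)` (τ = `calibration_temperature`). Because
probability and binary call derive from one latent, scores near 0.5 are
genuinely near-chance — the model is intrinsically aware of its own
uncertainty, which is what makes uncertainty-based deferral work. σ/τ
jointly control how much probability mass falls in the [3.5, 5.5) band.

Difficulties are drawn by shuffled quantile-grid (stratified) sampling by
default, so the realized difficulty distribution is essentially exact in
every cohort rather than fluctuating binomially; `stratified: false`
restores iid draws. This is a variance-reduction choice: study-sized
cohorts (~400 images) then reproduce the configured difficulty-linked
marginals (AI band rate, difficult fraction) stably.

### Calibrated defaults

Defaults were fixed by matching the emulated study's reported marginal and
stratified statistics, then frozen:

| parameter | default | role |
|---|---|---|
| reader base_accuracy | 9 values in [0.915, 0.975] | skill heterogeneity |
| reader difficulty_slope | 0.50 | accuracy loss per unit difficulty |
| reader calibration κ | {0.5, 0.9, 1.3} tiled | confidence informativeness |
| uncertain_rate_target | 0.056 | equivocal-read rate |
| AI base_accuracy / slope | 0.999 / 0.90 | AI accuracy curve |
| AI score_noise / temperature | 0.65 / 0.74 | probability dispersion / band share |
| difficulty distribution | Beta(0.5, 1.6), stratified | image-difficulty mix |

Under these conditions (30 simulated cohorts): mean reader accuracy 0.809
and AI accuracy 0.843 against LOO labels; AI-first deferral 0.862 with
burden 21.1%; weighted blend 0.864; equivocal reads 5.7%; AI band
~20.8%; both uncertain 1.5%; the AI clearly stronger on non-difficult
images (0.917 vs readers' 0.868) and the two comparable on difficult ones
(≈ 0.68), with readers beating the AI inside the AI's uncertainty band
(0.69 vs 0.60) and vice versa inside the readers' (0.78 vs 0.66).

### What the generator does not emulate

- **Correlated reader errors.** Reads are conditionally independent given
  difficulty. Real physicians share training and context and err on the
  same deceptive images; with independent errors at ~0.81 panel agreement
  the ≥ 2-disagreement rate settles near 31% of images, above a real
  study's ~25%, and the audit strategy (second reader adjudication) looks
  a few points better than it would with correlated panels. Passing tests
  therefore demonstrate the pipeline's correctness and the deferral
  ordering, not the exact difficult-image share of any real cohort.
- **Per-image AI-band stability.** Score noise is iid per image, so a
  414-image cohort's realized band share varies ±2 points (binomial)
  around its 20.8% center; tests compare review burden against each
  cohort's realized band share and the center against its target on
  average.
- No image content, acquisition effects, reader fatigue or order effects;
  no behavior change when readers know an AI backstop exists.

## Numerical and degenerate-input conventions

- All randomness flows from one master seed through named substreams
  (`cohort`, `ratings/reader/<id>`, `scores`, `audit/<reader>`,
  `bootstrap`), so stages are independently reproducible and regenerating
  one does not perturb another.
- `base_accuracy = 1` readers are kept finite in the confidence signal
  (z-score ≈ 7) so quantile thresholds stay defined; their binary reads
  still match the true label. A noiseless, perfectly separated AI emits
  exact {0, 1} probabilities.
- Metrics with zero denominators are NaN; empty strata are reported with
  n = 0, not raised.
- AUROC is deliberately absent: readers produce effectively binary
  decisions, so ranking-based comparison against a continuous scorer would
  be unfair.

## Problem sizes used in the test suite

Brute-force oracle checks enumerate all 12,861 rating multisets of sizes
2–8 and a rating × probability grid including the exact band edges.
Stochastic checks use study-scale cohorts (115 patients, 9 readers):
bootstrap-CI coverage is estimated from 200 simulated cohorts at B = 1000
(coverage required within 95% ± 3), and the deferral-ordering property
from 100 seeded cohorts (required in ≥ 90%). Large-sample generator
checks use ~10,000-image cohorts. The full suite runs in well under a
minute on one CPU.
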