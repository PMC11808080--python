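# Methods

## The problem

Retrospective questionnaires (PSQI) and consumer-wearable annotations
measure "sleep quality" differently: one records a month of subjective
impressions, the other a stream of device-inferred bed-rest and asleep
intervals. This package implements, end to end, the analysis style used
to compare the two in depression cohorts: extract per-night metrics and
windowed features from interval annotations, score and binarize the
questionnaires, train nested cross-validated classifiers to detect each
PHQ-14 symptom (or PSQI domain change) from either modality, and decide
which targets are detectable above chance with a repeated-measures
resampled AUROC layer under Benjamini–Hochberg FDR control.

Because no public cohort of this shape exists, the package is exercised
entirely on a synthetic generator that emulates the data streams and —
crucially — lets effects be planted or zeroed, so calibration and power
of the whole pipeline are testable properties rather than assumptions.

## Sleep features

Annotations are intervals `(participant, start, end, state ∈ {inBed,
asleep})` with offset-carrying timestamps. A *metric day* D spans
`[D−1 15:00, D 15:00)` local time, half-open, with intervals attributed
by their start; the longest bed-rest block on a metric day is the night,
shorter blocks (naps) are ignored. Per night we compute bed-rest and
sleep duration, efficiency (sleep/bed-rest), onset latency (bed-rest
start to first asleep interval, minutes), awakenings (gaps ≥ 1 minute
between asleep intervals inside the block), night awake time (sum of
those gaps), onset/offset clock times, and mean ambient noise over dB
samples inside the block. A night with bed rest but no sleep has
duration 0, efficiency 0 and *missing* latency (bounded, not infinite).

Windows of 8 days (before a PHQ-14) or 28 days (before a PSQI) are
reduced to 27 features: min/max/median/sample-SD for duration,
efficiency, latency and bed-rest duration; mean awake hours and summed
awakening count; median/SD of the four clock times; mean ambient noise.
Clock statistics are computed on an *anchored* scale (hours since 15:00)
so bedtimes spanning midnight stay contiguous; medians are reported back
as clock times, and the model matrix re-anchors them so classifiers see
a continuous axis. SDs use n−1 and require ≥ 2 nights; per-metric
missing nights are skipped pairwise. Watch wear is the fraction of
wall-clock hours in the window containing at least one heart-rate log;
events with wear < 0.80 or no annotated nights are excluded, as are
baseline waves (no sensor history), with one mutually exclusive reason
per exclusion so accounting reconciles exactly.

## Questionnaires

PSQI scoring follows the published instrument: seven 0–3 components
(quality, latency, duration, habitual sleep efficiency, disturbances,
medication, daytime dysfunction) summing to a 0–21 global score.
Binary targets: quality ∈ {2,3}; reported sleep < 7 h; HSE < 85 %
(both strict); ≥ 3 disturbance causes at ≥ 3×/week; any medication;
a daytime-dysfunction item ≥ 2 (at least weekly); global ≥ 5. The
latency rule's default reading — ≥30-minute item *less than
weekly* AND reported minutes-to-sleep ≥ 15 — is kept verbatim, with a
`latency_rule="frequency_geq_weekly"` switch exposing the opposite
frequency clause, since the stated direction is arguably inverted.

The PHQ-14 splits compound PHQ-9 symptoms, adds irritability and
libido, and drops suicidality. A PHQ-8-style total recombines split
pairs by max and excludes the additions; screening threshold ≥ 10.
Item targets are endorsement (> 0); missing libido rows drop for that
target only. Rate correct score = 1000 × accuracy / median RT (ms)
summarizes processing-speed tasks.

## Classification pipeline

Outer loop: stratified group 10-fold CV keyed by participant (no
participant crosses the train/test boundary). Inner loop: 5-fold
(participant-grouped by default; a flag restores plain K-fold) random
search scored by mean inner AUROC. Preprocessing, fitted on train rows
only: median imputation → drop zero-variance features → select-K-best
(K ∈ {10, all}; ANOVA F or seeded mutual information) → robust scaling
(median center, 5th–95th percentile range). Families: L2 logistic
regression (C ∈ {0.01, 0.1, 1, 10}, this package's documented choice),
random forest and gradient-boosted trees (estimators
{100, 200, 500}, depth {5, 10, 20}, min leaf {2, 5, 10}, max features
{none, √, log2}), and a train-prevalence dummy. The dummy is both a
*selectable candidate* — when nothing beats chance in the inner folds it
wins the fold, which is how baseline "0.500 / 1.000" rows arise in a
results table and what keeps the detection layer calibrated under the
null — and an always-fitted reference whose constant scores are reported
alongside every winner. Budget: 25 sampled configurations per family
per outer fold, exhaustive when a family's grid fits the budget; ties
break toward fewer selected features, then the simpler family (dummy
first).

## Statistical layer

Fold metrics: each fold's test events are resampled by drawing one
event per participant, 100 times; AUROC (midrank tie convention, so a
constant predictor scores exactly 0.5) and average precision are
aggregated per fold by the mean (median available). Detectability: a
one-sided Wilcoxon signed-rank test of fold AUROCs against 0.5, exact
enumeration (with midranks) for ≤ 15 nonzero differences, all-zero
differences giving p = 1 — which makes the dummy row's 0.500 / 1.000 an
analytic identity. BH step-up FDR is applied per questionnaire family
(α = 0.05). Feature-set augmentation uses a one-sided paired t over
folds (t = 0 ⇒ p = 0.5; zero-variance nonzero differences warn and
saturate). Subgroup comparisons resample per subgroup and compare fold
AUROCs with a two-sided Mann–Whitney U, uncorrected. Per-prediction
attributions use permutation-sampling Shapley values with
background-marginal imputation, reporting a Monte-Carlo SE per feature;
the efficiency identity (Σ values + base = score) holds within
sampling error and is tested against exact subset enumeration.

## Synthetic cohort generator

Each participant draws latent traits: habitual bed-rest onset
(23:00 ± 1.1 h), bed-rest duration (8 ± 0.8 h), log-normal onset
latency (median 15 min), log-normal awakening rate (≈ 1.3/night),
logit-normal efficiency baseline (median ≈ 0.92), a shared distress
factor loading on all questionnaire items, and ambient quietness.
Nights are laid on a 1-minute grid: per-night onset/duration/efficiency
jitter, a latency block, Poisson awakenings realized as ≥ 1-minute
gaps, and terminal wakefulness; asleep intervals always nest inside the
bed-rest block and every interval endpoint is a whole minute, which is
what makes the minute-grid oracle exact. Naps (default 0.05/day) add a
short afternoon bed-rest block exercising longest-block selection.
Watch wear is hourly Bernoulli (default 0.92) starting 8 days before
week 0; a configurable fraction (default 0.27) of participants emit no
annotations at all — device-based sleep annotation typically requires a
setup step many participants never complete, and the availability filter
needs exercising.

Symptom scores come from an ordered logit over participant propensity:
`P(score > 0) = logistic(baseline + loading·distress + propensity noise
+ Σ effect × standardized physiological latent)`, so a configured
effect (e.g. `{"sleep_too_much": ("sleep_offset", 1.5)}`) is exactly a
1.5 log-odds-per-SD planted link. PSQI self-reports derive from the
realized prior-28-day window: reported duration/bed/wake times get
additive Gaussian misperception noise (default SD 1.5 h — deliberately
large relative to between-person spread so concordance sits in the
weak-to-moderate regime typical of retrospective self-report), latency
gets the same SD on the log scale (reproducing gross overestimation),
and awakenings are binomially thinned (default perception probability
0.5) before frequency coding. Neurocognitive metrics derive from an
ability latent optionally (default off) linked negatively to the
disturbance propensity.

What the generator does *not* emulate: construct differences beyond
additive/thinning misperception, device-specific annotation artifacts
(e.g. systematically missed awakenings as a function of motion), DST
(the synthetic study runs in a fixed-offset timezone), weekday/weekend
structure, dropout over time, or demographic strata. Passing tests
therefore show the *pipeline* is correct and calibrated, not that any
particular real-world effect size is recoverable.

## Numerical and design choices

- Exactness: interval arithmetic runs on int64 nanoseconds; metrics are
  single divisions of minute counts, so the minute-grid oracle matches
  bitwise.
- AUROC/AP are computed by rank statistics vectorized across draws and
  verified against scikit-learn under ties.
- Wilcoxon enumeration covers n ≤ 15 (the 10-fold case); larger n uses
  the tie-corrected normal approximation with continuity correction.
- Scaled-down study sizes used by the replicated acceptance checks:
  null calibration runs 100 pipelines (50 participants, 5 targets);
  power runs 20 pipelines (100 participants, planted 1.5 log-odds/SD);
  both use a logistic-only search with 3-fold grouped inner CV. These
  sizes are the package's declared test conditions.
- All randomness flows from one master seed through named substreams
  (generator, folds, search, resampling, shapley), recorded in the run
  manifest; per-participant generator streams are keyed by (seed,
  participant index) so cohorts survive reordering.

## Known limitations

- The signed-rank test across cross-validation folds treats the 10 fold
  AUROCs as independent; they are not — folds share training
  participants, so their metrics are positively correlated (the
  well-known difficulty of estimating the variance of cross-validation).
  The test is therefore anticonservative at small cohort sizes, and more
  so the more strongly symptom labels cluster within participants. At a
  few dozen participants the replicate-level chance of declaring *some*
  symptom detectable under a null cohort noticeably exceeds the nominal
  FDR level even though the expected fraction of falsely declared models
  stays within it; at a couple hundred participants the effect shrinks.
  Including the dummy classifier as a selectable candidate (folds with
  no inner-CV signal then sit exactly at chance and drop out of the
  signed-rank test) removes most, but not all, of this inflation.

- PSQI component scoring assumes complete responses; there is no
  partial-credit or imputation path (by design — incomplete responses
  are dropped).
- The latency binarization's stated frequency direction is preserved
  by default even though it looks inverted; switch the rule explicitly
  if replicating conventional scoring.
- `GradientBoostingClassifier` stands in for XGBoost with the same
  hyperparameter grid; results will differ from an XGBoost fit in detail.
- Fold-level AUPRC differences are noisy at small event counts; the
  augmentation t-test is only as stable as the 10 fold values behind it.
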