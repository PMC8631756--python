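# Methods

`protolearn` simulates and analyses a probabilistic A/B prototype
category-learning experiment: a 10-binary-feature stimulus space learned under
observational and feedback-based training, with trial-by-trial strategy
classification and feedback-locked ERP (FRN/P3a) factor scoring. Because no
trial-level data from such studies are deposited, the package pairs every
analysis with a synthetic-data generator whose defaults emulate the study
conditions, so the full pipeline can be exercised and validated end to end.

## Task and stimulus model

A stimulus is a length-10 binary vector; value 0 of each feature is
characteristic of Prototype A, value 1 of Prototype B. The distance of a
stimulus from Prototype A is the number of B-characteristic values it carries
(0–10). Distances 1–4 are Category A, 6–9 Category B; the two prototypes and
the distance-5 (midline) stimuli never appear in training, and midline items
are conventionally coded A during testing.

**Training schedules** contain 80 trials: 20 unique stimuli (10 per category,
distances 1–4 from the respective prototype) shown four times each in a seeded
random order. The 20 stimuli are found by rejection sampling (default cap
10,000 draws): the A-side set is drawn with the fixed distance multiset
{1,1,2,2,2,3,3,3,4,4} and the B-side set is its bitwise complement. The
complement construction guarantees that every feature-value bin occurs in
exactly 10 of the 20 stimuli, and the rejection condition (each feature
present in 2–3 A-side stimuli) pins every bin's empirical co-occurrence with
its characteristic category to 0.70 or 0.80 — inside the 70–80% reinforcement
window that makes the task probabilistic. About 0.4% of raw draws satisfy the
condition, so sampling typically succeeds within a few hundred attempts.

**Testing schedules** contain 50 trials: each prototype 3 times
(configurable to 2), exactly 2 midline trials coded A, 10 trials re-showing
trained stimuli (5 per category, once each), and 32 novel distance-1–4
stimuli. Published descriptions of this design itemise 40 distance-1–4
trials plus 5–6 prototype trials plus 2 midline trials, which cannot sum to
the stated 50-trial total; we treat the hard constraints (50 trials, 2
midline, 10 seen, 2–3 prototype repetitions) as binding and let the
distance-1–4 count come out at 42.

Timing metadata (7,000 ms observational display; 4,000 ms response window,
500 ms feedback delay, 3,000 ms feedback) is carried on schedules for epoch
bookkeeping but not simulated in real time.

## Simulated learners

Three response strategies, matching the classes the fit is meant to recover:

* **multi_cue** — limited-attention evidence integration: on each trial the
  agent samples `attention_breadth` features (default 5) and responds B with
  probability logistic(`evidence_slope` × (B-votes − breadth/2)), plus a
  uniform `lapse_rate`. With breadth 10 this reduces to a logistic in the
  stimulus's distance from the midline. The default (breadth 5, slope 5,
  lapse 0) produces per-bin B-response rates near 0.71/0.29 — tracking the
  0.70–0.80 reinforcement rates that define multi-cue responding — and ~90%
  testing accuracy. A shallow configuration (breadth 3, lapse 0.2) produces
  probability-matching behaviour with testing accuracy in the 70–80% band.
  The design is deliberate: for any label-symmetric responder the per-bin
  B-rate satisfies rate − 0.5 = (accuracy − 0.5)/2, so a 75%-accurate
  symmetric agent has 0.625 bin rates — exactly between the multi-cue (0.75)
  and random (0.50) model profiles — and is not reliably classifiable from
  50-trial segments. Cross-feature attention sampling breaks that tie while
  keeping errors graded in stimulus difficulty.
* **single_feature** — keys on one feature: responds `keyed_direction`
  whenever the keyed feature shows its B-characteristic value (probability
  `consistency`, default 0.98) and the opposite label otherwise.
* **random** — a fair coin on every trial.

Observational-training responses are button-press echoes of the displayed
label (and are excluded from strategy analysis downstream). During feedback
training an optional acquisition ramp expresses the strategy with probability
rising linearly from `acquisition[0]` to `acquisition[1]`, guessing
otherwise. The default cohort preset — 26 multi-cue (acquisition 0.3→0.85),
8 single-feature, 4 random, i.e. the feedback-testing strategy counts of the
emulated study — yields roughly 13 negative feedbacks in early training and 9
in late training on average, and a realistic handful (typically 1–8) of
participants falling below the 6-negative-trial ERP inclusion threshold.
All randomness derives from a single master seed via `numpy` SeedSequence
spawning, so cohorts are bit-reproducible.

## Strategy fit

For a phase segment (observational testing, feedback testing, or the early /
late halves of feedback training — trials 1–40 vs 41–80), responses are
tallied per feature-value bin (20 bins): `n_presentations_F` trials showed
bin F, `b_actual_F` of them drew a B-response. Each of 22 candidate models
supplies expected B-counts per bin:

* the **multi-cue** model applies the delivered training schedule's per-bin
  B-reinforcement rates to the segment's presentation counts;
* each of the 20 **single-feature** models (10 features × 2 directions) is a
  deterministic trialwise rule — respond the keyed direction whenever the
  keyed feature shows value 1, the opposite label otherwise — accumulated
  over the segment's actual trials, so co-occurrence between features is
  respected;
* the **random** model expects half of each bin's presentations.

The fit score is

    score(M) = Σ_F (b_expected_F,M − b_actual_F)² / Σ_F n_presentations_F²,

bounded in [0, 1] and zero exactly when the model reproduces every bin count.
The printed form of this formula is typographically ambiguous about the
denominator grouping; we use Σ(n²), which respects the stated [0, 1] bound.
The alternative (Σn)² is available via `denominator="square_of_sum"` and
cannot change any classification, because the denominator does not depend on
the model — an invariance the tests verify exhaustively. The lowest score
wins; ties (which effectively arise only in toy inputs) resolve by fixed bank
order (random, then single-feature by feature index with the A direction
first, then multi-cue). Display percentages for strategy proportions are
truncated to whole numbers, which reproduces the convention under which 4/38
prints as 10%.

Bins are the 20 feature-value bins rather than 10 features, following the
worked description of the method (responses to both values of each feature
are tallied separately). Single-feature models are evaluated trialwise; a
bin-local variant would agree on the keyed bin and differ slightly elsewhere.

## Synthetic feedback-locked epochs

One single-channel ("FCz") epoch per feedback-training trial, −200..800 ms at
1,000 Hz: 1/f noise (default SD 1.5 µV) + white noise (SD 3 µV) + two Gaussian
components — an FRN-like negativity (peak 248 ms, width 40 ms; amplitude
−1 µV after positive feedback, −2.5 µV after negative) and a P3a-like
positivity (peak 360 ms, width 50 ms, +2.5 µV). Component amplitudes get a
participant-level offset (SD 0.5 / 1.0 µV) because between-participant
amplitude variance is what a temporal PCA of condition averages decomposes;
without it the P3a, which has no condition effects, would vanish into the
column means. The cohort preset adds +2 µV to the single-feature group's FRN
in late training — the injected phase-by-strategy interaction (FRN
attenuation with reduced feedback utilisation) that the pipeline must
recover. The generator does not emulate ocular artifacts, multi-channel
topography, latency jitter, or non-stationary noise; passing recovery tests
therefore validate the pipeline's numerics, not its robustness to artifacts
that the emulated study handled by manual inspection and ocular correction.

## ERP pipeline

1. **Filtering**: zero-phase 4th-order Butterworth bandpass, 0.1–30 Hz,
   applied per epoch with maximal (length−1) odd-reflection padding — the
   0.1 Hz transient outlasts the 1 s epoch, so default padding would leave
   visible edge artifacts.
2. **Baseline**: subtract the per-epoch mean over −200..−100 ms (idempotent).
3. **Rejection**: drop epochs whose absolute amplitude exceeds ±100 µV — a
   deterministic stand-in for manual artifact inspection.
4. **Exclusion**: participants with fewer than 6 negative-feedback epochs in
   either training half are excluded, with a per-participant report.
5. **Condition averages**: pointwise means for the four feedback-valence ×
   training-phase cells per retained participant.
6. **Temporal PCA**: covariance PCA of the participant×condition average
   waveforms (rows = observations, columns = time points), retaining 7
   factors by default (a cumulative-variance criterion is available),
   followed by varimax rotation (classic Kaiser algorithm, implemented
   in-package). Factors are ordered by rotated variance, sign-aligned so the
   loading peak is positive, and peak-normalised so the least-squares
   (regression-method) factor scores are microvolt-scaled amplitudes.
7. **Labelling**: the FRN is the factor whose loading peaks in 200–300 ms,
   the P3a in 300–450 ms (largest variance wins when several qualify; the
   FRN factor is excluded from P3a candidacy; an empty window yields a null
   label and a warning).
8. **Scores**: per participant and cell, the labelled factors' scores form
   the FRN/P3a amplitude measures for the statistics layer.

No latency ("jitter") correction is applied by default: the original
procedure is unspecified, and inventing one would change the measurand
silently; an optional cross-correlation alignment (`latency_align`) is
provided for data with genuine trial-to-trial latency jitter. Epochs are
single-channel throughout ("FCz" — the electrode the analysis uses), so
average re-referencing is a no-op and is not part of the pipeline.

## Statistics

`scipy.stats` and `statsmodels` back the standard procedures: chi-square
goodness of fit (expected counts from proportions, reproducing the convention
of testing feedback-condition counts against observational-condition
percentages), one-way between-subjects ANOVA with η² and Holm-adjusted
pairwise t post-hocs plus Levene's test (mean-centred; Brown–Forsythe via
`center="median"`), Kruskal–Wallis with tie correction, mean ranks, and
Holm-adjusted rank-sum post-hocs, and paired/independent t-tests with mean
difference CIs. Cohen's d_s uses the pooled SD with a noncentral-t 95% CI;
d_av divides by the average of the two SDs.

The 2 (feedback valence) × 2 (training phase) × 3 (strategy) split-plot ANOVA
is implemented via orthonormal within-subject contrasts: each within effect
corresponds to a unit-norm contrast over a participant's four cell means, and
regressing each contrast variable on the sum-to-zero-coded between factor
yields the classical split-plot sums of squares exactly — including Type III
tests for the unbalanced group sizes this design produces (e.g. 19/8/4).
Generalized eta-squared is SS_effect / (SS_effect + the sum of all four
error-stratum SS). The implementation is verified against a brute-force
textbook decomposition on balanced fixtures to 1e−10, and the η²_g arithmetic
against the published ANOVA table. Post-hoc early-vs-late contrasts per group
use the phase-stratum error term, sharing the omnibus denominator df.

Known reporting quirks of the emulated results are flagged, not chased: the
printed d_av for the FRN valence effect (−0.36) does not recompute from its
printed means and SDs (−0.35), and the printed H (21.62) is not exactly
recoverable from the printed mean ranks.

## Problem sizes and reproducibility

Default problem sizes: 38-participant cohorts, 80-trial training and 50-trial
testing phases, 1,000-sample epochs. Validation uses 100 seeded agents per
strategy on ~500-trial segments for parameter recovery (shorter segments make
graded multi-cue responders genuinely ambiguous — a property of the method,
not a bug), 1,000 random profiles for fit-score properties, and 50 seeded
cohort runs for ERP component recovery. `scripts/acceptance.py` recomputes
all headline quantities from scratch at these sizes (a few minutes on one
CPU). Every pipeline run is a pure function of its `RunConfig`; output
manifests record SHA-256 checksums, and repeated runs are byte-identical.

## Limitations

* Agents are stationary within testing phases and use the same strategy in
  both task conditions, so condition-dependent strategy shifts (the headline
  behavioural finding of the emulated study) are not in the generator's
  default repertoire; the chi-square machinery is exercised on printed counts
  and on whatever contrast the simulated cohort produces.
* Classification from 50-trial segments is noisy for graded multi-cue
  responders; cohort-level classified counts approximate, but do not equal,
  the generating mixture.
* The synthetic EEG is single-channel with Gaussian components and stationary
  noise; topography, source structure, and artifact families are out of scope.
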