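# Methods

This note documents the generative model, the signal-processing and
statistical choices, and the limits of what the synthetic experiments can
show. Everything quantitative below is computed by the test suite or the
analysis scripts; nothing is asserted that the code does not reproduce.

## Generative model of a suturing session

A cohort consists of `n_novices + n_experts` participants, each suturing a
task board of `slots` (default 6) incisions with `sutures_per_slot`
(default 2) sutures per slot. Each suture is divided into 10 ordered
segments. Of the segment labels, needle pick, edge touch, knots 1–3 and
cutting are standard microsurgical suturing events; the remaining four
defaults (`pierce`, `pull_through`, `regrasp`, `loop`) are placeholders and
freely configurable.

**Durations.** Suture duration is truncated-normal: `N(mean, sd)`
conditioned on `duration >= 10 s`, sampled exactly via the truncated-normal
distribution. Defaults are the observed group statistics — expert
N(70.6 s, 14.9 s), novice N(168.8 s, 68.7 s). For the novice parameters the
10 s floor raises the distribution mean by ≈1.9 s above the nominal 168.8 s
(the expert shift is ≈0.002 s); recovery tests therefore target the model's
analytic expectation. Segment durations split the suture by a Dirichlet
draw (concentration 4 per segment), since no per-segment timing is
available to calibrate against.

**Pupil signal.** Each participant has a resting pupil baseline drawn
uniformly from 400–600 arbitrary pupil units (the unit is deliberately
unspecified — all downstream features are PCPS-normalized and provably
scale-invariant). Per slot the baseline jitters by ±2%. During a suture,

```
pupil(t) = B_slot * (1 + tonic + jitter + phasic(segment(t))) + noise(t)
```

* `tonic` — group-level task-evoked dilation: expert +0.03, novice +0.10 of
  baseline by default. These magnitudes are design choices on the realistic
  scale of task-evoked pupillary responses (a few percent to ~10%); no
  published values exist for this task.
* `jitter` — i.i.d. per-suture tonic arousal fluctuation, `N(0, 0.03)`.
  This is the dominant within-group feature variance, as in real
  pupillometry where tonic arousal drifts on the minute scale. It is what
  makes group separability a genuinely statistical problem: without it the
  simulated features are so precise that a classifier can exploit shared
  baseline-estimation error and segment-level accuracy saturates.
* `phasic` — per-segment dilation amplitudes (defaults 0–0.06), identical
  across groups.
* `noise(t)` — white Gaussian noise plus one sinusoid at
  `high_freq_noise_hz` (default 6 Hz, i.e. above the 2 Hz "noise"
  boundary), both with SD `noise_sd` (default 5 pupil units) specified at a
  500-unit reference pupil and scaled proportionally with the baseline.
  The proportional scaling keeps relative measurement precision uniform
  across participants; with strictly absolute noise, SDPCPS ∝ 1/baseline
  becomes a stable participant fingerprint that repeated k-fold
  cross-validation memorizes, and a zero-effect cohort would classify above
  the majority baseline for purely structural reasons.

**Blinks.** Blink count per suture is Poisson(rate × on-microscope time) at
the group rate (defaults 4.69/4.68 blinks/min); events last 100–400 ms and
are placed uniformly with a guaranteed 0.1 s separation (a spacings
construction). The separation ensures discretized blink runs never merge at
30 Hz, so the blinks-per-minute estimator of the count is unbiased — a
naive Poisson arrival process would merge ~2% of events and bias the
measured rate low by more than its Monte-Carlo error at n = 10,000.

**Gaps and defects.** The final (cutting) segment ends with an `away` gap
(default 3 s, capped at 80% of the segment) while the scissors are picked
up; it is logged in the timeline. Sutures fail with probability 11/120 and
are flagged, not deleted (failed sutures get 3–9 segments). Each segment of
a successful suture independently goes `missing` with probability 5/1090.
All randomness flows from one integer seed through a single generator;
a fixed seed reproduces the cohort byte for byte.

**Illumination.** Scene illumination is simulated independently of pupil
size (configurable coupling coefficient, default 0), supporting the
sanity check that detrended pupil–illumination Pearson correlation stays
below 0.1 in magnitude.

## Pupil detection

Synthetic eye frames are rendered as a dark pupil disc inside an iris
annulus on bright sclera, with optional top-down eyelid occlusion,
multiplicative illumination and Gaussian pixel noise. Detection is a
gradient-edge circular Hough transform: Sobel-free `np.gradient` magnitude
thresholded into a binary edge map (default threshold 20 intensity units),
votes accumulated over integer radii for centers at distance `r ± 0.5 px`
of each edge pixel, peak normalized by ring pixel count to a score in
[0, 1]. `found` requires score ≥ 0.35. Ties break deterministically:
smallest radius, then smallest (y, x); coordinates are 0-based, origin
top-left. The vectorized accumulator is tested for exact integer equality
against a per-center brute-force distance scan, and against scikit-image's
`hough_circle` peak. Pupil size passed downstream is the *diameter* in
pixels (whether the original hardware reported diameter, radius or area is
unknown; PCPS is invariant to the choice). Runs of undetected frames
shorter than 0.5 s become `blink`, runs of at least 2 s become `away`,
intermediate runs `missing` — thresholds are package decisions, since the
reference workflow filtered blinks manually.

## Preprocessing

* **Resampling:** linear interpolation onto a uniform 30 Hz grid. Each grid
  point inherits the status of the raw inter-sample interval it falls in,
  which conserves gap durations to within one sample period. Blink gaps are
  bridged and flagged `blink_interp` (a drop mode exists); away and missing
  gaps are never bridged.
* **Filtering:** 2nd-order Butterworth, 4 Hz cutoff, applied forward and
  backward (`filtfilt`, zero phase, effective 4th order) independently per
  contiguous valued run, with even-reflection padding of 3 filter lengths.
  Runs shorter than 1 s pass through unfiltered with a warning record. The
  analytic bilinear-transform magnitude
  `|H|² = 1/(1 + (tan(πf/fs)/tan(πfc/fs))^4)` is the test oracle; measured
  gains at 0.5 / 4 / 10 Hz match it to 0.01.
* **Away masking:** logged away intervals from the event log are forced to
  `away` and the number of newly excluded samples reported.

## Features

Baseline μ per slot = mean pupil over the 200-frame window ending at the
slot's first suture onset, using measured (`valid`) frames only —
blink-interpolated values are excluded by default (configurable) so μ
reflects measured pupil; if the window is empty the nearest preceding
usable window is used and flagged. PCPS = (X − μ)/μ. Per segment: APCPS =
mean, SDPCPS = sample SD (ddof = 1, configurable) over valued samples;
segments with fewer than two valued samples are *missing* rather than
yielding SD = 0 from one point, and are imputed with the mean (APCPS,
SDPCPS) of the participant's other same-label segments from any slot
(the most literal reading of "similar segments"); rows without donors are
excluded with a warning, and imputation provably never touches non-missing
entries. Blink rate = contiguous blink runs (one event per run, regardless
of duration) per minute of non-away, non-missing time. Suture-level vector:
`apcps_01..10, sdpcps_01..10, blink_rate` (21 columns); only successful
sutures enter the tables.

## Classification

SVM with C = 0.25 and RBF kernel, bandwidth 1/(n_features × feature
variance) — the kernel is unrecorded in the reference protocol, so RBF (the
common default) is a documented package decision, with a linear option.
The exponential grid search (2⁻³…2¹⁷, 21 candidates, stratified 10-fold,
ties to the smallest C) is provided, but the pipeline fixes C = 0.25
throughout. Scaling default is the literal protocol — train and test folds
standardized *separately* to zero mean/unit variance — which is
non-standard; a conventional `train_fitted` mode exists. Block-wise PCA
reduces the APCPS and SDPCPS blocks to 4 components each (fitted on
training rows only; a leakage-free choice, as the reference wording is
ambiguous) and appends the blink rate: 9 features. Evaluation: repeated
stratified 10-fold × 10 repetitions = 100 fold scores; expert is the
positive class; per-metric mean ± 1.96 SE over fold scores (the CI method
is a package decision); undefined precision (no predicted positives) is
NaN-flagged and excluded from its mean. Leave-one-participant-out re-runs
the suture scheme with each participant's sutures withheld, skipping (with
a warning) any participant whose removal leaves a class below the fold
count.

A caution on the fold-score CI: fold scores re-test the same rows, so the
CI reflects fold-to-fold spread, not cohort-level sampling error. The
null-effect test therefore compares accuracy to the majority baseline
within a 99% binomial band over the evaluated rows (±2.576·√(p(1−p)/n)),
which is the appropriate "statistically indistinguishable" check.

## Statistics

Group summaries report duration and blink-rate means with sample SDs over
successful sutures. The duration test is a two-tailed two-sample t from
summary statistics; the pooled variant (df = n₁+n₂−2) is the default and
reproduces t = 10.78 from the printed group summaries (70.6/14.9/60 vs
168.8/68.7/49). Note the reference df label reads 108 for 109 sutures
while the pooled formula gives df = 107; the statistic matches the pooled
formula, and this package reports df = 107 without resolving the label.
Welch is available; both variants are cross-checked against
`scipy.stats.ttest_ind_from_stats`.

## Problem sizes

Monte-Carlo recovery runs use 10,000 simulated sutures per quantity
(duration means: direct draws; blink rate: fully synthesized traces through
the estimator). Classification properties use full default cohorts
(10 participants, ~110 successful sutures); the separability sweep uses 5
CV repetitions per offset and the null-effect check the full 10. The
complete suite and the acceptance script each run in well under a minute on
one core.

## What the synthetic experiments do and do not show

The generator reproduces the *structure* of the recorded study (counts,
durations, blink statistics, gap anatomy, noise spectrum above 2 Hz) but
not the human data itself, which was never deposited. In particular:

* Group separability is controlled by the configured tonic offsets and
  jitter; the published 74–76% suture-level accuracies are a property of
  the human cohort and are deliberately not a target. With the defaults the
  synthetic cohort is cleaner than human data (≈87% suture-level accuracy).
* Phasic amplitudes are identical across groups and tonic jitter is shared
  by all segments of a suture, so synthetic segment-level classification
  performs close to suture-level classification — unlike the human data,
  where segment-level features were too noisy. Group-specific phasic
  profiles would be needed to emulate that contrast.
* There is no between-participant tonic variance by default: repeated
  k-fold would otherwise legitimately exploit participant identity
  (sutures of one participant occur in train and test), which is exactly
  why leave-one-participant-out is also implemented. Participant-level
  heterogeneity can be emulated by raising per-group offsets per
  participant externally.
* No hand/instrument kinematics, no SURG-TLX response model (scores are
  pass-through metadata), no gaze-point or fixation parsing, no pupil
  foreshortening correction.
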