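# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of the `delaylick` pipeline.
It is written for someone who wants to judge what a passing test suite
does and does not establish.

## Task model and behavioral statistics

A trial is: 0.5-s click train (6 log-spaced rates, 20–125 clicks/s,
category boundary at 50 clicks/s), a delay drawn uniformly from
0.3–1.5 s, a go cue, and a 3-s response window. Licks before the go cue
are violations (excluded from all scored analyses); no lick within the
window is a miss. RT is go-cue onset to first lick.

The psychometric model is the 4-parameter sigmoid
`P(right) = y0 + a/(1 + exp(-(x - x0)/b))` with `x` the log click rate
normalized affinely to [-1, 1] over the stimulus set, so `x = 0` is the
category boundary (the geometric mean of 20 and 125 is exactly 50).
Fitting is bounded least squares on per-rate choice proportions weighted
by trial counts, with 5 restarts (1 canonical + 4 random within bounds),
ties broken by residual sum of squares; `y0, a ∈ [0, 1]` keeps the curve
a probability. Fits pinned at a probability boundary (one-sided
responders) are returned flagged, never silently.

Session accuracy is computed over scored (correct/error) trials only;
violation and miss rates over all trials; RT summaries use medians over
correct trials. Delay-resolved curves use 4 equal-width bins over
0.3–1.5 s. Paired condition comparisons (e.g. chemogenetic silencing vs
vehicle sessions) difference the per-session metrics and test the mean
paired delta with a two-sided sign-flip permutation across pairs (exact
enumeration up to 20 pairs, 5000 Monte-Carlo flips beyond).

## Perturbation choice models

The session-normalized ipsilateral bias subtracts, per session, the mean
control-trial P(lick ipsi) from each perturbation trial's ipsi indicator,
concatenates trials across sessions, and reports mean ± s.e.m. across
trials in percentage points (positive = more ipsilateral).

Choice models are logistic: model 1 is choice ~ normalized log rate +
epoch + region + epoch:region (perturbation levels, control as
reference); model 2 adds difficulty, defined as `1 - x_norm²`, and its
interactions up to epoch:region:difficulty. Aliased design columns are
dropped by QR before fitting (with single-region data the epoch:region
products duplicate the epoch dummies; the earliest column wins). The
original crossed random-effects structure is approximated by fixed
per-subject intercepts plus cluster-robust (by subject) covariance — a
deterministic, dependency-light default; this is an approximation, not a
GLMM, and per-coefficient p-values should be read accordingly. Suspected
separation (|coefficient| > 15) triggers a ridge-stabilized refit that is
flagged on the result. Nested models are compared by 2·Δloglik against
chi-squared with df = the difference in retained columns. Multiplicity
over planned contrasts uses the single-step max-|z| adjustment: the joint
null of the contrast z-statistics is simulated (100,000 seeded draws from
the fitted covariance's correlation) and `p_adj = P(max_j |z*_j| ≥
|z_i|)`; with one contrast this is the unadjusted normal p, with
perfectly correlated contrasts there is no penalty.

Two behaviors of these models are worth knowing. First, lapse rates
attenuate logistic coefficients: if choices are generated with a lapse
floor/ceiling, a pure logistic fit is misspecified and recovers shrunken
effects — parameter-recovery and LRT-calibration tests therefore use a
lapse-free observer. Second, bias terms for a perturbation epoch are only
as informed as that epoch's trial count; with 30% perturbation trials
spread over four epochs, the bias s.e. at 5,000 trials is ≈ 0.2 logits.

## Imaging preprocessing and selectivity

Slow fluorescence drift is removed by subtracting a rolling low
percentile: the 8th percentile over a 400-frame (~13 s at 30 Hz)
centered window for two-photon traces, and the 5th percentile over 1000
frames (~50 s at 20 Hz) for photometry. Windows at the trace edges are
truncated, not reflected — no fabricated look-ahead; an exact per-frame
brute-force oracle checks the implementation in the tests. F0 is the
mode of the corrected trace, estimated as the center of the tallest
Freedman–Diaconis histogram bin (a quantized trace with a heavily
repeated value uses the exact discrete mode). ΔF/F = (F − F0)/F0 is
invariant to multiplicative rescaling of the raw trace. Per trial, the
mean ΔF/F over the 0.5 s before sound onset is subtracted.

Epoch windows: sound = the 0.5-s stimulus; delay = the final 500 ms
before the go cue; response = go cue to first lick; lick = 1.0 s after
the first lick (configurable — the lick-epoch span is a package choice).
Trials with delays under 500 ms have a delay window overlapping the
stimulus tail; they are counted and flagged, and excluded only on
request. Unscored trials and zero-length responses are dropped with a
logged count.

Selectivity is the rank-based AUC (half credit for ties, so it equals
both the Mann–Whitney statistic scaled by n_a·n_b and the pairwise
probability P(a > b) + ½P(a = b)). The permutation null shuffles trial
labels 1000 times; because ranks are label-free, each shuffle is one
masked rank sum, vectorized. An ROI is selective if its AUC leaves the
[0.5th, 99.5th] percentile band in any epoch; a per-epoch two-sided
permutation p (add-one smoothed) is also reported for display-grade
α = 0.05 marking. Each ROI consumes its own seed spawned from the
session seed, so results are stable under per-ROI parallel execution.
Epoch distributions of AUC are compared pairwise by a paired permutation
test on the mean difference (each ROI's pair swapped with probability ½;
5000 shuffles), with Gaussian (μ, σ) fits per epoch for display.

## Synthetic imaging data: what it does and does not emulate

`gen_population` drives each ROI, within each epoch's analysis window, at
a per-trial amplitude drawn from one of two equal-variance Gaussians
(left vs right choice) separated by `δ = √2·σ·Φ⁻¹(AUC_target)` — so the
generating-distribution AUC equals the target exactly. The drive is
convolved with a double-exponential indicator kernel (defaults
tau_rise = 0.2 s, tau_decay = 1.5 s, typical of a slow calcium indicator),
multiplied onto a slow multiplicative drift (5% sinusoid, 80–160-s
period), and embedded in additive Gaussian shot-like noise around a
positive baseline. Selectivity is injected upstream of the fluorescence
model on purpose: the ΔF/F pipeline is genuinely exercised, not fed its
own answer.

Consequence of the slow kernel: activity from one epoch decays into the
next, so with the default kernel a delay-epoch target is partially
*diluted* in the delay window (the kernel reaches only ~15% of its
plateau within 500 ms, lowering the signal-to-noise of the epoch mean)
and partially *leaks* into the response epoch. This is a property of real
slow indicators, not an artifact. The AUC-recovery test therefore uses a
fast configured kernel (tau_decay 0.3 s) and silences the other epochs
(per-epoch base amplitude 0) to validate the injection itself; under
default settings the measured epoch AUCs should be read as lower bounds
on the injected ones. The generator does not emulate correlated noise
across ROIs, neuropil contamination, or movement-coupled imaging
artifacts — a passing suite says nothing about robustness to those.

## Decoding and the RT link

The decoder is an L2-regularized linear maximum-margin classifier (C = 1)
on epoch-averaged ΔF/F vectors, trained on mean-centered features
(centering makes decoding invariant to a common offset, which the
regularized intercept otherwise breaks). Cross-validation: 100 random
90/10 splits; within each training set the majority class is subsampled
to balance (seeded per resample, equality asserted); accuracy is the
held-out fraction correct, reported mean ± s.e.m. across resamples, with
a shuffled-label control computed identically. Leave-one-out decoding
trains M balanced models for M trials and emits per-trial 0/1
correctness.

The RT link bins trials at RT quintiles within 0–2.5 s per session and
correlates per-bin mean accuracy with per-bin mean RT; because "across
bins pooled over sessions" and "across per-bin session means" are both
defensible readings, both Pearson r values are returned. The mixed model
regresses per-trial RT on delay and decoding correctness (plus optional
performance/tongue/nose covariates) with by-subject random intercepts
(optional slopes) by maximum likelihood; a singular random-slope
covariance falls back to intercepts-only, and a random-intercept variance
estimated at zero falls back to OLS for the fixed effects (at the
boundary the ML fixed effects are OLS, and the mixed-model solver is
numerically unreliable there). Both fallbacks are recorded on the result.

## Photometry

Both channels are slow-corrected (1000 frames, 5th percentile), the 410
channel is regressed onto the 470 channel by OLS, and the fitted artifact
component is subtracted mean-preservingly (the corrected trace keeps its
positive offset so the mode-based ΔF/F remains well defined). Because the
410 regressor carries its own noise, the regression slope is attenuated
and a small artifact residue survives — artifact-removal checks use an
artifact that is large relative to channel noise. A zero-variance 410
channel skips the regression with a warning.

The AUC time course uses correct trials, 3-frame (150 ms at 20 Hz)
overlapping smoothing, alignment to delay onset or first lick, and per-
150-ms-bin AUC (contra = 1); in delay alignment, each trial's samples
after its own go cue are masked, so short-delay trials never contribute
post-delay activity. Early AUC averages the sound window; late AUC
averages 1–1.5 s after delay onset clipped at the go cue, so only trials
with delays ≥ 1 s contribute and the value is NaN (flagged) if none do.
A session is "consistent" if early and late AUC fall on the same side of
0.5 (exact 0.5 classifies as inconsistent and is flagged as a tie).
Cell-type comparisons: 2×2 chi-squared without continuity correction on
consistency counts (the uncorrected statistic is the one that reproduces
the printed p on the reference table; a corrected variant is available),
and — because a "variance test between cell types" admits more than one
reading — both a two-sample F-test and a permutation test on the variance
difference of early AUCs are reported, labeled as such.

## Slice electrophysiology

A transient is significant when the depolarization within 50 ms of a
pulse exceeds 3 s.d. of the 1-s pre-stimulation baseline. Responsiveness
uses the trial-averaged 10-pulse train (strictly >40% significant
pulses; 4/10 is not responsive); reliability uses per-sweep baselines on
single-pulse sweeps; latency (first threshold crossing) and amplitude
(max depolarization in 50 ms) come from the mean single-pulse trace.
Only depolarizations count; hyperpolarizing deflections are flagged
separately. Detection is scale-invariant by construction (threshold and
signal scale together).

Two estimator properties matter. The max-over-window rule is sensitive to
the noise spectrum: with white noise at 10 kHz the 50-ms max exceeds
3 s.d. in roughly half the windows by chance, so the generator produces
membrane-filtered noise (5-ms exponential autocorrelation), which is both
realistic and what makes the 3-s.d. rule discriminative. And the
threshold-crossing latency is biased late by roughly the EPSP rise time
scaled by threshold/amplitude (≈1.8 ms at an averaged-trace SNR of 5 for
a 2-ms rise); sub-sample latency accuracy is only expected at high SNR
of the averaged trace, which is how the tests probe it.

## Video movement analysis

Keypoint coordinates with tracking likelihood ≤ 0.1 are discarded;
Δpixel is the coordinate minus its session-wide mean. Trials are aligned
to delay onset and binned at 2 video frames (~83 ms at 24 Hz); per
session an ipsi-vs-contra AUC with a 1000-shuffle 99% band is computed
per bin, and across sessions the per-bin mean ipsi−contra difference is
bootstrap-tested against zero (α = 0.01). The reported divergence time is
the start of the earliest run of 2 consecutive significant bins: with m
sessions the sign-coincidence floor of the bootstrap is 2·0.5^m per bin,
so single-bin detection is unreliable for small m, and "earliest
sustained divergence" is the quantity of interest anyway. The run length
is configurable.

## Shared statistics

Bootstrap tests resample units (sessions/mice) with replacement and take
twice the smaller sign-tail of the resampled statistic; permutation tests
shuffle labels, enumerate exactly when all assignments fit the resample
budget, and otherwise report add-one smoothed `(k+1)/(n+1)` p-values (so
p ≥ 1/(n+1), never 0). The 2×2 chi-squared is the uncorrected Pearson
statistic, df 1, equal to `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`. The
repeated-measures two-way ANOVA operates on per-subject cell means of a
complete balanced design (no imputation) and tests each effect against
its own effect-by-subject interaction mean square; no sphericity
correction is applied. Calibration caveat: the sign-based bootstrap p is
visibly non-uniform for very few units (it is a known small-sample
property; the suite verifies uniformity at 30 units), and the logistic
LRT is only chi-squared-calibrated when the null model is correctly
specified — with a lapsing observer the difficulty terms genuinely
improve fit and the LRT correctly reports that.

## Problem sizes and determinism

All generators and resampling procedures consume a single integer seed
through `numpy.random.default_rng` / `SeedSequence.spawn`; the pipeline
entry point (`run_pipeline(config, seed)`) is bit-reproducible. The test
suite and acceptance script run at deliberately modest sizes — sessions
of 120–300 trials, 500–1000 resampling replicates for calibration
checks, 600 null neurons for the coverage check — chosen so each check
has enough resolution for its stated tolerance while the whole suite
stays cheap to run routinely.

## Known limitations

- Random effects in choice models are approximated (fixed subject
  intercepts + cluster-robust covariance), not a true GLMM.
- Synthetic data have independent noise across ROIs/trials and idealized
  event timing; conclusions about robustness to correlated artifacts,
  tracking errors, or non-stationary behavior do not follow from the
  suite.
- The early/late photometry comparison inherits the ambiguity of a
  "variance test between cell types"; both implemented readings are
  reported rather than one anointed.
- Headline fractions from the original study design (e.g. the fraction
  of side-selective neurons in real populations) depend on unreleased
  animal data and are out of reach by construction; the pipeline instead
  demonstrates calibration and recovery on data with known ground truth.
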