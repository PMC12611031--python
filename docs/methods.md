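# Methods

This note documents the models, algorithms and design choices behind
`ecgms`, an end-to-end pipeline for screening metabolic syndrome (MS) from
multi-lead ECG recordings: beat delineation, a 30-feature cardiac
interval/axis representation, three classifier back-ends under subject-wise
cross-validation, and a statistical feature screen. Because the clinical
OGTT cohort that motivates the pipeline (15 MS + 10 control males, 12-lead,
1 kHz, five stages) is not publicly deposited, a synthetic cohort generator
is a first-class component: it supplies ground truth that every downstream
stage is validated against.

## Synthetic cohort generator

Each beat is a sum of Gaussian deflections on a "cardiac source" channel:
an R spike (sigma 9 ms), Q and S troughs at -/+40 ms (sigma 6 ms, depths
0.15 and 0.25 of the R amplitude), and optional low-amplitude P and T waves
(at -180 ms and +280 ms). P/T waves are on by default so that the Q/S
search has realistic distractors. The source is projected onto frontal
leads by the subject's cardiac-axis angle `theta`: lead I gain
`cos(theta)`, aVF gain `sin(theta)` (general limb leads use
`cos(lead_angle - theta)`). Ground-truth Q/R/S annotations mark the
template extremum samples, so delineation accuracy is checkable to the
sample.

RR intervals are log-normal (positive support, direct coefficient-of-
variation parameterisation). Subject-level parameters are drawn once per
subject (axis ~ N(40, 8) degrees, heart rate ~ N(70, 4) bpm, R amplitude
~ N(1.1, 0.1) mV) and shared across that subject's OGTT stages; stages add
a small deterministic heart-rate modulation (0/+3/+5/+4/+2 bpm). All
randomness derives from `(spec.seed, crc32(subject_id), stage)`, so a
cohort is bit-reproducible regardless of generation order.

Group effects on the MS group — the contrasts the classifiers must learn —
are: axis shift +25 degrees, RR-CV scale 1.8, QRS width scale 1.2, R
amplitude scale 1.25. The clinical literature reports only the *direction*
of such effects (axis deviation, rate-variability changes); no quantitative
effect sizes exist, so these defaults were chosen once to produce a clearly
separable but non-degenerate cohort for classifier testing. They are not
clinical estimates, and passing classification tests on this substrate
demonstrates pipeline correctness, not clinical performance.

When RR dispersion and amplitude jitter are both zero and the RR period is
a whole number of samples, the generator tiles a single precomputed beat
window at integer offsets. This makes dispersion-free records yield
*exactly* identical sampled beats (and hence exactly zero variance
features); per-beat resampling would otherwise leave ~1e-15 amplitude
scatter from float rounding.

Noise (`add_noise`) is additive and exactly scaled per lead to the
requested SNR (powers about the lead mean): white Gaussian, baseline
wander (low-passed below 1 Hz) or electromyographic bursts (30-150 Hz,
~30% duty cycle). 24 dB is the reference level used in validation, the
SNR characterising the standard noise-stress recordings.

Defaults not derivable from the study description: record duration
defaults to 60 s (the study recorded 15 min; 60 s keeps simulation
turnaround short while giving ~60 beats per record, enough for stable
interval statistics — pass `duration=900` for study scale).

What the generator does **not** emulate: realistic 12-lead precordial
morphology, arrhythmias, ectopy, electrode motion transients, respiration
coupling, or glucose-dependent waveform dynamics. Results on this
substrate therefore say nothing about those failure modes.

## Delineation

R peaks: the classic Pan-Tompkins cascade — 5-15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, adaptive signal/noise
thresholds with half-threshold search-back, 200 ms refractory. The
original algorithm fixes these values; the source study names the
algorithm without numbers, so the classic constants are used. Filtering is
zero-phase (`filtfilt`) and the integration window centred, so no group
delay correction is needed. Each accepted detection is refined to the raw
signal extremum within +/-50 ms, with polarity taken from the band-passed
segment; a final amplitude sanity filter drops candidates below 35% of the
median detected amplitude (removes filter edge transients and residual
T-wave candidates without any absolute-voltage assumption).

S peaks: the first derivative-sign-inversion local minimum after each R
within a 120 ms window (upper range of a normal QRS with margin). Q peaks
reuse the S detector on the time-reversed signal `xf[n] = x[N-1-n]`; the S
index found after the mirrored R position maps back to `q = N-1-s'`. The
mirror identity is exact by construction and asserted bit-for-bit in the
tests. A beat whose search finds no inversion carries a sentinel and is
excluded from feature statistics (no interpolation — the simplest
bias-free rule).

One textual ambiguity in the source description deserves note: the S
search is described both as "to the left of" R and as the procedure that,
mirrored, yields Q. These are only consistent if S is searched *after* R
(so the mirrored search lands before R); that reading is implemented.

Detection runs on the lead with the largest band-passed energy by default
and the fiducials are shared across leads (QRS timing is lead-independent
in the dipole model). This matters at extreme axes: at +90 degrees lead I
is electrically silent and detection must come from aVF. Independent
per-lead delineation is available (`reuse_across_leads=False`).

## Features

The 30-entry vector: per lead (I, aVF), mean and sample variance of RR,
RS, QS, QR intervals (ms), of the signed R/Q and R/S amplitude ratios, and
of the R amplitude (mV); plus mean and variance of the per-beat cardiac
axis computed jointly from both leads. Amplitudes are read from the raw
(unfiltered) signal at the annotated samples with the per-lead record
median as baseline.

The axis formula (not specified in the source): per-beat net QRS amplitude
per lead = signed sum of the Q, R, S amplitudes; axis =
`atan2(net_aVF, net_I)` in degrees, the standard two-orthogonal-lead
estimate. Axis statistics are arithmetic on degrees in (-180, 180] — not
circular statistics — valid because physiological and synthetic axes stay
far from the +/-180 wrap; this is a documented limitation. Per-beat axes
are averaged (rather than computing one axis from averaged amplitudes)
because the feature set includes an axis *variance*, which only exists
per beat.

Numerical choices: variances use the n-1 convention everywhere (small beat
counts) and return exactly 0.0 for a constant run; ratio features drop
beats whose |Q| or |S| amplitude is below 1% of that beat's |R| (near-zero
denominators); ratios use signed amplitudes by default with an
absolute-value option.

## Classifiers

**SVM**: RBF kernel; features z-scored with training-fold statistics only;
kernel scale by the median-pairwise-distance heuristic; box constraint 1.
The scale and constraint are not fixed by the source, so standard defaults
are used.

**RobustBoost** (boost-by-majority approximation): 100 learning cycles
over depth-3 trees. Example weights are Gaussian-potential weights about a
target margin trajectory `mu(t)` with width `sigma(t)` over a robust time
`t` in [0, 1]:

    sigma(t)^2 = (sigma_f^2 + 1) e^{2(1-t)} - 1
    mu(t)      = (theta - 2 rho) e^{1-t} + 2 rho

Each cycle fits a tree to the weighted sample, then jointly solves for the
time advance `dt` and vote weight `alpha` such that the average potential
(normal survival function of the standardised margin) is conserved and the
new weights decorrelate from the fitted tree; the largest feasible `dt` is
taken (bisection over `dt`, Brent root-finding for `alpha`). Training
self-terminates when `t` reaches 1. The calibration constant `rho` is
derived from requiring the potential at `(t=0, m=0)` to equal the error
goal: `rho = (sigma(0) z_{1-eps} + theta e) / (2(e-1))`. Defaults:
error goal 0.1, final margin width 0.1, margin goal 0. A perfect weak
hypothesis jumps directly to `t=1`; when no `(alpha, dt)` pair conserves
potential, a minimal AdaBoost-weighted step keeps training progressing.
A plain AdaBoost fallback is available behind the same configuration
object for comparison. In the label-noise tests the robustness target is
set to the contamination rate, which is how the error-goal parameter is
meant to be used.

**CNN**: raw-signal windows. Each record is split into 300 equal
contiguous windows (remainder discarded); each window is a single-channel
(leads x samples) image. Architecture (10 layers): input, conv 100@5x5,
ReLU, 2x2 max-pool, conv 100@8x8, ReLU, 2x2 max-pool, fully connected,
softmax, 2-class output. Kernels and pool windows are clipped to the input
extent, so 2-lead input degenerates the lead dimension gracefully
(effective kernels 2x5 then 1x8). Training: SGD with momentum 0.9
(unspecified in the source; the conventional value), initial learning rate
1e-4 dropped by 0.1 every 8 epochs, L2 4e-4, 5 epochs, batch 30, seeded
He-style initialisation. The implementation is a compact NumPy network
(im2col convolutions with explicit backward passes); with a fixed seed,
training is bit-reproducible. Inputs are zero-centred with the
training-set mean and expressed in ADC units (200 adu/mV), mirroring a
16-bit acquisition front-end; per-window normalisation is deliberately
avoided because between-group amplitude contrasts are informative.
Subject-level predictions are majority votes over the subject's windows
(the source does not describe its aggregation; both window- and
subject-level metrics are reported). Pooling size/stride (2x2, stride 2,
clipped) are likewise conventional choices the source leaves open.

Subject isolation is an error-level contract: `train_cnn` raises if any
training window belongs to a declared test subject.

## Evaluation

Folds partition subjects, never records or windows, with k = 10 by
default. Stratification is on by default: with 15/10 groups and k = 10,
unstratified folds regularly contain a single class. (Stratification falls
back to a plain shuffled split when k exceeds the minority-class count,
e.g. leave-one-out.) MS is the positive class. Metrics are the standard
confusion-matrix set — FPR, FNR, PPV, NPV, Se, Sp, Acc — with zero
denominators reported as NaN, never silently 0. Reports give per-fold
mean +/- sd (the protocol used for the headline tables) alongside
pooled-count metrics for transparency. `repeated_cv` re-randomises both
fold assignment and classifier seed per repetition (500 repetitions, k=10
in the reference protocol) and emits the accuracy histogram.

## Statistics

- Normality: plain KS on z-scored data (the screen the protocol
  prescribes); estimating mean/sd from the sample inflates plain-KS
  p-values, so a Lilliefors-corrected option exists and the caveat is
  documented rather than silently "fixed".
- Mann-Whitney: exact enumeration when the pooled sample has <= 12
  tie-free observations; tie-corrected normal approximation with
  continuity correction otherwise. Verified against an exhaustive
  permutation oracle on tie-free grids.
- Feature screen: per feature x stage, MW p (control vs MS) and
  point-biserial Pearson r with the 0/1 group indicator; raw p-values at
  0.05 by default (the reference protocol reports raw values across the
  30 x 5 grid), Holm adjustment behind a flag; |r| binned at 0.20 / 0.50 /
  0.75.
- PCA relevance: on the correlation structure (features mix ms, ms^2,
  degrees and ratios, so covariance PCA would be unit-dominated);
  13 components retained by default with a cumulative-variance
  alternative, and a feature is relevant when some retained component
  loads at |coefficient| >= 0.2.
- Bland-Altman: marks paired by nearest neighbour within 50 ms; unmatched
  marks are counted as misses/false alarms, not differences; limits are
  mean +/- 1.96 x sample sd.

## Problem sizes used in the shipped checks

The automated checks run on deliberately compact configurations chosen as
the package's own defaults for fast, deterministic verification:
delineation on 25 subjects x 60 s at 1 kHz; noise robustness at 30 s /
500 Hz; feature-based classifiers on basal-stage cohorts at 30 s / 500 Hz;
the CNN on 300 windows of 25 samples (37.5 s at 200 Hz, 2 leads); the
null-calibration screen on 200 cohorts of 20 s / 250 Hz using ground-truth
annotations (the statistics under test do not depend on the detector).
Study-scale records (900 s at 1 kHz, 12 leads) are supported by the same
code paths.

## Known limitations

- The synthetic substrate is template-based; no claim of clinical validity
  attaches to any accuracy number computed on it.
- Axis statistics are non-circular (documented above).
- The KS screen with estimated parameters is anticonservative toward
  normality (Lilliefors option available).
- The WFDB support covers text headers + format-16 signal files only;
  binary WFDB annotation files are not written (annotations travel as
  CSV).
- RobustBoost follows the published potential-function scheme but derives
  its calibration constant from the stated error-goal condition; other
  implementations may differ in the exact step solver.
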