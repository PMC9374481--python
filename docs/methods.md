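# Methods

`visent` implements the analysis chain of a 15 Hz visual-entrainment
(steady-state visual evoked) MEG experiment comparing a patient-like
group ("ADS", Alzheimer's disease spectrum) with healthy controls
("HC"), exercised end-to-end on a synthetic cohort generator with full
ground truth.  This note documents the models, the numerical choices and
what the synthetic tests do and do not establish about real recordings.

## Synthetic cohort model

Each subject contributes epoched multi-sensor data (default −600..3200 ms
at 1 kHz, 3800 samples) built from a single cortical source:

```
s_i(t) = A_i · w(t) · [sin(2πf₀t + φ) + Σ_h g_h sin(2πhf₀t + φ_h)]
         + B · sin(2πf₀t + φ_b,i) + ε_1/f(t)
```

* `A_i` — per-trial entrainment amplitude, lognormal with subject mean
  `A` ~ N(mean, SD) per group and exact cross-trial coefficient of
  variation `cv_trial` (ADS 0.25, HC 0.40 by default: patients respond
  more consistently).  The stimulus-locked phase φ is fixed across
  trials, so the response is phase-locked (high inter-trial phase
  locking); harmonic gains default to 0.4 and 0.2 at 30 and 45 Hz.
* `w(t)` — response envelope: linear ramp 150→250 ms, plateau to the
  1500 ms stimulus offset, linear decay completing at 2000 ms.  This
  realizes a response extent of roughly 200–2000 ms without
  over-specifying onset dynamics.
* `B` — sustained baseline 15 Hz rhythm with a *random phase per trial*:
  it survives trial-averaged power but not evoked averaging, which is
  what distinguishes ongoing rhythm from stimulus-locked response.
  Defaults: ADS (0.20, 0.05), HC (0.30, 0.05) source units.  These were
  chosen once so the resulting periodic spectral peak sits ~0.5–0.7
  log₁₀-power units above the aperiodic background, the range typical of
  empirical baseline spectra; much larger peaks are unrealistic and
  their non-Gaussian leakage skirts contaminate the aperiodic fit.
* `ε_1/f` — aperiodic background synthesized by spectral shaping of
  white noise: log₁₀ PSD = offset − χ·log₁₀ f with defaults (−1.6, 1.0),
  identical across groups (the study found no aperiodic group
  difference).
* Sensor model: the source is projected through one voxel's row of a
  parametric lead field, then white sensor noise (SD 0.05) is added.
  With probability `artifact_rate` a trial receives a 100 ms half-sine
  transient of `artifact_gain` (10×) the RMS sensor amplitude on a third
  of the sensors, triggering both amplitude and gradient rejection
  criteria.
* Cognition: ADS subjects receive an MMSE-like score
  `18 + 6·mean(A_i) + N(0, 3)`, tying cognitive performance to absolute
  entrainment amplitude; HC scores are drawn near ceiling.

The cohort is a pure function of the configuration: per-subject seeds
derive deterministically from `master_seed`, and regeneration is
bit-identical.  Scaling every source amplitude and noise SD by `c`
(with the aperiodic offset shifted by `2·log₁₀ c`) scales the sensor
data by exactly `c`.

### Lead field

Sensors sit on a Fibonacci spiral over a spherical cap (radius 80 mm)
above a cubic voxel grid (default 4×4×4 at 10 mm).  Gains fall off as a
Gaussian of voxel–sensor distance (length scale 40 mm) with a 5% seeded
multiplicative perturbation, so neighboring voxels have correlated but
non-identical sensor patterns.  Beamformer algebra only needs a
consistent generator/estimator pair; Maxwell-equation gradiometer
physics would add realism but no test power, so it is deliberately
absent.  Consequences: no depth bias beyond the Gaussian falloff, no
correlated-source cancellation tests, and localization results say
nothing about real head-model mismatch.

## Time–frequency decomposition

Complex demodulation at 4–50 Hz in 0.5 Hz steps with 100 ms output
frames (93 × 39 grid): multiply by `exp(−i2πft)`, lowpass with a
501-tap Hamming windowed-sinc FIR (1 Hz cutoff), sample at the frame
grid.  The symmetric FIR applied as a centered convolution is zero-phase
by construction.  Coefficients carry a calibration factor of 2, so a
unit-amplitude sinusoid at a bin center returns envelope 1 (verified to
0.02%).

Numerical choices:

* **Filter order.** A "1 Hz transition" FIR at 1 kHz would need ~3300
  taps — its impulse response would cover most of the 3.8 s epoch and
  smear the response across the entire baseline.  501 taps give a
  ~6.6 Hz transition and a 250 ms temporal half-width: 5 Hz-distant bins
  receive <0.5% amplitude leakage, and onset/offset smearing stays
  within ±250 ms.  This is the package's time–frequency resolution
  trade-off, not a claim about any particular vendor implementation.
* **Epoch edges.** Kernels wrap circularly, with the demodulation phase
  attached to the unwrapped kernel offset (equivalently: circular
  convolution with a complex bandpass kernel).  For any circularly
  stationary input the envelope gain, noise bandwidth and phase response
  are then identical at every frame, so edge frames carry no power bias
  — truncated-and-renormalized kernels were tried first and biased the
  baseline power estimate upward by ~20% at the earliest frames, which
  corrupted every baseline-relative quantity downstream.  The wrapped-in
  samples come from the temporally distant opposite end of the epoch,
  which is quiet in this design (the response ends 1.2 s before the
  epoch does).

Baseline normalization is percent change of power against the mean over
the −600..0 ms frames (inclusive), computed per frequency.

## Sensor-level window selection

Per participant, trial-averaged sensor power maps are baseline
normalized and averaged over sensors; a one-sample t-map across
participants is thresholded at two-sided uncorrected p < 0.05,
4-connected supra-threshold clusters are scored by mass (Σ|t|), and the
max-cluster-mass null is built from random per-participant sign flips
(valid because a baseline-relative change has a symmetric null).
Clusters with corrected p below α are returned.

The default α is 0.01 rather than the study-scale 0.001: with 16 demo
participants the sign-flip null has resolution 1/(n_perm+1) and
occasional near-unanimous sign draws make the extreme tail unstable
across seeds; at cohort sizes of ~58 participants α = 0.001 is the
appropriate setting and remains configurable.  Note that cluster-mass
inference licenses statements about clusters, not individual bins; the
selected 15 Hz extent is expected to overshoot the true response window
by up to one frame of smoothing on each side.

## Beamforming

Frequency-domain (DICS-style) spatial filters from the band-limited CSD
(14.5–15.5 Hz; trial-, bin- and frame-averaged outer products of the
demodulation coefficients):

```
w(v) = (C_r + λI)⁻¹ l(v) / (l(v)ᵀ (C_r + λI)⁻¹ l(v)),   λ = 0.05 · mean diag C_r
```

using the real part of the CSD (power mapping).  Unit gain
`w(v)·l(v) = 1` holds to 1e-8 for every voxel.  Source power in the
active window (200–2000 ms) is normalized per voxel by the −600..0 ms
baseline window of equal bandwidth: `pseudo_t = (P_act − P_base)/P_base`,
a dimensionless, scale-invariant map.  Windows of unequal duration are
acceptable because both CSDs are averages — duration affects estimator
variance, not expectation.  The grand-average map's argmax defines the
peak voxel (ties break to the lowest index); virtual sensors apply that
voxel's weights sample-by-sample.  No extra weight normalization is
applied: with this parametric lead field the unit-gain denominator
suffices against depth bias.

## Entrainment metrics

From the virtual-sensor TFR (per kept trial): band envelope = mean |coeff|
over the 14.5/15.0/15.5 Hz bins, rectified per trial before averaging so
induced and evoked power both contribute.  Absolute amplitude averages
the envelope over 200–2000 ms; relative amplitude is the percent change
against the −600..0 ms baseline mean (the two satisfy
`rel = 100·(abs − base)/base` exactly).  ITPL is the magnitude of the
trial-averaged unit phase vector, computed pointwise per (f, t) bin and
then averaged over the band × window grid (bin-then-average order is a
declared choice; the alternative ordering differs only at second order).
The amplitude CV is sample SD / mean of trial-wise window-averaged
envelopes.  Amplitude (not power) is used for envelopes and CV; power is
used for sensor spectrograms and beamforming.

The measured CV overestimates the generating `cv_trial` slightly because
the envelope of signal-plus-noise is Rician; the group ordering is
preserved, which is what the group contrast tests.

## Spectral parameterization

Baseline PSDs (mean |coeff|² over pre-stimulus frames) are modeled in
log₁₀ space as a fixed-mode aperiodic line plus Gaussian peaks
(height in log₁₀-power units, bandwidth = 2σ clipped to 1–15 Hz,
no minimum height, 2-SD relative threshold, peak cap 12):

1. robust aperiodic fit (line fit, discard top-quartile residuals, refit);
2. iterative peak extraction from the flattened spectrum while the
   maximum residual exceeds 2·SD;
3. joint bounded least-squares refinement of all Gaussians;
4. final aperiodic refit on the peak-subtracted spectrum.

R² is reported against the log₁₀ PSD.  Band summaries (14.5–15.5 Hz)
average in log space throughout: `full` is the measured log PSD,
`aperiodic`/`periodic` the model components (which sum to the full model
exactly).  Because the PSD comes from the same demodulation as the
entrainment metrics, its frequency resolution is the analysis filter's
— narrow peaks inherit a ~3 Hz apparent bandwidth, and the absolute
offset is shifted by the transform's noise bandwidth (a constant; the
exponent is unaffected).

## Group statistics

Per metric, within-group outliers beyond 2.5 sample SDs are excluded in
a single pass, then a pooled-variance Student t-test (df = n₁+n₂−2; the
study's printed dfs identify the pooled form), Cohen's
d = |t|·√(1/n₁+1/n₂), and the JZS Bayes factor.  The Bayes factor uses
the default two-sided Cauchy(0, 0.707) prior on the standardized effect
size δ:

```
BF₀₁ = T_df(t | 0) / ∫ T_df(t | δ·√(n₁n₂/(n₁+n₂))) · Cauchy(δ; 0, 0.707) dδ
```

by adaptive quadrature over δ (cross-checked against a 10⁶-draw
Monte-Carlo prior integration and an independent implementation).
Regressions are ordinary least squares with intercept,
F = (R²/1)/((1−R²)/(n−2)) and η²p = F/(F + df₂).  Regression Bayes
factors under the JZS linear-model prior are not reproduced here: the
t-test BFs are the primary quantities, and the linear-model prior has
enough free conventions that exact agreement is not identifiable from
printed values alone.

## Pipeline scale and runtimes

The default demo configuration (8+8 subjects, 40 trials, 24 sensors,
64 voxels, 1000 permutations) runs the full chain in ~30 s on one CPU
and is the scale used by the test suite; group sizes, trial counts and
grid size scale up by configuration only.  Recovery and calibration
suites use 50 localization runs, 100 noisy spectra and 200 null
permutation cohorts.

## What passing tests do not show

The generator omits head motion, physiological artifacts beyond
parametric transients, realistic anatomy, sensor cross-talk and
correlated multi-source activity.  Tests therefore establish internal
consistency (estimators recover the generating model) and statistical
calibration, not robustness to real-world preprocessing failures.  The
FIF adapter for real epochs is experimental and untested against vendor
data.
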