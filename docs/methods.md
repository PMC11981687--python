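# Methods

## Scope and model

The package analyses parallelized diffuse correlation spectroscopy (PDCS)
data: binary photon streams from SPAD arrays in which each pixel observes one
speckle of multiply-scattered laser light.  The tissue is modelled as a
homogeneous semi-infinite half-space; the field autocorrelation g1(τ) is the
extrapolated-zero-boundary Green's-function solution of the correlation
diffusion equation with Brownian scatterer motion, parametrized by an
effective diffusion coefficient of red blood cells (the blood flow index,
BFI, cm²/s):

    g1(τ) = G1(τ)/G1(0),
    G1(τ) = exp(−K(τ)·r1)/r1 − exp(−K(τ)·rb)/rb,
    K(τ)  = sqrt(3·μa·μs′ + 6·μs′²·k0²·BFI·τ),
    r1 = sqrt(ρ² + z0²),  rb = sqrt(ρ² + (z0 + 2·zb)²),
    z0 = 1/μs′,  zb = 2(1+Reff)/(3·μs′(1−Reff)),

with k0 = 2π·n/λ the in-medium wavenumber and Reff the standard polynomial
approximation of the effective Fresnel reflection coefficient in the relative
index n_tissue/n_outside.  Multi-layer models are deliberately out of scope:
with the short delay grids the on-board correlator produces they are
ill-posed, and the homogeneous model is the robust default.  The measured
intensity autocorrelation follows the Siegert relation g2 = 1 + β|g1|², with
β the correlation amplitude set by speckle-to-pixel matching and the coherent
intensity fraction.

Default optical properties (μa = 0.17 cm⁻¹, μs′ = 8 cm⁻¹, n = 1.4 at
785 nm) are literature-typical values for adult forehead tissue.  They are
configurable everywhere and are assumptions, not ground truth; errors in them
translate into errors in absolute BFI, which is why downstream statistics use
only relative (normalized) BFI.

## Synthetic data generator

`speckle_sim` emulates the measurement end-to-end:

* **Field synthesis.**  Each pixel carries an independent circular complex
  Gaussian process with autocorrelation equal to the target g1, produced by
  spectral shaping: white complex noise filtered by the square root of the
  circulant spectrum of g1.  Second-order statistics are exact up to the
  circular wrap, which is negligible because g1 decays orders of magnitude
  faster than any simulated segment.
* **Correlation amplitude.**  Detected intensity mixes the dynamic speckle
  with a static background, I = f·|E|² + (1−f), so a single polarization
  mode realizes β = f².  The in vivo range β ≈ 0.15–0.3 corresponds to
  f ≈ 0.39–0.55; the default f = 0.5 gives β = 0.25.
* **Detection.**  A binary event per frame is drawn with probability
  1 − exp(−(μ·I + μ_dark)); μ is solved so the expected event rate equals
  mean_rate + dark_rate exactly.  There is no inter-frame dead time and no
  rolling-shutter row phase: the exposure is treated as the sampling
  interval.  Photon pile-up is therefore the only detector nonlinearity; it
  compresses the measured β by O(mean_rate) (≈5% at 0.05 events/frame,
  derivable from the shifted-exponential moment generating function) while
  leaving the decay shape — and hence the fitted BFI — essentially unbiased.
* **Pulsatility.**  The pulsatile BFI waveform is piecewise-monotone (PCHIP)
  through five control points per cycle — diastolic end, systolic peak,
  dicrotic notch, diastolic peak, next diastolic end — with seeded
  cycle-period jitter, a notch 0.22 s after the systolic peak by default, and
  a defaults band of 0.33–2.65 Hz.  The photon simulator holds BFI constant
  within each waveform sample (≥ 0.1 s, versus decorrelation times of tens of
  microseconds), i.e. the process is piecewise stationary.  The generator
  also emits an audit of the extrema actually present in the sampled
  waveform, so marker-detector tests have an exact reference and
  coarse-sampling cases (notch narrower than ~2 sample periods) are honestly
  reported as unresolved rather than invented.

What the generator does **not** emulate: spatial correlation between pixels,
afterpulsing/crosstalk, rolling-shutter row phase offsets, motion artifacts,
breathing and vasomotion drifts, and subject-to-subject physiology beyond
the exposed parameters.  Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to every in vivo
confound.

## Correlator

The linear estimator g2(τ_k) = ⟨I(t)I(t+τ_k)⟩/⟨I⟩² is computed per pixel
over averaging spans, using all frame pairs inside the span (lag-shrinking
denominator) and the squared span mean for normalization; a vectorized
implementation is verified exactly (1e-12) against a literal double-loop
oracle.  An averaging window ΔT is partitioned into consecutive spans of
n_delays frames — the arithmetic that reproduces the published curves-per-
window counts (744 at ΔT = 0.125 s/56 delays/3 μs; 198 at 0.1 s/168/3 μs;
201 at 0.1 s/46/10.81 μs) — and all valid sub-curves are averaged across
spans and pixels.  The span is configurable: per-span normalization over very
short spans carries the classic short-integration-window bias of g2, so
quantitative fits in the tests and acceptance runs use span = window, while
the short-span mode exists to emulate the on-board FPGA correlator (16
delays, τmax = 15 exposures).  The fourth published count (2295) is not
derivable from the printed exposure because the on-board frame overhead is
device-state dependent; the effective frame period is therefore a free
`SensorTiming` parameter rather than a hard-coded constant.

Pixels with zero counts in a span are dropped from the mean and recorded in
the provenance counts.  The τ = 0 bin is computed but never fitted: for
binary streams it equals 1/⟨I⟩ and is shot-noise dominated.

## BFI fitting

`fit_bfi` minimizes the squared residuals of 1 + β·g1(τ; BFI)² on a delay
subset (all nonzero delays by default; presets mirror the two instrument
configurations, 45 delays for the raw-stream arm setup and the first 12
nonzero delays for the on-board cerebral setup, where later delays are
noisier).  Numerical choices:

* BFI is fitted as log10(BFI) within [1e-12, 1e-5] cm²/s, β within [0, 0.7];
  trust-region-reflective least squares with xtol = ftol = gtol = 1e-12.
* The start point is fixed (log10 BFI = −8, β = 0.25) with three
  deterministic alternative starts on non-convergence, so fits are
  bit-reproducible.
* The per-window residual is the RMS of (model − data) over the fitted
  subset; the trial-level exclusion rule discards a trial when the median of
  these residuals strictly exceeds 0.03 (a trial exactly at the threshold is
  kept; the comparison carries a 1e-9 epsilon so float midpoints do not flip
  the decision).
* A fit is flagged unidentifiable when β collapses to its lower bound or the
  fitted model is fully decorrelated before the first fitted delay — both
  are the degenerate optima of a flat curve.
* Optional offset correction anchors the mean of the last quartile of delays
  to 1 before fitting, removing the additive part of the short-window bias;
  it is skipped, with a warning, when the tail is evidently still decaying
  (tail mean above 1 + β̂/2).  Residuals are computed after the correction.

`early_slope_metric` provides the simplified alternative flow metric: the
OLS slope of g2 over the first nonzero delays, monotone in BFI within the
quasi-linear regime.

## Pulse analysis

The pulse rate is the largest spectral peak of the mean-subtracted BFI trace
inside 0.33–2.65 Hz (4× zero-padded magnitude spectrum; the native
1/duration resolution is the honest uncertainty, and a count-based rate over
a segment of length L is quantized in steps of 1/L).  The candidate must
also be the dominant non-DC component of the spectrum; otherwise an explicit
no-pulse error is raised.  Systolic peaks are local maxima with a minimum
separation of 0.6 pulse periods — the published phrasing ("0.6 times the
pulse rate") is dimensionally a frequency, and 0.6/rate seconds is the only
physically coherent reading.  Diastolic ends are minima between consecutive
systolic peaks; dicrotic notches are the first strict local minima within
(SP, SP + 0.4 s], ties broken toward the earlier sample; diastolic peaks are
strict local maxima between the notch and the next diastolic end.  Cycles
whose notch and diastolic peak cannot be separated at the trace's sampling
are dropped in pairs and counted.  The pulsatility index is
(⟨BFI⟩_SP − ⟨BFI⟩_DE)/⟨BFI⟩ with the denominator averaged over valid samples
of the whole trial.

## Noise metric

The marker-conditioned noise of a trial is N(τ) = sample SD (n−1
denominator, appropriate at the ~8–15 markers a trial yields) of the
pixel-averaged g2(τ) across all windows nearest to systolic peaks
(respectively diastolic ends), averaged over the nonzero delays (switchable
to the fitted subset).  Markers map to the nearest window start; collisions
keep both draws so the count n is preserved.  For stationary flow the
conditioning is vacuous and the metric equals the unconditioned
across-window SD, which the tests verify.  `noise_vs_pixels` measures the
√M parallelization law directly on a stream by averaging seeded random pixel
subsets; on independent simulated pixels the log-log slope is −1/2 and the
1-versus-1024-pixel noise ratio is 32.

## Group statistics

Each trial's segments are normalized to 100% of the median of the valid
first-control samples; segment medians of this relative BFI (rBFI) feed the
group table.  Contrasts are fitted per condition pair with statsmodels
MixedLM:

    rBFI ~ Trial + Condition + (Condition | Subject)

Trial enters as a categorical fixed effect (the trial index is a label, not
a dose), Condition as a 0/1 indicator, with a random intercept and condition
slope per subject (REML).  When the random-slope fit does not converge or
its covariance is numerically singular, the model falls back to a random
intercept only and says so.  Wald t and p for the condition coefficient are
reported raw — no multiple-testing correction, matching the convention of
reporting three pairwise contrasts with star thresholds 0.05/0.01/0.001.
Cohen's d uses n−1-weighted pooled SD; medians use the midpoint convention.
Simulation tests at a realistic cohort (15 subjects, 2–3 trials each,
subject SD 8%, condition-slope SD 3%, residual 5%) show the contrast is
calibrated (type-I error ≈ 5% over 200 null replicates) with power > 0.8
for a 12% condition shift.

## Problem sizes in tests and acceptance runs

Simulation-backed checks use deliberately chosen desk scales: the noise-ratio
experiment runs 1024 pixels × 200 windows × 512 frames; the end-to-end
recovery check 1024 pixels × 80,000 frames at 10 μs exposure with ΔT = 0.1 s
windows; the closed-loop suppression analogue 256 pixels per segment.  These
sizes keep every Monte-Carlo tolerance (3–3.5 empirical standard errors, 10%
on recovered BFI, 10% on the 32× ratio) comfortably resolvable while the
whole suite completes in a few minutes.

## Known limitations

* Absolute BFI accuracy inherits the assumed optical properties and the
  offset-correction heuristic; conclusions should rest on relative BFI.
* The simulator's pile-up model (per-frame saturation, no dead time) is a
  simplification of real SPAD behaviour; measured β is compressed at high
  count rates.
* Sub-span (on-board emulation) g2 estimates at low count rates carry the
  finite-window normalization bias; offset correction removes only its
  additive component.
* The pulse detector assumes a single dominant fundamental; arrhythmic or
  strongly drifting traces will fail rate estimation (by design, loudly).
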