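# Methods

This note records the models implemented in `specklight`, their
assumptions, the defaults and why they were chosen, and the statistical
limits that govern what the validation suite can and cannot demonstrate.

## Speckle phantom model

**Dynamics.** Each pixel carries an independent complex Gaussian speckle
field E(t) evolved as a stationary Ornstein–Uhlenbeck process with field
autocorrelation `g1(τ) = exp(−τ/τ_f)`; the recorded intensity is
`I = |E|²`. For Gaussian speckle the Siegert relation gives
`g2(τ) − 1 = β·|g1(τ)|² = β·exp(−2τ/τ_f)`. This is the simplest process
consistent with Brownian scatterer motion whose g2 is closed-form, which
makes every estimator testable against an analytic target.

**Calibration.** The decorrelation time is *defined* throughout as the
1/e point of `g2 − 1`. Because the OU intensity correlation decays at
rate `2/τ_f`, the simulator sets `τ_f = 2·τc` so that the 1/e read-out of
the ideal curve returns exactly the requested τc. A unit test verifies
this exactly (to one lag step) on the analytic curve.

**Partial coherence.** β ∈ (0, 1] enters by mixing the fully developed
speckle intensity with a constant pedestal,
`I = √β·I_speckle + (1 − √β)·⟨I⟩`, which yields exactly
`g2 − 1 = β|g1|²` (a field-superposition model would add a heterodyne
cross-term with a different decay). Default β = 1, matching the noiseless
training-data convention; lower values emulate cross-polarised detection.

**Sampling.** Frames are instantaneous samples by default: at the
reference acquisition (9500 µs exposure, 100 fps) the exposure is ≪ τc
(0.39–0.67 s), so intra-frame blurring is negligible for the τc
pipelines. An `oversample` factor on `PhantomSpec` enables sub-exposure
integration for future exposure studies.

**Space.** Pixels are statistically independent — all three pipelines
are strictly pixel-wise, so spatial speckle correlation would not change
any result here; it is deliberately out of scope. Consequently the
phantom cannot exhibit resolution/PSF effects, and passing tests say
nothing about spatial blurring in real optics.

**Static pixels.** `tau_c = STATIC` (∞) freezes a pixel at one draw from
the exponential intensity distribution rather than special-casing ∞
arithmetic downstream.

**Determinism.** One master seed; pixel `i` draws from the stream
`(seed, i)`, so stacks are bit-reproducible and a pixel's series is
independent of the stack shape. Camera noise uses a separate stream.

**Camera noise.** Poisson shot noise on photoelectron counts, additive
Gaussian read noise, optional clip-and-round quantization at 8/10/12/16
bits. The model exists to exercise the denoising path; defaults are off
("noiseless").

## DCS estimator

`g2` uses the literal estimator: numerator `mean_t[I(t)I(t+k)]` over the
overlapping samples at each lag, denominator the squared **full-series**
mean (the printed definition). A `symmetric` per-lag normalization is
available as a config option; measurements during development showed it
does not materially change the error budget at these record lengths. The
lag grid is the native frame period; `max_lag` defaults to
`min(2 s, duration/3)` — covering the 0–2 s operating range while
bounding long-lag variance.

The 1/e read-out is a discrete argmin with ties broken toward the
smallest lag (deterministic); optional linear interpolation of the first
downward crossing is provided but off by default. Pixels are flagged
invalid — never silently filled — when the series is constant, when the
zero-lag contrast `g2(0) − 1` falls below the dynamic-range floor
(default 0.01, i.e. ~1% contrast; configurable), or when the curve has
not decayed to threshold within the lag range.

**Intrinsic accuracy limit.** A record of length T contains roughly
`T/τc` independent speckle decorrelations, so any single-pixel estimate
of τc carries a relative error of order `sqrt(2·τ_f/T) = sqrt(4·τc/T)`.
At the reference 60 s acquisition the measured median |error| is ≈10% at
τc = 0.1 s, ≈12% at 0.25 s, ≈19% at 0.5 s and ≈25% at 1.0 s — in line
with the scaling and with the field's rule of thumb that one should
acquire for ~100·τc. The acceptance suite asserts a uniform 10% bound
across this grid; the bound is attainable only at the fast end, and the
corresponding test documents the honest levels. There is also a small
downward bias (~2·τ_f/T relative) from normalizing by the squared
finite-record mean; it is second-order compared with the scatter.

## Temporal LSCI

`K = σ/⟨I⟩` per temporal window with the **population** σ (the
definition carries no sample correction; `ddof=1` is available) and the
**window** mean in the denominator. Default window 7 frames, stride 1
(every position), no partial windows; the final image averages K over
positions. The 3–51-frame sweep tabulates per-length ROI separation so
the 7-frame compromise can be re-examined per dataset. Windowed variances
are accumulated on offset-removed series so a temporally constant pixel
gives exactly K = 0.

With instantaneous frame sampling, K at fixed window length decreases
monotonically in τc (measured medians 0.58 → 0.15 over τc 0.05–2 s),
reproducing the stiff-appears-dark convention. Absolute K values are
larger than in long-exposure experimental data, where intra-exposure
averaging suppresses contrast; only orderings and separations are
comparable, not K magnitudes.

## ML-DCS

**Training data.** `n_train` independent windows from the phantom
simulator (β = 1, noiseless), 1000 samples at 100 fps, labels i.i.d.
uniform on (0, 2] s — the range typical of soft-tissue surface
measurements. Windows are normalized to zero mean/unit variance (the
intensity scale is arbitrary; g2 is scale-invariant), identically at
training and inference.

**Regressor.** The model is a physics-informed pipeline rather than an
end-to-end convolutional network: empirical autocorrelation coefficients
of the normalized window on a ~40-point log-spaced lag grid (for ideal
speckle these follow `exp(−lag/τc)`, an essentially sufficient summary of
the window for this task), standardized and fed to an sklearn
`MLPRegressor` (64×64, Adam, batch 128). Building the estimator on the
sufficient statistic makes it small, fast to train on a single CPU, and
directly interpretable. The fit targets
`log τc`, making squared error a relative-error surrogate aligned with
the MAPE metric (sklearn's MLP cannot minimize MAPE directly; an
`identity` target option exists). Training runs an explicit epoch loop
(`partial_fit`) with per-epoch train/validation MAPE history, stopping
early if validation MAPE < 5% (the conventional target) and otherwise at
`max_epochs` with `target_reached = False` — never an exception.
Benchmarked against a gradient-boosted-tree ceiling on the same task,
the MLP reaches the same validation MAPE, i.e. the limit is the data,
not the architecture.

**What MAPE is achievable.** Each training window is a single stochastic
realization, so the Bayes error is bounded by the same
`sqrt(4·τc/T)` scatter as above — at T = 10 s that is ≈25–40% MAPE over
the uniform prior, and both the shipped model and the boosted-tree
ceiling land there (~35–40%). A 5% validation MAPE is therefore not
reachable under these study conditions, and the acceptance test that
asserts it fails by design; the trivially separable two-level dataset
(τc ∈ {0.1, 1.9} s) does converge below 5%, confirming the training loop
itself. What the learned estimator *does* provide — and what the tests
verify — is prior-informed shrinkage: per-pixel predictions with far
lower variance than the 1/e read-out at equal 10 s acquisition (measured
tumour-ROI SNR ≈3× higher on the standard phantom), at the price of bias
toward the prior mean. Out-of-range predictions are clipped to (0, 2]
with a clip counter on the returned map.

**Inference.** `mldcs_map` denoises each pixel series with a first-order
low-pass Butterworth filter (critical frequency 0.1 in fraction-of-Nyquist
units — the natural reading for a digital filter — applied zero-phase to
avoid lag distortion; single-pass causal is an option), cuts it into
consecutive non-overlapping training-length windows (a 60 s stack → 6),
predicts each and averages. Averaging measurably reduces across-
realization variance (tested). The denoiser exists for real camera data;
on noiseless synthetic input it low-passes genuine speckle dynamics and
biases predictions upward, so validation scripts on noiseless phantoms
may disable it (`filter_cfg=False`). Models serialize to a single joblib
bundle and reload with bit-identical predictions; inputs of the wrong
window length are refused.

## ROI statistics

The tumour ROI is drawn (polygon JSON or mask TIFF); the control ROI is
its mirror image across the image's horizontal midline (upper ↔ lower
hemisphere — the geometry of a midline-symmetric brain viewed from
above). A mirrored ROI overlapping the original issues a warning, not an
error. Summaries use the sample (n−1) standard deviation — the t-test
convention; at thousands of pixels the distinction is negligible.
`SNR_T = μ_T/σ_T` deliberately uses only tumour-ROI statistics (in a
clinical image there is no guaranteed control region). Welch's t uses
Satterthwaite degrees of freedom and a two-sided Student-t p-value, and
is unit-tested against the raw-sample implementation in scipy.
Difference maps are plain element-wise post − pre on co-registered
inputs; invalidity propagates as NaN.

## Problem sizes in the validation suite

The suite and the acceptance script run simulations sized for a single
CPU: the standard lesion phantom at 64×64×6000 frames (≈1000 pixels per
ROI, the scale at which Welch p < 10⁻⁴ claims are tested), recovery
statistics over ≥100 pixels or seeds per condition, and ML-DCS training
at 5000 windows (the documented reduced scale for the training-target
check; accuracy at this task is data-limited, not sample-limited, so
larger sets do not move the validation MAPE). End to end, the suite
completes in a few minutes.

## Known limitations

- No photon-transport or multiple-scattering physics: τc is a
  phenomenological dynamics parameter; no absolute stiffness (Pa) is
  inferred.
- Spatially independent pixels (no speckle grain size, no PSF).
- Single-exponential g2 only; non-Brownian/viscoelastic dynamics are out
  of scope, and the ML model explicitly does not generalise to them.
- No image co-registration: difference maps and mirrored ROIs assume
  aligned inputs.
- The ML-DCS regressor is bias/variance-tuned by its prior: it is an
  imaging detector, not an unbiased per-pixel meter of τc.
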