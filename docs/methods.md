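# Methods

## The tracking problem

Scalp EEG rhythms in the alpha/mu range (~8–13 Hz) are not spectrally
static: their instantaneous frequency and magnitude drift over the
course of a recording session, and the direction and topography of that
drift carry physiological information (sensorimotor engagement,
vigilance, fatigue).  `oscitrack` estimates these drifts per channel by
tracking each bandpass-filtered channel with an extended Kalman filter
(EKF) over a reparametrized AR(2) / damped-oscillator state space, then
fitting robust session-long linear trends to the tracked trajectories.

## State-space model

Each narrowband channel is modelled as the output of a damped linear
oscillator with slowly drifting frequency and damping.  With a
quadrature state pair `x_t = (x1, x2)`:

    x_t = rho_t · R(omega_t) · x_{t-1} + w_t,     w_t ~ N(0, q_osc I2)
    y_t = x1_t + v_t,                             v_t ~ N(0, r_meas)

`R(omega)` is a 2×2 rotation by `omega` radians/sample and
`rho ∈ (0,1)` the pole radius.  Eliminating `x2` shows this is the
rotation-form realization of an AR(2) with complex pole pair
`rho·exp(±i·omega)` (coefficients `a1 = 2·rho·cos omega`,
`a2 = −rho²`; see `pole_to_ar2` / `ar2_to_pole`).  The rotation form is
used because its two states are a quadrature pair, so the Euclidean
norm `||x_t||` is the amplitude envelope of the rhythm — that norm is
what the package reports as instantaneous *magnitude* (a.u.).  Reported
instantaneous *frequency* is `omega_t · fs / 2π` (Hz).

`omega` and `rho` evolve as Gaussian random walks (variances `q_freq`,
`q_damp`).  The walks live in unconstrained coordinates

    u = log(omega / (π − omega)),      v = logit(rho)

so that no noise realization can push `omega` out of `(0, π)` or `rho`
out of `(0, 1)`; the filter linearizes the transition with its analytic
Jacobian in these coordinates at every step.  The covariance update
uses the Joseph form followed by symmetrization; non-finite
intermediates raise a divergence error carrying the step index.
Initialization: `x0 = 0`, `P0 = p0_scale · I`, `omega0` from `f_init`,
`rho0 = rho_init`.  The Frobenius norm of the 4×4 state covariance is
emitted per sample as an estimator-uncertainty feature.

Design choices that were genuinely open:

- **Magnitude definition.** The state norm `||x_t||` (envelope of the
  quadrature pair) rather than `|x1|` or a spectral peak height; the
  norm is phase-invariant and available at every sample.
- **Constraint handling.** Logit-space random walks rather than
  clipping; clipping distorts the Jacobian at the boundary, the
  transform does not.
- **Burn-in.** The first 2 s of every tracked trajectory are *flagged*
  (not removed).  Trend fits include all samples by default, matching
  session-long fits on real data; the flag lets callers exclude the
  transient when they need to.

## Hyperparameter tuning

The seven hyperparameters (`q_osc`, `q_freq`, `q_damp`, `r_meas`,
`f_init`, `rho_init`, `p0_scale`) are tuned per recording and band on
the first 60 s by minimizing the mean squared one-step innovation
averaged over channels, with a small genetic algorithm: population 40,
30 generations, tournament selection (k = 3), uniform crossover (rate
0.9), Gaussian mutation (sd = 10 % of the box width, per-gene rate
0.2), elitism 2.  Variance-like parameters are searched in log10 space
inside fixed boxes (e.g. `q_osc ∈ [1e−6, 1]`, `r_meas ∈ [1e−4, 1e2]`);
`f_init` is confined to the analysis band.  Candidates that diverge
receive a large finite penalty (1e9) so the search can continue.
Diagnosed caveat: `f_init` is only weakly identified, because the
frequency state adapts within the tuning window — the tuned *filter*
recovers the oscillation frequency essentially exactly even when the
tuned `f_init` itself is far from it (tests assert the former).

## Analytic-signal baseline

The comparison tracker bandpasses the channel (identical zero-phase
order-5 Butterworth), takes the analytic signal, and reports the
envelope as magnitude and the scaled first difference of the unwrapped
phase as frequency.  Phase slips in noise produce IF spikes, so the IF
trajectory is median-filtered with a 0.5 s window (configurable,
disable for ablation); the first and last 1 s are flagged as edge
transients, mirroring the EKF burn-in flag.

## Session-trend statistics

- **Robust slope.** Trajectories are z-scored, regressed on time in
  hours by IRLS with Tukey bisquare weights (tuning constant 4.685, MAD
  residual scale, tol 1e−6, max 50 iterations; the implementation wraps
  statsmodels RLM), and slope/intercept are mapped back to native units
  (Hz/hour or a.u./hour) via the trajectory's standard deviation and
  mean.  Constant trajectories return slope 0 with p = 1 and a
  degeneracy flag.  Trajectories are block-averaged to 4 Hz before
  fitting: session trends live on the minutes scale, block means leave
  the slope unchanged, and the averaging keeps the IRLS cheap.  The
  reported p-values treat samples as independent (the convention for
  these session fits); they are anticonservative under autocorrelation,
  which is why the false-positive calibration test uses white noise.
- **FDR.** Benjamini–Hochberg step-up across channels (level 0.05 by
  default); percentage maps count subjects whose corrected fit is
  significant *and* positive.
- **Slope-change likelihood.** Per channel, the single changepoint
  minimizing the total SSE of a two-piece linear fit (prefix-sum scan,
  O(n); the two-piece criterion targets slope breaks, not mean shifts).
  Breakpoints are marked in binary vectors, convolved with a noncausal
  Gaussian kernel, summed over channels and normalized to unit sum over
  the session.  The kernel bandwidth is sigma = 3 min (the natural
  reading of a "3-minute" kernel width; configurable).
- **Endpoints.** Session initial/final values are read off the fitted
  trend at t = 0 and t = T rather than from raw samples.
- **Band grid.** The frequency-resolved scan repeats
  bandpass → tune → track → slope per cell over all valid
  `(f_min, f_max)` pairs (1–30 Hz by default), averaging slopes over
  the selected channels; unstable or failing cells are NaN with a log
  entry.
- **Welch PSD.** 5 s Hamming windows at 50 % overlap by default, with
  optional normalization by total power in 0.5–60 Hz.

## Task-relevance statistics

Band selection computes the absolute Pearson correlation between the
tracked magnitude and a sample-aligned task reference per candidate
band and picks the band with the highest mean |r| (ties: narrowest
band, then lowest `f_min`).  Binary references are aligned by
zero-order hold, continuous kinematics by linear interpolation.  The
feature comparison contrasts four features — tracked frequency, tracked
magnitude, covariance Frobenius norm, and band log-power
`log10(x² + 1e−12)` — by each subject's maximum |r| over channels,
with pairwise Wilcoxon signed-rank tests (exact for n ≤ 25 without
ties, else normal approximation with continuity correction) under BH
correction.  Spatial statistics: paired t-tests on subject-wise slope
differences for every channel pair with Cohen's dz for surviving
pairs, and across-participant Pearson coupling of slopes for every
cross-ROI channel pair, BH-corrected jointly, averaged per ROI pair
(empty cells reported as absent, not zero).

## Synthetic validation data

Each synthetic channel is a weighted sum of unit-variance pink (1/f)
noise (spectral 1/√f shaping of white Gaussian noise) and three
band-limited oscillations: theta (6 Hz), alpha/mu (10 Hz), beta
(20 Hz).  The alpha component carries the imposed session-long drifts:
instantaneous frequency `f0 + freq_slope · t_hours` and envelope
`a0 + mag_slope · t_hours`, with per-channel slopes laid out as smooth
spatial gradients spanning ±1.5 Hz/hour and ±3 a.u./hour over a
virtual channel grid.  Defaults: 64 channels, 25 min at 120 Hz, alpha
base amplitude 2 a.u., theta/beta amplitudes 0.7/0.5, pink-noise weight
1, all with ±20 % per-channel spread.

Oscillations are realized as AM/FM sinusoids (phase = cumulative
integral of the instantaneous frequency) rather than simulated
time-varying AR(2) processes, so the ground truth is closed-form for
both frequency and envelope.  For realism the instantaneous frequency
additionally wanders as a band-limited Ornstein–Uhlenbeck process
(alpha: sd 0.6 Hz, correlation time 20 s — the scale of
moment-to-moment alpha-peak variability) and the envelope waxes and
wanes multiplicatively (OU, sd 0.25, 5 s — rhythm bursting).  Ground
truth stores the deterministic ramps; the realized frequency jitter is
stored separately.

What the generator does *not* emulate: volume conduction and channel
correlation, artifacts (blinks, EMG, line noise), non-stationary task
structure, and 1/f-slope variation.  Passing the synthetic suite
therefore demonstrates correct recovery of imposed narrowband drifts in
realistic in-band noise — not robustness to artifacts or to spatially
correlated backgrounds.

A consequence of the jitter realism deserves emphasis: the realized IF
trajectory differs from the deterministic ramp by the jitter, whose own
fitted slope has standard deviation ≈ sd·sqrt(12·tau/T³)·3600 ≈
0.96 Hz/hour for a 25 min session.  That is an information floor no
tracker can beat — it caps the achievable channel-map correlation with
the deterministic truth slopes at roughly r ≈ 0.67 under the default
conditions, and both trackers sit near that ceiling (EKF slightly above
the analytic-signal baseline).  The corresponding floor for magnitude
is much lower (≈ 0.24 a.u./hour against a ±3 a.u./hour map), so
magnitude-map correlations reach ≈ 0.98.

## Problem sizes and numerics

The slope-recovery suite evaluates 5 seeded datasets of 64 channels ×
25 min (the package's standard validation size; the generator yields
arbitrarily many).  The EKF inner loop is a numba kernel
(~6·10⁶ steps/s on one core); GA tuning of one band costs ~1.5 min per
64-channel dataset and full-session tracking ~2 s.  All randomness
flows from explicit integer seeds (`numpy.random.default_rng`); suite
dataset seeds are derived as `base_seed·1000 + i`.  Determinism of the
full pipeline given (inputs, config, seed) is asserted byte-for-byte in
the tests.

## Known limitations

- Single-oscillator model: one pole pair per band; broadband multi-pole
  tracking and RTS smoothing are out of scope.
- Robust-fit p-values ignore autocorrelation (see above).
- The GA tunes one shared hyperparameter set per (recording, band), not
  per channel.
- ICA artifact removal is a pass-through hook; clean your data first.
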