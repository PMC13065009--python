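# oscitrack

Extended-Kalman-filter oscillator tracking of EEG alpha/mu rhythms —
instantaneous frequency and magnitude per channel — plus the
session-trend statistics needed to study how those rhythms drift over a
recording: robust slope topographies, slope-change likelihood, band
scans, and task-relevance statistics.  Built for EEG/BCI researchers
who want to quantify within-session spectral drift (mu acceleration,
posterior alpha slowing, magnitude growth) rather than assume fixed
bands.

## The model

Each bandpass-filtered channel is treated as the output of a damped
linear oscillator whose frequency and damping drift slowly.  With a
quadrature state pair `x_t`:

```
x_t = ρ_t · R(ω_t) · x_{t−1} + w_t,     w_t ~ N(0, q_osc·I₂)
y_t = [1 0]·x_t + v_t,                  v_t ~ N(0, r_meas)
```

`R(ω)` is a rotation by ω radians/sample, so this is the rotation form
of a reparametrized AR(2) with pole pair `ρ·e^{±iω}` (`a1 = 2ρcos ω`,
`a2 = −ρ²`).  ω and ρ evolve as random walks in logit-transformed
coordinates (they can never leave `(0, π)` / `(0, 1)`), and an extended
Kalman filter with analytic Jacobians estimates everything jointly.
Per sample the tracker emits instantaneous frequency `ω·fs/2π` (Hz),
magnitude `‖x_t‖` (the envelope, a.u.), the Frobenius norm of the state
covariance (an uncertainty feature that is itself task-relevant), and
the one-step innovation.  Hyperparameters are tuned per recording and
band by a genetic algorithm on the first 60 s (mean squared innovation
across channels).  Session-long drifts are then summarized by robust
(Tukey bisquare) linear fits in Hz/hour and a.u./hour, with
Benjamini–Hochberg FDR across channels.  An analytic-signal (Hilbert)
tracker provides the baseline comparison, and a synthetic-EEG generator
with known per-channel drift slopes provides ground-truth validation.
See `docs/methods.md` for the full account.

## Worked example

`examples/track_drifting_rhythm.py` builds one noisy channel whose
10 Hz rhythm accelerates by +1 Hz/hour and whose envelope grows by
+1.5 a.u./hour, tunes the EKF on the first minute, tracks 20 minutes
and fits robust trends:

```
$ python examples/track_drifting_rhythm.py
tuned: q_osc=3.11e-03  r_meas=1.09e-04  f_init=7.17 Hz
frequency slope: +0.830 Hz/hour  (truth +1.000), p=8.5e-149
magnitude slope: +1.464 a.u./hour (truth +1.500), p=6.7e-140
```

The fitted slopes recover the imposed drifts (the frequency slope is
attenuated toward the rhythm's own moment-to-moment frequency wander,
which is part of the simulation); both trends are significant.  The
other examples cover the EKF-vs-Hilbert benchmark, the full pipeline
with slope maps and change likelihood, the four-feature task-relevance
comparison, and the band-grid scan — each prints its numbers with a
line on how to read them.

From the shell, the same stages are available as thin commands:
`oscitrack simulate|track|trends|bandscan|compare-features|benchmark|concat`.

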