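"""Synthetic multichannel EEG with known session-long spectral drifts.

Each channel is a weighted sum of band-limited components — pink (1/f)
noise plus theta, alpha/mu and beta oscillations — and the alpha
component carries an imposed linear session-long drift in instantaneous
frequency (Hz/hour) and envelope (a.u./hour) that differs smoothly
across channels.  The per-channel drift slopes are the ground truth the
trackers are validated against.

Realism choices (see docs/methods.md): oscillations are AM/FM sinusoids
with closed-form truth rather than simulated time-varying AR(2)
processes; instantaneous frequency additionally wanders as a band-limited
Ornstein-Uhlenbeck process (sd 0.6 Hz, correlation time 20 s for alpha),
and amplitude waxes and wanes multiplicatively (sd 0.25, 5 s), emulating
the moment-to-moment variability and bursting of scalp rhythms.  Ground
truth stores the deterministic ramps; jitter is recorded separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signals import SignalSet

__all__ = [
    "BandComponent", "SyntheticConfig", "GroundTruth", "SyntheticDataset",
    "pink_noise", "ou_process", "drifting_oscillation", "generate_dataset",
    "generate_suite", "default_config", "truth_table",
]


@dataclass(frozen=True)
class BandComponent:
    """A band-limited component: center frequency, bandwidth, base amplitude."""

    center: float      # Hz
    bandwidth: float   # Hz (full width; frequency jitter stays well inside)
    amplitude: float   # a.u.

    @property
    def edges(self) -> tuple[float, float]:
        return (self.center - self.bandwidth / 2, self.center + self.bandwidth / 2)


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the validation conditions.

    64 channels, 25 min at 120 Hz; theta at 6 Hz, alpha/mu at 10 Hz,
    beta at 20 Hz over a 1/f background.  Per-channel alpha drift slopes
    form smooth spatial gradients spanning +-1.5 Hz/hour (frequency) and
    +-3 a.u./hour (envelope); pass explicit ``freq_slopes`` /
    ``mag_slopes`` arrays to override.
    """

    n_channels: int = 64
    duration: float = 1500.0          # s
    fs: float = 120.0
    theta: BandComponent = field(default_factory=lambda: BandComponent(6.0, 2.0, 0.7))
    alpha: BandComponent = field(default_factory=lambda: BandComponent(10.0, 4.0, 2.0))
    beta: BandComponent = field(default_factory=lambda: BandComponent(20.0, 4.0, 0.5))
    noise_weight: float = 1.0         # pink-noise amplitude (unit-variance base)
    amp_variation: float = 0.2        # per-channel spread of component amplitudes
    freq_slope_span: float = 1.5      # Hz/hour, gradient half-range
    mag_slope_span: float = 3.0       # a.u./hour, gradient half-range
    freq_slopes: np.ndarray | None = None   # per-channel Hz/hour override
    mag_slopes: np.ndarray | None = None    # per-channel a.u./hour override
    freq_jitter_sd: float = 0.6       # Hz, alpha IF wander
    freq_jitter_tau: float = 20.0     # s
    amp_jitter_sd: float = 0.25       # fractional envelope wander
    amp_jitter_tau: float = 5.0       # s
    seed: int = 0
    store_trajectories: bool = True

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def validate(self) -> None:
        errors = []
        if self.n_channels < 1:
            errors.append("n_channels must be >= 1")
        if self.duration <= 0:
            errors.append("duration must be positive")
        top = max(c.edges[1] for c in (self.theta, self.alpha, self.beta))
        if self.fs <= 2 * top:
            errors.append(f"fs={self.fs} must exceed twice the highest band "
                          f"edge ({top} Hz)")
        for name in ("noise_weight", "freq_jitter_sd", "amp_jitter_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for comp in ("theta", "alpha", "beta"):
            if getattr(self, comp).amplitude < 0:
                errors.append(f"{comp}.amplitude must be >= 0")
        for name in ("freq_slopes", "mag_slopes"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.n_channels,):
                    errors.append(f"{name} must have exactly {self.n_channels} "
                                  f"entries, got shape {arr.shape}")
                elif not np.all(np.isfinite(arr)):
                    errors.append(f"{name} contains non-finite entries")
        if errors:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(errors))


@dataclass
class GroundTruth:
    """Per-channel imposed alpha drifts plus per-sample truth trajectories.

    ``true_freq`` / ``true_env`` are the deterministic ramps
    ``f0 + freq_slope * t_hours`` and ``a0 + mag_slope * t_hours``;
    the stochastic frequency wander actually applied is stored
    separately in ``freq_jitter``.
    """

    labels: list[str]
    freq_slope: np.ndarray            # Hz/hour
    mag_slope: np.ndarray             # a.u./hour
    f0: np.ndarray                    # Hz at t=0
    a0: np.ndarray                    # a.u. at t=0
    true_freq: np.ndarray | None = None     # (n_ch, n) float32
    true_env: np.ndarray | None = None      # (n_ch, n) float32
    freq_jitter: np.ndarray | None = None   # (n_ch, n) float32


@dataclass
class SyntheticDataset:
    signals: SignalSet
    truth: GroundTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def pink_noise(n: int, seed) -> np.ndarray:
    """Zero-mean, unit-variance 1/f noise via spectral 1/sqrt(f) shaping.

    The log-log PSD slope over the analysis range is -1 by construction.
    """
    if n < 256:
        raise ValueError(f"n must be >= 256, got {n}")
    rng = _rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=n)
    x -= x.mean()
    return x / x.std()


def ou_process(n: int, sd: float, tau_samples: float, rng) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck (band-limited, zero-mean) series."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = math.exp(-1.0 / tau_samples)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    e = innov_sd * rng.standard_normal(n)
    e[0] = sd * rng.standard_normal()      # stationary start
    x, _ = lfilter([1.0], [1.0, -a], e, zi=np.zeros(1))
    return x


@dataclass
class DriftingTone:
    series: np.ndarray
    true_freq: np.ndarray     # deterministic ramp, Hz
    true_env: np.ndarray      # deterministic ramp, a.u.
    freq_jitter: np.ndarray   # additive IF wander actually applied, Hz


def drifting_oscillation(f0: float, f_slope: float, a0: float, a_slope: float,
                         fs: float, n: int, seed,
                         freq_jitter_sd: float = 0.0,
                         freq_jitter_tau: float = 20.0,
                         amp_jitter_sd: float = 0.0,
                         amp_jitter_tau: float = 5.0) -> DriftingTone:
    """AM/FM sinusoid with linear drifts in frequency and envelope.

    Instantaneous frequency is ``f0 + f_slope * t_hours`` (plus optional
    zero-mean band-limited jitter); the envelope is
    ``a0 + a_slope * t_hours`` (plus optional multiplicative jitter).
    Phase is the cumulative integral of the instantaneous frequency, so
    the analytic-signal IF of the noiseless series is the truth itself.
    """
    rng = _rng(seed)
    t_h = np.arange(n) / fs / 3600.0
    f_det = f0 + f_slope * t_h
    if f_det.min() <= 0 or f_det.max() >= fs / 2:
        raise ValueError(
            f"frequency ramp {f_det.min():.3g}..{f_det.max():.3g} Hz leaves "
            f"(0, fs/2) at fs={fs}"
        )
    env = a0 + a_slope * t_h
    if env.min() <= 0:
        raise ValueError("magnitude drift underflow: envelope reaches zero")

    jitter = ou_process(n, freq_jitter_sd, freq_jitter_tau * fs, rng)
    f_inst = np.clip(f_det + jitter, 0.1, fs / 2 - 0.1)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    phase += rng.uniform(0, 2 * np.pi)

    amp = env.copy()
    if amp_jitter_sd > 0:
        wander = ou_process(n, amp_jitter_sd, amp_jitter_tau * fs, rng)
        amp = env * np.maximum(1.0 + wander, 0.05)
    return DriftingTone(series=amp * np.cos(phase), true_freq=f_det,
                        true_env=env, freq_jitter=f_inst - f_det)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _gradient_maps(cfg: SyntheticConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Smooth spatial slope gradients over a virtual channel grid.

    Frequency slopes ramp along grid columns, magnitude slopes along
    rows, each spanning the configured +-span with a small seeded
    perturbation so the topographies are not perfectly collinear.
    """
    n = cfg.n_channels
    ncols = int(math.ceil(math.sqrt(n)))
    idx = np.arange(n)
    col = idx % ncols
    row = idx // ncols
    nrows = max(row.max(), 1)
    fx = 2.0 * col / max(ncols - 1, 1) - 1.0
    fy = 2.0 * row / nrows - 1.0
    freq = cfg.freq_slope_span * np.clip(fx + 0.1 * rng.standard_normal(n), -1, 1)
    mag = cfg.mag_slope_span * np.clip(fy + 0.1 * rng.standard_normal(n), -1, 1)
    return freq, mag


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Deterministically (given ``cfg.seed``) synthesize one session."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, n_ch, fs = cfg.n_samples, cfg.n_channels, cfg.fs
    t_h = np.arange(n) / fs / 3600.0

    if cfg.freq_slopes is not None and cfg.mag_slopes is not None:
        freq_slopes = np.asarray(cfg.freq_slopes, dtype=float)
        mag_slopes = np.asarray(cfg.mag_slopes, dtype=float)
    else:
        freq_slopes, mag_slopes = _gradient_maps(cfg, rng)
        if cfg.freq_slopes is not None:
            freq_slopes = np.asarray(cfg.freq_slopes, dtype=float)
        if cfg.mag_slopes is not None:
            mag_slopes = np.asarray(cfg.mag_slopes, dtype=float)

    alpha_lo, alpha_hi = cfg.alpha.edges
    span = 0.2 * cfg.alpha.bandwidth / 2  # per-channel spread of f0 around center
    f0 = cfg.alpha.center + rng.uniform(-span, span, size=n_ch)
    vary = 1.0 + cfg.amp_variation * rng.uniform(-1, 1, size=n_ch)
    a0 = cfg.alpha.amplitude * vary
    w_theta = cfg.theta.amplitude * (
        1.0 + cfg.amp_variation * rng.uniform(-1, 1, size=n_ch))
    w_beta = cfg.beta.amplitude * (
        1.0 + cfg.amp_variation * rng.uniform(-1, 1, size=n_ch))
    w_pink = cfg.noise_weight * (
        1.0 + cfg.amp_variation * rng.uniform(-1, 1, size=n_ch))

    dur_h = cfg.duration / 3600.0
    f_end = f0 + freq_slopes * dur_h
    bad = (np.minimum(f0, f_end) < alpha_lo) | (np.maximum(f0, f_end) > alpha_hi)
    if np.any(bad):
        raise ValueError(
            "invalid SyntheticConfig: ground-truth alpha frequency leaves "
            f"the alpha band on channels {np.flatnonzero(bad).tolist()}"
        )

    data = np.empty((n_ch, n))
    labels = [f"ch{i:02d}" for i in range(n_ch)]
    store = cfg.store_trajectories
    true_freq = np.empty((n_ch, n), dtype=np.float32) if store else None
    true_env = np.empty((n_ch, n), dtype=np.float32) if store else None
    freq_jit = np.empty((n_ch, n), dtype=np.float32) if store else None

    for c in range(n_ch):
        theta_jit = min(0.5, cfg.theta.bandwidth / 6)
        beta_jit = min(0.8, cfg.beta.bandwidth / 6)
        theta = drifting_oscillation(
            cfg.theta.center, 0.0, max(w_theta[c], 1e-12), 0.0, fs, n, rng,
            freq_jitter_sd=theta_jit, freq_jitter_tau=cfg.freq_jitter_tau,
            amp_jitter_sd=cfg.amp_jitter_sd, amp_jitter_tau=cfg.amp_jitter_tau)
        beta = drifting_oscillation(
            cfg.beta.center, 0.0, max(w_beta[c], 1e-12), 0.0, fs, n, rng,
            freq_jitter_sd=beta_jit, freq_jitter_tau=cfg.freq_jitter_tau,
            amp_jitter_sd=cfg.amp_jitter_sd, amp_jitter_tau=cfg.amp_jitter_tau)
        alpha = drifting_oscillation(
            f0[c], freq_slopes[c], a0[c], mag_slopes[c], fs, n, rng,
            freq_jitter_sd=cfg.freq_jitter_sd,
            freq_jitter_tau=cfg.freq_jitter_tau,
            amp_jitter_sd=cfg.amp_jitter_sd, amp_jitter_tau=cfg.amp_jitter_tau)
        noise = w_pink[c] * pink_noise(n, rng) if w_pink[c] > 0 else 0.0
        data[c] = noise + theta.series + alpha.series + beta.series
        if store:
            true_freq[c] = alpha.true_freq
            true_env[c] = alpha.true_env
            freq_jit[c] = alpha.freq_jitter

    signals = SignalSet(data, fs, labels)
    truth = GroundTruth(labels=labels, freq_slope=freq_slopes,
                        mag_slope=mag_slopes, f0=f0, a0=a0,
                        true_freq=true_freq, true_env=true_env,
                        freq_jitter=freq_jit)
    return SyntheticDataset(signals=signals, truth=truth, config=cfg)


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    return replace(SyntheticConfig(seed=seed), **overrides)


def generate_suite(n_datasets: int = 20, base_seed: int = 0,
                   template: SyntheticConfig | None = None):
    """Yield ``n_datasets`` independently seeded datasets (lazy)."""
    template = template or SyntheticConfig()
    for i in range(n_datasets):
        seed = (base_seed * 1000 + i) % (2**31 - 1)
        yield generate_dataset(replace(template, seed=seed))


def truth_table(ds: SyntheticDataset):
    """Ground-truth slopes as a tidy table (channel, freq_slope, mag_slope)."""
    import pandas as pd

    return pd.DataFrame({
        "channel": ds.truth.labels,
        "freq_slope": ds.truth.freq_slope,
        "mag_slope": ds.truth.mag_slope,
    })
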