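"""Damped-oscillator state space and the extended Kalman filter tracker.

Model
-----
A narrowband rhythm is modelled as the output of a damped linear
oscillator whose frequency and damping drift slowly.  With a quadrature
state pair ``x_t = (x1, x2)``::

    x_t = rho_t * R(omega_t) @ x_{t-1} + w_t,      w_t ~ N(0, q_osc * I_2)
    y_t = x1_t + v_t,                              v_t ~ N(0, r_meas)

where ``R`` is a 2x2 rotation by ``omega`` radians/sample and
``rho in (0, 1)`` the pole radius.  This is the rotation-form
realization of a reparametrized AR(2) with complex pole pair
``rho * exp(+-i*omega)`` (see :func:`pole_to_ar2`).  ``omega`` and
``rho`` evolve as Gaussian random walks in unconstrained coordinates

    u = log(omega / (pi - omega)),   v = logit(rho)

so they can never leave ``(0, pi)`` / ``(0, 1)``.  The EKF linearizes
the transition with its analytic Jacobian at each step and updates the
4x4 covariance in Joseph form, symmetrizing afterwards.

Outputs per sample: instantaneous frequency ``omega * fs / 2pi`` (Hz),
magnitude ``||x||_2`` (the envelope of the quadrature pair, a.u.), the
Frobenius norm of the state covariance (estimator-uncertainty feature),
and the one-step innovation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .signals import SignalSet

__all__ = [
    "EKFHyperParams", "EKFState", "TrackResult", "TrackingDiverged",
    "pole_to_ar2", "ar2_to_pole", "ekf_step", "track_signal",
    "covariance_frobenius", "prediction_error_cost",
]

DEFAULT_BURN_IN_S = 2.0
#: Finite penalty returned by the tuning cost when a candidate diverges,
#: so a stochastic optimizer can keep going.
DIVERGENCE_PENALTY = 1e9


class TrackingDiverged(RuntimeError):
    """EKF produced a non-finite state; carries the offending step index."""

    def __init__(self, step: int, channel: str | int | None = None):
        self.step = step
        self.channel = channel
        where = f" on channel {channel}" if channel is not None else ""
        super().__init__(f"EKF diverged at step {step}{where}")


# ---------------------------------------------------------------------------
# AR(2) <-> pole parameterization
# ---------------------------------------------------------------------------

def pole_to_ar2(rho: float, omega: float) -> tuple[float, float]:
    """AR(2) coefficients of the complex pole pair ``rho * exp(+-i*omega)``.

    ``a1 = 2 rho cos(omega)``, ``a2 = -rho**2`` so that
    ``y_t = a1 y_{t-1} + a2 y_{t-2} + e_t`` has poles at the stated pair.
    """
    if not (0 < rho < 1):
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    if not (0 < omega < math.pi):
        raise ValueError(f"omega must lie in (0, pi), got {omega}")
    return 2.0 * rho * math.cos(omega), -rho * rho


def ar2_to_pole(a1: float, a2: float) -> tuple[float, float]:
    """Inverse of :func:`pole_to_ar2`; requires a complex-conjugate pair.

    Raises
    ------
    ValueError
        If ``a1**2 + 4*a2 >= 0`` (real poles: non-oscillatory AR(2)).
    """
    if a1 * a1 + 4.0 * a2 >= 0:
        raise ValueError(
            f"non-oscillatory AR(2): a1^2 + 4 a2 = {a1 * a1 + 4.0 * a2:g} >= 0"
        )
    rho = math.sqrt(-a2)
    omega = math.acos(a1 / (2.0 * rho))
    return rho, omega


# ---------------------------------------------------------------------------
# Hyperparameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EKFHyperParams:
    """Tunable EKF noise / initialization parameters.

    Parameters
    ----------
    q_osc : float
        Process-noise variance of each oscillator state (a.u.^2/sample).
    q_freq, q_damp : float
        Random-walk variances of the frequency and damping states, in the
        unconstrained (log-odds) coordinates.
    r_meas : float
        Measurement-noise variance (a.u.^2).
    f_init : float
        Initial frequency (Hz).
    rho_init : float
        Initial damping (pole radius), in (0, 1).
    p0_scale : float
        Initial state-uncertainty scale: ``P0 = p0_scale * I``.
    """

    q_osc: float
    q_freq: float
    q_damp: float
    r_meas: float
    f_init: float
    rho_init: float
    p0_scale: float

    def __post_init__(self):
        for name in ("q_osc", "q_freq", "q_damp", "r_meas", "p0_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.rho_init < 1):
            raise ValueError(f"rho_init must lie in (0, 1), got {self.rho_init}")
        if not self.f_init > 0:
            raise ValueError(f"f_init must be positive, got {self.f_init}")

    def validate_band(self, f_min: float, f_max: float) -> None:
        if not (f_min <= self.f_init <= f_max):
            raise ValueError(
                f"f_init={self.f_init} outside band [{f_min}, {f_max}]"
            )


@dataclass
class EKFState:
    """Filter state: oscillator pair, angular frequency, damping, covariance.

    ``P`` is ordered as ``(x1, x2, u, v)`` where ``u``/``v`` are the
    unconstrained frequency/damping coordinates.
    """

    x: np.ndarray          # (2,) oscillator phase-space pair, a.u.
    omega: float           # rad/sample, in (0, pi)
    rho: float             # damping, in (0, 1)
    P: np.ndarray          # (4, 4) covariance in (x1, x2, u, v) coordinates

    @classmethod
    def initial(cls, hp: EKFHyperParams, fs: float) -> "EKFState":
        omega = 2.0 * math.pi * hp.f_init / fs
        if not (0 < omega < math.pi):
            raise ValueError(f"f_init={hp.f_init} Hz not below Nyquist at fs={fs}")
        return cls(x=np.zeros(2), omega=omega, rho=hp.rho_init,
                   P=hp.p0_scale * np.eye(4))


@dataclass
class TrackResult:
    """Per-sample tracking trajectories for one channel.

    ``burn_in`` flags the initial transient (and, for the analytic-signal
    tracker, filter edges); downstream trend fits may exclude flagged
    samples but include everything by default.
    """

    t: np.ndarray          # seconds
    freq: np.ndarray       # Hz, in (0, fs/2)
    mag: np.ndarray        # a.u., >= 0
    cov_frob: np.ndarray   # Frobenius norm of P, >= 0
    innov: np.ndarray      # one-step prediction residuals
    fs: float
    burn_in: np.ndarray    # bool mask, True where estimates are transient

    def __post_init__(self):
        n = len(self.t)
        for name in ("freq", "mag", "cov_frob", "innov", "burn_in"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != time axis length")


def covariance_frobenius(P: np.ndarray) -> float:
    """Frobenius norm of a square covariance matrix."""
    P = np.asarray(P)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"P must be square, got shape {P.shape}")
    return float(np.sqrt(np.sum(P * P)))


# ---------------------------------------------------------------------------
# Jitted kernel (single implementation shared by ekf_step and track_signal)
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=False)
def _ekf_step_core(z, P, y, q_osc, q_freq, q_damp, r_meas, F, W, Pp):
    """One predict+update in unconstrained coordinates.

    ``z = (x1, x2, u, v)`` and ``P`` are updated in place; ``F``, ``W``,
    ``Pp`` are caller-provided 4x4 scratch buffers (no per-step
    allocation).  Returns (innovation, ok).
    """
    x1, x2, u, v = z[0], z[1], z[2], z[3]
    # constrained values at the linearization point
    su = 1.0 / (1.0 + math.exp(-u))
    omega = math.pi * su
    rho = 1.0 / (1.0 + math.exp(-v))
    c = math.cos(omega)
    s = math.sin(omega)

    # nonlinear prediction: rotate+damp the pair, random-walk u, v
    rx1 = c * x1 - s * x2
    rx2 = s * x1 + c * x2
    x1p = rho * rx1
    x2p = rho * rx2

    # analytic Jacobian of the transition wrt (x1, x2, u, v);
    # bottom 2x2 block is the identity (random walks)
    domega_du = math.pi * su * (1.0 - su)
    drho_dv = rho * (1.0 - rho)
    F[0, 0] = rho * c
    F[0, 1] = -rho * s
    F[0, 2] = rho * (-s * x1 - c * x2) * domega_du
    F[0, 3] = rx1 * drho_dv
    F[1, 0] = rho * s
    F[1, 1] = rho * c
    F[1, 2] = rho * (c * x1 - s * x2) * domega_du
    F[1, 3] = rx2 * drho_dv

    # Pp = F P F^T + Q, exploiting F = [[F12, F34], [0, I]]
    for i in range(4):
        for j in range(4):
            if i < 2:
                W[i, j] = (F[i, 0] * P[0, j] + F[i, 1] * P[1, j]
                           + F[i, 2] * P[2, j] + F[i, 3] * P[3, j])
            else:
                W[i, j] = P[i, j]
    for i in range(4):
        for j in range(4):
            if j < 2:
                Pp[i, j] = (W[i, 0] * F[j, 0] + W[i, 1] * F[j, 1]
                            + W[i, 2] * F[j, 2] + W[i, 3] * F[j, 3])
            else:
                Pp[i, j] = W[i, j]
    Pp[0, 0] += q_osc
    Pp[1, 1] += q_osc
    Pp[2, 2] += q_freq
    Pp[3, 3] += q_damp

    # scalar measurement y = x1 + noise
    innov = y - x1p
    S = Pp[0, 0] + r_meas
    if not (math.isfinite(innov) and math.isfinite(S) and S > 0.0):
        return innov, False

    k0 = Pp[0, 0] / S
    k1 = Pp[1, 0] / S
    k2 = Pp[2, 0] / S
    k3 = Pp[3, 0] / S
    z[0] = x1p + k0 * innov
    z[1] = x2p + k1 * innov
    z[2] = u + k2 * innov
    z[3] = v + k3 * innov

    # Joseph form (I-KH) Pp (I-KH)^T + K r K^T with H = e1^T, unrolled:
    # Pn = Pp - K row0 - col0 K^T + K K^T (Pp00 + r); then symmetrize.
    K = W[0]          # reuse scratch row
    K[0] = k0; K[1] = k1; K[2] = k2; K[3] = k3
    ok = True
    for i in range(4):
        for j in range(4):
            P[i, j] = (Pp[i, j] - K[i] * Pp[0, j] - Pp[i, 0] * K[j]
                       + K[i] * K[j] * S)
    for i in range(4):
        for j in range(i, 4):
            m = 0.5 * (P[i, j] + P[j, i])
            P[i, j] = m
            P[j, i] = m
            if not math.isfinite(m):
                ok = False
    for i in range(4):
        if not math.isfinite(z[i]):
            ok = False
    return innov, ok


@njit(cache=False)
def _ekf_run_jit(y, u0, v0, p0_scale, q_osc, q_freq, q_damp, r_meas, fs):
    """Filter a whole series.  Returns (freq, mag, cov_frob, innov, bad_step).

    ``bad_step`` is -1 on success, else the index of the diverging sample."""
    n = y.shape[0]
    freq = np.empty(n)
    mag = np.empty(n)
    frob = np.empty(n)
    innov = np.empty(n)
    z = np.zeros(4)
    z[2] = u0
    z[3] = v0
    P = p0_scale * np.eye(4)
    F = np.eye(4)
    W = np.empty((4, 4))
    Pp = np.empty((4, 4))
    for t in range(n):
        e, ok = _ekf_step_core(z, P, y[t], q_osc, q_freq, q_damp, r_meas,
                               F, W, Pp)
        if not ok:
            return freq, mag, frob, innov, t
        freq[t] = fs * 0.5 / (1.0 + math.exp(-z[2]))   # omega * fs / 2pi
        mag[t] = math.hypot(z[0], z[1])
        acc = 0.0
        for i in range(4):
            for j in range(4):
                acc += P[i, j] * P[i, j]
        frob[t] = math.sqrt(acc)
        innov[t] = e
    return freq, mag, frob, innov, -1


@njit(cache=False)
def _ekf_cost_jit(Y, u0, v0, p0_scale, q_osc, q_freq, q_damp, r_meas, fs,
                  penalty):
    """Mean over channels of mean squared one-step innovations."""
    C = Y.shape[0]
    total = 0.0
    for ch in range(C):
        _, _, _, innov, bad = _ekf_run_jit(
            Y[ch], u0, v0, p0_scale, q_osc, q_freq, q_damp, r_meas, fs)
        if bad >= 0:
            total += penalty
        else:
            mse = 0.0
            for t in range(innov.shape[0]):
                mse += innov[t] * innov[t]
            total += mse / innov.shape[0]
    return total / C


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _to_unconstrained(omega: float, rho: float) -> tuple[float, float]:
    return math.log(omega / (math.pi - omega)), math.log(rho / (1.0 - rho))


def ekf_step(state: EKFState, y: float,
             hp: EKFHyperParams) -> tuple[EKFState, float]:
    """Single EKF predict+update on measurement ``y``.

    Returns the posterior state and the innovation.  Raises
    :class:`TrackingDiverged` on non-finite intermediates.
    """
    if not math.isfinite(y):
        raise ValueError("measurement must be finite")
    u, v = _to_unconstrained(state.omega, state.rho)
    z = np.array([float(state.x[0]), float(state.x[1]), u, v])
    P = np.array(state.P, dtype=np.float64, copy=True)
    innov, ok = _ekf_step_core(
        z, P, float(y), hp.q_osc, hp.q_freq, hp.q_damp, hp.r_meas,
        np.eye(4), np.empty((4, 4)), np.empty((4, 4)))
    if not ok:
        raise TrackingDiverged(step=0)
    omega = math.pi / (1.0 + math.exp(-z[2]))
    rho = 1.0 / (1.0 + math.exp(-z[3]))
    return EKFState(x=z[:2].copy(), omega=omega, rho=rho, P=P), innov


def track_signal(signal: np.ndarray, fs: float, hp: EKFHyperParams,
                 burn_in_s: float = DEFAULT_BURN_IN_S,
                 channel: str | int | None = None) -> TrackResult:
    """Run the EKF over a bandpass-filtered single-channel series.

    The first ``burn_in_s`` seconds are flagged (not removed) in the
    result so downstream fits can optionally exclude the transient.
    """
    y = np.ascontiguousarray(signal, dtype=np.float64).ravel()
    if y.size < fs:
        raise ValueError(f"signal shorter than 1 s ({y.size} samples at fs={fs})")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    omega0 = 2.0 * math.pi * hp.f_init / fs
    if not (0 < omega0 < math.pi):
        raise ValueError(f"f_init={hp.f_init} Hz not below Nyquist at fs={fs}")
    u0, v0 = _to_unconstrained(omega0, hp.rho_init)
    freq, mag, frob, innov, bad = _ekf_run_jit(
        y, u0, v0, hp.p0_scale, hp.q_osc, hp.q_freq, hp.q_damp, hp.r_meas, fs)
    if bad >= 0:
        raise TrackingDiverged(step=int(bad), channel=channel)
    n = y.size
    t = np.arange(n) / fs
    burn = t < burn_in_s
    return TrackResult(t=t, freq=freq, mag=mag, cov_frob=frob, innov=innov,
                       fs=fs, burn_in=burn)


def track_signals(signals: SignalSet, hp: EKFHyperParams,
                  burn_in_s: float = DEFAULT_BURN_IN_S) -> list[TrackResult]:
    """EKF-track every channel of a :class:`SignalSet` with shared ``hp``."""
    return [
        track_signal(signals.data[c], signals.fs, hp, burn_in_s,
                     channel=signals.labels[c])
        for c in range(signals.n_channels)
    ]


def prediction_error_cost(head: SignalSet | np.ndarray, hp: EKFHyperParams,
                          fs: float | None = None,
                          penalty: float = DIVERGENCE_PENALTY) -> float:
    """Hyperparameter-tuning cost on a head segment (typically 60 s).

    Mean over channels of the mean squared one-step innovation; channels
    that diverge contribute a large finite ``penalty`` so a stochastic
    optimizer can continue.
    """
    if isinstance(head, SignalSet):
        Y, fs = head.data, head.fs
    else:
        if fs is None:
            raise ValueError("fs required when passing a bare array")
        Y = np.atleast_2d(np.asarray(head, dtype=np.float64))
    omega0 = 2.0 * math.pi * hp.f_init / fs
    if not (0 < omega0 < math.pi):
        return penalty
    u0, v0 = _to_unconstrained(omega0, hp.rho_init)
    return float(_ekf_cost_jit(
        np.ascontiguousarray(Y), u0, v0, hp.p0_scale,
        hp.q_osc, hp.q_freq, hp.q_damp, hp.r_meas, float(fs), penalty))
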