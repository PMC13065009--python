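"""Session-long trend statistics on tracked trajectories.

Robust (bisquare IRLS) slope fits expressed per hour, Benjamini-Hochberg
FDR over channels, a two-piece-linear slope-change likelihood curve,
regression-based session endpoints, across-subject percentage maps, a
band-grid slope scan, and Welch PSD utilities.

Trajectories are block-averaged to a few Hz before trend fitting
(``decimate_to``, default 4 Hz): session trends live on the minutes
scale, the averaging leaves slopes untouched, and it keeps the IRLS
fast.  Note the reported p-values treat samples as independent, as is
conventional for these session-trend fits; they are anticonservative
under autocorrelation, which is why the synthetic calibration tests use
white noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter1d
from scipy.signal import welch as _welch

from .core import track_signal
from .filters import BandpassSpec, bandpass
from .signals import SignalSet

__all__ = [
    "SlopeEstimate", "SlopeMap", "ChangeLikelihood", "SlopeMatrix",
    "block_average", "robust_slope", "slope_map", "bh_fdr",
    "best_breakpoint", "slope_change_likelihood", "endpoints_from_fit",
    "percent_positive", "band_grid_slopes", "welch_psd",
]

logger = logging.getLogger(__name__)

BISQUARE_C = 4.685
DEFAULT_DECIMATE_TO = 4.0   # Hz; trend-fit rate after block averaging


@dataclass(frozen=True)
class SlopeEstimate:
    """Robust linear-trend fit of one trajectory, slope per hour."""

    slope: float          # units/hour
    intercept: float      # units (value at t = 0)
    p_value: float
    stderr: float
    n_samples: int
    degenerate: bool = False


@dataclass
class SlopeMap:
    """Per-channel slope estimates with FDR-corrected significance flags."""

    labels: list[str]
    estimates: list[SlopeEstimate]
    flags: np.ndarray          # True where p survives BH at fdr_q
    p_adjusted: np.ndarray
    fdr_q: float = 0.05

    @property
    def slopes(self) -> np.ndarray:
        return np.array([e.slope for e in self.estimates])

    @property
    def p_values(self) -> np.ndarray:
        return np.array([e.p_value for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.labels,
            "slope": self.slopes,
            "intercept": [e.intercept for e in self.estimates],
            "p": self.p_values,
            "p_adj": self.p_adjusted,
            "significant": self.flags,
        })


@dataclass
class ChangeLikelihood:
    """Unit-sum slope-change likelihood over the session (density)."""

    t_min: np.ndarray          # time grid, minutes
    likelihood: np.ndarray     # >= 0, sums to 1
    breakpoints_min: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SlopeMatrix:
    """Mean slopes per (f_min, f_max) candidate band; NaN where invalid."""

    f_min: np.ndarray
    f_max: np.ndarray
    freq_slopes: np.ndarray    # Hz/hour, shape (len(f_min), len(f_max))
    mag_slopes: np.ndarray     # a.u./hour, same shape

    def to_frame(self, which: str = "freq") -> pd.DataFrame:
        mat = self.freq_slopes if which == "freq" else self.mag_slopes
        return pd.DataFrame(mat, index=self.f_min, columns=self.f_max)


# ---------------------------------------------------------------------------
# Robust slope
# ---------------------------------------------------------------------------

def block_average(x: np.ndarray, fs: float,
                  target_rate: float) -> tuple[np.ndarray, float]:
    """Average non-overlapping blocks down to ~``target_rate`` Hz."""
    x = np.asarray(x, dtype=np.float64).ravel()
    k = max(1, int(round(fs / target_rate)))
    if k == 1:
        return x, fs
    n = (x.size // k) * k
    return x[:n].reshape(-1, k).mean(axis=1), fs / k


def robust_slope(traj: np.ndarray, fs: float,
                 decimate_to: float | None = None) -> SlopeEstimate:
    """Bisquare-IRLS linear trend of a trajectory, in native units per hour.

    The trajectory is z-scored, regressed on time (hours) by iteratively
    reweighted least squares with Tukey bisquare weights (tuning constant
    4.685, MAD residual scale, tol 1e-6, max 50 iterations), and slope /
    intercept are mapped back to native units through the trajectory's
    standard deviation and mean.  A constant trajectory yields slope 0
    with p = 1 and the ``degenerate`` flag set.
    """
    y = np.asarray(traj, dtype=np.float64).ravel()
    if y.size < 10 * fs:
        raise ValueError(
            f"trajectory too short for a trend fit: {y.size} samples "
            f"(< 10 s at fs={fs})"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("trajectory contains non-finite values")
    if decimate_to is not None:
        y, fs = block_average(y, fs, decimate_to)
    n = y.size
    t_hours = np.arange(n) / fs / 3600.0
    mu, sd = y.mean(), y.std()
    if sd < 1e-15 or sd < 1e-12 * max(1.0, abs(mu)):
        return SlopeEstimate(0.0, mu, 1.0, 0.0, n, degenerate=True)
    z = (y - mu) / sd
    X = sm.add_constant(t_hours)

    # Noiseless-line fast path: IRLS scale collapses on exact fits.
    beta, res, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    if resid.std() < 1e-10:
        return SlopeEstimate(beta[1] * sd, beta[0] * sd + mu, 0.0, 0.0, n)

    rlm = sm.RLM(z, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    fit = rlm.fit(maxiter=50, tol=1e-6, scale_est="mad")
    return SlopeEstimate(
        slope=float(fit.params[1] * sd),
        intercept=float(fit.params[0] * sd + mu),
        p_value=float(fit.pvalues[1]),
        stderr=float(fit.bse[1] * sd),
        n_samples=n,
    )


def slope_map(trajs: np.ndarray, fs: float, labels: list[str],
              fdr_q: float = 0.05,
              decimate_to: float | None = DEFAULT_DECIMATE_TO) -> SlopeMap:
    """Robust slope per channel plus BH-FDR significance flags."""
    trajs = np.atleast_2d(np.asarray(trajs))
    if trajs.shape[0] != len(labels):
        raise ValueError("one label per trajectory required")
    ests = [robust_slope(trajs[c], fs, decimate_to) for c in range(len(labels))]
    flags, p_adj = bh_fdr(np.array([e.p_value for e in ests]), fdr_q)
    return SlopeMap(labels=list(labels), estimates=ests, flags=flags,
                    p_adjusted=p_adj, fdr_q=fdr_q)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = sm.stats.multipletests(p, alpha=q, method="fdr_bh")[:4]
    return reject, p_adj


# ---------------------------------------------------------------------------
# Slope-change likelihood
# ---------------------------------------------------------------------------

def best_breakpoint(y: np.ndarray, min_segment: int | None = None) -> int:
    """Index of the single changepoint minimizing the total SSE of a
    two-piece linear fit (independent lines left/right of the split).

    O(n) via prefix sums.  ``min_segment`` samples are kept on each side
    (default: max(5, 2% of the series)).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if min_segment is None:
        min_segment = max(5, int(0.02 * n))
    if n < 2 * min_segment + 1:
        raise ValueError(f"series too short for breakpoint scan (n={n})")
    x = np.arange(n, dtype=np.float64)

    def cums(a):
        c = np.zeros(n + 1)
        np.cumsum(a, out=c[1:])
        return c

    Sx, Sy = cums(x), cums(y)
    Sxx, Sxy, Syy = cums(x * x), cums(x * y), cums(y * y)

    def sse(i0, i1):
        """SSE of the least-squares line on windows [i0, i1) (vectorized)."""
        N = (i1 - i0).astype(float)
        sx = Sx[i1] - Sx[i0]
        sy = Sy[i1] - Sy[i0]
        sxx = Sxx[i1] - Sxx[i0]
        sxy = Sxy[i1] - Sxy[i0]
        syy = Syy[i1] - Syy[i0]
        vxx = sxx - sx * sx / N
        vxy = sxy - sx * sy / N
        vyy = syy - sy * sy / N
        b = np.divide(vxy, vxx, out=np.zeros_like(vxx), where=vxx > 0)
        return np.maximum(vyy - b * vxy, 0.0)

    ks = np.arange(min_segment, n - min_segment + 1)
    total = sse(np.zeros_like(ks), ks) + sse(ks, np.full_like(ks, n))
    return int(ks[np.argmin(total)])


def slope_change_likelihood(trajs: np.ndarray, fs: float,
                            kernel_sigma_min: float = 3.0,
                            decimate_to: float | None = DEFAULT_DECIMATE_TO,
                            ) -> ChangeLikelihood:
    """Kernel-smoothed density of per-channel slope-break locations.

    Per channel, the most prominent two-piece-linear changepoint is
    marked in a binary vector; the vectors are convolved with a
    noncausal Gaussian kernel (sigma in minutes), summed over channels
    and normalized to unit sum over the session.
    """
    trajs = np.atleast_2d(np.asarray(trajs, dtype=np.float64))
    if trajs.shape[0] < 1:
        raise ValueError("need at least one channel")
    ref, fs_d = (block_average(trajs[0], fs, decimate_to)
                 if decimate_to else (trajs[0], fs))
    n = ref.size
    sigma_samples = kernel_sigma_min * 60.0 * fs_d
    counts = np.zeros(n)
    bps = []
    for c in range(trajs.shape[0]):
        y = (block_average(trajs[c], fs, decimate_to)[0]
             if decimate_to else trajs[c])
        if y.size < 2 * sigma_samples:
            logger.warning(
                "channel %d shorter than two kernel widths; skipped", c)
            continue
        sd = y.std()
        k = best_breakpoint((y - y.mean()) / sd if sd > 0 else y)
        counts[k] += 1.0
        bps.append(k / fs_d / 60.0)
    smoothed = gaussian_filter1d(counts, sigma=sigma_samples, mode="constant")
    total = smoothed.sum()
    if total > 0:
        smoothed /= total
    t_min = np.arange(n) / fs_d / 60.0
    return ChangeLikelihood(t_min=t_min, likelihood=smoothed,
                            breakpoints_min=np.array(bps))


# ---------------------------------------------------------------------------
# Endpoints, percentage maps, band grid, PSD
# ---------------------------------------------------------------------------

def endpoints_from_fit(est: SlopeEstimate,
                       session_hours: float) -> tuple[float, float]:
    """(initial, final) values predicted by the fitted trend at t=0 and t=T."""
    return est.intercept, est.intercept + est.slope * session_hours


def percent_positive(maps: list[SlopeMap]) -> pd.Series:
    """Per channel, % of subjects with a significant positive slope."""
    if not maps:
        raise ValueError("need at least one SlopeMap")
    ref = set(maps[0].labels)
    for m in maps[1:]:
        if set(m.labels) != ref:
            diff = sorted(ref.symmetric_difference(m.labels))
            raise ValueError(f"channel sets differ between subjects: {diff}")
    labels = maps[0].labels
    counts = np.zeros(len(labels))
    for m in maps:
        df = m.to_frame().set_index("channel").loc[labels]
        counts += (df["significant"].to_numpy()
                   & (df["slope"].to_numpy() > 0))
    return pd.Series(100.0 * counts / len(maps), index=labels,
                     name="percent_positive")


def band_grid_slopes(signals: SignalSet, f_grid=None,
                     channels: list[str] | None = None,
                     tracker: str = "ekf",
                     ga_config=None,
                     order: int = 5,
                     opt_window_s: float = 60.0,
                     min_bandwidth: float = 2.0,
                     decimate_to: float | None = DEFAULT_DECIMATE_TO,
                     ) -> SlopeMatrix:
    """Mean frequency/magnitude slopes over a grid of candidate bands.

    For every valid cell (``f_min < f_max``, stable filter design) the
    selected channels are bandpass filtered, the EKF is tuned on the head
    segment (or the analytic-signal tracker is used directly), the full
    session is tracked and robust per-channel slopes are averaged.
    Unstable or failing cells become NaN with a log entry.
    """
    from .ga import GAConfig, default_bounds, optimize  # local: avoid cycle
    from .hilbert import hilbert_track

    if f_grid is None:
        f_grid = np.arange(1.0, 31.0)
    f_grid = np.asarray(f_grid, dtype=float)
    if channels is not None:
        idx = [signals.labels.index(c) for c in channels]
    else:
        idx = list(range(signals.n_channels))
    nf = len(f_grid)
    fmat = np.full((nf, nf), np.nan)
    mmat = np.full((nf, nf), np.nan)

    for i, lo in enumerate(f_grid):
        for j, hi in enumerate(f_grid):
            if hi - lo < min_bandwidth or hi >= signals.fs / 2:
                continue
            try:
                spec = BandpassSpec(lo, hi, order=order, fs=signals.fs)
                filt = bandpass(signals.data[idx], spec)
            except ValueError as exc:
                logger.info("band [%g, %g] skipped: %s", lo, hi, exc)
                continue
            try:
                if tracker == "ekf":
                    head = SignalSet(filt[:, : int(opt_window_s * signals.fs)],
                                     signals.fs,
                                     [signals.labels[k] for k in idx])
                    if ga_config is None:
                        cfg = GAConfig(bounds=default_bounds(lo, hi))
                    else:
                        cfg = _dc_replace(ga_config,
                                          bounds=default_bounds(lo, hi),
                                          seed=ga_config.seed + 101 * i + j)
                    hp = optimize(head, cfg).best
                    results = [track_signal(filt[k], signals.fs, hp)
                               for k in range(len(idx))]
                elif tracker == "hilbert":
                    results = [hilbert_track(filt[k], signals.fs)
                               for k in range(len(idx))]
                else:
                    raise ValueError(f"unknown tracker {tracker!r}")
                fslopes = [robust_slope(r.freq, signals.fs, decimate_to).slope
                           for r in results]
                mslopes = [robust_slope(r.mag, signals.fs, decimate_to).slope
                           for r in results]
                fmat[i, j] = float(np.mean(fslopes))
                mmat[i, j] = float(np.mean(mslopes))
            except (RuntimeError, ValueError) as exc:
                logger.info("band [%g, %g] failed: %s", lo, hi, exc)
    return SlopeMatrix(f_min=f_grid, f_max=f_grid,
                       freq_slopes=fmat, mag_slopes=mmat)


def welch_psd(signal: np.ndarray, fs: float, window_s: float = 5.0,
              overlap_frac: float = 0.5, window_kind: str = "hamming",
              normalize_band: tuple[float, float] | None = None,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with optional normalization by total power in a band.

    With ``normalize_band=(0.5, 60)`` the returned density integrates to
    1 over that range.
    """
    y = np.asarray(signal, dtype=np.float64).ravel()
    nperseg = int(round(window_s * fs))
    if nperseg > y.size:
        raise ValueError(
            f"window of {nperseg} samples longer than signal ({y.size})")
    f, pxx = _welch(y, fs=fs, window=window_kind, nperseg=nperseg,
                    noverlap=int(round(overlap_frac * nperseg)))
    if normalize_band is not None:
        lo, hi = normalize_band
        m = (f >= lo) & (f <= hi)
        total = np.trapezoid(pxx[m], f[m])
        if total > 0:
            pxx = pxx / total
    return f, pxx
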