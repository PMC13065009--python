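"""Task-correlation band selection, feature comparison, spatial statistics.

Implements the group-level analyses around the tracker: selecting the
analysis band by absolute correlation between tracked magnitude and a
task reference, comparing four task-relevance feature types (tracked
frequency, tracked magnitude, covariance Frobenius norm, band log-power)
via subject-wise maximum |r| and Wilcoxon signed-rank contrasts, paired
inter-channel slope tests with Cohen's dz, and across-participant ROI
coupling of slope topographies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .filters import BandpassSpec
from .trends import SlopeMap, bh_fdr

__all__ = [
    "TaskReference", "ROIMap", "ROIS", "resample_reference",
    "task_correlation", "select_band", "log_power_feature",
    "feature_comparison", "pairwise_channel_tests", "roi_coupling",
]

ROIS = ("frontal", "central", "centroparietal", "posterior")
LOG_POWER_EPS = 1e-12


@dataclass
class TaskReference:
    """Sample-aligned task reference series.

    ``kind`` is ``"binary"`` (e.g. task vs. rest labels; exactly two
    distinct values required) or ``"continuous"`` (kinematics).
    """

    values: np.ndarray
    kind: str = "binary"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"kind must be binary|continuous, got {self.kind}")
        if self.kind == "binary":
            uniq = np.unique(self.values)
            if uniq.size != 2:
                raise ValueError(
                    f"binary reference must contain exactly two distinct "
                    f"values, found {uniq.size}")


def resample_reference(ref: TaskReference, n_target: int) -> TaskReference:
    """Align a reference to a tracker's output length.

    Zero-order hold for binary labels, linear interpolation for
    continuous kinematics.
    """
    n = ref.values.size
    if n == n_target:
        return ref
    if ref.kind == "binary":
        idx = np.minimum((np.arange(n_target) * n) // n_target, n - 1)
        vals = ref.values[idx]
    else:
        x_old = np.linspace(0.0, 1.0, n)
        x_new = np.linspace(0.0, 1.0, n_target)
        vals = np.interp(x_new, x_old, ref.values)
    return TaskReference(vals, ref.kind)


def task_correlation(feature_traj: np.ndarray, ref: TaskReference) -> float:
    """Signed Pearson r between a feature trajectory and the reference.

    Callers take the absolute value where the analysis asks for |r|.
    """
    x = np.asarray(feature_traj, dtype=np.float64).ravel()
    y = ref.values
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def select_band(candidates: list[BandpassSpec],
                corr_tables: dict[BandpassSpec, np.ndarray]) -> BandpassSpec:
    """Candidate band maximizing the mean |r| over subjects and channels.

    ``corr_tables`` maps each candidate to an array of absolute
    correlations (any shape; typically subjects x channels).  Ties break
    deterministically: narrowest band first, then lowest ``f_min``.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    scored = []
    for spec in candidates:
        table = np.abs(np.asarray(corr_tables[spec], dtype=float))
        scored.append((-float(np.nanmean(table)), spec.width, spec.f_min, spec))
    scored.sort(key=lambda s: s[:3])
    return scored[0][3]


def log_power_feature(bandpassed: np.ndarray,
                      eps: float = LOG_POWER_EPS) -> np.ndarray:
    """Conventional band log-power: ``log10(x**2 + eps)``, no smoothing.

    ``eps`` guards the log at exact zeros of the filtered signal.
    """
    x = np.asarray(bandpassed, dtype=np.float64)
    return np.log10(x * x + eps)


def _wilcoxon(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p: exact for n <= 25 (no ties), else normal
    approximation with continuity correction."""
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0
    if diffs.size <= 25:
        try:
            return float(stats.wilcoxon(diffs, method="exact").pvalue)
        except ValueError:
            pass
    return float(stats.wilcoxon(diffs, method="approx", correction=True).pvalue)


def feature_comparison(features: dict[str, list[np.ndarray]],
                       refs: list[TaskReference],
                       fdr_q: float = 0.05,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-wise max |r| per feature plus pairwise Wilcoxon contrasts.

    Parameters
    ----------
    features : dict
        Maps feature name to a per-subject list of ``(channels, n)``
        trajectory arrays.
    refs : list of TaskReference
        One reference per subject (resampled to each feature's length).

    Returns
    -------
    (per_subject, contrasts)
        ``per_subject``: subjects x features table of max-over-channels
        absolute correlations.  ``contrasts``: Wilcoxon signed-rank
        results for every feature pair with BH-adjusted p-values.
    """
    n_subj = len(refs)
    if any(len(v) != n_subj for v in features.values()):
        raise ValueError("every feature needs one entry per subject")
    if n_subj < 6:
        raise ValueError(f"need >= 6 subjects for testing, got {n_subj}")

    table = {}
    for name, per_subj in features.items():
        vals = []
        for s, trajs in enumerate(per_subj):
            trajs = np.atleast_2d(np.asarray(trajs, dtype=float))
            ref = resample_reference(refs[s], trajs.shape[1])
            rs = []
            for ch in range(trajs.shape[0]):
                if trajs[ch].std() == 0:
                    continue   # constant feature channel: excluded
                rs.append(abs(task_correlation(trajs[ch], ref)))
            vals.append(max(rs) if rs else np.nan)
        table[name] = vals
    per_subject = pd.DataFrame(table, index=[f"s{i:02d}" for i in range(n_subj)])

    rows = []
    for a, b in combinations(per_subject.columns, 2):
        d = (per_subject[a] - per_subject[b]).dropna().to_numpy()
        rows.append({"feature_a": a, "feature_b": b, "n": d.size,
                     "median_diff": float(np.median(d)) if d.size else np.nan,
                     "p": _wilcoxon(d) if d.size else np.nan})
    contrasts = pd.DataFrame(rows)
    valid = contrasts["p"].notna().to_numpy()
    flags = np.zeros(len(contrasts), dtype=bool)
    p_adj = np.full(len(contrasts), np.nan)
    if valid.any():
        f, pa = bh_fdr(contrasts.loc[valid, "p"].to_numpy(), fdr_q)
        flags[valid], p_adj[valid] = f, pa
    contrasts["p_adj"] = p_adj
    contrasts["significant"] = flags
    return per_subject, contrasts


def pairwise_channel_tests(slope_maps: list[SlopeMap],
                           fdr_q: float = 0.05) -> pd.DataFrame:
    """Paired t-test on subject-wise slope differences for every channel
    pair, BH-corrected; Cohen's dz reported for surviving pairs.

    Zero-variance difference pairs are flagged (``dz`` NaN, not tested).
    """
    if len(slope_maps) < 3:
        raise ValueError("need >= 3 subjects")
    labels = slope_maps[0].labels
    if any(m.labels != labels for m in slope_maps[1:]):
        raise ValueError("subjects must share an identical channel set")
    S = np.vstack([m.slopes for m in slope_maps])   # subjects x channels
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        d = S[:, i] - S[:, j]
        sd = d.std(ddof=1)
        if sd == 0:
            rows.append({"ch_i": labels[i], "ch_j": labels[j],
                         "t": 0.0 if d.mean() == 0 else np.inf,
                         "p": 1.0 if d.mean() == 0 else 0.0,
                         "dz": np.nan, "zero_variance": True})
            continue
        t, p = stats.ttest_rel(S[:, i], S[:, j])
        rows.append({"ch_i": labels[i], "ch_j": labels[j], "t": float(t),
                     "p": float(p), "dz": float(d.mean() / sd),
                     "zero_variance": False})
    df = pd.DataFrame(rows)
    flags, p_adj = bh_fdr(df["p"].to_numpy(), fdr_q)
    df["p_adj"] = p_adj
    df["significant"] = flags
    df.loc[~df["significant"], "dz_significant"] = np.nan
    df["dz_significant"] = np.where(df["significant"], df["dz"], np.nan)
    return df


@dataclass
class ROIMap:
    """Partition of (a subset of) channels into anatomical regions."""

    assignments: dict[str, str]    # channel label -> ROI name

    def __post_init__(self):
        bad = {c: r for c, r in self.assignments.items() if r not in ROIS}
        if bad:
            raise ValueError(f"unknown ROI names: {bad}")

    def channels(self, roi: str) -> list[str]:
        return [c for c, r in self.assignments.items() if r == roi]


def roi_coupling(slope_maps: list[SlopeMap], roi: ROIMap,
                 fdr_q: float = 0.05) -> pd.DataFrame:
    """Across-participant ROI coupling of slope topographies.

    For every channel pair spanning two different ROIs, the Pearson
    correlation of slope values across subjects is computed (two-sided
    test); BH correction runs over all cross-ROI pairs jointly, and the
    surviving signed correlations are averaged per ROI pair.  ROI pairs
    with no surviving channel pair are reported as NaN (absent, not
    zero).
    """
    if len(slope_maps) < 8:
        raise ValueError("need >= 8 subjects for across-participant coupling")
    labels = slope_maps[0].labels
    if any(m.labels != labels for m in slope_maps[1:]):
        raise ValueError("subjects must share an identical channel set")
    used_rois = sorted({r for c, r in roi.assignments.items() if c in labels})
    for r in used_rois:
        if not any(c in labels for c in roi.channels(r)):
            raise ValueError(f"ROI {r!r} has no channels in the data")
    S = np.vstack([m.slopes for m in slope_maps])
    col = {c: k for k, c in enumerate(labels)}

    pairs = []
    for ra, rb in combinations(used_rois, 2):
        for ca in roi.channels(ra):
            for cb in roi.channels(rb):
                if ca not in col or cb not in col:
                    continue
                res = stats.pearsonr(S[:, col[ca]], S[:, col[cb]])
                pairs.append({"roi_a": ra, "roi_b": rb, "ch_a": ca,
                              "ch_b": cb, "r": float(res.statistic),
                              "p": float(res.pvalue)})
    df = pd.DataFrame(pairs)
    if df.empty:
        raise ValueError("no cross-ROI channel pairs found")
    flags, p_adj = bh_fdr(df["p"].to_numpy(), fdr_q)
    df["p_adj"] = p_adj
    df["significant"] = flags

    rows = []
    for (ra, rb), grp in df.groupby(["roi_a", "roi_b"]):
        surv = grp.loc[grp["significant"], "r"]
        rows.append({"roi_a": ra, "roi_b": rb,
                     "mean_r": float(surv.mean()) if len(surv) else np.nan,
                     "n_pairs": len(grp), "n_significant": len(surv)})
    return pd.DataFrame(rows)
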