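"""Run configuration, preprocessing and the end-to-end session pipeline.

The pipeline mirrors the full analysis chain: preprocess (high-pass,
optional notch, resample to 120 Hz) -> for each candidate alpha/mu band:
tune the EKF on the first 60 s, track the full session, correlate
tracked magnitude with the task reference -> select the band with the
highest mean absolute task correlation -> session-trend statistics
(robust slope maps with BH-FDR, slope-change likelihood, regression
endpoints) -> tidy CSV/JSON artifacts stamped with the config hash and
seed.  Everything is deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .core import track_signal
from .filters import BandpassSpec, bandpass
from .ga import GAConfig, default_bounds, optimize
from .hilbert import hilbert_track
from .signals import SignalSet
from .taskstats import TaskReference, resample_reference, select_band, task_correlation
from .trends import (DEFAULT_DECIMATE_TO, endpoints_from_fit,
                     slope_change_likelihood, slope_map)

__all__ = ["RunConfig", "preprocess", "run_pipeline", "concatenate_sessions"]

logger = logging.getLogger(__name__)

#: Default candidate grid: f_min in {6,7,8} Hz crossed with f_max in {12,13,14} Hz.
DEFAULT_CANDIDATES = tuple((lo, hi) for lo in (6.0, 7.0, 8.0)
                           for hi in (12.0, 13.0, 14.0))


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the standard analysis recipe
    (order-5 bandpass, 120 Hz, 60 s tuning window, BH-FDR at 0.05)."""

    band_candidates: tuple = DEFAULT_CANDIDATES
    filter_order: int = 5
    resample_to: float = 120.0
    highpass_hz: float = 0.5
    highpass_order: int = 4
    notch_hz: float | None = None
    opt_window_s: float = 60.0
    ga_population: int = 40
    ga_generations: int = 30
    ga_elitism: int = 2
    kernel_sigma_min: float = 3.0
    fdr_q: float = 0.05
    tracker: str = "ekf"
    decimate_to: float = DEFAULT_DECIMATE_TO
    seed: int = 0

    def __post_init__(self):
        if self.tracker not in ("ekf", "hilbert"):
            raise ValueError(f"tracker must be ekf|hilbert, got {self.tracker}")
        if not self.band_candidates:
            raise ValueError("need at least one band candidate")
        for lo, hi in self.band_candidates:
            if not 0 < lo < hi:
                raise ValueError(f"bad band candidate ({lo}, {hi})")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "band_candidates" in raw:
            raw["band_candidates"] = tuple(
                tuple(float(x) for x in b) for b in raw["band_candidates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_candidates"] = [list(b) for b in self.band_candidates]
        return d

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def ga_config(self, band: tuple[float, float], seed_offset: int = 0) -> GAConfig:
        return GAConfig(bounds=default_bounds(*band),
                        population_size=self.ga_population,
                        generations=self.ga_generations,
                        elitism=self.ga_elitism,
                        seed=self.seed + seed_offset)


def preprocess(signals: SignalSet, cfg: RunConfig) -> SignalSet:
    """High-pass, optional notch, polyphase resample to ``cfg.resample_to``.

    The ICA artifact-removal stage of a full EEG pipeline is a pass-through
    hook here: run your ICA of choice before handing data in.
    """
    data, fs = signals.data, signals.fs
    if cfg.highpass_hz > 0:
        sos = sps.butter(cfg.highpass_order, cfg.highpass_hz,
                         btype="highpass", fs=fs, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=-1)
    if cfg.notch_hz:
        b, a = sps.iirnotch(cfg.notch_hz, Q=30.0, fs=fs)
        data = sps.filtfilt(b, a, data, axis=-1)
    if cfg.resample_to != fs:
        if cfg.resample_to > fs:
            raise ValueError(
                f"resample target {cfg.resample_to} Hz exceeds fs={fs}")
        from fractions import Fraction

        frac = Fraction(cfg.resample_to / fs).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator,
                                 axis=-1)
        fs = cfg.resample_to
    return SignalSet(data, fs, list(signals.labels), events=signals.events)


def concatenate_sessions(sessions: list[SignalSet]) -> SignalSet:
    """Concatenate runs of one participant in the given order."""
    first = sessions[0]
    for s in sessions[1:]:
        if s.fs != first.fs or s.labels != first.labels:
            raise ValueError("sessions differ in sampling rate or channels")
    return SignalSet(np.concatenate([s.data for s in sessions], axis=1),
                     first.fs, list(first.labels))


def _track_band(filt: np.ndarray, signals: SignalSet, cfg: RunConfig,
                band: tuple[float, float], seed_offset: int):
    """Tune (EKF only) and track every channel of one candidate band."""
    hp = None
    if cfg.tracker == "ekf":
        head = SignalSet(filt[:, : int(cfg.opt_window_s * signals.fs)],
                         signals.fs, list(signals.labels))
        hp = optimize(head, cfg.ga_config(band, seed_offset)).best
        results = [track_signal(filt[c], signals.fs, hp)
                   for c in range(signals.n_channels)]
    else:
        results = [hilbert_track(filt[c], signals.fs)
                   for c in range(signals.n_channels)]
    return results, hp


def run_pipeline(signals: SignalSet, cfg: RunConfig,
                 task_ref: TaskReference | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Execute the full session analysis; optionally write artifacts.

    Returns a dict with the selected band, tuned hyperparameters, slope
    maps, change-likelihood curves, endpoint table and (when a task
    reference was supplied) the per-band correlation table.
    """
    pre = preprocess(signals, cfg)
    candidates = [BandpassSpec(lo, hi, order=cfg.filter_order, fs=pre.fs)
                  for lo, hi in cfg.band_candidates]
    if task_ref is None and len(candidates) > 1:
        raise ValueError(
            "band selection needs a task reference; supply one or restrict "
            "band_candidates to a single band")

    tracked: dict = {}
    corr_tables: dict = {}
    hps: dict = {}
    band_rows = []
    for k, spec in enumerate(candidates):
        filt = bandpass(pre.data, spec)
        results, hp = _track_band(filt, pre, cfg, (spec.f_min, spec.f_max), k)
        tracked[spec] = results
        hps[spec] = hp
        if task_ref is not None:
            ref = resample_reference(task_ref, results[0].mag.size)
            rs = np.array([abs(task_correlation(r.mag, ref)) for r in results])
            corr_tables[spec] = rs[None, :]
            band_rows.append({"f_min": spec.f_min, "f_max": spec.f_max,
                              "mean_abs_r": float(rs.mean()),
                              "max_abs_r": float(rs.max())})
            logger.info("band [%g, %g]: mean |r| = %.3f",
                        spec.f_min, spec.f_max, rs.mean())

    selected = (select_band(candidates, corr_tables)
                if task_ref is not None else candidates[0])
    results = tracked[selected]

    freq_trajs = np.vstack([r.freq for r in results])
    mag_trajs = np.vstack([r.mag for r in results])
    fmap = slope_map(freq_trajs, pre.fs, pre.labels, cfg.fdr_q,
                     cfg.decimate_to)
    mmap = slope_map(mag_trajs, pre.fs, pre.labels, cfg.fdr_q,
                     cfg.decimate_to)
    cl_freq = slope_change_likelihood(freq_trajs, pre.fs,
                                      cfg.kernel_sigma_min, cfg.decimate_to)
    cl_mag = slope_change_likelihood(mag_trajs, pre.fs,
                                     cfg.kernel_sigma_min, cfg.decimate_to)

    T_hours = pre.duration / 3600.0
    endpoints = pd.DataFrame([
        {"channel": lab,
         "freq_initial": endpoints_from_fit(fe, T_hours)[0],
         "freq_final": endpoints_from_fit(fe, T_hours)[1],
         "mag_initial": endpoints_from_fit(me, T_hours)[0],
         "mag_final": endpoints_from_fit(me, T_hours)[1]}
        for lab, fe, me in zip(pre.labels, fmap.estimates, mmap.estimates)
    ])

    out = {
        "selected_band": (selected.f_min, selected.f_max),
        "hyperparams": hps[selected],
        "freq_slopes": fmap,
        "mag_slopes": mmap,
        "change_likelihood_freq": cl_freq,
        "change_likelihood_mag": cl_mag,
        "endpoints": endpoints,
        "band_correlations": pd.DataFrame(band_rows) if band_rows else None,
        "config_hash": cfg.hash,
        "seed": cfg.seed,
    }
    if out_dir is not None:
        _write_artifacts(out, Path(out_dir))
    return out


def _write_artifacts(out: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    out["freq_slopes"].to_frame().to_csv(
        out_dir / "slopes_freq.csv", index=False, float_format="%.10g")
    out["mag_slopes"].to_frame().to_csv(
        out_dir / "slopes_mag.csv", index=False, float_format="%.10g")
    for key, fname in (("change_likelihood_freq", "change_likelihood_freq.csv"),
                       ("change_likelihood_mag", "change_likelihood_mag.csv")):
        cl = out[key]
        pd.DataFrame({"t_min": cl.t_min, "likelihood": cl.likelihood}).to_csv(
            out_dir / fname, index=False, float_format="%.10g")
    out["endpoints"].to_csv(out_dir / "endpoints.csv", index=False,
                            float_format="%.10g")
    if out["band_correlations"] is not None:
        out["band_correlations"].to_csv(out_dir / "band_correlations.csv",
                                        index=False, float_format="%.10g")
    hp = out["hyperparams"]
    summary = {
        "selected_band": list(out["selected_band"]),
        "config_hash": out["config_hash"],
        "seed": out["seed"],
        "hyperparams": None if hp is None else asdict(hp),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True))
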