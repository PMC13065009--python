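"""Multichannel time-series container and a simple on-disk signal format.

:class:`SignalSet` is the universal input of the package: a
``(n_channels, n_samples)`` float array plus sampling rate and channel
labels.  The on-disk container is deliberately minimal — a JSON header
next to a raw little-endian float32 array with a SHA-256 checksum — so
fixtures stay inspectable and round-trips are bit-exact at float32.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CONTAINER_VERSION = 1


@dataclass
class SignalSet:
    """Multichannel signal: ``data[channel, sample]`` at sampling rate ``fs``.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    labels : list of str
        One label per channel.
    events : list, optional
        Optional (onset_s, description) reference events, e.g. EDF
        annotations or task markers.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds (0-based sample indexing)."""
        return np.arange(self.n_samples) / self.fs

    def head(self, seconds: float) -> "SignalSet":
        """First ``seconds`` of the recording (e.g. the tuning window)."""
        n = min(self.n_samples, int(round(seconds * self.fs)))
        return SignalSet(self.data[:, :n].copy(), self.fs, list(self.labels))

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


def write_container(signals: SignalSet, stem: str | Path,
                    provenance: dict | None = None) -> Path:
    """Write ``<stem>.json`` + ``<stem>.f32`` (little-endian float32, row-major)."""
    stem = Path(stem)
    raw = np.ascontiguousarray(signals.data, dtype="<f4").tobytes()
    header = {
        "format_version": CONTAINER_VERSION,
        "fs": float(signals.fs),
        "labels": list(signals.labels),
        "n_channels": signals.n_channels,
        "n_samples": signals.n_samples,
        "dtype": "<f4",
        "units": "a.u.",
        "provenance": provenance or {},
        "sha256": hashlib.sha256(raw).hexdigest(),
    }
    stem.parent.mkdir(parents=True, exist_ok=True)
    stem.with_suffix(".f32").write_bytes(raw)
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1, sort_keys=True))
    return stem.with_suffix(".json")


def read_container(stem: str | Path) -> SignalSet:
    """Read a container written by :func:`write_container`.

    Raises
    ------
    ValueError
        On truncated payloads or checksum mismatch (never silently
        truncates).
    """
    stem = Path(stem)
    if stem.suffix == ".json":
        stem = stem.with_suffix("")
    header = json.loads(stem.with_suffix(".json").read_text())
    raw = stem.with_suffix(".f32").read_bytes()
    expected = header["n_channels"] * header["n_samples"] * 4
    if len(raw) != expected:
        raise ValueError(
            f"container payload truncated: {len(raw)} bytes at offset 0, "
            f"expected {expected}"
        )
    if hashlib.sha256(raw).hexdigest() != header["sha256"]:
        raise ValueError("container checksum mismatch")
    data = np.frombuffer(raw, dtype="<f4").reshape(
        header["n_channels"], header["n_samples"]
    ).astype(np.float64)
    return SignalSet(data, header["fs"], list(header["labels"]))
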