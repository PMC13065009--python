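"""Reading EEG recordings: EDF files and the package's signal container."""

from __future__ import annotations

from pathlib import Path

from .signals import SignalSet, read_container

__all__ = ["read_signals", "read_edf"]


def read_edf(path: str | Path) -> SignalSet:
    """Read an EDF recording via MNE; annotations become reference events.

    Requires the optional ``mne`` dependency (``pip install oscitrack[edf]``).
    """
    try:
        import mne
    except ImportError as exc:   # pragma: no cover - optional dependency
        raise ImportError(
            "EDF reading requires mne; install the 'edf' extra") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    events = [(float(a["onset"]), str(a["description"]))
              for a in raw.annotations]
    return SignalSet(raw.get_data(), float(raw.info["sfreq"]),
                     list(raw.ch_names), events=events)


def read_signals(path: str | Path, format: str | None = None) -> SignalSet:
    """Read a recording; format inferred from the suffix unless given.

    ``format`` may be ``"edf"`` or ``"container"``.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "container"
    if format == "edf":
        return read_edf(path)
    if format == "container":
        return read_container(path)
    raise ValueError(f"unknown format {format!r}")
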