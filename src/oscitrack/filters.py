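"""Bandpass specification and zero-phase Butterworth filtering.

All narrowband analysis in the package runs on forward-backward
(zero-phase) Butterworth bandpass output; order 5 is the default used
throughout the alpha/mu analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class BandpassSpec:
    """Bandpass band ``[f_min, f_max]`` Hz at sampling rate ``fs``.

    Invariants: ``0 < f_min < f_max < fs/2`` and ``order >= 1``.
    """

    f_min: float
    f_max: float
    order: int = 5
    fs: float = 120.0

    def __post_init__(self):
        if not (0 < self.f_min < self.f_max < self.fs / 2):
            raise ValueError(
                f"need 0 < f_min < f_max < fs/2, got "
                f"[{self.f_min}, {self.f_max}] at fs={self.fs}"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")

    @property
    def width(self) -> float:
        return self.f_max - self.f_min

    @property
    def center(self) -> float:
        return 0.5 * (self.f_min + self.f_max)

    def design(self) -> np.ndarray:
        """Second-order sections of the Butterworth design; checks stability."""
        sos = sps.butter(self.order, [self.f_min, self.f_max],
                         btype="bandpass", fs=self.fs, output="sos")
        _, poles, _ = sps.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                f"unstable Butterworth design for band "
                f"[{self.f_min}, {self.f_max}] Hz, order {self.order}"
            )
        return sos


def bandpass(x: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Zero-phase (filtfilt) Butterworth bandpass; output length = input length.

    Works on a single series or a ``(channels, samples)`` array.
    """
    sos = spec.design()
    x = np.asarray(x, dtype=np.float64)
    return sps.sosfiltfilt(sos, x, axis=-1)
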