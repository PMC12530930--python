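"""Core in-memory containers: chromatograms, peaks and peak tables.

A :class:`Chromatogram` is a uniformly sampled absorbance-vs-time trace
(minutes, mAU) as produced by a single UPLC-PDA injection at a fixed
wavelength.  A :class:`PeakTable` is the integrated representation of one
chromatogram: RT-sorted peaks with apex position, integration bounds,
height and trapezoid area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import NonMonotoneTimeError, NegativeAreaError


@dataclass
class Chromatogram:
    """Uniformly sampled absorbance trace.

    Parameters
    ----------
    time_min : ndarray
        Strictly increasing, uniformly spaced time axis in minutes.
    absorbance_mau : ndarray
        Detector response in mAU, same length as ``time_min``.
    meta : dict
        Free-form acquisition metadata; conventional keys are
        ``sample_id``, ``group`` and ``seed``.
    """

    time_min: np.ndarray
    absorbance_mau: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.absorbance_mau = np.asarray(self.absorbance_mau, dtype=float)
        if self.time_min.ndim != 1 or self.time_min.shape != self.absorbance_mau.shape:
            raise ValueError("time and absorbance must be 1-D arrays of equal length")
        if self.time_min.size >= 2:
            dt = np.diff(self.time_min)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise NonMonotoneTimeError(
                    f"time axis not strictly increasing at row {row}"
                )
        if np.any(~np.isfinite(self.absorbance_mau)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def sample_id(self) -> str:
        return str(self.meta.get("sample_id", ""))

    @property
    def dt_min(self) -> float:
        return float(self.time_min[1] - self.time_min[0])

    def copy(self) -> "Chromatogram":
        return Chromatogram(
            self.time_min.copy(), self.absorbance_mau.copy(), dict(self.meta)
        )


@dataclass(frozen=True)
class Peak:
    """One integrated chromatographic peak (minutes / mAU / mAU·min)."""

    apex_rt_min: float
    left_rt_min: float
    right_rt_min: float
    height: float
    area: float

    def __post_init__(self):
        if not (self.left_rt_min < self.apex_rt_min < self.right_rt_min):
            raise ValueError(
                f"integration bounds must bracket the apex: "
                f"{self.left_rt_min} < {self.apex_rt_min} < {self.right_rt_min}"
            )
        if self.area <= 0:
            raise NegativeAreaError(f"peak area must be positive, got {self.area}")
        if self.height <= 0:
            raise ValueError(f"peak height must be positive, got {self.height}")

    def shifted(self, apex: float, left: float, right: float) -> "Peak":
        """Same peak with a warped retention axis (area/height untouched)."""
        return Peak(apex, left, right, self.height, self.area)


@dataclass
class PeakTable:
    """RT-sorted peaks detected in one sample."""

    sample_id: str
    peaks: list[Peak]
    group: str | None = None

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.apex_rt_min)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def apex_rts(self) -> np.ndarray:
        return np.array([p.apex_rt_min for p in self.peaks])

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])

    def copy_with(self, peaks: list[Peak]) -> "PeakTable":
        return PeakTable(self.sample_id, list(peaks), self.group)
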