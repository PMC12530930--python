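"""Raw trace -> peak table: baseline correction, peak detection, QC precision.

The processing chain mirrors common chromatography practice: estimate and
subtract a smooth baseline (asymmetric least squares by default), detect
local maxima on a lightly smoothed copy of the trace, integrate by the
trapezoid rule between flanking valleys on the *unsmoothed* corrected
signal, and summarize replicate precision as RSD% of retention time and
area per matched peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

from .containers import Chromatogram, Peak, PeakTable
from .exceptions import RetentionWindowError, ShortTraceError

DEFAULT_WINDOW_MIN = (4.0, 12.0)


# --------------------------------------------------------------------------
# baseline

def _asls_baseline(y: np.ndarray, lam: float = 1e9, p: float = 1e-3,
                   n_iter: int = 10) -> np.ndarray:
    """Asymmetric least squares baseline (Whittaker smoother with
    asymmetric weights): points above the fit get weight ``p``, points
    below get ``1 - p``, so the solution hugs the lower envelope."""
    n = y.size
    # banded form of lam * D2'D2 (pentadiagonal), D2 = second difference
    diag = np.full(n, 6.0)
    diag[[0, -1]] = 1.0
    diag[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.ones(n - 2)
    ab = np.zeros((5, n))
    ab[0, 2:] = lam * off2
    ab[1, 1:] = lam * off1
    ab[2, :] = lam * diag
    ab[3, :-1] = lam * off1
    ab[4, :-2] = lam * off2
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        ab_w = ab.copy()
        ab_w[2, :] += w
        z = solve_banded((2, 2), ab_w, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def _rolling_min_baseline(y: np.ndarray, window_points: int = 301) -> np.ndarray:
    base = minimum_filter1d(y, size=window_points, mode="nearest")
    return uniform_filter1d(base, size=window_points, mode="nearest")


def correct_baseline(chrom: Chromatogram, method: str = "asls",
                     **params) -> Chromatogram:
    """Return the chromatogram with its estimated baseline subtracted.

    ``method`` is ``"asls"`` (default; params ``lam``, ``p``, ``n_iter``)
    or ``"rolling_min"`` (param ``window_points``).
    """
    if chrom.time_min.size < 10:
        raise ShortTraceError("need at least 10 points for baseline correction")
    if method == "asls":
        base = _asls_baseline(chrom.absorbance_mau, **params)
    elif method == "rolling_min":
        base = _rolling_min_baseline(chrom.absorbance_mau, **params)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    out = chrom.copy()
    out.absorbance_mau = chrom.absorbance_mau - base
    out.meta["baseline_method"] = method
    return out


# --------------------------------------------------------------------------
# detection

def estimate_noise(y: np.ndarray) -> float:
    """Robust detector-noise SD from the first difference of the trace.

    The median absolute deviation of successive differences is immune to
    the sparse peaks; scaling by 1.4826 converts MAD to SD and sqrt(2)
    undoes the differencing.
    """
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _descend(y: np.ndarray, apex: int, step: int, noise: float,
             max_steps: int) -> int:
    """Walk from the apex in one direction to the flanking valley.

    The bound is the running minimum of the walk; the walk ends at the
    first rise exceeding half the noise SD above that minimum (a genuine
    valley or the far side of the noise plateau) or after ``max_steps``.
    Requiring a significant rise keeps noise wiggles from truncating the
    bound at random positions; returning the minimum keeps the bound at
    the local background level.  Equal-valued valleys resolve to the one
    nearer the apex (first strict minimum wins).
    """
    i = apex
    best = apex
    while 0 < i < y.size - 1 and abs(i - apex) < max_steps:
        j = i + step
        if y[j] > y[best] + 0.5 * noise:  # significant rise past the minimum
            break
        i = j
        if y[i] < y[best]:
            best = i
    return best


def detect_peaks(chrom: Chromatogram,
                 window_min: tuple[float, float] = DEFAULT_WINDOW_MIN,
                 snr_min: float = 10.0,
                 min_width_points: int = 5) -> PeakTable:
    """Integrate all peaks whose apex falls in the half-open RT window.

    Maxima are located on a Savitzky-Golay smoothed copy (width 7,
    order 2); integration bounds and areas come from the unsmoothed
    corrected trace.  A peak apex exactly at the window's upper edge is
    excluded.
    """
    t, y = chrom.time_min, chrom.absorbance_mau
    lo, hi = window_min
    if lo < t[0] or hi > t[-1] + 1e-9:
        raise RetentionWindowError(
            f"window {window_min} outside trace range ({t[0]}, {t[-1]})"
        )
    noise = estimate_noise(y)
    height_floor = snr_min * noise if noise > 0 else 0.0
    ys = savgol_filter(y, 7, 2) if y.size >= 7 else y
    idx, _ = find_peaks(ys, height=max(height_floor, 1e-12),
                        distance=max(min_width_points, 1))
    peaks: list[Peak] = []
    dt = t[1] - t[0] if t.size > 1 else 1.0
    max_steps = max(int(round(0.3 / dt)), 3 * min_width_points)
    for i in idx:
        left = _descend(ys, i, -1, noise, max_steps)
        right = _descend(ys, i, +1, noise, max_steps)
        # refine apex on the raw trace near the smoothed maximum, staying
        # strictly inside the integration bounds
        lo_i = max(left + 1, i - 3)
        hi_i = min(right, i + 4)
        apex = lo_i + int(np.argmax(y[lo_i:hi_i]))
        rt = t[apex]
        if not (lo <= rt < hi):
            continue
        if y[apex] < height_floor:
            continue
        if right - left + 1 < max(min_width_points, 3):
            continue
        area = float(np.trapezoid(y[left:right + 1], t[left:right + 1]))
        if area <= 0:
            continue
        peaks.append(Peak(rt, t[left], t[right], float(y[apex]), area))
    # merge duplicates that refined to the same apex sample
    uniq: dict[float, Peak] = {}
    for p in peaks:
        uniq.setdefault(p.apex_rt_min, p)
    return PeakTable(chrom.sample_id, list(uniq.values()),
                     chrom.meta.get("group"))


# --------------------------------------------------------------------------
# precision

@dataclass
class PrecisionReport:
    """Per matched peak: RSD% of apex retention time and of area across
    replicate injections, for peaks present in every replicate."""

    table: pd.DataFrame  # columns: peak_id, rt_mean, rt_rsd_pct, area_mean, area_rsd_pct
    scope: str  # "intraday" | "interday"

    @property
    def max_rt_rsd(self) -> float:
        return float(self.table["rt_rsd_pct"].max())

    @property
    def max_area_rsd(self) -> float:
        return float(self.table["area_rsd_pct"].max())


def _rsd_pct(x: np.ndarray) -> float:
    return float(100.0 * np.std(x, ddof=1) / np.mean(x))


def precision_report(replicate_tables: list[PeakTable], scope: str = "intraday",
                     tol_min: float = 0.1) -> PrecisionReport:
    """Match peaks across replicate injections and compute per-peak RSD%.

    Peaks absent from any replicate are dropped with a warning (they carry
    no replicate statistics), not treated as an error.
    """
    if len(replicate_tables) < 3:
        raise ValueError("precision needs >= 3 replicate injections")
    from .fingerprint import match_peaks  # peak matching is owned there

    candidate = match_peaks(replicate_tables, tol_min)
    n_rep = len(replicate_tables)
    rows = []
    dropped = 0
    for k, cluster in enumerate(candidate.clusters):
        if len(cluster.members) < n_rep:
            dropped += 1
            continue
        rts = np.array([p.apex_rt_min for p in cluster.members.values()])
        areas = np.array([p.area for p in cluster.members.values()])
        rows.append((f"P{k + 1}", rts.mean(), _rsd_pct(rts),
                     areas.mean(), _rsd_pct(areas)))
    if dropped:
        warnings.warn(
            f"{dropped} peak cluster(s) absent from some replicate; dropped "
            "from the precision report", stacklevel=2)
    table = pd.DataFrame(
        rows, columns=["peak_id", "rt_mean", "rt_rsd_pct", "area_mean",
                       "area_rsd_pct"])
    return PrecisionReport(table, scope)
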