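"""Common-peak fingerprint: RT alignment, peak matching, reference, similarity.

Workflow: pick anchor peaks present in every sample, warp each sample's
retention axis onto the anchor consensus (multipoint, piecewise-linear),
cluster apexes across samples into candidate peaks, keep clusters present
in (by default) all samples as the common peaks, average their areas into
the reference fingerprint, and score each sample's common-peak vector
against the reference by Pearson correlation or cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Peak, PeakTable
from .exceptions import (
    AnchorError,
    ConstantVectorError,
    LengthMismatchError,
    NoCommonPeakError,
    NonMonotoneMapError,
    ToleranceError,
)

DEFAULT_MATCH_TOL_MIN = 0.10


# --------------------------------------------------------------------------
# matching

@dataclass
class PeakCluster:
    """One candidate common peak: at most one member peak per sample."""

    members: dict[str, Peak] = field(default_factory=dict)

    @property
    def consensus_rt(self) -> float:
        return float(np.mean([p.apex_rt_min for p in self.members.values()]))


@dataclass
class MatchResult:
    """Candidate common-peak clusters (may have missing samples)."""

    clusters: list[PeakCluster]
    sample_ids: list[str]
    groups: dict[str, str | None]
    tol_min: float


def match_peaks(tables: list[PeakTable], tol_min: float = DEFAULT_MATCH_TOL_MIN
                ) -> MatchResult:
    """Greedy RT clustering of apexes across samples.

    All apexes are processed in (RT, sample id) order; a new cluster opens
    when the gap to the running cluster's consensus (mean member RT)
    exceeds ``tol_min``.  Within a cluster a sample contributes at most
    one peak: the one nearer the consensus wins and the loser seeds a new
    cluster.  The (RT, sample id) sort key makes the result independent of
    the order the tables are supplied in.
    """
    if tol_min <= 0:
        raise ToleranceError(f"matching tolerance must be > 0, got {tol_min}")
    entries = sorted(
        ((p.apex_rt_min, t.sample_id, p) for t in tables for p in t),
        key=lambda e: (e[0], e[1]),
    )
    clusters: list[PeakCluster] = []
    for rt, sid, peak in entries:
        if clusters:
            current = clusters[-1]
            cons = current.consensus_rt
            if rt - cons <= tol_min:
                if sid in current.members:
                    incumbent = current.members[sid]
                    if abs(rt - cons) < abs(incumbent.apex_rt_min - cons):
                        current.members[sid] = peak
                        clusters.append(PeakCluster({sid: incumbent}))
                    else:
                        clusters.append(PeakCluster({sid: peak}))
                else:
                    current.members[sid] = peak
                continue
        clusters.append(PeakCluster({sid: peak}))
    clusters.sort(key=lambda c: c.consensus_rt)
    return MatchResult(
        clusters,
        [t.sample_id for t in tables],
        {t.sample_id: t.group for t in tables},
        tol_min,
    )


# --------------------------------------------------------------------------
# anchors and retention correction

@dataclass
class AlignmentMap:
    """Monotone piecewise-linear RT warp defined by anchor pairs
    (observed RT in this sample -> reference RT)."""

    observed: np.ndarray
    reference: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, float)
        self.reference = np.asarray(self.reference, float)
        if self.observed.shape != self.reference.shape or self.observed.size < 1:
            raise NonMonotoneMapError("anchor arrays must be equal-length, >= 1")
        if np.any(np.diff(self.observed) <= 0) or np.any(np.diff(self.reference) <= 0):
            raise NonMonotoneMapError("anchors must be strictly increasing")

    def warp(self, rt):
        """Map observed RTs to the reference axis; outside the anchor span
        the terminal segment's slope is continued (affine extrapolation)."""
        rt = np.asarray(rt, dtype=float)
        x, y = self.observed, self.reference
        if x.size == 1:
            return rt + (y[0] - x[0])
        out = np.interp(rt, x, y)
        slope0 = (y[1] - y[0]) / (x[1] - x[0])
        slope1 = (y[-1] - y[-2]) / (x[-1] - x[-2])
        out = np.where(rt < x[0], y[0] + slope0 * (rt - x[0]), out)
        out = np.where(rt > x[-1], y[-1] + slope1 * (rt - x[-1]), out)
        return out if out.ndim else float(out)


def _global_offset(apexes: np.ndarray, reference: np.ndarray,
                   span_min: float = 0.3, step_min: float = 0.005,
                   cap_min: float = 0.08) -> float:
    """Whole-axis RT offset of one sample against reference positions.

    A plain nearest-peak median fails once the drift exceeds half the peak
    spacing: every reference position then snaps to its neighbouring peak
    and the sample mis-registers by one peak.  Because peak spacing is
    irregular, the true offset minimizes the capped mean nearest-distance
    over a scan of candidate offsets; a final median of the matched
    residuals refines it.
    """
    cands = np.arange(-span_min, span_min + 1e-12, step_min)
    d = np.abs(reference[None, :, None] + cands[:, None, None]
               - apexes[None, None, :]).min(axis=2)
    costs = np.minimum(d, cap_min).mean(axis=1)
    o = float(cands[int(np.argmin(costs))])
    resid = np.array([
        apexes[np.argmin(np.abs(apexes - (r + o)))] - (r + o)
        for r in reference
    ])
    good = np.abs(resid) <= cap_min
    if good.any():
        o += float(np.median(resid[good]))
    return o


def _affine_registration(apexes: np.ndarray, reference: np.ndarray,
                         cap_min: float = 0.08) -> tuple[float, float]:
    """Offset + slope of one sample's RT axis against reference positions.

    Starts from the scanned global offset, then alternates nearest-peak
    matching with a least-squares line fit of the residual against RT, so
    a linear drift component does not push the extreme peaks onto their
    neighbours.  Returns (offset, slope) such that a reference position r
    is expected near ``r + offset + slope * (r - mean(reference))``.
    """
    o = _global_offset(apexes, reference, cap_min=cap_min)
    center = float(np.mean(reference))
    slope = 0.0
    for _ in range(3):
        targets = reference + o + slope * (reference - center)
        matched = np.array([
            apexes[np.argmin(np.abs(apexes - t))] for t in targets
        ])
        resid = matched - targets
        good = np.abs(resid) <= cap_min
        if good.sum() < 2:
            break
        x = reference[good] - center
        A = np.vstack([np.ones(good.sum()), x]).T
        do, ds = np.linalg.lstsq(A, resid[good], rcond=None)[0]
        o += float(do)
        slope += float(ds)
    return o, slope


def select_anchors(tables: list[PeakTable], k: int = 5,
                   coarse_tol_min: float = 0.2) -> list[float]:
    """Choose ``k`` anchor reference RTs: peaks present in every sample,
    maximally spread over the RT range, preferring the tallest (median
    height) candidate near each target position.

    Candidate identity is pinned to the peaks of one reference sample:
    every other sample is first shifted by its median RT offset against
    that sample, and a candidate counts as universal only if each sample
    then has a peak within half the coarse tolerance.  This keeps an
    anchor tied to one analyte even when whole-axis drift approaches the
    peak spacing.
    """
    if k < 2:
        raise AnchorError("need at least 2 anchors")
    if not tables or any(len(t) == 0 for t in tables):
        raise AnchorError("need non-empty peak tables")
    ref_table = tables[0]
    ref_rts = ref_table.apex_rts
    center = float(np.mean(ref_rts))
    reg = {t.sample_id: _affine_registration(t.apex_rts, ref_rts)
           for t in tables}
    universal = []
    for r in ref_rts:
        matched_rts, matched_heights = [], []
        for t in tables:
            apexes = t.apex_rts
            o, slope = reg[t.sample_id]
            target = r + o + slope * (r - center)
            j = int(np.argmin(np.abs(apexes - target)))
            if abs(apexes[j] - target) > coarse_tol_min / 2:
                break
            matched_rts.append(r + apexes[j] - target)
            matched_heights.append(t.peaks[j].height)
        else:
            universal.append((float(np.mean(matched_rts)),
                              float(np.median(matched_heights))))
    if len(universal) < k:
        raise AnchorError(
            f"only {len(universal)} peaks present in all samples; need {k}. "
            "Consider a larger coarse tolerance or fewer anchors."
        )
    rts = np.array([u[0] for u in universal])
    heights = np.array([u[1] for u in universal])
    targets = np.linspace(rts.min(), rts.max(), k)
    chosen: list[int] = []
    for tgt in targets:
        d = np.abs(rts - tgt)
        d[chosen] = np.inf
        near = np.flatnonzero(d <= d.min() + 1e-12)
        pick = near[np.argmax(heights[near])]
        chosen.append(int(pick))
    return sorted(float(rts[i]) for i in chosen)


def alignment_maps(tables: list[PeakTable], anchor_rts: list[float],
                   tol_min: float = 0.3,
                   registration_rts: np.ndarray | None = None
                   ) -> dict[str, AlignmentMap]:
    """For each sample, pair every anchor reference RT with an observed apex.

    Matching is drift-aware: a sample whose whole axis is shifted by more
    than half the typical peak spacing would otherwise pair an anchor with
    its neighbouring peak.  Each sample's affine drift is first estimated
    against ``registration_rts`` (a dense reference peak list; defaults to
    the anchors themselves), and anchors are then matched relative to that
    drift and must land within ``tol_min`` of the expected position.
    """
    anchor_rts = sorted(anchor_rts)
    anchor_arr = np.asarray(anchor_rts)
    reg_ref = (anchor_arr if registration_rts is None
               else np.asarray(registration_rts, float))
    center = float(np.mean(reg_ref))
    maps = {}
    for t in tables:
        apexes = t.apex_rts
        o, slope = _affine_registration(apexes, reg_ref)
        obs = []
        for a in anchor_rts:
            target = a + o + slope * (a - center)
            j = int(np.argmin(np.abs(apexes - target)))
            if abs(apexes[j] - target) > tol_min:
                raise AnchorError(
                    f"sample {t.sample_id}: no peak within {tol_min} min of "
                    f"anchor at {a:.3f} min (drift-corrected)"
                )
            obs.append(float(apexes[j]))
        if np.any(np.diff(obs) <= 0):
            raise AnchorError(
                f"sample {t.sample_id}: anchor assignment is not monotone; "
                "check the anchor spacing"
            )
        maps[t.sample_id] = AlignmentMap(np.array(obs), np.array(anchor_rts))
    return maps


def correct_retention(table: PeakTable, amap: AlignmentMap) -> PeakTable:
    """Warp apex and bound RTs onto the reference axis; areas and heights
    are untouched."""
    warped = [
        p.shifted(float(amap.warp(p.apex_rt_min)),
                  float(amap.warp(p.left_rt_min)),
                  float(amap.warp(p.right_rt_min)))
        for p in table
    ]
    return table.copy_with(warped)


def align_tables(tables: list[PeakTable], k: int = 5,
                 coarse_tol_min: float = 0.2) -> list[PeakTable]:
    """Convenience: select anchors, build maps, warp every table.

    Drift registration inside :func:`alignment_maps` uses the first
    table's full peak list, which disambiguates anchor identity far
    better than the sparse anchors alone."""
    anchors = select_anchors(tables, k=k, coarse_tol_min=coarse_tol_min)
    maps = alignment_maps(tables, anchors,
                          registration_rts=tables[0].apex_rts)
    return [correct_retention(t, maps[t.sample_id]) for t in tables]


# --------------------------------------------------------------------------
# common peaks and the reference fingerprint

@dataclass
class CommonPeakMatrix:
    """Samples x common peaks area matrix with consensus RTs and groups."""

    areas: pd.DataFrame          # index sample_id, columns P1..Pm
    consensus_rts: np.ndarray    # strictly increasing, one per column
    groups: pd.Series            # index sample_id
    presence_threshold: float

    @property
    def peak_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    def labels(self) -> np.ndarray:
        return self.groups.loc[self.areas.index].to_numpy()


def common_peaks(candidate: MatchResult, presence: float = 1.0
                 ) -> CommonPeakMatrix:
    """Keep clusters present in at least ``presence`` of samples and
    re-index them 1..m by consensus RT."""
    n = len(candidate.sample_ids)
    kept = [c for c in candidate.clusters if len(c.members) / n >= presence]
    if not kept:
        raise NoCommonPeakError(
            f"no cluster reaches presence {presence} over {n} samples"
        )
    kept.sort(key=lambda c: c.consensus_rt)
    data = {
        f"P{i + 1}": {sid: c.members[sid].area if sid in c.members else np.nan
                      for sid in candidate.sample_ids}
        for i, c in enumerate(kept)
    }
    areas = pd.DataFrame(data).loc[candidate.sample_ids]
    groups = pd.Series({sid: candidate.groups.get(sid) for sid in
                        candidate.sample_ids}, name="group")
    return CommonPeakMatrix(
        areas, np.array([c.consensus_rt for c in kept]), groups, presence
    )


@dataclass
class ReferenceFingerprint:
    """Average fusion vector: per-peak mean area with its RT register."""

    mean_areas: np.ndarray
    consensus_rts: np.ndarray
    peak_ids: list[str]


def reference_fingerprint(matrix: CommonPeakMatrix) -> ReferenceFingerprint:
    """Arithmetic mean of each common peak's area column (the "simulative
    average chromatogram" the similarity index is measured against)."""
    if matrix.areas.isna().any().any():
        raise ValueError("reference fingerprint requires a complete matrix")
    return ReferenceFingerprint(
        matrix.areas.mean(axis=0).to_numpy(),
        matrix.consensus_rts.copy(),
        matrix.peak_ids,
    )


# --------------------------------------------------------------------------
# similarity

def similarity(sample_vector, reference: ReferenceFingerprint | np.ndarray,
               metric: str = "pearson") -> float:
    """Similarity of one sample's common-peak vector to the reference.

    ``pearson`` is the centred correlation coefficient; ``cosine`` the
    included-angle cosine.  Both lie in [-1, 1] and equal 1 for the
    reference against itself.
    """
    x = np.asarray(sample_vector, dtype=float)
    r = (reference.mean_areas if isinstance(reference, ReferenceFingerprint)
         else np.asarray(reference, dtype=float))
    if x.shape != r.shape or x.size < 3:
        raise LengthMismatchError(
            f"vectors must have equal length >= 3, got {x.size} vs {r.size}"
        )
    if metric == "pearson":
        if np.ptp(r) == 0 or np.ptp(x) == 0:
            raise ConstantVectorError("pearson undefined for a constant vector")
        return float(np.corrcoef(x, r)[0, 1])
    if metric == "cosine":
        nx, nr = np.linalg.norm(x), np.linalg.norm(r)
        if nx == 0 or nr == 0:
            raise ConstantVectorError("cosine undefined for a zero vector")
        return float(np.clip(x @ r / (nx * nr), -1.0, 1.0))
    raise ValueError(f"unknown similarity metric {metric!r}")


def similarity_report(matrix: CommonPeakMatrix,
                      reference: ReferenceFingerprint | None = None,
                      metrics: tuple[str, ...] = ("pearson", "cosine"),
                      normalize_total_area: bool = False) -> pd.DataFrame:
    """Per-sample similarity coefficients against the reference.

    With ``normalize_total_area`` each sample vector (and the reference)
    is divided by its total area before scoring.
    """
    reference = reference or reference_fingerprint(matrix)
    ref_vec = reference.mean_areas
    if normalize_total_area:
        ref_vec = ref_vec / ref_vec.sum()
    rows = {}
    for sid in matrix.sample_ids:
        v = matrix.areas.loc[sid].to_numpy()
        if normalize_total_area:
            v = v / v.sum()
        rows[sid] = {m: similarity(v, ref_vec, m) for m in metrics}
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out
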