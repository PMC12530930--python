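"""Alignment, peak matching, common peaks, reference and similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilprint.containers import Peak, PeakTable
from soilprint.exceptions import (
    AnchorError,
    ConstantVectorError,
    NoCommonPeakError,
    NonMonotoneMapError,
    ToleranceError,
)
from soilprint.fingerprint import (
    AlignmentMap,
    align_tables,
    alignment_maps,
    common_peaks,
    correct_retention,
    match_peaks,
    reference_fingerprint,
    select_anchors,
    similarity,
    similarity_report,
)
from soilprint.pipeline import RunConfig, build_fingerprint
from soilprint.simulate import SimulationConfig, simulate_ground_truth


def _table(sample_id, rts, areas=None, heights=None, group=None):
    areas = areas if areas is not None else [10.0] * len(rts)
    heights = heights if heights is not None else [50.0] * len(rts)
    peaks = [Peak(rt, rt - 0.05, rt + 0.05, h, a)
             for rt, a, h in zip(rts, areas, heights)]
    return PeakTable(sample_id, peaks, group)


def truth_tables(config):
    """Peak tables built directly from ground truth (bypasses detection)."""
    truth = simulate_ground_truth(config)
    tables = []
    for sid, sub in truth.table.groupby("sample_id", sort=False):
        tables.append(_table(sid, sub["rt_min"].to_numpy(),
                             sub["area"].to_numpy(),
                             sub["area"].to_numpy(),
                             group=sub["group"].iloc[0]))
    return tables, truth


class TestMatchPeaks:
    def test_gap_rule_two_clusters(self):
        tables = [_table("A", [5.00]), _table("B", [5.25])]
        res = match_peaks(tables, tol_min=0.1)
        assert len(res.clusters) == 2

    def test_within_tolerance_single_cluster(self):
        tables = [_table("A", [5.00]), _table("B", [5.06])]
        res = match_peaks(tables, tol_min=0.1)
        assert len(res.clusters) == 1
        assert len(res.clusters[0].members) == 2

    def test_identical_tables_full_presence(self):
        tables = [_table(f"S{i}", [5.0, 6.0, 7.0]) for i in range(4)]
        res = match_peaks(tables, 0.1)
        assert all(len(c.members) == 4 for c in res.clusters)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ToleranceError):
            match_peaks([_table("A", [5.0])], 0.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_result_independent_of_table_order(self, seed):
        rng = np.random.default_rng(seed)
        tables = [
            _table(f"S{i}", np.sort(rng.uniform(4, 12, rng.integers(3, 8))))
            for i in range(4)
        ]
        a = match_peaks(tables, 0.1)
        b = match_peaks(tables[::-1], 0.1)
        rts_a = [sorted(p.apex_rt_min for p in c.members.values())
                 for c in a.clusters]
        rts_b = [sorted(p.apex_rt_min for p in c.members.values())
                 for c in b.clusters]
        assert rts_a == rts_b


class TestAnchors:
    def test_identical_tables_anchor_subset_of_apexes(self):
        rts = [4.5, 6.0, 7.5, 9.0, 10.5, 11.5]
        tables = [_table(f"S{i}", rts) for i in range(3)]
        anchors = select_anchors(tables, k=4)
        assert all(any(abs(a - r) < 1e-9 for r in rts) for a in anchors)

    def test_too_many_anchors_raises(self):
        tables = [_table(f"S{i}", [5.0, 6.0, 7.0]) for i in range(3)]
        with pytest.raises(AnchorError):
            select_anchors(tables, k=4)

    def test_cohort_anchors_span_most_of_window(self, peak_tables):
        anchors = select_anchors(peak_tables, k=5)
        assert (anchors[-1] - anchors[0]) >= 0.7 * (12.0 - 4.0)


class TestRetentionCorrection:
    def test_identity_anchors_leave_table_unchanged(self):
        table = _table("A", [5.0, 6.0, 7.0])
        amap = AlignmentMap(np.array([4.5, 8.0]), np.array([4.5, 8.0]))
        out = correct_retention(table, amap)
        assert np.allclose(out.apex_rts, table.apex_rts)

    def test_uniform_anchor_shift_moves_apex_exactly(self):
        table = _table("A", [6.0])
        amap = AlignmentMap(np.array([5.0, 7.0, 9.0]),
                            np.array([5.1, 7.1, 9.1]))
        out = correct_retention(table, amap)
        assert out.peaks[0].apex_rt_min == pytest.approx(6.1, abs=1e-12)
        assert out.peaks[0].area == table.peaks[0].area

    def test_affine_drift_correction_shrinks_rt_spread(self):
        cfg = SimulationConfig(seed=5, rt_drift_sd=(0.1, 0.01),
                               rt_jitter_sd_min=0.0)
        tables, truth = truth_tables(cfg)
        aligned = align_tables(tables, k=5)
        raw_sd, corr_sd = [], []
        for m in range(cfg.n_metabolites):
            raw = [t.apex_rts[m] for t in tables]
            corr = [t.apex_rts[m] for t in aligned]
            raw_sd.append(np.std(raw))
            corr_sd.append(np.std(corr))
        assert np.mean(raw_sd) / np.mean(corr_sd) >= 5.0

    def test_non_monotone_map_rejected(self):
        with pytest.raises(NonMonotoneMapError):
            AlignmentMap(np.array([5.0, 4.0]), np.array([5.0, 6.0]))

    def test_missing_anchor_peak_raises(self):
        tables = [_table("A", [5.0, 9.0])]
        with pytest.raises(AnchorError):
            alignment_maps(tables, [5.0, 7.0, 9.0], tol_min=0.2)


class TestCommonPeaks:
    def test_full_presence_candidate_kept_entirely(self):
        tables = [_table(f"S{i}", [5.0, 6.0]) for i in range(4)]
        matrix = common_peaks(match_peaks(tables, 0.1), presence=1.0)
        assert matrix.areas.shape == (4, 2)
        assert not matrix.areas.isna().any().any()

    def test_presence_threshold_arithmetic(self):
        tables = [_table(f"S{i}", [5.0, 6.0]) for i in range(17)]
        tables.append(_table("S17", [5.0]))  # peak at 6.0 missing in 1 of 18
        cand = match_peaks(tables, 0.1)
        strict = common_peaks(cand, presence=1.0)
        assert strict.areas.shape[1] == 1
        lax = common_peaks(cand, presence=0.9)
        assert lax.areas.shape[1] == 2

    def test_no_survivor_raises(self):
        tables = [_table("A", [5.0]), _table("B", [7.0])]
        with pytest.raises(NoCommonPeakError):
            common_peaks(match_peaks(tables, 0.1), presence=1.0)

    def test_default_cohort_recovers_30_common_peaks(self, common_matrix):
        assert len(common_matrix.peak_ids) == 30
        assert np.all(np.diff(common_matrix.consensus_rts) > 0)


class TestReferenceFingerprint:
    def test_mean_arithmetic(self):
        tables = [_table("A", [5.0, 6.0], [1.0, 3.0]),
                  _table("B", [5.0, 6.0], [3.0, 1.0])]
        fp = reference_fingerprint(common_peaks(match_peaks(tables, 0.1)))
        assert np.allclose(fp.mean_areas, [2.0, 2.0])

    def test_sample_order_symmetry(self):
        t1 = [_table("A", [5.0], [1.0]), _table("B", [5.0], [9.0])]
        f1 = reference_fingerprint(common_peaks(match_peaks(t1, 0.1)))
        f2 = reference_fingerprint(common_peaks(match_peaks(t1[::-1], 0.1)))
        assert np.allclose(f1.mean_areas, f2.mean_areas)

    def test_commutes_with_uniform_rescale(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(1, 10, size=(3, 4))
        rts = [5.0, 6.0, 7.0, 8.0]
        t1 = [_table(f"S{i}", rts, areas[i]) for i in range(3)]
        t2 = [_table(f"S{i}", rts, areas[i] * 3.5) for i in range(3)]
        f1 = reference_fingerprint(common_peaks(match_peaks(t1, 0.1)))
        f2 = reference_fingerprint(common_peaks(match_peaks(t2, 0.1)))
        assert np.allclose(f2.mean_areas, 3.5 * f1.mean_areas)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, 5.0, 2.0, 8.0])
        assert similarity(v, v, "pearson") == pytest.approx(1.0)
        assert similarity(v, v, "cosine") == pytest.approx(1.0)

    def test_cosine_scale_invariance(self):
        v = np.array([1.0, 5.0, 2.0, 8.0])
        assert similarity(3.7 * v, v, "cosine") == pytest.approx(1.0)

    def test_pearson_matches_hand_computed_value(self):
        # x=(1,2,3,4), y=(1,2,4,3): cov terms sum 4.0, var 5 each -> r=0.8
        assert similarity([1, 2, 3, 4], np.array([1.0, 2, 4, 3]),
                          "pearson") == pytest.approx(0.8)

    def test_constant_reference_pearson_rejected(self):
        with pytest.raises(ConstantVectorError):
            similarity([1, 2, 3], np.array([2.0, 2.0, 2.0]), "pearson")

    def test_zero_vector_cosine_rejected(self):
        with pytest.raises(ConstantVectorError):
            similarity([0, 0, 0], np.array([0.0, 0.0, 0.0]), "cosine")

    def test_cohort_similarities_span_plausible_band(self, fingerprint_result):
        """Against its own cohort reference every sample scores in (0.7, 1.0],
        the loose envelope around the 0.8-0.96 band regional soil
        fingerprints show."""
        sim = fingerprint_result[3]
        assert sim["pearson"].between(0.7, 1.0).all()
        assert sim["cosine"].between(0.7, 1.0).all()

    def test_total_area_normalization_flag(self, common_matrix):
        rep = similarity_report(common_matrix, normalize_total_area=True)
        assert rep["pearson"].between(-1, 1).all()
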