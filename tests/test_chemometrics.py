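"""PCA, PLS-DA/NIPALS, VIP, permutation validation and marker selection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilprint.chemometrics import (
    _apply_scale,
    _scale_params,
    fit_plsda,
    one_hot,
    peak_anova_pvalues,
    permutation_test,
    run_pca,
    select_markers,
    vip_scores,
)
from soilprint.exceptions import ConstantVectorError, LengthMismatchError
from soilprint.simulate import SimulationConfig, simulate_ground_truth


def random_labels(n, rng, k=2):
    labels = np.array([f"c{i % k}" for i in range(n)])
    rng.shuffle(labels)
    return labels


class TestPCA:
    def test_collinear_data_pc1_explains_everything(self):
        x = np.linspace(0, 1, 8)
        X = np.column_stack([x, 2 * x])
        model = run_pca(X, scaling="center_only")
        assert model.explained_pct[0] == pytest.approx(100.0)

    def test_explained_percentages_sum_to_100(self):
        X = np.random.default_rng(0).normal(size=(10, 6))
        model = run_pca(X)
        assert model.explained_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_covariance_eigendecomposition(self):
        """Loadings and explained variance agree with a brute-force eigen
        decomposition of the scaled covariance matrix."""
        X = np.random.default_rng(1).normal(size=(6, 4))
        model = run_pca(X)
        mean, sd = _scale_params(X, "unit_variance")
        Xs = _apply_scale(X, mean, sd)
        evals, evecs = np.linalg.eigh(Xs.T @ Xs / 5)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        assert np.allclose(model.explained_pct,
                           100 * evals / evals.sum(), atol=1e-9)
        for j in range(4):
            dot = abs(evecs[:, j] @ model.loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_constant_column_rejected_with_names(self):
        X = np.ones((5, 3))
        X[:, 0] = np.arange(5)
        with pytest.raises(ConstantVectorError, match=r"\[1, 2\]"):
            run_pca(X)

    def test_scores_stable_under_sample_reordering(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 4))
        perm = rng.permutation(9)
        a = run_pca(X).scores
        b = run_pca(X[perm]).scores
        assert np.allclose(np.abs(a[perm]), np.abs(b), atol=1e-8)


class TestPLSDA:
    def test_reproducible_y_gives_r2y_near_one(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(["a", "b", "c"], 6)
        Y, _ = one_hot(labels)
        X = Y + rng.normal(0, 1e-4, Y.shape)
        model = fit_plsda(X, labels, A=2, cv_folds=6)
        assert model.r2y > 0.999

    def test_one_component_matches_hand_nipals_iteration(self):
        """Weights/scores of a one-component fit equal an independent
        step-by-step NIPALS loop on a 5x3 toy."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        labels = np.array(["a", "a", "b", "b", "b"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsda(X, labels, A=1, cv_folds=5)
        Y, _ = one_hot(labels)
        mean, sd = _scale_params(X, "unit_variance")
        E = _apply_scale(X, mean, sd)
        F = Y - Y.mean(axis=0)
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        for _ in range(1000):
            w = E.T @ u / (u @ u)
            w /= np.linalg.norm(w)
            t = E @ w
            c = F.T @ t / (t @ t)
            u_new = F @ c / (c @ c)
            if np.linalg.norm(u_new - u) < 1e-13:
                u = u_new
                break
            u = u_new
        sign = 1.0 if w[np.flatnonzero(np.abs(w) > 1e-12)[0]] > 0 else -1.0
        assert np.allclose(sign * w, model.weights[:, 0], atol=1e-8)
        assert np.allclose(sign * t, model.scores[:, 0], atol=1e-8)

    def test_planted_cohort_clears_predictability_gate(self, truth_area_matrix):
        """Q2 > 0.5 is the conventional gate for a predictive model."""
        X, labels = truth_area_matrix
        model = fit_plsda(X, labels)
        assert model.q2 > 0.5
        assert model.q2 <= model.r2y + 1e-9

    def test_excess_components_truncated_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        with pytest.warns(UserWarning, match="truncat"):
            model = fit_plsda(X, labels, A=10, cv_folds=3)
        assert model.n_components <= 3

    def test_loo_and_sevenfold_q2_agree_on_planted_cohort(self,
                                                          truth_area_matrix):
        X, labels = truth_area_matrix
        q2_7 = fit_plsda(X, labels, cv_folds=7).q2
        q2_loo = fit_plsda(X, labels, cv_folds=len(labels)).q2
        assert abs(q2_7 - q2_loo) < 0.15


class TestVIP:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_squared_vip_sums_to_variable_count(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(6, 14)), int(rng.integers(3, 9))
        X = rng.normal(size=(n, p))
        labels = random_labels(n, rng, k=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsda(X, labels, A=1, cv_folds=min(7, n))
        vip = vip_scores(model)
        assert np.sum(vip**2) == pytest.approx(p, abs=1e-8)

    def test_symmetric_weights_give_unit_vip(self):
        X = np.array([[1.0, 1.0], [2, 2], [3, 3], [6, 6], [7, 7], [8, 8]])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsda(X + np.random.default_rng(0).normal(
                0, 1e-9, X.shape), labels, A=1, cv_folds=6)
        vip = vip_scores(model)
        assert np.allclose(vip, [1.0, 1.0], atol=1e-3)

    def test_matches_direct_formula_evaluation(self):
        """VIPs equal an independent evaluation of the formula from the
        stored weights and per-component explained Y sums of squares."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 5))
        labels = random_labels(8, rng, k=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsda(X, labels, A=2, cv_folds=4)
        W, ssy = model.weights, model.ssy
        p = W.shape[0]
        expected = np.array([
            np.sqrt(p * sum(ssy[a] * (W[j, a] / np.linalg.norm(W[:, a]))**2
                            for a in range(2)) / ssy.sum())
            for j in range(p)
        ])
        assert np.allclose(vip_scores(model), expected, atol=1e-10)


class TestPermutation:
    def test_null_data_permuted_r2y_matches_original(self):
        """When X carries no class signal the permuted fits are as good as
        the original on average."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(18, 8))
        labels = np.repeat(["a", "b", "c"], 6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = permutation_test(X, labels, n_perm=200, A=2, seed=0)
        assert abs(res.r2y.mean() - res.original_r2y) < 0.1

    def test_planted_cohort_beats_permutation_null(self, truth_area_matrix):
        X, labels = truth_area_matrix
        res = permutation_test(X, labels, n_perm=100, A=2, seed=1)
        assert res.q2_intercept < res.original_q2
        assert res.original_q2 > np.quantile(res.q2, 0.95)

    def test_fixed_seed_reproducible(self, truth_area_matrix):
        X, labels = truth_area_matrix
        a = permutation_test(X, labels, n_perm=25, A=2, seed=3)
        b = permutation_test(X, labels, n_perm=25, A=2, seed=3)
        assert np.array_equal(a.correlations, b.correlations)
        assert np.array_equal(a.q2, b.q2)


class TestMarkerSelection:
    def test_joint_rule(self):
        sel = select_markers(["P1", "P2"], [1.2, 0.8], [0.01, 0.01])
        assert sel.selected_ids == ["P1"]

    def test_boundary_vip_exactly_one_not_selected(self):
        sel = select_markers(["P1"], [1.0], [0.001])
        assert sel.selected_ids == []

    def test_boundary_p_exactly_cut_not_selected(self):
        sel = select_markers(["P1"], [1.5], [0.05])
        assert sel.selected_ids == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatchError):
            select_markers(["P1", "P2"], [1.0], [0.01, 0.01])

    def test_null_cohort_false_positives_within_alpha_budget(self):
        """With all fold changes zero, the VIP>1 AND p<0.05 rule selects at
        most the alpha-level expectation of peaks (0.05 * 30 + 1)."""
        counts = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed,
                                   log2_fold_changes=np.zeros((3, 17)))
            truth = simulate_ground_truth(cfg)
            X = truth.area_matrix().to_numpy(float)
            labels = truth.group_labels.to_numpy()
            model = fit_plsda(X, labels)
            vip = vip_scores(model)
            from soilprint.stats import anova_oneway
            groups = list(dict.fromkeys(labels))
            p = np.array([anova_oneway(
                [np.log2(X[labels == g, j]) for g in groups]).p_value
                for j in range(X.shape[1])])
            counts.append(len(select_markers(
                [f"P{j+1}" for j in range(30)], vip, p).selected_ids))
        assert np.mean(counts) <= 0.05 * 30 + 1

    def test_peak_anova_pvalues_align_with_matrix(self, common_matrix):
        p = peak_anova_pvalues(common_matrix)
        assert p.shape == (len(common_matrix.peak_ids),)
        assert np.all((p >= 0) & (p <= 1))
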