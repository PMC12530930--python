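"""Fisher classification functions, cross-validation, accuracy arithmetic
and hierarchical clustering."""

import numpy as np
import pytest

from soilprint import reference_data as ref
from soilprint.classification import (
    ConfusionMatrix,
    accuracy,
    adjusted_rand_index,
    classify,
    cross_validate,
    evaluate_function,
    fit_lda,
    hca,
)
from soilprint.exceptions import LengthMismatchError, SingularCovarianceError


def blobs(rng, centers, n=20, sd=0.1):
    X = np.vstack([c + rng.normal(0, sd, (n, len(c))) for c in centers])
    labels = np.repeat([f"g{i}" for i in range(len(centers))], n)
    return X, labels


class TestEvaluateFunction:
    @pytest.mark.parametrize("cls_name,expected", [
        ("MT I", -88.429), ("MT II", -787.894), ("QT", -342.565),
    ])
    def test_published_functions_at_zero_return_intercept(self, cls_name,
                                                          expected):
        coeffs, intercept = ref.FISHER_FUNCTIONS[cls_name]
        assert evaluate_function(coeffs, intercept,
                                 np.zeros(17)) == pytest.approx(expected)

    def test_unit_feature_adds_single_coefficient(self):
        coeffs, intercept = ref.FISHER_FUNCTIONS["MT I"]
        x = np.zeros(17)
        x[0] = 1.0  # X3 in the published feature order
        assert evaluate_function(coeffs, intercept, x) == pytest.approx(
            43.811 - 88.429)

    def test_affine_in_its_argument(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=6)
        x, y = rng.normal(size=6), rng.normal(size=6)
        a = 0.3
        lhs = evaluate_function(b, -2.0, a * x + (1 - a) * y)
        rhs = a * evaluate_function(b, -2.0, x) \
            + (1 - a) * evaluate_function(b, -2.0, y)
        assert lhs == pytest.approx(rhs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatchError):
            evaluate_function([1.0, 2.0], 0.0, [1.0])


class TestFitLDA:
    def test_separated_gaussians_classified_perfectly(self):
        rng = np.random.default_rng(1)
        X, labels = blobs(rng, [np.zeros(3), np.full(3, 5.0)], n=20, sd=0.1)
        model = fit_lda(X, labels)
        yhat, _ = classify(model, X)
        assert (yhat == labels).all()

    def test_duplicated_class_under_two_labels_equal_functions(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 4))
        X = np.vstack([base, base])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_lda(X, labels)
        assert np.allclose(model.coefficients[0], model.coefficients[1],
                           atol=1e-8)
        assert model.intercepts[0] == pytest.approx(model.intercepts[1])

    def test_class_mean_wins_its_own_function(self):
        rng = np.random.default_rng(3)
        X, labels = blobs(rng, [np.zeros(2), [3.0, 0.0], [0.0, 3.0]], n=10)
        model = fit_lda(X, labels)
        for k, c in enumerate(model.classes):
            mu = X[labels == c].mean(axis=0)
            pred, _ = classify(model, mu)
            assert pred == c

    def test_tied_scores_resolve_to_first_class_with_warning(self):
        model = fit_lda(np.array([[0.0], [0.1], [1.0], [0.9]]),
                        np.array(["a", "a", "b", "b"]))
        model.coefficients = np.zeros_like(model.coefficients)
        model.intercepts = np.zeros_like(model.intercepts)
        with pytest.warns(UserWarning, match="tied"):
            pred, _ = classify(model, np.array([0.5]))
        assert pred == "a"

    def test_common_intercept_shift_leaves_decision_unchanged(self):
        rng = np.random.default_rng(4)
        X, labels = blobs(rng, [np.zeros(3), np.full(3, 2.0)], n=8, sd=0.5)
        model = fit_lda(X, labels)
        base, _ = classify(model, X)
        model.intercepts = model.intercepts + 123.4
        shifted, _ = classify(model, X)
        assert (base == shifted).all()

    def test_large_shrinkage_approaches_diagonal_classifier(self):
        rng = np.random.default_rng(5)
        X, labels = blobs(rng, [np.zeros(4), np.full(4, 1.0)], n=15, sd=0.7)
        model = fit_lda(X, labels, regularization=("shrinkage", 1e6))
        # at lambda -> inf the regularized covariance is a scaled identity,
        # so coefficients align with the class means
        for k, c in enumerate(model.classes):
            mu = X[labels == c].mean(axis=0)
            cos = model.coefficients[k] @ mu / (
                np.linalg.norm(model.coefficients[k]) * np.linalg.norm(mu))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_singular_covariance_without_regularization_named_error(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 10))  # p > n: singular pooled covariance
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        with pytest.raises(SingularCovarianceError, match="shrinkage"):
            fit_lda(X, labels, regularization=("none",))

    def test_feature_id_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        X, labels = blobs(rng, [np.zeros(2), np.full(2, 4.0)], n=5)
        model = fit_lda(X, labels, feature_ids=["X1", "X2"])
        with pytest.raises(LengthMismatchError):
            classify(model, X[0], feature_ids=["X2", "X1"])

    def test_agrees_with_sklearn_lda_decisions(self):
        """Cross-check: with a well-conditioned pooled covariance the
        assignments match scikit-learn's LDA (same model, equal priors)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(8)
        X, labels = blobs(rng, [np.zeros(3), [1.5, 0, 0], [0, 1.5, 0]],
                          n=30, sd=1.0)
        ours, _ = classify(fit_lda(X, labels, regularization=("none",)), X)
        sk = LinearDiscriminantAnalysis(
            solver="lsqr", priors=np.full(3, 1 / 3)).fit(X, labels)
        assert (ours == sk.predict(X)).mean() > 0.98


class TestCrossValidation:
    def test_loo_on_separated_clusters_is_perfect(self):
        rng = np.random.default_rng(9)
        X, labels = blobs(rng, [np.zeros(2), np.full(2, 8.0)], n=10, sd=0.2)
        cm = cross_validate(X, labels, scheme=("loo",))
        assert accuracy(cm) == pytest.approx(100.0)

    def test_shuffled_labels_score_at_chance(self):
        """LOO accuracy on structureless data with shuffled labels sits
        near 1/k.  Leave-one-out is slightly pessimistic on balanced
        nulls (the held-out sample's own class loses a training member),
        so the band allows a small downward bias but no upward one."""
        rng = np.random.default_rng(10)
        accs = []
        for _ in range(20):
            X = rng.normal(size=(18, 6))
            labels = np.repeat(["a", "b", "c"], 6)
            rng.shuffle(labels)
            accs.append(accuracy(cross_validate(X, labels)) / 100.0)
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(accs.size)
        assert 1 / 3 - 0.12 < accs.mean() < 1 / 3 + 3 * max(se, 0.02)

    def test_single_sample_class_loo_rejected(self):
        X = np.array([[0.0], [0.1], [5.0]])
        labels = np.array(["a", "a", "b"])
        with pytest.raises(ValueError, match="class"):
            cross_validate(X, labels, scheme=("loo",))


class TestAccuracy:
    def test_published_cross_validation_rows_give_95_5(self):
        assert round(accuracy(ref.CONFUSION_CROSS_VALIDATION), 1) == 95.5

    def test_published_training_rows_give_100(self):
        assert accuracy(ref.CONFUSION_TRAINING) == pytest.approx(100.0)

    def test_per_class_row_1_0_6_gives_85_7(self):
        per = accuracy(ref.CONFUSION_CROSS_VALIDATION, mode="per_class")
        assert round(per[2], 1) == 85.7

    def test_overall_is_row_weighted_mean_of_per_class(self):
        counts = np.array([[5, 1, 0], [2, 7, 1], [0, 0, 4]])
        per = accuracy(counts, "per_class")
        weights = counts.sum(axis=1)
        assert accuracy(counts) == pytest.approx(
            np.sum(per * weights) / weights.sum())


class TestHCA:
    def test_three_separated_groups_recovered_exactly(self):
        rng = np.random.default_rng(11)
        X, labels = blobs(rng, [np.zeros(4), np.full(4, 6.0),
                                np.r_[6.0, -6.0, 6.0, -6.0]], n=6, sd=0.3)
        res = hca(X, k=3)
        assert adjusted_rand_index(res.assignments, labels) == pytest.approx(1.0)

    def test_duplicated_sample_merges_first_at_zero_height(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        res = hca(X, standardize=False)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError):
            hca(np.zeros((3, 2)), k=4)

    @pytest.mark.parametrize("method", ["average", "complete", "ward"])
    def test_matches_brute_force_agglomeration(self, method):
        """Merge heights equal an O(n^3) Lance-Williams agglomeration run
        independently on the same 5-point set."""
        X = np.random.default_rng(12).normal(size=(5, 3))
        res = hca(X, method=method, standardize=False)
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        active = list(range(5))
        sizes = {i: 1 for i in range(5)}
        dmat = {frozenset((i, j)): D[i, j]
                for i in range(5) for j in range(i + 1, 5)}
        heights = []
        nxt = 5
        while len(active) > 1:
            pair = min(dmat, key=lambda k: dmat[k])
            d = dmat[pair]
            i, j = sorted(pair)
            heights.append(d)
            ni, nj = sizes[i], sizes[j]
            updates = {}
            for k in active:
                if k in (i, j):
                    continue
                dik, djk, nk = dmat[frozenset((i, k))], dmat[frozenset((j, k))], sizes[k]
                if method == "average":
                    updates[k] = (ni * dik + nj * djk) / (ni + nj)
                elif method == "complete":
                    updates[k] = max(dik, djk)
                else:  # ward (Lance-Williams on euclidean distances)
                    updates[k] = np.sqrt(
                        ((ni + nk) * dik**2 + (nj + nk) * djk**2
                         - nk * d**2) / (ni + nj + nk))
            for kk in list(dmat):
                if i in kk or j in kk:
                    del dmat[kk]
            active = [k for k in active if k not in (i, j)] + [nxt]
            sizes[nxt] = ni + nj
            for k, v in updates.items():
                dmat[frozenset((nxt, k))] = v
            nxt += 1
        assert np.allclose(sorted(heights), res.linkage_matrix[:, 2],
                           atol=1e-10)

    def test_tree_text_renders_all_samples(self):
        X = np.random.default_rng(13).normal(size=(4, 2))
        res = hca(X, sample_ids=["s1", "s2", "s3", "s4"], standardize=False)
        text = res.tree_text()
        assert all(s in text for s in ["s1", "s2", "s3", "s4"])
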