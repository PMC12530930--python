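"""Origin tracing: Fisher linear classification functions and HCA.

The classifier fits one linear score function per origin class,
``Y_k(x) = b_k . x + c_k`` with ``b_k = S^-1 mu_k`` and
``c_k = -1/2 mu_k' S^-1 mu_k + ln(prior_k)``, where S is the pooled
within-class covariance.  A sample is assigned to the class with the
largest score.  With 17 peak features and only 15 pooled within-class
degrees of freedom (18 samples, 3 classes) S is singular, so shrinkage
toward a scaled identity is on by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .exceptions import LengthMismatchError, SingularCovarianceError


# --------------------------------------------------------------------------
# Fisher classification functions

@dataclass
class LDAModel:
    classes: list
    coefficients: np.ndarray      # k x p, rows b_k
    intercepts: np.ndarray        # k, entries c_k
    feature_ids: list[str]
    pooled_cov: np.ndarray
    regularization: tuple
    priors: np.ndarray

    def scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != len(self.feature_ids):
            raise LengthMismatchError(
                f"expected {len(self.feature_ids)} features, got {x.shape[1]}"
            )
        return x @ self.coefficients.T + self.intercepts


def evaluate_function(coeffs, intercept: float, x) -> float:
    """One linear classification function: inner product plus intercept,
    features taken in the model's declared order."""
    coeffs = np.asarray(coeffs, float)
    x = np.asarray(x, float)
    if coeffs.shape != x.shape:
        raise LengthMismatchError(
            f"coefficient/feature length mismatch: {coeffs.shape} vs {x.shape}"
        )
    return float(coeffs @ x + intercept)


def fit_lda(X, labels, regularization: tuple = ("shrinkage", 0.01),
            priors=None, feature_ids: list[str] | None = None) -> LDAModel:
    """Fit per-class Fisher linear classification functions.

    ``regularization`` is ``("shrinkage", lam)`` — S + lam*trace(S)/p*I —
    or ``("pseudoinverse",)``.  Priors default to equal across classes.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))
    n, p = X.shape
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    mus = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    S = np.zeros((p, p))
    for c, mu in zip(classes, mus):
        R = X[labels == c] - mu
        S += R.T @ R
    S /= n - len(classes)

    kind = regularization[0]
    if kind == "shrinkage":
        lam = float(regularization[1])
        S_reg = S + lam * np.trace(S) / p * np.eye(p)
        solve = lambda b: np.linalg.solve(S_reg, b)  # noqa: E731
    elif kind == "pseudoinverse":
        S_reg = S
        S_pinv = np.linalg.pinv(S)
        solve = lambda b: S_pinv @ b  # noqa: E731
    elif kind == "none":
        S_reg = S
        if np.linalg.cond(S) > 1e12:
            raise SingularCovarianceError(
                "pooled within-class covariance is singular; use "
                "('shrinkage', lam) or ('pseudoinverse',)"
            )
        solve = lambda b: np.linalg.solve(S, b)  # noqa: E731
    else:
        raise ValueError(f"unknown regularization {regularization!r}")

    priors = (np.full(len(classes), 1.0 / len(classes)) if priors is None
              else np.asarray(priors, float))
    B = np.vstack([solve(mu) for mu in mus])
    c0 = np.array([
        -0.5 * mu @ b + np.log(pr) for mu, b, pr in zip(mus, B, priors)
    ])
    ids = feature_ids or [f"X{j + 1}" for j in range(p)]
    if len(ids) != p:
        raise LengthMismatchError("feature_ids length must match columns")
    return LDAModel(classes, B, c0, list(ids), S_reg, tuple(regularization),
                    priors)


def classify(model: LDAModel, x, feature_ids: list[str] | None = None):
    """Assign sample(s) to the class with the largest score.

    Ties break deterministically to the earlier class in the model's
    class order, with a warning.
    """
    if feature_ids is not None and list(feature_ids) != model.feature_ids:
        raise LengthMismatchError(
            "feature ids do not match the model's feature order"
        )
    x = np.asarray(x, float)
    single = x.ndim == 1
    sc = model.scores(x)
    out = []
    for row in sc:
        winners = np.flatnonzero(row == row.max())
        if winners.size > 1:
            warnings.warn("tied classification scores; taking the first class",
                          stacklevel=2)
        out.append(model.classes[winners[0]])
    return (out[0], sc[0]) if single else (np.array(out), sc)


# --------------------------------------------------------------------------
# confusion matrices and accuracy

@dataclass
class ConfusionMatrix:
    classes: list
    counts: np.ndarray  # true x predicted
    scope: str  # training | cross_validation | external

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes, scope: str):
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        index = {c: i for i, c in enumerate(classes)}
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(list(classes), counts, scope)


def accuracy(cm: ConfusionMatrix | np.ndarray, mode: str = "overall"):
    """Overall = 100*trace/total; per_class = 100*diagonal/row-sum
    (NaN for an empty row)."""
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    if mode == "overall":
        return float(100.0 * np.trace(counts) / total)
    if mode == "per_class":
        rows = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * np.diag(counts) / np.where(rows == 0, np.nan, rows)
    raise ValueError(f"unknown accuracy mode {mode!r}")


def cross_validate(X, labels, scheme: tuple = ("loo",),
                   regularization: tuple = ("shrinkage", 0.01),
                   priors=None) -> ConfusionMatrix:
    """Refit excluding held-out unit(s); aggregate predictions.

    ``scheme`` is ``("loo",)`` or ``("kfold", k)`` with deterministic
    interleaved fold assignment by sample index.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))
    n = X.shape[0]
    if scheme[0] == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme[0] == "kfold":
        k = int(scheme[1])
        folds = [np.flatnonzero(np.arange(n) % k == f) for f in range(k)]
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    preds = np.empty(n, dtype=object)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        for c in classes:
            if np.sum(labels[train] == c) < 2:
                raise ValueError(
                    f"fold leaves class {c!r} with < 2 training samples"
                )
        model = fit_lda(X[train], labels[train], regularization, priors)
        yhat, _ = classify(model, X[test])
        preds[test] = np.atleast_1d(yhat)
    return ConfusionMatrix.from_predictions(labels, preds, classes,
                                            "cross_validation")


# --------------------------------------------------------------------------
# hierarchical clustering

@dataclass
class HCAResult:
    linkage_matrix: np.ndarray
    metric: str
    method: str
    assignments: np.ndarray | None
    sample_ids: list[str] | None = None

    def tree_text(self) -> str:
        """Bracketed (Newick-like) rendering of the merge tree."""
        n = self.linkage_matrix.shape[0] + 1
        names = self.sample_ids or [str(i) for i in range(n)]
        nodes = {i: names[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.4g}"
        return nodes[n + self.linkage_matrix.shape[0] - 1] + ";"


def hca(X, metric: str = "euclidean", method: str = "ward",
        k: int | None = None, sample_ids: list[str] | None = None,
        standardize: bool = True) -> HCAResult:
    """Agglomerative clustering of samples; cut to ``k`` clusters when
    requested.  Features are autoscaled by default so high-abundance
    peaks do not dominate the distances."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("HCA needs at least two samples")
    if k is not None and k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of samples {X.shape[0]}")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    Z = hierarchy.linkage(X, method=method, metric=metric)
    assignments = (hierarchy.fcluster(Z, t=k, criterion="maxclust")
                   if k is not None else None)
    return HCAResult(Z, metric, method, assignments, sample_ids)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise LengthMismatchError("partitions must cover the same samples")
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua])
    comb = lambda m: m * (m - 1) / 2.0  # noqa: E731
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    total = comb(a.size)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
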