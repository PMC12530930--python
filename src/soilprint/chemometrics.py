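"""Chemometrics: PCA, NIPALS PLS-DA with cross-validated Q2, VIP scores,
permutation validation and characteristic-peak selection.

PLS-DA regresses the autoscaled common-peak matrix against a centred
one-hot class indicator.  Model quality is summarized by R2Y (fraction of
class variance fitted) and Q2 (cross-validated 1 - PRESS/SS, venetian
blinds over sample index); Q2 > 0.5 is the conventional predictability
gate.  Variable importance in projection (VIP) scores, whose squares
average to 1, rank peaks; characteristic peaks are those with VIP > 1
and one-way ANOVA p < 0.05 across the groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConstantVectorError, LengthMismatchError
from .fingerprint import CommonPeakMatrix

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


# --------------------------------------------------------------------------
# scaling helpers

def _scale_params(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=1)
    elif scaling == "center_only":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return mean, sd


def _apply_scale(X, mean, sd):
    safe = np.where(sd == 0, 1.0, sd)
    return (X - mean) / safe


def _fix_sign(w: np.ndarray) -> float:
    """Sign convention: first element of largest magnitude-bearing position
    nonzero entry is positive."""
    nz = np.flatnonzero(np.abs(w) > 1e-12)
    if nz.size and w[nz[0]] < 0:
        return -1.0
    return 1.0


def one_hot(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))
    Y = np.zeros((labels.size, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y, classes


# --------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray        # p x A, orthonormal columns
    scores: np.ndarray          # n x A
    explained_pct: np.ndarray   # per component, sums to 100 over all


def run_pca(X, scaling: str = "unit_variance") -> PCAModel:
    """Principal components of the scaled matrix via singular value
    decomposition; explained % is each squared singular value over the
    total."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs a 2-D matrix with >= 2 samples and variables")
    mean, sd = _scale_params(X, scaling)
    if scaling == "unit_variance" and np.any(sd == 0):
        cols = np.flatnonzero(sd == 0).tolist()
        raise ConstantVectorError(
            f"constant column(s) {cols} cannot be unit-variance scaled"
        )
    Xs = _apply_scale(X, mean, sd)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    signs = np.array([_fix_sign(v) for v in Vt])
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    explained = 100.0 * S**2 / np.sum(S**2)
    return PCAModel(mean, sd, Vt.T, U * S, explained)


# --------------------------------------------------------------------------
# PLS-DA

@dataclass
class PLSDAModel:
    """NIPALS PLS2 fit against a centred one-hot class indicator."""

    classes: list
    n_components: int
    weights: np.ndarray        # W, p x A
    x_loadings: np.ndarray     # P, p x A
    y_loadings: np.ndarray     # C, g x A
    scores: np.ndarray         # T, n x A
    ssy: np.ndarray            # explained Y sum of squares per component
    r2y: float
    q2: float
    x_mean: np.ndarray = field(repr=False, default=None)
    x_sd: np.ndarray = field(repr=False, default=None)
    y_mean: np.ndarray = field(repr=False, default=None)
    scaling: str = "unit_variance"

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients B (p x g) on the scaled axes."""
        W, P, C = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, C.T)

    def predict_scores(self, X) -> np.ndarray:
        Xs = _apply_scale(np.asarray(X, float), self.x_mean, self.x_sd)
        return Xs @ self.coef + self.y_mean

    def predict(self, X) -> np.ndarray:
        Yhat = self.predict_scores(X)
        return np.array([self.classes[j] for j in np.argmax(Yhat, axis=1)])


def _nipals(Xs: np.ndarray, Y0: np.ndarray, A: int):
    E, F = Xs.copy(), Y0.copy()
    n, p = Xs.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    C = np.zeros((Y0.shape[1], A))
    T = np.zeros((n, A))
    ssy = np.zeros(A)
    for a in range(A):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if np.allclose(u, 0):
            break
        for _ in range(NIPALS_MAX_ITER):
            w = E.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = E @ w
            c = F.T @ t / (t @ t)
            u_new = F @ c / (c @ c)
            if np.linalg.norm(u_new - u) <= NIPALS_TOL * max(
                    np.linalg.norm(u_new), 1e-30):
                u = u_new
                break
            u = u_new
        s = _fix_sign(w)
        w, t, c = s * w, s * t, s * c
        pl = E.T @ t / (t @ t)
        E -= np.outer(t, pl)
        F -= np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, pl, c, t
        ssy[a] = (t @ t) * (c @ c)
    return W, P, C, T, ssy, F


def _venetian_folds(n: int, folds: int) -> list[np.ndarray]:
    return [np.arange(n)[np.arange(n) % folds == f] for f in range(folds)
            if np.any(np.arange(n) % folds == f)]


def fit_plsda(X, labels, A: int | None = None, cv_folds: int = 7,
              scaling: str = "unit_variance") -> PLSDAModel:
    """Fit PLS-DA and report R2Y and venetian-blind cross-validated Q2.

    ``A`` defaults to min(2, n_classes - 1).  Requesting more components
    than the rank of X supports truncates with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    Y, classes = one_hot(labels)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    if A is None:
        A = min(2, len(classes) - 1)
    if A < 1:
        raise ValueError("need at least one component")
    max_a = min(n - 1, p)
    if A > max_a:
        warnings.warn(f"A={A} exceeds the rank bound {max_a}; truncating",
                      stacklevel=2)
        A = max_a

    x_mean, x_sd = _scale_params(X, scaling)
    Xs = _apply_scale(X, x_mean, x_sd)
    y_mean = Y.mean(axis=0)
    Y0 = Y - y_mean
    ss_y = float(np.sum(Y0**2))
    W, P, C, T, ssy, F = _nipals(Xs, Y0, A)
    r2y = 1.0 - float(np.sum(F**2)) / ss_y

    # cross-validated Q2
    press = 0.0
    for test in _venetian_folds(n, cv_folds):
        train = np.setdiff1d(np.arange(n), test)
        counts = {c: int(np.sum(labels[train] == c)) for c in classes}
        if min(counts.values()) < 1:
            raise ValueError("a CV fold left a class empty; use fewer folds")
        if min(counts.values()) < 2:
            warnings.warn("a CV training fold has a single-member class",
                          stacklevel=2)
        m, s = _scale_params(X[train], scaling)
        Xtr = _apply_scale(X[train], m, s)
        ym = Y[train].mean(axis=0)
        Wf, Pf, Cf, _, _, _ = _nipals(Xtr, Y[train] - ym, A)
        B = Wf @ np.linalg.solve(Pf.T @ Wf, Cf.T)
        Yhat = _apply_scale(X[test], m, s) @ B + ym
        press += float(np.sum((Y[test] - Yhat) ** 2))
    q2 = 1.0 - press / ss_y

    return PLSDAModel(classes, A, W, P, C, T, ssy, r2y, q2,
                      x_mean, x_sd, y_mean, scaling)


def choose_components(X, labels, max_a: int = 5, cv_folds: int = 7,
                      scaling: str = "unit_variance") -> int:
    """Smallest A at the first local maximum of Q2 over 1..max_a."""
    best_a, best_q2 = 1, -np.inf
    for a in range(1, max_a + 1):
        try:
            q2 = fit_plsda(X, labels, A=a, cv_folds=cv_folds,
                           scaling=scaling).q2
        except (ValueError, np.linalg.LinAlgError):
            break
        if q2 <= best_q2:
            break
        best_a, best_q2 = a, q2
    return best_a


# --------------------------------------------------------------------------
# VIP

def vip_scores(model: PLSDAModel) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a)."""
    W, ssy = model.weights, model.ssy
    total = ssy.sum()
    if total <= 0:
        raise ConstantVectorError("zero explained Y variance; VIP undefined")
    p = W.shape[0]
    wn2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wn2 @ ssy) / total)


# --------------------------------------------------------------------------
# permutation test

@dataclass
class PermutationResult:
    """Label-permutation validation of a PLS-DA model.

    Per permutation: the Pearson correlation between the permuted and
    original (centred one-hot) class assignment, and the refit R2Y / Q2.
    The original model enters the fitted lines at correlation 1; the
    regression-line intercepts at zero correlation summarize chance-level
    performance.
    """

    correlations: np.ndarray
    r2y: np.ndarray
    q2: np.ndarray
    original_r2y: float
    original_q2: float
    r2_intercept: float
    q2_intercept: float
    seed: int


def permutation_test(X, labels, n_perm: int = 200, A: int | None = None,
                     cv_folds: int = 7, seed: int = 0,
                     scaling: str = "unit_variance") -> PermutationResult:
    """Refit PLS-DA under uniformly permuted labels.

    Permutations identical to the original assignment are kept: they are
    valid draws from the permutation null.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    labels = np.asarray(labels)
    original = fit_plsda(X, labels, A=A, cv_folds=cv_folds, scaling=scaling)
    Y0, _ = one_hot(labels)
    Y0c = (Y0 - Y0.mean(axis=0)).ravel()
    rng = np.random.default_rng(seed)
    corrs, r2s, q2s = [], [], []
    for _ in range(n_perm):
        perm = rng.permutation(labels.size)
        lp = labels[perm]
        Yp = Y0[perm] - Y0[perm].mean(axis=0)
        corrs.append(float(np.corrcoef(Yp.ravel(), Y0c)[0, 1]))
        m = fit_plsda(X, lp, A=original.n_components, cv_folds=cv_folds,
                      scaling=scaling)
        r2s.append(m.r2y)
        q2s.append(m.q2)
    corrs, r2s, q2s = map(np.asarray, (corrs, r2s, q2s))
    xs = np.append(corrs, 1.0)
    r2_line = np.polyfit(xs, np.append(r2s, original.r2y), 1)
    q2_line = np.polyfit(xs, np.append(q2s, original.q2), 1)
    return PermutationResult(corrs, r2s, q2s, original.r2y, original.q2,
                             float(r2_line[1]), float(q2_line[1]), seed)


# --------------------------------------------------------------------------
# marker selection

@dataclass
class MarkerSelection:
    table: pd.DataFrame  # peak_id, vip, p_value, selected (RT/ordinal order)

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "peak_id"])


def select_markers(peak_ids, vip, p_values, vip_cut: float = 1.0,
                   p_cut: float = 0.05) -> MarkerSelection:
    """Characteristic peaks: VIP strictly above ``vip_cut`` AND ANOVA p
    strictly below ``p_cut``."""
    vip = np.asarray(vip, float)
    p_values = np.asarray(p_values, float)
    peak_ids = list(peak_ids)
    if not (len(peak_ids) == vip.size == p_values.size):
        raise LengthMismatchError(
            f"ids/VIP/p lengths differ: {len(peak_ids)}, {vip.size}, "
            f"{p_values.size}"
        )
    selected = (vip > vip_cut) & (p_values < p_cut)
    table = pd.DataFrame({
        "peak_id": peak_ids, "vip": vip, "p_value": p_values,
        "selected": selected,
    })
    return MarkerSelection(table)


def peak_anova_pvalues(matrix: CommonPeakMatrix, log2: bool = True
                       ) -> np.ndarray:
    """One-way ANOVA p-value per common peak across the group labels,
    on log2 areas by default (areas are right-skewed)."""
    from .stats import anova_oneway

    labels = matrix.labels()
    groups = list(dict.fromkeys(labels))
    ps = []
    for pid in matrix.peak_ids:
        col = matrix.areas[pid].to_numpy(dtype=float)
        col = np.log2(col) if log2 else col
        ps.append(anova_oneway([col[labels == g] for g in groups]).p_value)
    return np.asarray(ps)
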