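"""One-way ANOVA, Duncan's multiple range test, and marker-vs-soil
correlation analysis.

``anova_from_summary`` accepts printed (mean, SD, n) summaries and is
algebraically identical to ``anova_oneway`` on matched raw data, which
lets published group summaries be tested directly.  Duncan's test uses
studentized-range quantiles at the span-dependent protection level
``alpha_p = 1 - (1 - alpha)**(p - 1)`` rather than tabulated constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError
from . import reference_data as ref


# --------------------------------------------------------------------------
# one-way ANOVA

@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: np.ndarray
    mse: float
    ss_between: float
    ss_within: float
    ns: np.ndarray


def _anova_from_ss(ssb: float, ssw: float, ns: np.ndarray,
                   means: np.ndarray) -> AnovaResult:
    k = means.size
    dfb = k - 1
    dfw = int(ns.sum()) - k
    if dfw < 1:
        raise DegenerateDataError("no within-group degrees of freedom")
    if ssw <= 0:
        if ssb <= 0:
            raise DegenerateDataError(
                "zero within-group variance with equal means: F undefined"
            )
        return AnovaResult(np.inf, dfb, dfw, 0.0, means, 0.0, ssb, 0.0, ns)
    mse = ssw / dfw
    f = (ssb / dfb) / mse
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), dfb, dfw, p, means, float(mse),
                       float(ssb), float(ssw), ns)


def anova_oneway(groups: list) -> AnovaResult:
    """Standard between/within sum-of-squares decomposition."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    return _anova_from_ss(ssb, ssw, ns, means)


def anova_from_summary(means, sds, ns) -> AnovaResult:
    """ANOVA from per-group (mean, SD, n): SSB = sum n_i (xbar_i - xbar)^2,
    SSW = sum (n_i - 1) s_i^2."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if not (means.size == sds.size == ns.size) or means.size < 2:
        raise ValueError("need matched means/SDs/ns for >= 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    grand = float(np.sum(ns * means) / ns.sum())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    return _anova_from_ss(ssb, ssw, ns, means)


# --------------------------------------------------------------------------
# Duncan's multiple range test

@dataclass
class DuncanLetters:
    letters: dict  # group label -> letter string
    ranked_groups: list
    ranges: dict   # span p -> least significant range R_p
    alpha: float


def duncan_critical_range(alpha: float, span: int, df: int, nh: float,
                          mse: float) -> float:
    """Least significant range R_p: studentized-range quantile at Duncan's
    protection level alpha_p = 1 - (1 - alpha)**(p - 1), scaled by
    sqrt(MSE / n_h)."""
    q = sps.studentized_range.ppf((1.0 - alpha) ** (span - 1), span, df)
    return float(q * np.sqrt(mse / nh))


def duncan_mrt(means, mse: float, df_error: int, ns, alpha: float = 0.05,
               labels=None) -> DuncanLetters:
    """Stepwise range comparisons with letter display.

    Means are ranked descending; the gap between the extremes of every
    span-p window is compared to R_p, except that windows inside an
    already non-significant window inherit non-significance (Duncan's
    protection rule).  Groups sharing a letter are not separated.
    """
    means = np.asarray(means, float)
    ns = np.asarray(ns, int)
    k = means.size
    if df_error < 1:
        raise DegenerateDataError("df_error must be >= 1")
    labels = list(labels) if labels is not None else [f"G{i+1}" for i in range(k)]
    nh = k / np.sum(1.0 / ns)  # harmonic mean (Kramer adjustment)
    order = np.argsort(-means)
    ranked = means[order]
    ranges = {p: duncan_critical_range(alpha, p, df_error, nh, mse)
              for p in range(2, k + 1)}

    # non-significant windows on the ranked means, widest spans first
    ns_windows: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in ns_windows):
                continue
            if ranked[i] - ranked[j] <= ranges[span]:
                ns_windows.append((i, j))
    # maximal windows plus uncovered singletons become the letter groups
    windows = [w for w in ns_windows
               if not any(w != o and o[0] <= w[0] and w[1] <= o[1]
                          for o in ns_windows)]
    covered = {i for a, b in windows for i in range(a, b + 1)}
    windows += [(i, i) for i in range(k) if i not in covered]
    windows.sort()
    letters = {lab: "" for lab in labels}
    for w_idx, (a, b) in enumerate(windows):
        ch = chr(ord("a") + w_idx)
        for i in range(a, b + 1):
            letters[labels[order[i]]] += ch
    return DuncanLetters(letters, [labels[i] for i in order], ranges, alpha)


def anova_duncan_report(table: pd.DataFrame, variables=ref.SOIL_VARIABLES,
                        group_col: str = "group", alpha: float = 0.05
                        ) -> pd.DataFrame:
    """Per-variable ANOVA + Duncan letters for a physicochemical table,
    rendered as ``mean ± SD`` with letter superscripts."""
    groups = list(dict.fromkeys(table[group_col]))
    rows = {}
    for var in variables:
        arrays = [table.loc[table[group_col] == g, var].to_numpy(float)
                  for g in groups]
        res = anova_oneway(arrays)
        letters = duncan_mrt(res.group_means, res.mse, res.df_within,
                             res.ns, alpha=alpha, labels=groups)
        rows[var] = {
            g: f"{a.mean():.2f} ± {a.std(ddof=1):.2f}{letters.letters[g]}"
            for g, a in zip(groups, arrays)
        }
        rows[var]["p_value"] = res.p_value
    return pd.DataFrame(rows).T


# --------------------------------------------------------------------------
# correlation matrix

@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """'**' for p < 0.01, '*' for p < 0.05, blank otherwise."""
        def mark(p):
            if np.isnan(p):
                return ""
            return "**" if p < 0.01 else ("*" if p < 0.05 else "")
        return self.p.map(mark)


def pearson_matrix(marker_areas: pd.DataFrame, soil_table: pd.DataFrame,
                   log2: bool = True) -> CorrelationMatrix:
    """Pairwise Pearson r (with two-sided t-based p) between marker peak
    areas and soil variables over matched samples.

    Marker areas are log2-transformed by default.  A constant column
    yields NaN cells rather than an error.
    """
    soil = soil_table.set_index("sample_id") if "sample_id" in soil_table else soil_table
    soil_vars = [v for v in ref.SOIL_VARIABLES if v in soil.columns]
    common = [s for s in marker_areas.index if s in soil.index]
    if len(common) < 3:
        raise ValueError("need >= 3 matched samples")
    M = marker_areas.loc[common]
    if log2:
        M = np.log2(M)
    r = pd.DataFrame(index=M.columns, columns=soil_vars, dtype=float)
    p = r.copy()
    for peak in M.columns:
        x = M[peak].to_numpy(float)
        for var in soil_vars:
            y = soil.loc[common, var].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r.loc[peak, var] = np.nan
                p.loc[peak, var] = np.nan
                continue
            rv, pv = sps.pearsonr(x, y)
            r.loc[peak, var] = rv
            p.loc[peak, var] = pv
    return CorrelationMatrix(r, p)
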