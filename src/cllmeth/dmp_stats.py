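"""Cohort descriptive statistics and per-probe differential methylation.

The probe-level model is ordinary least squares of M-values on group plus
covariates, with a two-sided t-test on the group coefficient, BH adjustment
across probes, and the decision rule |delta-beta| > 0.2 & q < 0.05.
An optional empirical-Bayes flag squeezes per-probe variances toward a
moment-matched scaled inverse-chi-square prior (limma-style moderation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ConfigError


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) in sorted order; ties share q
    and the map is order-preserving.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test (normal approximation, continuity + ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample in rank-sum test")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Chi-square with Yates continuity correction for a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("chi_square_2x2 expects a 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def cohort_table(sample_sheet: pd.DataFrame,
                 group_col: str = "group",
                 case: str = "CLL",
                 control: str = "control",
                 continuous: tuple[str, ...] = ("age", "wbc", "alc"),
                 categorical: tuple[str, ...] = ("sex",)) -> pd.DataFrame:
    """Per-group medians (IQRs) / frequencies with the matching tests.

    Continuous variables: two-sided Wilcoxon rank-sum. Categorical
    variables: 2x2 chi-square with Yates continuity correction. Missing
    values are dropped per variable.
    """
    groups = sample_sheet[group_col]
    a = sample_sheet[groups == case]
    b = sample_sheet[groups == control]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group: {case}={len(a)}, {control}={len(b)}")

    rows = []
    for var in continuous:
        if var not in sample_sheet.columns:
            continue
        xa = pd.to_numeric(a[var], errors="coerce").dropna()
        xb = pd.to_numeric(b[var], errors="coerce").dropna()
        _, p = wilcoxon_rank_sum(xa, xb)
        fmt = lambda s: f"{s.median():g} ({s.quantile(0.25):g}-{s.quantile(0.75):g})"
        rows.append((var, "wilcoxon", fmt(xa), fmt(xb), p))
    for var in categorical:
        if var not in sample_sheet.columns:
            continue
        va, vb = a[var].dropna(), b[var].dropna()
        levels = sorted(set(va) | set(vb))
        if len(levels) != 2:
            raise ValueError(f"categorical variable {var!r} must have two levels, got {levels}")
        table = np.array([[int((va == lv).sum()) for lv in levels],
                          [int((vb == lv).sum()) for lv in levels]])
        _, p = chi_square_2x2(table)
        fmt = lambda v: "/".join(f"{lv}:{int((v == lv).sum())}" for lv in levels)
        rows.append((var, "chi_square_yates", fmt(va), fmt(vb), p))
    return pd.DataFrame(rows, columns=["variable", "test", case, control, "p"])


@dataclass
class DMPCriteria:
    delta_beta: float = 0.2
    fdr: float = 0.05

    def validate(self) -> None:
        if not 0.0 < self.delta_beta < 1.0:
            raise ConfigError("delta_beta threshold must be in (0, 1)")
        if not 0.0 < self.fdr < 1.0:
            raise ConfigError("fdr threshold must be in (0, 1)")


def _build_design(sample_sheet: pd.DataFrame, samples: pd.Index, group_col: str,
                  case: str, control: str, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str], np.ndarray]:
    sheet = sample_sheet.loc[samples]
    mask = sheet[group_col].isin([case, control]).to_numpy()
    sheet = sheet[mask]
    cols: list[np.ndarray] = [np.ones(len(sheet)), (sheet[group_col] == case).to_numpy(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        col = sheet[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                names.append(f"{cov}[{c}]")
        else:
            cols.append(pd.to_numeric(col, errors="coerce").fillna(col.median()).to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify collinear columns by testing rank after removal
        collinear = []
        for j in range(X.shape[1]):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj) == np.linalg.matrix_rank(X):
                collinear.append(names[j])
        raise ConfigError(f"rank-deficient design; collinear columns: {collinear}")
    return X, names, mask


def _moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Squeeze variances toward a scaled inverse-chi-square prior.

    Prior (d0, s0^2) fitted by matching moments of log(s2) using
    digamma/trigamma identities; returns posterior variances and extra df.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1)
    target = var_z - special.polygamma(1, df / 2.0)
    if target <= 0:
        d0 = np.inf
        s02 = np.exp(e_z - special.digamma(df / 2.0) + np.log(df / 2.0))
        post = np.full_like(s2, s02)
        post[ok] = s02
        return post, np.inf
    # solve trigamma(d0/2) = target
    lo, hi = 1e-6, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2.0) > target:
            lo = mid
        else:
            hi = mid
    d0 = np.sqrt(lo * hi)
    s02 = np.exp(e_z - special.digamma(df / 2.0) + np.log(df / 2.0)
                 + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, float(d0)


def fit_dmp(m: pd.DataFrame, sample_sheet: pd.DataFrame,
            beta: pd.DataFrame | None = None,
            covariates: tuple[str, ...] = ("age", "sex"),
            criteria: DMPCriteria | None = None,
            group_col: str = "group", case: str = "CLL", control: str = "control",
            moderated: bool = False) -> pd.DataFrame:
    """Per-probe OLS of M on group + covariates; DMP calls per criteria.

    delta_beta is computed on the supplied beta matrix (pre-M, normalized);
    when absent it is derived by inverting the M transform. Zero-variance
    probes get p = 1 by convention so BH stays well-defined.
    """
    criteria = criteria or DMPCriteria()
    criteria.validate()
    X, names, mask = _build_design(sample_sheet, m.columns, group_col, case, control, covariates)
    used = m.columns[mask]
    n, k = X.shape
    if (X[:, 1] == 1).sum() < 3 or (X[:, 1] == 0).sum() < 3:
        raise ConfigError("need at least 3 samples per group")
    if n <= k:
        raise ConfigError("not enough samples for the design")

    Y = m[used].to_numpy(dtype=float)  # probes x n
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ X @ xtx_inv.T  # probes x k
    resid = Y - coefs @ X.T
    df = n - k
    s2 = (resid ** 2).sum(axis=1) / df

    zero_var = Y.var(axis=1) < 1e-14
    if moderated:
        s2_used, d0 = _moderate_variances(np.maximum(s2, 1e-300), df)
        df_total = df + d0 if np.isfinite(d0) else np.inf
    else:
        s2_used, df_total = s2, df
    se = np.sqrt(np.maximum(s2_used, 1e-300) * xtx_inv[1, 1])
    tstat = np.where(se > 0, coefs[:, 1] / se, 0.0)
    if np.isfinite(df_total):
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    pvals = np.where(zero_var, 1.0, pvals)
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance probes assigned p=1")
    qvals = bh_fdr(pvals)

    is_case = X[:, 1] == 1
    if beta is not None:
        Bv = beta.loc[m.index, used].to_numpy(dtype=float)
    else:
        Bv = 1.0 / (1.0 + np.exp2(-Y))
    delta = Bv[:, is_case].mean(axis=1) - Bv[:, ~is_case].mean(axis=1)

    out = pd.DataFrame(
        {
            "delta_beta": delta,
            "coef_m": coefs[:, 1],
            "p": pvals,
            "q": qvals,
            "direction": np.where(delta >= 0, "hyper", "hypo"),
            "is_dmp": (np.abs(delta) > criteria.delta_beta) & (qvals < criteria.fdr),
        },
        index=pd.Index(m.index, name="probe_id"),
    )
    return out


def feature_distribution(dmp_table: pd.DataFrame, annotation: pd.DataFrame,
                         background: pd.Index | None = None,
                         axis: str = "cgi") -> dict:
    """DMP category counts vs background with a chi-square goodness-of-fit.

    ``axis`` is "cgi" or "feature". Background defaults to every probe in
    the annotation restricted to the DMP table's index universe. Empty
    background categories are dropped with a warning.
    """
    if axis not in ("cgi", "feature"):
        raise ValueError("axis must be 'cgi' or 'feature'")
    if background is None:
        background = dmp_table.index
    dmps = dmp_table.index[dmp_table["is_dmp"].astype(bool)]
    if len(dmps) == 0:
        raise ValueError("no DMPs to tabulate")

    bg_cat = annotation.loc[background, axis].astype(str)
    bg_counts = bg_cat.value_counts()
    empty = bg_counts[bg_counts == 0]
    if len(empty):
        warnings.warn(f"dropping empty background categories: {list(empty.index)}")
    cats = list(bg_counts.index)

    dmp_cat = annotation.loc[dmps, axis].astype(str)
    direction = dmp_table.loc[dmps, "direction"]
    table = pd.DataFrame({
        "background": bg_counts,
        "dmp": dmp_cat.value_counts().reindex(cats).fillna(0).astype(int),
        "hyper": dmp_cat[direction == "hyper"].value_counts().reindex(cats).fillna(0).astype(int),
        "hypo": dmp_cat[direction == "hypo"].value_counts().reindex(cats).fillna(0).astype(int),
    })
    table["dmp_pct"] = 100.0 * table["dmp"] / table["dmp"].sum()
    table["background_pct"] = 100.0 * table["background"] / table["background"].sum()

    observed = table["dmp"].to_numpy(dtype=float)
    expected = table["background"].to_numpy(dtype=float)
    expected = expected / expected.sum() * observed.sum()
    chi2, p = stats.chisquare(observed, expected)
    return {"table": table, "chi2": float(chi2), "p": float(p), "axis": axis}
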