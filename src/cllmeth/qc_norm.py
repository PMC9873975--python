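"""Sample/probe quality control, normalization and batch correction.

Filtering follows detection-p, bead-count, sex-chromosome and SNP /
cross-reactive rules; normalization is a probe-design-type-stratified full
quantile normalization; batch correction is parametric empirical-Bayes
location/scale adjustment on the M scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ConfigError, QCReport


def filter_samples(beta: BetaMatrix, max_failed_fraction: float = 0.01,
                   detection_p_threshold: float = 0.05) -> tuple[BetaMatrix, QCReport]:
    """Drop samples whose fraction of failed probes exceeds the threshold.

    A probe fails in a sample when its detection p exceeds
    ``detection_p_threshold``.
    """
    if beta.detection_p is None:
        raise ConfigError("filter_samples requires a detection_p companion matrix")
    frac_failed = (beta.detection_p > detection_p_threshold).mean(axis=0)
    bad = list(beta.sample_ids[frac_failed > max_failed_fraction])
    report = QCReport()
    report.add_samples("detection", bad)
    keep = [s for s in beta.sample_ids if s not in set(bad)]
    return beta.subset(samples=keep), report


def sex_check(beta: BetaMatrix, annotation: pd.DataFrame,
              sample_sheet: pd.DataFrame) -> QCReport:
    """Flag samples whose recorded sex disagrees with X-probe clustering.

    Classical MDS (2 components, Euclidean distances; equivalent to PCA on
    centred data) of the X-chromosome betas, then 2-means clustering;
    clusters take the majority recorded sex. Degenerate clusterings (both
    clusters majority the same sex, or no separation) yield an
    "indeterminate" note and no exclusions.
    """
    x_probes = annotation.index[annotation["chrom"].astype(str) == "X"]
    x_probes = x_probes.intersection(beta.probe_ids)
    if len(x_probes) < 2:
        raise ConfigError("sex_check requires at least two X-chromosome probes")
    sexes = sample_sheet.loc[beta.sample_ids, "sex"]
    if sexes.value_counts().min() < 2 or sexes.nunique() < 2:
        raise ConfigError("sex_check requires at least two samples of each recorded sex")

    X = beta.values.loc[x_probes].to_numpy(dtype=float).T  # samples x probes
    Xc = X - X.mean(axis=0, keepdims=True)
    # classical MDS on Euclidean distances == PCA scores of the centred matrix
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = u[:, :2] * s[:2]

    report = QCReport()
    from sklearn.cluster import KMeans

    if s[0] < 1e-10:  # all samples identical on X: nothing to separate
        report.notes.append("sex_check indeterminate: no X-probe separation")
        return report
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(coords)
    labels = km.labels_
    sep = float(np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1]))
    spread = float(np.sqrt(km.inertia_ / len(labels))) or 1e-12
    if sep < 2.0 * spread:
        report.notes.append("sex_check indeterminate: clusters not separated")
        return report

    cluster_sex = {}
    for k in (0, 1):
        counts = sexes[labels == k].value_counts()
        cluster_sex[k] = counts.idxmax()
    if cluster_sex[0] == cluster_sex[1]:
        report.notes.append("sex_check indeterminate: clusters share a majority sex")
        return report
    predicted = pd.Series([cluster_sex[k] for k in labels], index=beta.sample_ids)
    mismatched = list(predicted.index[predicted != sexes])
    report.add_samples("sex_mismatch", mismatched)
    return report


@dataclass
class ProbeFilterRules:
    detection_p_threshold: float = 0.05
    max_failed_sample_fraction: float = 0.01
    bead_min: int = 3
    max_low_bead_fraction: float = 0.05
    drop_sex_chroms: bool = True
    drop_flagged: bool = True


def filter_probes(beta: BetaMatrix, annotation: pd.DataFrame,
                  rules: ProbeFilterRules | None = None) -> tuple[BetaMatrix, QCReport]:
    """Remove the union of the four probe exclusion rule sets.

    A probe matching several rules is counted under every matching reason
    but excluded once.
    """
    rules = rules or ProbeFilterRules()
    report = QCReport()
    probes = beta.probe_ids
    ann = annotation.loc[probes]

    if beta.detection_p is not None:
        frac = (beta.detection_p > rules.detection_p_threshold).mean(axis=1)
        report.add_probes("detection", list(probes[frac > rules.max_failed_sample_fraction]))
    if beta.bead_count is not None:
        frac = (beta.bead_count < rules.bead_min).mean(axis=1)
        report.add_probes("beads", list(probes[frac > rules.max_low_bead_fraction]))
    if rules.drop_sex_chroms:
        report.add_probes("sex_chrom", list(probes[ann["chrom"].astype(str).isin(["X", "Y"])]))
    if rules.drop_flagged:
        report.add_probes("snp_crossreactive",
                          list(probes[ann["snp_flag"] | ann["crossreactive_flag"]]))

    excluded = report.all_excluded_probes
    keep = [p for p in probes if p not in excluded]
    return beta.subset(probes=keep), report


def run_qc(beta: BetaMatrix, annotation: pd.DataFrame, sample_sheet: pd.DataFrame,
           max_failed_fraction: float = 0.01,
           probe_rules: ProbeFilterRules | None = None,
           check_sex: bool = True) -> tuple[BetaMatrix, QCReport]:
    """Sample filter -> sex check -> probe filter, with a merged report."""
    beta, rep_s = filter_samples(beta, max_failed_fraction)
    report = rep_s
    if check_sex:
        rep_x = sex_check(beta, annotation, sample_sheet)
        report = report.merge(rep_x)
        drop = rep_x.all_excluded_samples
        if drop:
            beta = beta.subset(samples=[s for s in beta.sample_ids if s not in drop])
    beta, rep_p = filter_probes(beta, annotation, probe_rules)
    return beta, report.merge(rep_p)


def beta_to_m(beta: pd.DataFrame | np.ndarray, epsilon: float = 1e-3):
    """M = log2(b' / (1 - b')) with b' = clip(beta, eps, 1 - eps)."""
    if not 0.0 < epsilon < 0.5:
        raise ConfigError("epsilon must be in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m: pd.DataFrame | np.ndarray):
    """Inverse of beta_to_m on the clipped range: beta = 2^M / (2^M + 1)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    return b


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Full quantile normalization across columns (mean order statistics)."""
    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n, k = values.shape
    rows = np.arange(n)
    for j in range(k):
        ranks[order[:, j], j] = rows
    sorted_vals = np.take_along_axis(values, order, axis=0)
    ref = sorted_vals.mean(axis=1)
    return ref[ranks]


def normalize(beta: BetaMatrix | None = None,
              intensities: tuple[pd.DataFrame, pd.DataFrame] | None = None,
              annotation: pd.DataFrame | None = None,
              method: str = "type_aware_quantile",
              offset: float = 100.0) -> BetaMatrix:
    """Probe-design-type-stratified quantile normalization.

    Within each design type (I, II), every sample's values are replaced by
    the mean order statistics of that stratum. When the intensity pair is
    given, methylated and unmethylated channels are normalized separately
    and beta is recomputed as M / (M + U + offset).
    """
    if method == "none":
        if beta is None:
            raise ConfigError("method 'none' requires a beta matrix")
        return beta
    if method != "type_aware_quantile":
        raise ConfigError(f"unknown normalization method {method!r}")
    if annotation is None:
        raise ConfigError("type_aware_quantile requires probe annotation")

    if intensities is not None:
        meth, unmeth = intensities
        probes = meth.index
        types = annotation.loc[probes, "design_type"].astype(str)
        meth_n, unmeth_n = meth.copy(), unmeth.copy()
        for t in types.unique():
            rows = probes[types == t]
            meth_n.loc[rows] = _quantile_normalize(meth.loc[rows].to_numpy(float))
            unmeth_n.loc[rows] = _quantile_normalize(unmeth.loc[rows].to_numpy(float))
        b = meth_n / (meth_n + unmeth_n + offset)
        det = beta.detection_p if beta is not None else None
        beads = beta.bead_count if beta is not None else None
        if det is not None:
            det, beads = det.loc[probes], beads.loc[probes] if beads is not None else None
        return BetaMatrix(b.clip(0.0, 1.0), det, beads)

    if beta is None:
        raise ConfigError("normalize requires a beta matrix or intensity pair")
    vals = beta.values.copy()
    types = annotation.loc[beta.probe_ids, "design_type"].astype(str)
    for t in types.unique():
        rows = beta.probe_ids[types == t]
        vals.loc[rows] = _quantile_normalize(beta.values.loc[rows].to_numpy(float))
    return BetaMatrix(vals.clip(0.0, 1.0), beta.detection_p, beta.bead_count)


def combat(m: pd.DataFrame, batch: pd.Series,
           covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standardizes each probe preserving covariate effects, shrinks per-batch
    location/scale estimates toward across-probe empirical priors
    (normal / inverse-gamma, moment-matched), adjusts, and restores scale.
    With a single batch the input is returned unchanged.
    """
    batch = batch.loc[m.columns].astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return m.copy()
    sizes = batch.value_counts()
    if (sizes < 2).any():
        raise ConfigError(f"each batch needs >= 2 samples; got {sizes.to_dict()}")

    Y = m.to_numpy(dtype=float)
    n_probes, n = Y.shape
    B = pd.get_dummies(batch)[levels].to_numpy(dtype=float)  # n x n_batch

    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.loc[m.columns]
        Xc = pd.get_dummies(C, drop_first=True).to_numpy(dtype=float)
        # a batch 1:1 confounded with a covariate makes the design singular
        full = np.hstack([B, Xc])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ConfigError(
                "batch is confounded with a covariate (design matrix is rank-deficient); "
                f"batches={levels}, covariates={list(C.columns)}")
    else:
        Xc = np.zeros((n, 0))

    design = np.hstack([B, Xc])
    beta_hat = np.linalg.lstsq(design, Y.T, rcond=None)[0]  # (n_batch + p) x n_probes
    n_batch = len(levels)
    batch_means = beta_hat[:n_batch]
    weights = sizes.loc[levels].to_numpy(dtype=float) / n
    grand_mean = weights @ batch_means  # per probe

    resid = Y.T - design @ beta_hat
    var_pooled = (resid ** 2).mean(axis=0)  # per probe, 1/n convention
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = np.tile(grand_mean, (n, 1))
    if Xc.shape[1] > 0:
        stand_mean = stand_mean + Xc @ beta_hat[n_batch:]
    Z = (Y.T - stand_mean) / np.sqrt(var_pooled)  # n x n_probes

    # per-batch location/scale estimates and moment-matched EB priors
    gamma_hat = np.vstack([Z[batch.values == lv].mean(axis=0) for lv in levels])
    delta_hat = np.vstack([Z[batch.values == lv].var(axis=0, ddof=1) for lv in levels])
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    # inverse-gamma prior by moments: lambda (shape), theta (scale)
    v = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    lam = (2 * s2 + v ** 2) / np.maximum(s2, 1e-12)
    theta = (v * s2 + v ** 3) / np.maximum(s2, 1e-12)

    Z_adj = Z.copy()
    for i, lv in enumerate(levels):
        rows = batch.values == lv
        n_b = rows.sum()
        g_hat, d_hat = gamma_hat[i], delta_hat[i]
        g_star, d_star = g_hat.copy(), d_hat.copy()
        for _ in range(100):  # iterative EB solution (Johnson et al. 2007)
            g_new = (n_b * tau2[i] * g_hat + d_star * gamma_bar[i]) / (n_b * tau2[i] + d_star)
            sse = ((Z[rows] - g_new) ** 2).sum(axis=0)
            d_new = (theta[i] + 0.5 * sse) / (n_b / 2.0 + lam[i] - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            if np.max(np.abs(g_new - g_star)) < 1e-8 and np.max(np.abs(d_new - d_star)) < 1e-8:
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        Z_adj[rows] = (Z[rows] - g_star) / np.sqrt(d_star)

    out = Z_adj * np.sqrt(var_pooled) + stand_mean
    return pd.DataFrame(out.T, index=m.index, columns=m.columns)
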