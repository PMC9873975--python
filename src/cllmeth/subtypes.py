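"""Methylation-based CLL subgrouping and B-cell-differentiation subtraction.

The subtype classifier is a 5-feature RBF SVM (C=10, gamma=0.01,
one-vs-one) trained on a labelled reference matrix; the B-cell machinery
identifies differentiation-related probes from sorted-subtype-vs-mixture
comparisons, removes them from the testing background, and re-screens for
case-control DMPs and DMEGs independent of B-cell maturation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .datatypes import ConfigError
from .dmp_stats import DMPCriteria, fit_dmp

BCELL_SUBTYPES = ("NBC", "CD5+NBC", "csMBC", "ncsMBC")


@dataclass
class SubtypeModel:
    svc: SVC
    feature_probes: list[str]
    classes: list[str]
    scale: str = "beta"  # "beta" | "m"

    def to_json(self) -> str:
        sv = self.svc
        return json.dumps({
            "feature_probes": self.feature_probes,
            "classes": self.classes,
            "scale": self.scale,
            "C": sv.C, "gamma": sv.gamma, "kernel": sv.kernel,
            "support_vectors": sv.support_vectors_.tolist(),
            "dual_coef": sv.dual_coef_.tolist(),
            "intercept": sv.intercept_.tolist(),
            "n_support": sv.n_support_.tolist(),
        }, indent=2)


def _feature_matrix(values: pd.DataFrame, probes: list[str]) -> np.ndarray:
    missing = [p for p in probes if p not in values.index]
    if missing:
        raise ConfigError(f"missing feature probes: {missing}")
    return values.loc[probes].to_numpy(dtype=float).T  # samples x 5


def train_subtype_model(reference: pd.DataFrame, labels: pd.Series,
                        feature_probes: list[str] | None = None,
                        C: float = 10.0, gamma: float = 0.01,
                        scale: str = "beta") -> SubtypeModel:
    """Fit the multiclass max-margin RBF classifier on 5 reference CpGs.

    ``reference`` is probes x samples; ``feature_probes`` defaults to all
    rows, which must number exactly five.
    """
    probes = list(feature_probes) if feature_probes is not None else list(reference.index)
    if len(probes) != 5:
        raise ConfigError(f"the subtype model uses exactly 5 feature probes, got {len(probes)}")
    labels = labels.loc[reference.columns]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ConfigError("subtype training needs at least 2 classes")
    X = _feature_matrix(reference, probes)
    svc = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    svc.fit(X, labels.to_numpy())
    return SubtypeModel(svc=svc, feature_probes=probes, classes=classes, scale=scale)


def classify_subtypes(model: SubtypeModel, values: pd.DataFrame) -> pd.Series:
    """One subtype label per sample; NaN-feature samples skipped with a warning."""
    X = _feature_matrix(values, model.feature_probes)
    ok = ~np.isnan(X).any(axis=1)
    if (~ok).any():
        warnings.warn(f"skipping samples with NaN features: "
                      f"{list(values.columns[~ok])}")
    calls = pd.Series(pd.NA, index=values.columns, dtype=object, name="subtype")
    if ok.any():
        calls.iloc[np.where(ok)[0]] = model.svc.predict(X[ok])
    return calls


def subtype_counts(calls: pd.Series) -> pd.Series:
    return calls.dropna().value_counts()


def subtype_dmps(m: pd.DataFrame, subtype_calls: pd.Series,
                 sample_sheet: pd.DataFrame,
                 covariates: tuple[str, ...] = ("age", "sex"),
                 criteria: DMPCriteria | None = None,
                 beta: pd.DataFrame | None = None) -> pd.DataFrame:
    """n-CLL vs m-CLL DMP table (i-CLL excluded), via the case-control fitter."""
    calls = subtype_calls.dropna()
    keep = calls[calls.isin(["n-CLL", "m-CLL"])]
    if (keep == "n-CLL").sum() < 3 or (keep == "m-CLL").sum() < 3:
        raise ConfigError("need >= 3 samples in each of n-CLL and m-CLL")
    sheet = sample_sheet.loc[keep.index].copy()
    sheet["subtype_group"] = keep
    sub_m = m[keep.index]
    sub_beta = beta[keep.index] if beta is not None else None
    return fit_dmp(sub_m, sheet, beta=sub_beta, covariates=covariates,
                   criteria=criteria, group_col="subtype_group",
                   case="n-CLL", control="m-CLL")


def dmp_overlap_fraction(dmp_a: pd.DataFrame, dmp_b: pd.DataFrame) -> float:
    """Fraction of A's DMPs that are also DMPs in B, as a percentage."""
    a = set(dmp_a.index[dmp_a["is_dmp"].astype(bool)])
    b = set(dmp_b.index[dmp_b["is_dmp"].astype(bool)])
    if not a:
        return 0.0
    return 100.0 * len(a & b) / len(a)


def bcell_differentiation_dmps(m: pd.DataFrame, sample_sheet: pd.DataFrame,
                               mixture_group: str = "mixture",
                               subtype_groups: tuple[str, ...] = BCELL_SUBTYPES,
                               covariates: tuple[str, ...] = (),
                               criteria: DMPCriteria | None = None,
                               beta: pd.DataFrame | None = None
                               ) -> tuple[pd.Index, dict[str, pd.Index]]:
    """Union of subtype-vs-mixture DMP sets with per-comparison provenance.

    Each sorted subtype is compared to the CD19+ mixture with the standard
    probe-wise fit; comparisons with fewer than 2 subtype samples are
    skipped with a warning. No covariates by default (n=3 per subtype makes
    adjustment rank-fragile).
    """
    groups = sample_sheet.loc[m.columns, "group"]
    if not (groups == mixture_group).any():
        raise ConfigError(f"no samples in mixture group {mixture_group!r}")
    petals: dict[str, pd.Index] = {}
    for sub in subtype_groups:
        ids = list(m.columns[groups.isin([sub, mixture_group])])
        n_sub = int((groups == sub).sum())
        if n_sub < 2:
            warnings.warn(f"skipping {sub}: only {n_sub} samples")
            continue
        table = fit_dmp(m[ids], sample_sheet, covariates=covariates,
                        criteria=criteria, case=sub, control=mixture_group,
                        beta=beta[ids] if beta is not None else None)
        petals[sub] = table.index[table["is_dmp"].astype(bool)]
    union = pd.Index(sorted(set().union(*map(set, petals.values())))) if petals else pd.Index([])
    return union, petals


def subtract_and_rescreen(background: pd.Index, bcell_set: pd.Index,
                          m: pd.DataFrame, sample_sheet: pd.DataFrame,
                          deg_table: pd.DataFrame | None = None,
                          annotation: pd.DataFrame | None = None,
                          dmp_table: pd.DataFrame | None = None,
                          covariates: tuple[str, ...] = ("age", "sex"),
                          criteria: DMPCriteria | None = None,
                          beta: pd.DataFrame | None = None) -> dict:
    """Remove B-cell probes from the background, refit, and re-derive DMEGs.

    Returns the residual-background DMP table, the CLL-specific DMP set,
    the fraction of the original CLL DMPs that were B-cell-related, and
    (when expression inputs are given) the surviving DMEG genes.
    """
    bcell = set(bcell_set)
    residual = pd.Index([p for p in background if p not in bcell])
    if len(residual) == 0:
        raise ConfigError("empty residual background after B-cell subtraction")
    table = fit_dmp(m.loc[residual], sample_sheet, covariates=covariates,
                    criteria=criteria,
                    beta=beta.loc[residual] if beta is not None else None)
    specific = table.index[table["is_dmp"].astype(bool)]

    bcell_fraction = float("nan")
    if dmp_table is not None:
        orig = set(dmp_table.index[dmp_table["is_dmp"].astype(bool)])
        if orig:
            bcell_fraction = 100.0 * len(orig & bcell) / len(orig)

    out = {"dmp_table": table, "cll_specific_probes": specific,
           "bcell_overlap_pct": bcell_fraction}
    if deg_table is not None and annotation is not None:
        from .integrate import dmegs
        records = dmegs(pd.Index(specific), deg_table, annotation, table)
        out["dmeg_records"] = records
        out["dmeg_genes"] = sorted({r.gene for r in records})
    return out
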