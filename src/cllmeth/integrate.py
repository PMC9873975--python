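"""Cross-cohort DMP replication, DMEG derivation with direction classes,
and hypergeometric over-representation of gene sets.

Direction classes are anchored to the two concrete sign patterns reported
for the headline gene groups: expression up with promoter and body both
hypomethylated ("83-type"), and expression down with promoter
hypermethylated and body hypomethylated ("9-type").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PROMOTER_FEATURES, explode_genes
from .dmp_stats import bh_fdr


def replicate_dmps(dmp_a: pd.DataFrame, dmp_b: pd.DataFrame,
                   sign_only: bool = False) -> pd.Index:
    """Probes that are DMPs in A, present (and by default DMPs) in B, with
    the same delta-beta sign in both tables."""
    a_dmps = dmp_a.index[dmp_a["is_dmp"].astype(bool)]
    common = a_dmps.intersection(dmp_b.index)
    if not sign_only:
        common = common[dmp_b.loc[common, "is_dmp"].astype(bool)]
    same_sign = (np.sign(dmp_a.loc[common, "delta_beta"])
                 == np.sign(dmp_b.loc[common, "delta_beta"]))
    return common[same_sign.to_numpy()]


def define_promoter_body(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per (probe, gene) region label: promoter / body / other.

    Promoter = TSS1500 | TSS200 | 1stExon; body = Body; everything else
    (5'UTR, 3'UTR, IGR) is other. A probe may be promoter for one gene and
    body for another.
    """
    long = explode_genes(annotation)
    region = np.where(long["feature"].isin(PROMOTER_FEATURES), "promoter",
                      np.where(long["feature"] == "Body", "body", "other"))
    long["region"] = region
    return long


@dataclass
class DMEGRecord:
    gene: str
    expression_direction: str  # "up" | "down"
    promoter_dmp_directions: list[str] = field(default_factory=list)
    body_dmp_directions: list[str] = field(default_factory=list)
    dmeg_class: str = "unclassified"
    probes: list[str] = field(default_factory=list)


def _classify(expr_dir: str, prom: list[str], body: list[str]) -> str:
    prom_set, body_set = set(prom), set(body)
    if prom and body:
        if expr_dir == "up" and prom_set == {"hypo"} and body_set == {"hypo"}:
            return "83-type"
        if expr_dir == "down" and prom_set == {"hyper"} and body_set == {"hypo"}:
            return "9-type"
    if prom and len(prom_set) == 1:
        opposite = {"up": "hypo", "down": "hyper"}[expr_dir]
        if next(iter(prom_set)) == opposite:
            return "promoter_discordant"
    if body and len(body_set) == 1:
        return "body_concordant"
    return "unclassified"


def derive_dmegs(replicated: pd.Index, deg_table: pd.DataFrame,
                 annotation: pd.DataFrame) -> list[DMEGRecord]:
    """DMEG = DEG covered by >= 1 replicated DMP; class per decision table.

    Probes mapping to several genes contribute to each independently; genes
    missing from the annotation are skipped with a warning.
    """
    long = define_promoter_body(annotation)
    long = long[long["probe_id"].isin(replicated)]
    per_gene = {g: sub for g, sub in long.groupby("gene")}
    annotated_genes = set(explode_genes(annotation)["gene"])

    records: list[DMEGRecord] = []
    degs = deg_table.index[deg_table["is_deg"].astype(bool)]
    for gene in degs:
        if gene not in annotated_genes:
            warnings.warn(f"DEG {gene!r} missing from annotation; skipped")
            continue
        sub = per_gene.get(gene)
        if sub is None or len(sub) == 0:
            continue
        expr_dir = "up" if deg_table.loc[gene, "log2fc"] > 0 else "down"
        records.append(DMEGRecord(gene=gene, expression_direction=expr_dir,
                                  probes=sorted(set(sub["probe_id"]))))
        records[-1]._regions = sub  # stashed for direction fill-in
    return records


def classify_dmegs(records: list[DMEGRecord], dmp_table: pd.DataFrame) -> list[DMEGRecord]:
    """Fill promoter/body direction multisets from the discovery DMP table
    and assign the direction class."""
    for rec in records:
        sub = getattr(rec, "_regions", None)
        if sub is None:
            continue
        directions = dmp_table.loc[sub["probe_id"], "direction"].to_numpy()
        rec.promoter_dmp_directions = sorted(directions[sub["region"].to_numpy() == "promoter"])
        rec.body_dmp_directions = sorted(directions[sub["region"].to_numpy() == "body"])
        rec.dmeg_class = _classify(rec.expression_direction,
                                   rec.promoter_dmp_directions, rec.body_dmp_directions)
        del rec._regions
    return records


def dmegs(replicated: pd.Index, deg_table: pd.DataFrame, annotation: pd.DataFrame,
          dmp_table: pd.DataFrame) -> list[DMEGRecord]:
    """Convenience wrapper: derive then classify."""
    return classify_dmegs(derive_dmegs(replicated, deg_table, annotation), dmp_table)


def dmegs_to_frame(records: list[DMEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": r.gene, "expression_direction": r.expression_direction,
             "promoter_dmp_directions": ";".join(r.promoter_dmp_directions),
             "body_dmp_directions": ";".join(r.body_dmp_directions),
             "class": r.dmeg_class, "probes": ";".join(r.probes)}
            for r in records
        ],
        columns=["gene", "expression_direction", "promoter_dmp_directions",
                 "body_dmp_directions", "class", "probes"],
    )


def ora(gene_list, gene_sets: dict[str, set[str]], universe,
        fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    p = P(X >= k) with k the overlap, K the (universe-restricted) set size,
    n the list size and N the universe size; BH across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for name, members in gene_sets.items():
        hit_set = members & universe
        K = len(hit_set)
        k = len(hit_set & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < fdr
    return out.sort_values("p", kind="stable").reset_index(drop=True)
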