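"""Region-level calls: DMR chaining from DMP coordinates and copy-number
profiling from total probe intensity.

DMRs are maximal runs of consecutive DMPs with inter-probe gaps below the
merge gap, kept when they contain at least ``min_dmps`` probes and span
more than ``min_len - 1`` bases. CNA segments come from the log2 ratio of a
case's total intensity to the control median, smoothed by a running median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ConfigError


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    n_dmps: int
    probes: list[str]
    genes: list[str]
    mean_delta_beta: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_dmrs(dmp_table: pd.DataFrame, annotation: pd.DataFrame,
              min_dmps: int = 8, min_len: int = 51,
              merge_gap: int = 1000) -> list[DMR]:
    """Chain DMPs into regions per chromosome.

    Consecutive DMPs with gap < ``merge_gap`` join a chain; chains with
    >= ``min_dmps`` members and span >= ``min_len`` bases become DMRs.
    Adjacent emitted DMRs are therefore separated by >= ``merge_gap``.
    """
    dmps = dmp_table.index[dmp_table["is_dmp"].astype(bool)]
    if len(dmps) == 0:
        return []
    ann = annotation.loc[dmps, ["chrom", "pos", "gene"]].copy()
    ann["chrom"] = ann["chrom"].astype(str)
    ann = ann.sort_values(["chrom", "pos"])

    out: list[DMR] = []
    for chrom, sub in ann.groupby("chrom", sort=True):
        positions = sub["pos"].to_numpy()
        probe_ids = sub.index.to_numpy()
        chain_start = 0
        for i in range(1, len(positions) + 1):
            at_end = i == len(positions)
            if at_end or positions[i] - positions[i - 1] >= merge_gap:
                members = probe_ids[chain_start:i]
                span = int(positions[i - 1] - positions[chain_start]) + 1
                if len(members) >= min_dmps and span >= min_len:
                    genes = sorted({g for gl in annotation.loc[members, "gene"]
                                    if isinstance(gl, str) and gl
                                    for g in gl.split(";")})
                    out.append(DMR(
                        chrom=str(chrom),
                        start=int(positions[chain_start]),
                        end=int(positions[i - 1]),
                        n_dmps=len(members),
                        probes=list(members),
                        genes=genes,
                        mean_delta_beta=float(dmp_table.loc[members, "delta_beta"].mean()),
                    ))
                chain_start = i
    return out


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": d.chrom, "start": d.start, "end": d.end, "n_dmps": d.n_dmps,
             "length": d.length, "mean_delta_beta": d.mean_delta_beta,
             "genes": ";".join(d.genes), "probes": ";".join(d.probes)}
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "n_dmps", "length",
                 "mean_delta_beta", "genes", "probes"],
    )


def dmr_chromosome_summary(dmrs: list[DMR]) -> pd.Series:
    counts = pd.Series([d.chrom for d in dmrs]).value_counts()
    counts.index.name = "chrom"
    return counts


@dataclass
class CNASegment:
    chrom: str
    start: int
    end: int
    mean_log2_ratio: float
    call: str  # "gain" | "loss"
    n_probes: int
    sample: str = ""


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) == 0:
        return x.copy()
    w = min(window, len(x))
    if w % 2 == 0:
        w -= 1
    if w <= 1:
        return x.copy()
    return pd.Series(x).rolling(w, center=True, min_periods=1).median().to_numpy()


def profile_cna(meth: pd.DataFrame, unmeth: pd.DataFrame,
                sample_sheet: pd.DataFrame, annotation: pd.DataFrame,
                window: int = 50, threshold: float = 0.2,
                bridge: int = 2, min_probes: int = 10,
                group_col: str = "group", case: str = "CLL",
                control: str = "control") -> tuple[list[CNASegment], pd.DataFrame]:
    """Per-case CNA segments from smoothed total-intensity log2 ratios.

    Per probe: log2((M+U)_case / median over controls of (M+U)); running
    median over ``window`` probes ordered by position; maximal runs with
    |smoothed| >= ``threshold`` (bridging sub-threshold interior gaps of up
    to ``bridge`` probes) spanning >= ``min_probes`` probes become segments.
    Returns the per-case segments and a per-probe recurrence table (fraction
    of cases called gain / loss).
    """
    if meth is None or unmeth is None:
        raise ConfigError("CNA profiling needs the methylated/unmethylated intensity "
                          "pair; beta-only mode is unsupported")
    groups = sample_sheet.loc[meth.columns, group_col]
    case_ids = list(meth.columns[groups == case])
    ctrl_ids = list(meth.columns[groups == control])
    if len(ctrl_ids) < 3:
        raise ConfigError(f"CNA profiling needs >= 3 controls, got {len(ctrl_ids)}")

    total = meth + unmeth
    ann = annotation.loc[total.index, ["chrom", "pos"]].copy()
    ann["chrom"] = ann["chrom"].astype(str)
    order = ann.sort_values(["chrom", "pos"]).index
    total = total.loc[order]
    ann = ann.loc[order]
    ctrl_median = total[ctrl_ids].median(axis=1).clip(lower=1e-9)

    segments: list[CNASegment] = []
    gain_carriers = pd.DataFrame(0.0, index=order, columns=["gain", "loss"])
    for s in case_ids:
        ratio = np.log2(total[s].clip(lower=1e-9) / ctrl_median)
        ratio = ratio - np.median(ratio)  # genome-wide centring: invariant to global rescaling
        for chrom, idx in ann.groupby("chrom", sort=True).groups.items():
            r = ratio.loc[idx].to_numpy()
            pos = ann.loc[idx, "pos"].to_numpy()
            sm = _running_median(r, window)
            for sign, name in ((1, "gain"), (-1, "loss")):
                hits = sign * sm >= threshold
                for a, b in _runs_with_bridge(hits, bridge):
                    if b - a < min_probes:
                        continue
                    seg_probes = np.asarray(idx)[a:b]
                    mean_lr = float(sm[a:b].mean())
                    if abs(mean_lr) < threshold:
                        continue
                    segments.append(CNASegment(
                        chrom=str(chrom), start=int(pos[a]), end=int(pos[b - 1]),
                        mean_log2_ratio=mean_lr, call=name,
                        n_probes=b - a, sample=s))
                    gain_carriers.loc[seg_probes, name] += 1.0
    recurrence = gain_carriers / max(len(case_ids), 1)
    recurrence.insert(0, "pos", ann["pos"])
    recurrence.insert(0, "chrom", ann["chrom"])
    return segments, recurrence


def _runs_with_bridge(hits: np.ndarray, bridge: int):
    """Maximal True runs, fusing runs separated by <= ``bridge`` Falses."""
    runs = []
    i = 0
    n = len(hits)
    while i < n:
        if not hits[i]:
            i += 1
            continue
        j = i
        while j < n and hits[j]:
            j += 1
        runs.append([i, j])
        i = j
    if not runs:
        return []
    fused = [runs[0]]
    for a, b in runs[1:]:
        if a - fused[-1][1] <= bridge:
            fused[-1][1] = b
        else:
            fused.append([a, b])
    return [tuple(r) for r in fused]


def cna_to_frame(segments: list[CNASegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample": s.sample, "chrom": s.chrom, "start": s.start, "end": s.end,
             "n_probes": s.n_probes, "mean_log2_ratio": s.mean_log2_ratio, "call": s.call}
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "n_probes", "mean_log2_ratio", "call"],
    )
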