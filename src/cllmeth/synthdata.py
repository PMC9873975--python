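"""Synthetic 450K-style dataset generator with a ground-truth ledger.

Emulates the statistical structure the downstream analysis assumes: bimodal
beta distributions (two-component Beta mixture weighted by CGI context),
case effects concentrated as hypomethylation in gene bodies / open sea and
hypermethylation in islands and promoters, batch shifts on the M scale,
sex-linked X-probe structure, attenuated effects in MBL samples,
intensity-encoded copy-number segments, B-cell-subtype shifts, and
negative-binomial RNA counts whose fold-change signs are coupled to the
methylation ground truth.

Every generator call is a pure function of its config and seed; independent
sub-streams decouple the matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AUTOSOMES,
    CGI_RELATIONS,
    GENOMIC_FEATURES,
    PROMOTER_FEATURES,
    BetaMatrix,
    ConfigError,
    GroundTruthLedger,
    explode_genes,
)

DEFAULT_FEATURE_MIX = {
    "TSS1500": 0.14, "TSS200": 0.12, "5'UTR": 0.10, "1stExon": 0.06,
    "Body": 0.32, "3'UTR": 0.04, "IGR": 0.22,
}
DEFAULT_CGI_MIX = {"Island": 0.31, "Shore": 0.23, "Shelf": 0.10, "OpenSea": 0.36}

# fraction of probes drawn from the low-methylation mode, by CGI context
LOW_MODE_WEIGHT = {"Island": 0.80, "Shore": 0.55, "Shelf": 0.35, "OpenSea": 0.20}

_FEATURE_ORDER = {"TSS1500": 0, "TSS200": 1, "5'UTR": 2, "1stExon": 3,
                  "Body": 4, "3'UTR": 5, "IGR": 6}


def _check_mix(mix: Mapping[str, float], categories: Sequence[str], name: str) -> np.ndarray:
    extra = set(mix) - set(categories)
    if extra:
        raise ConfigError(f"{name} has unknown categories: {sorted(extra)}")
    p = np.array([float(mix.get(c, 0.0)) for c in categories])
    if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ConfigError(f"{name} must be a probability vector summing to 1 (got sum {p.sum():.6f})")
    return p


def generate_annotation(
    n_probes: int,
    chromosomes: Sequence[str] | None = None,
    feature_mix: Mapping[str, float] | None = None,
    cgi_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    snp_frac: float = 0.02,
    crossreactive_frac: float = 0.02,
    gene_block: tuple[int, int] = (4, 14),
) -> pd.DataFrame:
    """Build a manifest-like probe annotation table.

    Probes get unique ids and sorted 1-based positions per chromosome. Genes
    own contiguous probe runs; within a run the features are ordered so runs
    span promoter (TSS1500/TSS200/1stExon) and body context. IGR probes
    carry no gene. Sex chromosomes are included iff listed in
    ``chromosomes``.
    """
    if n_probes < 1:
        raise ConfigError("n_probes must be >= 1")
    chromosomes = list(chromosomes) if chromosomes is not None else list(AUTOSOMES)
    p_feat = _check_mix(feature_mix or DEFAULT_FEATURE_MIX, GENOMIC_FEATURES, "feature_mix")
    p_cgi = _check_mix(cgi_mix or DEFAULT_CGI_MIX, CGI_RELATIONS, "cgi_mix")

    rng = np.random.default_rng(seed)
    chrom = rng.choice(chromosomes, size=n_probes)
    order = np.lexsort((np.arange(n_probes), pd.Categorical(chrom, chromosomes).codes))
    chrom = chrom[order]

    features = rng.choice(GENOMIC_FEATURES, size=n_probes, p=p_feat)
    cgi = rng.choice(CGI_RELATIONS, size=n_probes, p=p_cgi)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]

    pos = np.empty(n_probes, dtype=int)
    gene = np.array([""] * n_probes, dtype=object)
    gene_counter = 0
    idx = 0
    for c in chromosomes:
        n_c = int((chrom == c).sum())
        gaps = rng.integers(20, 2000, size=n_c)
        pos[idx:idx + n_c] = 10_000 + np.cumsum(gaps)
        j = idx
        while j < idx + n_c:
            block = int(rng.integers(gene_block[0], gene_block[1] + 1))
            end = min(j + block, idx + n_c)
            # order features within the run: promoter upstream, body downstream
            blk = sorted(features[j:end], key=_FEATURE_ORDER.__getitem__)
            features[j:end] = blk
            gname = f"G{gene_counter:05d}"
            for k in range(j, end):
                if features[k] != "IGR":
                    gene[k] = gname
            gene_counter += 1
            j = end
        idx += n_c

    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": rng.choice(["+", "-"], size=n_probes),
            "gene": gene,
            "feature": features,
            "cgi": cgi,
            "snp_flag": rng.random(n_probes) < snp_frac,
            "crossreactive_flag": rng.random(n_probes) < crossreactive_frac,
            "design_type": rng.choice(["I", "II"], size=n_probes, p=[0.28, 0.72]),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ann


def make_sample_design(
    n_cll: int = 48,
    n_control: int = 28,
    n_mbl: int = 0,
    n_batches: int = 2,
    seed: int = 0,
    extra_groups: Mapping[str, int] | None = None,
    subtype_split: tuple[float, float, float] = (0.5, 0.333, 0.167),
) -> pd.DataFrame:
    """Sample sheet with group, sex, age, batch, WBC/ALC and CLL subtypes.

    ``extra_groups`` adds sorted-B-cell cohorts (e.g. {"mixture": 14,
    "NBC": 3, ...}). CLL samples are split into n-CLL / m-CLL / i-CLL by
    ``subtype_split``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counts = {"CLL": n_cll, "control": n_control, "MBL": n_mbl}
    counts.update(extra_groups or {})
    i = 0
    for group, n in counts.items():
        for _ in range(n):
            sex = "F" if rng.random() < 0.6 else "M"
            is_case = group in ("CLL", "MBL")
            age = int(rng.normal(61 if is_case else 57, 10))
            wbc = float(np.round(rng.lognormal(math.log(29 if is_case else 7.4), 0.4), 1))
            alc = float(np.round(rng.lognormal(math.log(21 if is_case else 2.0), 0.4), 1))
            rai = rng.choice(["0", "I/II", "III/IV"], p=[0.46, 0.48, 0.06]) if group == "CLL" else ""
            rows.append((f"S{i:03d}", group, sex, age, f"B{i % n_batches + 1}", wbc, alc, rai))
            i += 1
    design = pd.DataFrame(
        rows, columns=["sample_id", "group", "sex", "age", "batch", "wbc", "alc", "rai_stage"]
    ).set_index("sample_id")

    cll = design.index[design["group"] == "CLL"]
    n_n = int(round(len(cll) * subtype_split[0]))
    n_m = int(round(len(cll) * subtype_split[1]))
    labels = ["n-CLL"] * n_n + ["m-CLL"] * n_m + ["i-CLL"] * (len(cll) - n_n - n_m)
    design["subtype"] = ""
    design.loc[cll, "subtype"] = labels
    return design


@dataclass
class MethylationEffects:
    """Knobs for injected structure in the methylation generator."""

    dmp_fraction: float = 0.0          # fraction of eligible probes given a random case effect
    hypo_delta: float = -0.3           # applied in Body / OpenSea context
    hyper_delta: float = 0.25          # applied in Island / promoter context
    probe_deltas: dict[str, float] = field(default_factory=dict)  # explicit probe -> delta-beta
    batch_shifts: dict[str, float] = field(default_factory=dict)  # batch -> M-scale offset
    sex_effect_x: float = 0.0          # female minus male beta shift on X probes
    mbl_attenuation: float = 1.0       # in (0, 1]; scales case deltas for MBL samples
    noise_sd_m: float = 0.5            # per-entry noise on the M scale
    baseline_params: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 18.0), (18.0, 2.0))
    low_mode_weight: dict[str, float] = field(default_factory=lambda: dict(LOW_MODE_WEIGHT))
    detection_fail_rate: float = 5e-4
    failed_sample_rates: dict[str, float] = field(default_factory=dict)  # sample -> entry fail rate
    bead_mean: float = 14.0
    bead_low_rate: float = 0.001
    cna_segments: list[tuple[str, int, int, float]] = field(default_factory=list)  # dosage per segment
    cna_case_fraction: float = 1.0
    subtype_probe_deltas: dict[str, float] = field(default_factory=dict)  # probe -> n-CLL minus m-CLL delta
    bcell_probe_deltas: dict[str, dict[str, float]] = field(default_factory=dict)  # probe -> {group: delta}
    sex_swaps: list[str] = field(default_factory=list)  # samples whose recorded sex is flipped
    intensity_scale: float = 4000.0
    intensity_noise_sd: float = 0.15  # per-entry log-scale sigma; probe scale cancels in ratios

    def validate(self) -> None:
        deltas = [self.hypo_delta, self.hyper_delta, self.sex_effect_x,
                  *self.probe_deltas.values(), *self.subtype_probe_deltas.values()]
        for d in self.bcell_probe_deltas.values():
            deltas.extend(d.values())
        for d in deltas:
            if not -1.0 < float(d) < 1.0:
                raise ConfigError(f"effect magnitude {d} outside (-1, 1)")
        if not 0.0 < self.mbl_attenuation <= 1.0:
            raise ConfigError("mbl_attenuation must be in (0, 1]")
        if not 0.0 <= self.dmp_fraction <= 1.0:
            raise ConfigError("dmp_fraction must be in [0, 1]")


def _context_delta(ann: pd.DataFrame, effects: MethylationEffects) -> pd.Series:
    """Signed case delta per probe from feature/CGI context."""
    is_hyper = ann["cgi"].eq("Island") | ann["feature"].isin(PROMOTER_FEATURES)
    is_hypo = ann["feature"].eq("Body") | ann["cgi"].eq("OpenSea")
    delta = pd.Series(effects.hypo_delta, index=ann.index)  # default hypo (paper-like)
    delta[is_hyper & ~is_hypo] = effects.hyper_delta
    return delta


def generate_methylation(
    annotation: pd.DataFrame,
    sample_design: pd.DataFrame,
    effects: MethylationEffects | None = None,
    seed: int = 0,
) -> tuple[BetaMatrix, tuple[pd.DataFrame, pd.DataFrame], GroundTruthLedger]:
    """Draw betas, intensity pair, detection-p / bead-count companions and ledger.

    Baseline betas come from a two-component Beta mixture (low mode near
    0.1, high mode near 0.9) with mixture weight set by CGI context; noise
    and batch shifts act on the M scale; case effects are added on the beta
    scale and clipped to [0, 1]; total intensity encodes CNA dosage
    multiplicatively.
    """
    effects = effects or MethylationEffects()
    effects.validate()
    n_p, n_s = len(annotation), len(sample_design)
    probes, samples = annotation.index, sample_design.index
    ss = np.random.SeedSequence(seed)
    rng_base, rng_eff, rng_int, rng_det, rng_bead = map(np.random.default_rng, ss.spawn(5))

    # resolve case effects up front so effect probes can get compatible baselines
    delta = pd.Series(0.0, index=probes)
    if effects.dmp_fraction > 0:
        eligible = ~annotation["chrom"].isin(["X", "Y"]) & ~annotation["snp_flag"] \
            & ~annotation["crossreactive_flag"]
        pool = probes[eligible]
        n_aff = int(round(effects.dmp_fraction * len(pool)))
        chosen = rng_eff.choice(pool, size=n_aff, replace=False)
        delta[chosen] = _context_delta(annotation.loc[chosen], effects)
    for probe, d in effects.probe_deltas.items():
        if probe not in delta.index:
            raise ConfigError(f"probe_deltas references unknown probe {probe!r}")
        delta[probe] = d

    # baseline per probe: two-component Beta mixture weighted by CGI context.
    # Probes carrying an injected effect draw their baseline from the mode
    # that leaves headroom for it (hypo effects need a methylated baseline,
    # hyper effects an unmethylated one, bidirectional shifts a mid-range one)
    # so effects survive the [0, 1] clip.
    (a_lo, b_lo), (a_hi, b_hi) = effects.baseline_params
    w_low = annotation["cgi"].map(lambda c: effects.low_mode_weight.get(c, 0.5)).to_numpy()
    take_low = rng_base.random(n_p) < w_low
    signs = pd.DataFrame({"pos": delta > 0, "neg": delta < 0}, index=probes)
    for probe, per_group in effects.bcell_probe_deltas.items():
        for d in per_group.values():
            signs.loc[probe, "pos" if d > 0 else "neg"] = True
    mid = pd.Series(False, index=probes)
    mid[list(effects.subtype_probe_deltas)] = True  # subtype shifts go both ways
    take_low = np.where(signs["neg"].to_numpy(), False, take_low)
    take_low = np.where(signs["pos"].to_numpy() & ~signs["neg"].to_numpy(), True, take_low)
    beta0 = np.where(take_low, rng_base.beta(a_lo, b_lo, n_p), rng_base.beta(a_hi, b_hi, n_p))
    beta0 = np.where(mid.to_numpy(), rng_base.beta(10.0, 10.0, n_p), beta0)

    eps = 1e-3
    m0 = np.log2(np.clip(beta0, eps, 1 - eps) / (1 - np.clip(beta0, eps, 1 - eps)))
    m = m0[:, None] + rng_base.normal(0.0, effects.noise_sd_m, (n_p, n_s))
    batch_off = sample_design["batch"].map(lambda b: effects.batch_shifts.get(b, 0.0)).to_numpy()
    m = m + batch_off[None, :]
    beta = 1.0 / (1.0 + 2.0 ** (-m))

    # sex-linked X structure (female higher by sex_effect_x on X probes)
    if effects.sex_effect_x:
        on_x = annotation["chrom"].astype(str).eq("X").to_numpy()
        is_f = sample_design["sex"].eq("F").to_numpy()
        beta[np.ix_(on_x, is_f)] += effects.sex_effect_x

    # case effects on the beta scale
    ledger = GroundTruthLedger()
    ledger.dmp_probes = {p: float(d) for p, d in delta.items() if d != 0.0}

    group = sample_design["group"]
    case_scale = group.map({"CLL": 1.0, "MBL": effects.mbl_attenuation}).fillna(0.0).to_numpy()
    beta = beta + delta.to_numpy()[:, None] * case_scale[None, :]

    # subtype effect: probe delta d is the n-CLL minus m-CLL contrast
    # (+d/2 in n-CLL, -d/2 in m-CLL, i-CLL stays at the shared baseline)
    subtype = sample_design.get("subtype", pd.Series("", index=samples))
    if effects.subtype_probe_deltas:
        sd = pd.Series(0.0, index=probes)
        for probe, d in effects.subtype_probe_deltas.items():
            sd[probe] = d
        is_n = subtype.eq("n-CLL").to_numpy()
        is_m = subtype.eq("m-CLL").to_numpy()
        beta = beta + 0.5 * sd.to_numpy()[:, None] * (is_n.astype(float) - is_m)[None, :]
        ledger.subtype_probes = {p: float(d) for p, d in sd.items() if d != 0.0}
    ledger.subtype_labels = {s: st for s, st in subtype.items() if st}

    # B-cell-subtype shifts (sorted-population cohorts)
    for probe, per_group in effects.bcell_probe_deltas.items():
        row = probes.get_loc(probe)
        for g, d in per_group.items():
            cols = group.eq(g).to_numpy()
            beta[row, cols] += d
    ledger.bcell_probes = {p: dict(v) for p, v in effects.bcell_probe_deltas.items()}

    beta = np.clip(beta, 0.0, 1.0)

    # intensities with CNA dosage; per-case segments applied to CLL samples
    probe_scale = rng_int.lognormal(math.log(effects.intensity_scale), 0.3, n_p)
    total = probe_scale[:, None] * rng_int.lognormal(0.0, effects.intensity_noise_sd, (n_p, n_s))
    dosage = np.ones((n_p, n_s))
    is_cll = group.eq("CLL").to_numpy()
    cll_idx = np.where(is_cll)[0]
    n_carriers = int(round(effects.cna_case_fraction * len(cll_idx)))
    carriers = cll_idx[:n_carriers]
    chrom_str = annotation["chrom"].astype(str).to_numpy()
    pos_arr = annotation["pos"].to_numpy()
    for chrom_seg, start, end, dos in effects.cna_segments:
        in_seg = (chrom_str == str(chrom_seg)) & (pos_arr >= start) & (pos_arr <= end)
        dosage[np.ix_(in_seg, carriers)] = dos
        ledger.cna_segments.append((str(chrom_seg), int(start), int(end), float(dos)))
    total = total * dosage
    meth = pd.DataFrame(beta * total, index=probes, columns=samples)
    unmeth = pd.DataFrame((1.0 - beta) * total, index=probes, columns=samples)

    # detection p: mostly tiny, a configurable failure rate; per-sample overrides
    det = rng_det.uniform(0.0, 0.01, (n_p, n_s))
    fail = rng_det.random((n_p, n_s)) < effects.detection_fail_rate
    for s, rate in effects.failed_sample_rates.items():
        j = samples.get_loc(s)
        fail[:, j] = rng_det.random(n_p) < rate
        ledger.failed_samples.append(s)
    det[fail] = rng_det.uniform(0.051, 1.0, int(fail.sum()))

    beads = rng_bead.poisson(effects.bead_mean, (n_p, n_s)) + 1
    low = rng_bead.random((n_p, n_s)) < effects.bead_low_rate
    beads[low] = rng_bead.integers(1, 3, int(low.sum()))

    ledger.batch_shifts = dict(effects.batch_shifts)
    ledger.sex_swapped_samples = list(effects.sex_swaps)

    bm = BetaMatrix(
        pd.DataFrame(beta, index=probes, columns=samples),
        detection_p=pd.DataFrame(det, index=probes, columns=samples),
        bead_count=pd.DataFrame(beads, index=probes, columns=samples),
    )
    return bm, (meth, unmeth), ledger


@dataclass
class CountsSpec:
    """Negative-binomial RNA count generator settings."""

    log2fc: dict[str, float] = field(default_factory=dict)  # gene -> injected log2FC (CLL vs control)
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (20.0, 2000.0)
    libsize_sd: float = 0.2
    low_depth_samples: dict[str, int] = field(default_factory=dict)  # sample -> forced total

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")


def generate_counts(
    genes: Sequence[str],
    sample_design: pd.DataFrame,
    deg_spec: CountsSpec | None = None,
    coupling: Mapping[str, str] | None = None,
    seed: int = 0,
    ledger: GroundTruthLedger | None = None,
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """NB counts (genes x samples) with library-size factors and injected DEGs.

    ``coupling`` maps gene -> intended direction class; it constrains the
    sign of that gene's log2FC (up for the promoter-hypo/body-hypo class,
    down for the promoter-hyper/body-hypo class) and is recorded in the
    ledger's ``dmeg_classes``.
    """
    spec = deg_spec or CountsSpec()
    spec.validate()
    ledger = ledger or GroundTruthLedger()
    genes = list(genes)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_g, n_s = len(genes), len(sample_design)

    lfc = pd.Series(0.0, index=genes)
    for g, v in spec.log2fc.items():
        if g not in lfc.index:
            raise ConfigError(f"log2fc references unknown gene {g!r}")
        lfc[g] = v
    if coupling:
        for g, cls in coupling.items():
            want_up = cls in ("83-type", "promoter_hypo_body_hypo_up", "up")
            if lfc.get(g, 0.0) == 0.0:
                lfc[g] = 2.5 if want_up else -2.5
            elif (lfc[g] > 0) != want_up:
                lfc[g] = -lfc[g]
            ledger.dmeg_classes[g] = cls

    lo, hi = spec.base_mean_range
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), n_g))
    size_f = rng.lognormal(0.0, spec.libsize_sd, n_s)
    is_case = sample_design["group"].isin(["CLL", "MBL"]).to_numpy()
    mu = base[:, None] * size_f[None, :] * np.power(2.0, lfc.to_numpy()[:, None] * is_case[None, :])

    if spec.dispersion > 0:
        lam = rng.gamma(1.0 / spec.dispersion, mu * spec.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    cdf = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_design.index)
    for s, target in spec.low_depth_samples.items():
        tot = int(cdf[s].sum())
        if tot > target:
            cdf[s] = rng.binomial(cdf[s].to_numpy(), target / tot)
            # binomial thinning overshoots/undershoots; trim to the exact total
            diff = int(cdf[s].sum()) - target
            if diff > 0:
                nz = cdf.index[cdf[s] > 0]
                take = rng.choice(nz, size=diff, replace=True)
                sub = pd.Series(0, index=cdf.index)
                sub.update(pd.Series(take).value_counts())
                cdf[s] = np.maximum(cdf[s] - sub, 0)
        ledger.low_depth_samples.append(s)

    ledger.deg_genes.update({g: float(v) for g, v in lfc.items() if v != 0.0})
    return cdf, ledger


@dataclass
class SimConfig:
    """Full synthetic-study configuration for ``simulate_dataset``."""

    n_probes: int = 20000
    chromosomes: Sequence[str] | None = None
    include_sex_chroms: bool = True
    n_cll: int = 48
    n_control: int = 28
    n_mbl: int = 2
    n_batches: int = 2
    n_dmeg_up: int = 10        # promoter-hypo/body-hypo, expression up
    n_dmeg_down: int = 5       # promoter-hyper/body-hypo, expression down
    n_random_dmps: int = 300
    effects: MethylationEffects = field(default_factory=MethylationEffects)
    counts: CountsSpec = field(default_factory=CountsSpec)
    n_subtype_probes: int = 0
    subtype_delta: float = 0.4
    n_bcell_samples: int = 0   # per sorted subtype; mixture gets 14 when > 0
    n_bcell_probes: int = 0
    bcell_delta: float = 0.3


@dataclass
class SimulatedStudy:
    annotation: pd.DataFrame
    sample_design: pd.DataFrame
    beta: BetaMatrix
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    counts: pd.DataFrame
    ledger: GroundTruthLedger


def plan_dmeg_effects(
    annotation: pd.DataFrame,
    n_up: int,
    n_down: int,
    rng: np.random.Generator,
    hypo: float = -0.3,
    hyper: float = 0.25,
) -> tuple[dict[str, float], dict[str, str]]:
    """Pick genes with promoter and body probes; return probe deltas + classes.

    Up-class genes get hypomethylation in both regions; down-class genes get
    promoter hypermethylation and body hypomethylation.
    """
    long = explode_genes(annotation)
    autosomal = set(annotation.index[~annotation["chrom"].isin(["X", "Y"])
                                     & ~annotation["snp_flag"]
                                     & ~annotation["crossreactive_flag"]])
    long = long[long["probe_id"].isin(autosomal)]
    has_prom = long[long["feature"].isin(PROMOTER_FEATURES)].groupby("gene").size()
    has_body = long[long["feature"] == "Body"].groupby("gene").size()
    eligible = sorted(set(has_prom.index) & set(has_body.index))
    if len(eligible) < n_up + n_down:
        raise ConfigError(
            f"only {len(eligible)} genes have promoter+body probes; need {n_up + n_down}")
    # prefer genes with redundant probes in both regions: they survive
    # random probe-level QC losses without changing class
    robust = sorted(g for g in eligible if has_prom[g] >= 2 and has_body[g] >= 2)
    pool = robust if len(robust) >= n_up + n_down else eligible
    chosen = rng.choice(pool, size=n_up + n_down, replace=False)
    probe_deltas: dict[str, float] = {}
    classes: dict[str, str] = {}
    for i, g in enumerate(chosen):
        cls = "83-type" if i < n_up else "9-type"
        classes[g] = cls
        sub = long[long["gene"] == g]
        for _, row in sub.iterrows():
            if row["feature"] in PROMOTER_FEATURES:
                probe_deltas[row["probe_id"]] = hypo if cls == "83-type" else hyper
            elif row["feature"] == "Body":
                probe_deltas[row["probe_id"]] = hypo
    return probe_deltas, classes


def simulate_dataset(config: SimConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """End-to-end synthetic study: annotation, methylation, intensities, counts.

    The DMEG plan is drawn first (genes with both promoter and body probes),
    its probe-level deltas are merged into the methylation effects, and the
    RNA fold changes are coupled to the planned classes, so the ledger's
    ``dmeg_classes`` is consistent with both matrices by construction.
    """
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    s_ann, s_plan, s_meth, s_cnt, s_design = ss.spawn(5)
    chroms = list(config.chromosomes) if config.chromosomes else list(AUTOSOMES)
    if config.include_sex_chroms:
        chroms = chroms + [c for c in ("X", "Y") if c not in chroms]
    ann = generate_annotation(config.n_probes, chromosomes=chroms,
                              seed=int(s_ann.generate_state(1)[0]))

    extra = {}
    if config.n_bcell_samples > 0:
        extra = {"mixture": 14, "NBC": config.n_bcell_samples,
                 "CD5+NBC": config.n_bcell_samples, "csMBC": config.n_bcell_samples,
                 "ncsMBC": config.n_bcell_samples}
    design = make_sample_design(config.n_cll, config.n_control, config.n_mbl,
                                n_batches=config.n_batches,
                                seed=int(s_design.generate_state(1)[0]),
                                extra_groups=extra)

    rng_plan = np.random.default_rng(s_plan)
    probe_deltas, classes = plan_dmeg_effects(ann, config.n_dmeg_up, config.n_dmeg_down, rng_plan)

    effects = replace(config.effects)
    effects.probe_deltas = dict(effects.probe_deltas)
    taken = set(probe_deltas)
    if config.n_random_dmps > 0:
        eligible = ann.index[~ann["chrom"].isin(["X", "Y"]) & ~ann["snp_flag"]
                             & ~ann["crossreactive_flag"]]
        pool = [p for p in eligible if p not in taken]
        extra_probes = rng_plan.choice(pool, size=min(config.n_random_dmps, len(pool)),
                                       replace=False)
        ctx = _context_delta(ann.loc[extra_probes], effects)
        probe_deltas.update({p: float(d) for p, d in ctx.items()})
    effects.probe_deltas.update(probe_deltas)

    if config.n_subtype_probes > 0:
        pool = [p for p in ann.index[~ann["chrom"].isin(["X", "Y"])]
                if p not in effects.probe_deltas]
        sub_probes = rng_plan.choice(pool, size=config.n_subtype_probes, replace=False)
        effects.subtype_probe_deltas = {p: config.subtype_delta for p in sub_probes}

    if config.n_bcell_probes > 0 and config.n_bcell_samples > 0:
        pool = [p for p in ann.index[~ann["chrom"].isin(["X", "Y"])]
                if p not in effects.probe_deltas and p not in effects.subtype_probe_deltas]
        bc_probes = rng_plan.choice(pool, size=config.n_bcell_probes, replace=False)
        subtypes = ["NBC", "CD5+NBC", "csMBC", "ncsMBC"]
        effects.bcell_probe_deltas = {
            p: {subtypes[i % 4]: config.bcell_delta} for i, p in enumerate(bc_probes)}

    beta, (meth, unmeth), ledger = generate_methylation(
        ann, design, effects, seed=int(s_meth.generate_state(1)[0]))

    genes = sorted(set(explode_genes(ann)["gene"]))
    counts, ledger = generate_counts(
        genes, design[design["group"].isin(["CLL", "MBL", "control"])],
        deg_spec=config.counts, coupling=classes,
        seed=int(s_cnt.generate_state(1)[0]), ledger=ledger)

    return SimulatedStudy(ann, design, beta, meth, unmeth, counts, ledger)
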