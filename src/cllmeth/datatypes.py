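"""Core containers shared across pipeline stages.

Matrices are pandas DataFrames with probes (or genes) in rows and samples
in columns. Annotation is a DataFrame indexed by probe id. Containers are
deliberately thin: they validate axes and carry optional companions, and
everything else stays in plain pandas so stages compose freely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

GENOMIC_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
PROMOTER_FEATURES = ("TSS1500", "TSS200", "1stExon")
CGI_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
AUTOSOMES = tuple(str(c) for c in range(1, 23))
VALID_CHROMS = AUTOSOMES + ("X", "Y")

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "strand",
    "gene",
    "feature",
    "cgi",
    "snp_flag",
    "crossreactive_flag",
    "design_type",
)


class ConfigError(ValueError):
    """Invalid user configuration or parameters."""


@dataclass
class BetaMatrix:
    """Beta values (probes x samples) with optional QC companions.

    ``detection_p`` and ``bead_count``, when present, must share shape and
    axes with ``values``.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        for name in ("detection_p", "bead_count"):
            comp = getattr(self, name)
            if comp is None:
                continue
            if comp.shape != v.shape:
                raise ValueError(f"{name} companion shape {comp.shape} != {v.shape}")
            if not comp.index.equals(v.index) or not comp.columns.equals(v.columns):
                raise ValueError(f"{name} companion axes do not match beta matrix")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, probes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "BetaMatrix":
        """Return a new BetaMatrix restricted to the given axes (order kept)."""
        probes = self.probe_ids if probes is None else pd.Index(probes)
        samples = self.sample_ids if samples is None else pd.Index(samples)

        def cut(df: pd.DataFrame | None) -> pd.DataFrame | None:
            return None if df is None else df.loc[probes, samples]

        return BetaMatrix(self.values.loc[probes, samples],
                          cut(self.detection_p), cut(self.bead_count))


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check required columns / value domains; returns the frame unchanged."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if annotation.index.has_duplicates:
        raise ValueError("duplicate probe ids in annotation")
    bad = set(annotation["chrom"].astype(str)) - set(VALID_CHROMS)
    if bad:
        raise ValueError(f"invalid chromosomes in annotation: {sorted(bad)}")
    return annotation


def explode_genes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-(probe, gene) rows: split ';'-joined gene and feature lists.

    450K manifests allow one probe to annotate several genes with distinct
    features; downstream gene-level logic consumes this long format.
    Probes with no gene are dropped.
    """
    ann = annotation
    rows = []
    for probe_id, gene, feature in zip(ann.index, ann["gene"], ann["feature"]):
        if not isinstance(gene, str) or gene == "":
            continue
        genes = gene.split(";")
        feats = feature.split(";") if isinstance(feature, str) else [""] * len(genes)
        if len(feats) == 1 and len(genes) > 1:
            feats = feats * len(genes)
        if len(feats) != len(genes):
            raise ValueError(f"probe {probe_id}: gene/feature lists not aligned")
        for g, f in zip(genes, feats):
            rows.append((probe_id, g, f))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "feature"])


@dataclass
class QCReport:
    """Exclusion bookkeeping for sample and probe QC.

    A probe may match several exclusion reasons; it is counted under every
    matching reason but excluded only once.
    """

    excluded_samples: dict[str, list[str]] = field(default_factory=dict)
    excluded_probes: dict[str, list[str]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    SAMPLE_REASONS = ("detection", "sex_mismatch")
    PROBE_REASONS = ("detection", "beads", "sex_chrom", "snp_crossreactive")

    def add_samples(self, reason: str, samples: Iterable[str]) -> None:
        if reason not in self.SAMPLE_REASONS:
            raise ValueError(f"unknown sample exclusion reason {reason!r}")
        self.excluded_samples.setdefault(reason, []).extend(samples)

    def add_probes(self, reason: str, probes: Iterable[str]) -> None:
        if reason not in self.PROBE_REASONS:
            raise ValueError(f"unknown probe exclusion reason {reason!r}")
        self.excluded_probes.setdefault(reason, []).extend(probes)

    @property
    def all_excluded_samples(self) -> set[str]:
        return set().union(*self.excluded_samples.values()) if self.excluded_samples else set()

    @property
    def all_excluded_probes(self) -> set[str]:
        return set().union(*self.excluded_probes.values()) if self.excluded_probes else set()

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            "samples": {k: len(v) for k, v in self.excluded_samples.items()},
            "probes": {k: len(v) for k, v in self.excluded_probes.items()},
        }

    def merge(self, other: "QCReport") -> "QCReport":
        out = QCReport(
            {k: list(v) for k, v in self.excluded_samples.items()},
            {k: list(v) for k, v in self.excluded_probes.items()},
            list(self.notes),
        )
        for k, v in other.excluded_samples.items():
            out.excluded_samples.setdefault(k, []).extend(v)
        for k, v in other.excluded_probes.items():
            out.excluded_probes.setdefault(k, []).extend(v)
        out.notes.extend(other.notes)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "excluded_samples": {k: sorted(v) for k, v in self.excluded_samples.items()},
                "excluded_probes": {k: sorted(v) for k, v in self.excluded_probes.items()},
                "counts": self.counts(),
                "notes": self.notes,
            },
            indent=2,
        )


@dataclass
class GroundTruthLedger:
    """Everything the generator injected, for downstream recovery checks."""

    dmp_probes: dict[str, float] = field(default_factory=dict)  # probe -> signed delta-beta
    deg_genes: dict[str, float] = field(default_factory=dict)  # gene -> injected log2FC
    dmeg_classes: dict[str, str] = field(default_factory=dict)  # gene -> intended class
    cna_segments: list[tuple] = field(default_factory=list)  # (chrom, start, end, dosage)
    batch_shifts: dict[str, float] = field(default_factory=dict)  # batch -> M offset
    subtype_labels: dict[str, str] = field(default_factory=dict)  # sample -> subtype
    subtype_probes: dict[str, float] = field(default_factory=dict)  # probe -> subtype delta
    bcell_probes: dict[str, dict[str, float]] = field(default_factory=dict)  # probe -> {subtype: delta}
    low_depth_samples: list[str] = field(default_factory=list)
    failed_samples: list[str] = field(default_factory=list)
    sex_swapped_samples: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["cna_segments"] = [list(s) for s in self.cna_segments]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLedger":
        d = json.loads(text)
        d["cna_segments"] = [tuple(s) for s in d.get("cna_segments", [])]
        return cls(**d)
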