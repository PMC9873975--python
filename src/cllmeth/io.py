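"""TSV / GMT / JSON readers and writers for the pipeline's on-disk dialect.

All tabular files are tab-separated UTF-8 with a header row; lines starting
with '#' are comments (used for seed provenance). Matrices carry row ids in
the first column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .datatypes import BetaMatrix, GroundTruthLedger, validate_annotation


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id",
                 header_comments: Sequence[str] = ()) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_table(df: pd.DataFrame, path: str | Path,
                header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str},
                      keep_default_na=False, na_values=[])
    ann = ann.set_index("probe_id")
    ann["pos"] = ann["pos"].astype(int)
    ann["snp_flag"] = ann["snp_flag"].astype(str).isin(("True", "true", "1"))
    ann["crossreactive_flag"] = ann["crossreactive_flag"].astype(str).isin(("True", "true", "1"))
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(ann)
    ann.to_csv(path, sep="\t", index_label="probe_id")


def read_beta(path: str | Path, detection_p: str | Path | None = None,
              bead_count: str | Path | None = None) -> BetaMatrix:
    return BetaMatrix(
        read_matrix(path),
        None if detection_p is None else read_matrix(detection_p),
        None if bead_count is None else read_matrix(bead_count),
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: tab-separated lines of set name, description, member genes."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name, *sorted(genes)]) + "\n")


def write_ledger(ledger: GroundTruthLedger, path: str | Path) -> None:
    Path(path).write_text(ledger.to_json(), encoding="utf-8")


def read_ledger(path: str | Path) -> GroundTruthLedger:
    return GroundTruthLedger.from_json(Path(path).read_text(encoding="utf-8"))


def write_bed(segments: pd.DataFrame, path: str | Path,
              name_col: str | None = None, score_col: str | None = None) -> None:
    """Write 1-based inclusive (chrom, start, end) rows as 0-based half-open BED."""
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in segments.iterrows():
            fields = [str(row["chrom"]), str(int(row["start"]) - 1), str(int(row["end"]))]
            if name_col is not None:
                fields.append(str(row[name_col]))
                if score_col is not None:
                    fields.append(str(row[score_col]))
            fh.write("\t".join(fields) + "\n")
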