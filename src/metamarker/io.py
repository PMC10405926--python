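"""TSV readers/writers for hit tables, lineages, abundance matrices, metadata.

All on-disk formats are plain TSV (gzip transparently supported via file
extension). Abundance matrices are stored features-as-rows: first column
``feature_id``, remaining columns one per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .profiles import AbundanceMatrix
from .taxonomy import HIT_COLUMNS, TaxLineage


@dataclass(frozen=True)
class HitTableDialect:
    """Column layout of a BLAST outfmt-6-like hits file.

    ``columns`` names the file's columns in order; recognized names are
    ``qseqid, sseqid, pident, length, qlen, qcovs, bitscore`` (others are
    ignored). Coverage comes from ``qcovs`` when present, else from
    ``100 * length / qlen``.
    """

    columns: tuple[str, ...] = ("qseqid", "sseqid", "pident", "length", "qlen", "bitscore")

    def __post_init__(self) -> None:
        need = {"qseqid", "sseqid", "pident", "bitscore"}
        missing = need - set(self.columns)
        if missing:
            raise DataError(f"dialect lacks required columns: {sorted(missing)}")
        if "qcovs" not in self.columns and not {"length", "qlen"} <= set(self.columns):
            raise DataError("dialect needs qcovs, or length and qlen")


def read_lineages(path) -> dict[str, TaxLineage]:
    """Read a subject->lineage TSV (subject_id, semicolon-delimited lineage)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["subject_id", "lineage"], dtype=str)
    if table.isna().any().any():
        raise DataError(f"{path}: malformed lineage rows")
    return {
        s: TaxLineage.from_string(t) for s, t in zip(table["subject_id"], table["lineage"])
    }


def read_hit_table(
    path, lineages: dict[str, TaxLineage], dialect: HitTableDialect | None = None
) -> pd.DataFrame:
    """Read alignment hits and attach subject lineages.

    Raises :class:`DataError` with a 1-based line number for malformed rows.
    """
    dialect = dialect or HitTableDialect()
    raw = pd.read_csv(path, sep="\t", header=None, names=list(dialect.columns), dtype=str)
    numeric = [c for c in ("pident", "length", "qlen", "qcovs", "bitscore") if c in raw.columns]
    parsed = raw.copy()
    for col in numeric:
        parsed[col] = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.index[parsed[col].isna()]
        if len(bad):
            raise DataError(f"{path}: line {bad[0] + 1}: non-numeric {col!r}")
    if "qcovs" in parsed.columns:
        coverage = parsed["qcovs"]
    else:
        if (parsed["qlen"] <= 0).any():
            line = int(parsed.index[parsed["qlen"] <= 0][0]) + 1
            raise DataError(f"{path}: line {line}: non-positive qlen")
        coverage = 100.0 * parsed["length"] / parsed["qlen"]
    out = pd.DataFrame(
        {
            "gene_id": parsed["qseqid"],
            "subject_id": parsed["sseqid"],
            "identity": parsed["pident"].astype(float),
            "coverage": coverage.astype(float).clip(upper=100.0),
            "bitscore": parsed["bitscore"].astype(float),
        }
    )
    for col, lo, hi in (("identity", 0, 100), ("coverage", 0, 100)):
        bad = out.index[(out[col] < lo) | (out[col] > hi)]
        if len(bad):
            raise DataError(f"{path}: line {int(bad[0]) + 1}: {col} out of [{lo}, {hi}]")
    bad = out.index[out["bitscore"] <= 0]
    if len(bad):
        raise DataError(f"{path}: line {int(bad[0]) + 1}: non-positive bit score")
    missing = set(out["subject_id"]) - set(lineages)
    if missing:
        raise DataError(f"{path}: subjects without lineage: {sorted(missing)[:5]}")
    out["lineage"] = [lineages[s] for s in out["subject_id"]]
    return out[list(HIT_COLUMNS)]


def write_hit_table(hits: pd.DataFrame, hits_path, lineage_path) -> None:
    """Write hits (outfmt-6-like, qcovs dialect) and the subject lineage TSV."""
    table = pd.DataFrame(
        {
            "qseqid": hits["gene_id"],
            "sseqid": hits["subject_id"],
            "pident": hits["identity"],
            "qcovs": hits["coverage"],
            "bitscore": hits["bitscore"],
        }
    )
    table.to_csv(hits_path, sep="\t", header=False, index=False)
    lineages = (
        hits[["subject_id", "lineage"]]
        .drop_duplicates("subject_id")
        .assign(lineage=lambda d: [ln.to_string() for ln in d["lineage"]])
    )
    lineages.to_csv(lineage_path, sep="\t", header=False, index=False)


QCOVS_DIALECT = HitTableDialect(("qseqid", "sseqid", "pident", "qcovs", "bitscore"))


def read_abundance(path, feature_kind: str = "gene", value_kind: str = "count") -> AbundanceMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise DataError(f"{path}: empty abundance matrix")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise DataError(f"{path}: duplicate feature id {dup!r}")
    values = table.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise DataError(f"{path}: non-numeric abundance values")
    return AbundanceMatrix(values.T, feature_kind=feature_kind, value_kind=value_kind)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    out = matrix.data.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(table.columns):
        raise DataError(f"{path}: metadata needs sample_id and group columns")
    return pd.Series(table["group"].values, index=table["sample_id"].values, name="group")


def write_metadata(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def write_assignments(assignments: dict[str, TaxLineage], path) -> None:
    pd.DataFrame(
        {"gene_id": list(assignments), "lineage": [ln.to_string() for ln in assignments.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> dict[str, TaxLineage]:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        g: TaxLineage.from_string(t) for g, t in zip(table["gene_id"], table["lineage"])
    }


def read_ko_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ko": str})
    return table


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
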