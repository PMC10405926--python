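"""Abundance matrices: depth normalization, aggregation and transforms.

The central container is :class:`AbundanceMatrix`, a thin wrapper around a
samples x features pandas DataFrame that records what the features are
(``gene``, ``taxon`` or ``KO``) and what the values are (``count``,
``relative`` or ``arcsin_sqrt``).

Processing order mirrors common shotgun-metagenomics practice: raw gene
counts are depth-adjusted to a fixed number of reads per sample (3 million by
default), converted to relative abundances, aggregated to taxa (via gene
lineages) or KEGG orthologs (via a best-hit map), and variance-stabilized with
the arcsine square-root transform before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .taxonomy import RANKS, TaxLineage

UNCLASSIFIED = "unclassified"
UNANNOTATED = "unannotated"

FEATURE_KINDS = ("gene", "taxon", "KO")
VALUE_KINDS = ("count", "relative", "arcsin_sqrt")


@dataclass(frozen=True)
class AbundanceMatrix:
    """Samples x features abundance table with feature/value kind metadata."""

    data: pd.DataFrame  # index: sample ids, columns: feature ids
    feature_kind: str = "gene"
    value_kind: str = "count"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ConfigurationError(f"feature_kind must be one of {FEATURE_KINDS}")
        if self.value_kind not in VALUE_KINDS:
            raise ConfigurationError(f"value_kind must be one of {VALUE_KINDS}")
        if self.data.size and (self.data.to_numpy() < 0).any():
            raise DataError("abundance values must be non-negative")
        if self.data.columns.has_duplicates or self.data.index.has_duplicates:
            raise DataError("duplicate sample or feature identifiers")
        if self.value_kind == "relative":
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise DataError("relative-abundance rows must sum to 1 (±1e-9)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def normalize_depth(
    counts: AbundanceMatrix,
    target_reads: int = 3_000_000,
    mode: str = "subsample",
    seed: int | None = None,
) -> AbundanceMatrix:
    """Adjust every sample to ``target_reads`` mapped reads.

    ``subsample`` (default) draws reads without replacement (multivariate
    hypergeometric), so each row sums to the target exactly; samples below the
    target raise a :class:`DataError` naming the sample. ``scale`` multiplies
    each row by ``target/total`` (non-integer values allowed), usable for
    coverage-style inputs.
    """
    if counts.value_kind != "count":
        raise ConfigurationError("normalize_depth expects a count matrix")
    if target_reads <= 0:
        raise ConfigurationError("target_reads must be positive")
    totals = counts.data.sum(axis=1)
    if mode == "scale":
        scaled = counts.data.mul(target_reads / totals, axis=0)
        return replace(counts, data=scaled)
    if mode != "subsample":
        raise ConfigurationError(f"unknown mode {mode!r}")
    low = totals[totals < target_reads]
    if len(low):
        raise DataError(
            f"sample {low.index[0]!r} has {int(low.iloc[0])} reads, "
            f"below the target of {target_reads}"
        )
    rng = np.random.default_rng(seed)
    arr = counts.data.to_numpy().astype(np.int64)
    out = np.empty_like(arr)
    for i, row in enumerate(arr):
        if row.sum() == target_reads:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, target_reads, method="marginals")
    return replace(counts, data=pd.DataFrame(out, index=counts.data.index, columns=counts.data.columns))


def relative_abundance(counts: AbundanceMatrix) -> AbundanceMatrix:
    """Convert counts (or coverages) to per-sample proportions summing to 1."""
    if counts.value_kind != "count":
        raise ConfigurationError("relative_abundance expects a count matrix")
    totals = counts.data.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise DataError(f"sample {zero.index[0]!r} has zero total abundance")
    rel = counts.data.div(totals, axis=0)
    return replace(counts, data=rel, value_kind="relative")


def _aggregate(matrix: AbundanceMatrix, label_of, fallback: str, feature_kind: str) -> AbundanceMatrix:
    labels = [label_of(f) or fallback for f in matrix.feature_ids]
    grouped = matrix.data.T.groupby(pd.Index(labels, name=feature_kind)).sum().T
    grouped = grouped[sorted(grouped.columns)]
    return AbundanceMatrix(grouped, feature_kind=feature_kind, value_kind=matrix.value_kind)


def aggregate_by_taxon(
    gene_matrix: AbundanceMatrix,
    assignments: dict[str, TaxLineage],
    rank: str,
) -> AbundanceMatrix:
    """Sum gene abundances per taxon label at ``rank``.

    Genes without an assignment at that rank (absent from the map or with a
    lineage truncated above the rank) aggregate into an ``unclassified``
    bucket, so per-sample totals are conserved exactly.
    """
    if gene_matrix.feature_kind != "gene":
        raise ConfigurationError("aggregate_by_taxon expects gene-level features")
    if rank not in RANKS:
        raise ConfigurationError(f"unknown rank {rank!r}; expected one of {RANKS}")

    def label_of(gene: str) -> str | None:
        lineage = assignments.get(gene)
        return lineage.label_at(rank) if lineage is not None else None

    return _aggregate(gene_matrix, label_of, UNCLASSIFIED, "taxon")


def aggregate_by_ko(gene_matrix: AbundanceMatrix, ko_map: dict[str, str]) -> AbundanceMatrix:
    """Sum gene abundances per KEGG ortholog; unmapped genes go to ``unannotated``."""
    if gene_matrix.feature_kind != "gene":
        raise ConfigurationError("aggregate_by_ko expects gene-level features")
    return _aggregate(gene_matrix, ko_map.get, UNANNOTATED, "KO")


def validate_ko_map(
    table: pd.DataFrame, min_identity: float = 30.0, min_coverage: float = 70.0
) -> dict[str, str]:
    """Build a gene -> KO map from a best-hit table, applying the identity and
    coverage floors (defaults 30% / 70%)."""
    required = {"gene_id", "ko", "identity", "coverage"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"KO table is missing columns: {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        raise DataError("KO table contains duplicate gene ids (best-hit expected)")
    ok = table[(table["identity"] >= min_identity) & (table["coverage"] >= min_coverage)]
    return dict(zip(ok["gene_id"].astype(str), ok["ko"].astype(str)))


def arcsin_sqrt_transform(rel: AbundanceMatrix) -> AbundanceMatrix:
    """Variance-stabilizing transform p -> arcsin(sqrt(p)) for proportions."""
    if rel.value_kind != "relative":
        raise ConfigurationError("arcsin_sqrt_transform expects relative abundances")
    values = rel.data.to_numpy()
    if values.size and (values.min() < 0 or values.max() > 1):
        raise DataError("relative abundances must lie in [0, 1]")
    out = pd.DataFrame(np.arcsin(np.sqrt(values)), index=rel.data.index, columns=rel.data.columns)
    return AbundanceMatrix(out, feature_kind=rel.feature_kind, value_kind="arcsin_sqrt")
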