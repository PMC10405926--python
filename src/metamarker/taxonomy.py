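"""Consensus taxonomy assignment for gene catalogs.

Each catalog gene carries a set of nucleotide alignment hits against reference
genomes. A gene's taxonomy is decided from those hits in three steps:

1. **Score filter** — keep hits with identity >= 65% and query coverage >= 80%,
   and, among those, hits whose bit score is within a fraction (default 0.9)
   of the best passing score. A top-decile reading ("keep the 10% highest
   scoring hits") is available via ``score_mode="top_decile"``.
2. **Rank consensus** — walking species -> genus -> phylum, a rank label wins
   if at least ``consensus_fraction`` (default 50%) of *all retained* hits
   support it at or above that rank's identity threshold (species 95, genus
   85, phylum 65). The finest winning rank gives the assignment, truncated at
   that rank.
3. **LCA fallback** — if no thresholded rank reaches consensus, the gene gets
   the lowest common ancestor of all retained hit lineages (possibly empty).

Hits are handled as a pandas DataFrame with columns ``gene_id``,
``subject_id``, ``identity``, ``coverage``, ``bitscore`` and ``lineage``
(:class:`TaxLineage` objects).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Canonical rank order, coarsest to finest.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

HIT_COLUMNS = ("gene_id", "subject_id", "identity", "coverage", "bitscore", "lineage")


@dataclass(frozen=True, order=True)
class TaxLineage:
    """An ordered lineage, possibly truncated at any rank.

    ``labels`` holds the labels from superkingdom downward; a lineage may stop
    at any rank (a gene resolved only to phylum has two labels). An empty
    tuple means unassigned.
    """

    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) > len(RANKS):
            raise ConfigurationError(
                f"lineage has {len(self.labels)} labels; at most {len(RANKS)} ranks exist"
            )
        if any(not lab for lab in self.labels):
            raise DataError(f"lineage contains an empty label: {self.labels!r}")

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "TaxLineage":
        labels = [t.strip() for t in text.split(sep)]
        while labels and not labels[-1]:
            labels.pop()
        return cls(tuple(labels))

    def to_string(self, sep: str = ";") -> str:
        return sep.join(self.labels)

    @property
    def depth(self) -> int:
        return len(self.labels)

    @property
    def deepest_rank(self) -> str | None:
        return RANKS[len(self.labels) - 1] if self.labels else None

    def label_at(self, rank: str) -> str | None:
        i = _rank_index(rank)
        return self.labels[i] if i < len(self.labels) else None

    def truncate(self, rank: str) -> "TaxLineage":
        return TaxLineage(self.labels[: _rank_index(rank) + 1])

    def is_prefix_of(self, other: "TaxLineage") -> bool:
        return other.labels[: len(self.labels)] == self.labels

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string() or "<unassigned>"


def _rank_index(rank: str) -> int:
    try:
        return _RANK_INDEX[rank]
    except KeyError:
        raise ConfigurationError(f"unknown rank {rank!r}; expected one of {RANKS}")


def lineage_lca(lineages) -> TaxLineage:
    """Lowest common ancestor: the longest label prefix shared by all lineages."""
    lineages = list(lineages)
    if not lineages:
        return TaxLineage()
    common: list[str] = []
    for labels in zip(*(ln.labels for ln in lineages)):
        if all(lab == labels[0] for lab in labels):
            common.append(labels[0])
        else:
            break
    # zip stops at the shortest lineage, which is the correct behaviour: a hit
    # lacking a genus cannot share a genus.
    return TaxLineage(tuple(common))


@dataclass(frozen=True)
class RankThresholds:
    """Filtering and consensus parameters for taxonomy assignment.

    Identity thresholds exist only for the ranks the assignment procedure
    uses as consensus candidates (species, genus, phylum by default);
    intermediate ranks appear in an assignment only through a finer-rank
    label's lineage or the LCA fallback.
    """

    rank_identity: dict = field(
        default_factory=lambda: {"species": 95.0, "genus": 85.0, "phylum": 65.0}
    )
    min_identity: float = 65.0
    min_coverage: float = 80.0
    score_fraction: float = 0.9
    consensus_fraction: float = 0.5
    score_mode: str = "best_fraction"  # or "top_decile"

    def __post_init__(self) -> None:
        if not 0 < self.consensus_fraction <= 1:
            raise ConfigurationError("consensus_fraction must lie in (0, 1]")
        if not 0 < self.score_fraction <= 1:
            raise ConfigurationError("score_fraction must lie in (0, 1]")
        if self.score_mode not in ("best_fraction", "top_decile"):
            raise ConfigurationError(f"unknown score_mode {self.score_mode!r}")
        ordered = [
            self.rank_identity[r] for r in RANKS if r in self.rank_identity
        ]
        if any(a > b for a, b in zip(ordered, ordered[1:])):
            raise ConfigurationError(
                "rank identity thresholds must be non-increasing from species toward phylum"
            )

    def candidate_ranks(self) -> list[str]:
        """Thresholded ranks, finest first."""
        return [r for r in reversed(RANKS) if r in self.rank_identity]


def filter_hits(hits: pd.DataFrame, thresholds: RankThresholds) -> pd.DataFrame:
    """Apply the identity/coverage floors and the top-score filter.

    Returns the retained hits (possibly empty — the gene is then unassigned).
    """
    if len(hits) == 0:
        raise DataError("filter_hits requires at least one hit")
    passing = hits[
        (hits["identity"] >= thresholds.min_identity)
        & (hits["coverage"] >= thresholds.min_coverage)
    ]
    if len(passing) == 0:
        return passing
    if thresholds.score_mode == "best_fraction":
        best = passing["bitscore"].max()
        return passing[passing["bitscore"] >= thresholds.score_fraction * best]
    # top_decile: the ceil(10%) highest-scoring passing hits
    n_keep = max(1, -(-len(passing) // 10))
    order = passing["bitscore"].sort_values(ascending=False, kind="stable")
    cutoff = order.iloc[n_keep - 1]
    return passing[passing["bitscore"] >= cutoff]


def consensus_at_rank(
    retained: pd.DataFrame, rank: str, thresholds: RankThresholds
) -> str | None:
    """Return the rank label supported by >= consensus_fraction of retained hits.

    Support requires a hit's identity to meet the rank's threshold and its
    lineage to carry a label at that rank. The denominator is the number of
    *retained* hits. An exact tie between two qualifying labels (only possible
    at consensus_fraction = 0.5) yields ``None``.
    """
    if len(retained) == 0:
        raise DataError("consensus_at_rank requires a non-empty retained set")
    if rank not in thresholds.rank_identity:
        raise ConfigurationError(f"rank {rank!r} has no identity threshold")
    threshold = thresholds.rank_identity[rank]
    labels = [
        ln.label_at(rank)
        for ln, ident in zip(retained["lineage"], retained["identity"])
        if ident >= threshold and ln.label_at(rank) is not None
    ]
    if not labels:
        return None
    counts = Counter(labels)
    denom = len(retained)
    winners = [lab for lab, c in counts.items() if c / denom >= thresholds.consensus_fraction]
    if len(winners) == 1:
        return winners[0]
    return None  # no winner, or an exact 50/50 tie


def assign_gene_taxonomy(
    hits: pd.DataFrame, thresholds: RankThresholds | None = None
) -> TaxLineage:
    """Assign a lineage to one gene from its hits (filter, consensus, LCA)."""
    thresholds = thresholds or RankThresholds()
    retained = filter_hits(hits, thresholds)
    if len(retained) == 0:
        return TaxLineage()
    for rank in thresholds.candidate_ranks():
        label = consensus_at_rank(retained, rank, thresholds)
        if label is None:
            continue
        threshold = thresholds.rank_identity[rank]
        prefixes = sorted(
            ln.truncate(rank).labels
            for ln, ident in zip(retained["lineage"], retained["identity"])
            if ident >= threshold and ln.label_at(rank) == label
        )
        # Supporting hits normally agree above the winning label; if reference
        # lineages disagree, take the most common prefix (ties: lexicographic).
        counts = Counter(prefixes)
        top = max(counts.values())
        chosen = min(p for p, c in counts.items() if c == top)
        return TaxLineage(chosen)
    return lineage_lca(retained["lineage"])


def assign_catalog(
    hit_table: pd.DataFrame, thresholds: RankThresholds | None = None
) -> dict[str, TaxLineage]:
    """Assign every gene in a hit table; genes without hits are absent."""
    thresholds = thresholds or RankThresholds()
    if len(hit_table) == 0:
        logger.warning("empty hit table: no genes to assign")
        return {}
    missing = [c for c in HIT_COLUMNS if c not in hit_table.columns]
    if missing:
        raise DataError(f"hit table is missing columns: {missing}")
    out: dict[str, TaxLineage] = {}
    for gene_id, group in hit_table.groupby("gene_id", sort=True):
        out[str(gene_id)] = assign_gene_taxonomy(group, thresholds)
    n_assigned = sum(1 for ln in out.values() if ln.depth > 0)
    logger.info("assigned %d/%d genes to at least superkingdom", n_assigned, len(out))
    return out
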