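"""Consensus/LCA taxonomy assignment rules."""

import numpy as np
import pytest

from metamarker import ConfigurationError, DataError, RankThresholds, TaxLineage
from metamarker.synthetic import generate_random_hit_table
from metamarker.taxonomy import (
    assign_catalog,
    assign_gene_taxonomy,
    consensus_at_rank,
    filter_hits,
    lineage_lca,
)

from conftest import FULL_LINEAGE, make_hits
from oracles import oracle_assign

THR = RankThresholds()


def sibling(rank, label):
    """FULL_LINEAGE diverging at `rank` with the given label downward."""
    idx = ("superkingdom", "phylum", "class", "order", "family", "genus", "species").index(rank)
    labels = list(FULL_LINEAGE.labels[:idx]) + [f"{label}_{r}" for r in range(7 - idx)]
    return TaxLineage(tuple(labels))


class TestTaxLineage:
    def test_round_trip_and_truncation(self):
        ln = TaxLineage.from_string("Bacteria;P;C;O;F;G;S")
        assert ln.to_string() == "Bacteria;P;C;O;F;G;S"
        assert ln.truncate("phylum").labels == ("Bacteria", "P")
        assert ln.label_at("genus") == "G"
        assert TaxLineage.from_string("Bacteria;P").label_at("species") is None

    def test_lca(self):
        a = TaxLineage(("Bacteria", "P", "C"))
        b = TaxLineage(("Bacteria", "P", "D"))
        assert lineage_lca([a, b]).labels == ("Bacteria", "P")
        assert lineage_lca([a, TaxLineage(("Archaea",))]).labels == ()

    def test_empty_label_rejected(self):
        with pytest.raises(DataError):
            TaxLineage(("Bacteria", ""))


class TestFilterHits:
    def test_single_hit_retained(self):
        hits = make_hits([(99, 95, 500, FULL_LINEAGE)])
        assert len(filter_hits(hits, THR)) == 1

    def test_identity_floor_removes_regardless_of_score(self):
        hits = make_hits([(60, 95, 9000, FULL_LINEAGE), (99, 95, 100, FULL_LINEAGE)])
        kept = filter_hits(hits, THR)
        assert list(kept["identity"]) == [99]

    def test_score_fraction_hand_example(self):
        hits = make_hits(
            [(90, 90, 500, FULL_LINEAGE), (90, 90, 460, FULL_LINEAGE), (90, 90, 440, FULL_LINEAGE)]
        )
        kept = filter_hits(hits, THR)
        assert sorted(kept["bitscore"]) == [460, 500]

    def test_all_filtered_returns_empty_not_error(self):
        hits = make_hits([(50, 50, 500, FULL_LINEAGE)])
        assert len(filter_hits(hits, THR)) == 0

    def test_empty_input_errors(self):
        with pytest.raises(DataError):
            filter_hits(make_hits([]), THR)

    def test_top_decile_mode(self):
        thr = RankThresholds(score_mode="top_decile")
        rows = [(90, 90, 100 + i, FULL_LINEAGE) for i in range(20)]
        kept = filter_hits(make_hits(rows), thr)
        assert sorted(kept["bitscore"]) == [118, 119]


class TestConsensus:
    def test_unanimous_species(self):
        hits = make_hits([(96, 90, 500, FULL_LINEAGE)] * 4)
        assert consensus_at_rank(hits, "species", THR) == FULL_LINEAGE.labels[-1]

    def test_exact_tie_yields_none(self):
        other = sibling("species", "alt")
        hits = make_hits(
            [(96, 90, 500, FULL_LINEAGE)] * 2 + [(96, 90, 500, other)] * 2
        )
        assert consensus_at_rank(hits, "species", THR) is None

    def test_identity_below_rank_threshold(self):
        hits = make_hits([(80, 90, 500, FULL_LINEAGE)] * 4)
        assert consensus_at_rank(hits, "genus", THR) is None
        assert consensus_at_rank(hits, "phylum", THR) == "Bacteroidota"

    def test_unknown_rank_errors(self):
        hits = make_hits([(96, 90, 500, FULL_LINEAGE)])
        with pytest.raises(ConfigurationError):
            consensus_at_rank(hits, "tribe", THR)


class TestAssignGene:
    def test_unanimous_full_lineage(self):
        hits = make_hits([(99, 95, 500, FULL_LINEAGE)] * 3)
        assert assign_gene_taxonomy(hits, THR) == FULL_LINEAGE

    def test_two_genera_one_phylum_truncates_at_phylum(self):
        a = sibling("genus", "g1")
        b = sibling("genus", "g2")
        hits = make_hits([(70, 90, 500, a)] * 2 + [(70, 90, 500, b)] * 2)
        result = assign_gene_taxonomy(hits, THR)
        assert result.deepest_rank == "phylum"
        assert result.labels == ("Bacteria", "Bacteroidota")

    def test_two_phyla_no_consensus_gives_lca(self):
        a = sibling("phylum", "p1")
        b = sibling("phylum", "p2")
        hits = make_hits([(70, 90, 500, a)] * 2 + [(70, 90, 500, b)] * 2)
        assert assign_gene_taxonomy(hits, THR).labels == ("Bacteria",)

    def test_all_hits_filtered_gives_empty(self):
        hits = make_hits([(50, 50, 500, FULL_LINEAGE)])
        assert assign_gene_taxonomy(hits, THR) == TaxLineage()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            hits = generate_random_hit_table(12, seed=seed)
            shuffled = hits.sample(frac=1, random_state=int(rng.integers(2**31)))
            assert assign_gene_taxonomy(hits, THR) == assign_gene_taxonomy(shuffled, THR)

    def test_raising_thresholds_never_refines_consensus(self):
        """Monotonicity: stricter identity thresholds can only coarsen the
        finest rank reaching consensus (support counts can only drop)."""
        strict = RankThresholds(
            rank_identity={"species": 98.0, "genus": 90.0, "phylum": 75.0}
        )

        def support(hits, thr, rank, label):
            retained = filter_hits(hits, thr)
            if len(retained) == 0:
                return 0.0
            t = thr.rank_identity[rank]
            n = sum(
                1
                for ln, ident in zip(retained["lineage"], retained["identity"])
                if ident >= t and ln.label_at(rank) == label
            )
            return n / len(retained)

        for seed in range(100):
            hits = generate_random_hit_table(10, seed=seed)
            # per-label support can only drop when thresholds rise; the
            # winning rank itself is not strictly monotone because raising a
            # threshold can break an exact 50/50 tie in favour of one label
            for rank in ("species", "genus", "phylum"):
                labels = {ln.label_at(rank) for ln in hits["lineage"]} - {None}
                for lab in labels:
                    assert support(hits, strict, rank, lab) <= support(hits, THR, rank, lab)

    def test_oracle_equivalence_sample(self):
        """Pipeline assignment equals brute-force enumeration on random tables."""
        for seed in range(300):
            hits = generate_random_hit_table(int(3 + seed % 15), seed=seed)
            expected = oracle_assign(
                [
                    {
                        "identity": h.identity,
                        "coverage": h.coverage,
                        "bitscore": h.bitscore,
                        "lineage": h.lineage.labels,
                    }
                    for h in hits.itertuples()
                ]
            )
            assert assign_gene_taxonomy(hits, THR).labels == expected, f"seed {seed}"


class TestAssignCatalog:
    def test_composes_per_gene_results(self):
        tables = []
        for g, seed in (("a", 1), ("b", 2), ("c", 3)):
            t = generate_random_hit_table(8, seed=seed, gene_id=g)
            tables.append(t)
        import pandas as pd

        catalog = pd.concat(tables, ignore_index=True)
        result = assign_catalog(catalog, THR)
        assert set(result) == {"a", "b", "c"}
        for t in tables:
            assert result[t["gene_id"].iloc[0]] == assign_gene_taxonomy(t, THR)

    def test_empty_table_warns_and_returns_empty(self, caplog):
        import pandas as pd

        with caplog.at_level("WARNING"):
            assert assign_catalog(pd.DataFrame(), THR) == {}
        assert "empty hit table" in caplog.text

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(DataError, match="missing columns"):
            assign_catalog(pd.DataFrame({"gene_id": ["g"]}), THR)
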