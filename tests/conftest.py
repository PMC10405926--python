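import numpy as np
import pandas as pd
import pytest

from metamarker import AbundanceMatrix, SimConfig, generate_cohort
from metamarker.taxonomy import TaxLineage

FULL_LINEAGE = TaxLineage(
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
     "Bacteroidaceae", "Bacteroides", "Bacteroides plebeius")
)


def make_hits(rows):
    """Build a hit DataFrame from (identity, coverage, bitscore, lineage) tuples."""
    return pd.DataFrame(
        [
            {
                "gene_id": "g1",
                "subject_id": f"s{i}",
                "identity": ident,
                "coverage": cov,
                "bitscore": score,
                "lineage": lineage,
            }
            for i, (ident, cov, score, lineage) in enumerate(rows)
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but clearly structured cohort used across modules."""
    cfg = SimConfig(
        n_per_group=(15, 15, 15),
        n_features=80,
        n_informative=8,
        effect_log2fc=2.0,
        depth_mean=20_000,
        depth_dispersion=50.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def tiny_counts():
    data = pd.DataFrame(
        [[2, 2, 4], [1, 0, 9]],
        index=["s1", "s2"],
        columns=["f1", "f2", "f3"],
    )
    return AbundanceMatrix(data, feature_kind="gene", value_kind="count")
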