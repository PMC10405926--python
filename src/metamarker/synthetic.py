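"""Synthetic cohorts and alignment fixtures with known ground truth.

Cohort model
------------
Three groups of stool metagenome profiles (healthy, mild/moderate disease,
severe disease; default sizes 80/31/49). Baseline feature proportions come
from a log-normal rank-abundance model (sigma defaults to 2.0, giving the
few-dominant-taxa skew typical of gut genus profiles). A minority of
"informative" features receive a group-specific fold change of
``2**(±effect_log2fc)``, monotone across the three groups (healthy <
mild < severe or the reverse, per feature); proportions are renormalized per
group. Each subject's own composition is the group profile perturbed by
multiplicative log-normal noise (``sample_sigma``) — without this term every
sample in a group would share one composition and, at realistic sequencing
depths, even the tiny renormalization shift on non-informative features would
become detectable, which no real cohort behaves like. Sequencing depth is
drawn per sample from a negative binomial and integer counts are multinomial
draws at that depth. All randomness derives from a single seed via
``numpy.random.SeedSequence`` spawning (baseline, effects, depths,
subject noise, counts, in that order).

Hit-table fixtures
------------------
Toy BLAST-style hit tables for one gene with a known true lineage, mixing
on-lineage and progressively off-lineage subjects with configurable identity,
coverage and bit-score ranges spanning the assignment thresholds; and fully
random tables over a small taxonomy pool for fuzzing the consensus rules
against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .profiles import AbundanceMatrix
from .taxonomy import RANKS, TaxLineage

GROUPS = ("healthy", "copd_mild", "copd_severe")


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters; defaults mirror the study cohort sizes."""

    n_per_group: tuple[int, int, int] = (80, 31, 49)
    n_features: int = 500
    n_informative: int = 10
    effect_log2fc: float = 2.0
    base_abundance_sigma: float = 2.0
    sample_sigma: float = 1.0  # subject-to-subject log-scale compositional noise
    depth_mean: float = 5_000_000
    depth_dispersion: float = 100.0  # negative-binomial size; larger = tighter depths
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n <= 0 for n in self.n_per_group):
            raise ConfigurationError("n_per_group must be three positive counts")
        if self.n_features <= 0:
            raise ConfigurationError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ConfigurationError("n_informative must lie in [0, n_features]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigurationError("depth parameters must be positive")
        if self.sample_sigma < 0:
            raise ConfigurationError("sample_sigma must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: which features carry signal and in which direction."""

    informative_features: tuple[str, ...]
    #: groups x features true mean proportions (post-renormalization)
    group_proportions: pd.DataFrame
    #: features x groups planted direction: +1 enriched, -1 depleted, 0 none
    directions: pd.DataFrame


def generate_cohort(config: SimConfig) -> tuple[AbundanceMatrix, pd.Series, GroundTruth]:
    """Simulate a three-group count cohort. Deterministic given the config."""
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_fx, rng_depth, rng_noise, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    p = config.n_features
    features = [f"F{i:05d}" for i in range(p)]
    base = rng_base.lognormal(mean=0.0, sigma=config.base_abundance_sigma, size=p)
    base /= base.sum()

    informative = np.sort(rng_fx.choice(p, size=config.n_informative, replace=False))
    signs = rng_fx.choice([-1.0, 1.0], size=config.n_informative)

    group_props = np.tile(base, (3, 1))
    directions = np.zeros((p, 3), dtype=int)
    for g in range(3):
        mult = np.ones(p)
        # monotone across groups: exponent -1, 0, +1 times the planted sign
        exponent = (g - 1) * signs
        mult[informative] = 2.0 ** (config.effect_log2fc * exponent)
        props = base * mult
        props /= props.sum()
        group_props[g] = props
        directions[informative, g] = np.sign(exponent).astype(int)

    depths = []
    rows = []
    sample_ids = []
    labels = []
    r = config.depth_dispersion
    nb_p = r / (r + config.depth_mean)
    for g, (group, n) in enumerate(zip(GROUPS, config.n_per_group)):
        d = rng_depth.negative_binomial(r, nb_p, size=n)
        d = np.maximum(d, 1)
        depths.extend(d)
        for i in range(n):
            # subject-level compositional variation around the group profile
            noisy = group_props[g] * rng_noise.lognormal(0.0, config.sample_sigma, p)
            noisy /= noisy.sum()
            rows.append(rng_counts.multinomial(int(d[i]), noisy))
            sample_ids.append(f"{group}_{i + 1:03d}")
            labels.append(group)

    data = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=features)
    truth = GroundTruth(
        informative_features=tuple(features[i] for i in informative),
        group_proportions=pd.DataFrame(group_props, index=list(GROUPS), columns=features),
        directions=pd.DataFrame(directions, index=features, columns=list(GROUPS)),
    )
    matrix = AbundanceMatrix(data, feature_kind="gene", value_kind="count")
    return matrix, pd.Series(labels, index=sample_ids, name="group"), truth


# ---------------------------------------------------------------------------
# Hit-table fixtures


@dataclass(frozen=True)
class NoiseProfile:
    """Mixture weights and score ranges for simulated alignment hits.

    The four weights partition hits into: exact true lineage, same genus but a
    sibling species, same phylum but a different genus, and a different
    phylum altogether.
    """

    p_species: float = 0.7
    p_genus: float = 0.15
    p_phylum: float = 0.1
    p_off: float = 0.05
    identity_range: tuple[float, float] = (65.0, 100.0)
    coverage_range: tuple[float, float] = (60.0, 100.0)
    bitscore_range: tuple[float, float] = (100.0, 1000.0)

    def __post_init__(self) -> None:
        w = (self.p_species, self.p_genus, self.p_phylum, self.p_off)
        if any(x < 0 for x in w) or not np.isclose(sum(w), 1.0):
            raise ConfigurationError("mixture weights must be non-negative and sum to 1")


def _sibling(true: TaxLineage, level: str, k: int) -> TaxLineage:
    """A lineage diverging from ``true`` at the given rank."""
    idx = RANKS.index(level)
    labels = list(true.labels[:idx])
    for j in range(idx, len(RANKS)):
        labels.append(f"alt_{RANKS[j]}_{k}")
    return TaxLineage(tuple(labels))


def generate_hit_table(
    n_hits: int,
    true_lineage: TaxLineage,
    noise: NoiseProfile | None = None,
    seed: int = 0,
    gene_id: str = "gene_1",
) -> tuple[pd.DataFrame, TaxLineage]:
    """Simulate one gene's hit table around a known true lineage."""
    if n_hits < 1:
        raise ConfigurationError("n_hits must be >= 1")
    if true_lineage.depth < len(RANKS):
        raise ConfigurationError("true_lineage must be resolved to species")
    noise = noise or NoiseProfile()
    rng = np.random.default_rng(seed)
    cats = rng.choice(4, size=n_hits, p=[noise.p_species, noise.p_genus, noise.p_phylum, noise.p_off])
    records = []
    for i, cat in enumerate(cats):
        if cat == 0:
            lineage = true_lineage
        elif cat == 1:
            lineage = _sibling(true_lineage, "species", int(rng.integers(1, 3)))
        elif cat == 2:
            lineage = _sibling(true_lineage, "genus", int(rng.integers(1, 3)))
        else:
            lineage = _sibling(true_lineage, "phylum", int(rng.integers(1, 3)))
        records.append(
            {
                "gene_id": gene_id,
                "subject_id": f"subj_{i + 1:04d}",
                "identity": float(rng.uniform(*noise.identity_range)),
                "coverage": float(rng.uniform(*noise.coverage_range)),
                "bitscore": float(rng.uniform(*noise.bitscore_range)),
                "lineage": lineage,
            }
        )
    return pd.DataFrame(records), true_lineage


def _taxonomy_pool() -> list[TaxLineage]:
    """A small fixed taxonomy: 3 phyla x 2 genera x 3 species (full 7 ranks),
    plus genus- and phylum-truncated variants to exercise partial lineages."""
    pool: list[TaxLineage] = []
    for ph in range(3):
        for ge in range(2):
            for sp in range(3):
                labels = (
                    "Bacteria",
                    f"phylum{ph}",
                    f"class{ph}",
                    f"order{ph}_{ge}",
                    f"family{ph}_{ge}",
                    f"genus{ph}_{ge}",
                    f"species{ph}_{ge}_{sp}",
                )
                pool.append(TaxLineage(labels))
            pool.append(TaxLineage(pool[-1].labels[:6]))  # genus-truncated
        pool.append(TaxLineage(pool[-1].labels[:2]))  # phylum-truncated
    return pool


def generate_random_hit_table(
    n_hits: int, seed: int = 0, gene_id: str = "gene_1"
) -> pd.DataFrame:
    """A fully random hit table over a small taxonomy pool, with identities,
    coverages and bit scores spanning the assignment thresholds. Used to fuzz
    the consensus/LCA rules against an independent oracle."""
    if n_hits < 1:
        raise ConfigurationError("n_hits must be >= 1")
    rng = np.random.default_rng(seed)
    pool = _taxonomy_pool()
    records = []
    for i in range(n_hits):
        lineage = pool[int(rng.integers(len(pool)))]
        records.append(
            {
                "gene_id": gene_id,
                "subject_id": f"subj_{i + 1:04d}",
                "identity": float(rng.uniform(55.0, 100.0)),
                "coverage": float(rng.uniform(60.0, 100.0)),
                "bitscore": float(rng.uniform(100.0, 1000.0)),
                "lineage": lineage,
            }
        )
    return pd.DataFrame(records)


def assign_catalog_lineages(
    n_genes: int, seed: int = 0
) -> dict[str, TaxLineage]:
    """Deterministically assign a species-level true lineage from the fixed
    pool to each of ``n_genes`` catalog genes (for end-to-end fixtures)."""
    rng = np.random.default_rng(seed)
    pool = [ln for ln in _taxonomy_pool() if ln.depth == len(RANKS)]
    return {
        f"F{i:05d}": pool[int(rng.integers(len(pool)))] for i in range(n_genes)
    }
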