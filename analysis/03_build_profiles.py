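#!/usr/bin/env python
"""Build normalized abundance profiles from the simulated gene counts.

Depth-adjusts every sample to 3 million reads by subsampling without
replacement, derives gene- and species-level relative abundances (using the
taxonomy assignments from step 02), and the arcsine-square-root transformed
matrices used by the classifiers.

Writes matrices under results/analysis/profiles/.
"""

from pathlib import Path

from metamarker.io import ensure_dir, read_abundance, read_assignments, write_abundance
from metamarker.profiles import (
    aggregate_by_taxon,
    arcsin_sqrt_transform,
    normalize_depth,
    relative_abundance,
)

ROOT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT = ensure_dir(ROOT / "profiles")
SEED = 20233
TARGET_DEPTH = 3_000_000

counts = read_abundance(ROOT / "cohort" / "counts.tsv")
assignments = read_assignments(ROOT / "taxonomy" / "assignments.tsv")

normalized = normalize_depth(counts, TARGET_DEPTH, seed=SEED)
print(f"depth-normalized {normalized.shape[0]} samples to {TARGET_DEPTH:,} reads each")

gene_rel = relative_abundance(normalized)
write_abundance(gene_rel, OUT / "gene_relative.tsv")

species = aggregate_by_taxon(normalized, assignments, "species")
species_rel = relative_abundance(species)
write_abundance(species_rel, OUT / "species_relative.tsv")
unclassified = species_rel.data.get("unclassified")
print(
    f"species-level profile: {species.shape[1]} features "
    f"(unclassified mass mean {0 if unclassified is None else unclassified.mean():.3f})"
)

write_abundance(arcsin_sqrt_transform(species_rel), OUT / "species_arcsin.tsv")
write_abundance(arcsin_sqrt_transform(gene_rel), OUT / "gene_arcsin.tsv")
print(f"-> {OUT}")
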