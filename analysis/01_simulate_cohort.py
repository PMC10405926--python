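#!/usr/bin/env python
"""Simulate the study cohort: 80 healthy / 31 mild / 49 severe subjects,
500 catalog genes, 10 planted disease-associated genes (|log2FC| = 2),
log-normal rank-abundance baseline and negative-binomial sequencing depths.

Writes counts, metadata and ground truth under results/analysis/cohort/.
"""

from pathlib import Path

from metamarker import SimConfig, generate_cohort
from metamarker.io import ensure_dir, write_abundance, write_metadata

OUT = ensure_dir(Path(__file__).resolve().parents[1] / "results" / "analysis" / "cohort")
SEED = 20231

cfg = SimConfig(seed=SEED)
counts, groups, truth = generate_cohort(cfg)

write_abundance(counts, OUT / "counts.tsv")
write_metadata(groups, OUT / "metadata.tsv")
truth.directions.to_csv(OUT / "ground_truth_directions.tsv", sep="\t")
truth.group_proportions.to_csv(OUT / "ground_truth_proportions.tsv", sep="\t")

depths = counts.data.sum(axis=1)
print(f"cohort: {counts.shape[0]} samples x {counts.shape[1]} gene features (seed {SEED})")
print(f"group sizes: {groups.value_counts().to_dict()}")
print(f"sequencing depth: median {depths.median():,.0f}, min {depths.min():,.0f}")
print(f"planted markers: {len(truth.informative_features)} -> {OUT}")
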