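# metamarker

Gut-metagenome biomarker discovery for three-group cohort studies —
healthy controls versus mild/moderate (GOLD I–II) and severe/very severe
(GOLD III–IV) chronic obstructive pulmonary disease — re-implemented as a
tested, reusable pipeline and exercised end to end on synthetic cohorts with
known ground truth.

The package covers the full analysis chain such studies run downstream of
read processing and gene-catalog construction:

1. **Consensus taxonomy assignment** — each catalog gene's BLAST-style hits
   are filtered (identity ≥ 65%, coverage ≥ 80%, bit score within 90% of the
   best), then a rank label is assigned where ≥ 50% of retained hits support
   it above rank-specific identity thresholds (species 95 / genus 85 /
   phylum 65), falling back to the last common ancestor of the retained
   lineages.
2. **Profiles** — depth adjustment to 3 million reads per sample by
   subsampling without replacement, relative abundances, taxon and
   KEGG-ortholog rollups (KO best hits at identity ≥ 30%, coverage ≥ 70%),
   and the arcsine-square-root transform `p → arcsin(√p)`.
3. **Diversity** — Shannon index `H = −Σ pᵢ ln pᵢ`, Bray–Curtis
   dissimilarity `Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ)`, principal coordinates analysis, and
   PERMANOVA with permutation p-values and R² = SS_between/SS_total.
4. **Differential abundance** — per-feature pairwise two-sided Wilcoxon
   rank-sum tests across the three groups, a Bonferroni-3 omnibus,
   Benjamini–Hochberg adjustment (FDR < 0.1 for taxa, < 0.05 for KOs), and
   per-group enriched/depleted calls by median ordering.
5. **Marker discovery** — one-vs-rest random forests under stratified
   5-fold cross-validation with grid-searched trees/mtry; features ranked by
   CV-averaged importance and added sequentially; the marker set is cut at
   `min mean CV error + SD at that point` (smallest set strictly below the
   cutoff); performance is the out-of-fold ROC/AUC with a 95% DeLong
   confidence interval.

A synthetic-cohort generator (log-normal rank-abundance baseline,
group-monotone planted fold changes, subject-level compositional noise,
negative-binomial depths, multinomial counts) provides ground truth for
every stage; see `docs/methods.md` for the model and its limits.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort of 80 healthy / 31 mild / 49 severe subjects with 500 catalog genes,
10 of which carry a planted |log2 fold change| of 2 monotone in severity:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_assign_taxonomy.py
python analysis/03_build_profiles.py
python analysis/04_diversity.py
python analysis/05_differential_abundance.py
python analysis/06_marker_discovery.py
```

Selected output (seeds fixed inside the scripts; all tables land under
`results/analysis/`):

```
cohort: 160 samples x 500 gene features (seed 20231)
sequencing depth: median 5,037,632, min 3,849,118

assigned 500 genes (seed 20232); deepest rank reached:
genus  224 / phylum  178 / species  94 / superkingdom  4
accuracy at phylum: 97.0%

PERMANOVA: R2 = 0.017, p = 0.026 (999 permutations)
Shannon index by group:
  healthy: mean 4.222   copd_mild: mean 4.195   copd_severe: mean 4.153

gene-level screen at FDR<0.1: 10/500 significant
planted-marker recovery: 10/10
direction agreement among recovered: 10/10

healthy:     AUC 0.7936 (95% CI 0.7260-0.8612), 2 markers retained
copd_mild:   AUC 0.4495 (95% CI 0.3440-0.5549), 8 markers retained
copd_severe: AUC 0.8008 (95% CI 0.7313-0.8703), 2 markers retained
```

Reading these numbers: the community-level effect is small but significant
(R² ≈ 0.017 — a few percent of Bray–Curtis variance explained by group,
detected at p < 0.05); the differential screen recovers exactly the ten
planted genes with their planted directions and no false calls; and the
species-level classifiers separate healthy and severe subjects from the
rest (AUC ≈ 0.8) while the mild group sits at chance — by design its
composition is the baseline between the two oppositely-shifted extremes,
and the coarse toy taxonomy further dilutes gene-level signal into ~20
species. On the undiluted gene-level profiles the same procedure reaches a
pooled out-of-fold AUC of 0.99 (`scripts/acceptance.py`, seed 1, six
cohorts) against 0.51 on matched cohorts with no planted effect.

The same stages are available as an umbrella CLI
(`metamarker simulate|assign-taxonomy|profile|diversity|diffabund|classify|run`),
with `metamarker run --config pipeline.yaml` executing everything and
writing a deterministic JSON report.

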