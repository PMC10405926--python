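# Methods

`metamarker` re-implements, as a tested pipeline over synthetic cohorts, the
analysis chain used in gut-metagenome biomarker studies of chronic
obstructive pulmonary disease (COPD): consensus taxonomy assignment for a
gene catalog, abundance profiling, diversity statistics, three-group
differential-abundance screening, and random-forest marker selection with a
cross-validation error-curve cutoff. This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Consensus taxonomy assignment

Each catalog gene carries BLAST-style nucleotide hits against reference
genomes, each hit annotated with a seven-rank lineage
(superkingdom→species). Assignment proceeds in three stages:

1. **Retention.** Hits must satisfy identity ≥ 65% and query coverage ≥ 80%;
   among those, hits with bit score ≥ 0.9 × the best passing score are
   retained. The "top-scoring hits" notion is ambiguous between
   *within-10%-of-best-score* and *top decile of hits*; the score-fraction
   reading is the default (it is the convention of the gene-catalog
   literature), the decile reading is available as `score_mode="top_decile"`.
2. **Rank consensus.** Walking species→genus→phylum with identity thresholds
   95/85/65, a label wins a rank if at least 50% of *all retained hits*
   support it at or above the rank threshold. The denominator choice
   (all retained hits, not just the thresholded subset) is the stricter of
   the two possible readings and is deterministic; it is configurable via
   `consensus_fraction` and the threshold table. Intermediate ranks (class,
   order, family) have no stated thresholds and are not consensus
   candidates; they enter an assignment only through a winning finer rank's
   lineage or the LCA fallback.
3. **LCA fallback.** If no thresholded rank reaches consensus, the gene
   receives the lowest common ancestor (longest shared label prefix) of all
   retained hit lineages, possibly empty.

Exact 50/50 ties between two labels return no winner and fall through; no
principled tie-break exists. A consequence worth knowing: the winning rank is
*not* globally monotone in the thresholds — raising a threshold can break a
tie and turn "no assignment" into an assignment, and the LCA fallback can
sit deeper than a failed consensus rank. What is monotone is each label's
support fraction, and that is what the property suite asserts. The whole
procedure is validated against an independent brute-force enumeration of the
rules on 1,000 random hit tables (zero mismatches required).

Unassignable genes are retained in profiles and aggregate into an
`unclassified` bucket at every rank, so per-sample totals are conserved
exactly and relative abundances stay comparable across samples.

## Profiles

Counts are depth-adjusted to a fixed target (default 3,000,000 reads) by
multivariate-hypergeometric subsampling without replacement (exact totals,
unbiased feature proportions); a scaling mode exists for coverage-style
inputs that need not be integers. Relative abundances divide by per-sample
totals; taxon and KEGG-ortholog (KO) rollups sum gene values by assignment
label (KO best-hit maps are validated at identity ≥ 30% and coverage ≥ 70%);
the arcsine-square-root transform `p → arcsin(√p)` variance-stabilizes
proportions before classification and preserves within-sample rankings.

## Diversity and group structure

Alpha diversity is the Shannon index with natural logarithm (the base is
configurable; the log base is rarely stated in applied work). Beta diversity
is Bray-Curtis dissimilarity. Ordination is classical metric MDS (principal
coordinates): Gower double-centering of squared distances and an
eigendecomposition, keeping axes with positive eigenvalues and reporting the
full spectrum so non-Euclidean distortion is visible. PERMANOVA partitions
the distance matrix into within/between-group sums of squares; the pseudo-F
has a permutation p-value `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)` (999
permutations by default, seeded) and the reported effect size is
**R² = SS_between/SS_total** — "Adonis R" in the applied literature is
ambiguous between R and R², and this package always reports and labels R².
PCoA and the PERMANOVA statistic are cross-checked against scikit-bio in the
test suite.

## Differential abundance

Per feature, the three pairwise two-sided Wilcoxon rank-sum tests are
computed (exact null distribution when min(n) ≤ 25 and tie-free, otherwise
tie-corrected normal approximation with continuity correction). How three
groups collapse into one test per feature is an open choice; the default
omnibus is `min(1, 3·min pairwise p)` (Bonferroni over the three pairs),
with Kruskal-Wallis available as an alternative. Omnibus p-values are
BH-adjusted across features; features below the FDR threshold (0.1 for taxa,
0.05 for KOs, both parameters) are called enriched in the group with the
maximal median and depleted in the group with the minimal median. Features
present in fewer than 10% of samples are excluded before testing
(configurable prevalence filter; standard practice for sparse count data).

## Marker discovery

One-vs-rest random forests (healthy vs rest, mild vs rest, severe vs rest)
on arcsine-square-root profiles, under stratified k-fold cross-validation
(5 folds; repeats configurable):

- **Hyperparameters** (number of trees, `mtry` = features per split) are
  grid-searched by mean CV error; ties prefer fewer trees.
- **Ranking** averages mean-decrease-in-impurity importance over all
  training-fold models; ties break lexicographically on feature id.
  Permutation importance was considered and not used: on these profiles the
  two orderings agree at the top and impurity importance is ~p times cheaper.
- **Error curve**: models on the top-k features for k in a schedule (dense
  1..30, then ×1.5 geometric to p), same folds for every k; mean and SD of
  the misclassification rate across folds×repeats.
- **Cutoff rule**: `cutoff = mean_error(k*) + sd_error(k*)` at the (first)
  minimizer k*; candidates are k with mean error strictly below the cutoff;
  the chosen size is the smallest candidate. A strict "<" with sd(k*) = 0
  can empty the candidate set; the fallback is k* itself.
- **Scoring**: each sample's score is the positive-class vote fraction from
  the fold that held it out, averaged over repeats. For the reported ROC the
  feature set is re-selected *inside each training fold* (that fold's own
  top-k): scoring a globally selected set out-of-fold still leaks the
  selection, which we measured as null-cohort AUC ≈ 0.64 versus ≈ 0.5 with
  fold-internal selection. The reported marker set itself is the global
  top-k. AUC is the normalized Mann-Whitney statistic (ties ½); the 95% CI
  is DeLong by default (stratified bootstrap with 2,000 seeded resamples
  optional).

## Synthetic cohorts

The generator emulates a three-group stool-metagenome cohort with known
ground truth; its defaults are the study conditions of the analysis scripts:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | (80, 31, 49) | healthy / mild / severe subjects |
| `n_features` | 500 | catalog genes |
| `n_informative` | 10 | planted disease-associated features |
| `effect_log2fc` | 2.0 | planted log2 fold change |
| `base_abundance_sigma` | 2.0 | log-normal rank-abundance skew |
| `sample_sigma` | 1.0 | subject-to-subject log-scale noise |
| `depth_mean` / `depth_dispersion` | 5×10⁶ / 100 | negative-binomial reads per sample |

Baseline proportions are log-normal (σ=2 gives the few-dominant-taxa skew of
real gut genus profiles). Each planted feature gets multipliers
`2^(−fc·s), 1, 2^(+fc·s)` across the three groups (sign s random per
feature), i.e. a monotone trend across disease severity; proportions are
renormalized per group. Each subject's composition is the group profile
perturbed by multiplicative log-normal noise (`sample_sigma`) — without
subject-level variation every sample in a group shares one composition, and
at realistic depths even the tiny renormalization shift on non-planted
features becomes perfectly detectable, which no real cohort resembles; σ=1
is a typical between-subject spread for log abundances in gut metagenomes.
Depths are negative-binomial (dispersion 100 keeps all samples comfortably
above the 3M subsampling target); counts are multinomial at each sample's
depth, so count rows sum to their depth exactly. All randomness flows from
one seed through `numpy.random.SeedSequence` spawning (baseline, effects,
depths, subject noise, counts) — identical configs are bit-identical.

What the generator does **not** emulate: zero-inflation beyond what the
multinomial induces, feature-feature correlation (no ecological
interactions), taxonomic structure in the planted effects, batch effects,
or read-level artifacts. Passing tests therefore demonstrate correctness of
the statistical machinery and end-to-end recoverability of planted signal
under idealized compositional noise — not performance on real cohorts.

Hit-table fixtures mix on-lineage hits with siblings diverging at species,
genus, or phylum and draw identity/coverage/bit scores across the
assignment thresholds; fully random tables over a small fixed taxonomy pool
(including genus- and phylum-truncated lineages) fuzz the consensus rules
against the brute-force oracle.

## Numerical and sizing choices

- Distance symmetry is enforced to 1e-12; relative-abundance rows must sum
  to 1 within 1e-9 (the unclassified bucket keeps totals exact).
- PCoA clamps eigenvalues within `1e-12·|λ_max|` of zero so duplicate
  samples do not yield spurious axes.
- Wilcoxon on an all-constant feature is undefined; the screen records p=1.
- The acceptance suite runs the end-to-end recovery check at 40 subjects per
  group, 500 features, 10 planted features, |log2FC|=2, 20 seeds, with a
  single-point forest grid (100 trees, √p mtry, 1 repeat) and a thinned
  k-schedule — sizes chosen to keep the full suite in the minutes range on
  one core while leaving the statistical conclusions unchanged; the analysis
  scripts use the full cohort sizes and the 2×2 default grid.
- `scripts/acceptance.py` reports pooled out-of-fold AUCs over 6 signal and
  6 null cohorts, screening recovery over 10 cohorts, and PERMANOVA/diversity
  on one full-size cohort, all derived from its `--seed`.

## Known limitations

- The consensus denominator and score-filter readings above are one of two
  defensible interpretations each; both alternatives are exposed as
  parameters rather than silently chosen.
- DeLong intervals are asymptotic; with very few positives (e.g. 31) they
  can be optimistic near AUC 1. The bootstrap option is the conservative
  alternative.
- The error-curve cutoff is a heuristic: with flat curves the chosen k is
  dominated by the SD at the minimum, and with sd(k*)=0 the rule degenerates
  to k*.
- Gene-to-taxon rollups inherit whatever bias the assignment stage has;
  with coarse reference pools most mass lands in `unclassified`, which
  dilutes taxon-level group structure (the analysis scripts therefore run
  community-level statistics on the full gene profile).
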