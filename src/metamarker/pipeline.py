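"""End-to-end pipeline driver: profiles -> diversity -> screening -> markers.

:class:`PipelineConfig` round-trips to/from YAML; :func:`run_pipeline`
executes every stage on a count matrix + metadata (optionally aggregating
genes to taxa/KOs first) and returns a fully deterministic, JSON-serializable
report keyed by stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import classifier, diffabund, diversity, io, profiles
from .exceptions import ConfigurationError, DataError
from .taxonomy import RankThresholds, assign_catalog

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str = ""
    metadata: str = ""
    out_dir: str = "results/pipeline"
    hits: str | None = None
    hit_lineages: str | None = None
    assignments: str | None = None
    rank: str = "genus"
    target_depth: int | None = None
    depth_mode: str = "subsample"
    score_fraction: float = 0.9
    fdr_taxa: float = 0.1
    fdr_ko: float = 0.05
    prevalence_min: float = 0.1
    n_permutations: int = 999
    n_folds: int = 5
    n_repeats: int = 2
    tree_grid: tuple[int, ...] = (100, 500)
    mtry_grid: tuple = ("sqrt", 0.33)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("tree_grid", "mtry_grid"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["tree_grid"] = list(self.tree_grid)
        data["mtry_grid"] = list(self.mtry_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate(self) -> None:
        for name in ("counts", "metadata"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise ConfigurationError(f"{name} file not found: {path!r}")
        for name in ("hits", "hit_lineages", "assignments"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise ConfigurationError(f"{name} file not found: {path!r}")
        if not 0 < self.score_fraction <= 1:
            raise ConfigurationError("score_fraction must lie in (0, 1]")
        if not (0 < self.fdr_taxa < 1 and 0 < self.fdr_ko < 1):
            raise ConfigurationError("FDR thresholds must lie in (0, 1)")


def _counts_report(matrix) -> dict:
    return {"n_samples": matrix.shape[0], "n_features": matrix.shape[1]}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write TSV outputs plus a JSON report to out_dir."""
    config.validate()
    out = io.ensure_dir(config.out_dir)
    report: dict = {"config": json.loads(json.dumps(asdict(config), default=list))}

    counts = io.read_abundance(config.counts)
    groups = io.read_metadata(config.metadata).reindex(counts.sample_ids)
    if groups.isna().any():
        raise DataError("metadata is missing samples present in the count matrix")
    logger.info("loaded %d samples x %d gene features", *counts.shape)

    # --- profiles -----------------------------------------------------------
    if config.assignments:
        assignments = io.read_assignments(config.assignments)
    elif config.hits and config.hit_lineages:
        lineages = io.read_lineages(config.hit_lineages)
        hits = io.read_hit_table(config.hits, lineages, io.QCOVS_DIALECT)
        assignments = assign_catalog(hits, RankThresholds(score_fraction=config.score_fraction))
        io.write_assignments(assignments, out / "assignments.tsv")
    else:
        assignments = None

    if config.target_depth:
        counts = profiles.normalize_depth(
            counts, config.target_depth, mode=config.depth_mode, seed=config.seed
        )
    if assignments is not None:
        feature_counts = profiles.aggregate_by_taxon(counts, assignments, config.rank)
    else:
        feature_counts = counts
    rel = profiles.relative_abundance(feature_counts)
    io.write_abundance(rel, out / "relative_abundance.tsv")
    report["profiles"] = _counts_report(rel) | {
        "rank": config.rank if assignments is not None else "gene",
        "aggregated": assignments is not None,
    }

    # --- diversity ----------------------------------------------------------
    alpha = diversity.alpha_diversity(rel)
    dist = diversity.bray_curtis_matrix(rel)
    ordination = diversity.pcoa(dist, n_axes=2)
    perm = diversity.permanova(dist, groups, config.n_permutations, seed=config.seed)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    dist.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
    ordination.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
    report["diversity"] = {
        "shannon_mean_by_group": {
            g: float(alpha[(groups == g).to_numpy()].mean()) for g in dict.fromkeys(groups)
        },
        "permanova_r2": perm.r_squared,
        "permanova_pseudo_f": perm.pseudo_f,
        "permanova_p": perm.p_value,
        "n_permutations": perm.n_permutations,
        "seed": config.seed,
    }

    # --- differential abundance --------------------------------------------
    fdr = config.fdr_ko if rel.feature_kind == "KO" else config.fdr_taxa
    screen = diffabund.screen_features(
        rel, groups, fdr_threshold=fdr, prevalence_min=config.prevalence_min
    )
    screen.to_csv(out / "differential_abundance.tsv", sep="\t")
    sig = screen[screen["significant"]]
    report["diffabund"] = {
        "n_tested": int(len(screen)),
        "fdr_threshold": fdr,
        "n_significant": int(len(sig)),
        "n_enriched_by_group": sig["enriched_in"].value_counts().to_dict(),
    }

    # --- classification -----------------------------------------------------
    transformed = profiles.arcsin_sqrt_transform(rel)
    cv = classifier.CVConfig(
        n_folds=config.n_folds,
        n_repeats=config.n_repeats,
        tree_grid=tuple(config.tree_grid),
        mtry_grid=tuple(config.mtry_grid),
        seed=config.seed,
    )
    report["classifier"] = {}
    for positive in dict.fromkeys(groups):
        sel, roc = classifier.run_marker_discovery(transformed, groups, positive, cv)
        sel.curve.to_frame().to_csv(out / f"cv_curve_{positive}.tsv", sep="\t", index=False)
        report["classifier"][positive] = {
            "auc": roc.auc,
            "ci_low": roc.ci_low,
            "ci_high": roc.ci_high,
            "ci_method": roc.ci_method,
            "chosen_k": sel.chosen_k,
            "cutoff": sel.cutoff,
            "chosen_features": list(sel.chosen_features),
            "best_params": {k: str(v) for k, v in sel.best_params.items()},
            "seed": config.seed,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report
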