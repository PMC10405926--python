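"""One-vs-rest random-forest marker discovery.

The procedure, applied to an (arcsine-square-root transformed) abundance
matrix and binary labels:

1. Grid-search the number of trees and ``mtry`` (features per split) by mean
   error under repeated stratified k-fold cross-validation (5 folds default).
2. Rank features by mean-decrease-in-impurity importance averaged over the
   cross-validation training folds (ties broken lexicographically).
3. Sequentially add top-ranked features, recording mean and SD of the CV
   error against the number of features (the CV error curve).
4. Select features with the error-curve cutoff: ``cutoff = min mean error +
   SD at the minimizing point``; candidates are the k with mean error
   strictly below the cutoff, and the chosen set is the smallest such k
   (falling back to the minimizer itself when the strict set is empty, which
   happens when the SD at the minimum is zero).
5. Score samples out-of-fold at the chosen set size (positive-class vote
   fraction, averaged across CV repeats) and summarize with ROC/AUC and a 95%
   DeLong confidence interval. For the ROC, each training fold re-ranks
   features internally and uses its own top-k, so the reported AUC carries no
   feature-selection optimism; the reported marker set is the global top-k.

Every random choice derives from a single seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, DataError
from .profiles import AbundanceMatrix


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and random-forest settings."""

    n_folds: int = 5
    n_repeats: int = 5
    tree_grid: tuple[int, ...] = (100, 500)
    mtry_grid: tuple = ("sqrt", 0.33)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if not self.tree_grid or not self.mtry_grid:
            raise ConfigurationError("hyperparameter grids must be non-empty")


@dataclass(frozen=True)
class CVCurve:
    """Mean/SD cross-validation error versus number of top-ranked features."""

    k: np.ndarray
    mean_error: np.ndarray
    sd_error: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.k) > 0):
            raise ConfigurationError("k values must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "mean_error": self.mean_error, "sd_error": self.sd_error}
        )


@dataclass(frozen=True)
class SelectionResult:
    ranked_features: tuple[str, ...]
    importances: pd.Series
    best_params: dict
    curve: CVCurve
    cutoff: float
    candidate_ks: tuple[int, ...]
    chosen_k: int
    chosen_features: tuple[str, ...]
    oof_scores: pd.Series | None = None


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str = "delong"


def make_binary_labels(groups, positive_class) -> np.ndarray:
    """Boolean one-vs-rest labels; ``positive_class`` may be a name or a list
    of names (e.g. pooling the two disease-severity groups)."""
    groups = pd.Series(list(groups))
    positive = {positive_class} if isinstance(positive_class, str) else set(positive_class)
    unknown = positive - set(groups)
    if unknown:
        raise DataError(f"positive class(es) not present: {sorted(unknown)}")
    y = groups.isin(positive).to_numpy()
    if y.all() or not y.any():
        raise DataError("binarization produced a single class")
    return y


def _seed_ints(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _splits(y: np.ndarray, config: CVConfig) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Fold index pairs per repeat; the same splits are reused across the grid
    and across curve points so errors are comparable."""
    out = []
    for rep_seed in _seed_ints(config.seed, config.n_repeats):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=rep_seed)
        out.append(list(skf.split(np.zeros_like(y), y)))
    return out


def _forest(n_trees: int, mtry, rs: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=rs, n_jobs=1
    )


def _cv_errors(X: np.ndarray, y: np.ndarray, splits, n_trees, mtry, fit_seed: int):
    errors = []
    for rep, folds in enumerate(splits):
        for fold, (tr, te) in enumerate(folds):
            model = _forest(n_trees, mtry, fit_seed + 7919 * rep + fold)
            model.fit(X[tr], y[tr])
            errors.append(float(np.mean(model.predict(X[te]) != y[te])))
    return errors


def cv_feature_importance(
    matrix: AbundanceMatrix, y: np.ndarray, config: CVConfig
) -> tuple[tuple[str, ...], pd.Series, dict]:
    """Grid-search hyperparameters and rank features by CV-averaged importance.

    Returns ``(ranked_feature_ids, mean_importances, best_params)``.
    """
    X = matrix.values().astype(float)
    y = np.asarray(y)
    counts = np.bincount(y.astype(int))
    if counts.min() < config.n_folds:
        raise DataError("each class needs at least n_folds samples")
    splits = _splits(y, config)
    fit_seed = _seed_ints(config.seed + 1, 1)[0]

    best = None
    for n_trees in config.tree_grid:
        for mtry in config.mtry_grid:
            mean_err = float(np.mean(_cv_errors(X, y, splits, n_trees, mtry, fit_seed)))
            key = (mean_err, n_trees, str(mtry))
            if best is None or key < best[0]:
                best = (key, {"n_trees": n_trees, "mtry": mtry})
    best_params = best[1]

    total = np.zeros(X.shape[1])
    n_models = 0
    for rep, folds in enumerate(splits):
        for fold, (tr, _te) in enumerate(folds):
            model = _forest(best_params["n_trees"], best_params["mtry"], fit_seed + 104729 * rep + fold)
            model.fit(X[tr], y[tr])
            total += model.feature_importances_
            n_models += 1
    importances = pd.Series(total / n_models, index=matrix.feature_ids, name="importance")
    order = sorted(matrix.feature_ids, key=lambda f: (-importances[f], f))
    return tuple(order), importances.loc[order], best_params


def default_k_schedule(n_features: int, dense_until: int = 30) -> tuple[int, ...]:
    """1..min(30, p), then geometric (x1.5) up to and including p."""
    ks = list(range(1, min(dense_until, n_features) + 1))
    k = ks[-1]
    while k < n_features:
        k = min(n_features, max(k + 1, int(np.ceil(k * 1.5))))
        ks.append(k)
    return tuple(ks)


def sequential_feature_curve(
    matrix: AbundanceMatrix,
    y: np.ndarray,
    ranked_features,
    config: CVConfig,
    params: dict | None = None,
    schedule=None,
) -> CVCurve:
    """CV error mean/SD for models on the top-k ranked features, per k."""
    ranked_features = list(ranked_features)
    if not ranked_features:
        raise DataError("ranked feature list is empty")
    if schedule is None:
        schedule = default_k_schedule(len(ranked_features))
    schedule = sorted({min(k, len(ranked_features)) for k in schedule})
    params = params or {"n_trees": config.tree_grid[0], "mtry": config.mtry_grid[0]}
    y = np.asarray(y)
    splits = _splits(y, config)
    fit_seed = _seed_ints(config.seed + 2, 1)[0]
    data = matrix.data[ranked_features].to_numpy().astype(float)

    means, sds = [], []
    for k in schedule:
        errs = _cv_errors(data[:, :k], y, splits, params["n_trees"], params["mtry"], fit_seed + k)
        means.append(float(np.mean(errs)))
        sds.append(float(np.std(errs, ddof=1)) if len(errs) > 1 else 0.0)
    return CVCurve(np.asarray(schedule), np.asarray(means), np.asarray(sds))


def select_features(curve: CVCurve, ranked_features=None) -> dict:
    """Apply the error-curve cutoff rule to a CV curve.

    ``cutoff = mean_error(k*) + sd_error(k*)`` with ``k*`` the (smallest)
    minimizer of the mean error; candidates are ks with mean error strictly
    below the cutoff; the chosen k is the smallest candidate, or ``k*`` when
    the strict candidate set is empty.
    """
    if len(curve.k) == 0:
        raise DataError("empty CV curve")
    i_star = int(np.argmin(curve.mean_error))  # argmin takes the first, i.e. smallest k
    cutoff = float(curve.mean_error[i_star] + curve.sd_error[i_star])
    candidates = tuple(int(k) for k, m in zip(curve.k, curve.mean_error) if m < cutoff)
    chosen_k = min(candidates) if candidates else int(curve.k[i_star])
    out = {"cutoff": cutoff, "candidate_ks": candidates, "chosen_k": chosen_k}
    if ranked_features is not None:
        out["chosen_features"] = tuple(list(ranked_features)[:chosen_k])
    return out


def _auc_mannwhitney(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic, ties counted 1/2."""
    ranks = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _delong_ci(scores: np.ndarray, y: np.ndarray, auc: float, level: float = 0.95):
    """DeLong variance of the AUC via the placement-value decomposition."""
    pos = scores[y]
    neg = scores[~y]
    m, n = pos.size, neg.size
    # v10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i); v01 symmetric
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def roc_auc(scores, labels, ci_method: str = "delong", seed: int | None = None) -> RocResult:
    """ROC curve, Mann-Whitney AUC, and a 95% confidence interval."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise DataError("both classes must be present")
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite")
    auc = _auc_mannwhitney(scores, y)
    fpr, tpr, thresholds = roc_curve(y, scores)
    if ci_method == "delong":
        lo, hi = _delong_ci(scores, y, auc)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx, neg_idx = np.flatnonzero(y), np.flatnonzero(~y)
        reps = np.empty(2000)
        for b in range(reps.size):
            idx = np.concatenate(
                [rng.choice(pos_idx, pos_idx.size), rng.choice(neg_idx, neg_idx.size)]
            )
            reps[b] = _auc_mannwhitney(scores[idx], y[idx])
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ConfigurationError(f"unknown ci_method {ci_method!r}")
    return RocResult(fpr, tpr, thresholds, auc, float(lo), float(hi), ci_method)


def out_of_fold_scores(
    matrix: AbundanceMatrix,
    y: np.ndarray,
    features,
    config: CVConfig,
    params: dict,
    rerank_k: int | None = None,
) -> pd.Series:
    """Positive-class vote fraction for each sample from models that never saw
    it, averaged across CV repeats.

    With ``rerank_k`` set, each training fold re-ranks all features by its own
    forest's importance and keeps its top ``rerank_k``; the held-out fold
    never influences which features its model uses. This removes the
    selection-bias optimism of scoring with a globally chosen feature set
    (``features`` is then the candidate pool, normally all features).
    """
    y = np.asarray(y)
    features = list(features)
    X = matrix.data[features].to_numpy().astype(float)
    splits = _splits(y, config)
    fit_seed = _seed_ints(config.seed + 3, 1)[0]
    acc = np.zeros(y.size)
    for rep, folds in enumerate(splits):
        seen = np.zeros(y.size, dtype=bool)
        for fold, (tr, te) in enumerate(folds):
            rs = fit_seed + 15485863 * rep + fold
            cols = np.arange(X.shape[1])
            if rerank_k is not None:
                ranker = _forest(params["n_trees"], params["mtry"], rs + 1)
                ranker.fit(X[tr], y[tr])
                imp = ranker.feature_importances_
                order = sorted(range(len(features)), key=lambda i: (-imp[i], features[i]))
                cols = np.asarray(order[:rerank_k])
            model = _forest(params["n_trees"], params["mtry"], rs)
            model.fit(X[np.ix_(tr, cols)], y[tr])
            pos_col = list(model.classes_).index(True)
            acc[te] += model.predict_proba(X[np.ix_(te, cols)])[:, pos_col]
            assert not seen[te].any(), "out-of-fold discipline violated"
            seen[te] = True
        assert seen.all()
    return pd.Series(acc / len(splits), index=matrix.sample_ids, name="oof_score")


def run_marker_discovery(
    matrix: AbundanceMatrix,
    groups,
    positive_class,
    config: CVConfig,
    schedule=None,
) -> tuple[SelectionResult, RocResult]:
    """Full marker-discovery pass for one one-vs-rest contrast."""
    y = make_binary_labels(groups, positive_class)
    ranked, importances, params = cv_feature_importance(matrix, y, config)
    curve = sequential_feature_curve(matrix, y, ranked, config, params, schedule)
    sel = select_features(curve, ranked)
    # score with fold-internal re-ranking at the chosen size so that the ROC
    # carries no feature-selection optimism
    oof = out_of_fold_scores(matrix, y, ranked, config, params, rerank_k=sel["chosen_k"])
    roc = roc_auc(oof.to_numpy(), y)
    selection = SelectionResult(
        ranked_features=ranked,
        importances=importances,
        best_params=params,
        curve=curve,
        cutoff=sel["cutoff"],
        candidate_ks=sel["candidate_ks"],
        chosen_k=sel["chosen_k"],
        chosen_features=sel["chosen_features"],
        oof_scores=oof,
    )
    return selection, roc
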