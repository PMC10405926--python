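"""Three-group differential-abundance screening.

Per feature, the three pairwise two-sided Wilcoxon rank-sum tests are
computed; the omnibus p-value is the smallest pairwise p multiplied by the
Bonferroni factor 3 (a Kruskal-Wallis omnibus is available as an alternative).
Omnibus p-values are adjusted across features with Benjamini-Hochberg, and
features passing the FDR threshold are called enriched in the group where
their median relative abundance is maximal and depleted where it is minimal.

Low-prevalence features (present in fewer than 10% of samples by default) are
excluded before testing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DataError
from .profiles import AbundanceMatrix


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank sum of ``x`` in the pooled ranking.
    The exact null distribution is used when min(n) <= 25 and the pooled data
    are tie-free; otherwise a tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Wilcoxon p set to 1", stacklevel=2)
        w = x.size * (pooled.size + 1) / 2
        return float(w), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2
    return w, float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pairwise_pvalues(values: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """p-values of the three pairwise rank-sum tests, shape (3, n_features)."""
    pairs = [(0, 1), (0, 2), (1, 2)]
    out = np.empty((3, values.shape[1]))
    for row, (a, b) in enumerate(pairs):
        xa = values[masks[a]]
        xb = values[masks[b]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant slices yield p=1 below
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto", axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        # A feature constant across both groups has an undefined test; treat as null.
        constant = np.all(np.concatenate([xa, xb]) == xa[0], axis=0)
        p[constant] = 1.0
        out[row] = p
    return out


def screen_features(
    matrix: AbundanceMatrix,
    groups,
    fdr_threshold: float = 0.1,
    prevalence_min: float = 0.1,
    omnibus: str = "pairwise",
) -> pd.DataFrame:
    """Screen every feature for differential abundance across three groups.

    Returns a DataFrame with one row per tested feature: pairwise p-values,
    omnibus p, BH q, per-group medians, and the enriched/depleted calls for
    significant features.
    """
    if matrix.value_kind != "relative":
        raise ConfigurationError("screen_features expects relative abundances")
    if omnibus not in ("pairwise", "kruskal"):
        raise ConfigurationError(f"unknown omnibus strategy {omnibus!r}")
    groups = pd.Series(list(groups), index=matrix.sample_ids)
    names = list(pd.unique(groups))
    if len(names) != 3:
        raise DataError(f"expected 3 groups, found {len(names)}")
    sizes = groups.value_counts()
    if sizes.min() < 2:
        raise DataError("every group needs at least 2 samples")
    if sizes.min() < 3:
        warnings.warn("a group has fewer than 3 samples; tests will be weak", stacklevel=2)

    values = matrix.values().astype(float)
    prevalence = (values > 0).mean(axis=0)
    keep = prevalence >= prevalence_min
    tested = np.asarray(matrix.feature_ids, dtype=object)[keep]
    values = values[:, keep]
    masks = [(groups == g).to_numpy() for g in names]

    p_pair = _pairwise_pvalues(values, masks)
    if omnibus == "pairwise":
        p_omni = np.minimum(1.0, 3.0 * p_pair.min(axis=0))
    else:
        p_omni = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            samples = [values[m, j] for m in masks]
            if all(np.all(s == samples[0][0]) for s in samples):
                p_omni[j] = 1.0
            else:
                p_omni[j] = stats.kruskal(*samples).pvalue
    q = bh_adjust(p_omni)

    medians = np.vstack([np.median(values[m], axis=0) for m in masks])
    significant = q < fdr_threshold
    enriched = np.array(names, dtype=object)[medians.argmax(axis=0)]
    depleted = np.array(names, dtype=object)[medians.argmin(axis=0)]
    result = pd.DataFrame(
        {
            "feature_id": tested,
            "p_omnibus": p_omni,
            "q_value": q,
            "significant": significant,
            "enriched_in": np.where(significant, enriched, "ns"),
            "depleted_in": np.where(significant, depleted, "ns"),
        }
    )
    for row, (a, b) in enumerate([(0, 1), (0, 2), (1, 2)]):
        result[f"p_{names[a]}_vs_{names[b]}"] = p_pair[row]
    for i, g in enumerate(names):
        result[f"median_{g}"] = medians[i]
    return result.set_index("feature_id")
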