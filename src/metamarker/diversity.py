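"""Alpha/beta diversity, ordination and permutational group testing.

Shannon entropy (natural log by default) summarizes within-sample diversity;
Bray-Curtis dissimilarity summarizes between-sample compositional turnover.
Ordination uses classical metric multidimensional scaling (principal
coordinates analysis): Gower double-centering of squared distances followed by
an eigendecomposition, keeping axes with positive eigenvalues and reporting
negative eigenvalues as diagnostics. Group structure is tested with
PERMANOVA: the pseudo-F from a within/between sum-of-squares partition of the
distance matrix, with a permutation p-value
``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` and effect size
``R^2 = SS_between / SS_total``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigurationError, DataError
from .profiles import AbundanceMatrix


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative sample-by-sample distances with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise DataError("distance matrix must be square and match the id list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric (tolerance 1e-12)")
        if np.any(np.diag(v) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if v.size and v.min() < 0:
            raise DataError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes, axes ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis


@dataclass(frozen=True)
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None


def shannon(values, base: float | None = None) -> float:
    """Shannon index H = -sum p ln p (renormalizing the input to proportions)."""
    p = np.asarray(values, dtype=float)
    if p.size == 0 or np.any(p < 0):
        raise DataError("shannon requires non-negative values")
    total = p.sum()
    if total <= 0:
        raise DataError("shannon requires a sample with positive total abundance")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def alpha_diversity(matrix: AbundanceMatrix, base: float | None = None) -> pd.Series:
    """Per-sample Shannon index."""
    return pd.Series(
        [shannon(row, base=base) for row in matrix.values()],
        index=matrix.sample_ids,
        name="shannon",
    )


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("bray_curtis requires equal-length vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise DataError("bray_curtis requires non-negative vectors")
    denom = (a + b).sum()
    if denom == 0:
        raise DataError("bray_curtis undefined for two all-zero samples")
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(matrix: AbundanceMatrix) -> DistanceMatrix:
    """All pairwise Bray-Curtis dissimilarities between samples."""
    values = matrix.values().astype(float)
    if np.any(values.sum(axis=1) == 0):
        raise DataError("all-zero sample in abundance matrix")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(tuple(matrix.sample_ids), squareform(condensed))


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis (classical MDS).

    Axes are restricted to positive eigenvalues; the full (possibly negative)
    eigenvalue spectrum is reported so non-Euclidean distortion is visible.
    Proportions explained use the sum of positive eigenvalues.
    """
    d2 = dist.values.astype(float) ** 2
    n = dist.n
    centerer = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # Clamp eigenvalues that are zero up to rounding so duplicate samples
    # and exact configurations don't yield spurious axes.
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    k = int(positive.sum())
    if n_axes is not None:
        k = min(k, n_axes)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcoaResult(frame, eigvals, proportion)


def _permanova_stats(d2: np.ndarray, groups: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(groups == g)
        if idx.size:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    f = (ss_between / df_between) / (ss_within / df_within)
    return float(f), float(ss_between / ss_total)


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against group labels."""
    labels = pd.Series(list(labels))
    if len(labels) != dist.n:
        raise DataError("labels must match the distance matrix samples")
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    counts = np.bincount(codes)
    if n_groups < 2 or counts.min() < 2:
        raise DataError("PERMANOVA needs >=2 groups with >=2 samples each")
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    d2 = dist.values.astype(float) ** 2
    f_obs, r2 = _permanova_stats(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        f_perm, _ = _permanova_stats(d2, perm, n_groups)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(r2, f_obs, p, n_permutations, seed)


def pairwise_group_dissimilarity(
    dist: DistanceMatrix, labels, pair: tuple[str, str]
) -> np.ndarray:
    """All between-group distances for one pair of groups (n1*n2 values)."""
    labels = pd.Series(list(labels), index=list(dist.ids))
    for g in pair:
        if g not in set(labels):
            raise DataError(f"group {g!r} not present in labels")
    idx_a = np.flatnonzero((labels == pair[0]).to_numpy())
    idx_b = np.flatnonzero((labels == pair[1]).to_numpy())
    return dist.values[np.ix_(idx_a, idx_b)].ravel()
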