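"""Alpha diversity, Bray-Curtis dissimilarity, PCoA ordination and matrix
permutation tests (ANOSIM, Mantel), plus WGS84 geodesic distance matrices.

Permutation tests use the add-one estimator p = (1 + #extreme) / (1 + n_perm)
so that p is never exactly zero; both tests also accept
``n_perm="exhaustive"``, in which case every label arrangement is enumerated
and p is the exact proportion of arrangements at least as extreme (identity
included).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .geodesic import geodesic_matrix
from .io_tables import FeatureTable, SampleMetadata, ValidationError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "shannon",
    "shannon_per_sample",
    "bray_curtis",
    "pcoa",
    "anosim",
    "mantel",
    "geodesic_distance_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max() != 0.0:
            raise ValidationError("distance matrix diagonal not zero")
        if (v < 0).any():
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray       # n x k
    eigenvalues: np.ndarray       # positive eigenvalues, descending
    pct_explained: np.ndarray     # percentages, same length
    ids: tuple[str, ...]


def shannon(counts_row, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over p_i > 0 (natural log by default)."""
    x = np.asarray(counts_row, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x / total
    p = p[p > 0]  # filter after normalizing: a subnormal count can underflow to 0
    return float(-(p * (np.log(p) / math.log(base))).sum())


def shannon_per_sample(ft: FeatureTable, base: float = math.e) -> dict[str, float]:
    return {s: shannon(row, base=base) for s, row in zip(ft.sample_ids, ft.values)}


def bray_curtis(ft: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    if (ft.values.sum(axis=1) <= 0).any():
        raise ValidationError("all-zero sample row: Bray-Curtis undefined")
    d = squareform(pdist(ft.values, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ft.sample_ids, d)


def pcoa(d: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    Eigendecomposes B = -J (D∘D) J / 2 with J = I - 11'/n; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) for the positive eigenvalues.
    ``pct_explained`` is relative to the sum of positive eigenvalues; negative
    eigenvalues are dropped without correction.
    """
    n = d.n
    if k is None:
        k = n - 1
    if k > n - 1:
        raise ValueError("k must be <= n - 1")
    D2 = d.values ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10 * max(abs(eigvals[0]), 1.0), 0.0)
    pos = eigvals > tol
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating to {n_pos} axes")
        k = n_pos
    lam = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(lam)[None, :]
    pos_sum = eigvals[pos].sum()
    pct = 100.0 * lam / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(coords, lam, pct, d.ids)


# ---------------------------------------------------------------------------
# permutation tests


def _anosim_r(ranks_condensed: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    mean_within = ranks_condensed[within_mask].mean()
    mean_between = ranks_condensed[~within_mask].mean()
    return (mean_between - mean_within) / (n * (n - 1) / 4.0)


def _within_mask(groups: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(groups), k=1)
    return groups[i] == groups[j]


def anosim(d: DistanceMatrix, groups, n_perm=999, seed: int | None = None):
    """ANOSIM: R = (mean between-group rank - mean within-group rank) / (N(N-1)/4).

    Distances are converted to midranks; the one-sided p-value counts
    permutations with R at least as large as observed.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ValueError("group labels do not match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with a single member: {small}")
    ranks = rankdata(d.condensed())
    n = d.n
    r_obs = _anosim_r(ranks, _within_mask(groups), n)

    if n_perm == "exhaustive":
        perms = set(itertools.permutations(groups.tolist()))
        r_perm = np.array([_anosim_r(ranks, _within_mask(np.asarray(p)), n) for p in perms])
        p = float((r_perm >= r_obs - 1e-12).mean())
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            perm = rng.permutation(groups)
            if _anosim_r(ranks, _within_mask(perm), n) >= r_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + int(n_perm))
    return float(r_obs), float(p)


def _upper(v: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(v.shape[0], k=1)
    return v[i, j]


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method="pearson",
           n_perm=999, seed: int | None = None, alternative="two-sided"):
    """Mantel test: correlation of the upper triangles of two distance matrices,
    with significance from joint row/column permutation of the second matrix.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices have mismatched ids")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs n >= 4")
    x = _upper(d1.values)
    y_mat = d2.values

    def _vec(v):
        if method == "spearman":
            return rankdata(v)
        if method == "pearson":
            return v
        raise ValueError(f"unknown method {method!r}")

    xv = _vec(x)
    if np.std(xv) == 0 or np.std(_vec(_upper(y_mat))) == 0:
        raise ValueError("zero-variance distance matrix: Mantel correlation undefined")

    xv = (xv - xv.mean()) / xv.std()

    def _r(perm):
        yv = _vec(_upper(y_mat[np.ix_(perm, perm)]))
        yv = (yv - yv.mean()) / yv.std()
        return float((xv * yv).mean())

    identity = np.arange(n)
    r_obs = _r(identity)

    def _extreme(r):
        if alternative == "two-sided":
            return abs(r) >= abs(r_obs) - 1e-12
        return r >= r_obs - 1e-12

    if n_perm == "exhaustive":
        rs = [_r(np.asarray(p)) for p in itertools.permutations(range(n))]
        p = float(np.mean([_extreme(r) for r in rs]))
    else:
        rng = np.random.default_rng(seed)
        count = sum(_extreme(_r(rng.permutation(n))) for _ in range(int(n_perm)))
        p = (1 + count) / (1 + int(n_perm))
    return float(r_obs), float(p)


def geodesic_distance_matrix(meta: SampleMetadata) -> DistanceMatrix:
    """Pairwise WGS84 geodesic distances (meters) between sample coordinates."""
    m = geodesic_matrix(meta.column("latitude"), meta.column("longitude"))
    return DistanceMatrix(meta.sample_ids, m)
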