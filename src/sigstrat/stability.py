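"""k-means clustering of samples and bootstrap-Jaccard stability selection
of the number of clusters.

Stability of a clustering at a given k is assessed cluster-wise: on each
bootstrap resample (with replacement) the data are reclustered at the same
k and each original cluster is matched to the bootstrap cluster maximizing
the Jaccard similarity computed on the multiset of resampled sample
indices (duplicates counted; equivalently, set Jaccard on draw positions).
The chosen k is the largest one whose worst per-cluster mean Jaccard
exceeds the stability cutoff (default 0.85).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import ValidationError

__all__ = [
    "KMeansResult",
    "StabilityReport",
    "kmeans_cluster",
    "bootstrap_jaccard",
    "choose_k",
    "standardize_features",
]


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    n_iter: int


@dataclass
class StabilityReport:
    k: int
    per_cluster_mean_jaccard: np.ndarray
    n_bootstrap: int
    seed: int
    chosen: bool = False

    def __post_init__(self) -> None:
        j = np.asarray(self.per_cluster_mean_jaccard, dtype=float)
        if j.size != self.k:
            raise ValidationError("jaccard vector length must equal k")
        if np.any(j < 0) or np.any(j > 1):
            raise ValidationError("Jaccard values must lie in [0, 1]")
        self.per_cluster_mean_jaccard = j

    @property
    def min_jaccard(self) -> float:
        return float(self.per_cluster_mean_jaccard.min())


def standardize_features(matrix: np.ndarray) -> np.ndarray:
    """Zero-mean/unit-variance scaling per feature (column); constant features -> 0."""
    m = np.asarray(matrix, dtype=float)
    mu = m.mean(axis=0)
    sd = m.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (m - mu) / sd


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d2 = np.sum((x - centroids[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[i:] = x[rng.integers(n, size=k - i)]
            break
        probs = d2 / total
        centroids[i] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((x - centroids[i]) ** 2, axis=1))
    return centroids


def _lloyd(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> KMeansResult:
    centroids = _kmeans_pp_init(x, k, rng)
    prev_wcss = np.inf
    labels = np.zeros(x.shape[0], dtype=int)
    for it in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # empty cluster: re-seed its centroid at the point farthest from its
        # assigned centroid (each reseed claims a distinct point)
        assigned_d2 = d2[np.arange(x.shape[0]), labels].copy()
        for c in range(k):
            if not np.any(labels == c):
                far = int(assigned_d2.argmax())
                centroids[c] = x[far]
                labels[far] = c
                assigned_d2[far] = -np.inf
        new_centroids = np.stack(
            [x[labels == c].mean(axis=0) if np.any(labels == c) else centroids[c]
             for c in range(k)]
        )
        d2_new = ((x - new_centroids[labels]) ** 2).sum(axis=1)
        wcss = float(d2_new.sum())
        if wcss > prev_wcss + 1e-9 * max(prev_wcss, 1.0):
            raise AssertionError("k-means WCSS increased across a Lloyd iteration")
        shift = float(np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max())
        centroids = new_centroids
        prev_wcss = wcss
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(x.shape[0]), labels].sum())
    return KMeansResult(labels, centroids, wcss, it + 1)


def kmeans_cluster(
    matrix: np.ndarray, k: int, n_init: int = 10, seed: int = 0
) -> KMeansResult:
    """Best-of-n_init Lloyd k-means (k-means++ starts), deterministic given seed."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("matrix must be samples x features")
    if not np.all(np.isfinite(x)):
        raise ValidationError("features must be finite")
    if not (1 <= k <= x.shape[0]):
        raise ValidationError(f"k={k} must lie in [1, n_samples={x.shape[0]}]")
    rng = np.random.default_rng(seed)
    best: Optional[KMeansResult] = None
    for _ in range(max(1, n_init)):
        res = _lloyd(x, k, rng)
        if best is None or res.wcss < best.wcss:
            best = res
    return best


def _multiset_jaccard(a_mask: np.ndarray, b_mask: np.ndarray) -> float:
    inter = np.sum(a_mask & b_mask)
    union = np.sum(a_mask | b_mask)
    return inter / union if union else 0.0


def bootstrap_jaccard(
    matrix: np.ndarray,
    k: int,
    n_bootstrap: int = 100,
    seed: int = 0,
    n_init: int = 10,
    boot_n_init: Optional[int] = None,
) -> StabilityReport:
    """Cluster-wise mean bootstrap Jaccard stability at a fixed k.

    Each resample (with replacement) is reclustered at the same k; every
    original cluster scores the Jaccard similarity to its best-matching
    bootstrap cluster over the resampled draws.  A cluster absent from a
    resample scores 0 for that draw (conservative).
    """
    if n_bootstrap < 20:
        raise ValidationError("n_bootstrap must be >= 20")
    x = np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(seed)
    base = kmeans_cluster(x, k, n_init=n_init, seed=int(rng.integers(2**31)))
    boot_n_init = boot_n_init or n_init
    n = x.shape[0]
    jacc = np.zeros((n_bootstrap, k))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        res = _lloyd_best(x[idx], k, rng, boot_n_init)
        orig = base.labels[idx]
        for c in range(k):
            a_mask = orig == c
            if not a_mask.any():
                jacc[b, c] = 0.0
                continue
            jacc[b, c] = max(
                _multiset_jaccard(a_mask, res.labels == j) for j in range(k)
            )
    return StabilityReport(
        k=k,
        per_cluster_mean_jaccard=jacc.mean(axis=0),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def _lloyd_best(x, k, rng, n_init) -> KMeansResult:
    best = None
    for _ in range(max(1, n_init)):
        res = _lloyd(x, k, rng)
        if best is None or res.wcss < best.wcss:
            best = res
    return best


def choose_k(
    matrix: np.ndarray,
    k_range: Sequence[int],
    jaccard_hi: float = 0.85,
    n_bootstrap: int = 100,
    seed: int = 0,
    n_init: int = 10,
    boot_n_init: Optional[int] = None,
) -> dict:
    """Pick the number of clusters by bootstrap-Jaccard stability.

    k_star is the largest k in ``k_range`` whose minimum per-cluster mean
    Jaccard exceeds ``jaccard_hi``; when no k qualifies, the k maximizing
    the minimum Jaccard is returned with ``stable=False``.
    """
    ks = sorted(set(int(k) for k in k_range))
    x = np.asarray(matrix, dtype=float)
    if not ks:
        raise ValidationError("k_range is empty")
    if ks[0] < 2 or ks[-1] > x.shape[0] - 1:
        raise ValidationError(f"k_range must lie within [2, n_samples-1], got {ks}")
    seeds = np.random.SeedSequence(seed).spawn(len(ks))
    reports = {}
    for k, ss in zip(ks, seeds):
        reports[k] = bootstrap_jaccard(
            x,
            k,
            n_bootstrap=n_bootstrap,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            n_init=n_init,
            boot_n_init=boot_n_init,
        )
    stable = [k for k in ks if reports[k].min_jaccard > jaccard_hi]
    if stable:
        k_star, flag = max(stable), True
    else:
        k_star = max(ks, key=lambda k: reports[k].min_jaccard)
        flag = False
    reports[k_star].chosen = True
    return {"k_star": k_star, "stable": flag, "reports": reports}
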