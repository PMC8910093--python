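"""Seeded k-means core used by the gap-statistic machinery.

A single gap-statistic model search performs thousands of small k-means fits
(every candidate k on the data plus B null-reference datasets, across many
nomination iterations), so the inner Lloyd loop is numba-compiled.
Initialization is k-means++; iteration cap 300, tolerance 1e-4 on the total
squared centroid shift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["kmeans_fit", "KMeansFit"]


@njit(cache=True)
def _lloyd(X, C, max_iter, tol):
    n, d = X.shape
    k = C.shape[0]
    labels = np.zeros(n, np.int64)
    for _ in range(max_iter):
        for i in range(n):
            best = 0
            bd = np.inf
            for j in range(k):
                s = 0.0
                for m in range(d):
                    t = X[i, m] - C[j, m]
                    s += t * t
                if s < bd:
                    bd = s
                    best = j
            labels[i] = best
        sums = np.zeros((k, d))
        counts = np.zeros(k)
        for i in range(n):
            counts[labels[i]] += 1.0
            for m in range(d):
                sums[labels[i], m] += X[i, m]
        shift = 0.0
        for j in range(k):
            if counts[j] > 0:
                for m in range(d):
                    v = sums[j, m] / counts[j]
                    shift += (v - C[j, m]) ** 2
                    C[j, m] = v
        if shift < tol * tol:
            break
    inertia = 0.0
    for i in range(n):
        j = labels[i]
        for m in range(d):
            t = X[i, m] - C[j, m]
            inertia += t * t
    return C, labels, inertia


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j] = X[rng.integers(n)]
            continue
        centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


class KMeansFit:
    """Result of one seeded k-means fit."""

    __slots__ = ("centroids", "labels", "inertia", "k", "n_empty")

    def __init__(self, centroids, labels, inertia, k):
        self.centroids = centroids
        self.labels = labels
        self.inertia = inertia
        self.k = k
        self.n_empty = k - len(np.unique(labels))


def kmeans_fit(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator | int,
    *,
    max_iter: int = 300,
    tol: float = 1e-4,
    refit_on_empty: int = 3,
) -> KMeansFit:
    """Fit k-means with k-means++ init; refit (new init) if a cluster empties.

    Parameters
    ----------
    refit_on_empty:
        Number of additional seeded restarts attempted when the converged fit
        leaves a cluster empty; the last attempt is returned regardless.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.ascontiguousarray(X, dtype=np.float64)
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} out of range for n={X.shape[0]} points")
    for _ in range(refit_on_empty + 1):
        C0 = _plusplus_init(X, k, rng)
        C, labels, inertia = _lloyd(X, C0, max_iter, tol)
        fit = KMeansFit(C, labels, inertia, k)
        if fit.n_empty == 0:
            return fit
    return fit
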