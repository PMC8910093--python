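"""Gap-statistic K-means cluster discovery for CTC morphometric profiles.

Two dimensionality-reduction routes feed the same model-selection engine:

* approach A (``pca_kmeans``): PCA retaining the smallest number of
  components explaining more than a variance threshold (default 99%),
  followed by repeated gap-statistic K-means searches; the modal selected k
  across iterations is nominated, then the final model is the
  highest-gap-score fit among many candidate K-means fits at that k.
* approach B (``nominated_features``): one feature per biological category,
  chosen as the feature with the least total pairwise mutual information
  with the other members of its category (minimum redundancy), then the same
  gap-statistic nomination.

Gap statistic: for each k, ``Gap(k) = mean_b log W_k(ref_b) - log W_k(X)``
with B uniform reference datasets drawn over the per-dimension range box of
the (preprocessed) data, ``W_k`` the total within-cluster sum of squared
distances, and ``s_k = sd_b(log W_k(ref_b)) * sqrt(1 + 1/B)``. k is selected
by the one-standard-error rule — the smallest k with
``Gap(k) >= Gap(k+1) - s_{k+1}`` — falling back to the argmax of the gap
profile when the rule never triggers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._kmeans import kmeans_fit
from .containers import FeatureMatrix
from .phenotyping import StandardizationParams

logger = logging.getLogger(__name__)

__all__ = [
    "PCATransform",
    "GapResult",
    "NominationResult",
    "ClusterModel",
    "fit_pca",
    "compute_gap",
    "select_k",
    "nominate_k",
    "fit_final_model",
    "pairwise_mi",
    "nominate_features",
    "assign_clusters",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCATransform:
    """Retained principal-component loadings (rows orthonormal)."""

    components: np.ndarray
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


def fit_pca(X: np.ndarray | FeatureMatrix, variance_threshold: float = 0.99) -> PCATransform:
    """Smallest set of leading components whose cumulative explained
    variance exceeds ``variance_threshold``."""
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    if isinstance(X, FeatureMatrix):
        X = X.values()
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells for PCA")
    mean = X.mean(axis=0)
    _, svals, vt = np.linalg.svd(X - mean, full_matrices=False)
    var = svals**2
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    above = np.nonzero(cum > variance_threshold - 1e-12)[0]
    m = int(above[0]) + 1 if above.size else len(ratio)
    return PCATransform(
        components=vt[:m],
        mean=mean,
        explained_variance_ratio=ratio[:m],
        n_components=m,
    )


# ---------------------------------------------------------------------------
# Gap statistic
# ---------------------------------------------------------------------------


def _log_wk(X: np.ndarray, k: int, rng: np.random.Generator, n_init: int = 1) -> float:
    inertia = min(kmeans_fit(X, k, rng).inertia for _ in range(n_init))
    return float(np.log(max(inertia, 1e-300)))


def compute_gap(
    X: np.ndarray,
    k: int,
    B: int = 10,
    rng: np.random.Generator | int = 0,
    n_init: int = 5,
) -> tuple[float, float]:
    """Gap(k) and its reference spread s_k for one candidate k.

    The data dispersion W_k takes the best of ``n_init`` k-means++ restarts
    (a poor local optimum on structured data distorts the gap curve);
    reference draws are structureless and use a single restart each.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(X, float)
    n = X.shape[0]
    if not (2 <= k <= n - 1):
        raise ValueError(f"k={k} outside [2, n-1] for n={n}")
    log_w = _log_wk(X, k, rng, n_init)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logs = np.empty(B)
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_logs[b] = _log_wk(ref, k, rng)
    gap = float(ref_logs.mean() - log_w)
    s_k = float(ref_logs.std() * np.sqrt(1.0 + 1.0 / B))
    return gap, s_k


@dataclass
class GapResult:
    """Gap profile over the (possibly lazily truncated) k search."""

    ks: list[int]
    gaps: list[float]
    s_ks: list[float]
    selected_k: int
    rule_triggered: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "gap": self.gaps, "s_k": self.s_ks})


def select_k(
    X: np.ndarray,
    k_range: tuple[int, int] = (2, 50),
    B: int = 10,
    seed: int = 0,
    rule: str = "1se",
) -> GapResult:
    """One gap-statistic search over the k range.

    With the default one-standard-error rule, evaluation proceeds in
    ascending k and the rule is checked as soon as Gap(k+1) is available, so
    well-structured data stops early; the full profile is only computed when
    the rule never triggers (argmax fallback). ``rule="argmax"`` always
    computes the full profile and takes the gap maximizer.
    """
    if rule not in ("1se", "argmax"):
        raise ValueError(f"unknown selection rule {rule!r}")
    X = np.asarray(X, float)
    n = X.shape[0]
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi < k_lo:
        raise ValueError(f"invalid k_range {k_range}")
    if k_hi > n - 1:
        logger.warning("k_range upper bound %d truncated to n-1=%d", k_hi, n - 1)
        k_hi = n - 1
    rng = np.random.default_rng(seed)
    ks: list[int] = []
    gaps: list[float] = []
    s_ks: list[float] = []
    for k in range(k_lo, k_hi + 1):
        gap, s_k = compute_gap(X, k, B, rng)
        ks.append(k)
        gaps.append(gap)
        s_ks.append(s_k)
        if rule == "1se" and len(ks) >= 2 and gaps[-2] >= gaps[-1] - s_ks[-1]:
            return GapResult(ks, gaps, s_ks, selected_k=ks[-2], rule_triggered=True)
    best = int(np.argmax(gaps))
    return GapResult(ks, gaps, s_ks, selected_k=ks[best], rule_triggered=False)


@dataclass
class NominationResult:
    """Histogram of selected k across repeated gap searches."""

    histogram: dict[int, int]
    nominated_k: int
    iteration_seeds: list[int]

    @property
    def iterations(self) -> int:
        return sum(self.histogram.values())


def nominate_k(
    X: np.ndarray,
    iterations: int = 400,
    k_range: tuple[int, int] = (2, 50),
    B: int = 10,
    seed: int = 0,
) -> NominationResult:
    """Repeat ``select_k`` with per-iteration derived seeds and nominate the
    modal selection (ties broken toward smaller k, logged)."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    hist: dict[int, int] = {}
    seeds = [seed + i for i in range(iterations)]
    for s in seeds:
        k_sel = select_k(X, k_range, B, seed=s).selected_k
        hist[k_sel] = hist.get(k_sel, 0) + 1
    top = max(hist.values())
    tied = sorted(k for k, c in hist.items() if c == top)
    if len(tied) > 1:
        logger.info("nomination tie among k=%s; choosing smallest", tied)
    return NominationResult(histogram=dict(sorted(hist.items())), nominated_k=tied[0],
                            iteration_seeds=seeds)


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """A fitted clustering model with its frozen preprocessing.

    ``approach`` is ``"pca_kmeans"`` (standardize -> PCA -> k-means) or
    ``"nominated_features"`` (standardize -> nominated feature subset ->
    k-means). The stored standardization/PCA parameters are train-fitted and
    reused verbatim for test-set assignment.
    """

    approach: str
    k: int
    centroids: np.ndarray
    gap_score: float
    standardization: StandardizationParams | None = None
    pca: PCATransform | None = None
    features: list[str] | None = None
    seed: int | None = None

    def transform(self, matrix: FeatureMatrix) -> np.ndarray:
        from .phenotyping import apply_standardization

        m = matrix
        if self.standardization is not None:
            m = apply_standardization(self.standardization, m)
        if self.pca is not None:
            return self.pca.transform(m.values())
        if self.features is not None:
            missing = [f for f in self.features if f not in m.data.columns]
            if missing:
                raise KeyError(f"matrix lacks model features: {missing}")
            return m.data[self.features].to_numpy(float)
        return m.values()

    def to_json(self, path: str | Path) -> None:
        payload: dict = {
            "approach": self.approach,
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "gap_score": self.gap_score,
            "seed": self.seed,
            "features": self.features,
        }
        if self.standardization is not None:
            payload["standardization"] = {
                "mean": self.standardization.mean.to_dict(),
                "sd": self.standardization.sd.to_dict(),
                "dropped": self.standardization.dropped,
            }
        if self.pca is not None:
            payload["pca"] = {
                "components": self.pca.components.tolist(),
                "mean": self.pca.mean.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
            }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        std = None
        if "standardization" in payload:
            std = StandardizationParams(
                mean=pd.Series(payload["standardization"]["mean"]),
                sd=pd.Series(payload["standardization"]["sd"]),
                dropped=payload["standardization"]["dropped"],
            )
        pca = None
        if "pca" in payload:
            pca = PCATransform(
                components=np.array(payload["pca"]["components"]),
                mean=np.array(payload["pca"]["mean"]),
                explained_variance_ratio=np.array(
                    payload["pca"]["explained_variance_ratio"]
                ),
                n_components=len(payload["pca"]["components"]),
            )
        return cls(
            approach=payload["approach"],
            k=payload["k"],
            centroids=np.array(payload["centroids"]),
            gap_score=payload["gap_score"],
            standardization=std,
            pca=pca,
            features=payload.get("features"),
            seed=payload.get("seed"),
        )


def fit_final_model(
    X: np.ndarray,
    k: int,
    n_candidates: int = 100,
    seed: int = 0,
    B: int = 10,
    *,
    approach: str = "pca_kmeans",
    standardization: StandardizationParams | None = None,
    pca: PCATransform | None = None,
    features: list[str] | None = None,
) -> ClusterModel:
    """Best-of-``n_candidates`` K-means fit at the nominated k.

    All candidates share one panel of B reference datasets, so the candidate
    with the highest gap score is exactly the one with the lowest
    within-cluster sum of squares. Fits that converge with an empty cluster
    are discarded and refit with a fresh initialization.
    """
    X = np.asarray(X, float)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logs = np.empty(B)
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_logs[b] = _log_wk(ref, k, rng)
    ref_mean = ref_logs.mean()

    best_fit, best_gap = None, -np.inf
    for _ in range(n_candidates):
        fit = kmeans_fit(X, k, rng)
        if fit.n_empty:
            logger.warning("candidate fit left %d empty clusters after refits", fit.n_empty)
        gap = float(ref_mean - np.log(max(fit.inertia, 1e-300)))
        if gap > best_gap:
            best_fit, best_gap = fit, gap
    return ClusterModel(
        approach=approach,
        k=k,
        centroids=best_fit.centroids,
        gap_score=best_gap,
        standardization=standardization,
        pca=pca,
        features=features,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mutual-information feature nomination (approach B)
# ---------------------------------------------------------------------------


def pairwise_mi(
    x: np.ndarray, y: np.ndarray, n_bins: int = 10, estimator: str = "binned"
) -> float:
    """Mutual information (nats) between two numeric vectors.

    The default estimator is the plug-in on 10 equal-frequency bins;
    ``estimator="knn"`` switches to the Kraskov nearest-neighbor estimator
    (scikit-learn). A constant vector carries no information; MI is defined
    as 0 for it (logged).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 4 * n_bins:
        raise ValueError(f"need at least {4 * n_bins} samples for {n_bins} bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("constant vector in MI computation; returning 0")
        return 0.0
    if estimator == "knn":
        from sklearn.feature_selection import mutual_info_regression

        return float(
            mutual_info_regression(x[:, None], y, random_state=0)[0]
        )
    if estimator != "binned":
        raise ValueError(f"unknown MI estimator {estimator!r}")
    bx = (rankdata(x, method="ordinal") - 1) * n_bins // n
    by = (rankdata(y, method="ordinal") - 1) * n_bins // n
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx.astype(int), by.astype(int)), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float((joint[mask] * np.log(joint[mask] / (px @ py)[mask])).sum())
    return max(mi, 0.0)


def nominate_features(
    matrix: FeatureMatrix, n_bins: int = 10
) -> tuple[list[str], pd.DataFrame]:
    """One minimum-redundancy feature per category.

    The nominee of each category minimizes the sum of pairwise MI with all
    other features in the category (ties -> lexicographically first,
    logged); singleton categories contribute their only feature.
    """
    nominees: list[str] = []
    records: list[dict] = []
    for cat, members in matrix.category_members().items():
        if not members:
            raise ValueError(f"empty category {cat!r}")
        if len(members) == 1:
            nominees.append(members[0])
            records.append({"category": cat, "feature": members[0], "mi_sum": 0.0})
            continue
        cols = {m: matrix.data[m].to_numpy(float) for m in members}
        mi_sum = {m: 0.0 for m in members}
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                mi = pairwise_mi(cols[a], cols[b], n_bins)
                mi_sum[a] += mi
                mi_sum[b] += mi
        best = min(mi_sum.values())
        tied = sorted(m for m, v in mi_sum.items() if v == best)
        if len(tied) > 1:
            logger.info("MI tie in category %s among %s; choosing first", cat, tied)
        nominees.append(tied[0])
        records.extend(
            {"category": cat, "feature": m, "mi_sum": v} for m, v in mi_sum.items()
        )
    return nominees, pd.DataFrame(records)


def assign_clusters(model: ClusterModel, matrix: FeatureMatrix) -> pd.Series:
    """Nearest-centroid assignment in the model's preprocessed space."""
    Z = model.transform(matrix)
    d = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return pd.Series(d.argmin(axis=1), index=matrix.data.index, name="cluster")
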