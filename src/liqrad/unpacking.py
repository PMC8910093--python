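"""Interpreting condensed K-means clusters with classification trees.

K-means clusters formed in a reduced space are opaque; a per-cluster
one-vs-rest CART grown on the raw (unreduced) features "unpacks" them into
threshold rules. Trees use Gini impurity, are pruned along the minimal
cost-complexity path with the penalty chosen by the one-standard-error rule
on 10-fold cross-validated deviance (log-loss), and are gated on
cross-validated sensitivity AND specificity both strictly exceeding 80%
before their rules are treated as an interpretation of the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.tree import DecisionTreeClassifier

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["CARTReport", "unpack_cluster", "gate_unpacking"]


@dataclass
class CARTReport:
    """Cross-validated one-vs-rest tree report for one cluster."""

    cluster_id: int
    tree: DecisionTreeClassifier | None
    rules: list[str]
    confusion: dict[str, int]  # keys tp, fp, fn, tn (cluster = positive class)
    sensitivity: float
    specificity: float
    ccp_alpha: float
    seed: int
    unreliable: bool = False

    @property
    def n_cells(self) -> int:
        return sum(self.confusion.values())

    def to_dict(self) -> dict:
        return {
            "cluster_id": int(self.cluster_id),
            "rules": self.rules,
            "confusion": self.confusion,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ccp_alpha": self.ccp_alpha,
            "seed": self.seed,
            "unreliable": self.unreliable,
        }


def _tree_rules(tree: DecisionTreeClassifier, feature_names: list[str]) -> list[str]:
    t = tree.tree_
    rules: list[str] = []

    def walk(node: int, path: list[str]) -> None:
        if t.children_left[node] == -1:
            counts = t.value[node][0]
            label = "cluster" if counts[-1] >= counts[0] and len(counts) == 2 else "rest"
            cond = " AND ".join(path) if path else "(root)"
            rules.append(f"IF {cond} THEN {label} (n={int(t.n_node_samples[node])})")
            return
        name = feature_names[t.feature[node]]
        thr = t.threshold[node]
        walk(t.children_left[node], path + [f"{name} <= {thr:.4g}"])
        walk(t.children_right[node], path + [f"{name} > {thr:.4g}"])

    walk(0, [])
    return rules


def unpack_cluster(
    matrix: FeatureMatrix,
    labels: pd.Series,
    cluster_id: int,
    seed: int = 0,
    *,
    n_folds: int = 10,
    min_leaf: int = 5,
    max_alphas: int = 12,
) -> CARTReport:
    """Fit and cross-validate a one-vs-rest tree for one cluster.

    Clusters with fewer than ``n_folds`` members make stratified folds
    degenerate; the report is returned flagged ``unreliable`` with no tree.
    """
    if cluster_id not in set(labels.unique()):
        raise ValueError(f"cluster {cluster_id} not present in labels")
    y = (labels.loc[matrix.data.index] == cluster_id).to_numpy(int)
    X = matrix.values()
    n_pos = int(y.sum())
    if n_pos < n_folds:
        logger.warning("cluster %s has %d members (<%d folds): unreliable",
                       cluster_id, n_pos, n_folds)
        return CARTReport(
            cluster_id=cluster_id,
            tree=None,
            rules=[],
            confusion={"tp": 0, "fp": 0, "fn": n_pos, "tn": int((1 - y).sum())},
            sensitivity=0.0,
            specificity=1.0,
            ccp_alpha=0.0,
            seed=seed,
            unreliable=True,
        )

    base = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_leaf, random_state=seed
    )
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0, None))
    if len(alphas) > max_alphas:  # subsample the path; endpoints kept
        idx = np.unique(np.linspace(0, len(alphas) - 1, max_alphas).round().astype(int))
        alphas = alphas[idx]
    # always offer the null (root) model: full-data path alphas need not
    # collapse per-fold trees, and the 1-SE rule needs the root as candidate
    alphas = np.unique(np.append(alphas, 1.0))

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    mean_dev = np.empty(len(alphas))
    se_dev = np.empty(len(alphas))
    for i, a in enumerate(alphas):
        devs = []
        for tr, te in folds:
            clf = DecisionTreeClassifier(
                criterion="gini", min_samples_leaf=min_leaf, random_state=seed, ccp_alpha=a
            ).fit(X[tr], y[tr])
            prob = clf.predict_proba(X[te])
            devs.append(log_loss(y[te], prob[:, -1] if prob.shape[1] == 2 else prob[:, 0],
                                 labels=[0, 1]))
        mean_dev[i] = np.mean(devs)
        se_dev[i] = np.std(devs, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean_dev))
    # 1-SE rule: the largest alpha (simplest tree) within one SE of the best
    ok = mean_dev <= mean_dev[best] + se_dev[best]
    alpha = float(alphas[np.max(np.nonzero(ok)[0])])

    clf = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_leaf, random_state=seed, ccp_alpha=alpha
    )
    pred = cross_val_predict(clf, X, y, cv=cv)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    clf.fit(X, y)
    return CARTReport(
        cluster_id=cluster_id,
        tree=clf,
        rules=_tree_rules(clf, matrix.feature_names),
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        ccp_alpha=alpha,
        seed=seed,
    )


def gate_unpacking(report: CARTReport, threshold: float = 0.80) -> bool:
    """Pass iff CV sensitivity AND specificity strictly exceed the gate."""
    return report.sensitivity > threshold and report.specificity > threshold
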