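"""Patient-level statistical integration of cluster, count, cfDNA and
radiomic readouts.

Cluster assignments are reduced to per-patient percent-CTC-per-cluster
profiles, correlated with platform CTC counts and plasma cfDNA by Spearman
rank correlation. Radiomic texture values (5 ROIs per patient) are related
to patient-level molecular readouts with a random-intercept mixed-effects
model fit by REML on z-scored variables, so the fixed-effect slope
approximates a correlation coefficient; the 66-feature multiple-testing
family is controlled with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "cluster_percentages",
    "spearman_table",
    "platform_concordance",
    "zscore",
    "zscore_panel",
    "mixed_association",
    "bh_adjust",
    "heatmap_table",
]


def cluster_percentages(
    labels: pd.Series, patient_ids: pd.Series, prefix: str = "c"
) -> pd.DataFrame:
    """Percent of each patient's CTCs in each cluster (rows sum to 100)."""
    if not labels.index.equals(patient_ids.index):
        patient_ids = patient_ids.reindex(labels.index)
    if patient_ids.isna().any():
        raise ValueError("every labeled cell needs a patient id")
    k = int(labels.max()) + 1
    counts = (
        pd.crosstab(patient_ids, labels)
        .reindex(columns=range(k), fill_value=0)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns = [f"{prefix}{k}_{j}" for j in pct.columns]
    pct.index.name = "patient_id"
    return pct


def spearman_table(
    profiles: pd.DataFrame, cluster_cols: list[str], readout_cols: list[str]
) -> pd.DataFrame:
    """Spearman rho, rho^2 and p per (cluster-percent, readout) pair.

    Ties get average ranks (scipy default). Constant columns make the
    correlation undefined; those pairs are reported with missing values.
    """
    if len(profiles) < 4:
        raise ValueError("need >= 4 patients for rank correlation")
    rows = []
    for c in cluster_cols:
        for r in readout_cols:
            x, y = profiles[c], profiles[r]
            if x.nunique() <= 1 or y.nunique() <= 1:
                logger.warning("constant column in pair (%s, %s); reported missing", c, r)
                rho = p = np.nan
            else:
                rho, p = spearmanr(x, y)
            rows.append(
                {"cluster": c, "readout": r, "rho": rho, "rho2": rho**2 if np.isfinite(rho) else np.nan, "p": p}
            )
    return pd.DataFrame(rows)


def platform_concordance(profiles: pd.DataFrame, log1p: bool = False) -> float:
    """Squared Pearson correlation between the two platform CTC counts."""
    x = profiles["cellsearch_count"].to_numpy(float)
    y = profiles["rarecyte_count"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need >= 3 patients with both counts")
    if log1p:
        x, y = np.log1p(x), np.log1p(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant platform counts; concordance undefined")
        return float("nan")
    r, _ = pearsonr(x, y)
    return float(r * r)


def zscore(values: pd.Series | np.ndarray) -> np.ndarray:
    """Population (divide-by-n) z-score."""
    v = np.asarray(values, float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (v - v.mean()) / sd


def zscore_panel(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Z-score each listed column; constant columns are dropped (logged)."""
    out = table.copy()
    for col in columns or table.select_dtypes("number").columns:
        sd = out[col].std(ddof=0)
        if sd == 0:
            logger.warning("dropping constant variable %r", col)
            out = out.drop(columns=[col])
            continue
        out[col] = (out[col] - out[col].mean()) / sd
    return out


@dataclass
class AssociationResult:
    feature: str
    readout: str
    beta: float
    p: float
    q: float = np.nan
    significant: bool = False
    converged: bool = True
    fallback_ols: bool = False


def _fit_pair(y: np.ndarray, x: np.ndarray, groups: np.ndarray) -> tuple[float, float, bool, bool]:
    """Random-intercept mixed model of ROI-level y on patient-level x.

    The Wald statistic is referenced to a t distribution with
    ``n_patients - 2`` degrees of freedom: the readout is constant within a
    patient, so the slope carries patient-level information only, and the
    normal reference is anticonservative at cohort sizes in the twenties.
    """
    from scipy.stats import t as _tdist

    df = len(np.unique(groups)) - 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(y, np.column_stack([np.ones_like(x), x]), groups=groups)
            fit = model.fit(reml=True)
            if np.isfinite(fit.bse[1]) and fit.bse[1] > 0:
                tval = fit.params[1] / fit.bse[1]
                p = float(2 * _tdist.sf(abs(tval), df)) if df > 0 else float(fit.pvalues[1])
                return float(fit.params[1]), p, bool(fit.converged), False
        except Exception:  # singular fits on degenerate data
            pass
    # fallback: OLS on patient means, flagged
    df = pd.DataFrame({"y": y, "x": x, "g": groups}).groupby("g").mean()
    import statsmodels.api as sm

    ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
    return float(ols.params.iloc[1]), float(ols.pvalues.iloc[1]), False, True


def mixed_association(
    roi_features: pd.DataFrame,
    readouts: pd.DataFrame,
    feature_cols: list[str] | None = None,
    readout_cols: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per (radiomic feature, molecular readout) mixed-model association.

    ``roi_features`` is ROI-level (one row per lesion, ``patient_id``
    column); ``readouts`` is patient-level. Both sides are z-scored over
    their own rows before fitting, so the slope is on the correlation scale.
    BH-adjusted q-values are computed within each readout's feature family.
    """
    feature_cols = feature_cols or [
        c for c in roi_features.columns if c not in ("patient_id", "lesion_id")
    ]
    readout_cols = readout_cols or [
        c for c in readouts.columns if c != "patient_id"
    ]
    n_pat = readouts["patient_id"].nunique()
    if n_pat < 5:
        raise ValueError("need >= 5 patients")
    merged = roi_features.merge(readouts, on="patient_id", how="inner")
    groups = merged["patient_id"].to_numpy()

    results: list[AssociationResult] = []
    for r in readout_cols:
        if merged[r].std(ddof=0) == 0:
            logger.warning("constant readout %r skipped", r)
            continue
        x = zscore(merged[r])
        batch: list[AssociationResult] = []
        for f in feature_cols:
            if merged[f].std(ddof=0) == 0:
                logger.warning("constant feature %r skipped for readout %r", f, r)
                continue
            y = zscore(merged[f])
            beta, p, converged, fallback = _fit_pair(y, x, groups)
            batch.append(
                AssociationResult(
                    feature=f, readout=r, beta=beta, p=p,
                    converged=converged, fallback_ols=fallback,
                )
            )
        qs, sig = bh_adjust([b.p for b in batch], fdr)
        for b, q, s in zip(batch, qs, sig):
            b.q, b.significant = float(q), bool(s)
        results.extend(batch)
    return pd.DataFrame([vars(b) for b in results])


def bh_adjust(pvalues, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    sig, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, sig


def heatmap_table(results: pd.DataFrame) -> pd.DataFrame:
    """Feature x readout matrix of slopes; non-fitted pairs stay missing.

    A companion ``*_sig`` column block marks BH significance.
    """
    beta = results.pivot(index="feature", columns="readout", values="beta")
    sig = results.pivot(index="feature", columns="readout", values="significant")
    sig.columns = [f"{c}_sig" for c in sig.columns]
    return pd.concat([beta, sig], axis=1)


def plot_heatmap(results: pd.DataFrame, path) -> None:
    """Optional matplotlib rendering of the association heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    beta = results.pivot(index="feature", columns="readout", values="beta")
    fig, ax = plt.subplots(figsize=(0.5 * beta.shape[1] + 3, 0.15 * beta.shape[0] + 2))
    im = ax.imshow(beta.to_numpy(float), cmap="PiYG", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(beta.shape[1]), beta.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(beta.shape[0]), beta.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="standardized slope")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
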