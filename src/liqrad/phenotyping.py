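"""Marker-positivity phenotyping and feature-matrix preparation.

Covers the steps between instrument export and clustering: classifying each
CTC as positive/negative for Arv7 and synaptophysin from mean fluorescence
intensities (MFI) against fixed cutoffs, summarizing marker co-occurrence,
paring the raw feature panel down via a droplist, and train-fitted
z-standardization so that an independent test cohort can be transformed with
training parameters only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerThresholds",
    "CooccurrenceSummary",
    "StandardizationParams",
    "classify_marker_positivity",
    "summarize_cooccurrence",
    "pare_features",
    "default_droplist",
    "standardize_features",
    "apply_standardization",
]


@dataclass(frozen=True)
class MarkerThresholds:
    """MFI positivity cutoffs. A cell is positive when MFI >= cutoff
    (inclusive boundary; set ``inclusive=False`` for strict exceedance)."""

    arv7_cutoff: float = 250.0
    syp_cutoff: float = 70.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.arv7_cutoff <= 0 or self.syp_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")


def classify_marker_positivity(
    cells: pd.DataFrame, thresholds: MarkerThresholds = MarkerThresholds()
) -> pd.DataFrame:
    """Per-cell positive/negative status for Arv7 and SYP.

    ``cells`` must carry ``mfi_arv7`` and ``mfi_syp`` columns. Negative MFIs
    are rejected (intensities are nonnegative by construction).
    """
    for col in ("mfi_arv7", "mfi_syp"):
        if col not in cells.columns:
            raise KeyError(f"missing MFI column {col!r}")
        if (cells[col] < 0).any():
            raise ValueError(f"negative MFI in column {col!r}")
    op = np.greater_equal if thresholds.inclusive else np.greater
    return pd.DataFrame(
        {
            "arv7_positive": op(cells["mfi_arv7"], thresholds.arv7_cutoff),
            "syp_positive": op(cells["mfi_syp"], thresholds.syp_cutoff),
        },
        index=cells.index,
    )


@dataclass
class CooccurrenceSummary:
    arv7_only: int
    syp_only: int
    double_positive: int
    double_negative: int
    per_patient: pd.DataFrame = field(repr=False, default=None)

    @property
    def total(self) -> int:
        return self.arv7_only + self.syp_only + self.double_positive + self.double_negative


def summarize_cooccurrence(
    positivity: pd.DataFrame, patient_ids: pd.Series | None = None
) -> CooccurrenceSummary:
    """Four-way marker co-occurrence counts (they sum to the number of cells)
    plus per-patient any-positive flags when patient ids are supplied."""
    a = positivity["arv7_positive"].to_numpy(bool)
    s = positivity["syp_positive"].to_numpy(bool)
    per_patient = None
    if patient_ids is not None:
        per_patient = (
            pd.DataFrame({"arv7": a, "syp": s, "patient_id": patient_ids.to_numpy()})
            .groupby("patient_id")[["arv7", "syp"]]
            .any()
            .rename(columns={"arv7": "any_arv7_positive", "syp": "any_syp_positive"})
        )
    return CooccurrenceSummary(
        arv7_only=int((a & ~s).sum()),
        syp_only=int((~a & s).sum()),
        double_positive=int((a & s).sum()),
        double_negative=int((~a & ~s).sum()),
        per_patient=per_patient,
    )


def pare_features(matrix: FeatureMatrix, droplist: list[str]) -> FeatureMatrix:
    """Drop the named features, preserving the order of survivors.

    Unknown names raise (listing them); dropping everything is forbidden.
    """
    unknown = [n for n in droplist if n not in matrix.data.columns]
    if unknown:
        raise KeyError(f"droplist names not in matrix: {unknown}")
    keep = [n for n in matrix.data.columns if n not in set(droplist)]
    if not keep:
        raise ValueError("droplist removes every feature")
    return matrix.select_features(keep)


def default_droplist(matrix: FeatureMatrix, fraction: float = 135 / 435) -> list[str]:
    """A deterministic synthetic droplist: the trailing ``fraction`` of
    features within each category (the real artifact-susceptibility list is
    instrument-specific and supplied by the user as a manifest)."""
    drops: list[str] = []
    for _, members in matrix.category_members().items():
        n_drop = int(round(len(members) * fraction))
        drops.extend(members[len(members) - n_drop :])
    return [d for d in drops if not d.startswith("mfi_")]


@dataclass
class StandardizationParams:
    mean: pd.Series
    sd: pd.Series
    dropped: list[str]


def standardize_features(
    matrix: FeatureMatrix,
) -> tuple[FeatureMatrix, StandardizationParams]:
    """Z-score each feature with population (divide-by-n) statistics.

    Constant features cannot be scaled; they are dropped with a warning
    rather than raising.
    """
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells to standardize")
    mean = matrix.data.mean()
    sd = matrix.data.std(ddof=0)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        logger.warning("dropping %d constant features: %s", len(dropped), dropped[:5])
    keep = [c for c in matrix.data.columns if c not in set(dropped)]
    params = StandardizationParams(mean=mean[keep], sd=sd[keep], dropped=dropped)
    return apply_standardization(params, matrix), params


def apply_standardization(params: StandardizationParams, matrix: FeatureMatrix) -> FeatureMatrix:
    """Transform any matrix with train-fitted parameters only."""
    missing = [c for c in params.mean.index if c not in matrix.data.columns]
    if missing:
        raise KeyError(f"matrix lacks required features: {missing}")
    cols = list(params.mean.index)
    data = (matrix.data[cols] - params.mean) / params.sd
    return FeatureMatrix(
        data=data,
        categories={c: matrix.categories[c] for c in cols},
        patient_ids=matrix.patient_ids.copy(),
        split=matrix.split,
    )
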