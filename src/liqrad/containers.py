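"""Shared in-memory containers for cell-level feature data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """Cells x named morphometric features, with category annotations.

    Attributes
    ----------
    data:
        Numeric table, one row per cell (index = cell id), one column per
        named feature.
    categories:
        Mapping from feature name to its biological category label (nuclear
        morphology, cytokeratin texture, ...). Every feature must belong to
        exactly one category.
    patient_ids:
        Per-cell patient identifier, aligned with ``data.index``.
    split:
        Free-form tag, conventionally ``"train"`` or ``"test"``.
    """

    data: pd.DataFrame
    categories: dict[str, str]
    patient_ids: pd.Series
    split: str = "train"

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        missing = [c for c in self.data.columns if c not in self.categories]
        if missing:
            raise ValueError(f"features without category annotation: {missing[:5]}")
        if not self.data.index.equals(self.patient_ids.index):
            self.patient_ids = self.patient_ids.reindex(self.data.index)
        if self.patient_ids.isna().any():
            raise ValueError("patient id missing for some cells")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_features(self, names: list[str], split: str | None = None) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureMatrix(
            data=self.data[names].copy(),
            categories={n: self.categories[n] for n in names},
            patient_ids=self.patient_ids.copy(),
            split=split or self.split,
        )

    def category_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for feat in self.data.columns:
            out.setdefault(self.categories[feat], []).append(feat)
        return out
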