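"""2D radiomic texture panel for masked lesion ROIs.

Implements the 66-metric texture panel used for bone-metastasis
characterization: 20 first-order intensity metrics computed over the masked
pixels, and 46 grey-level co-occurrence matrix (GLCM) metrics — 23 base
Haralick-style statistics summarized across 4 pixel directions at distance 1
by their directional mean and standard deviation, with one directional-SD
slot replaced by the median absolute deviation of the co-occurrence
distribution so that every metric reported in the study panel has a named
entry.

Intensities are quantized to a fixed number of grey levels (default 16) over
the masked min–max before GLCM tabulation, so the GLCM block is invariant to
affine intensity rescaling. Both pixels of a co-occurring pair must lie
inside the mask. All entropies use log base 2 with 0*log(0) = 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "ROI",
    "intensity_features",
    "quantize",
    "glcm_matrix",
    "glcm_features",
    "extract_panel",
    "panel_manifest",
    "INTENSITY_METRICS",
    "GLCM_BASE_METRICS",
    "DIRECTIONS",
]

#: Pixel offsets (dy, dx) for the 0, 45, 90 and 135 degree directions at
#: distance 1. The GLCM is symmetrized, so each offset also counts its
#: negation.
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (1, 0), (1, 1))

INTENSITY_METRICS: tuple[str, ...] = (
    "mean",
    "variance",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "range",
    "interquartile_range",
    "percentile_10",
    "percentile_90",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "median_absolute_deviation",
    "energy",
    "root_mean_square",
    "entropy",
    "uniformity",
    "coefficient_of_variation",
)

GLCM_BASE_METRICS: tuple[str, ...] = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
    "standard_deviation",
)


@dataclass
class ROI:
    """A 2D grayscale lesion image with its binary mask."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    lesion_id: str

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if self.image.ndim != 2:
            raise ValueError("ROI must be 2D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    def masked_values(self) -> np.ndarray:
        return self.image[self.mask]

    def save(self, directory: str | Path) -> tuple[Path, Path]:
        """Write the ROI as a 16-bit grayscale PNG plus an 8-bit mask PNG.

        Intensities must lie in [0, 1]; they are scaled to the uint16 range.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("PNG export expects intensities in [0, 1]")
        stem = f"{self.patient_id}_{self.lesion_id}"
        img_path = directory / f"{stem}_image.png"
        mask_path = directory / f"{stem}_mask.png"
        Image.fromarray((self.image * 65535).round().astype(np.uint16)).save(img_path)
        Image.fromarray((self.mask * 255).astype(np.uint8)).save(mask_path)
        return img_path, mask_path

    @classmethod
    def load(cls, img_path: str | Path, mask_path: str | Path) -> "ROI":
        img_path = Path(img_path)
        image = np.asarray(Image.open(img_path), dtype=float) / 65535.0
        mask = np.asarray(Image.open(mask_path)) > 0
        stem = img_path.stem.replace("_image", "")
        patient_id, _, lesion_id = stem.rpartition("_")
        return cls(image=image, mask=mask, patient_id=patient_id, lesion_id=lesion_id)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def intensity_features(roi: ROI, n_bins: int = 16) -> dict[str, float]:
    """First-order statistics of the masked intensities.

    Histogram entropy and uniformity use ``n_bins`` equal-width bins over the
    masked min–max. For a constant ROI, skewness, kurtosis and the
    coefficient of variation are defined as 0 (logged convention); entropy is
    0 and uniformity 1.
    """
    x = roi.masked_values()
    if x.size < 2:
        raise ValueError("need at least 2 masked pixels")
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    p10, q1, med, q3, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))
    if sd == 0:
        logger.debug("constant ROI %s/%s: skew/kurtosis/CV set to 0",
                     roi.patient_id, roi.lesion_id)
        skew = kurt = cv = 0.0
    else:
        z = (x - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())  # Pearson (non-excess) kurtosis
        cv = sd / mean if mean != 0 else 0.0
    sub = x[(x >= p10) & (x <= p90)]
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    else:
        hist = np.array([x.size])
    p = hist / hist.sum()
    return {
        "mean": mean,
        "variance": var,
        "standard_deviation": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "median": med,
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "interquartile_range": q3 - q1,
        "percentile_10": p10,
        "percentile_90": p90,
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": float(np.abs(sub - sub.mean()).mean())
        if sub.size
        else 0.0,
        "median_absolute_deviation": float(np.median(np.abs(x - med))),
        "energy": float((x**2).sum()),
        "root_mean_square": float(np.sqrt((x**2).mean())),
        "entropy": _entropy_bits(p),
        "uniformity": float((p**2).sum()),
        "coefficient_of_variation": cv,
    }


def quantize(roi: ROI, n_levels: int = 16) -> np.ndarray:
    """Quantize masked intensities to ``n_levels`` integer grey levels.

    Fixed-bin-count quantization over the masked min–max; pixels outside the
    mask never influence the bin edges. A constant ROI maps to level 0.
    Returns an integer array of the ROI's shape (outside-mask values are 0
    and must be ignored via the mask).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    x = roi.masked_values()
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(roi.image.shape, dtype=np.int64)
    if hi > lo:
        scaled = (roi.image - lo) / (hi - lo) * n_levels
        levels = np.clip(np.floor(scaled), 0, n_levels - 1).astype(np.int64)
        levels[~roi.mask] = 0
    return levels


def glcm_matrix(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int], n_levels: int | None = None
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix for one pixel offset.

    Counts pairs (p, p+offset) with both pixels inside the mask, accumulates
    the offset and its negation (symmetric tabulation), and normalizes the
    matrix to sum to 1.
    """
    dy, dx = offset
    if n_levels is None:
        n_levels = int(levels[mask].max()) + 1
    h, w = levels.shape
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    src_mask = mask[ys, xs]
    dst_mask = mask[max(0, dy) : min(h, h + dy), max(0, dx) : min(w, w + dx)]
    valid = src_mask & dst_mask
    a = levels[ys, xs][valid]
    b = levels[max(0, dy) : min(h, h + dy), max(0, dx) : min(w, w + dx)][valid]
    if a.size == 0:
        raise ValueError(f"no valid in-mask pixel pairs for offset {offset}")
    P = np.zeros((n_levels, n_levels))
    np.add.at(P, (a, b), 1.0)
    np.add.at(P, (b, a), 1.0)
    return P / P.sum()


def _glcm_base(P: np.ndarray) -> dict[str, float]:
    L = P.shape[0]
    i = np.arange(L)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    sd = float(np.sqrt(var))

    diff = np.abs(ii - jj)
    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=L)
    k_d = np.arange(L)
    da = float((k_d * p_diff).sum())

    s = ii + jj
    p_sum = np.bincount(s.ravel(), weights=P.ravel(), minlength=2 * L - 1)
    k_s = np.arange(2 * L - 1)
    sa = float((k_s * p_sum).sum())

    autoc = float((ii * jj * P).sum())
    corr = (autoc - mu * mu) / var if var > 0 else 1.0
    return {
        "autocorrelation": autoc,
        "joint_average": mu,
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * P).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * P).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * P).sum()),
        "contrast": float(((ii - jj) ** 2 * P).sum()),
        "correlation": float(corr),
        "difference_average": da,
        "difference_entropy": _entropy_bits(p_diff),
        "difference_variance": float(((k_d - da) ** 2 * p_diff).sum()),
        "dissimilarity": float((diff * P).sum()),
        "energy": float((P**2).sum()),
        "entropy": _entropy_bits(P.ravel()),
        "homogeneity": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference": float((P / (1.0 + diff)).sum()),
        "inverse_difference_normalized": float((P / (1.0 + diff / L)).sum()),
        "inverse_difference_moment_normalized": float(
            (P / (1.0 + ((ii - jj) / L) ** 2)).sum()
        ),
        "maximum_probability": float(P.max()),
        "sum_average": sa,
        "sum_entropy": _entropy_bits(p_sum),
        "sum_variance": float(((k_s - sa) ** 2 * p_sum).sum()),
        "variance": var,
        "standard_deviation": sd,
    }


def _weighted_mad(p: np.ndarray) -> float:
    """Median absolute deviation of the grey-level marginal distribution."""
    values = np.arange(p.size, dtype=float)

    def wmedian(v: np.ndarray, w: np.ndarray) -> float:
        order = np.argsort(v)
        cw = np.cumsum(w[order])
        return float(v[order][np.searchsorted(cw, 0.5 * cw[-1])])

    m = wmedian(values, p)
    return wmedian(np.abs(values - m), p)


def glcm_features(
    roi: ROI,
    n_levels: int = 16,
    directions: tuple[tuple[int, int], ...] = DIRECTIONS,
) -> dict[str, float]:
    """The 46-value GLCM block.

    Each base metric is summarized across the directional matrices by its
    mean and (population) standard deviation. The ``joint_average`` SD slot
    is replaced by ``glcm_median_absolute_deviation``, the MAD of the
    co-occurrence grey-level distribution averaged over directions.
    """
    levels = quantize(roi, n_levels)
    per_dir: list[dict[str, float]] = []
    mads: list[float] = []
    for off in directions:
        try:
            P = glcm_matrix(levels, roi.mask, off, n_levels)
        except ValueError:
            continue
        per_dir.append(_glcm_base(P))
        mads.append(_weighted_mad(P.sum(axis=1)))
    if len(per_dir) < 2:
        raise ValueError("fewer than 2 directions produced valid pixel pairs")
    out: dict[str, float] = {}
    for m in GLCM_BASE_METRICS:
        vals = np.array([d[m] for d in per_dir])
        out[f"{m}_mean"] = float(vals.mean())
        if m != "joint_average":
            out[f"{m}_sd"] = float(vals.std())
    out["median_absolute_deviation"] = float(np.mean(mads))
    return out


def panel_manifest() -> dict[str, list[str]]:
    """Names of the 66 panel features, grouped by family."""
    glcm = []
    for m in GLCM_BASE_METRICS:
        glcm.append(f"glcm_{m}_mean")
        if m != "joint_average":
            glcm.append(f"glcm_{m}_sd")
    glcm.append("glcm_median_absolute_deviation")
    return {
        "intensity": [f"intensity_{m}" for m in INTENSITY_METRICS],
        "glcm": glcm,
    }


def extract_panel(roi: ROI, n_levels: int = 16) -> dict[str, float]:
    """Extract all 66 named texture values for one ROI."""
    out = {f"intensity_{k}": v for k, v in intensity_features(roi).items()}
    out.update({f"glcm_{k}": v for k, v in glcm_features(roi, n_levels).items()})
    manifest = panel_manifest()
    expected = manifest["intensity"] + manifest["glcm"]
    assert list(out) == expected and len(out) == 66
    return out


def extract_cohort_panel(rois: list[ROI], n_levels: int = 16):
    """One row per ROI, keyed by patient and lesion id."""
    import pandas as pd

    rows = []
    for roi in rois:
        row = {"patient_id": roi.patient_id, "lesion_id": roi.lesion_id}
        row.update(extract_panel(roi, n_levels))
        rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(path: str | Path) -> None:
    Path(path).write_text(json.dumps(panel_manifest(), indent=2))
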