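"""Synthetic cohort generator for the multi-parametric liquid-biopsy pipeline.

Emulates a small metastatic prostate-cancer cohort profiled three ways at
once: CTC enumeration on two platforms plus per-cell morphometric features,
targeted amplicon sequencing of single CTCs / WBCs / buffy coat / plasma
cfDNA, and 2D texture images of segmented bone lesions. A single per-patient
latent "disease heterogeneity" factor couples CTC burden, cfDNA level,
cluster prevalence and lesion texture, so downstream association stages have
a planted signal whose strength is controlled by one knob.

All randomness flows from ``numpy.random.Generator`` streams derived from the
integer seeds carried on the config/spec objects, so identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .radiomics import ROI

__all__ = [
    "CohortConfig",
    "ClusterSpec",
    "VariantSpec",
    "TextureSpec",
    "CATEGORY_NAMES",
    "generate_cohort",
    "generate_ctc_features",
    "generate_amplicon_data",
    "generate_roi_images",
]

#: Eleven biologically flavored feature categories (nuclear, cytokeratin and
#: cell-level shape/texture families typically exported per detected CTC).
CATEGORY_NAMES: tuple[str, ...] = (
    "nuclear_morphology",
    "nuclear_texture",
    "nuclear_intensity",
    "cytokeratin_morphology",
    "cytokeratin_texture",
    "cytokeratin_intensity",
    "cell_shape",
    "cell_size",
    "membrane_texture",
    "marker_signal",
    "background_context",
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class CohortConfig:
    """Patient-level generative model.

    CTC burden is zero-inflated negative binomial: a fraction of patients has
    no detectable CTCs at all, and counts among the rest are heavily
    overdispersed (clinically, medians of a few cells against ranges of
    hundreds). cfDNA concentration is log-normal. ``latent_coupling`` in
    [0, 1] is the correlation-scale weight tying the N(0,1) latent factor to
    both readouts; 0 decouples everything (the null used for type-I error
    audits).
    """

    n_patients: int = 22
    zero_inflation: float = 0.23
    ctc_mean: float = 55.0
    ctc_dispersion: float = 0.22
    cfdna_log_mean: float = math.log(8.0)
    cfdna_log_sd: float = 1.2
    latent_coupling: float = 0.7
    platform_capture: tuple[float, float] = (0.85, 0.95)
    capture_concentration: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        _check_prob("zero_inflation", self.zero_inflation)
        _check_prob("latent_coupling", self.latent_coupling)
        for p in self.platform_capture:
            _check_prob("platform_capture", p)
        if self.ctc_mean <= 0 or self.ctc_dispersion <= 0:
            raise ValueError("ctc_mean and ctc_dispersion must be > 0")
        if self.cfdna_log_sd <= 0:
            raise ValueError("cfdna_log_sd must be > 0")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw the patient table.

    Both platform counts are independent binomial thinnings of one true CTC
    count, which makes cross-platform concordance high by construction;
    per-patient capture probabilities are Beta-jittered around the platform
    means (``capture_concentration`` controls the spread) so the concordance
    is high rather than perfect. The
    latent factor enters the NB mean multiplicatively (mean-preserving:
    ``mu_i = ctc_mean * exp(c*h - c^2/2)``) and the log-cfDNA level as a
    variance-preserving mixture ``c*h + sqrt(1-c^2)*z``.
    """
    rng = np.random.default_rng([config.seed, 0])
    c = config.latent_coupling
    h = rng.normal(size=config.n_patients)

    mu = config.ctc_mean * np.exp(c * h - 0.5 * c * c)
    r = config.ctc_dispersion
    true_counts = rng.negative_binomial(r, r / (r + mu))
    zero_mask = rng.random(config.n_patients) < config.zero_inflation
    true_counts = np.where(zero_mask, 0, true_counts)

    kappa = config.capture_concentration
    p_cs, p_rc = (
        rng.beta(p * kappa, (1 - p) * kappa, size=config.n_patients)
        for p in config.platform_capture
    )
    cellsearch = rng.binomial(true_counts, p_cs)
    rarecyte = rng.binomial(true_counts, p_rc)

    z = rng.normal(size=config.n_patients)
    log_cf = config.cfdna_log_mean + config.cfdna_log_sd * (
        c * h + math.sqrt(max(0.0, 1.0 - c * c)) * z
    )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(config.n_patients)],
            "latent": h,
            "true_ctc_count": true_counts,
            "cellsearch_count": cellsearch,
            "rarecyte_count": rarecyte,
            "cfdna_ng_ml": np.exp(log_cf),
        }
    )


# ---------------------------------------------------------------------------
# CTC morphometric features
# ---------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    """Gaussian-mixture model for per-cell morphometric features.

    Cluster means are mutually equidistant (pairwise distance exactly
    ``separation * spread``): each cluster is elevated on its own disjoint
    block of ``n_informative`` features (phenotypes differing on distinct
    feature groups, the way instrument panels separate e.g. large-nucleus
    from high-CK-texture cells); set ``n_informative=None`` for dense random
    orthonormal directions instead. Within a category, features share a
    latent factor giving uniform correlation ``redundancy`` (or a
    per-category mapping), emulating the heavy within-category redundancy of
    instrument-exported feature panels. ``prevalence_coupling`` tilts each
    patient's cluster mixture along the patient latent factor.
    """

    k_true: int = 4
    n_features: int = 33
    n_informative: int | None = 10
    separation: float = 6.0
    spread: float = 1.0
    redundancy: float | dict[str, float] = 0.5
    prevalence_coupling: float = 1.0
    categories: tuple[str, ...] = CATEGORY_NAMES
    p_arv7: float = 0.08
    p_syp: float = 0.08
    p_double: float = 0.003
    seed: int = 1

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n_features < self.k_true:
            raise ValueError("need n_features >= k_true for equidistant means")
        if len(self.categories) < 1:
            raise ValueError("at least one category required")
        reds = (
            self.redundancy.values()
            if isinstance(self.redundancy, dict)
            else [self.redundancy]
        )
        for v in reds:
            _check_prob("redundancy", v)

    def redundancy_for(self, category: str) -> float:
        if isinstance(self.redundancy, dict):
            return self.redundancy.get(category, 0.0)
        return self.redundancy


def _feature_names(spec: ClusterSpec) -> tuple[list[str], dict[str, str]]:
    names: list[str] = []
    cats: dict[str, str] = {}
    n_cat = len(spec.categories)
    base, extra = divmod(spec.n_features, n_cat)
    for i, cat in enumerate(spec.categories):
        n_i = base + (1 if i < extra else 0)
        for j in range(n_i):
            name = f"{cat}_{j:02d}"
            names.append(name)
            cats[name] = cat
    return names, cats


def _equidistant_means(
    k: int, d: int, distance: float, rng: np.random.Generator, n_informative: int | None
) -> np.ndarray:
    # Scaled orthonormal directions: |a e_i - a e_j| = a*sqrt(2) for i != j.
    if n_informative is None:
        q, _ = np.linalg.qr(rng.normal(size=(d, k)))
        return (distance / math.sqrt(2.0)) * q.T
    b = min(n_informative, d // k)  # disjoint blocks must fit
    perm = rng.permutation(d)
    means = np.zeros((k, d))
    for j in range(k):
        means[j, perm[j * b : (j + 1) * b]] = distance / math.sqrt(2.0 * b)
    return means


def generate_ctc_features(
    cohort: pd.DataFrame, spec: ClusterSpec
) -> tuple[FeatureMatrix, pd.Series]:
    """Draw one row per detected CTC plus ground-truth cluster labels.

    Cell counts come from the RareCyte-like platform column. Marker MFIs
    (Arv7 / SYP / CK) are attached as ``mfi_*`` columns on the returned
    table's sidecar attributes frame — they are not part of the clustering
    feature set. Arv7 and SYP positivity are near-mutually exclusive.
    """
    counts = cohort["rarecyte_count"].to_numpy()
    if counts.sum() < 1:
        raise ValueError("cohort has no CTCs to generate features for")
    if spec.k_true > counts.sum():
        raise ValueError("k_true exceeds total number of cells")
    rng = np.random.default_rng([spec.seed, 1])

    names, cats = _feature_names(spec)
    d = spec.n_features
    means = _equidistant_means(
        spec.k_true, d, spec.separation * spec.spread, rng, spec.n_informative
    )
    v = np.linspace(-1.0, 1.0, spec.k_true)  # per-cluster prevalence loadings

    rows, labels, patients, cell_ids = [], [], [], []
    cat_of = np.array([spec.categories.index(cats[n]) for n in names])
    sqrt_r = np.array([math.sqrt(spec.redundancy_for(cats[n])) for n in names])
    sqrt_1mr = np.sqrt(1.0 - sqrt_r**2)
    for pid, h, n_cells in zip(cohort["patient_id"], cohort["latent"], counts):
        if n_cells == 0:
            continue
        logits = spec.prevalence_coupling * h * v
        w = np.exp(logits - logits.max())
        w /= w.sum()
        lab = rng.choice(spec.k_true, size=n_cells, p=w)
        g_cat = rng.normal(size=(n_cells, len(spec.categories)))
        eps = rng.normal(size=(n_cells, d))
        noise = sqrt_r[None, :] * g_cat[:, cat_of] + sqrt_1mr[None, :] * eps
        rows.append(means[lab] + spec.spread * noise)
        labels.append(lab)
        patients.extend([pid] * n_cells)
        cell_ids.extend([f"{pid}_c{i:04d}" for i in range(n_cells)])

    X = np.vstack(rows)
    index = pd.Index(cell_ids, name="cell_id")
    data = pd.DataFrame(X, columns=names, index=index)

    # Marker MFIs: categorical phenotype per cell, near-exclusive markers.
    n_total = X.shape[0]
    u = rng.random(n_total)
    pheno = np.full(n_total, "neg", dtype=object)
    pheno[u < spec.p_arv7] = "arv7"
    pheno[(u >= spec.p_arv7) & (u < spec.p_arv7 + spec.p_syp)] = "syp"
    pheno[
        (u >= spec.p_arv7 + spec.p_syp)
        & (u < spec.p_arv7 + spec.p_syp + spec.p_double)
    ] = "double"

    def _mfi(positive: np.ndarray, cutoff: float) -> np.ndarray:
        neg = np.exp(rng.normal(math.log(cutoff * 0.25), 0.5, n_total))
        pos = np.exp(rng.normal(math.log(cutoff * 2.5), 0.5, n_total))
        out = np.where(positive, np.maximum(pos, cutoff), np.minimum(neg, cutoff * 0.9))
        return out

    data["mfi_arv7"] = _mfi(np.isin(pheno, ("arv7", "double")), 250.0)
    data["mfi_syp"] = _mfi(np.isin(pheno, ("syp", "double")), 70.0)
    data["mfi_ck"] = np.exp(rng.normal(math.log(500.0), 0.8, n_total))
    for m in ("mfi_arv7", "mfi_syp", "mfi_ck"):
        cats[m] = "marker_signal"

    matrix = FeatureMatrix(
        data=data,
        categories=cats,
        patient_ids=pd.Series(patients, index=index, name="patient_id"),
        split="train",
    )
    truth = pd.Series(np.concatenate(labels), index=index, name="true_cluster")
    return matrix, truth


# ---------------------------------------------------------------------------
# Amplicon sequencing
# ---------------------------------------------------------------------------

_DEFAULT_GENES = (
    "AR",
    "TP53",
    "PIK3CA",
    "PTEN",
    "ALK",
    "ARAF",
    "FGFR1",
    "CDK6",
    "KRAS",
    "CCND3",
    "KIT",
    "SF3B1",
)


@dataclass
class VariantSpec:
    """Generative model for targeted amplicon depths and allele counts.

    Each patient is heterozygous at a random ``het_fraction`` subset of the
    panel's germline loci (MAF 0.5); WBC and
    buffy-coat samples report them free of allelic dropout, single CTCs apply
    ADO: with probability ``ado_rate`` one allele, chosen uniformly, yields no
    reads (the dropped-alt half of those events creates germline false
    negatives). Somatic variants are planted in a carrier subset of patients
    at analyte-specific allele fractions. Gene copy-number events scale
    amplicon depth linearly (relative to the diploid baseline) in
    tumor-derived analytes of carrier patients.
    """

    n_germline: int = 40
    het_fraction: float = 0.85
    genes: tuple[str, ...] = _DEFAULT_GENES
    amplicons_per_gene: int = 4
    cn_events: dict[str, float] = field(default_factory=lambda: {"AR": 8.0, "ARAF": 5.0})
    cn_carrier_fraction: float = 0.3
    mean_depth: dict[str, float] = field(
        default_factory=lambda: {"cfDNA": 2000.0, "CTC": 600.0, "WBC": 600.0, "buffy": 1500.0}
    )
    depth_dispersion: float = 20.0
    ado_rate: float = 0.1
    error_rate: float = 1e-3
    n_ctc_samples: int = 3
    n_wbc_samples: int = 2
    somatic_carrier_fraction: float = 0.5
    somatic_per_carrier: int = 2
    somatic_maf: dict[str, float] = field(
        default_factory=lambda: {"cfDNA": 0.02, "CTC": 0.5}
    )
    seed: int = 2

    def __post_init__(self) -> None:
        _check_prob("ado_rate", self.ado_rate)
        _check_prob("het_fraction", self.het_fraction)
        _check_prob("cn_carrier_fraction", self.cn_carrier_fraction)
        _check_prob("somatic_carrier_fraction", self.somatic_carrier_fraction)
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be in [0, 0.1]")
        for g, cn in self.cn_events.items():
            if cn <= 0:
                raise ValueError(f"copy number for {g} must be > 0")
        for maf in self.somatic_maf.values():
            _check_prob("somatic MAF", maf)
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")


def _amplicon_map(spec: VariantSpec) -> pd.DataFrame:
    rows = []
    for gene in spec.genes:
        for j in range(spec.amplicons_per_gene):
            rows.append({"locus": f"{gene}_amp{j}", "gene": gene})
    return pd.DataFrame(rows)


def generate_amplicon_data(
    cohort: pd.DataFrame, spec: VariantSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (long amplicon table, truth call set).

    The table has one row per sample x amplicon with columns
    ``sample_id, patient_id, analyte, gene, locus, ref_depth, alt_depth``.
    The truth set lists, per patient, every germline locus and every planted
    somatic locus with its designed per-analyte allele fraction.
    """
    rng = np.random.default_rng([spec.seed, 2])
    amplicons = _amplicon_map(spec)
    n_amp = len(amplicons)

    germline_loci = [
        amplicons["locus"].iloc[i % n_amp] + f"_g{i}" for i in range(spec.n_germline)
    ]
    germline_gene = [
        amplicons["gene"].iloc[i % n_amp] for i in range(spec.n_germline)
    ]

    patients = cohort["patient_id"].tolist()
    het_sets = {
        p: set(
            np.array(germline_loci)[
                rng.random(spec.n_germline) < spec.het_fraction
            ]
        )
        for p in patients
    }
    cn_carriers = {
        p: dict(spec.cn_events) if rng.random() < spec.cn_carrier_fraction else {}
        for p in patients
    }
    somatic_sites: dict[str, list[tuple[str, str]]] = {p: [] for p in patients}
    somatic_genes = [g for g in spec.genes]
    for p in patients:
        if rng.random() < spec.somatic_carrier_fraction:
            chosen = rng.choice(len(somatic_genes), size=min(spec.somatic_per_carrier, len(somatic_genes)), replace=False)
            for idx in chosen:
                gene = somatic_genes[idx]
                amp = f"{gene}_amp{rng.integers(spec.amplicons_per_gene)}"
                somatic_sites[p].append((f"{amp}_s{len(somatic_sites[p])}", gene))

    # Build the sample roster.
    samples: list[tuple[str, str, str]] = []  # (sample_id, patient_id, analyte)
    ctc_counts = dict(zip(cohort["patient_id"], cohort["rarecyte_count"]))
    for p in patients:
        samples.append((f"{p}_cfDNA", p, "cfDNA"))
        samples.append((f"{p}_buffy", p, "buffy"))
        for j in range(spec.n_wbc_samples):
            samples.append((f"{p}_WBC{j}", p, "WBC"))
        for j in range(min(spec.n_ctc_samples, int(ctc_counts[p]))):
            samples.append((f"{p}_CTC{j}", p, "CTC"))

    r = spec.depth_dispersion
    tumor_analytes = {"CTC", "cfDNA"}
    rows: list[dict] = []
    for sample_id, pid, analyte in samples:
        base_depth = spec.mean_depth[analyte]
        events = cn_carriers[pid] if analyte in tumor_analytes else {}
        loci = list(zip(germline_loci, germline_gene, ["germline"] * spec.n_germline))
        loci += [(l, g, "somatic") for (l, g) in somatic_sites[pid]]
        # plain amplicon rows (no variant) still carry depth for CN estimation
        loci += [
            (l, g, "none")
            for l, g in zip(amplicons["locus"], amplicons["gene"])
        ]
        for locus, gene, vclass in loci:
            cn = events.get(gene, 2.0)
            mean = base_depth * cn / 2.0
            depth = int(rng.negative_binomial(r, r / (r + mean)))
            if depth == 0:
                alt = 0
            else:
                if vclass == "germline":
                    if locus in het_sets[pid]:
                        p_alt = 0.5
                        if analyte == "CTC" and rng.random() < spec.ado_rate:
                            p_alt = spec.error_rate if rng.random() < 0.5 else 1.0 - spec.error_rate
                    else:
                        p_alt = 0.0
                elif vclass == "somatic":
                    p_alt = spec.somatic_maf.get(analyte, 0.0)
                    if analyte == "CTC" and p_alt > 0 and rng.random() < spec.ado_rate:
                        p_alt = spec.error_rate if rng.random() < 0.5 else 1.0 - spec.error_rate
                else:
                    p_alt = 0.0
                p_alt = max(p_alt, spec.error_rate) if spec.error_rate > 0 else p_alt
                alt = int(rng.binomial(depth, p_alt))
            rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": pid,
                    "analyte": analyte,
                    "gene": gene,
                    "locus": locus,
                    "ref_depth": depth - alt,
                    "alt_depth": alt,
                }
            )
    table = pd.DataFrame(rows)

    truth_rows = []
    for p in patients:
        for locus, gene in zip(germline_loci, germline_gene):
            if locus not in het_sets[p]:
                continue
            truth_rows.append(
                {"patient_id": p, "locus": locus, "gene": gene, "class": "germline", "maf": 0.5}
            )
        for locus, gene in somatic_sites[p]:
            truth_rows.append(
                {"patient_id": p, "locus": locus, "gene": gene, "class": "somatic",
                 "maf": spec.somatic_maf.get("CTC", 0.5)}
            )
        for gene, cn in cn_carriers[p].items():
            truth_rows.append(
                {"patient_id": p, "locus": f"{gene}_cn", "gene": gene, "class": "cn_event", "maf": float(cn)}
            )
    truth = pd.DataFrame(truth_rows)
    return table, truth


# ---------------------------------------------------------------------------
# Lesion ROI images
# ---------------------------------------------------------------------------


@dataclass
class TextureSpec:
    """Generative model for 2D bone-lesion ROIs.

    Each patient contributes ``n_lesions`` disk-masked images. Texture
    heterogeneity is carried by the within-mask Gaussian noise amplitude,
    ``noise_base * exp(noise_coupling * latent)`` (monotone in the patient
    latent factor); optional stripe and gradient components add structured
    texture and default to off.
    """

    image_size: int = 64
    n_lesions: int = 5
    base_intensity: float = 0.55
    noise_base: float = 0.05
    noise_coupling: float = 0.6
    stripe_amp: float = 0.0
    gradient_amp: float = 0.0
    seed: int = 3

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.noise_base < 0:
            raise ValueError("noise_base must be >= 0")


def generate_roi_images(cohort: pd.DataFrame, spec: TextureSpec) -> list[ROI]:
    """Return ``n_lesions`` masked lesion images per patient."""
    rng = np.random.default_rng([spec.seed, 3])
    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    rois: list[ROI] = []
    for pid, h in zip(cohort["patient_id"], cohort["latent"]):
        amp = spec.noise_base * math.exp(spec.noise_coupling * h)
        for lesion in range(spec.n_lesions):
            radius = rng.uniform(0.28, 0.40) * size
            cy, cx = rng.uniform(0.45, 0.55, size=2) * size
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            img = np.zeros((size, size))
            img[:] = spec.base_intensity
            if spec.gradient_amp > 0:
                theta = rng.uniform(0, 2 * math.pi)
                ramp = (np.cos(theta) * xx + np.sin(theta) * yy) / size
                img += spec.gradient_amp * (ramp - ramp.mean())
            if spec.stripe_amp > 0:
                period = rng.integers(4, 9)
                img += spec.stripe_amp * np.sin(2 * math.pi * xx / period)
            noise = rng.normal(size=(size, size))
            img += amp * rng.uniform(0.9, 1.1) * noise
            img = np.clip(img, 0.0, 1.0)
            img[~mask] = 0.0
            rois.append(ROI(image=img, mask=mask, patient_id=pid, lesion_id=f"L{lesion}"))
    return rois
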