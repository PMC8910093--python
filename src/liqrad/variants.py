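"""Variant calling with analyte-specific floors, germline concordance QC,
and depth-ratio copy-number estimation for targeted amplicon data.

Calling combines a fixed per-analyte allele-fraction floor (0.1% for plasma
cfDNA, 10% for single CTCs) with a per-locus limit of detection derived from
an exact binomial tail test against the background error rate. Germline
ground truth per patient is the intersection of its WBC and buffy-coat
calls; single cells with many germline false negatives (allelic dropout
casualties) are filtered out. Copy number is the per-gene mean depth,
normalized by the sample's total aligned reads, divided by the per-gene
median of that quantity across samples, times baseline ploidy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FLOORS",
    "ConcordanceSummary",
    "compute_lod",
    "call_variants",
    "build_germline_truth",
    "germline_concordance",
    "filter_cells",
    "estimate_copy_number",
    "cn_concordance",
    "write_vcf",
]

#: Analyte-specific MAF call floors; analytes not listed use the single-cell
#: floor (germline calling in WBC/buffy targets ~50% MAF heterozygotes).
DEFAULT_FLOORS: dict[str, float] = {"cfDNA": 0.001, "CTC": 0.10, "WBC": 0.10, "buffy": 0.10}


def compute_lod(depth: int, error_rate: float, alpha: float = 0.01) -> float:
    """Smallest callable allele fraction at this depth.

    The LOD is the smallest MAF ``m`` such that observing ``ceil(m*depth)``
    or more error reads is improbable (tail probability <= alpha) under
    Binomial(depth, error_rate). With zero error a single read suffices
    (LOD = 1/depth). Monotone nonincreasing in depth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 <= error_rate <= 0.1):
        raise ValueError("error_rate must be in [0, 0.1]")
    if error_rate == 0.0:
        return 1.0 / depth
    # smallest count c with P(X >= c) <= alpha, X ~ Bin(depth, error_rate)
    c = int(binom.isf(alpha, depth, error_rate)) + 1
    while c > 1 and binom.sf(c - 2, depth, error_rate) <= alpha:
        c -= 1
    while binom.sf(c - 1, depth, error_rate) > alpha:
        c += 1
    return c / depth


def call_variants(
    table: pd.DataFrame,
    floors: dict[str, float] | None = None,
    error_rate: float = 1e-3,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-row variant calls on a long amplicon table.

    A variant is called when its MAF strictly exceeds both the analyte floor
    and the locus LOD. Rows with zero total depth are skipped (logged).
    Calls at loci present in the patient's germline truth (WBC ∩ buffy
    calls) are classed germline, others somatic.
    """
    floors = {**DEFAULT_FLOORS, **(floors or {})}
    df = table.copy()
    depth = df["ref_depth"] + df["alt_depth"]
    zero = depth == 0
    if zero.any():
        logger.info("skipping %d zero-depth locus rows", int(zero.sum()))
        df = df[~zero].copy()
        depth = depth[~zero]
    df["depth"] = depth
    df["maf"] = df["alt_depth"] / depth
    lods = {d: compute_lod(int(d), error_rate, alpha) for d in depth.unique()}
    df["lod"] = depth.map(lods)
    df["floor"] = df["analyte"].map(floors)
    if df["floor"].isna().any():
        raise KeyError(f"no floor for analytes {sorted(df['analyte'][df['floor'].isna()].unique())}")
    df["called"] = df["maf"] > np.maximum(df["floor"], df["lod"])

    truth = build_germline_truth(df)
    df["class"] = [
        "germline" if locus in truth.get(pid, set()) else "somatic"
        for pid, locus in zip(df["patient_id"], df["locus"])
    ]
    return df


def build_germline_truth(calls: pd.DataFrame) -> dict[str, set[str]]:
    """Per-patient germline truth: loci called in both WBC (any cell) and
    buffy coat for that patient."""
    truth: dict[str, set[str]] = {}
    called = calls[calls.get("called", pd.Series(True, index=calls.index)).astype(bool)]
    if "called" not in calls.columns:
        # operating on a raw table: treat MAF > 0.1 as a provisional call
        maf = calls["alt_depth"] / (calls["ref_depth"] + calls["alt_depth"]).clip(lower=1)
        called = calls[maf > 0.1]
    for pid, grp in called.groupby("patient_id"):
        wbc = set(grp.loc[grp["analyte"] == "WBC", "locus"])
        buffy = set(grp.loc[grp["analyte"] == "buffy", "locus"])
        truth[pid] = wbc & buffy
    return truth


@dataclass
class ConcordanceSummary:
    sample_id: str
    analyte: str
    tp: int
    fp: int
    fn: int
    excluded: bool = False

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")


def germline_concordance(
    calls: pd.DataFrame,
    truth: dict[str, set[str]] | None = None,
    candidate_loci: set[str] | None = None,
) -> list[ConcordanceSummary]:
    """Germline sensitivity / PPV per sample against per-patient truth.

    TP: truth loci called in the sample; FN: truth loci covered but not
    called; FP: germline-type calls the patient should not have — calls at
    loci in the cohort-wide germline candidate panel (by default, the union
    of all patients' truth sets) that are absent from this patient's own
    truth. Somatic calls never count against germline PPV.
    """
    if truth is None:
        truth = build_germline_truth(calls)
    if not any(truth.values()):
        raise ValueError("empty germline truth set")
    if candidate_loci is None:
        candidate_loci = set().union(*truth.values())
    out = []
    for (sid, pid, analyte), grp in calls.groupby(
        ["sample_id", "patient_id", "analyte"], sort=True
    ):
        t = truth.get(pid, set())
        covered = grp[grp["locus"].isin(t)]
        called = set(covered.loc[covered["called"], "locus"])
        tp = len(called)
        fn = covered["locus"].nunique() - tp
        fp = int(
            (grp["called"] & grp["locus"].isin(candidate_loci - t)).sum()
        )
        out.append(ConcordanceSummary(sample_id=sid, analyte=analyte, tp=tp, fp=fp, fn=fn))
    return out


def filter_cells(
    summaries: list[ConcordanceSummary], max_fn: int = 4
) -> tuple[list[ConcordanceSummary], list[ConcordanceSummary]]:
    """Partition samples into (retained, excluded): excluded iff FN > max_fn."""
    retained, excluded = [], []
    for s in summaries:
        s.excluded = s.fn > max_fn
        (excluded if s.excluded else retained).append(s)
    return retained, excluded


def estimate_copy_number(
    table: pd.DataFrame, ploidy_map: dict[str, float] | None = None, default_ploidy: float = 2.0
) -> pd.DataFrame:
    """Depth-ratio copy number per (sample, gene).

    For sample s and gene g: ``d(s,g)`` = mean amplicon depth of g in s
    divided by s's total aligned reads; the ratio is ``d(s,g)`` over the
    median of ``d(.,g)`` across samples; copies = ratio x baseline ploidy
    (default 2 for every gene; supply ``ploidy_map`` for e.g. chrX genes in
    males). Normalizing by total aligned reads makes the estimate invariant
    to rescaling all of a sample's depths.
    """
    ploidy_map = ploidy_map or {}
    df = table.copy()
    df["depth"] = df["ref_depth"] + df["alt_depth"]
    if df["sample_id"].nunique() < 3:
        raise ValueError("need >= 3 samples for a meaningful median baseline")
    totals = df.groupby("sample_id")["depth"].sum()
    if (totals <= 0).any():
        raise ValueError("sample with zero total aligned reads")
    gene_depth = (
        df.groupby(["sample_id", "patient_id", "analyte", "gene"])["depth"].mean().reset_index()
    )
    gene_depth["d"] = gene_depth["depth"] / gene_depth["sample_id"].map(totals)
    dead = gene_depth.groupby("gene")["d"].transform("max") == 0
    if dead.any():
        logger.warning("omitting genes with zero depth everywhere: %s",
                       sorted(gene_depth.loc[dead, "gene"].unique()))
        gene_depth = gene_depth[~dead]
    med = gene_depth.groupby("gene")["d"].transform("median")
    gene_depth["ratio"] = gene_depth["d"] / med
    gene_depth["copies"] = gene_depth["ratio"] * gene_depth["gene"].map(
        lambda g: ploidy_map.get(g, default_ploidy)
    )
    return gene_depth[["sample_id", "patient_id", "analyte", "gene", "ratio", "copies"]]


def cn_concordance(estimates: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Cross-analyte consistency of copy-number calls for one gene.

    Per patient with >= 2 estimates: the per-analyte values and the maximum
    pairwise relative difference |a-b| / mean(a,b).
    """
    sub = estimates[estimates["gene"] == gene]
    rows = []
    for pid, grp in sub.groupby("patient_id"):
        vals = grp["copies"].to_numpy(float)
        if len(vals) < 2:
            continue
        diffs = [
            abs(a - b) / ((a + b) / 2.0)
            for i, a in enumerate(vals)
            for b in vals[i + 1 :]
            if (a + b) > 0
        ]
        rows.append(
            {
                "patient_id": pid,
                "gene": gene,
                "n_estimates": len(vals),
                "mean_copies": vals.mean(),
                "max_rel_diff": max(diffs) if diffs else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF export of called variants (one record per called row)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=LOD,Number=1,Type=Float,Description="MAF limit of detection">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="germline or somatic">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, row in enumerate(calls[calls["called"]].to_dict("records"), start=1):
        info = (
            f"AF={row['maf']:.6f};DP={int(row['depth'])};LOD={row['lod']:.6f};"
            f"SAMPLE={row['sample_id']};CLASS={row['class']}"
        )
        lines.append(f"{row['gene']}\t{i}\t{row['locus']}\tN\tA\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")
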