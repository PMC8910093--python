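"""End-to-end orchestration: simulate -> phenotype -> cluster -> unpack ->
variant QC -> radiomics -> associate -> report.

One master seed drives every stage; a fixed offset scheme derives the
per-stage generator seeds so reruns are byte-identical. Artifact files
(CSV/JSON/VCF/PNG) are written under the output directory; the returned
:class:`PipelineResult` also carries the in-memory tables.

Default sizes mirror the emulated study: a larger multi-tumor training
cohort (~1500 CTCs, 435 features pared to 300) for model fitting and an
independent 22-patient test cohort (~900 CTCs, 5 lesion ROIs per patient)
for all downstream statistics. Nomination iteration counts and the k search
range default to reduced values that keep a desktop run in minutes; the
study-scale settings (400 iterations, k in [2, 50]) are reachable through
the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import clustering, phenotyping, radiomics, synthetic, unpacking, variants

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    n_train_patients: int = 38
    n_test_patients: int = 22
    n_features: int = 435
    k_true: int = 4
    separation: float = 30.0
    n_informative: int = 30
    k_range: tuple[int, int] = (2, 15)
    iterations_a: int = 100
    iterations_b: int = 30
    candidates_a: int = 100
    candidates_b: int = 50
    gap_B: int = 10
    variance_threshold: float = 0.99
    cart_gate: float = 0.80
    max_fn: int = 4
    fdr: float = 0.05
    n_levels: int = 16
    save_images: bool = True


@dataclass
class PipelineResult:
    outdir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    models: dict[str, clustering.ClusterModel] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    cart_reports: dict[str, list[unpacking.CARTReport]] = field(default_factory=dict)


def _fit_approach_a(train_std, cfg, seed):
    pca = clustering.fit_pca(train_std.values(), cfg.variance_threshold)
    Z = pca.transform(train_std.values())
    nom = clustering.nominate_k(Z, cfg.iterations_a, cfg.k_range, cfg.gap_B, seed=seed)
    model = clustering.fit_final_model(
        Z, nom.nominated_k, cfg.candidates_a, seed=seed + 10_000, B=cfg.gap_B,
        approach="pca_kmeans", pca=pca,
    )
    return model, nom


def _fit_approach_b(train_std, cfg, seed):
    nominated, mi_table = clustering.nominate_features(train_std)
    Z = train_std.data[nominated].to_numpy(float)
    nom = clustering.nominate_k(Z, cfg.iterations_b, cfg.k_range, cfg.gap_B, seed=seed)
    model = clustering.fit_final_model(
        Z, nom.nominated_k, cfg.candidates_b, seed=seed + 10_000, B=cfg.gap_B,
        approach="nominated_features", features=nominated,
    )
    return model, nom, mi_table


def run_pipeline(
    seed: int = 0, outdir: str | Path = "liqrad_out", config: PipelineConfig | None = None
) -> PipelineResult:
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(outdir=outdir)

    # -- simulate ----------------------------------------------------------
    train_cohort_cfg = synthetic.CohortConfig(n_patients=cfg.n_train_patients, seed=seed + 1)
    test_cohort_cfg = synthetic.CohortConfig(n_patients=cfg.n_test_patients, seed=seed + 2)
    cluster_spec = synthetic.ClusterSpec(
        k_true=cfg.k_true,
        n_features=cfg.n_features,
        n_informative=cfg.n_informative,
        separation=cfg.separation,
        seed=seed + 3,
    )
    cluster_spec_test = dataclasses.replace(cluster_spec, seed=seed + 4)
    variant_spec = synthetic.VariantSpec(seed=seed + 5)
    texture_spec = synthetic.TextureSpec(seed=seed + 6)

    train_cohort = synthetic.generate_cohort(train_cohort_cfg)
    test_cohort = synthetic.generate_cohort(test_cohort_cfg)
    train_mat, train_truth = synthetic.generate_ctc_features(train_cohort, cluster_spec)
    test_mat, test_truth = synthetic.generate_ctc_features(test_cohort, cluster_spec_test)
    test_mat.split = "test"
    res.tables["patients"] = test_cohort
    res.tables["patients_train"] = train_cohort
    test_cohort.to_csv(outdir / "patients.csv", index=False)
    test_mat.data.assign(patient_id=test_mat.patient_ids).to_csv(outdir / "ctc_features.csv")
    test_truth.to_frame().to_csv(outdir / "ctc_truth_labels.csv")

    # -- phenotype ---------------------------------------------------------
    positivity = phenotyping.classify_marker_positivity(test_mat.data)
    cooc = phenotyping.summarize_cooccurrence(positivity, test_mat.patient_ids)
    res.metrics["n_test_ctcs"] = float(test_mat.n_cells)
    res.metrics["double_positive_ctcs"] = float(cooc.double_positive)

    # -- prepare + cluster -------------------------------------------------
    droplist = phenotyping.default_droplist(train_mat)
    train_pared = phenotyping.pare_features(train_mat, droplist)
    test_pared = phenotyping.pare_features(test_mat, droplist)
    train_std, std_params = phenotyping.standardize_features(train_pared)

    model_a, nom_a = _fit_approach_a(train_std, cfg, seed + 100)
    model_b, nom_b, mi_table = _fit_approach_b(train_std, cfg, seed + 200)
    model_a.standardization = std_params
    model_b.standardization = std_params
    model_a.to_json(outdir / "model_pca_kmeans.json")
    model_b.to_json(outdir / "model_nominated_features.json")
    mi_table.to_csv(outdir / "mi_nomination.csv", index=False)
    res.models = {"pca_kmeans": model_a, "nominated_features": model_b}
    res.metrics["nominated_k_pca"] = float(nom_a.nominated_k)
    res.metrics["nominated_k_features"] = float(nom_b.nominated_k)

    labels_a = clustering.assign_clusters(model_a, test_pared)
    labels_b = clustering.assign_clusters(model_b, test_pared)
    pd.DataFrame(
        {"cluster_pca": labels_a, "cluster_features": labels_b}
    ).to_csv(outdir / "cluster_assignments.csv")

    # -- unpack ------------------------------------------------------------
    reports: dict[str, list[unpacking.CARTReport]] = {}
    for name, labels in (("pca_kmeans", labels_a), ("nominated_features", labels_b)):
        reports[name] = [
            unpacking.unpack_cluster(test_pared, labels, cid, seed=seed + 300)
            for cid in sorted(labels.unique())
        ]
    res.cart_reports = reports
    (outdir / "cart_reports.json").write_text(
        json.dumps(
            {name: [r.to_dict() for r in reps] for name, reps in reports.items()}, indent=2
        )
    )
    gated = [
        unpacking.gate_unpacking(r, cfg.cart_gate)
        for reps in reports.values()
        for r in reps
        if not r.unreliable
    ]
    res.metrics["cart_pass_fraction"] = float(np.mean(gated)) if gated else float("nan")

    # -- variant / CN QC ---------------------------------------------------
    amplicons, truth = synthetic.generate_amplicon_data(test_cohort, variant_spec)
    amplicons.to_csv(outdir / "amplicons.csv", index=False)
    calls = variants.call_variants(amplicons, error_rate=variant_spec.error_rate)
    calls.to_csv(outdir / "variant_calls.csv", index=False)
    variants.write_vcf(calls, outdir / "variant_calls.vcf")
    summaries = variants.germline_concordance(calls)
    cell_summaries = [s for s in summaries if s.analyte == "CTC"]
    retained, excluded = variants.filter_cells(cell_summaries, cfg.max_fn)
    cf = [s for s in summaries if s.analyte == "cfDNA"]
    res.metrics["cfdna_germline_sensitivity"] = float(
        np.mean([s.sensitivity for s in cf])
    )
    res.metrics["cfdna_germline_ppv"] = float(np.mean([s.ppv for s in cf]))
    res.metrics["ctc_cells_excluded"] = float(len(excluded))
    if retained:
        res.metrics["ctc_germline_ppv"] = float(np.mean([s.ppv for s in retained]))
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "analyte": s.analyte,
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
                "sensitivity": s.sensitivity,
                "ppv": s.ppv,
                "excluded": s.excluded,
            }
            for s in summaries
        ]
    ).to_csv(outdir / "germline_concordance.csv", index=False)
    somatic = calls[(calls["class"] == "somatic") & calls["called"]]
    n_pat = test_cohort["patient_id"].nunique()
    res.metrics["somatic_cfdna_patient_fraction"] = float(
        somatic.loc[somatic["analyte"] == "cfDNA", "patient_id"].nunique() / n_pat
    )
    ctc_patients = calls.loc[calls["analyte"] == "CTC", "patient_id"].nunique()
    if ctc_patients:
        res.metrics["somatic_ctc_patient_fraction"] = float(
            somatic.loc[somatic["analyte"] == "CTC", "patient_id"].nunique()
            / ctc_patients
        )
    cn = variants.estimate_copy_number(amplicons)
    cn.to_csv(outdir / "copy_number.csv", index=False)
    cn_ar = variants.cn_concordance(
        cn[cn["analyte"].isin(["cfDNA", "CTC"])], gene="AR"
    )
    cn_ar.to_csv(outdir / "cn_concordance_AR.csv", index=False)
    if len(cn_ar):
        res.metrics["ar_cn_max_rel_diff_mean"] = float(cn_ar["max_rel_diff"].mean())

    # -- radiomics ---------------------------------------------------------
    rois = synthetic.generate_roi_images(test_cohort, texture_spec)
    if cfg.save_images:
        for roi in rois:
            roi.save(outdir / "rois")
    panel = radiomics.extract_cohort_panel(rois, cfg.n_levels)
    panel.to_csv(outdir / "radiomic_features.csv", index=False)
    radiomics.write_manifest(outdir / "radiomic_manifest.json")
    res.tables["radiomics"] = panel

    # -- associate ---------------------------------------------------------
    pct_a = assoc.cluster_percentages(labels_a, test_mat.patient_ids, prefix="c")
    pct_b = assoc.cluster_percentages(labels_b, test_mat.patient_ids, prefix="c")
    if set(pct_a.columns) & set(pct_b.columns):  # same k on both approaches
        pct_b.columns = [f"{c}b" for c in pct_b.columns]
    profiles = (
        test_cohort.set_index("patient_id")[
            ["cellsearch_count", "rarecyte_count", "cfdna_ng_ml"]
        ]
        .join(pct_a, how="left")
        .join(pct_b, how="left", rsuffix="_b")
    )
    profiles.to_csv(outdir / "patient_profiles.csv")
    res.tables["profiles"] = profiles
    with_ctcs = profiles.dropna()
    readout_cols = ["cellsearch_count", "rarecyte_count", "cfdna_ng_ml"]
    cluster_cols = list(pct_a.columns) + list(pct_b.columns)
    spear = assoc.spearman_table(with_ctcs, cluster_cols, readout_cols)
    spear.to_csv(outdir / "spearman.csv", index=False)
    res.tables["spearman"] = spear
    res.metrics["platform_r2"] = assoc.platform_concordance(test_cohort)

    readouts = with_ctcs.reset_index()[["patient_id"] + readout_cols + cluster_cols]
    associations = assoc.mixed_association(panel, readouts, fdr=cfg.fdr)
    associations.to_csv(outdir / "associations.csv", index=False)
    heat = assoc.heatmap_table(associations)
    heat.to_csv(outdir / "heatmap.csv")
    res.tables["associations"] = associations
    res.tables["heatmap"] = heat

    # -- report ------------------------------------------------------------
    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "stage_seeds": {
            "train_cohort": seed + 1,
            "test_cohort": seed + 2,
            "cluster_spec": seed + 3,
            "cluster_spec_test": seed + 4,
            "variant_spec": seed + 5,
            "texture_spec": seed + 6,
            "approach_a": seed + 100,
            "approach_b": seed + 200,
            "cart": seed + 300,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.json").write_text(json.dumps(res.metrics, indent=2))
    return res
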