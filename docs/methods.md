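# Methods

This note records the models, numerical choices and limitations behind each
stage of the package, and what the synthetic generator does and does not
emulate.

## Synthetic cohort model

The generator produces every input the analysis consumes, with one
per-patient latent factor `h ~ N(0,1)` ("disease heterogeneity/burden")
coupling the layers.

**Patient scalars.** True CTC count is zero-inflated negative binomial:
with probability `zero_inflation` (default 0.23) the count is 0, otherwise
NB with mean `ctc_mean · exp(c·h − c²/2)` (mean-preserving latent tilt,
`c = latent_coupling ∈ [0,1]`, default 0.7) and shape `ctc_dispersion`
(default 0.22). Defaults were chosen so a 22-patient cohort carries on the
order of 10³ CTCs with a small median and a several-hundred tail — the
regime of heavily pretreated metastatic prostate cancer cohorts — and are
deliberately bracketing rather than calibrated: only medians/ranges of such
cohorts are ever published. Two platform counts are independent binomial
thinnings of the true count with per-patient capture probabilities drawn
from Beta distributions (means 0.85/0.95, concentration 8, i.e. ~15%
capture CV); concordance between platforms is therefore high by
construction but not degenerate. cfDNA (ng/mL) is log-normal with
`log-mean log 8`, `log-sd 1.2` (marginal mean ≈ 16 ng/mL, range typically
0.5–200), sharing the latent factor through a variance-preserving mixture
`c·h + √(1−c²)·z`. Setting `latent_coupling = 0` severs every planted
association; the association layer's type-I error is audited under exactly
this null.

**CTC features.** Cells per patient follow the RareCyte-like count. Features
(default 435 at pipeline scale, names grouped into 11 biological categories)
are Gaussian around cluster means that are mutually equidistant: each
cluster is elevated on its own disjoint block of `n_informative` features
(block value `separation·spread/√(2b)`, so pairwise centroid distance is
exactly `separation·spread`). Sparse blocks — not dense random directions —
are how morphometric phenotypes actually differ (a large-nucleus cluster
moves nuclear features, not all 435), and they matter operationally: dense
offsets spread the between-cluster variance so thin across dimensions that
neither the gap statistic nor axis-aligned CART can see it. Within a
category, features share a latent factor giving uniform correlation
`redundancy` (default 0.5), emulating instrument-panel redundancy; this is
what the mutual-information nomination exploits. Per-patient cluster
prevalence is softmax-tilted along `h` (`prevalence_coupling`, default 1),
which later makes percent-per-cluster correlate with counts and cfDNA.
Marker MFIs (Arv7, SYP, CK) are log-normal with near-mutually-exclusive
positivity (defaults: 8% Arv7+, 8% SYP+, 0.3% double) around the 250/70
positivity cutoffs.

**Amplicons.** A panel of 12 genes × 4 amplicons (per-test configurable up
to the 52-gene × 15-amplicon scale of pan-cancer assays) is sequenced for
each patient's cfDNA, buffy coat, 2 WBCs and up to 3 single CTCs. Depths are
negative binomial (per-analyte means, dispersion 20); gene-level
copy-number events scale depth linearly (×cn/2) in tumor-derived analytes
of carrier patients. Each patient is heterozygous at a `het_fraction`
(0.85) subset of 40 panel germline loci; WBC/buffy report them dropout-free
while single CTCs suffer allelic dropout: with probability `ado_rate` one
allele, chosen uniformly, contributes no reads — so the germline
false-negative rate per site is analytically `ado_rate/2`. Somatic variants
are planted in half the patients at analyte-specific fractions (cfDNA 2%,
CTC 50%). Background error adds `error_rate` (1e-3) alt reads everywhere.

**Lesion ROIs.** Five disk-masked 64×64 images per patient; the within-mask
Gaussian noise amplitude is `noise_base · exp(noise_coupling · h)`, i.e.
texture heterogeneity is monotone in the latent factor. Optional stripe and
gradient components default to off. What the generator does **not** emulate:
scanner/stainer artifacts, real morphometric feature distributions
(multimodality, boundedness), CT acquisition physics, partial-volume
effects, UMI chemistry, or amplicon dropout. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated statistical structure — not clinical performance on real cohorts.

## Cluster discovery

- Standardization: population (divide-by-n) SD; constant features dropped
  with a warning; test cohorts transformed with train-fitted parameters
  only.
- PCA retains the smallest leading set of components with cumulative
  explained variance `> 0.99` (ties broken with a 1e-12 tolerance so that a
  threshold of exactly 1.0 keeps all components).
- Gap statistic: B = 10 uniform references over the per-dimension min–max
  box; `W_k` is the total within-cluster SS; `s_k` uses the population SD
  across references times `√(1+1/B)`; selection by the one-standard-error
  rule with argmax fallback; the search range is truncated to n−1 with a
  warning when n is small. The rule is evaluated in ascending k and stops at
  the first satisfying k — mathematically identical to computing the full
  profile, and the reason structured data is cheap to search.
- K-means: k-means++ initialization, Lloyd iterations (cap 300, tolerance
  1e-4 on total squared centroid shift), numba-compiled inner loop (a model
  search performs ~10⁴–10⁵ small fits). The data-side `W_k` in each gap
  evaluation takes the best of 5 restarts; single restarts occasionally land
  in merged-cluster optima at k ≥ 8 and distort the gap curve, while the
  structureless references are insensitive and use one. Empty-cluster fits
  are refit with a fresh initialization (up to 3 times, logged).
- Nomination: iteration i uses seed `base + i`; modal k wins, ties go to the
  smaller k (logged). The final model is the best of `n_candidates` fits
  scored against one shared reference panel, which makes "highest gap
  score" equivalent to lowest within-cluster SS.
- Mutual information: plug-in estimator on 10 equal-frequency bins
  (rank-based, ordinal tie-breaks), natural log; constant vectors have MI 0
  by convention; nominee ties go to the lexicographically first name
  (logged). The estimator requires n ≥ 4·bins.
- Pipeline defaults are scaled for a desktop run: approach A uses 100
  nomination iterations and k ∈ [2, 15] (study-scale 400 and [2, 50] are
  config fields), approach B 30 iterations; 100/50 final candidates.

## Cluster unpacking (CART)

One-vs-rest Gini trees per cluster on the raw (unreduced) features,
`min_samples_leaf = 5`, unlimited depth. Pruning: minimal cost-complexity
path computed on the full data, subsampled to ≤ 12 α values plus an explicit
root-forcing α — the path's own maximum does not necessarily collapse
per-fold trees, and the one-standard-error rule needs the null model among
its candidates (without it, spurious trees survive permutation nulls and
bias CV balanced accuracy below 0.5). α is chosen as the largest value whose
10-fold stratified CV log-loss is within one SE of the minimum; the reported
confusion matrix comes from seeded 10-fold cross-validated predictions at
that α. Clusters with fewer members than folds are flagged unreliable. The
interpretability gate requires CV sensitivity AND specificity strictly
greater than 0.80.

## Variant calling, germline QC, copy number

- LOD: smallest `m` with `P(Bin(depth, error) ≥ ceil(m·depth)) ≤ α`
  (α = 0.01, error 1e-3 defaults); with zero error, 1/depth. Exact binomial
  tail, verified against a brute-force scan.
- Calling: MAF must strictly exceed `max(analyte floor, LOD)`; floors 0.001
  (cfDNA) and 0.10 (single cells, WBC, buffy). Zero-depth rows are skipped
  and logged.
- Germline truth per patient = loci called in both WBC and buffy coat. A
  call is classed germline iff its locus is in the patient's truth set.
  Concordance counts TP/FN over the patient's truth loci; FP counts calls at
  cohort-panel germline loci (union of truth sets) absent from the patient's
  own truth — the natural notion of a germline-type call that should not be
  there, and non-degenerate because patients are het at different subsets.
  Cells with FN > 4 are excluded.
- Copy number: per-sample totals normalize each gene's mean amplicon depth;
  per-gene medians across samples anchor the ratio; copies = ratio × ploidy
  (default 2 for every gene; a per-gene map accommodates chrX conventions —
  reported AR copies here use the diploid baseline, and the flag exists
  because the field's convention is genuinely ambiguous). The estimator is
  exactly invariant to rescaling all of one sample's depths. Note an
  inherent property of total-reads normalization: a strong amplification
  inflates its own sample's total, deflating the estimate by
  `(G−1+cn/2)/G` for a G-gene panel (~5% for 8 copies on 52 genes).

## Association layer

- Percent-CTC-per-cluster per patient (rows sum to 100; zero-CTC patients
  are excluded from correlations, logged).
- Spearman correlations with average-rank ties; ρ² reported alongside ρ.
  Platform concordance is squared Pearson correlation (raw scale by
  default, log1p optional).
- Mixed model: for each (radiomic feature, molecular readout) pair,
  `z(feature) = β·z(readout) + patient intercept + ε`, REML via statsmodels
  MixedLM; z-scores use population SD so β is on the correlation scale. The
  Wald statistic is referenced to `t(n_patients − 2)`: the readout is
  constant within patient, so the slope carries only patient-level
  information, and the normal reference is anticonservative at n ≈ 22
  (measured 7.5% type-I at nominal 5%; the t reference is
  rejection-identical to the exact patient-means OLS t-test on balanced
  data). Non-convergent or singular fits fall back to patient-means OLS and
  are flagged. BH adjustment is applied within each readout's feature
  family; q ≥ p and monotonicity are guaranteed by the step-up
  construction.

## Radiomics

- Quantization: fixed bin count (default 16) over the masked min–max;
  masked-out pixels never influence edges; constant ROIs map to level 0.
  This makes the whole GLCM block invariant to affine intensity rescaling —
  and, for pure i.i.d. noise, to noise amplitude; amplitude sensitivity
  enters through intensity metrics and through structure degradation.
- GLCM: both pixels of a pair must lie in the mask; each offset and its
  negation are accumulated (symmetric) and normalized to sum 1; directions
  0°/45°/90°/135° at distance 1. 23 base metrics × directional mean and SD,
  with the `joint_average` SD slot (redundant: joint average is the marginal
  mean, nearly direction-free) replaced by the MAD of the co-occurrence
  grey-level distribution, yielding 46 named values; all entropies are
  log₂ with 0·log 0 = 0.
- Degenerate conventions (logged): skewness, kurtosis (Pearson) and CV of a
  constant ROI are 0; GLCM correlation of a zero-variance matrix is 1.
- I/O: 16-bit grayscale PNG + 8-bit mask PNG round-trip at 1/65535
  precision.

## Pipeline and problem sizes

`run_pipeline(seed, outdir)` trains both cluster models on an independent
synthetic multi-tumor cohort (38 patients, ≈1500 CTCs, 435 features pared
to ≈300 by a deterministic per-category droplist standing in for the
instrument-specific artifact list) and applies everything downstream to a
22-patient test cohort (≈10³ CTCs, 110 ROIs). Stage seeds are fixed offsets
from the master seed and recorded in `manifest.json`; reruns are
byte-identical. A full run takes a few minutes on one CPU; the reduced
configuration in `examples/full_pipeline.py` finishes in about one minute.

## Known limitations

- The gap machinery is validated on Gaussian block-sparse mixtures;
  heavy-tailed or manifold-structured feature sets may need the k-NN MI
  estimator and different reference distributions (neither is implemented).
- Germline FP/PPV depends on the cohort-panel definition above; with a
  single patient (no cross-patient panel) PPV degenerates to 1.
- The CN estimator inherits the self-normalization shrinkage noted above;
  panels much smaller than ~40 genes make it material.
- MixedLM fits one pair at a time (~40 ms each); the 66 × ~12 family in the
  pipeline costs ~30 s. Random slopes, covariate adjustment and
  repeated-measures correlation structures are out of scope.
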