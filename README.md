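# cthperf

Leakage-insensitive DSC-MRI microvascular analysis: parametric gamma-variate
deconvolution producing CBF/CBV/MTT/CTH/RTH maps, biophysical tissue-oxygen-
tension (PtO2) estimation, lesion/ROI filtering and normalization rules, and
covariate-adjusted group comparisons — with a synthetic digital phantom and
cohort generator providing ground truth for every stage.

## The scientific problem

White matter lesions in multiple sclerosis (MS) are hard to distinguish from
unspecific lesions on conventional MRI, yet the two differ in their
*microvascular* flow organization.  Dynamic susceptibility contrast (DSC)
perfusion MRI tracks a gadolinium bolus through tissue; deconvolving each
voxel's concentration curve against an arterial input function (AIF) yields
not only cerebral blood flow (CBF) and volume (CBV) but — with a parametric
residue-function model — the full distribution of capillary transit times
h(t).

`cthperf` models h(t) as a gamma variate with shape α and scale β:

- **MTT** = αβ — mean transit time (s); CBV = CBF · MTT (central volume theorem)
- **CTH** = √α · β — capillary transit-time heterogeneity, the SD of h(t) (s)
- **RTH** = CTH / MTT = 1/√α — relative heterogeneity, computed voxelwise
  before any averaging

The tissue curve is fitted with the leakage-augmented forward model

```
Ct(t) = CBF · (Ca ⊛ R)(t − delay) + k_leak · ∫₀^{t−delay} Ca(s) ds
```

where R(t) = 1 − CDF_gamma(t; α, β) is the residue function and the
unidirectional uptake rate `k_leak` absorbs contrast extravasation across a
disrupted blood-brain barrier.  The leakage term is fitted in *every* voxel
so the estimator's variance structure is uniform across enhancing and
non-enhancing tissue.

Tissue oxygen tension is obtained from the extended flow-diffusion model:
oxygen extraction along a single capillary follows
dC/dx = −k·τ·(c_p(x) − c_t), the voxel OEF is the h(t)-weighted average of
single-capillary extractions, and PtO2 is the back-pressure at which
delivery matches a fixed resting metabolic rate,
CBF · CaO2 · OEF(PtO2) = CMRO2 = 2.5 mL O2/100 mL/min.

## Worked example

```bash
cthperf full --out subj0 --seed 0 --shape 6,6,2
```

simulates a small digital phantom (3 mm DSC grid, 1 mm lesion masks),
deconvolves it, applies the mask rules and writes `subj0/roi_summaries.csv`
(values below are the actual output of the command above):

```
roi                 rcbf   rcbv   mtt_s  cth_s  rth    pto2_mmHg  n_voxels_used
ms_t1               0.866  1.116  2.147  1.180  0.550  6.278      1
ms_t2flair          0.789  1.186  2.522  1.518  0.608  3.236      4
nagm_region         2.419  1.343  0.933  0.861  0.948  24.077     6
nawm_control        0.986  0.982  1.727  1.357  0.827  2.470      53
unspecific_t2flair  1.213  0.888  1.220  1.032  0.846  5.345      2
```

Reading the numbers: relative to the unspecific lesion class, the MS-like
T2-FLAIR lesion shows prolonged MTT (2.52 s vs 1.22 s), raised CTH, raised
relative CBV — vasodilation with heterogeneous flow — while its voxelwise
RTH (0.61 vs 0.85) and modelled PtO2 (3.2 vs 5.3 mmHg) are both lower:
inefficient oxygen extraction without increased blood supply.  The
enhancing-lesion class is fitted with its leakage term free, and the
small-ROI values (1-6 DSC voxels here) carry visible single-voxel noise;
exact values vary with seed and grid size.

A 60-subject synthetic cohort with the full contrast suite:

```bash
cthperf cohort --cohort-out cohort.csv --seed 0
cthperf stats --cohort cohort.csv --out results.csv
```

`results.csv` has one row per contrast × metric with the adjusted estimate,
95 % CI, two-sided p, and a Benjamini-Hochberg column (reported, never used
for decisions).

## Layout

| module | contents |
| --- | --- |
| `cthperf.transit` | gamma transit-time distribution, residue function, MTT/CTH/RTH |
| `cthperf.deconv` | signal↔concentration, leakage-augmented forward model, per-voxel fits, maps |
| `cthperf.oxygen` | capillary O2 extraction, OEF quadrature, PtO2 solver, calibration |
| `cthperf.roi` | lesion size filter, 50 % partial-volume rule, vessel exclusion, NAWM normalization, ROI summaries |
| `cthperf.stats` | paired tests, covariate-adjusted OLS contrasts, comparison suite |
| `cthperf.phantom` | digital phantom and cohort generator with known ground truth |
| `cthperf.cli` / `config` / `niftiio` | pipeline orchestration, YAML config, NIfTI/CSV plumbing |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
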