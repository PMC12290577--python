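# Methods

## Perfusion model

Capillary transit times in a voxel are modelled as a gamma variate h(t)
with shape α > 0 and scale β > 0 (seconds).  The tissue residue function is
the survival function R(t) = 1 − CDF_gamma(t; α, β), evaluated through the
regularized incomplete gamma function (`scipy.special.gammaincc`, accurate
to well below 1e−10).  Summary statistics are closed forms: MTT = αβ,
CTH = √α·β, RTH = 1/√α.  The parameterization is canonical (shape, scale);
the `from_moments(mtt, cth)` constructor converts through it.

The forward model of the voxel concentration curve is

    Ct(t) = CBF · (Ca ⊛ R)(t − delay) + k_leak · ∫₀^{t−delay} Ca(s) ds

with Ca the arterial input function.  The convolution is a
trapezoid-weighted discrete sum at the acquisition spacing dt on a grid
extended to three times the acquisition window (AIF zero-padded), which
keeps the tails of slow-transit voxels unbiased; the area identity
∫Ct = CBF·MTT·∫Ca holds to better than 1e−4 on a dense grid.  The bolus
arrival delay shifts the curve by linear interpolation (no circular
deconvolution).  The leakage term is a unidirectional (irreversible) uptake
integral; it is deliberately the simplest extravasation model and is
isolated in one function should a different variant be needed.

Signal and concentration are related by C = −ln(S/S0)/TE with S0 the
pre-bolus baseline mean.  Concentration is kept in arbitrary units
throughout — CBF and CBV are therefore relative quantities and are reported
normalized to a deep normal-appearing white matter (NAWM) control region
(rCBF, rCBV); MTT, CTH, RTH and PtO2 are absolute.

## Per-voxel estimation

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF)
over (CBF, α, β, k_leak, delay), with bounds CBF ∈ [0, 50·scale] (scale =
peak ratio of tissue to AIF), α ∈ [0.1, 50], β ∈ [0.05, 20] s,
k_leak ∈ [0, 0.1] /s, delay ∈ [0, 10] s.  The leakage rate is always a free
parameter; it is never frozen per voxel, so the estimator behaves
identically in enhancing and non-enhancing tissue.  A deterministic
multi-start grid over initial α ∈ {1, 4, 16} × delay ∈ {0, 2 s} guards
against local minima; the lowest residual sum of squares wins, ties broken
by lower k_leak then lower delay.  There is no randomness anywhere in the
fit.

Residuals are whitened for the signal-domain noise model: additive Gaussian
noise on the MR signal has concentration-domain standard deviation
proportional to exp(TE·C), so residuals are weighted by exp(−TE·C̃) with C̃
the measured curve (configurable; `weighting="none"` gives plain least
squares).  A voxel is invalid (and excluded from every map) when any signal
sample is nonpositive, the curve is all-zero or non-finite, the optimizer
fails, or the fit does not beat the all-zero null model.

Derived maps obey the central volume theorem voxelwise (CBV = CBF·MTT) and
the ratio convention RTH = CTH/MTT per voxel — ROI averages of RTH are
means of voxelwise ratios, never ratios of ROI means.  The distinction
matters: for two voxels with (CTH, MTT) = (1, 1) and (1, 4) the mean of
ratios is 0.625 while the ratio of means is 0.4.

## Oxygenation model

Single-capillary oxygen transport follows the extended flow-diffusion
model: hemoglobin-bound oxygen content C(x) along the normalized capillary
axis obeys dC/dx = −k·τ·(c_p(x) − c_t), where τ is the transit time,
c_p = α_p·P(x) the plasma oxygen content at the local tension, and
c_t = α_p·PtO2 the tissue-equivalent content; P(x) inverts the Hill curve
P = p50·(S/(1−S))^{1/h}, S = C/B.  The tissue compartment is treated as
well mixed (constant back-pressure along the capillary).  Integration is
classical RK4 on a fixed 128-step grid, vectorized over transit times; the
extraction fraction is Q(τ) = 1 − C(1)/C(0), clipped to [0, 1].

The voxel OEF integrates Q over h(t) by 64-node Gauss–Legendre quadrature
on [0, q(1−1e−8)].  PtO2 solves CBF·CaO2·OEF(PtO2) = CMRO2 by bisection on
[0, inflow tension] to 0.01 mmHg, with CMRO2 fixed at the resting value
2.5 mL O2/100 mL/min; when even zero back-pressure cannot supply the
demand the voxel is flagged infeasible and floored at PtO2 = 0.  A
vectorized batch solver (32 nodes, 64 RK4 steps, 18 bisection iterations)
serves cohort-scale workloads; it agrees with the scalar solver to well
under 0.05 mmHg.

Constants (all config-exposed): p50 = 26 mmHg, Hill exponent h = 2.8,
hemoglobin-bound capacity B = 0.1943 mL O2/mL, arterial content
CaO2 = 0.19 mL/mL (inflow tension ≈ 100 mmHg, physiological), plasma
solubility α_p = 3.1e−5 mL O2/mL/mmHg (a fixed convention — only the
product k·α_p is identified).  The wall transfer rate k is not assumed: it
is calibrated by bisection so that a reference white-matter-like state
(MTT 1.4 s, CTH 1.33 s) at PtO2 25 mmHg extracts OEF = 0.30; this yields
k ≈ 103 /s.  Relative CBF is anchored to absolute units by mapping the
NAWM-mean rCBF to 22 mL/100 mL/min (config-exposed).  With this anchor the
required NAWM extraction fraction (≈ 0.60) sits close to the model's
capacity ceiling, so solved PtO2 values are low (a few mmHg in white
matter) and strongly sensitive to the transit-time distribution; this is a
property of the anchor convention, not of the solver.

## Mask and ROI rules

* **Lesion size filter.**  26-connected components (config-exposed) are
  kept only if they have ≥ 3 voxels *and* at least two contiguous slices in
  which the in-plane extent along some axis reaches 3 mm.  The rule is
  scale-aware through the mask's voxel metadata: at a 3 mm mask scale the
  smallest surviving component has exactly 3 voxels; at 1 mm the effective
  minimum is correspondingly larger.  The filter is idempotent.
* **Partial-volume rule.**  High-resolution masks are reduced onto the DSC
  grid by exact block counting (the high-res grid is an integer refinement);
  a DSC voxel is retained iff its lesion fraction is ≥ 0.5.  The boundary
  is inclusive: the exclusion rule omits voxels with *less than* 50 %
  lesion, so exactly half survives.
* **Vessel exclusion.**  The upper 8 % of valid voxels by CBV are removed
  (exactly ceil(0.08·N); ties broken by lexicographic voxel index for
  determinism), per subject over the valid brain.
* **Normalization.**  rCBF and rCBV divide by the arithmetic mean over the
  NAWM control region after vessel exclusion and validity filtering
  (mean, not median — config-exposed).
* **Bookkeeping.**  Every ROI summary satisfies
  n_total = n_used + n_invalid + n_excluded_pve + n_excluded_vessel, and a
  summary with zero usable voxels is flagged missing rather than raising.

## Statistics

Within-subject comparisons use a paired t-test or Wilcoxon signed-rank
test, chosen automatically by Shapiro–Wilk on the paired differences at
0.05 (forceable).  The Wilcoxon estimate is the Hodges–Lehmann
pseudo-median with a distribution-free CI from Walsh averages.
Between-group differences are ordinary least squares of the metric on a
group indicator plus covariates (age, sex; plus lesion volume for
disease-course contrasts), reporting the group coefficient with 95 % CI and
two-sided p.  Constant covariates are dropped with a logged warning;
rank-deficient designs raise an error naming the collinear columns.  Sex is
a single indicator with the reference level logged.  No multiple-testing
correction enters any decision (two-sided p < 0.05 throughout); a
Benjamini–Hochberg column is emitted for reference only.

## The synthetic phantom and cohort

The generator emulates what the pipeline needs with exact, recorded ground
truth; it does not attempt anatomical realism (no real geometry, motion,
susceptibility artifacts, or multi-echo acquisition), so passing tests
demonstrate correct *method* behavior, not clinical performance on real
scans.

Acquisition defaults: TE 40 ms, frame interval 1.2 s, 100 frames, baseline
frames [0, 8).  The AIF is a gamma-variate bolus A·(t−t0)^2·e^{−(t−t0)/0.6}
arriving at t0 = 12 s with amplitude chosen so a reference tissue voxel
peaks near 38 concentration units (≈ 80 % peak signal drop at TE 40 ms) —
a compact, high-contrast bolus at the favorable end of what a 3 T
acquisition delivers.  Tissue curves are shifted by a 2 s bolus-arrival
delay.  Noise is additive Gaussian on the signal at a configurable baseline
SNR (Gaussian, not Rician: at the simulated SNRs the difference is
negligible; config-exposed).  These were chosen once, as the generator's
study conditions, because transit-time *shape* parameters are only weakly
identified from single-voxel least squares: with a broad bolus or weak
contrast the CBF/MTT ridge dominates and CTH estimates degrade well beyond
the tolerances the recovery tests assert.

Tissue-class truths are multipliers on an NAWM base state
(rCBF 1.0, MTT 1.6 s, CTH 1.4 s), so scaling every deviation to zero gives
an exact null cohort:

| class | rCBF | MTT (s) | CTH (s) | RTH | k_leak (1/s) |
| --- | --- | --- | --- | --- | --- |
| NAWM control | 1.00 | 1.60 | 1.40 | 0.875 | 0 |
| NAGM | 2.00 | 1.20 | 0.80 | 0.667 | 0 |
| unspecific T2-FLAIR | 1.10 | 1.35 | 0.95 | 0.704 | 0 |
| MS T2-FLAIR | 0.80 | 2.40 | 1.55 | 0.646 | 0 |
| MS T1 (enhancing) | 0.90 | 2.00 | 1.15 | 0.575 | 0.01 |

These numbers are generator conventions, not empirical claims.  They were
derived under the oxygenation model so the full directional contrast
pattern of MS vs unspecific lesions is expressed simultaneously: CTH and
MTT up, rCBV up, RTH down, and PtO2 down.  Within the flow-diffusion model
that combination has a sharp consequence: a lesion state with longer MTT
and lower RTH *stochastically dominates* the comparison distribution and
would extract more oxygen — so low PtO2 can only coexist with low RTH if
absolute flow is somewhat reduced.  The MS lesion class therefore carries
mildly reduced relative CBF (0.80), the model-consistent mechanism (resting
flow attenuation under capillary dysfunction) for jointly low RTH and low
PtO2.  Only the enhancing-lesion class leaks contrast.

The phantom lays these classes out on a 3 mm DSC grid with a 3× refined
(1 mm) label field; lesion blobs are placed so that, by construction, at
least one component is below the minimum size and at least one DSC voxel is
covered at under 50 % — the mask filters always have work to do.  DSC
voxels take the volume-majority class.  Cohorts are drawn in fast mode: per
subject and ROI, 12 voxel-level parameter draws (log-normal within-ROI
spread 0.10) around a subject-level state (log-normal between-subject
spread 0.06), with disease-course severity scaling the lesion deviation
(CIS/RIS 0.75, RRMS 1.0, PPMS 1.25); metrics are averaged exactly as the
imaging pipeline averages them and PtO2 is solved per draw.  Study
structure mirrors a 60-subject cohort: 50 MS (course split 5/7/31/7),
10 symptomatic controls, 48 MS subjects with lesion ROIs, 16 with
enhancing lesions, 31 with additional unspecific lesions.

## Numerical and testing notes

* All randomness flows through `numpy.random.default_rng(seed)`; fits are
  seed-free and bit-reproducible.
* Recovery tests use a fixed seed and problem sizes of 200–500 voxels
  (chosen to keep the suite's runtime proportionate while the medians are
  stable); the statistical calibration test uses 1000 OLS replicates at
  n = 30 per group.
* The per-voxel estimator is biased at clinical noise levels: at baseline
  SNR 20 the median biases under the default study conditions are roughly
  −8 to −10 % for CBF, +6 to +8 % for MTT and −9 to −13 % for CTH
  (noise-stream dependent).  Every multistart branch converges to the same
  weighted-least-squares minimum, so this is a property of the estimator on
  the CBF/MTT/shape ridge, not of the optimization; it shrinks with
  contrast-to-noise and would be removed by the spatial or Bayesian
  regularization that production DSC pipelines employ.
* Degenerate inputs are contracts, not surprises: all-zero voxels fit as
  non-converged results, empty ROIs flag missing summaries, empty control
  regions and non-nesting grids raise configuration errors.

## Known limitations

* The leakage model is unidirectional uptake; bidirectional exchange
  (e.g. extended Tofts-like behavior) is out of scope and would slot into
  the same forward-model term.
* Absolute CBF calibration, automatic AIF detection, motion and
  slice-timing correction, registration, and tissue segmentation are out of
  scope; the pipeline consumes masks and an AIF.
* PtO2 values inherit the arbitrariness of the absolute-flow anchor; only
  their ordering across tissue states is meaningful, and the model assumes
  normal resting oxygen utilization everywhere.
* Estimates are per-voxel maximum-likelihood under least squares; no
  spatial regularization or Bayesian shrinkage is applied, so single-voxel
  transit-shape estimates remain noisy at clinical SNR.
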