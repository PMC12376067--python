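# Methods

`pitnet_ith` re-implements, as a tested library, an MRI-based analysis of
intratumor heterogeneity (ITH) and postoperative hormone remission in
growth-hormone-secreting pituitary neuroendocrine tumors (GH-secreting
PitNETs). The pipeline has four stages — heterogeneity radiomics, ITH
scoring, voxel-level habitat clustering, and cohort statistics — plus a
single-cell QC/dispersion stage and a synthetic-data generator that stands
in for the clinical cohort, which is not publicly available.

## Heterogeneity radiomics

Features are computed on a 3D tumor ROI over discretized gray levels.
The default registry holds 42 signed features: 9 first-order
(variance, SD, mean absolute deviation, robust MAD over the 10–90
percentile band, IQR, range, histogram entropy, uniformity, energy) and 33
texture features from five matrix families (12 GLCM, 7 GLRLM, 6 GLSZM, 3
NGTDM, 5 GLDM). Conventions are fixed so every value is exactly testable:

* GLCM/GLRLM use distance-1 offsets over the 13 unique 3D directions;
  per-direction features are averaged (GLCM matrices are symmetric and
  restricted to voxel pairs fully inside the mask).
* GLSZM zones are 26-connected equal-level components; GLDM dependence is
  1 + the number of same-level 26-neighbors; NGTDM averages gray tone over
  the masked 26-neighborhood.
* Each feature carries a heterogeneity sign: dispersion, entropy and
  non-uniformity measures are +1; uniformity, energy, inverse difference
  moment, correlation, coarseness and long-run emphasis are −1.

First-order dispersion statistics are computed on raw in-mask intensities
with population moments; entropy/uniformity on the gray-level histogram.
`energy` is defined as the **mean** squared intensity rather than the sum:
the summed form grows linearly with ROI volume, which would make the
cohort-z-scored ITH sum a proxy for tumor size.

All texture machinery is verified in the test suite against brute-force
pair/run/zone enumeration written as plain Python loops, and all 42
features are invariant under axis-aligned 90° rotations.

### Discretization

Two schemes are provided:

* `discretize_fixed_bins` — a fixed bin count (default 32), equal-width
  over the in-mask range. This is retained for per-ROI work (and is the
  scheme used inside the voxel-level pipeline, with 16 bins), but it makes
  texture *relative* to each ROI's own dynamic range.
* `discretize_fixed_width` — fixed bin width anchored at the in-mask
  minimum (the IBSI-recommended scheme for cross-patient comparability).
  **Cohort-level ITH features use this scheme.** The reason is measurable:
  under min–max fixed-count binning a homogeneous (single-Gaussian) ROI
  fills every bin and therefore *maximizes* apparent texture, while adding
  a genuinely distinct intensity compartment widens the range and
  compresses resolution — on planted phantoms the mean ITH score then
  strictly *decreases* with the planted habitat count. With fixed-width
  binning the mean ITH score is strictly increasing in both the planted
  habitat count and the planted contrast. Choose a width comparable to the
  image noise SD (the test and acceptance suites use 8, the phantom base
  texture scale).

No resampling to isotropic spacing is performed; offsets are in voxel
units and spacing is carried through for volumetry only.

## ITH score

Per-patient features are z-scored column-wise over an explicit
normalization cohort (sample SD, n−1), then summed with their registry
signs: score_i = Σ_j sign_j · z_ij. Consequences used as tests: the cohort
mean score is exactly 0, and flipping every sign negates every score.
Constant columns are an error by default (`drop_constant` excludes them
with a warning). The choice of normalization cohort (full cohort vs a
subcohort) is the caller's, passed explicitly.

## Habitat clustering

Every ROI voxel receives the full 42-feature vector computed over its
3×3×3 window ∩ mask; voxels with fewer than 6 masked neighbors (or, in
pathological masks, no co-occurring pair) are excluded. Discretization is
done once per patient over the whole ROI (16 bins) and reused per window.
Voxel vectors are pooled across patients, standardized per feature
(population SD; zero-SD features pass through unscaled), and clustered
with seeded K-means (k-means++, 10 restarts, 300 iterations, tol 1e-4)
for k = 3..8. The Calinski-Harabasz score on the pooled standardized
voxels selects k unless `k_override` fixes it (the replication profile
uses k = 5). The pooled matrix is sorted lexicographically before fitting,
which makes the fit independent of patient order; with a fixed seed the
labels are bit-identical across runs. A patient's habitat count is the
number of distinct cluster labels present in their ROI.

### What recovery on phantoms does and does not show

The 42 features are deliberately location-invariant (they quantify
dispersion, not intensity level), so a planted compartment that differs
from its surroundings *only in mean intensity* is essentially invisible to
them — measured recovery on such phantoms is near chance. The phantom
generator therefore plants habitats that differ in per-habitat texture
scale (geometric progression, ratio 3) as well as mean, which is also the
more realistic reading of imaging habitats (necrotic, cystic and enhancing
compartments are textured differently). Recovery is evaluated on
*habitat-pure* voxels, whose full 3×3×3 window lies inside one habitat: a
boundary window's features describe a mixed neighborhood, so its planted
label is not a meaningful target for a windowed descriptor (with ~40% of
voxels near boundaries at the phantom sizes used, whole-ROI ARI plateaus
around 0.6 from this ambiguity alone). On pure windows, pooled recovery
ARI is ≈ 0.95 and Calinski-Harabasz selects the planted k.

## Cohort statistics

* Remission rules: center rule = postoperative GH strictly below the
  center's upper normal limit (a required configuration value, not
  defaulted); consensus rule = (random GH < 1 ng/mL or OGTT nadir < 0.4
  ng/mL) with age/sex-normalized IGF-1.
* Derived categories: preoperative GH bins ≤10 / (10,30] / >30 ng/mL; ICA
  encasement 0 / (0,30] / (30,50] / >50 %; invasive iff Knosp grade 3–4 or
  Hardy grade III/IV or Hardy stage C/D/E.
* Univariate battery: Shapiro–Wilk gate at α = 0.05 per group → Welch
  t-test if both groups pass, otherwise two-sided Mann–Whitney U
  (asymptotic, tie-corrected). Categorical factors: Pearson chi-square
  *without* continuity correction, switching to Fisher's exact test when
  any expected count is < 5 (Monte-Carlo fixed-margin sampling for tables
  beyond 2×2). The no-correction choice is validated by reproducing the
  published 2×2 p-values (0.044 intrasellar, 0.459 suprasellar) to ±0.002.
* Multivariate logistic regression: all terms entered simultaneously
  (Enter method), categorical terms dummy-coded against an explicit
  reference; OR = exp(β) with Wald 95% CIs. Quasi-separation (SE > 50) is
  an error, not a silent result.
* Mediation: quasi-Bayesian (Imai-style) with a linear mediator model and
  a logistic outcome model; `n_sim` parameter draws from each fit's
  asymptotic normal, potential-outcome contrasts averaged over the sample
  and over both exposure arms; percentile 95% CIs and simulation
  p-values; fully seeded. The statsmodels implementation is used as an
  independent cross-check in the tests, never as the implementation.

## Single-cell QC and GH1 dispersion

Rules: cells with fewer than 100 detected genes (strict <) or more than
10% mitochondrial counts (strict >) are removed using metrics from the
current matrix; genes expressed in fewer than 3 retained cells are then
removed. Because gene removal can push a retained cell back across a
threshold, the two-step pass is iterated to a fixed point — the output
then satisfies all three rules with respect to itself and the filter is
idempotent. On matrices with only a few hundred genes this iteration can
legitimately cascade to an empty result, which raises an error.

Tumor cells are flagged by marker expression (POU1F1, counts-per-10k +
log1p, cutoff > 0 by default — a configuration point, not a calibrated
constant). GH1 dispersion per sample is the CV (sample SD / mean) of
normalized GH1 over tumor-flagged cells; samples with fewer than two tumor
cells report NaN.

## Synthetic data

All generators are pure functions of (spec, seed).

* **Phantoms**: an ellipsoidal ROI partitioned into habitats by
  farthest-point-seeded Voronoi cells (compact, well-separated; nested
  shells available). Default means 100 + 40·h (5 base texture scales
  apart), per-habitat texture SD 8·3^h, global noise SD 4. Emulated: a
  contrast-enhanced T1 tumor with internally textured subregions. Not
  emulated: MRI bias fields, partial-volume averaging, spatial noise
  correlation, scanner effects — so passing recovery tests show the
  clustering machinery works on identifiable planted structure, not that
  real CE-T1 habitats are recoverable at these rates.
* **Cohorts**: covariate marginals match the published cohort tables
  (surgical approach 178/256/24, IHC 66/340/52, residual-location rates
  from the residual subcohort, ITH ~ N(−2.9, 8), preoperative GH
  log-normal(2.83, 1.1)); remission is Bernoulli with a logit linear in GH
  bin, resection rate, ITH and the direct exposure term, with the
  published multivariate ORs (0.48, 0.13, 18.29, 1.06) as default effects.
  The mediation path is intrasellar residual → resection rate (linear,
  noise SD 0.18, clipped to [0,1] with the clipped fraction reported) →
  remission, with zero direct effect by default.
* **Count matrices**: Gamma-Poisson counts, 13 "MT-" genes at ~5% of
  counts, POU1F1 positive in ~96% of cells, per-sample GH1 with a planted
  Gamma-Poisson dispersion; designated cells are forced below 100 detected
  genes or to ~30% mitochondrial content, and the planted rosters are
  returned for exact-recovery checks.

## Problem sizes in the default suites

The test and acceptance suites use 32³ phantom grids for ROI-level ITH
cohorts (20 phantoms per condition level), 16³ grids (≈1300 ROI voxels)
for the voxel-level habitat cohorts and 10³ grids for the 60-phantom
habitat-count sweep, n = 2000 × 100 replicates for logistic recovery and
n = 1000 with 1000 draws for mediation. These sizes give stable planted-
recovery statistics while keeping a full run in the minutes range on one
CPU.

## Known limitations

* The 42-feature registry is a documented reconstruction from the standard
  radiomics feature definitions with signs assigned by definition; the
  original study's exact supplementary feature list is not public.
* Remission thresholds depend on a center-specific GH reference limit that
  must be supplied by the user.
* Habitat labels are not spatially regularized; per-patient (rather than
  population) clustering is out of scope.
* The mediation component models are covariate-free; confounding of the
  exposure–mediator path is not adjusted for.
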