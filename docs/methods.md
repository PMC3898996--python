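# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the design decisions behind
`vbmglobals`, together with what the shipped tests do and do not show
about real data.

## The mass-univariate model

Every analysis fits, per unit (voxel or ROI), an ordinary-least-squares
GLM of modulated gray-matter density on a second-degree polynomial
expansion of age built *separately per sex*: columns
`age_lin_M, age_quad_M, age_lin_F, age_quad_F, const_M, const_F, tiv`
(plus `tgm` under Local Covariation).  "Separately per sex" follows the
usual neuroimaging group-model convention — sex-partitioned age columns
that are zero for the other sex — and the reported decline contrast
averages the two linear slopes with weights 0.5/0.5, tested one-tailed
(lower tail of the signed slope = decline).

### Centering and the LGM identity

Age columns are centered at the cohort mean age and then demeaned
within their own sex; TIV and TGM are demeaned over the whole cohort.
Every non-constant column therefore has exactly zero grand mean, which
gives the *local gray matter* (LGM) identity: the sex-weighted constant
`(n_M·const_M + n_F·const_F)/n` equals the per-unit mean of the data to
machine precision.  Local Scaling divides the sex-averaged slope by
this quantity, so its output reads as *fraction of the local mean GM
lost per year*.  Whether TIV should be mean-centered in such models is
a free choice; centering was chosen here for interpretability of the
constants.  All means used in centering are recorded in the design's
`centering` record so held-out subjects can be projected onto exactly
the training basis.

Degenerate covariates (zero-variance TIV or TGM, e.g. in constructed
equivalence tests) are dropped with a warning rather than tripping the
rank check; genuinely collinear designs raise an error naming the
offending columns.

### Contrasts, partial R², FWE

t statistics use the analytic `w'(X'X)⁻¹w` variance form; a degenerate
0/0 statistic (zero effect and zero residual variance, which arises on
noiseless constructed data) is reported as t = 0, p = 0.5 for the
one-tailed test.  Partial R² is `(RSS_reduced − RSS_full)/RSS_reduced`
for nested designs, clipped to [0, 1] against floating-point noise.

Familywise error is controlled by Bonferroni (deterministic default) or
by Freedman–Lane max-T permutation: the nuisance-only model (all
columns with zero contrast weight) is fit, its residuals are permuted
as whole subject rows (preserving the spatial correlation of the maps)
and added back to the nuisance fit, the full model is refit, and each
unit's observed t is ranked against the permutation distribution of the
most extreme statistic across units.  Permutation p-values live on the
lattice `{1/(B+1), …, 1}`.  Random-field-theory corrections are out of
scope; both implemented alternatives control FWE validly, which the
suite verifies by simulation (500 global-null replicates, rejection
count bounded by the upper 95% binomial quantile at the 5% level).

### Global tissue trends

`fit_global_trend` fits `value ~ age + age² (+ TIV)` pooled across
sexes for one global measure per subject (TIV, TGM, TWM, TCSF),
reporting per-term one-tailed p (in the direction of the estimate),
partial R², the combined age R², and the percent change implied by the
fitted curve at the ends of the observed age range with covariates at
their means.  Covarying TIV out of TIV itself is refused.

## The synthetic generator

The generator emulates the *output* of a VBM preprocessing chain —
modulated, spatially normalized, optionally smoothed GM maps — never
raw T1 intensities, segmentation or registration.  Its defaults are the
study conditions the analyses target:

* **Cohort**: 70 subjects per decade across ages 18–77 (420 total),
  ages continuous and uniform within 10-year bands (per-decade counts
  are a design constraint; continuous ages avoid ties), a 50/50 sex
  split per decade (the within-decade balance is configurable), and
  TIV ~ Normal(1550, 100) mL for males, Normal(1400, 100) mL for
  females — realistic magnitudes with a realistic sex difference.
* **Atlas**: an ellipsoidal "brain" on a 24³ grid of 1.5 mm voxels,
  split at the midline and parcellated into 58 Voronoi regions per
  hemisphere (116 total, matching the cardinality of the standard
  anatomical parcellation).  Real atlas label tables can be supplied;
  none is bundled.  The toy brain's absolute tissue totals are far
  below physiological values (a ~19 mL miniature); all couplings are
  relative, so no analysis depends on that scale.
* **Voxel model** (additive generator):
  `y_iv = p_v·[m_r + b_r·Δa + q_r·Δa² + h_r·ΔTIV + λ_r·g_i] + ε_iv`,
  clipped at 0, with `g_i` a shared standard-normal global factor and
  `p_v` a partial-volume weight.  Region means `m_r ~ U(0.4, 0.9)`;
  decline rates are drawn as *fractions of the mean per year*,
  `b_r = −m_r·U(0.001, 0.004)` (0.1–0.4 %/yr, a realistic adult range),
  which makes slope magnitude proportional to local mean with a
  between-region spread — the minimal mechanism for the slope–LGM
  coupling.  Quadratic terms are small and negative, TIV coupling is a
  modest fraction of the mean, and the global loading `λ_r` is either
  heterogeneous (`m_r·U(0.005, 0.06)`) or common (`0.03·m_r`).
* **Partial volume**: `p_v = floor + (1−floor)·(1 − d/d_max)`, linear
  in normalized distance from the region centroid (1 at the centroid,
  0.3 at the rim by default).  Voxel noise sd 0.04 keeps the
  negative-value clip rate well below 1% (it is recorded, and a
  warning fires if exceeded).
* **Smoothing** 8 mm FWHM isotropic Gaussian with mirrored boundaries
  (sigma = FWHM/2.355/voxel size).  Reflect padding approximately
  preserves image totals, unlike the implicit zero padding of common
  neuroimaging tooling; the difference is negligible at this scale but
  is a documented divergence.
* **Globals from images**: TGM is *defined* as the voxel integral of
  the subject's unsmoothed ("native") image, so conservation is exact
  by construction; TCSF is rebalanced so TIV = TGM + TWM + TCSF holds.

Seeds: a master seed expands into per-stage child seeds through
`SeedSequence(master).spawn(n)`, each reduced to 31 bits; stages draw
children in a fixed documented order.  All generators are bit-for-bit
deterministic given their seed.

### The proportional (Global-Scaling-correct) regime

`generate_proportional_dataset` produces
`y_iv = G_i · (p_v·m_r + ε_iv)` with `G_i = (1 − 0.004·Δa)·u_i` and
`u_i` lognormal (sd 0.03): the whole image, measurement noise included,
scales with the subject's global factor.  Noise placed *inside* the
scaling is deliberate: with additive (unscaled) noise, dividing by an
age-declining global makes the scaled residual variance age-dependent,
and that heteroskedasticity alone inflates the Bonferroni familywise
error of the null decline contrast to roughly 13% per replicate — a
calibration artifact of the noise model, not a property of the method.
In the fully proportional world the scaled data are exactly i.i.d. in
age and the null calibration is clean.  With `noise_sd = 0` every voxel
is exactly proportional to TGM and Global Scaling zeroes the age slope
identically.

ROI-level counterparts (`generate_roi_dataset`,
`generate_proportional_roi_dataset`) draw per-region means directly
with the ROI-scale noise level (0.006, matching voxel noise averaged
over a typical region) and define TGM as a volume-weighted sum over
regions; they are used where image resolution adds nothing (e.g. the
cross-validation studies).

### What passing tests do and do not show

The generator reproduces the statistical *structure* the analyses
assume — polynomial age trends, a shared global factor, partial-volume
slope attenuation, sex differences in TIV — but not segmentation error,
registration misalignment, spatially correlated noise beyond the
applied smoothing, site effects, or non-Gaussian biological
heterogeneity.  Passing tests therefore demonstrate internal
correctness and the qualitative behavior of the adjustment methods in
their intended regimes, not quantitative agreement with any real
cohort.

## Local Covariation recovery: the partialled truth

With TGM in the model, the population age coefficient is *not* the raw
generative slope.  Writing the ROI mean as
`ȳ_r = p̄_r(m_r + b_r Δa + … + λ_r g) + ε̄` and
`t = Σ_r S_r(m_r + b_r Δa + … + λ_r g)·v` (S_r the sum of
partial-volume weights, v the voxel volume), substituting
`g = (t − … − B·Δa)/Λ` with `B = Σ S_r b_r` and `Λ = Σ S_r λ_r` gives
the conditional slope

    slope_r | TGM  =  p̄_r · (b_r − λ_r·B/Λ).

The coverage checks target this quantity; noise-driven attenuation of
the TGM coefficient is negligible at the default settings (the noise
contribution to TGM's variance is orders of magnitude below the global
factor's).  Raw `b_r` is the correct target only for the unadjusted
model, and is verified there (95% CI coverage ≥ 93% across 200
replicates).

## Split-half cross-validation

Each iteration splits the cohort in half (optionally stratified by sex
and decade; odd cells alternate the extra subject), fits the adjusted
model on the training half, and scores the held-out half:

* the test half is adjusted with *its own* parameters — scaled by its
  own TGM under Global Scaling, or with the TGM fit re-estimated on the
  test half jointly with the test nuisance under Local Covariation;
* test-half nuisance (per-sex constants, TIV) is re-estimated and
  residualized out before computing TSS and RSS — otherwise train-half
  intercept offsets dominate the test error;
* the prediction `X_age,test·β_age,train` (age columns built with
  training centering by default; `test_centering="test"` is available)
  is projected off the same test nuisance space removed from the data,
  so both sides of the comparison live in that space and a perfectly
  estimated noiseless model scores exactly R² = 1;
* `R²_test = 1 − RSS/TSS`; negative values are retained, not floored,
  so medians stay unbiased.

Summaries are per-iteration ROI means (histograms), per-ROI
across-iteration medians, and per-method win counts on those medians.
The headline design uses 10,000 iterations; the package default is
1,000 — the summaries are medians and stabilize well below that, which
the suite exercises at 200–1,000 iterations.

### The two generative regimes

On heterogeneous additive-coupling data, Local Covariation is the
correctly specified adjustment: it removes the global factor exactly,
while Global Scaling leaves a residual `(λ_r − m_r Λ/M)·g` in every
region whose loading is not proportional to its mean.  The result is a
large, stable generalization advantage for Local Covariation (mean
held-out age R² higher by ~0.1–0.25 across datasets, a winning majority
of ROIs).

On proportional data the comparison is a structural near-tie, because
the proportional model (`y ∝ t`) is *nested* in the affine model Local
Covariation fits: both adjustments are then correctly specified, and
Global Scaling's only possible edge is small-sample parsimony, which
coherent scoring largely cancels.  Empirically the per-ROI median
test-R² differences on proportional data are of order 3·10⁻⁴ —
indistinguishable from zero — and the per-ROI win split hovers at
58/58 of 116 across seeds and noise structures (additive, globally
scaled, per-region multiplicative; collinearity between TGM and age
swept to 0.99).  The suite therefore asserts the robust statement:
Local Covariation's advantage is substantive on additive data and
collapses to a tie on proportional data.  A strict Global Scaling
majority on proportional data is not a stable property of any
parameterization examined.

## ROI analysis

Ranking averages the voxelwise *parameter-estimate* map within each
region (in-mask voxels only; regions with no in-mask voxels are
reported missing), sorts ascending (fastest decline first) and breaks
ties by atlas label order, recorded in the output.  Per-ROI age
summaries instead *refit* the GLMs on ROI-mean data; both aggregations
are provided and labelled distinctly.  TIV-residualized ROI values
(grand mean restored) are provided for plotting.  Kendall's tau between
mode rankings is reported, never assumed.

Normality checks use the Kolmogorov–Smirnov statistic with estimated
mean and SD, calibrated by a seeded Monte-Carlo null (2,000 draws with
parameters re-estimated per draw — the Lilliefors correction).  The
statistic matches the standard implementation exactly; the Monte-Carlo
p agrees with its table-based approximation and is preferred for
seeded reproducibility.  Constant input is reported as p = 0 with a
warning.

## Slope-vs-LGM coupling

The Pearson correlation across in-mask voxels between the sex-averaged
linear slope and the constant (LGM) map, recomputed after dividing the
slope by the LGM.  Units with |constant| below 10⁻³ density units are
excluded from both computations (the same floor as Local Scaling, which
avoids division blow-up in low-GM voxels).  The sampling error of the
constant term is ignored when treating LGM as an axis — it is well
below 1% of the constant on the default configuration — but its mean
relative magnitude is reported for transparency.  A 200×200 2-D
histogram summarizes the voxel scatter in place of a full-resolution
density plot.

## Pipeline and problem sizes

`run_pipeline` executes simulate → globals → mask → fit (per mode) →
ROI ranking → LGM → cross-validation → toy demo, records every artifact
with a SHA-256 checksum and its stage seed in `manifest.json`, writes
NIfTI uncompressed so reruns are byte-identical, and isolates failures
per adjustment mode.  The toy (two-region) demo fits the models of the
introductory example exactly as stated there — age and constant only,
no TIV and no sex terms, age centered so the constant is the mean —
which is a documented divergence from the main pipeline's designs.

The shipped tests and the acceptance script run the full 420-subject
cohort on the 24³ grid (the package's reference problem size), with
12³–16³ grids and 8–16 regions for unit-level checks, 100 proportional
null replicates, 50 slope-LGM replicates, 1,000 cross-validation
iterations, and 500 permutation-FWE replicates at 100 permutations
each.

## Known limitations

* No random-field-theory or cluster-extent inference; voxelwise
  Bonferroni and max-T permutation only.
* No registration, reslicing or segmentation; the generator starts
  where preprocessing ends.
* The Global Scaling grand-mean re-multiplication (on by default, so
  scaled values stay interpretable densities) affects beta magnitudes
  only; tooling differs on this convention and it is configurable.
* The Fig-style toy demo and the main pipeline intentionally differ in
  design (no TIV/sex terms in the toy models).
* Single-sex cohorts are handled by dropping the absent sex's columns
  with a warning; cohorts below ~10 subjects per half cannot support
  the full per-sex quadratic design in cross-validation.
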