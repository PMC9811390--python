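# Methods

`mbdeform` quantifies tumor mass effect in pediatric medulloblastoma (MB)
as a *deformation-heterogeneity* radiomic descriptor of the brain-around-
tumor (BAT) region, and relates that descriptor to the four consensus
molecular subgroups (WNT, SHH, Group 3, Group 4) and to overall survival.
This note records the models, the parameter choices where the design was
genuinely open, and what the synthetic validation does and does not show.

## Deformation-magnitude maps

A growing tumor displaces the surrounding parenchyma. On Gd-T1w MRI this
is measured by deformable registration against a healthy age-appropriate
atlas: the atlas is non-rigidly registered to the subject (affine
initialization, then a three-level multi-resolution B-spline free-form
deformation driven by Mattes mutual information with 32 bins; control-point
spacing refines 40 → 20 → 10 mm), the forward field is inverted by
fixed-point iteration (converged when the composition residual RMS is
below 0.1 voxel), and the per-voxel Euclidean norm of the inverse field —
the tissue displacement of the subject into atlas space, in mm — is the
deformation-magnitude map.

Two details matter:

- **Tumor exclusion.** The infiltrating T2/FLAIR-hyperintense region has no
  atlas counterpart, so its voxels are excluded from the metric (metric
  masking), and the region is additionally neutralized by a
  nearest-boundary fill — *not* zero-filled, which would create an
  artificial edge. The fill matters because the multi-resolution pyramid
  smooths intensities across the mask boundary before sampling; with it,
  the recovered field is exactly independent of what is inside the tumor —
  a unit test edits tumor voxels and asserts a bit-identical field.
- **Metric sampling per resolution level.** Sampling percentages are
  (100%, 50%, 25%) from coarse to fine. Sparse sampling on the coarse level
  (which may hold only a few hundred in-mask voxels) lets the B-spline chase
  sampling noise and produces spurious ~1-voxel deformation even for
  identical images; full coarse-level sampling removes this at negligible
  cost.

Age-to-atlas assignment uses half-open brackets [0,1), [1,5), [5,10),
[10,18) years, with ages at a boundary going to the older atlas and ages
above 18 clamped to the oldest.

Approximate diffeomorphism is enforced post hoc: the Jacobian determinant
of (Id + u) is checked, and the field is Gaussian-smoothed (3 mm, up to 3
passes, with a warning) if folding is detected.

## Band features

Distances are measured from the tumor infiltrating edge as the
anisotropic-spacing Euclidean distance transform of the tumor-mask
complement (nearest tumor *voxel*; no sub-voxel surface model). Twelve
cumulative annular bands cover 0 < d ≤ 5k mm, k = 1…12 — each band
includes all inner margins — clipped to the brain mask. Five statistics of
the in-band magnitudes give the 60-feature descriptor in stat-major order
`M_5…M_60, MD_5…, STD_5…, SK_5…, K_5…K_60`:

- M (mean), MD (median), STD (population standard deviation, ddof = 0),
- SK = m₃/m₂^{3/2} (population skewness),
- K = m₄/m₂² − 3 (population excess kurtosis).

Conventions for degenerate inputs: a zero-variance band reports SK = K = 0
(so constant phantoms stay well-defined); an empty band reports NaN for
all five statistics. A disjoint-shell mode ((5k−5, 5k]) exists but is
non-default.

## Synthetic ground truth

Real MB cohorts are not public, so every stage is validated on phantoms
with known truth.

**Geometry and appearance.** The phantom brain is an axis-aligned ellipsoid
(default semi-axes 60 × 70 × 58 mm on a 52 × 60 × 52 grid at 2.5 mm —
child-head scale at a resolution where a cohort of hundreds of subjects is
computable in minutes). Intensities are concentric tissue shells (four
levels spanning CSF-to-WM-like contrast), optionally plus a smooth seeded
random texture (Gaussian-filtered noise, 10–12 mm correlation length) that
gives the MI metric gradients away from shell boundaries — without it,
deformable registration of piecewise-constant phantoms is ill-posed in the
flat interior — and iid Gaussian noise.

**Displacement model.** For a voxel at distance d from the surface of a
spherical tumor (radius R) and azimuth θ about the z-axis through the
tumor center,

    m(d, θ) = A0 · (1 + h·cos(kθ)) · exp(−d/τ),

applied along the radial unit vector and zero inside the tumor. A0 (mm)
is the peak displacement at the tumor edge, h ∈ [0, 1] the angular
heterogeneity, k the harmonic (default 2: a bilobed push), τ the decay
length (default 15 mm, so mass effect is appreciable across the measured
0–60 mm range). Subjects are defined by pull-back, I_subj(x) =
I_atlas(x − u(x)), with a bright sphere painted in as tumor — so the
returned u is *exactly* the displacement a perfect registration should
recover on the subject grid, not an approximation to it.

**Analytic band features (quadrature oracle).** Because m depends only on
(d, θ), band statistics over a spherical shell are weighted moments of m
on a dense (d, θ) grid with weight (R + d)² (the polar integral is
constant). This path shares no code with the voxel path (no distance
transform, no rasterization) and deliberately ignores the brain boundary,
which is what makes it an independent oracle: rasterized and analytic
features agree to ≈2–5% at 1.5 mm voxels for bands fully inside the brain.
The fourth moment (kurtosis) converges slowest in voxel size and is
checked at 10%. Outer bands that a real brain boundary clips are *meant*
to disagree — the voxel path clips, the oracle does not.

**Cohort simulation.** Each subject draws a subgroup from configurable
proportions (default WNT 10%, SHH 30%, G3 15%, G4 45% — the WNT-poor,
Group-4-heavy mix of consecutive pediatric series), then (A0, h) around
per-subgroup means following the clinical aggressiveness gradient — WNT
(2.0 mm, 0.20), SHH (2.8, 0.35), G4 (3.5, 0.50), G3 (4.5, 0.65) — with
jitter SDs 0.6 mm and 0.08, tumor radius 10 ± 1.5 mm, and age from a
log-normal (median 5 y) matching pediatric MB presentation. Survival
follows an exponential proportional-hazards model: the linear predictor is
β·z(x_true) with x_true the subject's own ground-truth band features
z-scored across the cohort (so β is a per-SD log hazard ratio; the default
{K_10: 1} makes peritumoral kurtosis the prognostic feature), baseline
rate 1/1500 events/day (mean OS ≈ 4 years for the baseline subject),
censoring uniform on (0, 3000) days. Chang class, extent of resection and
metastasis are Bernoulli(0.5) pass-through covariates. All randomness
derives from one seed via named streams, so e.g. the survival draw can be
reproduced without regenerating images.

**What the phantoms do not show.** No MR contrast physics, no skull/CSF
compartments, no infiltration (the tumor is a sphere), no biomechanics
(the radial-decay model is phenomenological), single focal tumor, and the
survival model is exactly proportional hazards — so passing tests
demonstrate the *pipeline's* correctness and statistical operating
characteristics under its stated model, not clinical performance.

## Preprocessing

Bias correction fits an order-3 polynomial to in-mask log-intensities and
divides out the exponentiated field (unit geometric mean in the mask,
arithmetic in-mask mean preserved within 1%). This is a deliberately
desk-scale multiplicative-field corrector honoring the same contract as
N4; an external N4 implementation can be substituted upstream.

Intensity standardization is piecewise-linear landmark matching: template
landmarks are the mean in-mask percentile intensities of a random
~10% of the cohort (minimum two volumes) at percentiles
{1, 10, 20, …, 90, 99}; each volume's landmarks are mapped onto the
template's with linear interpolation between and linear extrapolation
beyond. The map is monotone and idempotent to within interpolation error.

## Subgroup statistics

The analysis chain is: greedy correlation pruning in canonical column
order (drop a column whose |Pearson r| with any retained column exceeds
0.95 — deterministic and order-stable), per-column z-scoring with stored
training parameters, one-way ANOVA per feature across the four canonical
subgroups (groups with < 2 members excluded with a warning; transitional
G3/G4 and missing labels excluded), and Tukey-HSD post-hoc pairs for
significant features. Per-feature p-values are reported without
across-feature correction (Benjamini–Hochberg can be applied downstream).
On null cohorts the full chain's per-feature type-I error is ≈4–5% at
α = 0.05 (computed by the acceptance script over 500 replicates).

Semantic tumor features (horizontal/vertical position, necrosis,
brainstem involvement, contrast uptake) are tested one-vs-all across five
groups (including G3/G4): Fisher's exact test for two-level features,
Pearson chi-square otherwise, with low-expected-count warnings and an
explicit skipped status for single-level features.

Hierarchical clustering of subjects on significant features uses Ward
linkage on Euclidean distances with a two-cluster cut.

## Survival analysis

- **Split:** stratified by subgroup at the requested fraction (default
  70/30), singleton strata to training.
- **LASSO-Cox:** coxnet path (L1), penalty chosen by 3-fold CV minimizing
  held-out Breslow partial-likelihood deviance ("min" rule; "1-SE"
  available). Folds are re-drawn until every fold contains an event.
  Nonzero coefficients define the radiomic risk score
  RRS(x) = Σ coefⱼ·zⱼ(x).
- **Cutpoint:** grid search over midpoints of consecutive unique training
  scores, both groups ≥ 10% of subjects, maximizing the log-rank
  chi-square; ties go to the lower cut; no optimism correction. The
  training cutpoint is transferred unchanged to the test cohort.
- **Log-rank:** standard observed-minus-expected form with hypergeometric
  variance (implemented in-package; equal to lifelines to 9 digits on
  random data).
- **Cox models:** lifelines (Efron ties), per-stratum hazard ratios with a
  configurable baseline stratum printed as HR = 1; rows missing a model
  covariate (e.g. unknown subgroup) are dropped with a logged count.
  Separation is flagged, and a small ridge penalty is the fallback when
  the unpenalized fit fails outright.
- **C-index:** Harrell's, ties at 1/2; SE by the binomial-style
  approximation √(C(1−C)/m) over the m comparable pairs — an intentional
  simplification, adequate for phantom-scale comparisons.
- **Agreement:** McNemar on discordant cells (no continuity correction;
  b + c = 0 ⇒ p = 1) and Pearson chi-square independence (no Yates
  correction; empty rows/columns dropped with a warning).

## Numerical and testing choices

- Problem sizes: the registration-recovery experiment uses a 64³, 2 mm
  phantom (A0 = 4 mm, τ = 10 mm) and achieves MAE ≈ 10% of A0 in the
  0–30 mm shell (bound: 20%); cohort experiments use 210 subjects
  (150/60 split, 20 replicates), LASSO operating characteristics n = 200
  with 20 features (50 replicates), type-I control n = 80 (500
  replicates).
- The end-to-end stratification experiment injects ground-truth fields
  (the pipeline's first-class bypass) so that its pass/fail reflects the
  feature and survival stages, not registration error; registration
  accuracy is measured separately.
- Distance maps are validated against an O(n²) brute-force
  nearest-tumor-voxel oracle exactly; band statistics against hand-computed
  moments and scipy's population conventions; ANOVA against the textbook
  sum-of-squares formula; Fisher against hypergeometric enumeration;
  partial likelihood against an O(n²) brute force.

## Known limitations

Oblique NIfTI affines are rejected rather than resampled; registration
accuracy is only characterized on phantoms (real pediatric MRI has
contrast and artifact structure the phantoms lack); the X-tile-style
cutpoint has no optimism correction, so training log-rank p-values are
anti-conservative by construction (as in the emulated workflow); the
polynomial bias corrector is not a full N4 replacement for strong
high-frequency inhomogeneity.
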