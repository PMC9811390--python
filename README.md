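# mbdeform

Deformation-heterogeneity radiomics for pediatric medulloblastoma (MB).

A growing MB tumor displaces the surrounding parenchyma (mass effect), and
the magnitude and heterogeneity of that displacement in the brain-around-
tumor (BAT) region carry information about tumor biology. `mbdeform`
turns a Gd-T1w volume, a tumor mask and an age-matched atlas into:

1. a **per-voxel deformation-magnitude map** — the Euclidean norm ‖u(x)‖
   of the tissue displacement field obtained by tumor-masked deformable
   registration of the subject to an age-appropriate atlas (B-spline FFD,
   mutual information, inverse mapping);
2. a **60-feature band descriptor** — five statistics (mean M, median MD,
   standard deviation STD, skewness SK, excess kurtosis K) of ‖u‖ in each
   of 12 cumulative annular bands at distance 0 < d ≤ 5k mm (k = 1…12)
   from the tumor infiltrating edge;
3. **subgroup statistics** — correlation pruning, z-scoring, one-way ANOVA
   of each feature across the WNT / SHH / Group 3 / Group 4 molecular
   subgroups with Tukey-HSD post-hoc pairs, one-vs-all Fisher/chi-square
   tests of semantic tumor features, and Ward hierarchical clustering;
4. a **radiomic risk score (RRS)** — RRS(x) = Σⱼ βⱼ zⱼ(x) over the band
   features selected by a 3-fold cross-validated LASSO-Cox model,
   dichotomized at the training cutpoint that maximizes the two-group
   log-rank χ², with Kaplan–Meier curves, per-stratum Cox hazard ratios
   (baseline stratum HR = 1), Harrell's C-index, and McNemar / chi-square
   agreement tests against Chang and molecular risk stratifications.

Because real pediatric MB cohorts are not public, the package ships a
first-class synthetic module: phantom brains deformed by a tumor-centered
radial field m(d, θ) = A₀(1 + h·cos kθ)e^(−d/τ) with exact ground-truth
displacement per voxel, and cohorts whose survival is drawn from a
proportional-hazards model on each subject's own ground-truth band
features. Every pipeline stage is validated against that truth. See
`docs/methods.md` for the models, defaults and their rationale.

Intended users: imaging scientists building peritumoral / mass-effect
radiomics pipelines, and methodologists who need a fully synthetic,
ground-truthed testbed for registration-derived features and survival
model selection.

## Worked example

A complete in-memory run on an 88-subject synthetic cohort:

```python
import numpy as np
from mbdeform import synthetic, subgroups, survival

ccfg = synthetic.CohortSimConfig(n_subjects=88, seed=7)
cohort = synthetic.generate_cohort(ccfg)   # features + clinical table

# Experiment 1: which band features separate the molecular subgroups?
res = subgroups.run_subgroup_analysis(
    cohort.features, cohort.clinical["subgroup"].to_numpy()
)
print(res[res.comparison == "omnibus"].nsmallest(3, "p")
        [["feature", "statistic", "p"]].to_string(index=False))

# Experiment 2: LASSO-Cox risk score and survival stratification
ex = survival.rrs_stratification_experiment(
    cohort.features, cohort.clinical, train_fraction=0.7, seed=7
)
print("selected:", ex.model.selected_features)
print(f"cutpoint: {ex.model.cutpoint:.3f}")
print(f"train log-rank chi2 = {ex.train_km.chi2:.2f}, p = {ex.train_km.p:.2e}")
print(f"test  log-rank chi2 = {ex.test_km.chi2:.2f}, p = {ex.test_km.p:.2e}")
```

which prints:

```
feature  statistic            p
   SK_5  84.955516 2.324067e-25
  STD_5  59.648360 9.377863e-21
  SK_40  56.346320 4.663097e-20
selected: ['SK_5', 'SK_15', 'SK_40']
cutpoint: 1.014
train log-rank chi2 = 34.55, p = 4.16e-09
test  log-rank chi2 = 8.58, p = 3.39e-03
```

Read: skewness of the deformation magnitudes (SK, the heterogeneity
signature) is the strongest subgroup discriminator in this simulated
cohort — by construction, since the simulated subgroups differ in
amplitude A₀ and heterogeneity h — and the LASSO-selected skewness
features produce a risk score whose low/high dichotomy separates overall
survival on both the 70% training and the held-out 30% test cohort.

The same steps are scriptable from the shell (`mbdeform simulate`,
`mbdeform preprocess`, `mbdeform register`, `mbdeform extract`,
`mbdeform subgroups`, `mbdeform survival`); volumes, masks and fields are
read and written as NIfTI, tables as CSV.

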