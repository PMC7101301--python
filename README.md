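# voxdose

Monte Carlo voxel-wise internal dosimetry for ¹⁷⁷Lu peptide receptor
radionuclide therapy (PRRT), with robust alpha-stable lesion-dose
summaries and cohort statistics.

## The problem

Patients with somatostatin-receptor-positive neuroendocrine tumors are
treated with ¹⁷⁷Lu-labelled somatostatin analogs (DOTATOC/DOTATATE).
¹⁷⁷Lu emits soft betas (mean ≈ 134 keV, endpoint 498 keV, range < 2 mm)
plus imageable gammas at 113 and 208 keV, so serial quantitative
SPECT/CT can track the activity a(r,t) in kidneys, spleen and every
tracer-positive lesion. Standard MIRD dosimetry folds this into
organ-level S-values on a reference phantom; `voxdose` instead computes
a patient-specific, voxel-wise absorbed dose map:

1. **Kinetics** — activity in each region, measured at t = 4, 24, 48,
   72 h, is fit by a mono-exponential washout a(t) = a₀·e^(−t/τ)
   (least squares in linear space). The time-integrated activity (TIA)
   is the analytic integral A = a₀·τ, the number of decays. The same
   fit runs per voxel; voxel TIAs are normalized within each region and
   scaled by the region-level TIA, giving a per-voxel decay map.
2. **Monte Carlo dose** — the decay map and the CT-derived mass density
   map (ρ = 1 + HU/1000) feed a voxel Monte Carlo engine: betas deposit
   locally (range < voxel) or along straight CSDA tracks; photons are
   ray-traced with photoelectric absorption and Klein–Nishina Compton
   scattering. Output is dose in Gy with per-voxel batch standard
   errors. A dose-point-kernel convolution mode provides the
   homogeneous-medium cross-check.
3. **Lesion summary** — voxel-dose histograms inside lesions are
   asymmetric and heavy-tailed, so each lesion is summarized by a
   four-parameter alpha-stable fit (impulsiveness α, skewness β, scale
   γ, location μ) after a single-pass Mahalanobis filter
   (|x−mean|/sd < 1). The lesion dose D is the fitted location μ.
4. **Patient/cohort statistics** — the total tumor dose is the
   volume-weighted mean over lesions,
   TTD = Σᵢ Dᵢ·Vᵢ / Σᵢ Vᵢ,
   and the cohort stage computes means ± population SD, dose per
   injected activity (mGy/MBq), Pearson correlations of TTD with
   chromogranin A (CgA), and Wilcoxon rank-sum comparisons by tumor
   grade. A transcribed 14-patient, 198-lesion cohort table ships as a
   packaged fixture.

A digital-phantom simulator (ellipsoidal structures with known a₀, τ,
HU; Gaussian PSF blur; signal-proportional noise) provides ground truth
for every stage, so the whole chain is testable without patient data.

## Worked example

Simulate a liver lesion (radius 12 mm, a₀ = 150 kBq/mL, τ = 70 h) and
run the full chain:

```yaml
# phantom.yaml
grid_dims: [20, 20, 20]
structures:
  - {name: lesion_1, category: liver, center_mm: [47.9, 47.9, 47.9],
     radii_mm: 12.0, a0_kbq_ml: 150.0, tau_h: 70.0}
noise_scale: 0.05
n_histories: 100000
seed: 7
```

```bash
voxdose full-run phantom.yaml --out run1
```

prints (abridged):

```
 label     name category  voxels  volume_ml  dose_gy  alpha  beta    gamma       mu  outliers_removed status
     1 lesion_1    liver      81   8.902081 0.817767    2.0   0.0 0.008331 0.817767                23 stable
```

The lesion covers 81 voxels (8.90 mL). Its voxel-dose histogram is
nearly Gaussian here (α = 2.0) with location μ = 0.818 Gy — the
reported lesion dose per cycle. The Mahalanobis filter removed 23 of 81
voxels (threshold 1 removes ≈32% on Gaussian data by construction —
the filter rule is kept as specified, not "fixed"). The closed-form
self-irradiation dose for these kinetics is a₀·V·τ·(decays/kBq·h)·Ē/m ≈
0.83 Gy; the small deficit is photon escape from a 9.6 cm phantom.

Other subcommands: `simulate`, `fit-kinetics`, `dose`, `lesion-stats`,
`cohort-stats` (each a thin wrapper over the library; see `--help`).

```bash
voxdose cohort-stats           # summaries/correlations of the fixture
```

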