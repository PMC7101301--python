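# Methods

This note documents the models, parameters, numerical choices and
validation design of `voxdose`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Grids, units and containers

All volumes in a run share one voxel grid (`VoxelGrid`): 0-based
indices, voxel-center world coordinates in mm, no implicit resampling.
The default spacing is 4.79 mm isotropic, the resolution of a
128×128 quantitative SPECT reconstruction with CT downsampled to match;
the voxel volume is 4.79³/1000 = 0.1099 mL. Activity images are
calibrated concentrations in kBq/mL; dose maps are Gy (J/kg). Grid
equality is checked to 10⁻⁶ mm and violations name the offending axis.
NIfTI-1 is the on-disk format (nibabel), with an RAS+ diagonal affine;
label masks carry a JSON sidecar mapping label → (name, category).

## Nuclide data (¹⁷⁷Lu defaults, editable YAML)

* physical half-life 160.8 h (6.7 d); beta endpoint 498 keV and maximal
  range ≈ 2 mm in soft tissue (both below one voxel).
* beta spectrum: three-branch discrete approximation at the branch mean
  energies (47.0, 111.7, 149.4 keV with intensities 0.116/0.090/0.794),
  overall mean 134.1 keV. For local-deposition transport only the mean
  matters; the discrete branches add the correct spectrum variance to
  the tallies.
* photon lines: 112.95 keV (6.17%), 208.37 keV (10.36%), plus the two
  weak lines at 249.7/321.3 keV (≈0.2% each); photon energy per decay
  ≈ 30 keV, total ≈ 164 keV per decay.
* water interaction tables, log-log interpolated: incoherent scattering
  from the free-electron Klein–Nishina cross section × electron density
  of water (3.343·10²³ e/g); photoelectric from a power law (~E^−3.05)
  anchored to tabulated water values near 100 keV; electron CSDA ranges
  from standard range tables. Coherent scattering and bound-electron
  effects are omitted (≤ a few percent of the attenuation at the ¹⁷⁷Lu
  lines and irrelevant to energy balance, which is exact by
  construction).

## Kinetics

The washout model is a single exponential anchored at injection,
a(t) = a₀·e^(−t/τ), fit by *unweighted least squares in linear space*
— linear-space residuals weight the high early-activity points the way
signal-proportional reconstruction noise suggests. For fixed τ the
amplitude is closed-form, so the fit is a 1-D profile minimization over
τ solved deterministically: a 240-point logarithmic bracket grid over
τ ∈ [10⁻², 10⁵] h followed by golden-section refinement to machine
precision. A dense-grid SSE search is the independent oracle in the
tests. Degenerate inputs: all samples ≤ 0 → `failed`; a non-decaying
TAC (SSE minimum at the τ boundary) → `fallback`.

TIA is the analytic 0→∞ integral A = a₀·τ (kBq·h), ×3.6·10⁶ decays per
kBq·h. There is no uptake phase: activity before the 4 h scan is
extrapolated by the same exponential. τ is deliberately *not* clamped
to the physical half-life — apparent effective half-lives above 160.8 h
occur in measured tumor TACs (continued uptake between scans) and are
reported with a warning, not altered.

Voxel-wise TIA: each voxel's TAC (concentration × voxel volume) is fit
independently (vectorized over the ROI); voxel TIAs are normalized to
fractions summing to 1 (±10⁻⁹) and scaled by the ROI-level fit's TIA.
This two-step scheme makes the voxel map exactly consistent with the
ROI total while keeping relative intra-ROI structure; the alternative
(absolute scale from the voxel-TIA sum) is exposed as
`absolute_scale="voxel_sum"`. Voxels whose own fit fails keep the ROI τ
and refit only their amplitude; the count is reported.

## Monte Carlo dose engine

Per history: an emission voxel is sampled from the source
probabilities (inverse-CDF), the position uniform inside the voxel; one
beta per decay with branch energy from the spectrum; each photon line
fires with its yield.

* **Betas, `local` mode (default):** the full sampled energy is
  deposited in the emission voxel — justified because the CSDA range at
  the spectrum mean (≈0.14 mm) and even at the endpoint (≈1.8 mm) is
  below the 4.79 mm voxel.
* **Betas, `track` mode:** straight-line isotropic transport; the
  electron's water CSDA range scales as 1/ρ and energy is deposited
  uniformly per water-equivalent path length crossed, voxel by voxel.
* **Photons:** exact ray stepping (distance-to-boundary marching)
  through the density grid with μ(E) = (μ/ρ)_water·ρ; interaction type
  chosen photoelectric vs incoherent by cross-section ratio;
  photoelectric deposits the full energy locally; Compton scattering
  angle/energy sampled from Klein–Nishina by Kahn's rejection method,
  the recoil electron deposited on the spot; scattered photons are
  followed until they fall below the cutoff (default 20 keV, then
  deposited locally) or leave the grid. No coherent scattering, no
  bremsstrahlung, no secondary electron transport.
* **Uncertainty and determinism:** histories are split into batches
  (default 10), each with an RNG stream spawned deterministically from
  the master seed (`SeedSequence(seed).spawn`). The per-voxel relative
  SE is the batch standard error; identical (inputs, seed, config) give
  bit-identical dose maps. Energy bookkeeping (emitted = deposited +
  escaped) is tracked and asserted in tests; with photons off and local
  betas the balance is exact to float precision.
* **`uniform_density` mode** replaces the patient density by 1 g/cm³ —
  the package's simplified stand-in for reference-phantom dosimetry.

The **kernel-convolution mode** precomputes a per-decay
energy-deposition kernel by running the same engine for a single-voxel
source in uniform water, then convolves the absolute decay map with it
(FFT). It is valid only for uniform density (enforced), is linear in
the source by construction, and serves as the independent cross-check
against direct transport.

The closed-form **equilibrium dose** D = N·Ē/m (infinite uniform
self-irradiating medium) is the analytic oracle. The validation phantom
is a 41³ grid at 10 mm spacing (half-width ≈ 5 mean free paths of the
208 keV photons), and the check compares the *mean over the central 5³
region* with its batch standard error: at 10⁵ histories a single
central voxel receives ~1 decay, so a central-voxel comparison would be
statistically vacuous; the region mean makes the 3-SE criterion
meaningful. Batch-level region statistics require `keep_batches=True`.

## Lesion statistics

Voxel-dose histograms in lesions are asymmetric and heavy-tailed, so
lesions are summarized by an alpha-stable law in the standard (S1)
parameterization, whose characteristic function has the α ≠ 1 branch
exp(−|γω|^α[1 − i·sign(ω)·β·tan(πα/2)] + iμω) and the α = 1 branch with
the (2/π)·log|ω| term. φ(0) = 1 and |φ(ω)| = e^(−|γω|^α) are property-
tested.

**Outlier rejection** uses the univariate Mahalanobis distance
d = |x − mean|/sd with the population-sd convention (n denominator —
the same convention that reproduces the cohort table's printed SDs),
keeping d < 1 in a *single pass*. On Gaussian data this removes ≈32% of
voxels; the rule is preserved as specified and the removed fraction is
logged, not "corrected". A second pass could remove more; exactly one
is made. Distances use raw sample moments, not the fitted law.

**Stable fit** (deterministic, no density inversion): quantile
initialization — α from the tail ratio (q95−q05)/(q75−q25) and γ from
the IQR via a table precomputed from the symmetric stable law — then
three iterations of empirical-characteristic-function regression on the
fixed grid ω = 0.1, 0.2, …, 1.0 of the standardized sample:
log(−log|φ̂|²) vs log ω gives (α, γ); the unwrapped phase regressed on
(ω, ω^α·tan(πα/2)) gives (μ, β), with the special α ≈ 1 design using
the ω·log ω regressor. β is pinned to 0 above α = 1.99 where it is
unidentifiable. Recovery tolerances verified at n = 10⁴: Gaussian
(α ∈ [1.9, 2], γ = sd/√2 ± 10%, μ ± 0.1), Cauchy (α = 1 ± 0.1,
μ ± 0.2), and a skewed case (1.6, 0.6, 0.2, 1.2). scipy's stable
distribution is used only as the *sampler* in these tests, never in the
fit path.

The lesion dose D is the fitted location μ, clamped into the range of
the kept voxel doses (the fit can stray outside on badly non-stable
inputs); lesions with constant dose report that value (`degenerate`),
and lesions with fewer than 20 kept voxels report the median of the
kept doses (`small`) — single-voxel-scale lesions exist in real
cohorts, so this path is first-class.

## Patient and cohort statistics

TTD = Σ Dᵢ·Vᵢ / Σ Vᵢ (volume-weighted mean lesion dose; invariant to
volume rescaling, bounded by the min/max lesion dose). Dose per
injected activity is dose·1000/activity in mGy/MBq. Summaries use the
population SD. Pearson correlations use the two-sided t transform. The
Wilcoxon rank-sum test is implemented with midranks: exact enumeration
of all C(n₁+n₂, n₁) assignments for groups of ≤ 10 (two-sided on the
deviation of the rank sum from its mean), otherwise the tie-corrected
normal approximation. The CgA change is defined post − pre, so a
dose-driven marker decline yields a negative correlation with TTD.

## Packaged cohort fixture and its provenance

`voxdose/data/cohort_table.csv` + `lesion_table.csv` transcribe a
published 14-patient, 39-cycle, 198-lesion ¹⁷⁷Lu-DOTATOC per-cycle
dosimetry table. The dose columns (kidney, spleen, per-category lesion
doses with counts, TTD) reproduce the published summary row exactly:
kidney 3.41 ± 1.28 Gy (1.91–6.22), spleen 4.40 ± 2.90 Gy, TTD
9.70 ± 8.96 Gy (max 39.49), category counts 155/16/18/7/2, and the
single-lesion identity TTD = lesion dose for patient 9 (7.10 Gy).
Per-patient injected activities were not published; the cohort mean
(6532 MBq) is stored for every patient, and dose-per-activity is mean
dose / mean activity (0.52 mGy/MBq for kidneys).

**Known limitation — CgA columns.** The source table was only available
as undelimited extracted text. The transcription packaged here is the
unique tokenization (over an exhaustive constrained search of all
field-width assignments) that reproduces the published grade mean
(2.3), cycle total (39), CgA-interval mean (3.9 months), age mean, and
the grade-wise TTD rank-sum p = 0.042 exactly, with CgA means within
≈2.6% (pre) and ≈1.9% (post) of the published 589.8/768.1 µg/L. No
tokenization reproduces the published CgA–TTD Pearson correlations
(0.67 and −0.54) simultaneously with those means — the constraint sets
are mathematically incompatible given the published TTD column — so the
correlations computed from this fixture (≈0.16 and ≈+0.36) do not match
the published values, and the corresponding acceptance-suite assertions
fail by design rather than being loosened. Lesion-category column
assignment for rows with empty cells is the unique one consistent with
within-row column order and the summary row's category counts;
per-category mean doses in that row appear volume-weighted with
unpublished volumes and are asserted nowhere.

## Digital phantom and noise model

Structures are spheres/ellipsoids rasterized by voxel-center inclusion
(earlier-listed structure wins overlaps, with a warning); each has
(a₀, τ, HU), and the noise-free series is exactly a₀·e^(−t/τ) at the
default times 4/24/48/72 h. The simulator emulates *reconstructed*
quantitative SPECT: Gaussian PSF blur (zero-padded borders) followed by
Gaussian noise with sd = noise_scale·√value — a reconstructed-image
surrogate rather than projection-domain Poisson, because the pipeline
consumes reconstructed images and this keeps the simulator free of a
reconstruction stage. Negative values are clipped to zero and counted.
What passing tests show: the estimation chain is unbiased and exact
under its own model assumptions; what they do not show: robustness to
reconstruction artifacts, partial-volume bias beyond Gaussian blur,
registration error, or non-mono-exponential kinetics.

Density from HU uses the single-segment calibration ρ = 1 + HU/1000
clamped to [0.001, 3.0] — exact for water, adequate for soft
tissue/lung/bone contrast on coarse grids; a site CT calibration table
can replace it by constructing `DensityMap` directly.

## Verification problem sizes

The shipped tests and acceptance script use: 24³ grids for end-to-end
chains (5·10⁶ histories for the 10⁻³-relative analytic-dose check), the
41³/10 mm equilibrium phantom at 10⁵ histories, 17³ kernel-vs-direct
comparisons at 4·10⁴ histories, and n = 10⁴ samples for stable-fit
recovery — sizes at which every stochastic criterion has a comfortable
error margin while the full suite runs in well under a minute on one
CPU. Multi-voxel "within 3σ" comparisons allow the chance exceedances
expected across hundreds of voxels (≥98.5% within 3σ, none beyond 6σ).

## Known limitations

* Photon physics omits coherent scattering and bound-electron effects;
  all materials are water-like in composition (density-only scaling).
* Beta `track` mode ignores multiple scattering (straight CSDA lines).
* The stable-law ECF estimator targets well-populated lesions; below 20
  voxels it degrades gracefully to a median, which is a different
  estimator.
* The fixture's CgA columns carry the transcription uncertainty
  described above; dose columns do not.
* No registration, no DICOM-RT, no projection-domain simulation.
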