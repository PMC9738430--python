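# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind phasepath. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Physical model

A fresh tissue slice of thickness L ≤ 6 µm is treated as a weakly scattering
phase object: light accumulates phase φ(r) = β₀ (n(r) − n₀) L along straight
rays, with β₀ = 2π/λ the vacuum wavenumber, n(r) the local refractive index
and n₀ its spatial mean. Under this weak-phase model a phase-contrast camera
records counts linear in φ, so a gain/offset calibration (counts per radian,
background counts) inverts the imaging chain. The spatial statistics of φ then
estimate the statistics of n:

- **Refractive-index variance** σₙ² = ⟨|∇φ|²⟩ / β₀². Gradients are central
  differences scaled by the pixel size, one-sided at borders, no apodization.
- **Scattering coefficient** μₛ = ⟨Δφ²⟩ / L (scattering-phase theorem), where
  ⟨Δφ²⟩ is the population variance (divisor N) of φ about its spatial mean.
  Reported in rad²/mm (L in mm).
- **Anisotropy factor**: with x = ⟨|∇φ|²⟩ / (2k₀²⟨Δφ²⟩), the default form is
  g = (1 − x)²; a `no_square` variant g = 1 − x is also provided because the
  trailing exponent of the defining expression admits both readings. The form
  used is recorded in diagnostics. k₀ defaults to the vacuum wavenumber; a
  `medium` convention (×n₀) is selectable and logged.
- **Spectrum model**: the index fluctuation n − n₀ = φ/(β₀L) is assumed wide-
  sense stationary and isotropic with the Von Kármán density
  Φ(κ) = 4π σₙ² L₀² (m−1)(1 + κ²L₀²)^(−m), κ = |κ| angular (rad/µm). The
  normalization is chosen so that ∫Φ d²κ/(2π)² = σₙ² exactly for m > 1.
- **Fractal dimension**: spectral identity d_f = 4 − m applied to a converged
  fit, or box counting on an Otsu-binarized phase map (Otsu is one of several
  defensible binarization rules; it is the package's fixed choice). Box sizes
  are dyadic from 2 to min(H, W)/4; boxes tile a zero-padded cover of the
  image so every occupied pixel is counted; the dimension is the least-squares
  slope of log(count) versus log(1/size).

## Spectrum estimation and fitting

The 2-D periodogram is normalized as Φ̂ = Δ²|FFT(f − f̄)|²/N so that the
discrete Parseval identity Σ Φ̂/(NΔ²) = var(f) holds, making Φ̂ directly
comparable to the analytic Φ. Azimuthal averaging uses 48 logarithmic bins in
κ; the DC bin is excluded and the band is cut at 0.8× the Nyquist wavenumber
to avoid leakage into the aliased spectral corner. The fit minimizes the
residual of log Φ over the band by bounded least squares in
(log σₙ², log L₀, m), with bounds m ∈ (1.01, 6], L₀ ∈ (pixel, 10×extent),
initialized at L₀ = extent/4, m = 3, and σₙ² from the discrete integral of the
binned spectrum. A solution pinned at a bound (within 10⁻⁶) or a failed solver
clears the `converged` flag; parameters are still reported so callers can
inspect them, and the outer scale and spectral d_f become flagged missing
values downstream. On white noise the fit correctly lands at a bound and is
flagged.

Log-binned unweighted fitting slightly down-weights the few low-κ bins that
constrain L₀, so single-image L₀ estimates scatter by roughly 10–20% on 1024²
fields (the seeded recovery test quantifies this).

## Phantom generator

The generator defines the test-bed conditions; its defaults are fixed, not
tuning knobs.

- **Fields**: unit white Gaussian noise is filtered in the Fourier domain by
  √Φ(κ) with the DC bin zeroed (zero spatial mean by construction, hence
  |mean| < 10⁻¹² exactly). The filter amplitude is rescaled so the *discrete*
  spectral sum equals the target σₙ²: finite grids truncate the continuous
  Von Kármán integral, and discrete-sum normalization makes the expected
  sample variance equal the target regardless of grid size. A consequence
  used by the tests: at fixed seed, doubling σₙ² scales the field by √2
  exactly. Boundary conditions are periodic.
- **Projection**: φ = β₀(n − n₀)L with λ = 0.55 µm and L = 6 µm by default.
  Neither the illumination wavelength nor n₀ (default 1.35) is fixed by the
  reference acquisition description; both are configurable and recorded in
  reports.
- **Rendering**: counts = clip(round(offset + gain·φ + N(0, σ)), 0, 2ᵇ−1),
  default 12-bit, gain 400 counts/rad, offset 2048, noise SD 2 counts.
  Saturation above 1% of pixels raises a warning. The fixture design uses
  index variances of order 3–5×10⁻⁵ so that a 6 µm slice projects to a phase
  swing of well under the count range; a fully-correlated-through-thickness
  projection of tissue-table-scale variances (~10⁻²) would saturate any
  camera, a known idealization of the 2-D phantom (real slices decorrelate
  through depth, which the straight-ray 2-D model cannot represent).
- **Feature cohorts**: labeled tables drawn as independent Gaussians per
  parameter per group, optionally parameterized from the published per-tissue
  means/SDs shipped in `phasepath.reference`. Independence across parameters
  is a documented simplification — no cross-parameter covariances are
  published — so cohort-based classifier results characterize the bench, not
  the joint feature geometry of real tissue.
- Pixel sizes 0.64 / 0.3225 / 0.1632 µm for 10× / 20× / 40× follow the
  reference acquisition geometry.

What phantom-passing tests do **not** show: performance on real tissue
morphology (nuclei, vessels, halo and shade-off artifacts of phase-contrast
optics, mosaic seams), none of which the generator emulates.

## Statistical screen

Group summaries use the sample SD (divisor n−1). The worked mean-difference
report rounds |mean_T − mean_H| to each parameter's reporting precision
(RIV 4 decimals, SC 2, AF 5, FD 3, OS 2) and flags whether the difference
exceeds both, one, or neither group SD. The ANOVA is the textbook one-way
decomposition (F = MS_between/MS_within with an F-tail p-value), computed
explicitly so degenerate inputs have defined limits: all-identical data gives
F = 0, p = 1; zero within-group variance with unequal means gives p = 0. The
test suite cross-checks it against an independent library routine and the
two-group identity F = t². The operative significance rule is α = 0.005 per
cell with no multiple-testing correction; the table records the number of
tests so users can apply their own. Images within a cohort are treated as
independent experimental units.

## Classifier bench

Eight families, all on features z-scored with training-split statistics only:

| algorithm | configuration |
|---|---|
| LDA | empirical priors, zero threshold |
| QDA | regularized covariance, reg_param 10⁻³ |
| NB | Gaussian conditionals |
| kNB | per-feature Gaussian KDE conditionals, Silverman bandwidth per feature per class |
| kNN | k = 5, Euclidean |
| SVM | linear kernel; with two classes the one-vs-one coding reduces to a single binary machine |
| DT | Gini, minimum parent size 10, no further pruning |
| ANN | one hidden layer of 10 units, L-BFGS training, max 500 iterations |

Design notes: "10 hidden layers" in the source description is read as the
conventional single hidden layer of width 10 (a `deep` option builds 10×10 if
wanted). The kernel naive Bayes is implemented in-package because the
scikit-learn naive Bayes family offers only parametric conditionals. The QDA
regularization floor keeps exactly collinear or constant features from
producing singular class covariances (a warning is emitted and rows with
non-finite features are dropped before fitting). The SVM kernel and the CV
protocol are not fixed by the source description; defaults are linear kernel
and stratified 10-fold × 5 repeats.

Evaluation: *re-substitution* trains and tests on all data (optimistic);
*cross-validation* pools held-out predictions within each repeat and averages
the FP/FN rates over repeats, with fold assignment controlled by the seed and
folds reduced (with a warning) if a class is smaller than the fold count.
Tumoral is the positive class throughout: FP = healthy called tumoral,
FN = tumoral called healthy, total = FP + FN (so chance on balanced classes
sits near 1.0), sensitivity = 1 − FN, specificity = 1 − FP — identities that
hold exactly for every report cell. Cells with total < 0.1 are flagged, and a
report cell with a missing class is emitted blank with a warning.

## Pipeline and reproducibility

A run is one configuration mapping with a global seed. Stage seeds derive
from the global seed by hashing the stage name (so stages re-run
independently yet reproducibly), every CSV carries a provenance header
(package version, config hash, seed), and identical configurations produce
byte-identical outputs. Manifest validation checks columns, state and
magnification vocabularies, and file existence, returning per-row
diagnostics.

## Problem sizes

The shipped tests and the acceptance script use desk-scale problems chosen to
exercise every code path with comfortable statistical margins: 64×64 fields
for estimator/oracle equivalence, a single 1024² field for spectrum recovery,
2000 null replicates for the type-I-error check, and cohorts of 100 per class
for the bench. The acceptance checks on cohort-based quantities assert only
properties that these sample sizes guarantee decisively; e.g. for the
ganglion scattering coefficient the simulated cohorts separate 20×
(|Δ|/SD ≈ 1.8) from 10× (≈ 0.25), while the 40× effect (≈ 0.3) is large
enough to reach p < 0.005 at n = 100/group with appreciable probability and
is therefore not asserted as non-significant.

## Known limitations

- The intensity→phase mapping assumes weak-phase linearity; no phase
  unwrapping, halo correction, or quantitative-phase reconstruction is
  attempted. Without a gain/offset calibration the `relative` mode gives
  scale-free parameters only (σₙ² scales as gain⁻²); group discrimination is
  unaffected as long as one cohort shares one camera setting.
- The 2-D phantom treats the index field as constant through the slice
  thickness; absolute projected-phase magnitudes are therefore upper bounds.
- Single-image L₀ estimates are biased low by a few percent to ~20% depending
  on how many outer-scale lengths fit in the field of view.
- Cohort draws ignore cross-parameter covariance.
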