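# phasepath

Label-free discrimination of healthy and tumoral tissue from phase-contrast
microscopy, as a tested, reusable Python pipeline.

Fresh, unstained tissue slices are nearly transparent, but their internal
refractive-index heterogeneity carries diagnostic information. From a
phase-contrast image — a 2-D phase map φ(r), in radians — phasepath computes
five physical parameters of the index distribution, screens them for
healthy-vs-tumoral statistical significance, and benchmarks eight classifier
families on the resulting feature tables, reporting errors split into
false-positive and false-negative rates.

## The five phase-contrast parameters

With β₀ = 2π/λ the vacuum wavenumber, L the slice thickness, and
Δφ = φ − ⟨φ⟩ the mean-centered phase:

| parameter | symbol | estimator |
|---|---|---|
| refractive-index variance | σₙ² (RIV) | σₙ² = ⟨\|∇φ\|²⟩ / β₀² |
| scattering coefficient | μₛ (SC) | μₛ = ⟨Δφ²⟩ / L, in rad²/mm |
| anisotropy factor | g (AF) | g = (1 − ⟨\|∇φ\|²⟩ / (2k₀²⟨Δφ²⟩))² |
| fractal dimension | d_f (FD) | d_f = 4 − m (spectral) or box counting |
| outer scale | L₀ (OS) | Von Kármán fit of the index power spectrum |

The exponent m and the outer scale L₀ come from a nonlinear least-squares fit
of the radially averaged power spectrum of the index fluctuation to the
Von Kármán form

    Φ(κ) = 4π σₙ² L₀² (m − 1) [1 + κ²L₀²]^(−m),

the turbulence-inspired model of spatially correlated heterogeneity: a power
law at high κ that saturates below κ ≈ 1/L₀, the largest correlation length
("eddy") in the tissue.

Because no public image set accompanies this problem, the `phantoms` module
generates ground-truth test data: Gaussian random index fields with exactly
this spectrum (spectral synthesis), projected to phase maps for a thin slice
and rendered to 12-bit camera counts, plus labeled Gaussian feature cohorts
parameterized from published per-tissue group statistics
(`phasepath.reference`).

## Worked example

```python
from phasepath import (FieldSpec, generate_von_karman_field, field_to_phase,
                       AcquisitionConfig, extract_features)

# a 512x512 phantom with known ground truth: sigma_n^2 = 5e-5, L0 = 20 um, m = 1.5
spec = FieldSpec(shape=(512, 512), pixel_size=0.3225, sigma_n2=5e-5,
                 outer_scale=20.0, exponent=1.5, seed=11)
phase = field_to_phase(generate_von_karman_field(spec), thickness=6.0, wavelength=0.55)

vec = extract_features(phase, AcquisitionConfig.for_magnification("20x"))
print(f"riv = {vec.riv:.6f}")
print(f"sc  = {vec.sc:.2f} rad^2/mm")
print(f"af  = {vec.af:.5f}")
print(f"fd  = {vec.fd:.3f}")
print(f"os  = {vec.os:.1f} um")
```

prints

```
riv = 0.000524
sc  = 45.63 rad^2/mm
af  = 0.99809
fd  = 2.514
os  = 24.4 um
```

The anisotropy is near 1 (strongly forward scattering, as expected for
tissue-scale heterogeneity), the fitted fractal dimension 2.514 is close to
the generator's 4 − m = 2.5, and the fitted outer scale 24.4 µm recovers the
prescribed 20 µm to within the single-image fit scatter. Note that the
gradient-based `riv` estimator measures roughness at the pixel scale, not the
prescribed full-field variance; the two agree only for spectra dominated by
the resolved band.

The statistical screen works directly on feature tables:

```python
from phasepath.significance import reference_summaries, mean_difference

healthy, tumoral = reference_summaries("ganglion", "20x", "sc")
rep = mean_difference(healthy, tumoral)
print(rep.abs_difference, rep.exceeds)   # -> 25.39 both
```

i.e. the healthy/tumoral scattering-coefficient means of ganglion at 20×
differ by 25.39 rad²/mm, more than both group standard deviations — a strong
discriminator, which the ANOVA screen (`significance_table`, threshold
p < 0.005) and the classifier bench (`error_report`) confirm.

## Command line

```bash
phasepath simulate --seed 1 --out run/           # phantom images + manifest
phasepath extract --manifest run/                # five parameters per image
phasepath stats --features run/features.csv --out run/
phasepath classify --features run/cohort.csv --classifiers LDA,DT --out run/
phasepath run --config config.yaml --out run/    # all stages, reproducibly
phasepath validate-manifest run/manifest.csv
```

All stages are seeded; re-running with an identical configuration reproduces
every output byte for byte.

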