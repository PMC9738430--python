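"""Synthetic phantoms with known ground truth.

Two kinds of synthetic data are produced:

* **Image phantoms** — zero-mean Gaussian random refractive-index fields whose
  isotropic power spectrum follows the Von Kármán form

      Phi(kappa) = 4 pi sigma_n^2 L0^2 (m - 1) [1 + kappa^2 L0^2]^(-m),

  projected to phase maps ``phi = (2 pi / lambda) (n - n0) L`` for a thin slice
  of thickness ``L`` and rendered to quantized camera counts.  Every downstream
  estimator (refractive-index variance, scattering coefficient, anisotropy,
  spectrum fit, fractal dimension) can therefore be checked against the known
  generator parameters.

* **Feature cohorts** — labeled tables of the five phase parameters drawn as
  independent Gaussians per group, parameterized either explicitly or from the
  published per-tissue reference statistics (:mod:`phasepath.reference`).

Fields are synthesized spectrally: unit white noise is filtered in the Fourier
domain by ``sqrt(Phi)`` with the DC bin zeroed (which enforces a zero spatial
mean exactly), and the amplitude is rescaled so that the *discrete* spectral
sum equals the requested variance; the sample variance of a realization then
fluctuates around ``sigma_n2`` without any grid-truncation bias.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .reference import PARAMETERS, PIXEL_SIZE_UM, reference_group


def von_karman_spectrum(kappa: np.ndarray, sigma_n2: float, outer_scale: float, exponent: float) -> np.ndarray:
    """Analytic Von Kármán power spectral density at angular wavenumber ``kappa`` (1/um).

    Normalized so that integrating ``Phi`` over the 2-D kappa plane with
    measure ``d^2 kappa / (2 pi)^2`` returns exactly ``sigma_n2``.
    """
    kappa = np.asarray(kappa, dtype=float)
    l0 = float(outer_scale)
    m = float(exponent)
    return 4.0 * np.pi * sigma_n2 * l0**2 * (m - 1.0) * (1.0 + kappa**2 * l0**2) ** (-m)


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic refractive-index field."""

    shape: tuple[int, int]
    pixel_size: float  # um
    sigma_n2: float  # target spatial variance of n - n0
    outer_scale: float  # L0, um
    exponent: float  # m, spectral exponent (> 1)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 16 or w < 16:
            raise ValueError("field shape must be at least 16x16")
        if not np.isfinite([self.pixel_size, self.sigma_n2, self.outer_scale, self.exponent]).all():
            raise ValueError("field parameters must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.sigma_n2 < 0:
            raise ValueError("sigma_n2 must be non-negative")
        if self.outer_scale <= 0:
            raise ValueError("outer_scale must be positive")
        if self.exponent <= 1:
            raise ValueError("exponent must exceed 1 (spectrum prefactor m - 1 > 0)")


@dataclass(frozen=True)
class RefractiveIndexField:
    """Realized index fluctuation n(r) - n0 on a regular grid."""

    values: np.ndarray
    pixel_size: float  # um
    spec: FieldSpec


@dataclass(frozen=True)
class PhaseImage:
    """2-D phase map phi(r) in radians."""

    phi: np.ndarray
    pixel_size: float  # um
    provenance: str = ""

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi)
        if phi.ndim != 2 or min(phi.shape) < 16:
            raise ValueError("phase image must be 2-D and at least 16x16")
        if not np.isfinite(phi).all():
            raise ValueError("phase image must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class IntensityImage:
    """Quantized camera counts with the rendering calibration recorded."""

    counts: np.ndarray
    pixel_size: float  # um
    bit_depth: int
    gain: float  # counts per radian
    offset: float  # counts
    provenance: str = ""


def _angular_frequency_grid(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    ky = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=pixel_size)
    kx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=pixel_size)
    return np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)


def generate_von_karman_field(spec: FieldSpec) -> RefractiveIndexField:
    """Synthesize a zero-mean Gaussian field with a Von Kármán spectrum.

    Deterministic for a fixed ``spec.seed``.  The amplitude filter is scaled so
    the discrete spectral sum equals ``spec.sigma_n2``; hence the *expected*
    sample variance of the realization is exactly the target, and doubling
    ``sigma_n2`` at a fixed seed scales the field by ``sqrt(2)`` exactly.
    """
    h, w = spec.shape
    if spec.sigma_n2 == 0.0:
        return RefractiveIndexField(np.zeros((h, w)), spec.pixel_size, spec)

    kappa = _angular_frequency_grid((h, w), spec.pixel_size)
    power = von_karman_spectrum(kappa, spec.sigma_n2, spec.outer_scale, spec.exponent)
    power[0, 0] = 0.0  # DC removed: zero-mean field by construction
    # discrete Parseval sum of the prescribed spectrum on this grid
    n_tot = h * w
    discrete_var = power.sum() / (n_tot * spec.pixel_size**2)
    power *= spec.sigma_n2 / discrete_var
    amplitude = np.sqrt(power) / spec.pixel_size

    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((h, w))
    fld = np.fft.ifft2(np.fft.fft2(white) * amplitude).real
    return RefractiveIndexField(fld, spec.pixel_size, spec)


def field_to_phase(fld: RefractiveIndexField, thickness: float, wavelength: float) -> PhaseImage:
    """Project an index-fluctuation field to a phase map for a thin slice.

    ``phi(r) = (2 pi / wavelength) * (n(r) - n0) * thickness`` (radians), the
    weak-scattering straight-ray accumulation through thickness ``L``.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    phi = (2.0 * np.pi / wavelength) * thickness * fld.values
    prov = f"phantom(seed={fld.spec.seed}, L0={fld.spec.outer_scale}, m={fld.spec.exponent})"
    return PhaseImage(phi=phi, pixel_size=fld.pixel_size, provenance=prov)


def render_intensity_image(
    phase: PhaseImage,
    bit_depth: int = 12,
    gain: float = 400.0,
    offset: float = 2048.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IntensityImage:
    """Render a phase map to quantized camera counts.

    ``counts = clip(round(offset + gain * phi + N(0, noise_sd)), 0, 2^bits - 1)``.
    The gain/offset calibration is stored on the result so
    :func:`phasepath.features.intensity_to_phase` can invert the mapping.
    A saturation fraction above 1% raises a warning.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if bit_depth not in (8, 12, 16):
        raise ValueError("bit_depth must be 8, 12 or 16")
    rng = np.random.default_rng(seed)
    raw = offset + gain * phase.phi
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=phase.phi.shape)
    top = 2**bit_depth - 1
    counts = np.clip(np.rint(raw), 0, top).astype(np.uint16)
    saturated = float(np.mean((raw < 0) | (raw > top)))
    if saturated > 0.01:
        warnings.warn(
            f"{saturated:.1%} of pixels saturated at {bit_depth}-bit range", stacklevel=2
        )
    return IntensityImage(
        counts=counts,
        pixel_size=phase.pixel_size,
        bit_depth=bit_depth,
        gain=gain,
        offset=offset,
        provenance=phase.provenance,
    )


# ---------------------------------------------------------------------------
# feature cohorts


@dataclass(frozen=True)
class GroupSpec:
    """One labeled group of a synthetic feature cohort."""

    tissue: str
    state: str  # healthy | tumoral
    magnification: str
    params: dict[str, tuple[float, float]] = field(default_factory=dict)  # name -> (mean, sd)

    def __post_init__(self) -> None:
        if self.state not in ("healthy", "tumoral"):
            raise ValueError("state must be 'healthy' or 'tumoral'")
        for name, (_, sd) in self.params.items():
            if sd < 0:
                raise ValueError(f"negative SD for parameter {name!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-class (or multi-group) synthetic feature cohort."""

    groups: tuple[GroupSpec, ...]
    n_per_group: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not self.groups:
            raise ValueError("cohort needs at least one group")


def generate_feature_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a labeled feature cohort: independent Gaussians per parameter per group.

    Returns a DataFrame with one row per sample and columns
    ``tissue, state, magnification`` plus one column per parameter.
    Reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for grp in spec.groups:
        data = {
            "tissue": grp.tissue,
            "state": grp.state,
            "magnification": grp.magnification,
        }
        for name, (mean, sd) in grp.params.items():
            data[name] = rng.normal(mean, sd, size=spec.n_per_group) if sd > 0 else np.full(
                spec.n_per_group, mean
            )
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def reference_cohort_spec(
    tissue: str,
    magnification: str,
    n_per_group: int,
    seed: int = 0,
) -> CohortSpec:
    """Cohort spec for one tissue/magnification, parameterized from the
    published reference statistics (healthy vs tumoral)."""
    groups = tuple(
        GroupSpec(
            tissue=tissue,
            state=state,
            magnification=magnification,
            params=reference_group(tissue, magnification, state),
        )
        for state in ("healthy", "tumoral")
    )
    return CohortSpec(groups=groups, n_per_group=n_per_group, seed=seed)


# ---------------------------------------------------------------------------
# fixture image sets

MANIFEST_COLUMNS = [
    "path",
    "tissue",
    "state",
    "magnification",
    "pixel_size_um",
    "thickness_um",
    "wavelength_um",
    "seed",
]


def write_fixture_set(
    field_specs: list[dict],
    output_dir: str | Path,
    thickness_um: float = 6.0,
    wavelength_um: float = 0.55,
    gain: float = 400.0,
    offset: float = 2048.0,
    noise_sd: float = 2.0,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Render a set of phantom images to TIFF and write a manifest CSV.

    ``field_specs`` is a list of dicts each holding a :class:`FieldSpec` under
    key ``"spec"`` plus ``tissue``/``state``/``magnification`` labels.  Counts
    are stored in a 16-bit TIFF container.  Returns the manifest frame; refuses
    to clobber an existing manifest unless ``overwrite`` is set.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    rows = []
    for i, entry in enumerate(field_specs):
        spec: FieldSpec = entry["spec"]
        fld = generate_von_karman_field(spec)
        phase = field_to_phase(fld, thickness_um, wavelength_um)
        img = render_intensity_image(
            phase, gain=gain, offset=offset, noise_sd=noise_sd, seed=spec.seed
        )
        name = f"phantom_{i:04d}_{entry['tissue']}_{entry['state']}_{entry['magnification']}.tif"
        tifffile.imwrite(out / name, img.counts)
        rows.append(
            {
                "path": name,
                "tissue": entry["tissue"],
                "state": entry["state"],
                "magnification": entry["magnification"],
                "pixel_size_um": spec.pixel_size,
                "thickness_um": thickness_um,
                "wavelength_um": wavelength_um,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def default_fixture_specs(
    base_seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    tissues: tuple[str, ...] = ("liver", "kidney", "ganglion", "testicle", "brain"),
) -> list[dict]:
    """A small 5-tissue x 2-state x 3-magnification phantom design.

    Tumoral fields get a larger index variance and a rougher spectrum (smaller
    exponent) than healthy ones so that downstream discrimination has a real
    signal; per-image seeds are derived deterministically from ``base_seed``.
    The index variance is kept small enough that a 6-um slice projects to a
    phase swing of well under the 12-bit count range at the default gain.
    """
    specs = []
    for t_i, tissue in enumerate(tissues):
        for s_i, state in enumerate(("healthy", "tumoral")):
            for magnification, px in PIXEL_SIZE_UM.items():
                sigma_n2 = 3e-5 + 1e-5 * s_i + 2e-6 * t_i
                exponent = 1.5 - 0.15 * s_i
                outer_scale = 40.0 if magnification != "10x" else 80.0
                digest = hashlib.sha256(
                    f"{base_seed}|{tissue}|{state}|{magnification}".encode()
                ).digest()
                seed = int.from_bytes(digest[:4], "little") % 2**31
                specs.append(
                    {
                        "spec": FieldSpec(
                            shape=shape,
                            pixel_size=px,
                            sigma_n2=sigma_n2,
                            outer_scale=outer_scale,
                            exponent=exponent,
                            seed=seed,
                        ),
                        "tissue": tissue,
                        "state": state,
                        "magnification": magnification,
                    }
                )
    return specs


__all__ = [
    "FieldSpec",
    "RefractiveIndexField",
    "PhaseImage",
    "IntensityImage",
    "GroupSpec",
    "CohortSpec",
    "von_karman_spectrum",
    "generate_von_karman_field",
    "field_to_phase",
    "render_intensity_image",
    "generate_feature_cohort",
    "reference_cohort_spec",
    "write_fixture_set",
    "default_fixture_specs",
    "MANIFEST_COLUMNS",
    "PARAMETERS",
]
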