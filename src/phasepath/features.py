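"""Estimators of the five advanced phase-contrast parameters.

From a 2-D phase map ``phi(r)`` (radians) of a thin, weakly scattering tissue
slice the module computes:

* ``sigma_n^2`` (RIV) — refractive-index spatial variance, from the mean
  squared phase gradient: ``sigma_n^2 = <|grad phi|^2> / beta0^2`` with
  ``beta0 = 2 pi / lambda`` the vacuum wavenumber.
* ``mu_s`` (SC) — scattering coefficient from the scattering-phase theorem,
  ``mu_s = <Delta phi^2> / L`` where ``Delta phi`` is the mean-centered phase
  and ``L`` the slice thickness; reported in rad^2/mm.
* ``g`` (AF) — anisotropy of scattering, from the ratio of gradient to
  variance statistics (see :func:`anisotropy_factor`); values near 1 indicate
  strongly forward scattering.
* ``df`` (FD) — fractal dimension, either from the fitted Von Kármán exponent
  through the spectral identity ``df = 4 - m`` or by box counting.
* ``L0`` (OS) — outer scale, the saturation length of the Von Kármán spectrum
  fitted to the radially averaged power spectrum of the index fluctuation.

Each estimator is deterministic and is validated in the test suite against an
independently coded brute-force oracle.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from skimage.filters import threshold_otsu

from .phantoms import IntensityImage, PhaseImage, von_karman_spectrum

logger = logging.getLogger(__name__)

MAGNIFICATION_PIXEL_SIZE_UM = {"10x": 0.64, "20x": 0.3225, "40x": 0.1632}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Optical and geometric context of one acquisition.

    ``wavelength`` and ``mean_index`` are not fixed by the reference setup and
    default to a mid-visible illumination and a typical soft-tissue index;
    both are configurable and recorded in reports.
    """

    pixel_size: float  # um
    magnification: str = "20x"
    wavelength: float = 0.55  # um
    thickness: float = 6.0  # um
    mean_index: float = 1.35  # n0
    k0_convention: str = "vacuum"  # vacuum | medium

    def __post_init__(self) -> None:
        for name in ("pixel_size", "wavelength", "thickness", "mean_index"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k0_convention not in ("vacuum", "medium"):
            raise ValueError("k0_convention must be 'vacuum' or 'medium'")

    @property
    def beta0(self) -> float:
        """Vacuum wavenumber 2 pi / lambda (1/um)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def k0(self) -> float:
        """Incident wavenumber under the configured convention (1/um)."""
        return self.beta0 * (self.mean_index if self.k0_convention == "medium" else 1.0)

    @classmethod
    def for_magnification(cls, magnification: str, **kwargs) -> "AcquisitionConfig":
        px = MAGNIFICATION_PIXEL_SIZE_UM[magnification]
        return cls(pixel_size=px, magnification=magnification, **kwargs)


@dataclass(frozen=True)
class SpectrumFit:
    """Result of fitting the Von Kármán model to a radial spectrum."""

    outer_scale: float  # L0, um
    exponent: float  # m
    sigma_n2_fit: float
    residual_rms: float
    converged: bool
    kappa_band: tuple[float, float]  # (kappa_min, kappa_max), 1/um


@dataclass(frozen=True)
class PhaseParameterVector:
    """The five phase-contrast parameters of one image, plus diagnostics.

    Missing values (degenerate inputs, non-converged fits) are NaN with an
    explanatory entry in ``warnings``; extraction never raises on such images.
    """

    riv: float  # sigma_n^2, dimensionless
    sc: float  # mu_s, rad^2/mm
    af: float  # g, dimensionless
    fd: float  # df, dimensionless
    os: float  # L0, um
    diagnostics: SpectrumFit | None = None
    relative_scale: bool = False
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = {
            "riv": self.riv,
            "sc_rad2_per_mm": self.sc,
            "af": self.af,
            "fd": self.fd,
            "os_um": self.os,
        }
        if self.diagnostics is not None:
            d["m"] = self.diagnostics.exponent
            d["converged"] = self.diagnostics.converged
        else:
            d["m"] = float("nan")
            d["converged"] = False
        d["warnings"] = ";".join(self.warnings)
        return d


def intensity_to_phase(
    image: IntensityImage | np.ndarray,
    gain: float | None = None,
    offset: float | None = None,
    pixel_size: float | None = None,
    normalized: bool = False,
) -> tuple[PhaseImage, bool]:
    """Map camera counts to phase under the linear weak-phase model.

    ``phi = (counts - offset) / gain``.  When the calibration is unknown,
    ``normalized=True`` rescales counts to [0, 1] and flags the result as
    *relative phase*: all downstream magnitudes then carry an unknown global
    scale (sigma_n^2 scales as gain^-2), but group discrimination is
    unaffected as long as one cohort shares one camera setting.

    Returns ``(phase, relative_flag)``.
    """
    if isinstance(image, IntensityImage):
        counts = image.counts.astype(float)
        if gain is None:
            gain = image.gain
        if offset is None:
            offset = image.offset
        px = image.pixel_size
        prov = image.provenance
        top = 2**image.bit_depth - 1
    else:
        counts = np.asarray(image, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required for a bare count array")
        px = pixel_size
        prov = "array"
        top = float(counts.max()) if counts.size else 1.0

    if normalized:
        phi = counts / (top if top > 0 else 1.0)
        return PhaseImage(phi=phi, pixel_size=px, provenance=prov + "|relative"), True
    if gain is None or offset is None:
        raise ValueError(
            "intensity-to-phase calibration missing: supply gain (counts/rad) and "
            "offset (counts), or use normalized=True for relative phase"
        )
    if gain == 0:
        raise ValueError("gain must be nonzero")
    phi = (counts - offset) / gain
    return PhaseImage(phi=phi, pixel_size=px, provenance=prov), False


def gradient_square_mean(phase: PhaseImage) -> float:
    """Spatial mean of ``|grad phi|^2`` in rad^2/um^2.

    Central differences in the interior, one-sided at borders, scaled by the
    pixel size.
    """
    phi = np.asarray(phase.phi, dtype=float)
    if min(phi.shape) < 3:
        raise ValueError("image must be at least 3x3 for gradients")
    gy, gx = np.gradient(phi, phase.pixel_size)
    return float(np.mean(gx**2 + gy**2))


def refractive_index_variance(phase: PhaseImage, acq: AcquisitionConfig) -> float:
    """``sigma_n^2 = <|grad phi|^2> / beta0^2`` (dimensionless)."""
    return gradient_square_mean(phase) / acq.beta0**2


def phase_spatial_variance(phase: PhaseImage) -> float:
    """``<Delta phi^2>``: spatial variance of phi about its mean (rad^2, divisor N)."""
    return float(np.var(np.asarray(phase.phi, dtype=float)))


def scattering_coefficient(phase: PhaseImage, acq: AcquisitionConfig) -> float:
    """``mu_s = <Delta phi^2> / L`` in rad^2/mm."""
    if acq.thickness <= 0:
        raise ValueError("thickness must be positive")
    thickness_mm = acq.thickness * 1e-3
    return phase_spatial_variance(phase) / thickness_mm


def anisotropy_factor(
    phase: PhaseImage, acq: AcquisitionConfig, form: str = "outer_square"
) -> float:
    """Anisotropy of scattering g from phase statistics.

    With ``x = <|grad phi|^2> / (2 k0^2 <Delta phi^2>)`` (dimensionless):
    ``form='outer_square'`` (default) gives ``g = (1 - x)^2``;
    ``form='no_square'`` gives ``g = 1 - x``.  Both readings of the trailing
    exponent of the defining expression are provided; the default squares the
    bracket.  Returns NaN when the phase variance is zero (g undefined).
    """
    if form not in ("outer_square", "no_square"):
        raise ValueError("form must be 'outer_square' or 'no_square'")
    var = phase_spatial_variance(phase)
    if var <= 0:
        return float("nan")
    x = gradient_square_mean(phase) / (2.0 * acq.k0**2 * var)
    g = 1.0 - x
    return float(g**2) if form == "outer_square" else float(g)


def phase_to_index_fluctuation(phase: PhaseImage, acq: AcquisitionConfig) -> np.ndarray:
    """Invert the thin-slice projection: ``n - n0 = phi / (beta0 L)``."""
    return np.asarray(phase.phi, dtype=float) / (acq.beta0 * acq.thickness)


def radial_power_spectrum(
    values: np.ndarray,
    pixel_size: float,
    n_bins: int = 48,
    kmax_fraction: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged power spectral density of a 2-D field.

    The 2-D periodogram is normalized as ``Phi_hat = dx^2 |FFT(f - mean)|^2 / N``
    so that ``sum(Phi_hat) / (N dx^2)`` equals the sample variance (discrete
    Parseval) and the estimate is directly comparable to the analytic Von
    Kármán density.  Averaging uses logarithmic bins in angular wavenumber
    ``kappa`` (1/um); the DC bin is excluded and the band is cut at
    ``kmax_fraction`` of the Nyquist wavenumber to avoid the aliased corner
    of the spectral plane.

    Returns ``(kappa_centers, power)`` for non-empty bins.
    """
    f = np.asarray(values, dtype=float)
    if f.ndim != 2 or min(f.shape) < 64:
        raise ValueError("spectrum estimation needs a 2-D field of at least 64x64")
    h, w = f.shape
    n_tot = h * w
    spec2d = pixel_size**2 * np.abs(np.fft.fft2(f - f.mean())) ** 2 / n_tot

    ky = 2.0 * np.pi * np.fft.fftfreq(h, d=pixel_size)
    kx = 2.0 * np.pi * np.fft.fftfreq(w, d=pixel_size)
    kappa = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)

    k_nyquist = np.pi / pixel_size
    k_max = kmax_fraction * k_nyquist
    k_min = 2.0 * np.pi / (max(h, w) * pixel_size)  # fundamental
    mask = (kappa > 0) & (kappa <= k_max)

    edges = np.geomspace(k_min * 0.999, k_max, n_bins + 1)
    idx = np.digitize(kappa[mask], edges) - 1
    valid = (idx >= 0) & (idx < n_bins)
    idx, pw, kv = idx[valid], spec2d[mask][valid], kappa[mask][valid]

    sums = np.bincount(idx, weights=pw, minlength=n_bins)
    ksums = np.bincount(idx, weights=kv, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    nonzero = counts > 0
    return ksums[nonzero] / counts[nonzero], sums[nonzero] / counts[nonzero]


def fit_von_karman(
    kappa: np.ndarray,
    power: np.ndarray,
    field_extent: float,
    pixel_size: float,
    init: tuple[float, float, float] | None = None,
) -> SpectrumFit:
    """Fit the Von Kármán model to a radial spectrum by least squares on logs.

    Free parameters: ``sigma_n^2``, ``L0``, ``m``; the fit minimizes the
    residual of ``log Phi`` over the supplied band.  Bounds:
    ``m in (1.01, 6]``, ``L0 in (pixel_size, 10 x field_extent)``.  Default
    initialization: ``L0 = field_extent / 4``, ``m = 3``, ``sigma_n^2`` from
    the discrete integral of the supplied spectrum (the plug-in variance).
    Non-convergence or a parameter pinned at a bound clears the ``converged``
    flag; parameters are still reported so callers can inspect them.
    """
    kappa = np.asarray(kappa, dtype=float)
    power = np.asarray(power, dtype=float)
    ok = (power > 0) & np.isfinite(power) & (kappa > 0)
    kappa, power = kappa[ok], power[ok]
    if kappa.size < 10:
        raise ValueError("need at least 10 valid spectral bins to fit")

    if init is None:
        # plug-in variance from the 2-D integral of the isotropic spectrum
        sigma0 = float(np.trapezoid(kappa * power, kappa) / (2.0 * np.pi))
        init = (max(sigma0, 1e-12), field_extent / 4.0, 3.0)

    log_p = np.log(power)

    def resid(x: np.ndarray) -> np.ndarray:
        s, l0, m = np.exp(x[0]), np.exp(x[1]), x[2]
        return np.log(von_karman_spectrum(kappa, s, l0, m)) - log_p

    lo = [np.log(1e-16), np.log(pixel_size), 1.01]
    hi = [np.log(1e8), np.log(10.0 * field_extent), 6.0]
    x0 = np.clip(
        [np.log(init[0]), np.log(init[1]), init[2]],
        np.array(lo) + 1e-9,
        np.array(hi) - 1e-9,
    )
    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), max_nfev=2000)

    sigma_n2 = float(np.exp(sol.x[0]))
    outer_scale = float(np.exp(sol.x[1]))
    exponent = float(sol.x[2])
    residual_rms = float(np.sqrt(np.mean(sol.fun**2)))

    at_bound = (
        sol.x[1] <= lo[1] + 1e-6
        or sol.x[1] >= hi[1] - 1e-6
        or exponent <= lo[2] + 1e-6
        or exponent >= hi[2] - 1e-6
    )
    converged = bool(sol.success) and not at_bound
    return SpectrumFit(
        outer_scale=outer_scale,
        exponent=exponent,
        sigma_n2_fit=sigma_n2,
        residual_rms=residual_rms,
        converged=converged,
        kappa_band=(float(kappa.min()), float(kappa.max())),
    )


def box_counting_dimension(binary: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary image.

    Counts occupied boxes over dyadic box sizes 2, 4, ..., min(H, W)/4 and
    returns the slope of ``log(count)`` against ``log(1/box_size)``.
    """
    img = np.asarray(binary, dtype=bool)
    if img.ndim != 2:
        raise ValueError("box counting needs a 2-D image")
    max_size = min(img.shape) // 4
    sizes = []
    s = 2
    while s <= max_size:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        raise ValueError("image too small for box counting")
    counts = []
    for s in sizes:
        # pad so every occupied pixel lies in some box (grid covers the image)
        hh = -(-img.shape[0] // s) * s
        ww = -(-img.shape[1] // s) * s
        padded = np.zeros((hh, ww), dtype=bool)
        padded[: img.shape[0], : img.shape[1]] = img
        blocks = padded.reshape(hh // s, s, ww // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)
    return float(slope)


def fractal_dimension(
    source: SpectrumFit | PhaseImage | np.ndarray, method: str = "spectral"
) -> float:
    """Fractal dimension ``df`` of the index heterogeneity.

    ``method='spectral'`` applies the identity ``df = 4 - m`` to a converged
    Von Kármán fit (NaN when the fit did not converge).  ``method='box_counting'``
    binarizes a phase image by Otsu's threshold (one of several valid
    binarization choices) and counts occupied dyadic boxes; a pre-binarized
    boolean array is used as-is.
    """
    if method == "spectral":
        if not isinstance(source, SpectrumFit):
            raise TypeError("spectral method needs a SpectrumFit")
        if not source.converged:
            return float("nan")
        return 4.0 - source.exponent
    if method == "box_counting":
        if isinstance(source, PhaseImage):
            phi = np.asarray(source.phi, dtype=float)
            if np.ptp(phi) == 0:
                return float("nan")
            binary = phi > threshold_otsu(phi)
        else:
            arr = np.asarray(source)
            if arr.dtype == bool:
                binary = arr
            else:
                if np.ptp(arr) == 0:
                    return float("nan")
                binary = arr > threshold_otsu(arr.astype(float))
        return box_counting_dimension(binary)
    raise ValueError("method must be 'spectral' or 'box_counting'")


def extract_features(
    phase: PhaseImage,
    acq: AcquisitionConfig,
    af_form: str = "outer_square",
    fd_method: str = "spectral",
    relative_scale: bool = False,
) -> PhaseParameterVector:
    """Compute all five phase parameters of one image, with diagnostics.

    Degenerate inputs (zero variance, non-converged spectrum fits) produce NaN
    entries with warnings rather than exceptions, so batch runs always
    complete.  Emits one log line per image with timings and warnings.
    """
    t0 = time.perf_counter()
    warn: list[str] = []

    riv = refractive_index_variance(phase, acq)
    sc = scattering_coefficient(phase, acq)

    af = anisotropy_factor(phase, acq, form=af_form)
    if math.isnan(af):
        warn.append("af undefined: zero phase variance")

    fit: SpectrumFit | None = None
    fd = float("nan")
    os_um = float("nan")
    if phase_spatial_variance(phase) > 0 and min(phase.phi.shape) >= 64:
        fluct = phase_to_index_fluctuation(phase, acq)
        kap, pw = radial_power_spectrum(fluct, phase.pixel_size)
        extent = max(phase.phi.shape) * phase.pixel_size
        try:
            fit = fit_von_karman(kap, pw, field_extent=extent, pixel_size=phase.pixel_size)
        except ValueError as exc:
            warn.append(f"spectrum fit failed: {exc}")
        if fit is not None:
            os_um = fit.outer_scale if fit.converged else float("nan")
            if not fit.converged:
                warn.append("spectrum fit did not converge; os/fd flagged")
            if fd_method == "spectral":
                fd = fractal_dimension(fit, method="spectral")
    else:
        warn.append("no spectrum: image degenerate or smaller than 64x64")
    if fd_method == "box_counting":
        fd = fractal_dimension(phase, method="box_counting")
        if math.isnan(fd):
            warn.append("fd undefined: constant image")

    elapsed = time.perf_counter() - t0
    logger.info(
        "extracted %s: riv=%.4g sc=%.4g af=%.4g fd=%.4g os=%.4g (%.2fs)%s",
        phase.provenance or "<image>",
        riv,
        sc,
        af,
        fd,
        os_um,
        elapsed,
        " WARN " + "; ".join(warn) if warn else "",
    )
    return PhaseParameterVector(
        riv=riv,
        sc=sc,
        af=af,
        fd=fd,
        os=os_um,
        diagnostics=fit,
        relative_scale=relative_scale,
        warnings=tuple(warn),
    )


__all__ = [
    "AcquisitionConfig",
    "SpectrumFit",
    "PhaseParameterVector",
    "intensity_to_phase",
    "gradient_square_mean",
    "refractive_index_variance",
    "phase_spatial_variance",
    "scattering_coefficient",
    "anisotropy_factor",
    "phase_to_index_fluctuation",
    "radial_power_spectrum",
    "fit_von_karman",
    "fractal_dimension",
    "box_counting_dimension",
    "extract_features",
    "MAGNIFICATION_PIXEL_SIZE_UM",
]
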