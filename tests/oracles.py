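"""Independent brute-force oracles for the phase-parameter estimators.

Everything here is deliberately naive (explicit loops, direct DFT matrices)
and shares no code with the package implementation, so agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import numpy as np


def naive_gradient_square_mean(phi: np.ndarray, pixel_size: float) -> float:
    """<|grad phi|^2> by explicit loops: central differences inside, one-sided at edges."""
    h, w = phi.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            if 0 < i < h - 1:
                gy = (phi[i + 1, j] - phi[i - 1, j]) / (2 * pixel_size)
            elif i == 0:
                gy = (phi[1, j] - phi[0, j]) / pixel_size
            else:
                gy = (phi[h - 1, j] - phi[h - 2, j]) / pixel_size
            if 0 < j < w - 1:
                gx = (phi[i, j + 1] - phi[i, j - 1]) / (2 * pixel_size)
            elif j == 0:
                gx = (phi[i, 1] - phi[i, 0]) / pixel_size
            else:
                gx = (phi[i, w - 1] - phi[i, w - 2]) / pixel_size
            total += gx * gx + gy * gy
    return total / (h * w)


def naive_spatial_variance(phi: np.ndarray) -> float:
    """Population variance (divisor N) by explicit accumulation."""
    h, w = phi.shape
    mean = 0.0
    for i in range(h):
        for j in range(w):
            mean += phi[i, j]
    mean /= h * w
    acc = 0.0
    for i in range(h):
        for j in range(w):
            acc += (phi[i, j] - mean) ** 2
    return acc / (h * w)


def naive_anisotropy(
    phi: np.ndarray, pixel_size: float, k0: float, outer_square: bool = True
) -> float:
    """Direct evaluation of g from the naive statistics above."""
    var = naive_spatial_variance(phi)
    gsm = naive_gradient_square_mean(phi, pixel_size)
    g = 1.0 - gsm / (2.0 * k0**2 * var)
    return g**2 if outer_square else g


def dft_periodogram(values: np.ndarray, pixel_size: float) -> np.ndarray:
    """2-D power spectral density via explicit DFT matrices (no FFT)."""
    f = values - values.mean()
    h, w = f.shape
    jh = np.arange(h)
    jw = np.arange(w)
    eh = np.exp(-2j * np.pi * np.outer(jh, jh) / h)
    ew = np.exp(-2j * np.pi * np.outer(jw, jw) / w)
    dft = eh @ f @ ew
    return pixel_size**2 * np.abs(dft) ** 2 / (h * w)


def naive_radial_average(
    spec2d: np.ndarray,
    pixel_size: float,
    n_bins: int = 48,
    kmax_fraction: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Loop-based logarithmic radial binning of a 2-D spectrum."""
    h, w = spec2d.shape
    ky = 2 * np.pi * np.fft.fftfreq(h, d=pixel_size)
    kx = 2 * np.pi * np.fft.fftfreq(w, d=pixel_size)
    k_max = kmax_fraction * np.pi / pixel_size
    k_min = 2 * np.pi / (max(h, w) * pixel_size)
    edges = np.geomspace(k_min * 0.999, k_max, n_bins + 1)
    sums = np.zeros(n_bins)
    ksums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(h):
        for j in range(w):
            kappa = np.hypot(ky[i], kx[j])
            if kappa <= 0 or kappa > k_max:
                continue
            b = int(np.searchsorted(edges, kappa, side="right")) - 1
            if 0 <= b < n_bins:
                sums[b] += spec2d[i, j]
                ksums[b] += kappa
                counts[b] += 1
    nz = counts > 0
    return ksums[nz] / counts[nz], sums[nz] / counts[nz]


def hand_anova(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """One-way ANOVA F via the textbook sum-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic."""
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def sierpinski_carpet(depth: int) -> np.ndarray:
    """Boolean raster of the Sierpinski carpet at the given recursion depth."""
    img = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        h, w = img.shape
        nxt = np.zeros((3 * h, 3 * w), dtype=bool)
        for i in range(3):
            for j in range(3):
                if (i, j) != (1, 1):
                    nxt[i * h : (i + 1) * h, j * w : (j + 1) * w] = img
        img = nxt
    return img
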