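"""Published reference statistics for phase-contrast parameters of fresh tissue.

Per-group mean and standard deviation of the five phase-contrast parameters
(refractive index variance RIV, scattering coefficient SC in rad^2/mm,
anisotropy factor AF, fractal dimension FD, outer scale OS in um) measured on
label-free cryo-sliced human tissue of five types (liver, kidney, ganglion,
testicle, brain), in healthy (H) and tumoral (T) state, at 10x/20x/40x
magnification.  These group statistics parameterize synthetic feature cohorts
(see :mod:`phasepath.phantoms`) and drive the worked mean-difference examples
in :mod:`phasepath.significance`.
"""

from __future__ import annotations

import io

import pandas as pd

PARAMETERS = ("riv", "sc", "af", "fd", "os")

#: printed decimals of each parameter in the reference table, used when a
#: worked mean-difference report is rounded to reporting precision
REPORTING_DECIMALS = {"riv": 4, "sc": 2, "af": 5, "fd": 3, "os": 2}

_REFERENCE_CSV = """\
tissue,magnification,state,riv_mean,riv_sd,sc_mean,sc_sd,af_mean,af_sd,fd_mean,fd_sd,os_mean,os_sd
liver,10x,healthy,0.0244,0.0059,18.15,20.30,0.98087,0.05989,2.707,0.250,81.56,8.65
liver,10x,tumoral,0.0267,0.0041,32.17,30.34,0.88799,0.52312,2.525,0.363,80.18,14.84
liver,20x,healthy,0.0217,0.0049,36.57,29.09,0.99653,0.00472,2.670,0.285,40.90,3.45
liver,20x,tumoral,0.0169,0.0080,20.81,19.99,0.99802,0.00324,2.485,0.405,39.10,5.57
liver,40x,healthy,0.0124,0.0050,23.29,14.78,0.99932,0.00030,3.194,0.207,25.40,2.54
liver,40x,tumoral,0.0128,0.0067,25.99,26.17,0.99924,0.00038,3.129,0.309,24.60,3.77
kidney,10x,healthy,0.0278,0.0058,25.77,26.86,0.95906,0.14489,2.402,0.357,81.18,26.20
kidney,10x,tumoral,0.0246,0.0065,19.53,25.48,0.99178,0.01074,2.529,0.372,81.32,13.49
kidney,20x,healthy,0.0168,0.0051,23.94,17.52,0.99856,0.00147,2.553,0.487,41.38,7.87
kidney,20x,tumoral,0.0194,0.0040,41.66,19.09,0.99897,0.00083,2.647,0.384,41.44,6.16
kidney,40x,healthy,0.0104,0.0041,14.50,16.04,0.99871,0.00252,3.215,0.273,26.69,4.87
kidney,40x,tumoral,0.0136,0.0037,30.45,16.89,0.99937,0.00030,3.172,0.320,25.67,4.62
ganglion,10x,healthy,0.0223,0.0042,11.10,15.23,0.99132,0.00988,2.615,0.163,78.76,4.83
ganglion,10x,tumoral,0.0290,0.0043,16.37,26.96,0.96354,0.04785,2.218,0.255,71.32,5.31
ganglion,20x,healthy,0.0206,0.0021,43.46,12.91,0.99913,0.00017,2.629,0.132,39.54,2.45
ganglion,20x,tumoral,0.0144,0.0063,18.07,15.31,0.99884,0.00036,2.665,0.416,41.05,6.36
ganglion,40x,healthy,0.0108,0.0042,18.39,11.12,0.99938,0.00013,3.275,0.233,26.26,4.62
ganglion,40x,tumoral,0.0126,0.0035,22.74,16.10,0.99930,0.00020,3.166,0.222,24.51,2.75
testicle,10x,healthy,0.0201,0.0038,21.76,24.11,0.93896,0.11773,2.661,0.254,80.36,7.43
testicle,10x,tumoral,0.0238,0.0052,33.17,37.61,0.98946,0.02517,2.558,0.311,78.10,7.05
testicle,20x,healthy,0.0143,0.0083,16.99,15.30,0.99882,0.00077,2.777,0.699,45.26,11.38
testicle,20x,tumoral,0.0182,0.0021,39.35,21.37,0.99888,0.00178,2.617,0.242,39.61,3.43
testicle,40x,healthy,0.0156,0.0044,39.12,17.51,0.99932,0.00043,3.123,0.547,26.16,6.65
testicle,40x,tumoral,0.0127,0.0020,27.96,13.16,0.99943,0.00020,3.144,0.207,24.20,2.52
brain,10x,healthy,0.0261,0.0019,66.19,24.08,0.99693,0.00677,2.428,0.065,74.67,3.57
brain,10x,tumoral,0.0302,0.0032,43.64,35.87,0.99349,0.00748,2.179,0.155,70.42,3.60
brain,20x,healthy,0.0148,0.0013,17.18,6.24,0.99886,0.00019,2.604,0.065,39.16,1.47
brain,20x,tumoral,0.0138,0.0048,15.97,8.98,0.99891,0.00028,2.683,0.373,40.87,4.96
brain,40x,healthy,0.0097,0.0010,10.60,2.94,0.99923,0.00007,3.249,0.075,25.08,1.42
brain,40x,tumoral,0.0099,0.0031,16.03,12.24,0.99940,0.00015,3.322,0.194,26.38,2.83
"""

#: pixel sizes (um) of the three magnifications of the reference setup
PIXEL_SIZE_UM = {"10x": 0.64, "20x": 0.3225, "40x": 0.1632}

TISSUES = ("liver", "kidney", "ganglion", "testicle", "brain")
MAGNIFICATIONS = ("10x", "20x", "40x")
STATES = ("healthy", "tumoral")


def reference_statistics(long: bool = False) -> pd.DataFrame:
    """Return the reference group statistics.

    Parameters
    ----------
    long
        If False (default), one row per (tissue, magnification, state) with
        ``<param>_mean`` / ``<param>_sd`` columns.  If True, one row per
        (tissue, magnification, state, parameter) with ``mean`` / ``sd``.
    """
    wide = pd.read_csv(io.StringIO(_REFERENCE_CSV))
    if not long:
        return wide
    rows = []
    for _, r in wide.iterrows():
        for p in PARAMETERS:
            rows.append(
                {
                    "tissue": r["tissue"],
                    "magnification": r["magnification"],
                    "state": r["state"],
                    "parameter": p,
                    "mean": r[f"{p}_mean"],
                    "sd": r[f"{p}_sd"],
                }
            )
    return pd.DataFrame(rows)


def reference_group(tissue: str, magnification: str, state: str) -> dict[str, tuple[float, float]]:
    """(mean, sd) of each of the five parameters for one reference group."""
    wide = reference_statistics()
    sel = wide[
        (wide.tissue == tissue)
        & (wide.magnification == magnification)
        & (wide.state == state)
    ]
    if len(sel) != 1:
        raise KeyError(f"no reference group {tissue}/{magnification}/{state}")
    r = sel.iloc[0]
    return {p: (float(r[f"{p}_mean"]), float(r[f"{p}_sd"])) for p in PARAMETERS}
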