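"""Spectral vegetation indices from 4-band canopy radiometry.

Bands: 531 and 570 nm (photochemical pair) and 670/850 nm (red/NIR pair).
Indices are computed either from band reflectances or from raw paired
readings of a dual (incident + reflected) radiometer, where the reflected
signals are in nanoamps and a per-pair ratio sensitivity Z calibrates the
two channels:

    VI = (Z*R1r*Y - R2r*X) / (Z*R1r*Y + R2r*X)

with X, Y the incident readings for bands R1, R2.  For NDVI and SAVI,
R1 = 850 nm and R2 = 670 nm; for PRI, R1 = 570 nm and R2 = 531 nm.

WDRVI is obtained from NDVI through the Moebius transform
WDRVI = [(a+1)*NDVI + (a-1)] / [(a-1)*NDVI + (a+1)] with a = 0.2, which
linearizes the high-biomass range, and sWDRVI = (WDRVI+1)/2 rescales it
to [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "vi_from_raw",
    "ndvi",
    "savi",
    "pri",
    "wdrvi_from_ndvi",
    "swdrvi",
    "vi_table",
]

DEFAULT_SAVI_L = 0.5
DEFAULT_WDRVI_ALPHA = 0.2


def _nd(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    if np.any(denom == 0):
        raise ZeroDivisionError("normalized difference with zero denominator")
    out = (a - b) / denom
    return out if out.shape else float(out)


def vi_from_raw(r1r, r2r, x, y, z):
    """Normalized difference of calibrated raw radiometer signals.

    r1r, r2r: reflected readings (nanoamps) for bands R1, R2; x, y:
    incident readings for R1, R2 (umol m-2 s-1); z: ratio sensitivity of
    the reflected R1:R2 channel pair.  With z = 1 and equal incident
    readings this reduces to the reflectance normalized difference.
    """
    return _nd(np.asarray(z, float) * np.asarray(r1r, float) * np.asarray(y, float),
               np.asarray(r2r, float) * np.asarray(x, float))


def ndvi(rho850, rho670):
    """NDVI = (rho850 - rho670) / (rho850 + rho670)."""
    return _nd(rho850, rho670)


def savi(rho850, rho670, l_factor: float = DEFAULT_SAVI_L):
    """SAVI = (rho850 - rho670) / (rho850 + rho670 + L) * (1 + L)."""
    a = np.asarray(rho850, dtype=float)
    b = np.asarray(rho670, dtype=float)
    denom = a + b + l_factor
    if np.any(denom == 0):
        raise ZeroDivisionError("SAVI with zero denominator")
    out = (a - b) / denom * (1.0 + l_factor)
    return out if out.shape else float(out)


def pri(rho570, rho531):
    """PRI = (rho570 - rho531) / (rho570 + rho531)."""
    return _nd(rho570, rho531)


def wdrvi_from_ndvi(ndvi_value, alpha: float = DEFAULT_WDRVI_ALPHA):
    """Wide-dynamic-range transform of NDVI (strictly increasing, 1 -> 1)."""
    v = np.asarray(ndvi_value, dtype=float)
    denom = (alpha - 1.0) * v + (alpha + 1.0)
    if np.any(denom == 0):
        raise ZeroDivisionError("WDRVI transform with zero denominator")
    out = ((alpha + 1.0) * v + (alpha - 1.0)) / denom
    return out if out.shape else float(out)


def swdrvi(wdrvi_value):
    """Shift WDRVI from [-1, 1] to [0, 1]: sWDRVI = (WDRVI + 1) / 2."""
    v = np.asarray(wdrvi_value, dtype=float)
    if np.any((v < -1 - 1e-12) | (v > 1 + 1e-12)):
        raise ValueError("WDRVI outside [-1, 1]")
    out = (v + 1.0) / 2.0
    return out if out.shape else float(out)


def vi_table(
    reflectance: pd.DataFrame,
    savi_l: float = DEFAULT_SAVI_L,
    wdrvi_alpha: float = DEFAULT_WDRVI_ALPHA,
) -> pd.DataFrame:
    """Compute all indices from a table with rho531/rho570/rho670/rho850.

    Returns the input plus ndvi, savi, pri, wdrvi and swdrvi columns.
    """
    out = reflectance.copy()
    nd = ndvi(out["rho850"].to_numpy(), out["rho670"].to_numpy())
    out["ndvi"] = nd
    out["savi"] = savi(out["rho850"].to_numpy(), out["rho670"].to_numpy(), savi_l)
    out["pri"] = pri(out["rho570"].to_numpy(), out["rho531"].to_numpy())
    wd = wdrvi_from_ndvi(nd, wdrvi_alpha)
    out["wdrvi"] = wd
    out["swdrvi"] = swdrvi(wd)
    return out
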