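"""Vegetative/reproductive phase splitting, slope-difference tests, LUE.

Winter crops show hysteresis: the GEP_d-vs-NDVI relation differs between
the green-up (vegetative) and senescence (reproductive) halves of the
season because NDVI saturates early while photosynthesis keeps rising.
Each crop-year is split at its seasonal LAI (or GEP_d) maximum, the
GEP_d-vs-predictor slope is fitted per phase, and a Welch-type
two-sample t-test compares the two slopes.  Daily light-use efficiency
(LUE, gC per mol incident photons) complements the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhaseSplit",
    "SlopeFit",
    "SlopeTest",
    "split_phases",
    "simple_slope_fit",
    "slope_difference_test",
    "lue_daily",
    "hysteresis_table",
]


@dataclass(frozen=True)
class PhaseSplit:
    crop: str
    year: int
    split_date: pd.Timestamp
    rule_used: str  # max_lai / max_gep / manual


@dataclass(frozen=True)
class SlopeFit:
    """Slope, its standard error and n from a simple linear regression."""

    slope: float
    se: float
    n: int
    intercept: float = float("nan")


@dataclass(frozen=True)
class SlopeTest:
    slope1: float
    slope2: float
    se1: float
    se2: float
    t_stat: float
    df: float
    p_value: float
    significant: bool  # at alpha = 0.05


def split_phases(
    records: pd.DataFrame,
    rule: str = "max_lai",
    manual_date=None,
    min_per_phase: int = 3,
) -> PhaseSplit:
    """Split one crop-year's daily records into two phenological phases.

    ``max_lai`` (default) splits at the date of seasonal maximum LAI,
    ``max_gep`` at maximum GEP_d; a manual date overrides both.  Requires
    at least ``min_per_phase`` records on each side.
    """
    if manual_date is not None:
        split = pd.Timestamp(manual_date)
        rule_used = "manual"
    elif rule == "max_lai":
        split = pd.Timestamp(records.loc[records["lai"].idxmax(), "date"])
        rule_used = "max_lai"
    elif rule == "max_gep":
        split = pd.Timestamp(records.loc[records["gep_d"].idxmax(), "date"])
        rule_used = "max_gep"
    else:
        raise ValueError(f"unknown phase rule {rule!r}")
    dates = pd.to_datetime(records["date"])
    n_veg = int((dates <= split).sum())
    n_rep = int((dates > split).sum())
    if n_veg < min_per_phase or n_rep < min_per_phase:
        raise ValueError(
            f"too few records per phase (vegetative {n_veg}, reproductive {n_rep})"
        )
    crop = str(records["crop"].iloc[0]) if "crop" in records else ""
    return PhaseSplit(crop=crop, year=int(split.year), split_date=split,
                      rule_used=rule_used)


def simple_slope_fit(x, y) -> SlopeFit:
    """OLS slope with its standard error (closed form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 points for a slope fit")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate predictor")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    s2 = float(np.sum(resid**2)) / (n - 2)
    return SlopeFit(slope=slope, se=float(np.sqrt(s2 / sxx)), n=n,
                    intercept=intercept)


def slope_difference_test(fit1: SlopeFit, fit2: SlopeFit) -> SlopeTest:
    """Welch-type two-sample t-test on two regression slopes.

    t = (a1 - a2) / sqrt(se1^2 + se2^2) with Welch–Satterthwaite degrees
    of freedom built from the per-fit residual degrees of freedom
    (n_i - 2); two-sided p-value.
    """
    if fit1.n < 3 or fit2.n < 3:
        raise ValueError("both fits need n >= 3")
    v1, v2 = fit1.se**2, fit2.se**2
    pooled = v1 + v2
    if pooled == 0:
        raise ValueError("zero pooled standard error")
    t = (fit1.slope - fit2.slope) / np.sqrt(pooled)
    df = pooled**2 / (v1**2 / (fit1.n - 2) + v2**2 / (fit2.n - 2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return SlopeTest(
        slope1=fit1.slope,
        slope2=fit2.slope,
        se1=fit1.se,
        se2=fit2.se,
        t_stat=float(t),
        df=float(df),
        p_value=min(p, 1.0),
        significant=p < 0.05,
    )


def lue_daily(gep_d: float, par_d: float, daylength_s: float) -> float:
    """Light-use efficiency: gC fixed per mol incident photons.

    LUE = GEP_d / (PAR_d * daylength * 1e-6), with GEP_d in
    gCO2-C m-2 d-1, PAR_d the daylight-mean PAR in umol m-2 s-1 and the
    daylength in seconds (so the denominator is mol photons m-2 d-1).
    """
    if par_d <= 0 or daylength_s <= 0:
        raise ValueError("PAR_d and daylength must be positive")
    return gep_d / (par_d * daylength_s * 1e-6)


def hysteresis_table(
    records: pd.DataFrame,
    predictors: dict[str, pd.Series] | None = None,
    rule: str = "max_lai",
) -> pd.DataFrame:
    """Phase slope tests for a set of predictors on one crop-year.

    By default tests NDVI and NDVI*LAI (the saturation-prone index and
    its LAI-product correction).  Returns one row per predictor with the
    phase slopes, t, df, p and the significance flag.
    """
    split = split_phases(records, rule=rule)
    dates = pd.to_datetime(records["date"])
    veg = dates <= split.split_date
    if predictors is None:
        predictors = {
            "NDVI": records["ndvi"],
            "NDVI*LAI": records["ndvi"] * records["lai"],
        }
    rows = []
    for name, x in predictors.items():
        f1 = simple_slope_fit(x[veg], records.loc[veg, "gep_d"])
        f2 = simple_slope_fit(x[~veg], records.loc[~veg, "gep_d"])
        test = slope_difference_test(f1, f2)
        rows.append(
            {
                "predictor": name,
                "crop": split.crop,
                "split_date": split.split_date,
                "slope_veg": test.slope1,
                "slope_rep": test.slope2,
                "t": test.t_stat,
                "df": test.df,
                "p": test.p_value,
                "significant": test.significant,
            }
        )
    return pd.DataFrame(rows)
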