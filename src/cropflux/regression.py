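"""Linear spectral models of daily GEP and their evaluation.

Four single-predictor linear models are compared:

    1: GEP_d = a*LAI + b
    2: GEP_d = a*VI + b
    3: GEP_d = a*(VI*PAR_d) + b
    4: GEP_d = a*(VI*LAI) + b

with VI one of NDVI, SAVI, sWDRVI or PRI (PRI enters model 2 only).
Goodness of fit is reported as R2, RMSE (population form, divisor n, in
gCO2-C m-2 d-1) and NRMSE = 100*RMSE/(max - min) of the observed GEP_d.
A fitted general (pooled-crop) model is validated per crop by the
observed-vs-predicted regression and the relative bias of the seasonal
sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "GEPRegression",
    "GEPRegressionResults",
    "ValidationResult",
    "build_predictor",
    "fit_model",
    "model_table",
    "predict_and_validate",
]

VI_COLUMNS = {"NDVI": "ndvi", "SAVI": "savi", "sWDRVI": "swdrvi", "PRI": "pri"}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four model formulations."""

    model_id: int
    vi_name: str | None = None  # NDVI / SAVI / sWDRVI / PRI; ignored by model 1

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError("model_id must be 1..4")
        if self.model_id != 1 and self.vi_name not in VI_COLUMNS:
            raise ValueError("models 2-4 need vi_name in NDVI/SAVI/sWDRVI/PRI")

    @property
    def label(self) -> str:
        if self.model_id == 1:
            return "LAI"
        if self.model_id == 2:
            return self.vi_name
        if self.model_id == 3:
            return f"{self.vi_name}*PARd"
        return f"{self.vi_name}*LAI"


def build_predictor(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.Series, int]:
    """Predictor x and response y for one model, with pairwise deletion.

    Rows missing any required component (LAI for models 1 and 4, PAR_d
    for model 3, the VI for 2-4, or GEP_d) are dropped; the number
    dropped is returned so the differing n per model row is accounted
    for.
    """
    y = records["gep_d"]
    if spec.model_id == 1:
        x = records["lai"]
    else:
        vi = records[VI_COLUMNS[spec.vi_name]]
        if spec.model_id == 2:
            x = vi
        elif spec.model_id == 3:
            x = vi * records["par_d"]
        else:
            x = vi * records["lai"]
    ok = x.notna() & y.notna()
    return x[ok], y[ok], int((~ok).sum())


@dataclass
class GEPRegressionResults:
    """OLS fit of GEP_d on a single predictor, with the field's statistics."""

    spec: ModelSpec
    dataset_label: str
    slope: float
    intercept: float
    n: int
    r2: float
    rmse: float  # gCO2-C m-2 d-1, divisor n
    nrmse: float  # % of the observed GEP_d range
    p_value: float  # two-sided slope t-test
    slope_se: float
    y_range: float
    dropped: int = 0
    _sm: object = field(default=None, repr=False)

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> str:
        return (
            f"GEP_d ~ {self.spec.label} [{self.dataset_label}]\n"
            f"  GEP_d = {self.slope:.2f} * {self.spec.label} + {self.intercept:.2f}\n"
            f"  n = {self.n}   R2 = {self.r2:.2f}   RMSE = {self.rmse:.2f} "
            f"gCO2-C m-2 d-1   NRMSE = {self.nrmse:.2f} %   p = {self.p_value:.2g}"
        )


class GEPRegression:
    """statsmodels-backed simple linear model of GEP_d on one predictor."""

    def __init__(self, x: Sequence[float], y: Sequence[float],
                 spec: ModelSpec | None = None, dataset_label: str = "",
                 dropped: int = 0):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y length mismatch")
        if self.x.size < 3:
            raise ValueError("need at least 3 records")
        if np.ptp(self.x) == 0:
            raise ValueError("degenerate predictor: zero variance")
        self.spec = spec or ModelSpec(1)
        self.dataset_label = dataset_label
        self.dropped = dropped

    @classmethod
    def from_dataframe(
        cls, records: pd.DataFrame, spec: ModelSpec, dataset_label: str = ""
    ) -> "GEPRegression":
        x, y, dropped = build_predictor(records, spec)
        return cls(x, y, spec=spec, dataset_label=dataset_label, dropped=dropped)

    def fit(self) -> GEPRegressionResults:
        res = sm.OLS(self.y, sm.add_constant(self.x)).fit()
        intercept, slope = res.params
        resid = self.y - res.fittedvalues
        rmse = float(np.sqrt(np.mean(resid**2)))
        y_range = float(np.ptp(self.y))
        nrmse = 100.0 * rmse / y_range if y_range > 0 else float("nan")
        r_squared = float(res.rsquared)
        if not np.isfinite(r_squared):  # constant response: no explainable variance
            r_squared = 0.0
        return GEPRegressionResults(
            spec=self.spec,
            dataset_label=self.dataset_label,
            slope=float(slope),
            intercept=float(intercept),
            n=int(self.y.size),
            r2=r_squared,
            rmse=rmse,
            nrmse=nrmse,
            p_value=float(res.pvalues[1]),
            slope_se=float(res.bse[1]),
            y_range=y_range,
            dropped=self.dropped,
            _sm=res,
        )


def fit_model(x, y, spec: ModelSpec | None = None,
              dataset_label: str = "") -> GEPRegressionResults:
    """Convenience wrapper: OLS of y on x with the package's statistics."""
    return GEPRegression(x, y, spec=spec, dataset_label=dataset_label).fit()


DEFAULT_SPECS = (
    [ModelSpec(1)]
    + [ModelSpec(2, vi) for vi in ("NDVI", "SAVI", "sWDRVI", "PRI")]
    + [ModelSpec(3, vi) for vi in ("NDVI", "SAVI", "sWDRVI")]
    + [ModelSpec(4, vi) for vi in ("NDVI", "SAVI", "sWDRVI")]
)


def model_table(
    records: pd.DataFrame,
    groups: dict[str, pd.DataFrame] | None = None,
    specs: Sequence[ModelSpec] = DEFAULT_SPECS,
) -> pd.DataFrame:
    """Fit every (group x model x VI) combination and tabulate the stats.

    ``groups`` maps dataset labels to record subsets; by default each crop
    plus the pooled set.  Combinations whose predictor is entirely missing
    or degenerate are skipped.
    """
    if groups is None:
        groups = {str(c): records[records["crop"] == c] for c in records["crop"].unique()}
        groups["all crops"] = records
    rows = []
    for label, sub in groups.items():
        if sub.empty:
            continue
        for spec in specs:
            try:
                fit = GEPRegression.from_dataframe(sub, spec, dataset_label=label).fit()
            except (ValueError, KeyError):
                continue
            rows.append(
                {
                    "dataset": label,
                    "model": spec.model_id,
                    "predictor": spec.label,
                    "n": fit.n,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r2": fit.r2,
                    "rmse": fit.rmse,
                    "nrmse": fit.nrmse,
                    "p": fit.p_value,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ValidationResult:
    """Per-crop check of a general model: obs-vs-pred line and bias."""

    crop: str
    n: int
    slope: float  # observed-vs-predicted OLS slope
    intercept: float
    r2: float
    bias_percent: float  # 100 * (sum(pred) - sum(obs)) / sum(obs)
    bias_exceeds_25: bool


def predict_and_validate(
    general: GEPRegressionResults, records: pd.DataFrame
) -> list[ValidationResult]:
    """Apply a pooled-crop model to each crop and measure its bias.

    Predicted GEP_d is regressed on observed GEP_d per crop;
    bias_percent compares the summed predictions with the summed
    observations (defined only when the observed sum is positive).
    """
    out = []
    for crop, sub in records.groupby("crop"):
        x, y, _ = build_predictor(sub, general.spec)
        if len(y) < 3:
            continue
        pred = general.predict(x)
        obs_sum = float(np.sum(y))
        if obs_sum <= 0:
            continue
        ols = sm.OLS(pred, sm.add_constant(np.asarray(y, float))).fit()
        bias = 100.0 * (float(np.sum(pred)) - obs_sum) / obs_sum
        out.append(
            ValidationResult(
                crop=str(crop),
                n=int(len(y)),
                slope=float(ols.params[1]),
                intercept=float(ols.params[0]),
                r2=float(ols.rsquared),
                bias_percent=bias,
                bias_exceeds_25=abs(bias) > 25.0,
            )
        )
    return out
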