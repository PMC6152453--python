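"""Campaign flux-model fitting and 30-min GEP/Reco/NEP reconstruction.

The measurement design is campaign-based: on each field day, repeated
transparent (NEP) and opaque (Reco) chamber closures are taken from
sunrise to late afternoon.  Per campaign we fit

* a Lloyd–Taylor temperature-response model for ecosystem respiration,

      Reco(T) = Rref * exp( E0 * (1/(Tref - T0) - 1/(T - T0)) )

  with Tref = 283.15 K, T0 = 227.13 K (the model's canonical constants),
  Rref in umol CO2 m-2 s-1 and E0 in K;

* a rectangular-hyperbola (Michaelis–Menten) light response for gross
  ecosystem production,

      GEP(PAR) = alpha * PAR * GPmax / (alpha * PAR + GPmax),

  fitted to GEP_obs = NEP + Reco(T), where Reco(T) comes from the fitted
  respiration model evaluated at each NEP closure's temperature.

The four parameters (Rref, E0, alpha, GPmax) are interpolated linearly in
time between campaign days (anchored at 12:00 local solar time, held
constant outside the campaign span), driven by continuous 30-min PAR and
temperature to reconstruct GEP/Reco/NEP, and summed sunrise-to-sunset into
daily GEP (GEP_d, gCO2-C m-2 d-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import solar
from .chamber import FluxRecord

__all__ = [
    "TREF_K",
    "T0_K",
    "E0_DEFAULT",
    "GC_PER_UMOL",
    "CampaignParams",
    "UnfittableCampaignError",
    "reco_model",
    "light_response",
    "fit_reco_campaign",
    "fit_light_campaign",
    "estimate_reco_at_nep_times",
    "interpolate_params",
    "reconstruct_30min",
    "daily_gep",
    "daily_par",
    "FluxPartitionModel",
    "FluxPartitionResults",
]

TREF_K = 283.15  # reference temperature (10 degC)
T0_K = 227.13  # Lloyd-Taylor zero-activity temperature
E0_DEFAULT = 308.56  # K, fallback temperature sensitivity
GC_PER_UMOL = 12.011e-6  # g C per umol CO2
STEP_S = 1800.0  # 30-min step

RREF_BOUNDS = (1e-6, 50.0)
E0_BOUNDS = (50.0, 450.0)
ALPHA_BOUNDS = (1e-6, 0.3)
GPMAX_BOUNDS = (1e-6, 120.0)
_LIGHT_STARTS = [(0.02, 20.0), (0.05, 40.0), (0.10, 80.0)]


class UnfittableCampaignError(ValueError):
    """Raised when a campaign has too few usable fluxes to fit a model."""


@dataclass
class CampaignParams:
    """Fitted flux-model parameters for one campaign day and plot."""

    campaign_date: pd.Timestamp
    plot_id: str
    rref: float  # umol CO2 m-2 s-1 at Tref
    e0: float  # K
    alpha: float  # umol CO2 per umol photons
    gpmax: float  # umol CO2 m-2 s-1
    diagnostics: dict = field(default_factory=dict)


def reco_model(t_c, rref, e0):
    """Lloyd–Taylor ecosystem respiration at air/soil temperature t_c (degC)."""
    t_k = np.asarray(t_c, dtype=float) + 273.15
    if np.any(t_k <= T0_K):
        raise ValueError(f"temperature at or below T0 ({T0_K - 273.15:.2f} degC)")
    out = rref * np.exp(e0 * (1.0 / (TREF_K - T0_K) - 1.0 / (t_k - T0_K)))
    return out if out.shape else float(out)


def light_response(par, alpha, gpmax):
    """Rectangular-hyperbola light response, GEP(0) = 0, GEP(inf) = GPmax."""
    par = np.asarray(par, dtype=float)
    out = alpha * par * gpmax / (alpha * par + gpmax)
    return out if out.shape else float(out)


def _reco_inverse_to_rref(flux: np.ndarray, t_c: np.ndarray, e0: float) -> float:
    """Map measured respiration at temperature t back to Rref for fixed E0."""
    scale = np.exp(e0 * (1.0 / (TREF_K - T0_K) - 1.0 / (np.asarray(t_c) + 273.15 - T0_K)))
    return float(np.mean(np.asarray(flux) / scale))


def fit_reco_campaign(
    temps: Sequence[float], fluxes: Sequence[float]
) -> tuple[float, float, dict]:
    """Fit (Rref, E0) to one campaign's respiration fluxes.

    Requires >= 4 fluxes.  When the temperature span is below 2 degC the
    temperature sensitivity is not identifiable; E0 is then fixed at
    308.56 K and only Rref is estimated (closed form).
    """
    t = np.asarray(temps, dtype=float)
    f = np.asarray(fluxes, dtype=float)
    if t.size < 4:
        raise UnfittableCampaignError(f"need >= 4 Reco fluxes, got {t.size}")
    span = float(t.max() - t.min())
    if span < 2.0:
        rref = _reco_inverse_to_rref(f, t, E0_DEFAULT)
        rref = float(np.clip(rref, *RREF_BOUNDS))
        sse = float(np.sum((f - reco_model(t, rref, E0_DEFAULT)) ** 2))
        return rref, E0_DEFAULT, {"n": int(t.size), "sse": sse, "fixed_e0": True}
    p0 = (max(float(np.median(f)), 0.1), E0_DEFAULT)
    popt, _ = curve_fit(
        reco_model,
        t,
        f,
        p0=p0,
        bounds=([RREF_BOUNDS[0], E0_BOUNDS[0]], [RREF_BOUNDS[1], E0_BOUNDS[1]]),
        maxfev=20000,
    )
    rref, e0 = float(popt[0]), float(popt[1])
    sse = float(np.sum((f - reco_model(t, rref, e0)) ** 2))
    return rref, e0, {"n": int(t.size), "sse": sse, "fixed_e0": False}


def fit_light_campaign(
    par: Sequence[float], gep: Sequence[float]
) -> tuple[float, float, dict]:
    """Fit (alpha, GPmax) to one campaign's GEP-vs-PAR points.

    Requires >= 4 points spanning >= 200 umol m-2 s-1 of PAR.  Three fixed
    starting points are tried and the fit with the smallest SSE wins (ties
    broken toward the smaller GPmax).  All-zero GEP is flagged degenerate.
    """
    p = np.asarray(par, dtype=float)
    g = np.asarray(gep, dtype=float)
    if p.size < 4:
        raise UnfittableCampaignError(f"need >= 4 GEP points, got {p.size}")
    if float(p.max() - p.min()) < 200.0:
        raise UnfittableCampaignError("PAR span below 200 umol m-2 s-1")
    degenerate = bool(np.allclose(g, 0.0, atol=1e-9))
    best: tuple[float, float, float] | None = None  # (sse, alpha, gpmax)
    for a0, g0 in _LIGHT_STARTS:
        try:
            popt, _ = curve_fit(
                light_response,
                p,
                g,
                p0=(a0, g0),
                bounds=(
                    [ALPHA_BOUNDS[0], GPMAX_BOUNDS[0]],
                    [ALPHA_BOUNDS[1], GPMAX_BOUNDS[1]],
                ),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((g - light_response(p, *popt)) ** 2))
        cand = (sse, float(popt[0]), float(popt[1]))
        if best is None or cand[0] < best[0] - 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[2] < best[2]
        ):
            best = cand
    if best is None:
        raise UnfittableCampaignError("light-response fit failed from all starts")
    sse, alpha, gpmax = best
    return alpha, gpmax, {"n": int(p.size), "sse": sse, "degenerate": degenerate}


def estimate_reco_at_nep_times(
    rref: float, e0: float, temps: Sequence[float]
) -> np.ndarray:
    """Modelled Reco at each NEP closure's temperature (for GEP = NEP + Reco)."""
    t = np.asarray(temps, dtype=float)
    if np.any(~np.isfinite(t)):
        raise ValueError("missing temperature at an NEP closure")
    return np.asarray(reco_model(t, rref, e0))


def interpolate_params(
    campaigns: Sequence[CampaignParams], grid: pd.DatetimeIndex
) -> pd.DataFrame:
    """Linear interpolation of campaign parameters onto a 30-min grid.

    Campaigns are anchored at 12:00 local time on their date; parameters
    are held constant before the first and after the last campaign.
    """
    if len(campaigns) == 0:
        raise UnfittableCampaignError("no fittable campaigns")
    camps = sorted(campaigns, key=lambda c: c.campaign_date)
    anchors = np.array(
        [
            (pd.Timestamp(c.campaign_date).normalize() + pd.Timedelta(hours=12)).value
            for c in camps
        ],
        dtype=float,
    )
    tgrid = grid.asi8.astype(float)
    out = {}
    for name in ("rref", "e0", "alpha", "gpmax"):
        vals = np.array([getattr(c, name) for c in camps], dtype=float)
        out[name] = np.interp(tgrid, anchors, vals)
    return pd.DataFrame(out, index=grid)


def reconstruct_30min(params: pd.DataFrame, drivers: pd.DataFrame) -> pd.DataFrame:
    """Evaluate the flux models on the 30-min driver grid.

    ``drivers`` needs columns ``par`` and ``t_reco`` (the temperature used
    for respiration — soil where available, else air).  Returns gep, reco
    and nep = gep - reco per step.
    """
    if not params.index.equals(drivers.index):
        raise ValueError("parameter and driver grids are misaligned")
    gep = light_response(drivers["par"].to_numpy(), params["alpha"].to_numpy(),
                         params["gpmax"].to_numpy())
    reco = reco_model(drivers["t_reco"].to_numpy(), params["rref"].to_numpy(),
                      params["e0"].to_numpy())
    gep = np.where(drivers["par"].to_numpy() > 0, gep, 0.0)
    return pd.DataFrame(
        {"gep": gep, "reco": reco, "nep": gep - reco}, index=params.index
    )


def _window_mask(index: pd.DatetimeIndex, date, window: tuple[float, float]):
    day = pd.Timestamp(date).normalize()
    t0 = day + pd.Timedelta(hours=window[0])
    t1 = day + pd.Timedelta(hours=window[1])
    return (index >= t0) & (index <= t1)


def daily_gep(series30: pd.DataFrame, date, window: tuple[float, float]) -> float:
    """Daily GEP: sum of 30-min GEP inside the daylight window, gCO2-C m-2 d-1."""
    mask = _window_mask(series30.index, date, window)
    sub = series30.loc[mask, "gep"]
    # grid positions a complete 30-min series would have inside the window
    expected = int(np.floor(window[1] * 2) - np.ceil(window[0] * 2)) + 1
    if sub.size < expected or sub.isna().any():
        raise ValueError(
            f"{pd.Timestamp(date).date()}: missing 30-min steps in the daylight window"
        )
    return float(sub.sum() * STEP_S * GC_PER_UMOL)


def daily_par(drivers: pd.DataFrame, date, window: tuple[float, float]) -> float:
    """PAR_d: mean 30-min PAR between sunrise and sunset, umol m-2 s-1."""
    mask = _window_mask(drivers.index, date, window)
    sub = drivers.loc[mask, "par"]
    if sub.empty or sub.isna().any():
        raise ValueError(f"{pd.Timestamp(date).date()}: missing PAR in daylight window")
    return float(sub.mean())


def par_threshold_window(
    drivers: pd.DataFrame, date, threshold: float = 1.0
) -> tuple[float, float]:
    """Daylight window from the drivers: first/last step with PAR > threshold."""
    day = pd.Timestamp(date).normalize()
    mask = (drivers.index >= day) & (drivers.index < day + pd.Timedelta(days=1))
    sub = drivers.loc[mask]
    lit = sub[sub["par"] > threshold]
    if lit.empty:
        raise ValueError(f"{day.date()}: no PAR above threshold")
    h0 = lit.index[0] - day
    h1 = lit.index[-1] - day
    return h0.total_seconds() / 3600.0, h1.total_seconds() / 3600.0


class FluxPartitionModel:
    """Campaign-wise flux partitioning for one plot.

    Built from QC'd flux records (grouped into campaigns by calendar date)
    and a continuous 30-min driver table with columns ``par``, ``t_air``
    and optionally ``t_soil``.  ``fit()`` returns a
    :class:`FluxPartitionResults` carrying campaign parameters, the
    reconstructed 30-min flux series and the daily GEP_d/PAR_d table.
    """

    def __init__(
        self,
        records: Sequence[FluxRecord],
        drivers: pd.DataFrame,
        latitude: float,
        plot_id: str | None = None,
        reco_temperature: str = "auto",
        window_mode: str = "solar",
        campaign_dates: Sequence | None = None,
        record_dates: Sequence | None = None,
    ):
        self.records = list(records)
        self.drivers = drivers
        self.latitude = latitude
        self.plot_id = plot_id or (records[0].plot_id if records else "plot")
        self.window_mode = window_mode
        if reco_temperature == "auto":
            has_soil = all(np.isfinite(r.t_soil) for r in self.records if r.flux_kind == "Reco")
            reco_temperature = "t_soil" if has_soil and "t_soil" in drivers else "t_air"
        self.reco_temperature = reco_temperature
        if record_dates is None:
            record_dates = [r.meta.get("date") for r in self.records]
        self.record_dates = [pd.Timestamp(d).normalize() for d in record_dates]
        if campaign_dates is None:
            campaign_dates = sorted(set(self.record_dates))
        self.campaign_dates = [pd.Timestamp(d).normalize() for d in campaign_dates]

    def _reco_temp(self, rec: FluxRecord) -> float:
        if self.reco_temperature == "t_soil" and np.isfinite(rec.t_soil):
            return rec.t_soil
        return rec.t_air

    def fit(self) -> "FluxPartitionResults":
        campaigns: list[CampaignParams] = []
        skipped: list[tuple[pd.Timestamp, str]] = []
        for day in self.campaign_dates:
            recs = [r for r, d in zip(self.records, self.record_dates) if d == day]
            reco_recs = [r for r in recs if r.flux_kind == "Reco"]
            nep_recs = [r for r in recs if r.flux_kind == "NEP"]
            try:
                rref, e0, diag_r = fit_reco_campaign(
                    [self._reco_temp(r) for r in reco_recs],
                    [r.flux for r in reco_recs],
                )
                reco_at_nep = estimate_reco_at_nep_times(
                    rref, e0, [self._reco_temp(r) for r in nep_recs]
                )
                gep_obs = np.array([r.flux for r in nep_recs]) + reco_at_nep
                alpha, gpmax, diag_l = fit_light_campaign(
                    [r.par for r in nep_recs], gep_obs
                )
            except UnfittableCampaignError as err:
                skipped.append((day, str(err)))
                continue
            campaigns.append(
                CampaignParams(
                    campaign_date=day,
                    plot_id=self.plot_id,
                    rref=rref,
                    e0=e0,
                    alpha=alpha,
                    gpmax=gpmax,
                    diagnostics={"reco": diag_r, "light": diag_l},
                )
            )
        params = interpolate_params(campaigns, self.drivers.index)
        drv = self.drivers.copy()
        if self.reco_temperature == "t_soil" and "t_soil" in drv:
            drv["t_reco"] = drv["t_soil"]
        else:
            drv["t_reco"] = drv["t_air"]
        series30 = reconstruct_30min(params, drv)
        daily = self._daily_table(series30)
        return FluxPartitionResults(
            model=self,
            campaign_params=campaigns,
            skipped_campaigns=skipped,
            param_series=params,
            series30=series30,
            daily=daily,
        )

    def _daily_table(self, series30: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for day in pd.DatetimeIndex(series30.index.normalize().unique()):
            doy = int(day.dayofyear)
            if self.window_mode == "par_threshold":
                try:
                    window = par_threshold_window(self.drivers, day)
                except ValueError:
                    continue
            else:
                window = solar.day_window(doy, self.latitude)
            try:
                g = daily_gep(series30, day, window)
                p = daily_par(self.drivers, day, window)
            except ValueError:
                continue  # partial day at the series edges
            rows.append(
                {"date": day, "plot_id": self.plot_id, "gep_d": g, "par_d": p}
            )
        return pd.DataFrame(rows)


@dataclass
class FluxPartitionResults:
    """Fitted campaign parameters plus reconstructed and daily series."""

    model: FluxPartitionModel
    campaign_params: list[CampaignParams]
    skipped_campaigns: list
    param_series: pd.DataFrame
    series30: pd.DataFrame
    daily: pd.DataFrame

    def campaign_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "campaign_date": c.campaign_date,
                    "plot_id": c.plot_id,
                    "rref": c.rref,
                    "e0": c.e0,
                    "alpha": c.alpha,
                    "gpmax": c.gpmax,
                }
                for c in self.campaign_params
            ]
        )

    def summary(self) -> str:
        lines = [
            f"Flux partitioning: plot {self.model.plot_id}",
            f"  campaigns fitted : {len(self.campaign_params)}"
            f" (skipped {len(self.skipped_campaigns)})",
            f"  respiration temp : {self.model.reco_temperature}",
            "",
            "  date        Rref    E0      alpha    GPmax",
        ]
        for c in self.campaign_params:
            lines.append(
                f"  {c.campaign_date.date()}  {c.rref:6.2f}  {c.e0:6.1f}"
                f"  {c.alpha:7.4f}  {c.gpmax:6.1f}"
            )
        if not self.daily.empty:
            lines += [
                "",
                f"  daily records    : {len(self.daily)}",
                f"  GEP_d max        : {self.daily['gep_d'].max():.2f} gCO2-C m-2 d-1",
                f"  PAR_d mean       : {self.daily['par_d'].mean():.0f} umol m-2 s-1",
            ]
        return "\n".join(lines)
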