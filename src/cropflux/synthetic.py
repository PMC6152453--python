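"""Synthetic crop seasons with known ground truth.

Everything downstream — per-closure flux fitting, campaign model fits,
parameter interpolation, daily aggregation, index computation, GEP_d
regression and the phase/hysteresis analysis — is testable against the
truth carried by these objects.

What is emulated
----------------
* 30-min drivers: clear-sky PAR as a half-sinusoid between sunrise and
  sunset (solar geometry for the configured latitude) scaled by a
  seasonal noon amplitude, optionally damped by a per-day cloudiness
  factor; air and soil temperature as seasonal + diurnal sinusoids.
* LAI phenology: logistic green-up to ``lai_max`` exactly at
  ``lai_peak_doy``, then a logistic decline of total LAI to a plateau
  (senesced leaves persist) while *green* LAI declines linearly at
  ``green_fraction_decline`` per day.
* Canopy reflectance: NDVI saturates with greenness,
  NDVI = ndvi_inf - (ndvi_inf - ndvi_soil) * exp(-k_ext * greenness),
  where greenness = greenLAI + senescent_greenness * (LAI - greenLAI);
  the senescent term keeps reflectance high after the peak relative to
  photosynthesis, which is what produces the vegetative/reproductive
  hysteresis of the GEP_d-vs-NDVI relation in winter-crop-like seasons.
* Campaign-style chamber closures: 5-12 transparent (120 s) and opaque
  (180 s) closures per campaign day at 1 Hz, whose traces drift linearly
  at slope = F_true * A * Mv / V plus gaussian noise.

True flux parameters vary piecewise-linearly between campaign days
(anchored at 12:00), with GPmax tied to green LAI and Rref carrying a
small biomass-linked seasonal term; closures on a campaign day draw
their true fluxes from that day's anchor parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .chamber import (
    DEFAULT_AREA_M2,
    DEFAULT_VOLUME_M3,
    ChamberClosure,
    molar_volume,
)
from .partition import interpolate_params, light_response, reco_model, CampaignParams

__all__ = [
    "SeasonConfig",
    "TruthBundle",
    "generate_drivers",
    "generate_lai_curve",
    "generate_reflectance",
    "generate_closures",
    "generate_season",
]

STANDARD_PRESSURE_PA = 101325.0
BASE_CO2_PPM = 400.0


@dataclass(frozen=True)
class SeasonConfig:
    """Configuration of one synthetic crop season.

    Defaults describe a winter-wheat-like season at a central-European
    site (52.43 N): green-up from early March, LAI peaking at 3.3 m2 m-2
    in late May, harvest at the start of August.
    """

    crop_label: str = "winter_wheat"
    year: int = 2012
    start_doy: int = 60
    end_doy: int = 215
    latitude: float = 52.43
    # LAI phenology
    lai_max: float = 3.3  # m2 m-2
    lai_start: float = 0.8  # m2 m-2 at start_doy (winter crops are already green)
    lai_peak_doy: int = 150
    lai_rise_rate: float = 0.12  # d-1
    lai_fall_rate: float = 0.10  # d-1
    lai_plateau: float = 2.5  # m2 m-2, senesced canopy persists
    green_fraction_decline: float = 0.02  # d-1 after the peak
    # flux-model truth
    gpmax_per_lai: float = 20.0  # umol CO2 m-2 s-1 per unit green LAI
    alpha_true: float = 0.05  # umol CO2 per umol photons
    rref_true: float = 2.5  # umol CO2 m-2 s-1 at 10 degC
    rref_seasonal_amp: float = 0.25  # fraction of rref tied to green LAI
    e0_true: float = 308.56  # K
    # drivers
    par_noon_max: float = 1700.0  # umol m-2 s-1 at the seasonal maximum
    t_mean_annual: float = 8.5  # degC
    t_seasonal_amp: float = 10.0  # degC, peak late July
    t_diurnal_amp: float = 5.0  # degC, peak mid-afternoon
    weather_noise: float = 0.35  # 0..1, strength of daily cloudiness
    # reflectance
    ndvi_soil: float = 0.15
    ndvi_inf: float = 0.92
    k_ext: float = 0.85  # per unit greenness LAI
    senescent_greenness: float = 0.35  # greenness carried by senesced leaves
    rho850: float = 0.45
    rho570: float = 0.08
    pri_level: float = -0.19
    # sampling / noise
    campaign_interval_days: int = 12
    closures_per_day: int | None = None  # None: scale with daylength, 5..12
    conc_noise_sd: float = 0.0  # umol mol-1 on the concentration trace
    refl_noise_sd: float = 0.0  # absolute, per band
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lai_max <= 0:
            raise ValueError("lai_max must be positive")
        if not (self.start_doy < self.lai_peak_doy < self.end_doy):
            raise ValueError("need start_doy < lai_peak_doy < end_doy")
        if not (self.ndvi_soil < self.ndvi_inf <= 1.0):
            raise ValueError("need ndvi_soil < ndvi_inf <= 1")
        if self.conc_noise_sd < 0 or self.refl_noise_sd < 0 or self.weather_noise < 0:
            raise ValueError("noise levels must be >= 0")
        if self.end_doy <= self.start_doy:
            raise ValueError("end_doy must exceed start_doy")

    def date(self, doy: int | float) -> pd.Timestamp:
        return pd.Timestamp(f"{self.year}-01-01") + pd.Timedelta(days=float(doy) - 1)

    @classmethod
    def winter_cereal_hysteresis(cls, seed: int = 0, **overrides) -> "SeasonConfig":
        """A winter-cereal season exhibiting the VI-vs-GEP_d hysteresis.

        The canopy is already dense when the analyzed period opens
        (LAI 1.5), so NDVI sits near its asymptote throughout green-up
        while photosynthesis keeps rising with green biomass; during
        senescence the canopy loses function (green LAI) faster than
        structure (total LAI), and residual senesced leaves keep a small
        greenness signal.  The GEP_d-vs-NDVI relation therefore has very
        different slopes in the vegetative and reproductive phases,
        while the NDVI*LAI product tracks GEP_d in both.
        """
        kwargs = dict(
            lai_start=1.5,
            k_ext=1.8,
            lai_plateau=2.0,
            senescent_greenness=0.1,
            green_fraction_decline=0.008,
            weather_noise=0.10,
            refl_noise_sd=0.002,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def hysteresis_free(cls, seed: int = 0, **overrides) -> "SeasonConfig":
        """A season whose green LAI never detaches from total LAI.

        With ``green_fraction_decline`` 0 the reflectance-driving
        greenness equals the photosynthesis-driving green LAI at every
        date, so GEP_d and NDVI trace the same curve in both phenological
        phases and there is no hysteresis to detect.
        """
        kwargs = dict(green_fraction_decline=0.0, seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TruthBundle:
    """Ground truth for one synthetic season."""

    config: SeasonConfig
    drivers: pd.DataFrame  # 30-min par, t_air, t_soil
    series30: pd.DataFrame  # true gep, reco, nep on the driver grid
    param_series: pd.DataFrame  # rref, e0, alpha, gpmax on the driver grid
    campaign_days: list[pd.Timestamp]
    campaign_truth: pd.DataFrame  # per campaign day: anchor parameters
    lai: pd.DataFrame  # per day: lai, green_lai, greenness
    daily: pd.DataFrame  # per day: gep_d, par_d, lai, reflectance + indices

    def params_on(self, day) -> dict:
        day = pd.Timestamp(day).normalize()
        row = self.campaign_truth.loc[self.campaign_truth["date"] == day]
        if row.empty:
            raise KeyError(f"{day.date()} is not a campaign day of this season")
        return row.iloc[0].to_dict()


def _noon_par(config: SeasonConfig, doys: np.ndarray) -> np.ndarray:
    """Seasonal noon-PAR amplitude, = par_noon_max at the in-season maximum."""
    elev = np.array(
        [
            np.pi / 2
            - abs(np.radians(config.latitude) - solar.solar_declination(d))
            for d in doys
        ]
    )
    shape = np.sin(np.clip(elev, 0.0, None))
    return config.par_noon_max * shape / shape.max()


def generate_drivers(config: SeasonConfig) -> pd.DataFrame:
    """30-min PAR and air/soil temperature for the season.

    PAR is a half-sinusoid between solar sunrise and sunset, exactly zero
    at night; with ``weather_noise`` 0 the noon value on the brightest day
    equals ``par_noon_max``.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    doys = np.arange(config.start_doy, config.end_doy + 1)
    noon = _noon_par(config, doys)
    # per-day cloudiness factor in (0, 1]
    if config.weather_noise > 0:
        cloud = 1.0 - config.weather_noise * rng.beta(2.0, 2.0, size=doys.size)
    else:
        cloud = np.ones(doys.size)
    frames = []
    for doy, par_noon, cf in zip(doys, noon, cloud):
        day = config.date(int(doy))
        idx = pd.date_range(day, periods=48, freq="30min")
        hours = idx.hour + idx.minute / 60.0
        sunrise, sunset = solar.day_window(int(doy), config.latitude)
        daylen = sunset - sunrise
        par = np.where(
            (hours >= sunrise) & (hours <= sunset),
            cf * par_noon * np.sin(np.pi * (hours - sunrise) / daylen),
            0.0,
        )
        par = np.clip(par, 0.0, None)
        seasonal = config.t_seasonal_amp * np.cos(2 * np.pi * (doy - 202) / 365.0)
        diurnal = config.t_diurnal_amp * np.cos(2 * np.pi * (hours - 15.0) / 24.0)
        t_air = config.t_mean_annual + seasonal + diurnal
        t_soil = config.t_mean_annual + 0.8 * seasonal + 0.3 * diurnal
        frames.append(
            pd.DataFrame({"par": par, "t_air": t_air, "t_soil": t_soil}, index=idx)
        )
    return pd.concat(frames)


def generate_lai_curve(config: SeasonConfig) -> pd.DataFrame:
    """Daily total LAI, green LAI and reflectance-driving greenness.

    Total LAI rises logistically to exactly ``lai_max`` at
    ``lai_peak_doy``, then declines logistically toward ``lai_plateau``.
    Green LAI equals total LAI before the peak and declines linearly at
    ``green_fraction_decline`` per day after it.
    """
    doys = np.arange(config.start_doy, config.end_doy + 1, dtype=float)
    peak = float(config.lai_peak_doy)
    t1 = (config.start_doy + peak) / 2.0
    rise = 1.0 / (1.0 + np.exp(-config.lai_rise_rate * (doys - t1)))
    rise_norm = rise / (1.0 / (1.0 + np.exp(-config.lai_rise_rate * (peak - t1))))
    plateau_frac = min(config.lai_plateau / config.lai_max, 1.0)
    t2 = peak + 0.35 * (config.end_doy - peak)
    fall = 1.0 / (1.0 + np.exp(config.lai_fall_rate * (doys - t2)))
    fall_norm = fall / (1.0 / (1.0 + np.exp(config.lai_fall_rate * (peak - t2))))
    start_frac = min(config.lai_start / config.lai_max, 1.0)
    rise_scaled = start_frac + (1.0 - start_frac) * (rise_norm - rise_norm[0]) / (
        1.0 - rise_norm[0]
    )
    g = np.where(doys <= peak, rise_scaled, plateau_frac + (1 - plateau_frac) * fall_norm)
    lai = config.lai_max * np.clip(g, 0.0, 1.0)
    green_frac = np.where(
        doys <= peak,
        1.0,
        np.clip(1.0 - config.green_fraction_decline * (doys - peak), 0.0, 1.0),
    )
    green = lai * green_frac
    greenness = green + config.senescent_greenness * (lai - green)
    return pd.DataFrame(
        {
            "doy": doys.astype(int),
            "lai": lai,
            "green_lai": green,
            "greenness": greenness,
        },
        index=[config.date(int(d)) for d in doys],
    )


def generate_reflectance(
    lai_green: float | np.ndarray,
    config: SeasonConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Band reflectances consistent with a saturating NDVI.

    NDVI(g) = ndvi_inf - (ndvi_inf - ndvi_soil) * exp(-k_ext * g) for
    greenness g; rho850 is held fixed and rho670 solved from NDVI.  The
    photochemical bands sit near a constant PRI level.  Additive gaussian
    band noise (sd ``refl_noise_sd``) is truncated at zero.
    """
    g = np.atleast_1d(np.asarray(lai_green, dtype=float))
    if np.any(g < 0):
        raise ValueError("greenness LAI must be >= 0")
    nd = config.ndvi_inf - (config.ndvi_inf - config.ndvi_soil) * np.exp(
        -config.k_ext * g
    )
    rho850 = np.full_like(nd, config.rho850)
    rho670 = rho850 * (1.0 - nd) / (1.0 + nd)
    rho570 = np.full_like(nd, config.rho570)
    # PRI = (rho570 - rho531)/(rho570 + rho531) at pri_level
    rho531 = rho570 * (1.0 - config.pri_level) / (1.0 + config.pri_level)
    bands = np.column_stack([rho531, rho570, rho670, rho850])
    if config.refl_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        bands = bands + rng.normal(0.0, config.refl_noise_sd, size=bands.shape)
        bands = np.clip(bands, 1e-6, None)
    return pd.DataFrame(bands, columns=["rho531", "rho570", "rho670", "rho850"])


def _campaign_days(config: SeasonConfig) -> list[int]:
    first = config.start_doy + 5
    last = config.end_doy - 3
    return list(range(first, last + 1, config.campaign_interval_days))


def _true_campaign_params(config: SeasonConfig, lai: pd.DataFrame) -> pd.DataFrame:
    days = _campaign_days(config)
    rows = []
    for doy in days:
        green = float(lai.loc[lai["doy"] == doy, "green_lai"].iloc[0])
        gpmax = max(config.gpmax_per_lai * green, 0.5)
        rref = config.rref_true * (
            1.0 + config.rref_seasonal_amp * green / config.lai_max
        )
        rows.append(
            {
                "date": config.date(doy),
                "doy": doy,
                "rref": rref,
                "e0": config.e0_true,
                "alpha": config.alpha_true,
                "gpmax": gpmax,
            }
        )
    return pd.DataFrame(rows)


def generate_closures(
    day,
    truth: TruthBundle,
    config: SeasonConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[ChamberClosure]:
    """Chamber closures for one campaign day of a synthetic season.

    Transparent closures (120 s at 1 Hz) record NEP, opaque closures
    (180 s) record Reco, spread from just after sunrise to late
    afternoon; the number of transparent/opaque pairs scales with
    daylength from 5 to 12.  Each trace is
    C(t) = C0 + slope_true * t + noise with
    slope_true = F_true * A * Mv / V — negative for CO2 uptake in the
    transparent chamber, positive for respiration in the opaque one.
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    day = pd.Timestamp(day).normalize()
    params = truth.params_on(day)  # KeyError if not a campaign day
    doy = int(day.dayofyear)
    sunrise, sunset = solar.day_window(doy, config.latitude)
    daylen = sunset - sunrise
    if config.closures_per_day is not None:
        n = int(config.closures_per_day)
    else:
        n = int(round(5 + 7 * (daylen - 8.0) / 8.0))
    n = int(np.clip(n, 5, 12))
    # sunrise+0.5h to ~2h before sunset ("sunrise to late afternoon")
    hours = np.linspace(sunrise + 0.5, sunset - 2.0, n)
    closures: list[ChamberClosure] = []
    drv = truth.drivers
    for i, h in enumerate(hours):
        step = day + pd.Timedelta(hours=(np.floor(h * 2) / 2))
        row = drv.loc[step]
        par = float(row["par"])
        t_air = float(row["t_air"])
        t_soil = float(row["t_soil"])
        mv = molar_volume(t_air, STANDARD_PRESSURE_PA)
        gep = light_response(par, params["alpha"], params["gpmax"]) if par > 0 else 0.0
        reco = reco_model(t_soil, params["rref"], params["e0"])
        nep = gep - reco
        for kind, dur, f_true, sign in (
            ("transparent", 120, nep, -1.0),
            ("opaque", 180, reco, +1.0),
        ):
            t = np.arange(0, dur + 1, dtype=float)  # 1 Hz
            slope = sign * f_true * DEFAULT_AREA_M2 * mv / DEFAULT_VOLUME_M3
            co2 = BASE_CO2_PPM + slope * t
            if config.conc_noise_sd > 0:
                co2 = co2 + rng.normal(0.0, config.conc_noise_sd, size=t.size)
            closures.append(
                ChamberClosure(
                    closure_id=f"{config.crop_label}-{day.date()}-{kind[:1]}{i:02d}",
                    plot_id=config.crop_label,
                    chamber_kind=kind,
                    timestamps=t,
                    co2=co2,
                    t_air=t_air,
                    pressure=STANDARD_PRESSURE_PA,
                    par=par,
                    t_soil=t_soil,
                    volume=DEFAULT_VOLUME_M3,
                    area=DEFAULT_AREA_M2,
                )
            )
    return closures


def generate_season(config: SeasonConfig) -> TruthBundle:
    """Full synthetic season: drivers, truth fluxes, LAI, daily table.

    The daily table carries true GEP_d (sunrise-to-sunset sum of true
    30-min GEP), PAR_d, LAI and band reflectances with spectral indices —
    a drop-in for the observed daily table of a real season.
    """
    drivers = generate_drivers(config)
    lai = generate_lai_curve(config)
    camp = _true_campaign_params(config, lai)
    campaigns = [
        CampaignParams(
            campaign_date=row["date"],
            plot_id=config.crop_label,
            rref=row["rref"],
            e0=row["e0"],
            alpha=row["alpha"],
            gpmax=row["gpmax"],
        )
        for _, row in camp.iterrows()
    ]
    params = interpolate_params(campaigns, drivers.index)
    par = drivers["par"].to_numpy()
    gep = np.where(
        par > 0,
        light_response(par, params["alpha"].to_numpy(), params["gpmax"].to_numpy()),
        0.0,
    )
    reco = reco_model(
        drivers["t_soil"].to_numpy(), params["rref"].to_numpy(), params["e0"].to_numpy()
    )
    series30 = pd.DataFrame(
        {"gep": gep, "reco": reco, "nep": gep - reco}, index=drivers.index
    )
    rng = np.random.default_rng(config.seed + 2)
    refl = generate_reflectance(lai["greenness"].to_numpy(), config, rng=rng)
    refl.index = lai.index
    from .indices import vi_table  # local import to avoid cycle at module load

    daily_rows = []
    for day, lrow in lai.iterrows():
        doy = int(lrow["doy"])
        window = solar.day_window(doy, config.latitude)
        mask = (series30.index >= day + pd.Timedelta(hours=window[0])) & (
            series30.index <= day + pd.Timedelta(hours=window[1])
        )
        gep_d = float(series30.loc[mask, "gep"].sum() * 1800.0 * 12.011e-6)
        par_d = float(drivers.loc[mask, "par"].mean())
        daily_rows.append(
            {
                "date": day,
                "doy": doy,
                "crop": config.crop_label,
                "gep_d": gep_d,
                "par_d": par_d,
                "lai": float(lrow["lai"]),
                "green_lai": float(lrow["green_lai"]),
            }
        )
    daily = pd.DataFrame(daily_rows).set_index("date")
    daily = daily.join(vi_table(refl))
    return TruthBundle(
        config=config,
        drivers=drivers,
        series30=series30,
        param_series=params,
        campaign_days=list(camp["date"]),
        campaign_truth=camp,
        lai=lai,
        daily=daily.reset_index(),
    )
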