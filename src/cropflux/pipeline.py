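"""End-to-end orchestration: simulate -> fluxes -> partition -> daily ->
indices -> fit -> validate -> hysteresis -> report.

Each stage reads the previous stage's CSV from the output directory and
writes its own, so synthetic output and externally supplied tables are
interchangeable.  A structured log accounts for every record dropped at
QC and merge steps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chamber, io, phases, regression, synthetic
from .partition import FluxPartitionModel

__all__ = ["RunConfig", "STAGES", "run_pipeline"]

log = logging.getLogger("cropflux")

STAGES = [
    "simulate",
    "fluxes",
    "partition",
    "daily",
    "indices",
    "fit",
    "validate",
    "hysteresis",
    "report",
]


@dataclass
class RunConfig:
    out_dir: str = "cropflux_run"
    seed: int = 0
    latitude: float = 52.43
    r2_min: float = 0.8
    near_zero_abs: float = 0.5
    discard_initial_s: float = 10.0
    savi_l: float = 0.5
    wdrvi_alpha: float = 0.2
    phase_rule: str = "max_lai"
    season: dict = field(default_factory=dict)  # SeasonConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def season_config(self) -> synthetic.SeasonConfig:
        kwargs = dict(self.season)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("latitude", self.latitude)
        return synthetic.SeasonConfig(**kwargs)


def _p(config: RunConfig, name: str) -> Path:
    return Path(config.out_dir) / name


def _require(config: RunConfig, name: str, stage: str) -> Path:
    path = _p(config, name)
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {path} — run the upstream stage first"
        )
    return path


def stage_simulate(config: RunConfig) -> None:
    season = config.season_config()
    truth = synthetic.generate_season(season)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_drivers(truth.drivers, _p(config, "drivers.csv"))
    closures, dates = [], []
    rng = np.random.default_rng(season.seed + 1)
    for day in truth.campaign_days:
        cls = synthetic.generate_closures(day, truth, season, rng=rng)
        closures.extend(cls)
        dates.extend([pd.Timestamp(day).date()] * len(cls))
    io.write_closures(closures, _p(config, "closures.csv"), dates=dates)
    truth.lai.to_csv(_p(config, "lai.csv"), index_label="date")
    truth.daily.to_csv(_p(config, "daily_truth.csv"), index=False)
    log.info("simulate: %d closures over %d campaigns", len(closures),
             len(truth.campaign_days))


def stage_fluxes(config: RunConfig) -> None:
    closures, dates = io.read_closures(_require(config, "closures.csv", "fluxes"))
    records = [
        chamber.process_closure(c, discard_initial_s=config.discard_initial_s)
        for c in closures
    ]
    records = chamber.qc_filter(records, r2_min=config.r2_min,
                                near_zero_abs=config.near_zero_abs)
    rows = []
    for rec, date in zip(records, dates):
        rows.append(
            {
                "closure_id": rec.closure_id,
                "plot_id": rec.plot_id,
                "date": date,
                "flux_kind": rec.flux_kind,
                "flux": rec.flux,
                "raw_slope": rec.raw_slope,
                "r2": rec.r2,
                "par": rec.par,
                "t_air": rec.t_air,
                "t_soil": rec.t_soil,
                "qc_flag": rec.qc_flag,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(_p(config, "fluxes.csv"), index=False)
    n_in, n_ex = len(df), int((df["qc_flag"] == "excluded_r2").sum())
    log.info("fluxes: %d closures, %d excluded by r2 < %.2f, %d retained",
             n_in, n_ex, config.r2_min, n_in - n_ex)


def stage_partition(config: RunConfig) -> None:
    flux_df = pd.read_csv(_require(config, "fluxes.csv", "partition"))
    drivers = io.read_drivers(_require(config, "drivers.csv", "partition"))
    usable = flux_df[flux_df["qc_flag"] != "excluded_r2"]
    records = [
        chamber.FluxRecord(
            closure_id=r.closure_id,
            plot_id=r.plot_id,
            flux_kind=r.flux_kind,
            flux=r.flux,
            raw_slope=r.raw_slope,
            r2=r.r2,
            par=r.par,
            t_air=r.t_air,
            t_soil=r.t_soil,
            qc_flag=r.qc_flag,
        )
        for r in usable.itertuples()
    ]
    model = FluxPartitionModel(
        records,
        drivers,
        latitude=config.latitude,
        record_dates=list(usable["date"]),
    )
    results = model.fit()
    results.campaign_table().to_csv(_p(config, "campaign_params.csv"), index=False)
    results.series30.to_csv(_p(config, "series30.csv"), index_label="timestamp")
    results.daily.to_csv(_p(config, "daily_flux.csv"), index=False)
    log.info("partition: %d campaigns fitted, %d skipped",
             len(results.campaign_params), len(results.skipped_campaigns))


def stage_daily(config: RunConfig) -> None:
    daily = pd.read_csv(_require(config, "daily_flux.csv", "daily"),
                        parse_dates=["date"])
    lai = pd.read_csv(_require(config, "lai.csv", "daily"), parse_dates=["date"])
    merged = daily.merge(lai[["date", "lai", "green_lai"]], on="date", how="left")
    n_missing = int(merged["lai"].isna().sum())
    merged.to_csv(_p(config, "daily.csv"), index=False)
    log.info("daily: %d records, %d without LAI", len(merged), n_missing)


def stage_indices(config: RunConfig) -> None:
    truth = pd.read_csv(_require(config, "daily_truth.csv", "indices"),
                        parse_dates=["date"])
    daily = pd.read_csv(_require(config, "daily.csv", "indices"),
                        parse_dates=["date"])
    refl = truth[["date", "rho531", "rho570", "rho670", "rho850"]].set_index("date")
    from .indices import vi_table

    vi = vi_table(refl, savi_l=config.savi_l,
                  wdrvi_alpha=config.wdrvi_alpha).reset_index()
    merged = daily.merge(
        vi[["date", "ndvi", "savi", "pri", "wdrvi", "swdrvi"]],
        on="date", how="left",
    )
    merged["crop"] = truth["crop"].iloc[0]
    merged.to_csv(_p(config, "daily_vi.csv"), index=False)
    log.info("indices: %d daily records with VIs", len(merged))


def stage_fit(config: RunConfig) -> None:
    daily = pd.read_csv(_require(config, "daily_vi.csv", "fit"),
                        parse_dates=["date"])
    daily = daily.rename(columns={"crop_x": "crop"}) if "crop_x" in daily else daily
    table = regression.model_table(daily)
    table.to_csv(_p(config, "model_table.csv"), index=False)
    log.info("fit: %d model rows", len(table))


def stage_validate(config: RunConfig) -> None:
    daily = pd.read_csv(_require(config, "daily_vi.csv", "validate"),
                        parse_dates=["date"])
    daily = daily.rename(columns={"crop_x": "crop"}) if "crop_x" in daily else daily
    spec = regression.ModelSpec(4, "NDVI")
    general = regression.GEPRegression.from_dataframe(
        daily, spec, dataset_label="all crops"
    ).fit()
    results = regression.predict_and_validate(general, daily)
    pd.DataFrame([dataclasses.asdict(v) for v in results]).to_csv(
        _p(config, "validation.csv"), index=False
    )
    with open(_p(config, "general_model.json"), "w") as fh:
        json.dump({"slope": general.slope, "intercept": general.intercept,
                   "r2": general.r2, "rmse": general.rmse,
                   "nrmse": general.nrmse, "n": general.n}, fh, indent=1)
    log.info("validate: general model slope %.2f intercept %.2f", general.slope,
             general.intercept)


def stage_hysteresis(config: RunConfig) -> None:
    daily = pd.read_csv(_require(config, "daily_vi.csv", "hysteresis"),
                        parse_dates=["date"])
    daily = daily.rename(columns={"crop_x": "crop"}) if "crop_x" in daily else daily
    table = phases.hysteresis_table(daily, rule=config.phase_rule)
    table.to_csv(_p(config, "hysteresis.csv"), index=False)
    log.info("hysteresis: %s", ", ".join(
        f"{r.predictor} t={r.t:.2f} p={r.p:.3g}" for r in table.itertuples()
    ))


def stage_report(config: RunConfig) -> None:
    lines = ["# cropflux run report", ""]
    mt = _p(config, "model_table.csv")
    if mt.exists():
        table = pd.read_csv(mt)
        lines += ["## GEP_d model goodness of fit", "",
                  table.to_string(index=False,
                                  float_format=lambda v: f"{v:.3g}"), ""]
    vp = _p(config, "validation.csv")
    if vp.exists():
        val = pd.read_csv(vp)
        lines += ["## Per-crop validation of the general NDVI*LAI model", "",
                  val.to_string(index=False,
                                float_format=lambda v: f"{v:.3g}"), ""]
    hp = _p(config, "hysteresis.csv")
    if hp.exists():
        hyst = pd.read_csv(hp)
        lines += ["## Phase slope tests", "",
                  hyst.to_string(index=False,
                                 float_format=lambda v: f"{v:.3g}"), ""]
    _p(config, "report.md").write_text("\n".join(lines))
    log.info("report: written to %s", _p(config, "report.md"))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fluxes": stage_fluxes,
    "partition": stage_partition,
    "daily": stage_daily,
    "indices": stage_indices,
    "fit": stage_fit,
    "validate": stage_validate,
    "hysteresis": stage_hysteresis,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the selected stages in canonical order; returns a run report."""
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ran = []
    for stage in STAGES:
        if stage in stages:
            _STAGE_FUNCS[stage](config)
            ran.append(stage)
    return {"stages": ran, "out_dir": str(config.out_dir)}
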