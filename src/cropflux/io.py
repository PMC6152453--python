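"""CSV interchange formats shared by the synthetic generator and pipeline.

All tables are plain CSV with headers.  The closure table is long format
(one row per concentration sample); drivers and daily tables are one row
per timestamp/date.  A column-map dict adapts externally exported daily
tables (e.g. a supplementary data export) to the package's column names.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chamber import ChamberClosure

__all__ = [
    "write_closures",
    "read_closures",
    "write_drivers",
    "read_drivers",
    "load_supplementary_daily",
]

CLOSURE_COLUMNS = [
    "closure_id",
    "plot_id",
    "chamber_kind",
    "t_s",
    "co2_ppm",
    "t_air_c",
    "pressure_pa",
    "par",
    "t_soil_c",
    "volume_m3",
    "area_m2",
    "date",
]


def write_closures(closures: Sequence[ChamberClosure], path, dates=None) -> None:
    """Write closures as a long-format CSV (one row per sample)."""
    rows = []
    dates = list(dates) if dates is not None else [None] * len(closures)
    for cl, date in zip(closures, dates):
        for t, c in zip(cl.timestamps, cl.co2):
            rows.append(
                {
                    "closure_id": cl.closure_id,
                    "plot_id": cl.plot_id,
                    "chamber_kind": cl.chamber_kind,
                    "t_s": t,
                    "co2_ppm": c,
                    "t_air_c": cl.t_air,
                    "pressure_pa": cl.pressure,
                    "par": cl.par,
                    "t_soil_c": cl.t_soil,
                    "volume_m3": cl.volume,
                    "area_m2": cl.area,
                    "date": date,
                }
            )
    pd.DataFrame(rows, columns=CLOSURE_COLUMNS).to_csv(path, index=False)


def read_closures(path) -> tuple[list[ChamberClosure], list]:
    """Read a long-format closure CSV back into closure objects."""
    df = pd.read_csv(path)
    closures, dates = [], []
    for cid, grp in df.groupby("closure_id", sort=False):
        first = grp.iloc[0]
        closures.append(
            ChamberClosure(
                closure_id=str(cid),
                plot_id=str(first["plot_id"]),
                chamber_kind=str(first["chamber_kind"]),
                timestamps=grp["t_s"].to_numpy(dtype=float),
                co2=grp["co2_ppm"].to_numpy(dtype=float),
                t_air=float(first["t_air_c"]),
                pressure=float(first["pressure_pa"]),
                par=float(first["par"]),
                t_soil=float(first["t_soil_c"]),
                volume=float(first["volume_m3"]),
                area=float(first["area_m2"]),
            )
        )
        dates.append(first.get("date"))
    return closures, dates


def write_drivers(drivers: pd.DataFrame, path) -> None:
    drivers.to_csv(path, index_label="timestamp")


def read_drivers(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="timestamp", parse_dates=True)


DEFAULT_DAILY_MAP = {
    "crop": "crop",
    "year": "year",
    "date": "date",
    "gep_d": "gep_d",
    "lai": "lai",
    "ndvi": "ndvi",
    "savi": "savi",
    "swdrvi": "swdrvi",
    "pri": "pri",
    "par_d": "par_d",
}


def load_supplementary_daily(
    path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Load an externally exported daily table via a column map.

    ``column_map`` maps package column names to the file's column names;
    unmapped optional columns become NaN (rows stay usable for the
    models that do not need them).  A mappable GEP_d column is required.
    Rows with no finite GEP_d are dropped (and counted in the returned
    frame's ``attrs['dropped']``).
    """
    cmap = dict(DEFAULT_DAILY_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    raw.columns = [c.strip().lower() for c in raw.columns]
    if cmap["gep_d"].lower() not in raw.columns:
        raise ValueError(f"no mappable GEP_d column {cmap['gep_d']!r} in {path}")
    out = pd.DataFrame(index=raw.index)
    for ours, theirs in cmap.items():
        theirs = theirs.lower()
        if theirs in raw.columns:
            out[ours] = raw[theirs]
        else:
            out[ours] = np.nan
    keep = pd.to_numeric(out["gep_d"], errors="coerce").notna()
    dropped = int((~keep).sum())
    out = out[keep].reset_index(drop=True)
    for col in ("gep_d", "lai", "ndvi", "savi", "swdrvi", "pri", "par_d"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out.attrs["dropped"] = dropped
    return out
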