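"""Per-closure CO2 flux computation for closed dynamic chambers.

A chamber closure yields a short CO2 concentration trace C(t) in the
chamber headspace.  The flux across the enclosed soil/canopy area is

    F = dC/dt * V / (A * Mv)

where V is chamber volume (m3), A the collar area (m2) and Mv the molar
volume of air (m3 mol-1) at the chamber air temperature and pressure.
dC/dt is the ordinary least-squares slope of the trace; its r2 drives
quality control (fluxes with r2 < 0.8 are excluded unless they are
near-zero, which a linear fit cannot resolve from noise).

Sign convention: transparent-chamber closures measure net ecosystem
production (NEP, uptake-positive, so an uptake draws concentration down
and the raw slope is negative); opaque closures measure ecosystem
respiration (Reco, release-positive, raw slope positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "DEFAULT_VOLUME_M3",
    "DEFAULT_AREA_M2",
    "ChamberClosure",
    "FluxRecord",
    "fit_concentration_slope",
    "molar_volume",
    "compute_flux",
    "process_closure",
    "qc_filter",
]

GAS_CONSTANT = 8.31446  # J mol-1 K-1

# Chamber geometry defaults: 0.78 x 0.78 x 0.50 m chamber (0.296 m3 total)
# on a 0.75 x 0.75 m collar.
DEFAULT_VOLUME_M3 = 0.296
DEFAULT_AREA_M2 = 0.5625

ChamberKind = Literal["transparent", "opaque"]


@dataclass(frozen=True)
class ChamberClosure:
    """One chamber deployment: concentration trace plus environment."""

    closure_id: str
    plot_id: str
    chamber_kind: ChamberKind
    timestamps: np.ndarray  # seconds from closure start
    co2: np.ndarray  # umol mol-1
    t_air: float  # degC, mean over the closure
    pressure: float  # Pa
    par: float  # umol m-2 s-1, mean during closure
    t_soil: float = float("nan")  # degC
    volume: float = DEFAULT_VOLUME_M3  # m3
    area: float = DEFAULT_AREA_M2  # m2

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        c = np.asarray(self.co2, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "co2", c)
        if t.size < 10:
            raise ValueError(
                f"closure {self.closure_id}: needs >= 10 samples, got {t.size}"
            )
        if t.size != c.size:
            raise ValueError(f"closure {self.closure_id}: trace length mismatch")
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"closure {self.closure_id}: timestamps must be strictly increasing"
            )
        if self.volume <= 0 or self.area <= 0:
            raise ValueError(f"closure {self.closure_id}: V and A must be positive")
        if self.chamber_kind not in ("transparent", "opaque"):
            raise ValueError(f"closure {self.closure_id}: bad chamber_kind")


@dataclass
class FluxRecord:
    """One quality-controlled flux with its provenance."""

    closure_id: str
    plot_id: str
    flux_kind: Literal["NEP", "Reco"]
    flux: float  # umol CO2 m-2 s-1, NEP uptake-positive / Reco release-positive
    raw_slope: float  # umol mol-1 s-1, sign as observed
    r2: float
    par: float
    t_air: float
    t_soil: float = float("nan")
    qc_flag: Literal["pass", "excluded_r2", "near_zero_review"] = "pass"
    meta: dict = field(default_factory=dict)


def fit_concentration_slope(closure: ChamberClosure) -> tuple[float, float]:
    """OLS slope (umol mol-1 s-1) and r2 of the CO2 trace.

    A trace with zero concentration variance has, by convention, slope 0
    and r2 = 0 so that QC deterministically flags it.
    """
    t = closure.timestamps
    c = closure.co2
    sst = float(np.sum((c - c.mean()) ** 2))
    if sst == 0.0:
        return 0.0, 0.0
    slope, intercept = np.polyfit(t, c, 1)
    resid = c - (slope * t + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return float(slope), float(min(max(r2, 0.0), 1.0))


def molar_volume(t_air: float, pressure: float) -> float:
    """Ideal-gas molar volume of air, m3 mol-1.

    Parameters are chamber air temperature (degC) and pressure (Pa).
    """
    if t_air <= -100.0:
        raise ValueError(f"implausible chamber temperature {t_air} degC")
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    return GAS_CONSTANT * (t_air + 273.15) / pressure


def compute_flux(slope: float, volume: float, area: float, mv: float) -> float:
    """Raw area flux F = slope * V / (A * Mv), umol CO2 m-2 s-1."""
    if volume <= 0 or area <= 0 or mv <= 0:
        raise ValueError("V, A and Mv must all be positive")
    return slope * volume / (area * mv)


def process_closure(
    closure: ChamberClosure, discard_initial_s: float = 10.0
) -> FluxRecord:
    """Turn a closure into a signed flux record.

    The first ``discard_initial_s`` seconds are dropped to let headspace
    mixing settle (set to 0 to keep the full trace).  Transparent closures
    give NEP = -F_raw (uptake-positive); opaque closures give Reco = F_raw.
    """
    if discard_initial_s > 0:
        keep = closure.timestamps >= closure.timestamps[0] + discard_initial_s
        if keep.sum() >= 10:
            closure = replace(
                closure, timestamps=closure.timestamps[keep], co2=closure.co2[keep]
            )
    slope, r2 = fit_concentration_slope(closure)
    mv = molar_volume(closure.t_air, closure.pressure)
    f_raw = compute_flux(slope, closure.volume, closure.area, mv)
    if closure.chamber_kind == "transparent":
        kind, flux = "NEP", -f_raw
    else:
        kind, flux = "Reco", f_raw
    return FluxRecord(
        closure_id=closure.closure_id,
        plot_id=closure.plot_id,
        flux_kind=kind,
        flux=flux,
        raw_slope=slope,
        r2=r2,
        par=closure.par,
        t_air=closure.t_air,
        t_soil=closure.t_soil,
    )


def qc_filter(
    records: Sequence[FluxRecord],
    r2_min: float = 0.8,
    near_zero_abs: float = 0.5,
    keep_near_zero: bool = True,
) -> list[FluxRecord]:
    """Apply the r2 quality rule, flagging each record.

    r2 >= r2_min passes.  Below the threshold, fluxes larger than
    ``near_zero_abs`` (umol m-2 s-1) are excluded; smaller ones are flagged
    ``near_zero_review`` and retained by default — a genuinely tiny flux
    produces a flat trace whose r2 is low for lack of signal, not quality.
    """
    if not 0 < r2_min <= 1:
        raise ValueError("r2_min must lie in (0, 1]")
    out = []
    for rec in records:
        if rec.r2 >= r2_min:
            flag = "pass"
        elif abs(rec.flux) <= near_zero_abs:
            flag = "near_zero_review"
        else:
            flag = "excluded_r2"
        out.append(replace(rec, qc_flag=flag))
    return out


def passed(records: Sequence[FluxRecord], keep_near_zero: bool = True) -> list[FluxRecord]:
    """Records usable for model fitting after QC."""
    ok = {"pass", "near_zero_review"} if keep_near_zero else {"pass"}
    return [r for r in records if r.qc_flag in ok]
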