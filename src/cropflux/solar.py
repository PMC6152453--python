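"""Solar geometry: sunrise/sunset and daylight windows.

Uses the standard NOAA low-precision approximation for solar declination
and the sunrise hour angle at a refracted zenith of 90.833 degrees.  Times
are local solar time (solar noon at 12:00), which is the convention used
throughout the package for synthetic seasons and daily aggregation.
"""

from __future__ import annotations

import math

__all__ = ["solar_declination", "day_window", "daylength_hours"]

_SUNRISE_ZENITH_DEG = 90.833


def solar_declination(doy: int | float, hour: float = 12.0) -> float:
    """Solar declination (radians) for a day of year, NOAA series expansion."""
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)
    return (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )


def day_window(doy: int | float, latitude: float) -> tuple[float, float]:
    """Sunrise and sunset in local solar hours for a day of year.

    Parameters
    ----------
    doy : day of year (1..365).
    latitude : site latitude in decimal degrees; polar latitudes
        (|latitude| >= 66.5) are rejected because the sunrise hour angle is
        undefined there for part of the year.

    Returns
    -------
    (sunrise, sunset) in hours; solar noon is 12.0.
    """
    if abs(latitude) >= 66.5:
        raise ValueError(f"polar latitude {latitude} not supported")
    lat = math.radians(latitude)
    decl = solar_declination(doy)
    cos_ha = math.cos(math.radians(_SUNRISE_ZENITH_DEG)) / (
        math.cos(lat) * math.cos(decl)
    ) - math.tan(lat) * math.tan(decl)
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha_deg = math.degrees(math.acos(cos_ha))
    half = ha_deg / 15.0
    return 12.0 - half, 12.0 + half


def daylength_hours(doy: int | float, latitude: float) -> float:
    sunrise, sunset = day_window(doy, latitude)
    return sunset - sunrise
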