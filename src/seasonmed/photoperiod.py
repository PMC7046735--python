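"""Day length (photoperiod) from latitude and calendar date.

Photoperiod is the interval between sunrise and sunset, in hours.  It is
computed with the standard NOAA-style sunrise equation: the solar
declination and equation of time come from a low-order Fourier series in
the fractional year, and the sunrise/sunset hour angle uses a zenith of
90.833 deg (geometric horizon plus standard atmospheric refraction and the
solar half-diameter).  Longitude shifts the clock times of sunrise and
sunset but cancels in their difference, so it is accepted for interface
completeness and ignored by the duration.

At polar latitudes the hour-angle equation has no solution; the day length
is clamped to 0 h (polar night) or 24 h (polar day).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortValidationError

#: solar zenith angle at sunrise/sunset, degrees (refraction + solar radius)
ZENITH_DEG = 90.833

__all__ = ["ZENITH_DEG", "SolarPosition", "solar_position", "day_length", "annotate_photoperiod"]


@dataclass(frozen=True)
class SolarPosition:
    """Intermediate solar quantities for one date/latitude.

    Attributes
    ----------
    declination : float
        Solar declination, radians (bounded by the Earth's obliquity).
    equation_of_time : float
        Difference between apparent and mean solar time, minutes.
    hour_angle_sunrise : float
        Half the diurnal arc of the Sun above the 90.833 deg zenith
        horizon, radians, clamped to [0, pi].
    """

    declination: float
    equation_of_time: float
    hour_angle_sunrise: float


def _fractional_year(date: _dt.date) -> float:
    """Fractional year angle (radians) at local noon of ``date``."""
    year_days = 366 if _is_leap(date.year) else 365
    doy = date.timetuple().tm_yday
    return 2.0 * np.pi / year_days * (doy - 1 + 0.5)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _declination(gamma: float) -> float:
    # NOAA low-accuracy series; adequate at the month-level resolution of
    # the seasonality models downstream (error < 0.3 deg).
    return (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )


def _equation_of_time(gamma: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )


def _hour_angle(latitude_rad: float, decl: float) -> float:
    zen = np.radians(ZENITH_DEG)
    cos_ha = (np.cos(zen) - np.sin(latitude_rad) * np.sin(decl)) / (
        np.cos(latitude_rad) * np.cos(decl)
    )
    # cos_ha > 1: sun never rises (polar night); < -1: never sets (polar day)
    return float(np.arccos(np.clip(cos_ha, -1.0, 1.0)))


def solar_position(latitude: float, date: _dt.date) -> SolarPosition:
    """Solar declination, equation of time and sunrise hour angle."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude!r} outside [-90, 90]")
    gamma = _fractional_year(date)
    decl = _declination(gamma)
    return SolarPosition(
        declination=float(decl),
        equation_of_time=float(_equation_of_time(gamma)),
        hour_angle_sunrise=_hour_angle(np.radians(latitude), decl),
    )


def day_length(latitude: float, longitude: float, date: _dt.date | str) -> float:
    """Hours of daylight (sunset minus sunrise) on ``date`` at ``latitude``.

    Parameters
    ----------
    latitude : float
        Degrees north, in [-90, 90].
    longitude : float
        Degrees east.  Kept in the signature because residence coordinates
        come as (latitude, longitude) pairs; it does not affect duration.
    date : datetime.date or ISO string

    Returns
    -------
    float
        Day length in hours, in [0, 24].  0 for polar night, 24 for
        polar day.
    """
    del longitude  # duration depends on latitude and date only
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    pos = solar_position(latitude, date)
    # The Earth rotates 15 deg/h; the diurnal arc is twice the hour angle.
    return 2.0 * np.degrees(pos.hour_angle_sunrise) / 15.0


def annotate_photoperiod(
    table: pd.DataFrame,
    lat_col: str = "latitude",
    lon_col: str = "longitude",
    date_col: str = "scan_date",
    out_col: str = "photoperiod",
) -> pd.DataFrame:
    """Return a copy of ``table`` with a photoperiod (hours) column.

    Idempotent: rerunning on its own output recomputes identical values.
    Raises :class:`CohortValidationError` if coordinates or dates are
    missing.
    """
    for col in (lat_col, lon_col, date_col):
        if col not in table.columns:
            raise CohortValidationError(f"missing column {col!r} required for photoperiod")
    out = table.copy()
    if len(out) == 0:
        out[out_col] = pd.Series(dtype=float)
        return out
    if out[[lat_col, lon_col]].isna().any().any():
        raise CohortValidationError("missing coordinates: latitude/longitude contain NA")
    dates = out[date_col]
    if not np.issubdtype(np.asarray(dates).dtype, np.datetime64):
        dates = pd.to_datetime(dates)
    out[out_col] = [
        day_length(lat, lon, d.date() if hasattr(d, "date") else d)
        for lat, lon, d in zip(out[lat_col], out[lon_col], dates)
    ]
    return out
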