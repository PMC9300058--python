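"""Solar geometry and accumulated-daylight computation.

"Daylight" here is the dawn-to-dusk period with dawn/dusk defined by the
sun's centre crossing a configurable altitude threshold — by default the
civil-twilight convention of −6°, so that the long Arctic twilight counts
as usable foraging light for a visually foraging herbivore.  Setting the
threshold to −0.833° gives conventional sunrise/sunset instead.

The solar position uses the NOAA fractional-year Fourier series for solar
declination and the equation of time; day length then follows from the
sunset hour-angle equation

    cos(H0) = (sin(a0) − sin(φ)·sin(δ)) / (cos(φ)·cos(δ)),

with the cosine clamped to [−1, 1] so polar day (24 h) and polar night
(0 h) fall out naturally.  Accuracy is a few minutes of day length, far
below the day-to-day variation that matters for accumulated hours.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from functools import lru_cache
from math import acos, cos, degrees, pi, radians, sin

import numpy as np

#: sun-centre altitude at civil dawn/dusk, degrees
CIVIL_TWILIGHT_DEG = -6.0
#: sun-centre altitude at sunrise/sunset (refraction + solar radius), degrees
SUNRISE_SUNSET_DEG = -0.833


def _fractional_year(date: dt.date, hour: float = 12.0) -> float:
    doy = date.timetuple().tm_yday
    return 2.0 * pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)


def solar_declination_and_equation_of_time(date: dt.date) -> tuple[float, float]:
    """Solar declination (degrees) and equation of time (minutes) at solar noon.

    NOAA series: declination within ±23.45°, equation of time within ±17 min.
    """
    g = _fractional_year(date)
    decl = (
        0.006918
        - 0.399912 * cos(g)
        + 0.070257 * sin(g)
        - 0.006758 * cos(2 * g)
        + 0.000907 * sin(2 * g)
        - 0.002697 * cos(3 * g)
        + 0.00148 * sin(3 * g)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * cos(g)
        - 0.032077 * sin(g)
        - 0.014615 * cos(2 * g)
        - 0.040849 * sin(2 * g)
    )
    return degrees(decl), eqtime


def _sunset_hour_angle_deg(lat: float, decl_deg: float, threshold_deg: float) -> float:
    phi, delta, a0 = radians(lat), radians(decl_deg), radians(threshold_deg)
    cos_h0 = (sin(a0) - sin(phi) * sin(delta)) / (cos(phi) * cos(delta))
    cos_h0 = min(1.0, max(-1.0, cos_h0))  # polar day/night clamp
    return degrees(acos(cos_h0))


@lru_cache(maxsize=100_000)
def daylight_duration(
    lat: float,
    lon: float,
    date: dt.date,
    sun_altitude_threshold_deg: float = CIVIL_TWILIGHT_DEG,
) -> float:
    """Dawn-to-dusk duration in hours for one calendar date.

    Returns exactly 24.0 during polar day and 0.0 during polar night.
    Longitude does not change the duration (only its clock placement) and
    is accepted for interface symmetry.
    """
    if abs(lat) > 90:
        raise ValueError("latitude out of range")
    decl, _ = solar_declination_and_equation_of_time(date)
    h0 = _sunset_hour_angle_deg(lat, decl, sun_altitude_threshold_deg)
    return 2.0 * h0 / 15.0


def dawn_dusk_utc(
    lat: float,
    lon: float,
    date: dt.date,
    sun_altitude_threshold_deg: float = CIVIL_TWILIGHT_DEG,
) -> tuple[float, float] | None:
    """Dawn and dusk as fractional UTC hours, or None under polar day/night."""
    decl, eqtime = solar_declination_and_equation_of_time(date)
    h0 = _sunset_hour_angle_deg(lat, decl, sun_altitude_threshold_deg)
    if h0 in (0.0, 180.0):
        return None
    solar_noon_utc = 12.0 - lon / 15.0 - eqtime / 60.0
    return solar_noon_utc - h0 / 15.0, solar_noon_utc + h0 / 15.0


def accumulated_daylight(
    lat: float,
    lon: float,
    hatch_date: dt.date,
    capture_date: dt.date,
    sun_altitude_threshold_deg: float = CIVIL_TWILIGHT_DEG,
) -> float:
    """Daylight hours accumulated over [hatch_date, capture_date).

    Whole days are counted, hatch day inclusive and capture day exclusive;
    coincident dates give 0.
    """
    if capture_date < hatch_date:
        raise ValueError("capture_date precedes hatch_date")
    total = 0.0
    d = hatch_date
    while d < capture_date:
        total += daylight_duration(lat, lon, d, sun_altitude_threshold_deg)
        d += dt.timedelta(days=1)
    return total


@dataclass(frozen=True)
class DaylightProfile:
    """Daily and accumulated daylight for a site over a date range."""

    latitude_deg: float
    longitude_deg: float
    dates: tuple[dt.date, ...]
    daily_daylight_h: np.ndarray
    accumulated_h: np.ndarray

    def mean_daily_h(self) -> float:
        return float(np.mean(self.daily_daylight_h))


def daylight_profile(
    lat: float,
    lon: float,
    start: dt.date,
    end: dt.date,
    sun_altitude_threshold_deg: float = CIVIL_TWILIGHT_DEG,
) -> DaylightProfile:
    """Per-day daylight and its running sum for dates in [start, end]."""
    if end < start:
        raise ValueError("end precedes start")
    dates = tuple(
        start + dt.timedelta(days=i) for i in range((end - start).days + 1)
    )
    daily = np.array(
        [daylight_duration(lat, lon, d, sun_altitude_threshold_deg) for d in dates]
    )
    return DaylightProfile(lat, lon, dates, daily, np.cumsum(daily))
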