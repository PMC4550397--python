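"""Solar geometry: sun azimuth/zenith, sunrise/sunset and the solar index.

All computations use the NOAA low-precision solar position equations
(fractional year -> equation of time and declination -> hour angle ->
azimuth/zenith). Stated accuracy is well under 0.5 degrees of azimuth for
1950-2050, far below the 10-degree bearing bins used in the orientation
analysis. All timestamps are UTC; the local civil date only enters when
bracketing sunrise/sunset through the longitude.

The solar index of a deployment is the fraction of daylight elapsed at its
mean time: 0 at sunrise, 1 at sunset, 0.5 when the sun is highest. It is a
scalar proxy for the (interdependent) solar zenith and azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SolarPosition",
    "SunTimes",
    "sun_position",
    "sun_times",
    "solar_index",
    "mean_time",
    "APPARENT_SUNRISE_ZENITH",
]

#: zenith angle (deg) of the sun's upper limb at apparent sunrise/sunset:
#: 90 deg + 34' refraction + 16' solar semi-diameter
APPARENT_SUNRISE_ZENITH = 90.833

#: geometric alternative (center of the disk on the true horizon)
GEOMETRIC_SUNRISE_ZENITH = 90.0


@dataclass(frozen=True)
class SolarPosition:
    """Sun direction: azimuth clockwise from true North in [0, 360),
    zenith from the vertical in [0, 180]."""

    azimuth: float
    zenith: float


@dataclass(frozen=True)
class SunTimes:
    """Apparent sunrise and sunset (UTC) for one civil date at one site."""

    sunrise: pd.Timestamp
    sunset: pd.Timestamp


def _to_utc(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts is pd.NaT:
        raise ValueError(f"invalid timestamp: {t!r}")
    if ts.tzinfo is None:
        return ts.tz_localize("UTC")
    return ts.tz_convert("UTC")


def _fractional_year(ts: pd.Timestamp) -> float:
    """Fractional year gamma (radians) at a UTC instant."""
    doy = ts.dayofyear
    hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    days_in_year = 366.0 if ts.is_leap_year else 365.0
    return 2.0 * np.pi / days_in_year * (doy - 1 + (hours - 12.0) / 24.0)


def _eqtime_decl(gamma: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    return float(eqtime), float(decl)


def sun_position(lat: float, lon: float, t) -> SolarPosition:
    """Sun azimuth and zenith at a site (WGS84 degrees, east-positive
    longitude) and UTC time.

    The hour angle is derived from true solar time (UTC + equation of time
    + 4 min/deg of longitude); azimuth is measured clockwise from true
    North, so it is < 180 before local solar noon and > 180 after, at
    mid-northern latitudes.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude out of range: {lat}")
    ts = _to_utc(t)
    gamma = _fractional_year(ts)
    eqtime, decl = _eqtime_decl(gamma)
    minutes_utc = ts.hour * 60.0 + ts.minute + ts.second / 60.0 + ts.microsecond / 6e7
    tst = minutes_utc + eqtime + 4.0 * lon  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle, 0 at solar noon
    lat_r = np.radians(lat)
    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    zen = np.arccos(cos_zen)
    sin_zen = np.sin(zen)
    if sin_zen < 1e-9:  # sun at zenith/nadir: azimuth degenerate
        return SolarPosition(azimuth=0.0, zenith=float(np.degrees(zen)))
    sin_az = -np.cos(decl) * np.sin(ha) / sin_zen
    cos_az = (np.sin(decl) - np.sin(lat_r) * cos_zen) / (np.cos(lat_r) * sin_zen)
    az = np.degrees(np.arctan2(sin_az, cos_az)) % 360.0
    return SolarPosition(azimuth=float(az), zenith=float(np.degrees(zen)))


def sun_azimuth_series(lat: float, lon: float, times) -> np.ndarray:
    """Vectorized sun azimuth (degrees) for a sequence of UTC timestamps.

    Same equations as :func:`sun_position`, evaluated on arrays; agrees
    with the scalar path to numerical precision.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(np.asarray(times), utc=True))
    days_in_year = np.where(idx.is_leap_year, 366.0, 365.0)
    hours = (
        idx.hour.to_numpy(float)
        + idx.minute.to_numpy(float) / 60.0
        + idx.second.to_numpy(float) / 3600.0
        + idx.microsecond.to_numpy(float) / 3.6e9
    )
    gamma = 2.0 * np.pi / days_in_year * (idx.dayofyear.to_numpy(float) - 1 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    tst = hours * 60.0 + eqtime + 4.0 * lon
    ha = np.radians(tst / 4.0 - 180.0)
    lat_r = np.radians(lat)
    cos_zen = np.clip(
        np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha), -1.0, 1.0
    )
    zen = np.arccos(cos_zen)
    sin_zen = np.sin(zen)
    sin_zen_safe = np.where(sin_zen < 1e-9, 1.0, sin_zen)
    sin_az = -np.cos(decl) * np.sin(ha) / sin_zen_safe
    cos_az = (np.sin(decl) - np.sin(lat_r) * cos_zen) / (np.cos(lat_r) * sin_zen_safe)
    az = np.degrees(np.arctan2(sin_az, cos_az)) % 360.0
    return np.where(sin_zen < 1e-9, 0.0, az)


def sun_times(lat: float, lon: float, date, zenith: float = APPARENT_SUNRISE_ZENITH) -> SunTimes:
    """Apparent sunrise and sunset (UTC) on a civil date at a site.

    The crossing zenith defaults to 90.833 deg (atmospheric refraction plus
    the solar semi-diameter); pass ``zenith=90.0`` for geometric rise/set.
    The civil date is interpreted at the site: the returned times bracket
    the local solar noon nearest 12:00 local mean time.

    Raises
    ------
    ValueError
        If the sun does not cross the requested zenith on that date
        (polar day or night).
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude out of range: {lat}")
    d = pd.Timestamp(date)
    if d is pd.NaT:
        raise ValueError(f"invalid date: {date!r}")
    # evaluate eqtime/declination at local solar noon (approx)
    noon_utc_minutes = 720.0 - 4.0 * lon
    noon_guess = pd.Timestamp(d.year, d.month, d.day, tz="UTC") + pd.Timedelta(
        minutes=noon_utc_minutes
    )
    gamma = _fractional_year(noon_guess)
    eqtime, decl = _eqtime_decl(gamma)
    lat_r = np.radians(lat)
    cos_ha = (np.cos(np.radians(zenith)) - np.sin(lat_r) * np.sin(decl)) / (
        np.cos(lat_r) * np.cos(decl)
    )
    if not -1.0 < cos_ha < 1.0:
        raise ValueError(
            f"sun does not cross zenith {zenith} deg at lat {lat} on {d.date()} "
            "(polar day or night)"
        )
    ha = np.degrees(np.arccos(cos_ha))  # degrees of hour angle
    midnight = pd.Timestamp(d.year, d.month, d.day, tz="UTC")
    sunrise = midnight + pd.Timedelta(minutes=720.0 - 4.0 * (lon + ha) - eqtime)
    sunset = midnight + pd.Timedelta(minutes=720.0 - 4.0 * (lon - ha) - eqtime)
    return SunTimes(sunrise=sunrise, sunset=sunset)


def mean_time(t_start, t_end) -> pd.Timestamp:
    """Midpoint of a deployment's observation window (UTC)."""
    a, b = _to_utc(t_start), _to_utc(t_end)
    return a + (b - a) / 2


def solar_index(t_deployment, times: SunTimes) -> float:
    """Fraction of daylight elapsed at a UTC instant.

    (t - sunrise) / (sunset - sunrise): 0 at sunrise, 1 at sunset, affine
    in between. Values outside [0, 1] indicate a deployment outside
    daylight and are returned as-is for the caller to flag.
    """
    day = (times.sunset - times.sunrise).total_seconds()
    if day <= 0:
        raise ValueError("sunset must be after sunrise")
    t = _to_utc(t_deployment)
    return float((t - times.sunrise).total_seconds() / day)
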