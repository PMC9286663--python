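"""Solar geometry: relative azimuths and reference solar zenith angles.

A group of flightlines acquired over several hours spans a range of solar
zenith angles; normalizing every line to a single reference zenith removes
the resulting line-to-line brightness offsets.  Four conventions for that
reference are supported:

``flight_noon``
    zenith at local solar noon on the acquisition date,
``season_noon``
    daily solar-noon zenith averaged over a season window,
``observed_mean``
    mean of the observed per-pixel solar zenith over the whole group,
``solstice_noon``
    zenith at local solar noon on the summer solstice of the acquisition
    year (winter solstice in the southern hemisphere),

plus ``fixed`` (user-supplied value) and ``none`` (keep each pixel's own
solar zenith, i.e. nadir-view-only normalization).

The ephemeris is the NOAA solar-position set of equations (declination
accurate to ~0.1 degree); declination is evaluated at 0h UT of the calendar
day, the convention of daily almanac tables.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError

_EPOCH_J2000 = 2451545.0


def _julian_century(date: _dt.date, hour_ut: float = 0.0) -> float:
    jd = date.toordinal() + 1721424.5 + hour_ut / 24.0
    return (jd - _EPOCH_J2000) / 36525.0


def solar_declination(date: _dt.date) -> float:
    """Apparent solar declination (degrees) at 0h UT, NOAA equations."""
    g = _julian_century(date)
    gmls = math.fmod(280.46646 + g * (36000.76983 + 0.0003032 * g), 360.0)
    gmas = 357.52911 + g * (35999.05029 - 0.0001537 * g)
    seqc = (
        math.sin(math.radians(gmas)) * (1.914602 - g * (0.004817 + 0.000014 * g))
        + math.sin(math.radians(2 * gmas)) * (0.019993 - 0.000101 * g)
        + math.sin(math.radians(3 * gmas)) * 0.000289
    )
    stl = gmls + seqc
    sal = stl - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * g))
    moe = 23.0 + (26.0 + (21.448 - g * (46.815 + g * (0.00059 - g * 0.001813))) / 60.0) / 60.0
    oc = moe + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * g))
    return math.degrees(
        math.asin(math.sin(math.radians(oc)) * math.sin(math.radians(sal)))
    )


def relative_azimuth(phi_s, phi_v):
    """Sun-sensor relative azimuth folded into [0, 180] degrees.

    The kernels are even functions of the relative azimuth, so the sign and
    the 360-degree wrap are immaterial; only the folded magnitude is kept.
    """
    phi_s = np.asarray(phi_s, dtype=float)
    phi_v = np.asarray(phi_v, dtype=float)
    if np.any((phi_s < 0) | (phi_s >= 360) | (phi_v < 0) | (phi_v >= 360)):
        raise DataError("azimuths must lie in [0, 360)")
    delta = np.mod(phi_s - phi_v, 360.0)
    folded = np.where(delta > 180.0, 360.0 - delta, delta)
    return folded if folded.ndim else float(folded)


def solar_noon_zenith(date: _dt.date, latitude: float) -> float:
    """Solar zenith angle (degrees) at local solar noon.

    At solar noon the hour angle is zero and the zenith reduces to
    ``|latitude - declination|``.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ConfigurationError("latitude outside [-90, 90]")
    return abs(latitude - solar_declination(date))


def seasonal_mean_zenith(start: _dt.date, end: _dt.date, latitude: float) -> float:
    """Unweighted mean of the daily solar-noon zenith over [start, end]."""
    if start > end:
        raise ConfigurationError("season_start must not be after season_end")
    n_days = (end - start).days + 1
    total = sum(
        solar_noon_zenith(start + _dt.timedelta(days=i), latitude)
        for i in range(n_days)
    )
    return total / n_days


def observed_mean_zenith(group, line_weighted: bool = False) -> float:
    """Mean observed solar zenith over all valid pixels of a flightline group.

    Pixel-weighted by default (each line contributes proportionally to its
    valid-pixel count); ``line_weighted`` averages per-line means instead.
    """
    if not group:
        raise DataError("empty flightline group")
    means, counts = [], []
    for obs in group:
        m = obs.valid_mask
        if not m.any():
            continue
        means.append(float(obs.solar_zenith[m].mean()))
        counts.append(int(m.sum()))
    if not means:
        raise DataError("no valid pixels in any line of the group")
    if line_weighted:
        return float(np.mean(means))
    return float(np.average(means, weights=counts))


def _summer_solstice(year: int, latitude: float) -> _dt.date:
    """Date of minimum solar-noon zenith in the acquisition year."""
    month_range = (5, 8) if latitude >= 0 else (11, 2)
    days = []
    for month in (range(5, 9) if latitude >= 0 else (11, 12, 1, 2)):
        y = year if month >= month_range[0] or latitude >= 0 else year + 1
        d = _dt.date(y, month, 1)
        while d.month == month:
            days.append(d)
            d += _dt.timedelta(days=1)
    return min(days, key=lambda d: solar_noon_zenith(d, latitude))


@dataclass
class SolarReferenceSpec:
    """Which reference solar zenith to use and the inputs it needs."""

    mode: str = "none"
    latitude: float | None = None
    acquisition_date: _dt.date | None = None
    season_start: _dt.date | None = None
    season_end: _dt.date | None = None
    fixed_value: float | None = None
    line_weighted: bool = False

    MODES = ("flight_noon", "season_noon", "observed_mean", "solstice_noon",
             "none", "fixed")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ConfigurationError(f"unknown solar reference mode {self.mode!r}")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ConfigurationError("latitude outside [-90, 90]")


def resolve_reference_zenith(spec: SolarReferenceSpec, group=()) -> float | None:
    """Dispatch to the mode-appropriate reference-zenith computation.

    Returns degrees, or ``None`` for mode ``none`` (per-pixel solar zenith
    is then used during correction).
    """
    mode = spec.mode
    if mode == "none":
        return None
    if mode == "fixed":
        if spec.fixed_value is None:
            raise ConfigurationError("fixed mode requires fixed_value")
        return float(spec.fixed_value)
    if mode == "observed_mean":
        return observed_mean_zenith(group, line_weighted=spec.line_weighted)
    if spec.latitude is None:
        raise ConfigurationError(f"mode {mode!r} requires a latitude")
    if mode == "flight_noon":
        if spec.acquisition_date is None:
            raise ConfigurationError("flight_noon requires acquisition_date")
        return solar_noon_zenith(spec.acquisition_date, spec.latitude)
    if mode == "season_noon":
        if spec.season_start is None or spec.season_end is None:
            raise ConfigurationError("season_noon requires season_start and season_end")
        return seasonal_mean_zenith(spec.season_start, spec.season_end, spec.latitude)
    # solstice_noon
    if spec.acquisition_date is None:
        raise ConfigurationError("solstice_noon requires acquisition_date (for the year)")
    day = _summer_solstice(spec.acquisition_date.year, spec.latitude)
    return solar_noon_zenith(day, spec.latitude)
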