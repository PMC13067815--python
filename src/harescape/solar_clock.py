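"""Astronomical day/night bookkeeping.

Sunrise, sunset, and civil twilight times from the NOAA low-accuracy solar
ephemeris (declination and equation-of-time trigonometric series), plus the
derived quantities the rest of the pipeline needs: night length (civil dusk
to the next civil dawn) and the double-anchored solar-time transform that
maps each day's clock times onto a reference day whose sunrise and sunset
sit at the study-period mean positions.

Sunrise/sunset use the standard -0.833 deg altitude threshold (atmospheric
refraction plus the solar half-diameter); civil dawn/dusk use -6 deg.
Accuracy is within about +-2 minutes of almanac values for the mid- and
high-latitude, non-polar sites this package targets.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SiteLocation",
    "SolarEvents",
    "DielWindow",
    "NoSolarEventError",
    "solar_altitude",
    "solar_events",
    "night_length",
    "to_solar_time",
    "mean_anchors",
]

#: altitude thresholds, degrees
SUN_HORIZON = -0.833
CIVIL_TWILIGHT = -6.0

TWO_PI = 2.0 * np.pi


class NoSolarEventError(ValueError):
    """The sun never crosses the requested altitude on the given date."""


@dataclass(frozen=True)
class SiteLocation:
    """A study site.

    Longitude follows the +E convention (91 degrees W is -91.0); utc_offset
    is the fixed offset (hours) of the local clock used in the tabular data.
    """

    name: str
    latitude: float
    longitude: float
    utc_offset: float

    def __post_init__(self) -> None:
        if not abs(self.latitude) < 66.5:
            raise ValueError(
                f"latitude {self.latitude} outside supported range (|lat| < 66.5)"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class SolarEvents:
    """Local clock times (fractional hours) of the four diel anchors."""

    date: _dt.date
    sunrise: float
    sunset: float
    civil_dawn: float
    civil_dusk: float


@dataclass(frozen=True)
class DielWindow:
    """An arc on the 24-h circle, in radians (2*pi == 24 h)."""

    start: float
    end: float
    label: str

    def length(self) -> float:
        return (self.end - self.start) % TWO_PI

    def contains(self, theta: np.ndarray) -> np.ndarray:
        rel = (np.asarray(theta) - self.start) % TWO_PI
        return rel < self.length()


def solar_altitude(site: SiteLocation, date: _dt.date, local_hours) -> np.ndarray:
    """Solar altitude (degrees) at fractional local clock hours on ``date``.

    Hours may exceed [0, 24); they roll into neighbouring dates.
    """
    local_hours = np.asarray(local_hours, dtype=float)
    doy = date.timetuple().tm_yday
    hours_utc = local_hours - site.utc_offset
    day_shift = np.floor(hours_utc / 24.0)
    hu = hours_utc - 24.0 * day_shift
    g = TWO_PI / 365.0 * (doy + day_shift - 1 + (hu - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    tst = hu * 60.0 + eqtime + 4.0 * site.longitude  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)
    lat = np.radians(site.latitude)
    cos_zen = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))


def _crossings(site: SiteLocation, date: _dt.date, thresh: float) -> tuple[float, float]:
    """(rising, setting) local hours where altitude crosses ``thresh``.

    1-minute scan over the local day followed by linear refinement.
    """
    t = np.arange(0, 24 * 60 + 1) / 60.0
    alt = solar_altitude(site, date, t)
    sign = np.sign(alt - thresh)
    dsign = np.diff(sign)
    up = np.flatnonzero(dsign > 0)
    down = np.flatnonzero(dsign < 0)
    if len(up) == 0 or len(down) == 0:
        raise NoSolarEventError(
            f"sun does not cross {thresh} deg at {site.name} on {date}"
        )

    def refine(i: int) -> float:
        f = (thresh - alt[i]) / (alt[i + 1] - alt[i])
        return float(t[i] + f / 60.0)

    return refine(up[0]), refine(down[0])


def solar_events(site: SiteLocation, date: _dt.date) -> SolarEvents:
    """Sunrise/sunset and civil dawn/dusk (local fractional hours) on ``date``."""
    sunrise, sunset = _crossings(site, date, SUN_HORIZON)
    dawn, dusk = _crossings(site, date, CIVIL_TWILIGHT)
    return SolarEvents(date=date, sunrise=sunrise, sunset=sunset,
                       civil_dawn=dawn, civil_dusk=dusk)


def night_length(site: SiteLocation, date: _dt.date) -> float:
    """Hours from civil dusk on ``date`` to civil dawn on ``date + 1``."""
    dusk = solar_events(site, date).civil_dusk
    dawn = solar_events(site, date + _dt.timedelta(days=1)).civil_dawn
    return (24.0 - dusk) + dawn


def night_window(site: SiteLocation, date: _dt.date) -> DielWindow:
    """The night arc [civil dusk, next civil dawn) on the 24-h circle."""
    ev = solar_events(site, date)
    dawn_next = solar_events(site, date + _dt.timedelta(days=1)).civil_dawn
    return DielWindow(start=ev.civil_dusk * TWO_PI / 24.0,
                      end=dawn_next * TWO_PI / 24.0, label="night")


def mean_anchors(site: SiteLocation, dates) -> tuple[float, float]:
    """Mean sunrise and mean sunset (local hours) over an iterable of dates."""
    evs = [solar_events(site, d) for d in dates]
    return (float(np.mean([e.sunrise for e in evs])),
            float(np.mean([e.sunset for e in evs])))


def to_solar_time(timestamps, site: SiteLocation,
                  anchors: tuple[float, float] | None = None,
                  anchor_dates=None) -> np.ndarray:
    """Double-anchored solar-time transform, radians on [0, 2*pi).

    Each clock time is mapped piecewise-linearly so that its own date's
    sunrise lands on the study-period mean sunrise and its date's sunset on
    the mean sunset; the day and night segments are stretched independently.
    This removes the seasonal drift of day length before circular density
    estimation.

    Parameters
    ----------
    timestamps : sequence of datetime.datetime (local clock time)
    anchors : optional (mean_sunrise, mean_sunset) in local hours; computed
        from ``anchor_dates`` (default: the dates present in ``timestamps``)
        when omitted.
    """
    ts = list(timestamps)
    if len(ts) == 0:
        return np.empty(0)
    if anchors is None:
        if anchor_dates is None:
            anchor_dates = sorted({t.date() for t in ts})
        anchors = mean_anchors(site, anchor_dates)
    mean_rise, mean_set = anchors

    events_cache: dict[_dt.date, SolarEvents] = {}

    def ev(d: _dt.date) -> SolarEvents:
        if d not in events_cache:
            events_cache[d] = solar_events(site, d)
        return events_cache[d]

    out = np.empty(len(ts))
    for i, t in enumerate(ts):
        d = t.date()
        h = t.hour + t.minute / 60.0 + t.second / 3600.0
        e = ev(d)
        if e.sunrise <= h < e.sunset:  # day segment
            frac = (h - e.sunrise) / (e.sunset - e.sunrise)
            sh = mean_rise + frac * (mean_set - mean_rise)
        elif h >= e.sunset:  # evening: stretch to next sunrise
            nxt = ev(d + _dt.timedelta(days=1)).sunrise + 24.0
            frac = (h - e.sunset) / (nxt - e.sunset)
            sh = mean_set + frac * (mean_rise + 24.0 - mean_set)
        else:  # morning before sunrise: tail of the previous night
            prev = ev(d - _dt.timedelta(days=1)).sunset - 24.0
            frac = (h - prev) / (e.sunrise - prev)
            sh = mean_set - 24.0 + frac * (mean_rise + 24.0 - mean_set)
        out[i] = (sh % 24.0) * TWO_PI / 24.0
    return out
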