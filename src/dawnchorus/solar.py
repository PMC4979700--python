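"""Local sunrise computation and dawn-window extraction.

Sunrise is computed offline with the NOAA solar-calculator equations
(Julian-century polynomials for the solar geometric mean longitude/anomaly,
apparent longitude, obliquity, declination and equation of time; zenith
90.833 deg for upper-limb rise with standard refraction).  Accuracy is
within about +/-1 minute of almanac values for |lat| < 66.5 deg.

The dawn analysis window runs from 0.5 h before to 2.5 h after local
sunrise — a fixed 3-h span centred on the dawn chorus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date as date_type
from datetime import datetime, timedelta, timezone

import numpy as np

from .bandspl import BandSpectrogram

#: Solar zenith angle of the upper limb at rise/set, including refraction (deg).
SUNRISE_ZENITH_DEG = 90.833


class NoSunriseError(ValueError):
    """The sun does not rise (or set) on this date at this latitude."""


def _solar_position(julian_day: float) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes).

    Julian-century polynomial expansions of the solar orbital elements,
    with nutation/aberration corrections to the apparent longitude.
    """
    T = (julian_day - 2451545.0) / 36525.0
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = math.radians(357.52911 + T * (35999.05029 - 0.0001537 * T))
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        (1.914602 - T * (0.004817 + 0.000014 * T)) * math.sin(M)
        + (0.019993 - 0.000101 * T) * math.sin(2 * M)
        + 0.000289 * math.sin(3 * M)
    )
    omega = math.radians(125.04 - 1934.136 * T)
    app_long = L0 + C - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(eps) * math.sin(math.radians(app_long)))
    y = math.tan(eps / 2.0) ** 2
    L0r = math.radians(L0)
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * L0r)
        - 2.0 * e * math.sin(M)
        + 4.0 * e * y * math.sin(M) * math.cos(2 * L0r)
        - 0.5 * y * y * math.sin(4 * L0r)
        - 1.25 * e * e * math.sin(2 * M)
    )
    return decl, eqtime


def sunrise_time(lat: float, lon: float, date: date_type, utc_offset: float) -> datetime:
    """Local civil time of sunrise at (``lat``, ``lon``) on ``date``.

    Parameters
    ----------
    lat, lon : float
        Site coordinates in degrees; east longitude positive.
    date : datetime.date
        Civil date at the site.
    utc_offset : float
        Hours ahead of UTC of the local clock (user input; no DST database).

    Returns
    -------
    datetime
        Sunrise with tzinfo set to the fixed ``utc_offset``.

    Raises
    ------
    NoSunriseError
        Polar day/night: the hour-angle equation has no solution.
    """
    if abs(lat) >= 89.9:
        raise NoSunriseError("latitude at pole")
    jd_midnight = date.toordinal() + 1721424.5  # Julian date at 00:00 UTC

    # Iterate: the declination and equation of time depend (weakly) on the
    # time of day being solved for; two passes converge to well under 1 s.
    hour_utc = 12.0 - lon / 15.0  # first guess: local solar noon
    for _ in range(3):
        decl, eqtime = _solar_position(jd_midnight + hour_utc / 24.0)
        lat_r = math.radians(lat)
        cos_ha = (
            math.cos(math.radians(SUNRISE_ZENITH_DEG)) / (math.cos(lat_r) * math.cos(decl))
            - math.tan(lat_r) * math.tan(decl)
        )
        if not -1.0 <= cos_ha <= 1.0:
            raise NoSunriseError(
                f"no sunrise at lat {lat:g} on {date.isoformat()} (polar day/night)"
            )
        ha_deg = math.degrees(math.acos(cos_ha))
        minutes_utc = 720.0 - 4.0 * (lon + ha_deg) - eqtime
        hour_utc = minutes_utc / 60.0

    tz = timezone(timedelta(hours=utc_offset))
    midnight_utc = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)
    return (midnight_utc + timedelta(minutes=minutes_utc)).astimezone(tz)


@dataclass(frozen=True)
class DawnWindow:
    """The 3-h dawn analysis window: sunrise - 0.5 h to sunrise + 2.5 h."""

    date: date_type
    sunrise: datetime

    @property
    def start(self) -> datetime:
        return self.sunrise - timedelta(hours=0.5)

    @property
    def end(self) -> datetime:
        return self.sunrise + timedelta(hours=2.5)

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


def dawn_window(lat: float, lon: float, date: date_type, utc_offset: float) -> DawnWindow:
    """Convenience: the dawn window for a site/date."""
    return DawnWindow(date=date, sunrise=sunrise_time(lat, lon, date, utc_offset))


def extract_dawn_window(spec: BandSpectrogram, window: DawnWindow) -> BandSpectrogram:
    """Restrict a spectrogram to rows with timestamps in [start, end).

    Partial coverage yields a partial result with a warning; a window fully
    outside the recording yields an empty result with a warning.
    """
    start_time = spec.start_time
    if start_time.tzinfo is None and window.start.tzinfo is not None:
        start_time = start_time.replace(tzinfo=window.start.tzinfo)
    offset_start = (window.start - start_time).total_seconds()
    offset_end = (window.end - start_time).total_seconds()
    lo = int(np.ceil(max(offset_start, 0.0)))
    hi = int(np.ceil(min(offset_end, spec.n_seconds)))
    hi = max(hi, lo)
    expected = int(round(window.duration_s))
    if hi - lo == 0:
        warnings.warn("dawn window lies fully outside the recording")
    elif hi - lo < expected:
        warnings.warn(
            f"dawn window only partially covered: {hi - lo} of {expected} seconds"
        )
    return BandSpectrogram(
        values=spec.values[lo:hi],
        band_centers=spec.band_centers.copy(),
        start_time=start_time + timedelta(seconds=lo),
        weighting=spec.weighting,
        calibration_offset=spec.calibration_offset,
    )
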