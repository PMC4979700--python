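"""Weather/noise screening and band restriction for index analysis.

Wind, rain and most anthropogenic noise concentrate energy at low
frequencies, so a second is flagged as obscured when its energy-summed level
over the low bands (centres <= 800 Hz by default) exceeds the day's median
of that same quantity by a threshold.  A day is excluded outright when
strictly more than 25 % of its window seconds are flagged.  Index analysis is
restricted to the eight 1/3-octave bands with nominal centres between 1250
and 6300 Hz, isolating avian biophony from low-frequency noise.

Flagging is baseline-relative, so the exclusion decision is invariant to the
calibration offset; a uniformly elevated (constantly windy) day is absorbed
into its own baseline and yields no flags — the rule targets transient
obscuration, not chronically loud sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as date_type

import numpy as np
import pandas as pd

from .bandspl import BandSpectrogram

logger = logging.getLogger(__name__)

#: Fraction of flagged seconds above which (strictly) a day is excluded.
EXCLUSION_FRACTION = 0.25


@dataclass(frozen=True)
class ScreenReport:
    """Per-day obscuration screening outcome."""

    date: date_type
    fraction_obscured: float
    excluded: bool
    flag_mask: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_obscured <= 1.0:
            raise ValueError("fraction_obscured must be in [0, 1]")


def flag_obscured_seconds(
    spec: BandSpectrogram,
    low_band_ceiling: float = 800.0,
    threshold_db_above_baseline: float = 10.0,
    baseline_window_s: int | None = None,
) -> np.ndarray:
    """Boolean mask of seconds obscured by broadband low-frequency noise.

    A second is flagged iff its energy-summed level over bands with centres
    <= ``low_band_ceiling`` exceeds the day's baseline of that series by at
    least ``threshold_db_above_baseline`` dB.  The baseline defaults to the
    whole-window median, which resists multi-hour weather events (a rolling
    median would be dragged up inside any event longer than its window);
    pass ``baseline_window_s`` for a centred rolling median instead when
    slow diel level drift matters.  Deterministic.
    """
    low = spec.band_centers <= low_band_ceiling
    if not np.any(low):
        raise ValueError(
            f"no bands at or below {low_band_ceiling:g} Hz in spectrogram"
        )
    level = 10.0 * np.log10(np.sum(10.0 ** (spec.values[:, low] / 10.0), axis=1))
    if baseline_window_s is None:
        baseline = np.median(level)
    else:
        win = min(baseline_window_s, level.size)
        if win % 2 == 0:
            win = max(win - 1, 1)
        baseline = (
            pd.Series(level).rolling(win, center=True, min_periods=1).median().to_numpy()
        )
    return level - baseline >= threshold_db_above_baseline


def apply_exclusion_rule(date: date_type, flag_mask: np.ndarray) -> ScreenReport:
    """Exclusion decision for one day: excluded iff > 25 % seconds flagged.

    The inequality is strict: a day with exactly 25 % flagged is retained.
    """
    mask = np.asarray(flag_mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty flag mask")
    frac = float(np.count_nonzero(mask)) / mask.size
    excluded = frac > EXCLUSION_FRACTION
    if excluded:
        logger.info(
            "excluding %s: %.1f%% of seconds obscured", date, 100.0 * frac
        )
    return ScreenReport(
        date=date, fraction_obscured=frac, excluded=excluded, flag_mask=mask
    )


def restrict_bands(
    spec: BandSpectrogram, min_freq: float = 1250.0, max_freq: float = 6300.0
) -> BandSpectrogram:
    """Keep bands with nominal centres in ``[min_freq, max_freq]`` inclusive.

    With the standard series and the defaults this retains the eight bands
    1250, 1600, 2000, 2500, 3150, 4000, 5000 and 6300 Hz used for the
    complexity index.  Idempotent.
    """
    keep = (spec.band_centers >= min_freq) & (spec.band_centers <= max_freq)
    if not np.any(keep):
        raise ValueError(
            f"no nominal band centres in [{min_freq:g}, {max_freq:g}] Hz"
        )
    return BandSpectrogram(
        values=spec.values[:, keep],
        band_centers=spec.band_centers[keep],
        start_time=spec.start_time,
        weighting=spec.weighting,
        calibration_offset=spec.calibration_offset,
    )


def screen_reports_to_csv(reports: list[ScreenReport], path) -> None:
    pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in reports],
            "fraction_obscured": [round(r.fraction_obscured, 6) for r in reports],
            "excluded": [r.excluded for r in reports],
        }
    ).to_csv(path, index=False)
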