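"""The Acoustic Complexity Index (ACI) on 1-s 1/3-octave-band SPL.

For one band with per-second SPL values ``SPL_1 .. SPL_n`` over the dawn
window::

    ACI_f = sum_{t=1}^{n-1} |SPL_t - SPL_{t+1}|  /  sum_{t=1}^{n} SPL_t

i.e. summed absolute adjacent-second differences normalised by the summed
SPL of the band.  The per-band values over the retained bands (N = 8 thirds
between 1250 and 6300 Hz) are summed into a single daily value::

    ACI_tot = sum_f ACI_f

ACI is high for intermittent biotic sound (song syllables against silence)
and low for stationary noise, which is what makes it track vocal activity.
Two properties matter in practice and are enforced by tests: the index is
invariant to rescaling the SPL series but *not* to adding a dB offset
(the denominator shifts while the numerator does not), so calibrated
absolute levels are required for cross-site comparison; and it depends on
temporal order (sorting a series minimises the numerator).

A fine-resolution variant computes the classic ACI on STFT magnitudes
(default 0.01-s steps, ~86.1 Hz bins) for sensitivity comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as date_type

import numpy as np
import pandas as pd
from scipy.signal import stft

from .bandspl import BandSpectrogram


@dataclass(frozen=True)
class AciResult:
    """Per-band and summed ACI for one site-day dawn window."""

    date: date_type
    per_band: dict[float, float]
    aci_tot: float
    n_seconds: int

    @property
    def band_count(self) -> int:
        return len(self.per_band)


def aci_band(series: np.ndarray, gaps: np.ndarray | None = None) -> float:
    """ACI for one band's per-second SPL series.

    Parameters
    ----------
    series : array
        Per-second SPL values (dB); length >= 2, finite, positive sum.
    gaps : bool array, optional
        ``gaps[t] = True`` marks a discontinuity *between* ``series[t]`` and
        ``series[t+1]`` (missing seconds removed upstream); differences are
        not taken across gaps.

    Raises
    ------
    ValueError
        If the series is too short or its sum is not strictly positive.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("ACI needs at least 2 seconds")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite SPL in series")
    denom = float(np.sum(x))
    if denom <= 0.0:
        raise ValueError(
            "ACI denominator (summed SPL) must be positive; "
            "check calibration offset"
        )
    diffs = np.abs(np.diff(x))
    if gaps is not None:
        gaps = np.asarray(gaps, dtype=bool)
        if gaps.size != x.size - 1:
            raise ValueError("gaps must have length len(series) - 1")
        diffs = diffs[~gaps]
    return float(np.sum(diffs) / denom)


def aci_total(
    spec: BandSpectrogram, date: date_type | None = None
) -> AciResult:
    """Daily ACI: per-band ACI summed over the retained bands.

    ``spec`` must already be restricted to the index band range and to the
    dawn window (use :func:`dawnchorus.screening.restrict_bands` and
    :func:`dawnchorus.solar.extract_dawn_window`).
    """
    per_band: dict[float, float] = {}
    for j, fc in enumerate(spec.band_centers):
        try:
            per_band[float(fc)] = aci_band(spec.values[:, j])
        except ValueError as exc:
            raise ValueError(f"band {fc:g} Hz: {exc}") from exc
    if date is None:
        date = spec.start_time.date()
    return AciResult(
        date=date,
        per_band=per_band,
        aci_tot=float(sum(per_band.values())),
        n_seconds=spec.n_seconds,
    )


def aci_fine(
    audio: np.ndarray,
    sample_rate: int,
    window_s: float = 0.01,
    freq_resolution: float = 86.1,
    fmin: float = 1250.0,
    fmax: float = 6300.0,
) -> float:
    """Classic fine-resolution ACI on STFT magnitudes.

    The STFT uses ``nperseg = round(sample_rate / freq_resolution)`` bins and
    a hop of ``round(window_s * sample_rate)`` samples (no overlap at the
    defaults).  Per frequency bin within ``[fmin, fmax]``, absolute
    adjacent-frame magnitude differences are summed and normalised by the
    bin's summed magnitude over the whole signal; bin values are then summed.
    """
    audio = np.asarray(audio, dtype=float)
    sr = int(sample_rate)
    nperseg = int(round(sr / freq_resolution))
    hop = int(round(window_s * sr))
    if nperseg < 2 or hop < 1:
        raise ValueError("STFT parameters not representable at this sample rate")
    noverlap = max(nperseg - hop, 0)
    freqs, _, zxx = stft(
        audio,
        fs=sr,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        boundary=None,
        padded=False,
    )
    mag = np.abs(zxx)
    sel = (freqs >= fmin) & (freqs <= fmax)
    mag = mag[sel]
    if mag.shape[1] < 2:
        raise ValueError("audio too short for two STFT frames")
    num = np.sum(np.abs(np.diff(mag, axis=1)), axis=1)
    den = np.sum(mag, axis=1)
    ok = den > 0
    return float(np.sum(num[ok] / den[ok]))


def daily_series(results: list[AciResult], reports=None, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the daily ACI table used downstream.

    Parameters
    ----------
    results : list of AciResult
        One per processed day (dates need not be complete).
    reports : list of ScreenReport, optional
        Exclusion decisions; excluded days carry ``aci_tot = NaN``.
    covariates : DataFrame indexed by date, optional
        Daily weather columns merged in by date.

    Returns
    -------
    DataFrame with columns ``date``, ``aci_tot``, ``excluded`` (+ covariates),
    sorted by strictly increasing date.
    """
    df = pd.DataFrame(
        {
            "date": [r.date for r in results],
            "aci_tot": [r.aci_tot for r in results],
        }
    )
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in ACI results")
    df = df.sort_values("date").reset_index(drop=True)
    excl = {}
    if reports is not None:
        excl = {r.date: r.excluded for r in reports}
    df["excluded"] = df["date"].map(lambda d: excl.get(d, False))
    df.loc[df["excluded"], "aci_tot"] = np.nan
    if covariates is not None:
        cov = covariates.copy()
        cov.index = pd.Index(
            [pd.Timestamp(d).date() for d in cov.index], name="date"
        )
        df = df.merge(cov, left_on="date", right_index=True, how="left")
    return df
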