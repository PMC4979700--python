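"""Calibrated 1-second 1/3-octave-band sound pressure levels.

A waveform is reduced to a ``BandSpectrogram``: one row per elapsed second,
one column per nominal 1/3-octave band, each cell the band-passed mean-square
level in dB plus a user-supplied calibration offset.  Band filtering uses
FFT-bin power aggregation on non-overlapping 1-s rectangular frames: each
spectral bin's power is assigned to the band whose passband contains its
frequency.  This is deterministic and energy-preserving (Parseval) within the
covered range; an ANSI filter bank would satisfy the same contract.

The per-second broadband A-weighted level and its hourly median (L50) are the
standard summaries used to locate the dawn chorus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .bands import DEFAULT_CENTERS, a_weighting_db, band_edges

#: Level assigned to zero-power cells instead of -inf (dB re digital full scale).
DB_FLOOR = -120.0


@dataclass
class BandSpectrogram:
    """Time x band matrix of SPL in dB at 1-second resolution.

    Attributes
    ----------
    values : ndarray, shape (n_seconds, n_bands)
        Calibrated SPL in dB.  Row ``k`` covers samples ``[k*sr, (k+1)*sr)``.
    band_centers : ndarray
        Nominal 1/3-octave centre frequencies (Hz), strictly increasing.
    start_time : datetime
        Timestamp of the first second; should carry an explicit UTC offset.
    weighting : str
        ``"flat"`` or ``"A"`` — whether the cells already include A-weighting.
    calibration_offset : float
        dB offset already added to every cell (0 = uncalibrated digital ref).
    """

    values: np.ndarray
    band_centers: np.ndarray
    start_time: datetime
    weighting: str = "flat"
    calibration_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (seconds x bands)")
        if self.values.shape[1] != self.band_centers.size:
            raise ValueError("one column per band centre required")
        if self.band_centers.size and np.any(np.diff(self.band_centers) <= 0):
            raise ValueError("band_centers must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all SPL values must be finite")
        if self.weighting not in ("flat", "A"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def n_seconds(self) -> int:
        return self.values.shape[0]

    def second_times(self) -> pd.DatetimeIndex:
        """Timestamp of each row (start of its half-open second)."""
        return pd.date_range(self.start_time, periods=self.n_seconds, freq="1s")

    def broadband_level(self, apply_a_weighting: bool = True) -> np.ndarray:
        """Per-second broadband level: energy sum across bands, in dB.

        When ``apply_a_weighting`` and the cells are flat-weighted, the
        standard A-curve is applied per band centre before summation.
        """
        v = self.values
        if apply_a_weighting and self.weighting == "flat":
            v = v + a_weighting_db(self.band_centers)[None, :]
        return 10.0 * np.log10(np.sum(10.0 ** (v / 10.0), axis=1))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.round(self.values, 2),
            index=self.second_times(),
            columns=[f"{c:g}" for c in self.band_centers],
        )
        df.index.name = "time"
        header = (
            f"# weighting={self.weighting} "
            f"calibration_offset={self.calibration_offset:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, date_format="%Y-%m-%dT%H:%M:%S%z")

    @classmethod
    def from_csv(cls, path) -> "BandSpectrogram":
        with open(path) as fh:
            meta = fh.readline().strip().lstrip("# ").split()
            kv = dict(item.split("=", 1) for item in meta)
            df = pd.read_csv(fh, index_col=0, parse_dates=[0])
        return cls(
            values=df.to_numpy(float),
            band_centers=np.array([float(c) for c in df.columns]),
            start_time=df.index[0].to_pydatetime(),
            weighting=kv.get("weighting", "flat"),
            calibration_offset=float(kv.get("calibration_offset", 0.0)),
        )


@dataclass(frozen=True)
class LevelSummary:
    """Hourly median broadband A-weighted level."""

    hour_of_day: int
    L50: float
    n_seconds: int


def audio_to_band_spl(
    audio: np.ndarray,
    sample_rate: int,
    calibration_offset: float = 0.0,
    weighting: str = "flat",
    band_centers=DEFAULT_CENTERS,
    start_time: datetime | None = None,
) -> BandSpectrogram:
    """Convert a waveform to a calibrated 1-s 1/3-octave-band SPL matrix.

    Each full second of audio is FFT-analysed; bin powers (mean-square units,
    Parseval-normalised) are summed into the 1/3-octave band containing the
    bin frequency, converted to dB, and offset by ``calibration_offset``.
    Bands whose upper edge exceeds the Nyquist frequency are omitted with a
    warning.  ``weighting="A"`` additionally adds the A-curve per band.

    Raises
    ------
    ValueError
        If the audio is shorter than 1 s or contains non-finite samples.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be single-channel (1-D)")
    bad = np.flatnonzero(~np.isfinite(audio))
    if bad.size:
        raise ValueError(f"non-finite sample at index {bad[0]}")
    sr = int(sample_rate)
    if audio.size < sr:
        raise ValueError(f"audio shorter than 1 s ({audio.size} samples at {sr} Hz)")

    centers = np.asarray(band_centers, dtype=float)
    low, high = band_edges(centers)
    nyquist = sr / 2.0
    keep = high <= nyquist
    if not np.all(keep):
        dropped = centers[~keep]
        warnings.warn(
            f"omitting {dropped.size} band(s) above Nyquist ({nyquist:g} Hz): "
            f"{', '.join(f'{c:g}' for c in dropped)}"
        )
        centers, low, high = centers[keep], low[keep], high[keep]

    n_sec = audio.size // sr
    frames = audio[: n_sec * sr].reshape(n_sec, sr)
    spec = np.fft.rfft(frames, axis=1)
    # Mean-square (power) per bin such that sum over bins = mean(x**2).
    power = np.abs(spec) ** 2 / sr**2
    power[:, 1:] *= 2.0
    if sr % 2 == 0:
        power[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(sr, d=1.0 / sr)

    # Half-open bin->band assignment: bin belongs to band with low <= f < high.
    band_idx = np.searchsorted(low, freqs, side="right") - 1
    in_band = (band_idx >= 0) & (freqs < high[np.clip(band_idx, 0, len(high) - 1)])
    band_power = np.zeros((n_sec, centers.size))
    idx = band_idx[in_band]
    np.add.at(band_power.T, idx, power[:, in_band].T)

    with np.errstate(divide="ignore"):
        spl = 10.0 * np.log10(band_power)
    spl = np.maximum(spl, DB_FLOOR)
    spl += calibration_offset
    if weighting == "A":
        spl += a_weighting_db(centers)[None, :]

    if start_time is None:
        start_time = datetime(2000, 1, 1)
    return BandSpectrogram(
        values=spl,
        band_centers=centers,
        start_time=start_time,
        weighting=weighting,
        calibration_offset=calibration_offset,
    )


def hourly_L50(spec: BandSpectrogram) -> list[LevelSummary]:
    """Hourly median (L50) of per-second broadband A-weighted levels.

    Seconds are grouped by local clock hour (from the spectrogram's
    ``start_time``); hours with no data are omitted.
    """
    levels = spec.broadband_level(apply_a_weighting=True)
    hours = spec.second_times().hour
    out = []
    for h in sorted(set(hours)):
        sel = levels[hours == h]
        out.append(LevelSummary(hour_of_day=int(h), L50=float(np.median(sel)), n_seconds=int(sel.size)))
    return out
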