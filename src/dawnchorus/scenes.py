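"""Seeded synthetic dawn-chorus scenes with exhaustive ground truth.

The generator emulates the acoustic structure a dawn-chorus phenology
analysis assumes: a handful of "species" with distinct spectro-temporal song
templates singing as a homogeneous Poisson process whose daily rate steps up
on the arrival day, over a stationary ambient noise floor, with occasional
broadband wind/rain events and a daily weather covariate table.

Two render paths share one event sampler (so a given config/seed/date yields
the same call log either way):

* :func:`synthesize_day` renders waveform audio for the dawn window —
  whistles as vibrato sines, complex songs as concatenated chirps, phrases
  as repeated two-note motifs, weather as band-limited pink-noise bursts.
* :func:`synthesize_day_band_spl` constructs the calibrated 1-s
  1/3-octave-band SPL matrix directly (songs and weather added as in-band
  power on top of a jittered ambient level).  This keeps season-scale
  simulation cheap: downstream index/change-point analyses consume only the
  band-SPL substrate.

Determinism: every random draw derives from ``(config.seed, day index,
stream)`` via ``numpy.random.SeedSequence``, so identical configs reproduce
bit-identical scenes and any single day can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as date_type
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .bands import DEFAULT_CENTERS, band_edges
from .bandspl import BandSpectrogram
from .solar import dawn_window

SONG_TYPES = ("tonal_whistle", "fm_complex", "phrase")

#: Fraction of the syllable duration separating syllables within a song.
_SYLLABLE_GAP_FRACTION = 0.3


@dataclass(frozen=True)
class SpeciesTemplate:
    """Spectro-temporal song template of one synthetic species."""

    name: str
    song_type: str
    freq_range: tuple[float, float]
    syllable_duration: float
    syllables_per_song: int = 1
    source_level: float = 20.0  # dB above the ambient floor

    def __post_init__(self) -> None:
        if self.song_type not in SONG_TYPES:
            raise ValueError(f"song_type must be one of {SONG_TYPES}")
        lo, hi = self.freq_range
        if not 0 < lo < hi:
            raise ValueError("freq_range must satisfy 0 < low < high")
        if self.syllable_duration <= 0:
            raise ValueError("syllable_duration must be positive")
        if self.syllables_per_song < 1:
            raise ValueError("syllables_per_song must be >= 1")

    @property
    def song_duration(self) -> float:
        """Total song duration: syllables plus inter-syllable gaps."""
        n = self.syllables_per_song
        return self.syllable_duration * (n + _SYLLABLE_GAP_FRACTION * (n - 1))


#: Default community: a whistled-tone singer (thrush-like, 2500-5850 Hz), a
#: fast FM singer (wren-like, 3-9 kHz) and an intermediate phrase singer.
DEFAULT_SPECIES: tuple[SpeciesTemplate, ...] = (
    SpeciesTemplate("whistler", "tonal_whistle", (2500.0, 5850.0), 0.8, 1, 25.0),
    SpeciesTemplate("fm_singer", "fm_complex", (3000.0, 9000.0), 0.1, 18, 20.0),
    SpeciesTemplate("phraser", "phrase", (2700.0, 6000.0), 0.25, 6, 22.0),
)


@dataclass(frozen=True)
class WeatherEvent:
    """A broadband wind/rain burst obscuring part of one day's window."""

    date: date_type
    start_s: float
    duration_s: float
    band_extent: tuple[float, float] = (12.5, 1000.0)
    level: float = 20.0  # dB above ambient


@dataclass(frozen=True)
class SceneConfig:
    """Full parameterization of a synthetic season."""

    lat: float = 58.45625
    lon: float = -135.86603
    utc_offset: float = -8.0
    season_start: date_type = date_type(2012, 3, 17)
    season_end: date_type = date_type(2012, 5, 15)
    arrival_day: date_type = date_type(2012, 4, 16)
    pre_arrival_rate: float = 2.0  # songs/h per species
    post_arrival_rate: float = 40.0
    species: tuple[SpeciesTemplate, ...] = DEFAULT_SPECIES
    noise_floor_db: float = -50.0  # audio path: RMS re digital full scale
    band_ambient_db: float = 30.0  # band path: calibrated per-band SPL
    noise_jitter_db: float = 0.3  # per-second, per-band ambient sd
    weather_events: tuple[WeatherEvent, ...] = ()
    sample_rate: int = 22050
    window_s: float = 10800.0
    seed: int = 0
    temp_range: tuple[float, float] = (-2.0, 10.0)
    temp_noise_sd: float = 1.5
    temp_arrival_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.season_end < self.season_start:
            raise ValueError("empty season: season_end before season_start")
        if not self.season_start <= self.arrival_day <= self.season_end:
            raise ValueError("arrival_day must lie inside the season")
        if self.pre_arrival_rate < 0 or self.post_arrival_rate < 0:
            raise ValueError("song rates must be >= 0")
        if self.sample_rate < 22050:
            raise ValueError("sample_rate must be >= 22050 Hz")
        fmax = max(t.freq_range[1] for t in self.species)
        if self.sample_rate < 2 * fmax:
            raise ValueError(
                f"sample_rate {self.sample_rate} too low for template "
                f"frequencies up to {fmax:g} Hz"
            )

    @property
    def dates(self) -> list[date_type]:
        n = (self.season_end - self.season_start).days + 1
        return [self.season_start + timedelta(days=i) for i in range(n)]

    def day_index(self, date: date_type) -> int:
        idx = (date - self.season_start).days
        if not 0 <= idx <= (self.season_end - self.season_start).days:
            raise ValueError(
                f"{date.isoformat()} outside season "
                f"[{self.season_start.isoformat()}, {self.season_end.isoformat()}]"
            )
        return idx


def _day_rng(config: SceneConfig, date: date_type, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, config.day_index(date), stream])
    )


def sample_day_events(config: SceneConfig, date: date_type) -> pd.DataFrame:
    """Ground-truth call log for one day (the shared event sampler).

    Each species sings as a homogeneous Poisson process at its daily rate
    (pre- or post-arrival); onsets are uniform over the window such that the
    whole song fits.  Returns a frame sorted by onset with columns
    ``species, date, onset_s, duration_s, freq_low, freq_high``.
    """
    window_h = config.window_s / 3600.0
    rows = []
    for s_idx, sp in enumerate(config.species):
        rng = _day_rng(config, date, 100 + s_idx)
        rate = (
            config.post_arrival_rate
            if date >= config.arrival_day
            else config.pre_arrival_rate
        )
        n = rng.poisson(rate * window_h)
        dur = sp.song_duration
        span = max(config.window_s - dur, 0.0)
        for onset in np.sort(rng.uniform(0.0, span, size=n)):
            rows.append(
                {
                    "species": sp.name,
                    "date": date,
                    "onset_s": float(onset),
                    "duration_s": dur,
                    "freq_low": sp.freq_range[0],
                    "freq_high": sp.freq_range[1],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["species", "date", "onset_s", "duration_s", "freq_low", "freq_high"],
    )
    return df.sort_values(["date", "onset_s"], kind="stable").reset_index(drop=True)


def concat_call_logs(truths: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-day call logs, tolerating empty days."""
    nonempty = [t for t in truths if len(t)]
    if not nonempty:
        cols = ["species", "date", "onset_s", "duration_s", "freq_low", "freq_high"]
        return truths[0].copy() if truths else pd.DataFrame(columns=cols)
    return pd.concat(nonempty, ignore_index=True)


def _syllable_times(sp: SpeciesTemplate) -> list[float]:
    step = sp.syllable_duration * (1.0 + _SYLLABLE_GAP_FRACTION)
    return [i * step for i in range(sp.syllables_per_song)]


def _render_song(
    sp: SpeciesTemplate, sr: int, rng: np.random.Generator
) -> np.ndarray:
    """Render one song at unit peak amplitude (envelope applied)."""
    lo, hi = sp.freq_range
    n_syl = int(round(sp.syllable_duration * sr))
    t = np.arange(n_syl) / sr
    env = tukey(n_syl, 0.3)
    total = np.zeros(int(round(sp.song_duration * sr)) + 1)
    # keep instantaneous frequency off the band edges so spectral energy
    # (including envelope sidebands) stays within the template range
    margin = 0.08 * (hi - lo)
    flo, fhi = lo + margin, hi - margin
    motif = rng.uniform(flo, fhi, size=2)  # used by the phrase type only
    for k, t0 in enumerate(_syllable_times(sp)):
        if sp.song_type == "tonal_whistle":
            f0 = rng.uniform(flo, fhi)
            inst = f0 * (1.0 + 0.004 * np.sin(2 * np.pi * 8.0 * t + rng.uniform(0, 2 * np.pi)))
        elif sp.song_type == "fm_complex":
            fa, fb = rng.uniform(flo, fhi, size=2)
            inst = fa + (fb - fa) * t / t[-1] if n_syl > 1 else np.full(n_syl, fa)
        else:  # phrase: alternating two-note motif
            inst = np.full(n_syl, motif[k % 2])
        phase = 2 * np.pi * np.cumsum(inst) / sr
        syl = env * np.sin(phase)
        i0 = int(round(t0 * sr))
        total[i0 : i0 + n_syl] += syl
    return total


def _pink_burst(
    n: int, sr: int, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS pink noise confined to a frequency band, via FFT shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / sr)
    gain = np.zeros_like(freqs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    gain[sel] = 1.0 / np.sqrt(np.maximum(freqs[sel], 1.0))
    shaped = np.fft.irfft(spec * gain, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def synthesize_day(
    config: SceneConfig, date: date_type
) -> tuple[np.ndarray, int, pd.DataFrame]:
    """Render one day's dawn-window audio and its ground-truth call log.

    Returns ``(audio, sample_rate, truth)``.  The ambient floor is white
    noise at ``noise_floor_db`` RMS re full scale; each song is rendered at
    ``source_level`` dB above it; weather events add band-limited pink-noise
    bursts.  Bit-identical for identical ``(config, date)``.
    """
    sr = config.sample_rate
    n = int(round(config.window_s * sr))
    truth = sample_day_events(config, date)
    noise_rms = 10.0 ** (config.noise_floor_db / 20.0)
    rng_noise = _day_rng(config, date, 0)
    audio = noise_rms * rng_noise.standard_normal(n)

    sp_by_name = {sp.name: sp for sp in config.species}
    rng_song = _day_rng(config, date, 1)
    for ev in truth.itertuples():
        sp = sp_by_name[ev.species]
        song = _render_song(sp, sr, rng_song)
        peak = np.max(np.abs(song))
        if peak > 0:
            # scale so the song RMS sits source_level dB above the floor
            song_rms = np.sqrt(np.mean(song[np.abs(song) > 0] ** 2))
            song = song * (noise_rms * 10.0 ** (sp.source_level / 20.0) / song_rms)
        i0 = int(round(ev.onset_s * sr))
        seg = song[: max(n - i0, 0)]
        audio[i0 : i0 + seg.size] += seg

    rng_wx = _day_rng(config, date, 2)
    for wx in config.weather_events:
        if wx.date != date:
            continue
        i0 = int(round(wx.start_s * sr))
        nw = int(round(wx.duration_s * sr))
        nw = min(nw, n - i0)
        if nw <= 0:
            continue
        burst = _pink_burst(nw, sr, wx.band_extent, rng_wx)
        ramp = tukey(nw, min(1.0, 2.0 * sr / nw)) if nw > 4 else np.ones(nw)
        audio[i0 : i0 + nw] += noise_rms * 10.0 ** (wx.level / 20.0) * burst * ramp
    return audio, sr, truth


def _bands_covered(freq_range: tuple[float, float], centers: np.ndarray) -> np.ndarray:
    low, high = band_edges(centers)
    return (low <= freq_range[1]) & (high >= freq_range[0])


def synthesize_day_band_spl(
    config: SceneConfig, date: date_type, band_centers=DEFAULT_CENTERS
) -> tuple[BandSpectrogram, pd.DataFrame]:
    """Construct one day's calibrated band-SPL matrix directly.

    The ambient floor is ``band_ambient_db`` per band with iid Gaussian dB
    jitter (sd ``noise_jitter_db``) per cell.  Each song adds its source
    power (``source_level`` dB above ambient, split evenly over the bands its
    frequency range covers) to the seconds it overlaps, weighted by the
    overlap fraction; weather events add ``level`` dB above ambient to every
    covered band-second.  Same call log as the audio path.
    """
    n_sec = int(round(config.window_s))
    centers = np.asarray(band_centers, dtype=float)
    truth = sample_day_events(config, date)
    rng = _day_rng(config, date, 3)
    jitter = rng.normal(0.0, config.noise_jitter_db, size=(n_sec, centers.size))
    power = 10.0 ** ((config.band_ambient_db + jitter) / 10.0)

    for ev in truth.itertuples():
        covered = _bands_covered((ev.freq_low, ev.freq_high), centers)
        nb = int(np.count_nonzero(covered))
        sp_level = next(
            sp.source_level for sp in config.species if sp.name == ev.species
        )
        p_song = 10.0 ** ((config.band_ambient_db + sp_level) / 10.0) / nb
        t0, t1 = ev.onset_s, ev.onset_s + ev.duration_s
        for sec in range(int(np.floor(t0)), min(int(np.ceil(t1)), n_sec)):
            frac = min(t1, sec + 1) - max(t0, sec)
            if frac > 0:
                power[sec, covered] += frac * p_song

    for wx in config.weather_events:
        if wx.date != date:
            continue
        covered = _bands_covered(wx.band_extent, centers)
        s0 = int(np.floor(wx.start_s))
        s1 = min(int(np.ceil(wx.start_s + wx.duration_s)), n_sec)
        power[s0:s1, covered] += 10.0 ** ((config.band_ambient_db + wx.level) / 10.0)

    spec = BandSpectrogram(
        values=10.0 * np.log10(power),
        band_centers=centers,
        start_time=dawn_window(config.lat, config.lon, date, config.utc_offset).start,
        weighting="flat",
        calibration_offset=0.0,
    )
    return spec, truth


def season_weather(config: SceneConfig) -> pd.DataFrame:
    """Daily weather covariates: temperature ramp + noise, wind, humidity,
    pressure, and the per-day obscured duration from configured events."""
    dates = config.dates
    n = len(dates)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000]))
    t0, t1 = config.temp_range
    ramp = np.linspace(t0, t1, n) if n > 1 else np.array([(t0 + t1) / 2.0])
    temp = ramp + rng.normal(0.0, config.temp_noise_sd, n)
    arrived = np.array([d >= config.arrival_day for d in dates])
    temp = temp + config.temp_arrival_coupling * arrived
    wx_days = {}
    for wx in config.weather_events:
        wx_days[wx.date] = wx_days.get(wx.date, 0.0) + wx.duration_s
    wind = np.abs(rng.normal(3.0, 2.0, n))
    wind += np.array([8.0 if d in wx_days else 0.0 for d in dates])
    return pd.DataFrame(
        {
            "date": dates,
            "temperature": temp,
            "wind": wind,
            "humidity": np.clip(rng.normal(75.0, 10.0, n), 5.0, 100.0),
            "pressure": rng.normal(1013.0, 5.0, n),
            "obscured_s": [wx_days.get(d, 0.0) for d in dates],
        }
    )


def synthesize_season(
    config: SceneConfig,
    out_dir=None,
    mode: str = "band",
    site_name: str = "SITE",
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Generate the whole season.

    ``mode="band"`` yields per-day :class:`BandSpectrogram` objects (or CSVs
    under ``out_dir``); ``mode="audio"`` writes one PCM-16 WAV per day named
    ``SITE_YYYYMMDD.wav`` (``out_dir`` required).  Returns
    ``(artifacts, truth, weather)`` where artifacts are the per-day objects
    or file paths, truth is the aggregated call log, and weather the daily
    covariate table.
    """
    import pathlib

    if mode not in ("band", "audio"):
        raise ValueError("mode must be 'band' or 'audio'")
    if mode == "audio" and out_dir is None:
        raise ValueError("audio mode requires out_dir")
    artifacts: list = []
    truths = []
    for date in config.dates:
        if mode == "band":
            spec, truth = synthesize_day_band_spl(config, date)
            if out_dir is not None:
                path = pathlib.Path(out_dir) / f"{site_name}_{date:%Y%m%d}_bandspl.csv"
                spec.to_csv(path)
                artifacts.append(path)
            else:
                artifacts.append(spec)
        else:
            from scipy.io import wavfile

            audio, sr, truth = synthesize_day(config, date)
            path = pathlib.Path(out_dir) / f"{site_name}_{date:%Y%m%d}.wav"
            scaled = np.clip(audio, -1.0, 1.0)
            wavfile.write(path, sr, (scaled * 32767).astype(np.int16))
            artifacts.append(path)
        truths.append(truth)
    truth = concat_call_logs(truths)
    weather = season_weather(config)
    if out_dir is not None:
        truth.to_csv(pathlib.Path(out_dir) / "call_log.csv", index=False)
        weather.to_csv(pathlib.Path(out_dir) / "weather.csv", index=False)
    return artifacts, truth, weather
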