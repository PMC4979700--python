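"""Band-SPL conversion: energy placement, calibration, medians."""

import warnings
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from dawnchorus import BandSpectrogram, audio_to_band_spl, hourly_L50
from dawnchorus.bands import band_edges
from dawnchorus.bandspl import DB_FLOOR

from conftest import flat_spectrogram

SR = 22050


def _sine(freq, seconds, sr=SR, amp=1.0):
    t = np.arange(int(seconds * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


def test_sine_energy_lands_in_its_nominal_band():
    spec = audio_to_band_spl(_sine(1000.0, 3.0), SR)
    linear = 10 ** (spec.values / 10.0)
    j = int(np.argmin(np.abs(spec.band_centers - 1000.0)))
    assert spec.band_centers[j] == 1000.0
    assert (linear[:, j] / linear.sum(axis=1)).min() >= 0.9
    # absolute level: mean square of a unit sine is 1/2 -> -3.01 dB
    assert spec.values[:, j] == pytest.approx(10 * np.log10(0.5), abs=0.1)


def test_calibration_offset_is_purely_additive():
    rng = np.random.default_rng(0)
    audio = rng.standard_normal(3 * SR)
    s1 = audio_to_band_spl(audio, SR, calibration_offset=12.0)
    s2 = audio_to_band_spl(audio, SR, calibration_offset=-5.0)
    np.testing.assert_allclose(s1.values - s2.values, 17.0, atol=1e-9)


def test_digital_silence_hits_the_db_floor():
    spec = audio_to_band_spl(np.zeros(2 * SR), SR)
    assert np.all(spec.values == DB_FLOOR)


def test_six_db_gain_raises_every_band_six_db():
    rng = np.random.default_rng(1)
    audio = rng.standard_normal(2 * SR)
    s1 = audio_to_band_spl(audio, SR)
    s2 = audio_to_band_spl(2.0 * audio, SR)
    np.testing.assert_allclose(s2.values - s1.values, 6.0206, atol=0.1)


def test_band_energy_sum_matches_direct_power():
    """Parseval check: banded energy equals in-range signal power within 1 dB."""
    rng = np.random.default_rng(2)
    white = rng.standard_normal(4 * SR)
    spec = audio_to_band_spl(white, SR)
    low, high = band_edges(spec.band_centers)
    # reference: power of the signal restricted to the covered range
    fft = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(white.size, 1.0 / SR)
    mask = (freqs >= low[0]) & (freqs < high[-1])
    ref_power = np.sum(np.abs(fft[mask]) ** 2) * 2 / white.size**2
    band_power = np.sum(10 ** (spec.values / 10.0), axis=1).mean()
    assert abs(10 * np.log10(band_power / ref_power)) < 1.0


def test_rows_cover_half_open_seconds():
    audio = np.concatenate([np.zeros(SR), _sine(1000.0, 1.0)])
    spec = audio_to_band_spl(audio, SR)
    j = int(np.argmin(np.abs(spec.band_centers - 1000.0)))
    assert spec.values[0, j] == DB_FLOOR
    assert spec.values[1, j] > -10.0


def test_bands_above_nyquist_are_dropped_with_warning():
    with pytest.warns(UserWarning, match="Nyquist"):
        spec = audio_to_band_spl(np.random.default_rng(3).standard_normal(8000), 8000)
    assert spec.band_centers.max() <= 8000 / 2 / 10 ** (1 / 20)


def test_rejections():
    with pytest.raises(ValueError, match="shorter than 1 s"):
        audio_to_band_spl(np.zeros(100), SR)
    bad = np.zeros(2 * SR)
    bad[123] = np.nan
    with pytest.raises(ValueError, match="index 123"):
        audio_to_band_spl(bad, SR)


def test_hourly_l50_is_the_hourly_median():
    spec = flat_spectrogram(3600, level_db=60.0, band_centers=(1000.0,))
    spec.weighting = "A"  # values already broadband-equivalent
    (row,) = hourly_L50(spec)
    assert row.L50 == pytest.approx(60.0)
    assert row.n_seconds == 3600

    spec3 = flat_spectrogram(3, level_db=0.0, band_centers=(1000.0,))
    spec3.weighting = "A"
    spec3.values[:, 0] = [50.0, 60.0, 70.0]
    (row3,) = hourly_L50(spec3)
    assert row3.L50 == pytest.approx(60.0)


def test_l50_peaks_within_one_hour_of_sunrise():
    """A day whose songs cluster at sunrise shows its L50 maximum there."""
    tz = timezone(timedelta(hours=-8))
    sunrise_hour = 6
    start = datetime(2012, 4, 16, 0, 0, tzinfo=tz)
    values = np.full((24 * 3600, 2), 30.0)
    rng = np.random.default_rng(5)
    sec_of_day = np.arange(24 * 3600)
    near_dawn = (sec_of_day >= 5.5 * 3600) & (sec_of_day < 7 * 3600)
    # dense chorus energy in the biotic band around sunrise
    singing = near_dawn & (rng.random(24 * 3600) < 0.9)
    values[singing, 1] += 25.0
    spec = BandSpectrogram(values, np.array([500.0, 3150.0]), start)
    rows = hourly_L50(spec)
    peak_hour = max(rows, key=lambda r: r.L50).hour_of_day
    assert abs(peak_hour - sunrise_hour) <= 1


def test_csv_round_trip(tmp_path):
    spec = flat_spectrogram(5, level_db=42.5)
    path = tmp_path / "spec.csv"
    spec.to_csv(path)
    back = BandSpectrogram.from_csv(path)
    np.testing.assert_allclose(back.values, spec.values, atol=0.005)
    np.testing.assert_array_equal(back.band_centers, spec.band_centers)
    assert back.weighting == spec.weighting
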