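"""Synthetic-scene generator: determinism, Poisson statistics, ground truth."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from dawnchorus import SceneConfig, SpeciesTemplate, WeatherEvent
from dawnchorus.scenes import (
    sample_day_events,
    season_weather,
    synthesize_day,
    synthesize_day_band_spl,
    synthesize_season,
)


def test_same_config_and_seed_reproduces_bit_identical_output(tiny_scene):
    d = date(2012, 4, 7)
    a1, sr1, t1 = synthesize_day(tiny_scene, d)
    a2, sr2, t2 = synthesize_day(tiny_scene, d)
    assert sr1 == sr2
    np.testing.assert_array_equal(a1, a2)
    pd.testing.assert_frame_equal(t1, t2)
    s1, _ = synthesize_day_band_spl(tiny_scene, d)
    s2, _ = synthesize_day_band_spl(tiny_scene, d)
    np.testing.assert_array_equal(s1.values, s2.values)


def test_zero_rate_day_is_noise_floor_only(whistler):
    cfg = SceneConfig(
        season_start=date(2012, 4, 1),
        season_end=date(2012, 4, 10),
        arrival_day=date(2012, 4, 5),
        pre_arrival_rate=0.0,
        post_arrival_rate=0.0,
        species=(whistler,),
        window_s=30.0,
        seed=1,
    )
    audio, sr, truth = synthesize_day(cfg, date(2012, 4, 8))
    assert len(truth) == 0
    rms_db = 20 * np.log10(np.sqrt(np.mean(audio**2)))
    assert abs(rms_db - cfg.noise_floor_db) < 0.5


def test_poisson_event_counts_match_rate(whistler):
    counts = []
    for seed in range(50):
        cfg = SceneConfig(
            season_start=date(2012, 4, 1),
            season_end=date(2012, 4, 2),
            arrival_day=date(2012, 4, 1),
            post_arrival_rate=60.0,
            species=(whistler,),
            window_s=10800.0,
            seed=seed,
        )
        counts.append(len(sample_day_events(cfg, date(2012, 4, 1))))
    # 3-sigma band around the Poisson mean of 180 songs per 3-h window
    assert abs(np.mean(counts) - 180.0) < 3 * np.sqrt(180.0)


def test_arrival_step_separates_daily_counts(tiny_scene):
    cfg = SceneConfig(
        season_start=tiny_scene.season_start,
        season_end=tiny_scene.season_end,
        arrival_day=date(2012, 4, 6),
        pre_arrival_rate=2.0,
        post_arrival_rate=40.0,
        species=tiny_scene.species,
        window_s=10800.0,
        seed=11,
    )
    counts = {d: len(sample_day_events(cfg, d)) for d in cfg.dates}
    pre = [c for d, c in counts.items() if d < cfg.arrival_day]
    post = [c for d, c in counts.items() if d >= cfg.arrival_day]
    assert max(pre) < min(post)


def test_season_cardinality_and_truth_span(tiny_scene, tmp_path):
    artifacts, truth, weather = synthesize_season(tiny_scene, out_dir=tmp_path)
    assert len(artifacts) == 10
    assert len(weather) == 10
    assert truth["date"].min() >= tiny_scene.season_start
    assert truth["date"].max() <= tiny_scene.season_end
    assert (tmp_path / "call_log.csv").exists()
    assert (tmp_path / "weather.csv").exists()


def test_single_day_season_runs(whistler, tmp_path):
    cfg = SceneConfig(
        season_start=date(2012, 4, 1),
        season_end=date(2012, 4, 1),
        arrival_day=date(2012, 4, 1),
        species=(whistler,),
        window_s=30.0,
        seed=0,
    )
    artifacts, truth, weather = synthesize_season(cfg, out_dir=tmp_path, mode="audio")
    assert len(artifacts) == 1
    assert artifacts[0].name.endswith("20120401.wav")


def test_truth_shared_between_audio_and_band_paths(tiny_scene):
    d = date(2012, 4, 8)
    _, _, t_audio = synthesize_day(tiny_scene, d)
    _, t_band = synthesize_day_band_spl(tiny_scene, d)
    pd.testing.assert_frame_equal(t_audio, t_band)


@pytest.mark.parametrize("song_type", ["tonal_whistle", "fm_complex", "phrase"])
def test_song_energy_confined_to_template_band(song_type):
    sp = SpeciesTemplate(
        "sp", song_type, (3000.0, 6000.0),
        syllable_duration=0.2, syllables_per_song=4, source_level=40.0,
    )
    cfg = SceneConfig(
        season_start=date(2012, 4, 1),
        season_end=date(2012, 4, 1),
        arrival_day=date(2012, 4, 1),
        post_arrival_rate=240.0,
        species=(sp,),
        noise_floor_db=-110.0,  # essentially clean signal
        window_s=30.0,
        seed=4,
    )
    audio, sr, truth = synthesize_day(cfg, date(2012, 4, 1))
    assert len(truth) > 0
    spec = np.abs(np.fft.rfft(audio)) ** 2
    freqs = np.fft.rfftfreq(audio.size, 1.0 / sr)
    inband = spec[(freqs >= 3000) & (freqs <= 6000)].sum()
    assert inband / spec.sum() >= 0.9


def test_weather_event_elevates_low_bands(whistler):
    d = date(2012, 4, 3)
    wx = WeatherEvent(date=d, start_s=10.0, duration_s=20.0, band_extent=(12.5, 1000.0), level=20.0)
    cfg = SceneConfig(
        season_start=date(2012, 4, 1),
        season_end=date(2012, 4, 10),
        arrival_day=date(2012, 4, 6),
        species=(whistler,),
        weather_events=(wx,),
        window_s=60.0,
        seed=2,
    )
    spec, _ = synthesize_day_band_spl(cfg, d)
    low = spec.band_centers <= 1000.0
    in_event = spec.values[12:28][:, low].mean()
    outside = spec.values[35:][:, low].mean()
    assert in_event - outside > 10.0


def test_invalid_configs_are_rejected(whistler):
    with pytest.raises(ValueError, match="outside season"):
        synthesize_day(
            SceneConfig(species=(whistler,), window_s=30.0), date(2020, 1, 1)
        )
    with pytest.raises(ValueError, match="arrival_day"):
        SceneConfig(species=(whistler,), arrival_day=date(1999, 1, 1))
    with pytest.raises(ValueError, match="sample_rate"):
        SceneConfig(species=(whistler,), sample_rate=16000)
    with pytest.raises(ValueError, match="too low"):
        SceneConfig(
            species=(SpeciesTemplate("hi", "tonal_whistle", (9000.0, 12000.0), 0.2),),
            sample_rate=22050,
        )
    with pytest.raises(ValueError, match="empty season"):
        SceneConfig(season_end=date(2012, 3, 1))


def test_temperature_ramp_spans_configured_range(tiny_scene):
    wx = season_weather(tiny_scene)
    assert list(wx["date"]) == tiny_scene.dates
    # ramp from -2 to 10 C with sd-1.5 noise: ends differ clearly
    assert wx["temperature"].iloc[-1] > wx["temperature"].iloc[0] - 2.0
    assert wx["temperature"].mean() == pytest.approx(4.0, abs=3.0)
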