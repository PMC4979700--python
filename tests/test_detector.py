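"""Band-limited energy detector: events, matching, count correction."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from dawnchorus import Detection, DetectorConfig, correct_counts, detect, evaluate

SR = 22050


def _whistle_scene(onsets, duration=0.5, freq=3000.0, snr_db=20.0, seconds=20.0, seed=0):
    """White noise with tone bursts ``snr_db`` above the in-band noise level."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(int(seconds * SR))
    audio = noise.copy()
    # in-band noise power within 2500-5850 Hz is bandwidth/(SR/2) of total
    band_frac = (5850 - 2500) / (SR / 2)
    tone_rms = np.sqrt(band_frac) * 10 ** (snr_db / 20.0)
    t = np.arange(int(duration * SR)) / SR
    burst = tone_rms * np.sqrt(2) * np.sin(2 * np.pi * freq * t)
    env = np.minimum(1, np.minimum(t, t[-1] - t) / 0.01) if t.size else burst
    for onset in onsets:
        i0 = int(onset * SR)
        audio[i0 : i0 + burst.size] += burst * env
    return audio


CONFIG = DetectorConfig(
    species="whistler",
    freq_range=(2500.0, 5850.0),
    min_duration=0.2,
    max_duration=1.0,
    snr_threshold=10.0,
)


def test_noise_only_high_threshold_yields_nothing():
    audio = _whistle_scene([], seed=1)
    config = DetectorConfig(
        species="x", freq_range=(2500.0, 5850.0), snr_threshold=30.0
    )
    assert detect(audio, SR, config) == []


def test_single_whistle_is_detected_once_at_its_onset():
    audio = _whistle_scene([8.0])
    dets = detect(audio, SR, CONFIG)
    assert len(dets) == 1
    d = dets[0]
    assert d.onset_s == pytest.approx(8.0, abs=0.1)
    assert 0.2 <= d.duration_s <= 1.0
    assert d.peak_snr >= 10.0


def test_duration_filter_drops_short_events():
    audio = _whistle_scene([8.0], duration=0.5)
    config = DetectorConfig(
        species="x", freq_range=(2500.0, 5850.0),
        min_duration=0.8, max_duration=2.0, snr_threshold=10.0,
    )
    assert detect(audio, SR, config) == []


def test_raising_threshold_never_adds_detections():
    audio = _whistle_scene([3.0, 8.0, 14.0], snr_db=15.0, seed=3)
    counts = []
    for thr in (6.0, 10.0, 14.0, 20.0):
        cfg = DetectorConfig(
            species="x", freq_range=(2500.0, 5850.0),
            min_duration=0.2, max_duration=1.0, snr_threshold=thr,
        )
        counts.append(len(detect(audio, SR, cfg)))
    assert counts == sorted(counts, reverse=True)


def test_global_gain_does_not_change_detections():
    audio = _whistle_scene([5.0, 12.0])
    base = detect(audio, SR, CONFIG)
    for gain_db in (-6.0, 6.0):
        scaled = detect(audio * 10 ** (gain_db / 20.0), SR, CONFIG)
        assert len(scaled) == len(base)
        for a, b in zip(base, scaled):
            assert a.onset_s == pytest.approx(b.onset_s, abs=1e-9)


def _truth(onsets, day=date(2012, 4, 16)):
    return pd.DataFrame(
        {
            "species": "whistler",
            "date": day,
            "onset_s": onsets,
            "duration_s": 0.5,
            "freq_low": 2500.0,
            "freq_high": 5850.0,
        }
    )


def _dets(onsets, day=date(2012, 4, 16)):
    return [
        Detection("whistler", o, 0.5, 15.0, (2500.0, 5850.0), day) for o in onsets
    ]


def test_perfect_detections_score_perfectly():
    truth = _truth([1.0, 5.0, 9.0])
    ev = evaluate(_dets([1.0, 5.0, 9.0]), truth)
    assert (ev.true_positives, ev.false_positives, ev.false_negatives) == (3, 0, 0)
    assert ev.fn_rate == 0.0
    assert ev.precision == 1.0


def test_partial_detections_give_fn_rate():
    truth = _truth(np.arange(10, dtype=float) * 3)
    ev = evaluate(_dets([0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0]), truth)
    assert ev.true_positives == 8
    assert ev.false_negatives == 2
    assert ev.fn_rate == pytest.approx(0.2)


def test_matching_is_order_invariant():
    truth = _truth([2.0, 4.0, 6.0])
    fwd = evaluate(_dets([2.1, 4.1, 6.1]), truth)
    rev = evaluate(list(reversed(_dets([2.1, 4.1, 6.1]))), truth)
    assert fwd == rev


def test_band_mismatch_is_a_false_positive():
    truth = _truth([2.0])
    dets = [Detection("other", 2.0, 0.5, 15.0, (8000.0, 9000.0), date(2012, 4, 16))]
    ev = evaluate(dets, truth)
    assert ev.true_positives == 0
    assert ev.false_positives == 1
    assert ev.false_negatives == 1


def test_count_correction_inverse_sensitivity():
    d = date(2012, 4, 16)
    assert correct_counts({d: 80}, 0.2)[d] == pytest.approx(100.0)
    assert correct_counts({d: 7}, 0.0)[d] == 7
    with pytest.raises(ValueError, match="cap"):
        correct_counts({d: 1}, 0.96)
    with pytest.raises(ValueError, match="in \\[0, 1\\)"):
        correct_counts({d: 1}, 1.0)
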