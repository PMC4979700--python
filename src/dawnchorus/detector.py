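"""Band-limited energy detection of song events, evaluation, FN correction.

A band-limited (time–frequency) energy detector integrates STFT power over a
configured frequency band, tracks the background level with a per-second
running median, and emits an event for every contiguous run of frames whose
in-band level exceeds the background by the SNR threshold, subject to
duration limits and gap merging.  Because the background estimate is a
median of the same in-band level, detections are invariant to a global gain
change.

Detector output is scored against a ground-truth call log by greedy
one-to-one onset matching; the resulting false-negative rate corrects raw
daily counts by inverse sensitivity: ``corrected = count / (1 - fn_rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_type

import numpy as np
import pandas as pd
from scipy.signal import stft

#: Detectors with a false-negative rate above this are considered unreliable.
MAX_CORRECTABLE_FN_RATE = 0.95


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of one species' band-limited energy detector."""

    species: str
    freq_range: tuple[float, float]
    min_duration: float = 0.15
    max_duration: float = 3.0
    snr_threshold: float = 10.0
    min_gap: float = 0.15
    stft_window_s: float = 0.023
    stft_overlap: float = 0.5
    background_window_s: float = 60.0

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        if not 0 < lo < hi:
            raise ValueError("freq_range must satisfy 0 < low < high")
        if not 0 < self.min_duration <= self.max_duration:
            raise ValueError("need 0 < min_duration <= max_duration")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive (dB)")


@dataclass(frozen=True)
class Detection:
    """One detected event."""

    species: str
    onset_s: float
    duration_s: float
    peak_snr: float
    band: tuple[float, float]
    date: date_type | None = None


@dataclass(frozen=True)
class DetectorEvaluation:
    """Detector performance against ground truth."""

    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def fn_rate(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.false_negatives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        return 1.0 - self.fn_rate

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 1.0


def _inband_level_db(
    audio: np.ndarray, sample_rate: int, config: DetectorConfig
):
    """Per-frame in-band level (dB) and the frame time axis."""
    sr = int(sample_rate)
    nperseg = max(int(round(config.stft_window_s * sr)), 8)
    noverlap = int(nperseg * config.stft_overlap)
    freqs, times, zxx = stft(
        audio, fs=sr, nperseg=nperseg, noverlap=noverlap,
        boundary=None, padded=False,
    )
    lo, hi = config.freq_range
    if hi > sr / 2:
        raise ValueError(
            f"detector band {lo:g}-{hi:g} Hz exceeds Nyquist ({sr / 2:g} Hz)"
        )
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError("detector band contains no STFT bins")
    power = np.sum(np.abs(zxx[sel]) ** 2, axis=0)
    return 10.0 * np.log10(np.maximum(power, 1e-30)), times


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    window = min(window, x.size)
    if window % 2 == 0:
        window = max(window - 1, 1)
    return pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()


def detect(
    audio: np.ndarray,
    sample_rate: int,
    config: DetectorConfig,
    date: date_type | None = None,
) -> list[Detection]:
    """Run the band-limited energy detector over one recording.

    Returns detections sorted by onset.  Deterministic: no randomness in the
    background tracker or the run segmentation.
    """
    level, times = _inband_level_db(np.asarray(audio, dtype=float), sample_rate, config)
    dt = times[1] - times[0] if times.size > 1 else 1.0
    bg_frames = max(int(round(config.background_window_s / dt)), 3)
    background = _running_median(level, bg_frames)
    snr = level - background
    active = snr >= config.snr_threshold

    # contiguous runs of active frames
    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))  # [start, stop) frame indices

    # merge runs separated by < min_gap
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and (times[start] - times[merged[-1][1] - 1]) < config.min_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    out = []
    for start, stop in merged:
        onset = float(times[start])
        duration = float(times[stop - 1] - times[start] + dt)
        if not config.min_duration <= duration <= config.max_duration:
            continue
        out.append(
            Detection(
                species=config.species,
                onset_s=onset,
                duration_s=duration,
                peak_snr=float(np.max(snr[start:stop])),
                band=config.freq_range,
                date=date,
            )
        )
    return out


def _bands_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def evaluate(
    detections: list[Detection],
    truth: pd.DataFrame,
    match_tolerance_s: float = 1.0,
) -> DetectorEvaluation:
    """Score detections against a ground-truth call log.

    ``truth`` needs columns ``onset_s``, ``freq_low``, ``freq_high`` (and
    optionally ``date``; when present, matches are restricted within dates).
    Matching is greedy one-to-one: truth events in onset order claim the
    nearest unmatched detection within ``match_tolerance_s`` whose band
    overlaps; ties break to the earliest detection, so the result is
    independent of input detection order.
    """
    det = sorted(detections, key=lambda d: (str(d.date), d.onset_s))
    used = np.zeros(len(det), dtype=bool)
    tp = 0
    rows = truth.sort_values(
        [c for c in ("date", "onset_s") if c in truth.columns]
    ).itertuples()
    for ev in rows:
        best = None
        best_dist = match_tolerance_s
        for j, d in enumerate(det):
            if used[j]:
                continue
            if "date" in truth.columns and d.date is not None and d.date != ev.date:
                continue
            dist = abs(d.onset_s - ev.onset_s)
            if dist <= best_dist and _bands_overlap(d.band, (ev.freq_low, ev.freq_high)):
                if best is None or dist < best_dist or d.onset_s < det[best].onset_s:
                    best, best_dist = j, dist
        if best is not None:
            used[best] = True
            tp += 1
    fn = len(truth) - tp
    fp = len(det) - tp
    return DetectorEvaluation(true_positives=tp, false_positives=fp, false_negatives=fn)


def correct_counts(
    daily_counts: dict[date_type, int] | pd.Series, fn_rate: float
) -> dict[date_type, float]:
    """Inflate raw daily true-detection counts by the false-negative rate.

    ``corrected = count / (1 - fn_rate)`` — the inverse-sensitivity
    estimator of the true number of calls.  Rejected above
    ``MAX_CORRECTABLE_FN_RATE`` where the correction is unstable.
    """
    if not 0.0 <= fn_rate < 1.0:
        raise ValueError("fn_rate must be in [0, 1)")
    if fn_rate > MAX_CORRECTABLE_FN_RATE:
        raise ValueError(
            f"fn_rate {fn_rate:.3f} exceeds correctable cap {MAX_CORRECTABLE_FN_RATE}"
        )
    return {d: c / (1.0 - fn_rate) for d, c in dict(daily_counts).items()}


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Detections as a Raven-selection-table-compatible table."""
    return pd.DataFrame(
        {
            "species": [d.species for d in detections],
            "date": [d.date.isoformat() if d.date else "" for d in detections],
            "begin_time_s": [d.onset_s for d in detections],
            "end_time_s": [d.onset_s + d.duration_s for d in detections],
            "low_freq_hz": [d.band[0] for d in detections],
            "high_freq_hz": [d.band[1] for d in detections],
            "score_db": [d.peak_snr for d in detections],
        }
    )
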