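"""Shared fixtures: small, seeded synthetic scenes and spectrograms."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest

from dawnchorus import BandSpectrogram, SceneConfig, SpeciesTemplate


@pytest.fixture
def whistler() -> SpeciesTemplate:
    return SpeciesTemplate(
        "whistler", "tonal_whistle", (2500.0, 5850.0), 0.8, 1, 25.0
    )


@pytest.fixture
def tiny_scene(whistler) -> SceneConfig:
    """A desk-scale scene: 10-day season, 60-s windows, one species."""
    return SceneConfig(
        season_start=date(2012, 4, 1),
        season_end=date(2012, 4, 10),
        arrival_day=date(2012, 4, 6),
        species=(whistler,),
        window_s=60.0,
        seed=11,
    )


def flat_spectrogram(
    n_seconds: int,
    level_db: float = 30.0,
    band_centers=(500.0, 1000.0, 2000.0),
    start: datetime | None = None,
) -> BandSpectrogram:
    """Constant-level spectrogram helper used across test modules."""
    centers = np.asarray(band_centers, dtype=float)
    return BandSpectrogram(
        values=np.full((n_seconds, centers.size), level_db),
        band_centers=centers,
        start_time=start or datetime(2012, 4, 16, 5, 0, tzinfo=timezone(timedelta(hours=-8))),
    )
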