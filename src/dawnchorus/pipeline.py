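"""End-to-end orchestration: scene -> SPL -> screen -> ACI -> change point
-> detection/diversity/association, as one reproducible seeded run.

A run is driven by a YAML config (see :func:`validate_config`) and writes
CSV outputs plus a machine-readable manifest into a run directory.  One
global seed is split deterministically per stage, so a rerun with the same
config reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field
from datetime import date as date_type

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aci import aci_total, daily_series
from .changepoint import bcp_fit, detect_transition
from .community import associate, diversity
from .detector import DetectorConfig, correct_counts, detect, detections_to_frame, evaluate
from .scenes import (
    SceneConfig,
    concat_call_logs,
    SpeciesTemplate,
    WeatherEvent,
    season_weather,
    synthesize_day,
    synthesize_day_band_spl,
)
from .screening import (
    apply_exclusion_rule,
    flag_obscured_seconds,
    restrict_bands,
    screen_reports_to_csv,
)

logger = logging.getLogger(__name__)

_DEFAULT_STAGES = ("synth", "screen", "aci", "changepoint", "detect", "diversity", "associate")


@dataclass
class RunConfig:
    """Validated, normalized parameters of one pipeline run."""

    scene: SceneConfig
    site_name: str = "SITE"
    mode: str = "band"  # "band" (SPL substrate) or "audio" (waveform)
    screen_low_band_ceiling: float = 800.0
    screen_threshold_db: float = 10.0
    aci_min_freq: float = 1250.0
    aci_max_freq: float = 6300.0
    cp_iterations: int = 10000
    cp_burn_in: int = 5000
    cp_threshold: float = 0.5
    cp_p0: float = 0.2
    cp_w0: float = 0.2
    detectors: list[DetectorConfig] = field(default_factory=list)
    match_tolerance_s: float = 1.0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: s != "detect" for s in _DEFAULT_STAGES}
    )
    seed: int = 0


def _parse_date(value) -> date_type:
    if isinstance(value, date_type):
        return value
    return date_type.fromisoformat(str(value))


def validate_config(source) -> RunConfig:
    """Parse and range-check a YAML config (text, path, or dict).

    All problems are collected and reported at once in the raised
    ``ValueError``; a valid file yields the normalized :class:`RunConfig`.
    """
    if isinstance(source, dict):
        raw = source
    else:
        text = (
            pathlib.Path(source).read_text()
            if isinstance(source, (str, pathlib.Path)) and "\n" not in str(source)
            and pathlib.Path(source).exists()
            else str(source)
        )
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")

    errors: list[str] = []

    def need(section: dict, key: str, default=None):
        if key in section:
            return section[key]
        if default is None:
            errors.append(f"missing required key: {key}")
        return default

    site = raw.get("site", {})
    season = raw.get("season", {})
    scene_raw = raw.get("scene", {})
    stages = {s: s != "detect" for s in _DEFAULT_STAGES}
    stages.update(raw.get("stages", {}))
    mode = scene_raw.get("mode", "band")
    if mode not in ("band", "audio"):
        errors.append(f"scene.mode must be 'band' or 'audio', got {mode!r}")
    if stages.get("detect") and mode != "audio":
        errors.append("detect stage requires scene.mode: audio")

    lat = need(site, "lat")
    lon = need(site, "lon")
    utc_offset = site.get("utc_offset", 0.0)
    if lat is not None and not -66.5 < float(lat) < 66.5:
        errors.append(f"site.lat must be within +/-66.5 deg, got {lat}")

    cp = raw.get("changepoint", {})
    iterations = int(cp.get("iterations", 10000))
    burn_in = int(cp.get("burn_in", 5000))
    if burn_in >= iterations:
        errors.append(f"changepoint.burn_in ({burn_in}) must be < iterations ({iterations})")
    threshold = float(cp.get("threshold", 0.5))
    if not 0.0 < threshold < 1.0:
        errors.append(f"changepoint.threshold must be in (0,1), got {threshold}")

    species = []
    for i, sp in enumerate(raw.get("species", [])):
        try:
            species.append(
                SpeciesTemplate(
                    name=sp["name"],
                    song_type=sp["song_type"],
                    freq_range=(float(sp["freq_low"]), float(sp["freq_high"])),
                    syllable_duration=float(sp.get("syllable_duration", 0.3)),
                    syllables_per_song=int(sp.get("syllables_per_song", 1)),
                    source_level=float(sp.get("source_level", 20.0)),
                )
            )
        except (KeyError, ValueError) as exc:
            errors.append(f"species[{i}]: {exc}")

    weather_events = []
    for i, wx in enumerate(raw.get("weather_events", [])):
        try:
            weather_events.append(
                WeatherEvent(
                    date=_parse_date(wx["date"]),
                    start_s=float(wx["start_s"]),
                    duration_s=float(wx["duration_s"]),
                    band_extent=(
                        float(wx.get("band_low", 12.5)),
                        float(wx.get("band_high", 1000.0)),
                    ),
                    level=float(wx.get("level", 20.0)),
                )
            )
        except (KeyError, ValueError) as exc:
            errors.append(f"weather_events[{i}]: {exc}")

    detectors = []
    for i, dc in enumerate(raw.get("detectors", [])):
        try:
            detectors.append(
                DetectorConfig(
                    species=dc["species"],
                    freq_range=(float(dc["freq_low"]), float(dc["freq_high"])),
                    min_duration=float(dc.get("min_duration", 0.15)),
                    max_duration=float(dc.get("max_duration", 3.0)),
                    snr_threshold=float(dc.get("snr_threshold", 10.0)),
                    min_gap=float(dc.get("min_gap", 0.15)),
                )
            )
        except (KeyError, ValueError) as exc:
            errors.append(f"detectors[{i}]: {exc}")

    scene = None
    if not errors:
        try:
            scene = SceneConfig(
                lat=float(lat),
                lon=float(lon),
                utc_offset=float(utc_offset),
                season_start=_parse_date(need(season, "start", "2012-03-17")),
                season_end=_parse_date(need(season, "end", "2012-05-15")),
                arrival_day=_parse_date(need(season, "arrival_day", "2012-04-16")),
                pre_arrival_rate=float(scene_raw.get("pre_arrival_rate", 2.0)),
                post_arrival_rate=float(scene_raw.get("post_arrival_rate", 40.0)),
                species=tuple(species) or SceneConfig.__dataclass_fields__["species"].default,
                noise_floor_db=float(scene_raw.get("noise_floor_db", -50.0)),
                band_ambient_db=float(scene_raw.get("band_ambient_db", 30.0)),
                noise_jitter_db=float(scene_raw.get("noise_jitter_db", 0.3)),
                weather_events=tuple(weather_events),
                sample_rate=int(scene_raw.get("sample_rate", 22050)),
                window_s=float(scene_raw.get("window_s", 10800.0)),
                seed=int(raw.get("seed", 0)),
            )
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))

    screen = raw.get("screen", {})
    aci_cfg = raw.get("aci", {})
    return RunConfig(
        scene=scene,
        site_name=str(site.get("name", "SITE")),
        mode=mode,
        screen_low_band_ceiling=float(screen.get("low_band_ceiling", 800.0)),
        screen_threshold_db=float(screen.get("threshold_db", 10.0)),
        aci_min_freq=float(aci_cfg.get("min_freq", 1250.0)),
        aci_max_freq=float(aci_cfg.get("max_freq", 6300.0)),
        cp_iterations=iterations,
        cp_burn_in=burn_in,
        cp_threshold=threshold,
        cp_p0=float(cp.get("p0", 0.2)),
        cp_w0=float(cp.get("w0", 0.2)),
        detectors=detectors,
        stages=stages,
        seed=int(raw.get("seed", 0)),
    )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages; returns a summary dict (also written as
    ``manifest.json``).  Any stage failure propagates with its stage named;
    outputs written so far are retained."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = config.scene
    stages = config.stages
    summary: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {"dawnchorus": __version__, "numpy": np.__version__},
        "outputs": {},
    }

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        summary["outputs"][name.rsplit(".", 1)[0]] = str(path)

    try:
        truths, reports, results = [], [], []
        if stages.get("synth", True):
            weather = season_weather(scene)
            _write("weather.csv", weather)
            for day in scene.dates:
                if config.mode == "audio":
                    from scipy.io import wavfile

                    audio, sr, truth = synthesize_day(scene, day)
                    wavfile.write(
                        out / f"{config.site_name}_{day:%Y%m%d}.wav",
                        sr,
                        (np.clip(audio, -1, 1) * 32767).astype(np.int16),
                    )
                    from .bandspl import audio_to_band_spl
                    import warnings as _w

                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        spec = audio_to_band_spl(audio, sr, calibration_offset=94.0)
                else:
                    spec, truth = synthesize_day_band_spl(scene, day)
                truths.append(truth)
                if stages.get("screen", True):
                    mask = flag_obscured_seconds(
                        spec,
                        low_band_ceiling=config.screen_low_band_ceiling,
                        threshold_db_above_baseline=config.screen_threshold_db,
                    )
                    report = apply_exclusion_rule(day, mask)
                    reports.append(report)
                    if report.excluded:
                        continue
                if stages.get("aci", True):
                    idx = restrict_bands(spec, config.aci_min_freq, config.aci_max_freq)
                    results.append(aci_total(idx, date=day))
            truth = concat_call_logs(truths)
            _write("call_log.csv", truth)
            if reports:
                screen_reports_to_csv(reports, out / "screen_report.csv")
                summary["outputs"]["screen_report"] = str(out / "screen_report.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'synth/screen/aci' failed: {exc}") from exc

    series = None
    if results:
        weather_idx = season_weather(scene).set_index("date").drop(columns="obscured_s")
        series = daily_series(results, reports or None, covariates=weather_idx)
        per_band = pd.DataFrame(
            [dict({"date": r.date, "aci_tot": r.aci_tot}, **{f"aci_{c:g}": v for c, v in r.per_band.items()}) for r in results]
        )
        _write("daily_aci.csv", per_band)

    if stages.get("changepoint", True):
        if series is None:
            raise RuntimeError("stage 'changepoint' failed: no ACI series (enable aci stage)")
        try:
            retained = series.dropna(subset=["aci_tot"])
            result = bcp_fit(
                retained["aci_tot"].to_numpy(),
                dates=list(retained["date"]),
                iterations=config.cp_iterations,
                burn_in=config.cp_burn_in,
                seed=config.seed,
                p0=config.cp_p0,
                w0=config.cp_w0,
            )
            _write("changepoint.csv", result.to_frame(retained["aci_tot"].to_numpy()))
            transition = detect_transition(
                result, retained["aci_tot"].to_numpy(), threshold=config.cp_threshold
            )
            if transition is None:
                line = "no transition: no change probability peak above threshold"
                summary["transition"] = None
            else:
                line = (
                    f"transition {transition.date} prob={transition.prob:.2f} "
                    f"fold_change={transition.fold_change:.2f} "
                    f"(baseline {transition.baseline_days} days)"
                )
                summary["transition"] = {
                    "date": str(transition.date),
                    "prob": transition.prob,
                    "fold_change": transition.fold_change,
                }
            (out / "transition.txt").write_text(line + "\n")
            logger.info(line)
        except Exception as exc:
            raise RuntimeError(f"stage 'changepoint' failed: {exc}") from exc

    if stages.get("detect") and config.mode == "audio":
        try:
            all_dets = []
            for day in scene.dates:
                audio, sr, _ = synthesize_day(scene, day)
                for dc in config.detectors:
                    all_dets.extend(detect(audio, sr, dc, date=day))
            _write("detections.csv", detections_to_frame(all_dets))
            truth_all = concat_call_logs(truths)
            ev = evaluate(all_dets, truth_all, config.match_tolerance_s)
            daily = truth_all.groupby("date").size().to_dict()
            corrected = correct_counts(daily, ev.fn_rate)
            summary["detector"] = {
                "tp": ev.true_positives,
                "fp": ev.false_positives,
                "fn": ev.false_negatives,
                "fn_rate": ev.fn_rate,
            }
            _write(
                "corrected_counts.csv",
                pd.DataFrame(
                    {"date": list(corrected), "corrected_count": list(corrected.values())}
                ),
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'detect' failed: {exc}") from exc

    if stages.get("diversity", True) and truths:
        truth_all = concat_call_logs(truths)
        rows = []
        for day, grp in truth_all.groupby("date"):
            d = diversity(grp.groupby("species").size())
            rows.append(
                {"date": day, "richness": d.richness, "shannon": d.shannon, "simpson": d.simpson}
            )
        _write("diversity.csv", pd.DataFrame(rows))

    if stages.get("associate", True) and series is not None:
        try:
            truth_all = concat_call_logs(truths)
            counts = truth_all.groupby("date").size()
            merged = series.dropna(subset=["aci_tot"]).copy()
            merged["calls"] = merged["date"].map(counts).fillna(0)
            rows = []
            for pred in ("calls", "temperature", "wind"):
                a = associate(merged["aci_tot"], merged[pred])
                rows.append(
                    {
                        "predictor": pred,
                        "slope": a.slope,
                        "slope_se": a.slope_se,
                        "r_squared": a.r_squared,
                        "n": a.n,
                    }
                )
            _write("association.csv", pd.DataFrame(rows))
        except Exception as exc:
            raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
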