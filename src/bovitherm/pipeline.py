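"""Staged pipeline: simulate -> preprocess -> episodes -> features -> thi ->
alerts -> report.

Each stage reads the CSV artifacts of the previous stages from a working
directory and writes its own, so stages can be rerun individually (the CLI
exposes one subcommand per stage). ``run_pipeline`` runs them all and writes
a manifest (config hash, seed, per-table row counts); with a fixed config
the manifest — and every table — is byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alerting, episodes as ep_mod, preprocessing as pp, reporting
from . import thermal_features as tf
from .environment import period_max_thi
from .synthetic_herd import HerdConfig, SignalParams, simulate_herd

ISO = "%Y-%m-%dT%H:%M:%S"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one place.

    Cuts and thresholds default to the study constants: activity alert index
    35, median splits at 80 index / 12 h, THI cutoff 72, 25% missingness
    tolerance, 120 h baseline window with a 90-point minimum (75%), and the
    0.5-3 STD alert ladder.
    """

    herd: HerdConfig = field(default_factory=HerdConfig)
    thresholds: tuple[float, ...] = alerting.DEFAULT_THRESHOLDS
    activity_threshold: float = 35.0
    gap_blocks: int = 3
    peak_cut: float = 80.0
    duration_cut: float = 12.0
    missing_max: float = 0.25
    window_h: int = 120
    min_window_points: int = 90
    sd_floor: float = 0.05
    drop_threshold: float = 0.8
    recovery_limit: float = 3.0
    hour_matched_baseline: bool = False

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        for name in ("activity_threshold", "peak_cut", "duration_cut",
                     "missing_max", "window_h", "sd_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["herd"]["duration_choices"] = list(self.herd.duration_choices)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        herd_raw = raw.pop("herd", {})
        sig_raw = herd_raw.pop("signal", {})
        herd = HerdConfig(signal=SignalParams(**sig_raw), **{
            k: tuple(v) if k == "duration_choices" else v
            for k, v in herd_raw.items()})
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(herd=herd, **raw)


def _read(d: Path, name: str, stage: str, dates=()) -> pd.DataFrame:
    path = d / name
    if not path.exists():
        raise StageError(stage, f"missing input table {name}")
    return pd.read_csv(path, parse_dates=list(dates))


def stage_simulate(config: PipelineConfig, d: Path) -> None:
    simulate_herd(config.herd, out_dir=d)


def stage_preprocess(config: PipelineConfig, d: Path) -> None:
    rrt = _read(d, "rrt.csv", "preprocess", dates=["timestamp"])
    clean_parts, base_parts, z_parts = [], [], []
    for _, g in rrt.groupby("cow_id", sort=True):
        clean, base, z = pp.preprocess_cow(
            g[["cow_id", "timestamp", "temp_c"]],
            drop_threshold=config.drop_threshold,
            recovery_limit=config.recovery_limit, window_h=config.window_h,
            min_window_points=config.min_window_points,
            sd_floor=config.sd_floor,
            hour_matched=config.hour_matched_baseline)
        clean_parts.append(clean)
        base_parts.append(base)
        z_parts.append(z)
    pd.concat(clean_parts, ignore_index=True).to_csv(
        d / "rrt_clean.csv", index=False, date_format=ISO)
    base = pd.concat(base_parts, ignore_index=True)
    base.to_csv(d / "baseline.csv", index=False, date_format=ISO,
                float_format="%.6f")
    pd.concat(z_parts, ignore_index=True).to_csv(
        d / "zscores.csv", index=False, date_format=ISO, float_format="%.6f")


def stage_episodes(config: PipelineConfig, d: Path) -> None:
    activity = _read(d, "activity.csv", "episodes", dates=["block_start"])
    exams = _read(d, "exams.csv", "episodes", dates=["exam_time"])
    eps, ov = ep_mod.process_episodes(
        activity, exams, alert_threshold=config.activity_threshold,
        gap_blocks=config.gap_blocks, peak_cut=config.peak_cut,
        duration_cut=config.duration_cut)
    eps.to_csv(d / "episodes.csv", index=False, date_format=ISO)
    ov.to_csv(d / "ovulations.csv", index=False, date_format=ISO)


def _load_clean_base(config: PipelineConfig, d: Path, stage: str):
    clean = _read(d, "rrt_clean.csv", stage, dates=["timestamp"])
    base = _read(d, "baseline.csv", stage, dates=["timestamp"])
    clean_by = {c: g.reset_index(drop=True) for c, g in clean.groupby("cow_id")}
    base_by = {c: g.reset_index(drop=True) for c, g in base.groupby("cow_id")}
    return clean_by, base_by


def stage_features(config: PipelineConfig, d: Path) -> None:
    eps = _read(d, "episodes.csv", "features", dates=["onset", "end"])
    ov = _read(d, "ovulations.csv", "features",
               dates=["ovulation_time", "bracket_start", "bracket_end"])
    clean_by, base_by = _load_clean_base(config, d, "features")
    feats = tf.compute_features(eps, ov, clean_by, base_by,
                                missing_max=config.missing_max)
    feats.to_csv(d / "features.csv", index=False, float_format="%.6f")


def stage_thi(config: PipelineConfig, d: Path) -> None:
    weather = _read(d, "weather.csv", "thi", dates=["timestamp"])
    period_max_thi(weather).to_csv(d / "thi_periods.csv", index=False,
                                   float_format="%.4f")


def stage_alerts(config: PipelineConfig, d: Path) -> None:
    eps = _read(d, "episodes.csv", "alerts", dates=["onset", "end"])
    ov = _read(d, "ovulations.csv", "alerts",
               dates=["ovulation_time", "bracket_start", "bracket_end"])
    feats = _read(d, "features.csv", "alerts")
    z = _read(d, "zscores.csv", "alerts", dates=["timestamp"])
    z_by = {c: g.reset_index(drop=True) for c, g in z.groupby("cow_id")}
    alerts, intervals = alerting.alert_events(z_by, eps, ov, feats,
                                              thresholds=config.thresholds)
    alerts.to_csv(d / "alerts.csv", index=False, date_format=ISO,
                  float_format="%.4f")
    intervals.to_csv(d / "intervals.csv", index=False, float_format="%.4f")
    n_eligible = intervals["episode_id"].nunique()
    if n_eligible:
        summary = alerting.summarize_alerts(intervals, n_eligible)
        summary.to_csv(d / "alert_summary.csv", index=False, float_format="%.4f")


def stage_report(config: PipelineConfig, d: Path) -> None:
    eps = _read(d, "episodes.csv", "report", dates=["onset", "end"])
    ov = _read(d, "ovulations.csv", "report",
               dates=["ovulation_time", "bracket_start", "bracket_end"])
    feats = _read(d, "features.csv", "report")
    periods = _read(d, "thi_periods.csv", "report")
    periods["date"] = pd.to_datetime(periods["date"]).dt.date
    ledger = reporting.account_events(eps, ov, feats)
    ledger["reasons"] = {str(k): v for k, v in ledger["reasons"].items()}
    peak_med, dur_med = reporting.compute_median_cuts(eps)
    ledger["empirical_peak_median"] = peak_med
    ledger["empirical_duration_median_h"] = dur_med
    (d / "ledger.json").write_text(json.dumps(ledger, indent=2, sort_keys=True))
    labelled = reporting.attach_thi_labels(feats, eps, ov, periods)
    gm = pd.concat([reporting.group_means(labelled, eps, g)
                    for g in ("peak_category", "duration_category")],
                   ignore_index=True)
    gm.to_csv(d / "group_means.csv", index=False, float_format="%.6f")


STAGES = (("simulate", stage_simulate), ("preprocess", stage_preprocess),
          ("episodes", stage_episodes), ("features", stage_features),
          ("thi", stage_thi), ("alerts", stage_alerts),
          ("report", stage_report))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage into ``out_dir`` and write manifest.json.

    Returns the manifest. Any stage failure raises :class:`StageError`
    naming the stage.
    """
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        try:
            fn(config, d)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage-named rewrap
            raise StageError(name, str(exc)) from exc
    counts = {}
    for f in sorted(d.glob("*.csv")):
        with open(f) as fh:
            counts[f.name] = sum(1 for _ in fh) - 1
    manifest = {"config_hash": config.config_hash(), "seed": config.herd.seed,
                "row_counts": counts}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                sort_keys=True))
    return manifest
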