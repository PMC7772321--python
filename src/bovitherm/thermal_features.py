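"""Baseline-relative thermal features: positive AUC, PTC, NTC.

For each event two windows are scored: the estrus window (AAM onset through
the end of the above-threshold span) and the ovulation window (the exam that
confirmed ovulation back to the preceding exam). Within a window the
relative series y_t = temp_t - baseline_mean_t is formed at the valid hourly
readings and three features are computed:

* positive AUC (degC*h): trapezoidal integral of max(y, 0) over the observed
  time stamps (hours, to the nearest second). Clamping happens before
  integration, so the quantity equals the area under the clamped linear
  interpolant exactly.
* PTC (degC): max(y), the positive amplitude — left unclamped, so a window
  wholly below baseline yields a negative PTC.
* NTC (degC): min(y), the negative amplitude.

Events missing more than 25% of the expected hourly points in either window
are flagged excluded and drop out of downstream summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)
MISSING_MAX = 0.25


def frozen_baseline(baseline: pd.DataFrame, at_time: pd.Timestamp) -> pd.DataFrame:
    """Baseline frame with mean/SD held at their values at ``at_time``.

    The trailing baseline lets the early hours of a long episode leak into
    the window used later in that same episode; freezing at the window start
    gives a leakage-free reference for closed-form checks and sensitivity
    analyses. Raises if the baseline is undefined at ``at_time``.
    """
    row = baseline[baseline["timestamp"] == at_time]
    if row.empty or np.isnan(row["baseline_mean"].iloc[0]):
        raise ValueError(f"baseline undefined at {at_time}")
    out = baseline.copy()
    out["baseline_mean"] = row["baseline_mean"].iloc[0]
    out["baseline_sd"] = row["baseline_sd"].iloc[0]
    return out


def window_relative(series: pd.DataFrame, baseline: pd.DataFrame,
                    t_start: pd.Timestamp, t_end: pd.Timestamp
                    ) -> tuple[pd.DataFrame, float]:
    """Baseline-relative series over [t_start, t_end] plus missing fraction.

    Expected points are the ``floor(t_end - t_start) + 1`` hourly slots of the
    window (endpoints inclusive); a point is present when the reading is
    valid and the baseline defined there. Returns ``(rel, missing_fraction)``
    with ``rel`` holding ``timestamp, y``.
    """
    if t_end < t_start:
        raise ValueError("empty window")
    n_expected = int(np.floor((t_end - t_start) / HOUR)) + 1
    if n_expected <= 0:
        raise ValueError("window contains no expected points")
    m = series.merge(baseline[["timestamp", "baseline_mean"]], on="timestamp",
                     how="left")
    m = m[(m["timestamp"] >= t_start) & (m["timestamp"] <= t_end)]
    ok = m["valid"].to_numpy(dtype=bool) & \
        ~np.isnan(m["baseline_mean"].to_numpy(dtype=float))
    m = m[ok]
    rel = pd.DataFrame({"timestamp": m["timestamp"],
                        "y": m["temp_c"].to_numpy(dtype=float)
                        - m["baseline_mean"].to_numpy(dtype=float)})
    missing = 1.0 - len(rel) / n_expected
    return rel.reset_index(drop=True), missing


def _x_hours(ts: pd.Series) -> np.ndarray:
    """Time stamps as hours from the first point, to the nearest second."""
    sec = np.round((ts - ts.iloc[0]).dt.total_seconds().to_numpy())
    return sec / 3600.0


def positive_auc(rel: pd.DataFrame) -> float:
    """Trapezoidal integral of max(y, 0); NaN with fewer than 2 points."""
    if len(rel) < 2:
        return float("nan")
    y = np.maximum(rel["y"].to_numpy(dtype=float), 0.0)
    return float(np.trapezoid(y, _x_hours(rel["timestamp"])))


def ptc(rel: pd.DataFrame) -> float:
    """Maximum of y (unclamped); NaN on an empty window."""
    return float(rel["y"].max()) if len(rel) else float("nan")


def ntc(rel: pd.DataFrame) -> float:
    """Minimum of y (unclamped); NaN on an empty window."""
    return float(rel["y"].min()) if len(rel) else float("nan")


def _one_window(series, baseline, t0, t1, freeze):
    base = frozen_baseline(baseline, t0) if freeze else baseline
    rel, miss = window_relative(series, base, t0, t1)
    return {"auc": positive_auc(rel), "ptc": ptc(rel), "ntc": ntc(rel),
            "n_points": len(rel), "missing_fraction": miss}


def event_features(episode: pd.Series, ovulation: pd.Series,
                   series: pd.DataFrame, baseline: pd.DataFrame,
                   block_hours: int = 2, missing_max: float = MISSING_MAX,
                   freeze_baseline: bool = False) -> list[dict]:
    """Feature rows for the estrus and ovulation windows of one event.

    The estrus window runs from episode onset through the end of the last
    above-threshold block (onset + duration); the ovulation window spans the
    bracketing exam pair. The event is excluded when either window misses
    more than ``missing_max`` of its hourly points. ``freeze_baseline`` holds
    the baseline of both windows at its value at episode onset — the last
    point guaranteed free of the episode's own thermal signature (leakage
    control; the default is the hourly rolling baseline).
    """
    if freeze_baseline:
        baseline = frozen_baseline(baseline, episode["onset"])
    est = _one_window(series, baseline, episode["onset"],
                      episode["onset"] + pd.Timedelta(hours=float(episode["duration_h"])),
                      False)
    ovu = _one_window(series, baseline, ovulation["bracket_start"],
                      ovulation["bracket_end"], False)
    excluded = (est["missing_fraction"] > missing_max
                or ovu["missing_fraction"] > missing_max)
    rows = []
    for kind, feats in (("estrus", est), ("ovulation", ovu)):
        rows.append({"cow_id": episode["cow_id"],
                     "episode_id": int(episode["episode_id"]),
                     "window_kind": kind, **feats, "excluded": excluded})
    return rows


def compute_features(episodes: pd.DataFrame, ovulations: pd.DataFrame,
                     clean_by_cow: dict, baseline_by_cow: dict,
                     missing_max: float = MISSING_MAX,
                     freeze_baseline: bool = False) -> pd.DataFrame:
    """Herd-level feature table over true-estrus, ovulated events.

    Events whose baseline is undefined over a window are flagged with
    ``excluded=True`` and reason ``baseline_undefined`` rather than dropped.
    """
    ov = ovulations.set_index("episode_id")
    rows = []
    for _, ep in episodes.iterrows():
        eid = int(ep["episode_id"])
        if eid not in ov.index:
            continue
        rec = ov.loc[eid]
        if not ep["is_true_estrus"] or rec["status"] != "ovulated":
            continue
        series = clean_by_cow[ep["cow_id"]]
        baseline = baseline_by_cow[ep["cow_id"]]
        try:
            rows.extend(event_features(ep, rec, series, baseline,
                                       missing_max=missing_max,
                                       freeze_baseline=freeze_baseline))
        except ValueError:
            for kind in ("estrus", "ovulation"):
                rows.append({"cow_id": ep["cow_id"], "episode_id": eid,
                             "window_kind": kind, "auc": np.nan, "ptc": np.nan,
                             "ntc": np.nan, "n_points": 0,
                             "missing_fraction": 1.0, "excluded": True})
    return pd.DataFrame(rows, columns=["cow_id", "episode_id", "window_kind",
                                       "auc", "ptc", "ntc", "n_points",
                                       "missing_fraction", "excluded"])
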