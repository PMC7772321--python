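"""STD-threshold temperature alerting and detection-interval statistics.

An alert fires when two consecutive hourly standardized readings both exceed
a threshold (0.5 to 3 STD by default): positive excursions are estrus
alerts, negative ones ovulation alerts. Alerts are searched from 12 h before
the AAM activity alert until 12 h after ovulation; one alert is issued per
maximal qualifying run, timed at the run's first reading, and only the first
alert per event x threshold x direction enters the interval statistics.

Interval sign convention: alert minus anchor. AAM-anchored intervals are
therefore bounded below by -12 h (the search-window start) and
ovulation-anchored intervals are negative when the alert precedes ovulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)
DEFAULT_THRESHOLDS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
SEARCH_BEFORE_H = 12.0
SEARCH_AFTER_H = 12.0
INTERVAL_COLS = ("aam_to_estrus_alert", "estrus_alert_to_ovulation",
                 "aam_to_ovulation_alert", "ovulation_alert_to_ovulation")


def _run_starts(cond: np.ndarray, contiguous: np.ndarray) -> list[int]:
    """Start indices of maximal runs of True of length >= 2.

    ``contiguous[i]`` says reading i+1 follows reading i by exactly one hour;
    a gap breaks the run.
    """
    starts = []
    i, n = 0, len(cond)
    while i < n:
        if not cond[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and cond[j + 1] and contiguous[j]:
            j += 1
        if j > i:
            starts.append(i)
        i = j + 1
    return starts


def detect_temp_alerts(z: pd.DataFrame, aam_alert_time: pd.Timestamp,
                       ovulation_time: pd.Timestamp | None,
                       thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """All two-in-a-row threshold alerts for one event.

    Returns ``direction, threshold, alert_time, z1, z2`` rows; empty when the
    search window is undefined (no ovulation time). Undefined z values break
    runs. Thresholds are inclusive (>= thr, <= -thr).
    """
    cols = ["direction", "threshold", "alert_time", "z1", "z2"]
    if ovulation_time is None or pd.isna(ovulation_time):
        return pd.DataFrame(columns=cols)
    lo = aam_alert_time - pd.Timedelta(hours=SEARCH_BEFORE_H)
    hi = ovulation_time + pd.Timedelta(hours=SEARCH_AFTER_H)
    w = z[(z["timestamp"] >= lo) & (z["timestamp"] <= hi)].reset_index(drop=True)
    if len(w) < 2:
        return pd.DataFrame(columns=cols)
    zs = w["z"].to_numpy(dtype=float)
    ts = w["timestamp"]
    contiguous = (ts.diff().iloc[1:] == HOUR).to_numpy()
    rows = []
    for thr in thresholds:
        for direction, cond in (("estrus", zs >= thr), ("ovulation", zs <= -thr)):
            cond = cond & ~np.isnan(zs)
            for i in _run_starts(cond, contiguous):
                rows.append({"direction": direction, "threshold": thr,
                             "alert_time": ts.iloc[i], "z1": zs[i],
                             "z2": zs[i + 1]})
    return pd.DataFrame(rows, columns=cols)


def first_alerts(alerts: pd.DataFrame) -> pd.DataFrame:
    """Earliest alert per threshold x direction (the first-alert rule)."""
    if alerts.empty:
        return alerts.copy()
    idx = alerts.groupby(["threshold", "direction"])["alert_time"].idxmin()
    return alerts.loc[idx].reset_index(drop=True)


def compute_intervals(firsts: pd.DataFrame, aam_alert_time: pd.Timestamp,
                      ovulation_time: pd.Timestamp,
                      thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Detection intervals (h) per threshold for one event.

    Sign convention: alert minus anchor (negative = alert precedes the
    anchor). Absent alerts leave the corresponding intervals NaN.
    """
    by = {(r["threshold"], r["direction"]): r["alert_time"]
          for _, r in firsts.iterrows()}
    rows = []
    for thr in thresholds:
        row = {"threshold": thr}
        for direction, aam_col, ov_col in (
                ("estrus", "aam_to_estrus_alert", "estrus_alert_to_ovulation"),
                ("ovulation", "aam_to_ovulation_alert",
                 "ovulation_alert_to_ovulation")):
            t = by.get((thr, direction))
            row[aam_col] = (t - aam_alert_time) / HOUR if t is not None else np.nan
            row[ov_col] = (t - ovulation_time) / HOUR if t is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_alerts(intervals: pd.DataFrame, n_events: int) -> pd.DataFrame:
    """Detection-interval summary per threshold x direction.

    ``intervals`` stacks the per-event interval rows; ``n_events`` is the
    number of eligible (true-estrus, ovulated, non-excluded) events. For each
    threshold and direction: % alerted and mean / sample SD / min / max of
    both the AAM-anchored and the ovulation-anchored interval over alerted
    events.
    """
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    rows = []
    for thr, g in intervals.groupby("threshold", sort=True):
        for direction, aam_col, ov_col in (
                ("estrus", "aam_to_estrus_alert", "estrus_alert_to_ovulation"),
                ("ovulation", "aam_to_ovulation_alert",
                 "ovulation_alert_to_ovulation")):
            vals = g[aam_col].dropna()
            ovals = g[ov_col].dropna()
            n_alerted = len(vals)
            row = {"threshold": thr, "direction": direction,
                   "n_alerted": n_alerted, "n_eligible": n_events,
                   "pct_alerted": 100.0 * n_alerted / n_events}
            for prefix, v in (("aam_to_alert", vals), ("alert_to_ovulation", ovals)):
                row[f"{prefix}_mean"] = v.mean() if len(v) else np.nan
                row[f"{prefix}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
                row[f"{prefix}_min"] = v.min() if len(v) else np.nan
                row[f"{prefix}_max"] = v.max() if len(v) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def alert_events(z_by_cow: dict, episodes: pd.DataFrame,
                 ovulations: pd.DataFrame, features: pd.DataFrame | None = None,
                 thresholds=DEFAULT_THRESHOLDS
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alerts and per-event intervals for every eligible herd event.

    Eligible events are true estrus with a timed ovulation; when a feature
    table is supplied, events it flags as excluded (missing data) are dropped
    as well. Returns ``(alerts, intervals)`` with event identifiers attached.
    """
    excluded_ids: set[int] = set()
    if features is not None and len(features):
        excluded_ids = set(features.loc[features["excluded"], "episode_id"]
                           .astype(int))
    ov = ovulations.set_index("episode_id")
    alert_rows, int_rows = [], []
    for _, ep in episodes.iterrows():
        eid = int(ep["episode_id"])
        if not ep["is_true_estrus"] or eid in excluded_ids or eid not in ov.index:
            continue
        rec = ov.loc[eid]
        if rec["status"] != "ovulated":
            continue
        z = z_by_cow[ep["cow_id"]]
        al = detect_temp_alerts(z, ep["onset"], rec["ovulation_time"], thresholds)
        al.insert(0, "episode_id", eid)
        al.insert(0, "cow_id", ep["cow_id"])
        alert_rows.append(al)
        iv = compute_intervals(first_alerts(al), ep["onset"],
                               rec["ovulation_time"], thresholds)
        iv.insert(0, "episode_id", eid)
        iv.insert(0, "cow_id", ep["cow_id"])
        int_rows.append(iv)
    alerts = (pd.concat(alert_rows, ignore_index=True) if alert_rows
              else pd.DataFrame(columns=["cow_id", "episode_id", "direction",
                                         "threshold", "alert_time", "z1", "z2"]))
    intervals = (pd.concat(int_rows, ignore_index=True) if int_rows
                 else pd.DataFrame(columns=["cow_id", "episode_id", "threshold",
                                            *INTERVAL_COLS]))
    return alerts, intervals
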