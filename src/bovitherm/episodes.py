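"""Estrus episodes from AAM activity, and ovulation timing from ultrasound.

An estrus episode is a maximal run of 2 h activity blocks at or above the
alert index (35); runs separated by fewer than 3 quiet blocks (6 h) are
merged so single-block dropouts do not split one estrus. Peak activity is
the run maximum, duration the above-threshold span (last block start minus
onset plus one block length).

An episode is a true estrus when the exam at the alert shows at least one
dominant pre-ovulatory follicle > 15 mm with no large corpus luteum
(> 20 mm). Ovulation is timed as the midpoint of the first consecutive exam
pair across which the tracked dominant follicle disappears; events whose
follicle persists through all (at most six) exams are resolved by the day-7
scan: a new CL means a late ovulation, its absence a failed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)
ALERT_THRESHOLD = 35
PEAK_CUT = 80
DURATION_CUT = 12.0
FOLLICLE_MIN_MM = 15.0
CL_MAX_MM = 20.0
MATCH_TOL = 0.25  # relative diameter tolerance when tracking the dominant follicle


@dataclass
class OvulationRecord:
    cow_id: str
    episode_id: int
    status: str                       # ovulated | late | failed | undetermined
    ovulation_time: pd.Timestamp | None = None
    bracket_start: pd.Timestamp | None = None
    bracket_end: pd.Timestamp | None = None
    reason: str = ""


def parse_diams(text) -> list[float]:
    """Parse a ';'-separated diameter list; empty/NaN means none recorded."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    return [float(x) for x in text.split(";")]


def detect_episodes(activity: pd.DataFrame, alert_threshold: float = ALERT_THRESHOLD,
                    gap_blocks: int = 3, block_hours: int = 2) -> pd.DataFrame:
    """Episodes per cow from the 2 h activity blocks.

    Returns one row per episode with ``cow_id, episode_id, onset, end,
    peak_index, duration_h`` where ``end`` is the start of the last
    above-threshold block and ``duration_h = end - onset + block_hours``.
    """
    rows = []
    eid = 0
    for cow_id, g in activity.groupby("cow_id", sort=True):
        g = g.sort_values("block_start").reset_index(drop=True)
        above = g["index"].to_numpy() >= alert_threshold
        idx = np.flatnonzero(above)
        if len(idx) == 0:
            continue
        # split where the quiet gap is >= gap_blocks blocks
        splits = np.flatnonzero(np.diff(idx) > gap_blocks)
        runs = np.split(idx, splits + 1)
        for run in runs:
            onset = g["block_start"].iloc[run[0]]
            end = g["block_start"].iloc[run[-1]]
            span = g.iloc[run[0]:run[-1] + 1]
            peak = int(span["index"].max())
            eid += 1
            rows.append({"cow_id": cow_id, "episode_id": eid, "onset": onset,
                         "end": end, "peak_index": peak,
                         "duration_h": (end - onset) / HOUR + block_hours})
    return pd.DataFrame(rows, columns=["cow_id", "episode_id", "onset", "end",
                                       "peak_index", "duration_h"])


def classify_estrus(follicle_diams, cl_diams,
                    follicle_min: float = FOLLICLE_MIN_MM,
                    cl_max: float = CL_MAX_MM) -> bool:
    """True estrus: a follicle > 15 mm and no corpus luteum > 20 mm."""
    fols = list(follicle_diams)
    cls = list(cl_diams)
    if not fols or max(fols) <= follicle_min:
        return False
    return not cls or max(cls) <= cl_max


def time_ovulation(exams: pd.DataFrame, day7_exam: pd.Series | None,
                   cow_id: str = "", episode_id: int = 0,
                   match_tol: float = MATCH_TOL) -> OvulationRecord:
    """Ovulation time from serial exams, or late/failed from the day-7 scan.

    ``exams`` are the serial (non day-7) exams sorted by time with columns
    ``exam_time, follicle_diams, cl_diams`` (diameters as ';'-lists). The
    dominant follicle is the largest at the first exam and is matched across
    exams by nearest diameter within +-25%; the first exam where no match
    exists marks disappearance and the ovulation time is the midpoint of
    that exam pair.
    """
    rec = OvulationRecord(cow_id=cow_id, episode_id=episode_id, status="undetermined")
    exams = exams.sort_values("exam_time").reset_index(drop=True)
    if len(exams) < 2:
        rec.reason = "insufficient_exams"
        return rec
    fols0 = parse_diams(exams["follicle_diams"].iloc[0])
    if not fols0:
        rec.reason = "no_follicle_at_first_exam"
        return rec
    dom = max(fols0)
    prev_time = exams["exam_time"].iloc[0]
    for k in range(1, len(exams)):
        t = exams["exam_time"].iloc[k]
        fols = parse_diams(exams["follicle_diams"].iloc[k])
        cand = [f for f in fols if abs(f - dom) <= match_tol * dom]
        if not cand:
            rec.status = "ovulated"
            rec.bracket_start = prev_time
            rec.bracket_end = t
            rec.ovulation_time = prev_time + (t - prev_time) / 2
            return rec
        dom = min(cand, key=lambda f: abs(f - dom))
        prev_time = t
    if day7_exam is None:
        rec.reason = "no_day7_exam"
        return rec
    cls = parse_diams(day7_exam["cl_diams"])
    rec.status = "late" if (cls and max(cls) > CL_MAX_MM) else "failed"
    return rec


def categorize(episodes: pd.DataFrame, peak_cut: float = PEAK_CUT,
               duration_cut: float = DURATION_CUT) -> pd.DataFrame:
    """Median-split labels: peak >= 80 is high, duration >= 12 h is long.

    Both cut values belong to the upper class (the 80-100 index range is
    "high"; the duration tie mirrors that rule).
    """
    if peak_cut <= 0 or duration_cut <= 0:
        raise ValueError("cuts must be positive")
    out = episodes.copy()
    out["peak_category"] = np.where(out["peak_index"] >= peak_cut, "high", "low")
    out["duration_category"] = np.where(out["duration_h"] >= duration_cut,
                                        "long", "short")
    return out


def process_episodes(activity: pd.DataFrame, exams: pd.DataFrame,
                     alert_threshold: float = ALERT_THRESHOLD,
                     gap_blocks: int = 3, peak_cut: float = PEAK_CUT,
                     duration_cut: float = DURATION_CUT,
                     exam_horizon_days: float = 10.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect, classify and time every episode of a herd.

    Each episode is paired with the exams of its cow from 2 h before onset up
    to ``exam_horizon_days`` later (and before the next episode of the same
    cow). Returns ``(episodes, ovulations)`` where episodes carry
    ``is_true_estrus`` plus category labels and ovulations one row per
    episode with status, ovulation time, bracketing exams and the interval
    from the AAM alert (onset) to ovulation.
    """
    eps = categorize(detect_episodes(activity, alert_threshold, gap_blocks),
                     peak_cut, duration_cut)
    exams = exams.sort_values(["cow_id", "exam_time"]).reset_index(drop=True)
    is_true, excl_reason, ov_rows = [], [], []
    for _, ep in eps.iterrows():
        cow_exams = exams[exams["cow_id"] == ep["cow_id"]]
        later = eps[(eps["cow_id"] == ep["cow_id"]) & (eps["onset"] > ep["onset"])]
        cutoff = later["onset"].min() if len(later) else \
            ep["onset"] + pd.Timedelta(days=exam_horizon_days)
        win = cow_exams[(cow_exams["exam_time"] >= ep["onset"] - 2 * HOUR)
                        & (cow_exams["exam_time"] < cutoff)]
        serial = win[~win["day7"].astype(bool)] if "day7" in win.columns else win
        day7 = win[win["day7"].astype(bool)] if "day7" in win.columns else win.iloc[0:0]
        day7_row = day7.iloc[0] if len(day7) else None
        if serial.empty:
            is_true.append(False)
            excl_reason.append("missing_alert_exam")
            ov_rows.append(OvulationRecord(ep["cow_id"], int(ep["episode_id"]),
                                           "undetermined", reason="missing_alert_exam"))
            continue
        first = serial.iloc[0]
        true_e = classify_estrus(parse_diams(first["follicle_diams"]),
                                 parse_diams(first["cl_diams"]))
        is_true.append(true_e)
        excl_reason.append("" if true_e else "false_alert")
        if not true_e:
            ov_rows.append(OvulationRecord(ep["cow_id"], int(ep["episode_id"]),
                                           "false", reason="false_alert"))
            continue
        ov_rows.append(time_ovulation(serial.iloc[:6], day7_row,
                                      cow_id=ep["cow_id"],
                                      episode_id=int(ep["episode_id"])))
    eps["is_true_estrus"] = is_true
    eps["exclusion_reason"] = excl_reason
    ov = pd.DataFrame([{
        "cow_id": r.cow_id, "episode_id": r.episode_id, "status": r.status,
        "ovulation_time": r.ovulation_time, "bracket_start": r.bracket_start,
        "bracket_end": r.bracket_end, "reason": r.reason,
    } for r in ov_rows])
    ov = ov.merge(eps[["episode_id", "onset"]], on="episode_id", how="left")
    for col in ("ovulation_time", "bracket_start", "bracket_end"):
        ov[col] = pd.to_datetime(ov[col])
    ov["ovulation_interval_h"] = (ov["ovulation_time"] - ov["onset"]) / HOUR
    ov = ov.drop(columns=["onset"])
    return eps, ov
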