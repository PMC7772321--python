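"""RRT cleaning, rolling baseline, and standardisation.

The raw bolus series is put on a strict hourly grid (gaps become invalid
readings, never imputed), drinking-bout transients are flagged invalid by a
drop/recovery heuristic, and each reading is referenced to a trailing 5-day
(120 h) baseline: per timestamp t the mean and population SD of the valid
readings in the half-open window [t-120 h, t). The standardized change score

    z_t = (temp_t - baseline_mean_t) / max(baseline_sd_t, sd_floor)

drives the threshold alerting downstream. The current reading never enters
its own baseline, which keeps the estrus rise from inflating the baseline at
onset; later in-window readings of a long episode still leak in (a known
limitation of any trailing baseline).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)
TEMP_MIN, TEMP_MAX = 30.0, 45.0
RECOVERY_TOL = 0.2  # degC band around the pre-drop median that ends a transient


def ensure_hourly_grid(series: pd.DataFrame) -> pd.DataFrame:
    """Reindex one cow's readings onto a complete hourly grid.

    Missing hours get ``valid=False`` and NaN temperature; physiologically
    impossible readings (outside 30-45 degC) are likewise invalidated. Adds
    the ``valid`` column if absent.
    """
    s = series.sort_values("timestamp").reset_index(drop=True)
    full = pd.date_range(s["timestamp"].iloc[0], s["timestamp"].iloc[-1], freq="h")
    s = s.set_index("timestamp").reindex(full)
    s.index.name = "timestamp"
    if "cow_id" in s.columns:
        s["cow_id"] = s["cow_id"].ffill().bfill()
    temp = s["temp_c"].to_numpy(dtype=float)
    valid = s["valid"].fillna(False).to_numpy(dtype=bool) if "valid" in s.columns \
        else ~np.isnan(temp)
    valid &= ~np.isnan(temp)
    valid &= np.where(np.isnan(temp), False, (temp >= TEMP_MIN) & (temp <= TEMP_MAX))
    s["valid"] = valid
    return s.reset_index()


def correct_water_intake(series: pd.DataFrame, drop_threshold: float = 0.8,
                         recovery_limit: float = 3.0) -> pd.DataFrame:
    """Flag drinking-bout transients invalid; temperatures are never modified.

    A valid reading starts a transient when it sits ``drop_threshold`` degC or
    more below the median of the previous 3 valid, unflagged readings.
    Subsequent readings stay flagged until one returns within 0.2 degC of that
    median or ``recovery_limit`` hours elapse since the drop. The reference
    median is only trusted while its newest reading is at most
    ``recovery_limit`` hours old; after a longer invalid gap the next readings
    re-establish the reference instead of being flagged against a stale one
    — this is what makes correcting an already corrected series flag nothing
    new (idempotent). With fewer than 3 valid readings the series is returned
    unchanged with a warning.
    """
    s = series.copy().reset_index(drop=True)
    if "valid" not in s.columns:
        s["valid"] = ~s["temp_c"].isna()
    valid = s["valid"].to_numpy(dtype=bool).copy()
    temp = s["temp_c"].to_numpy(dtype=float)
    ts = s["timestamp"].to_numpy()
    if valid.sum() < 3:
        warnings.warn("fewer than 3 valid readings; water correction skipped")
        s["water_flagged"] = False
        return s

    flagged = np.zeros(len(s), dtype=bool)
    recent: list[float] = []          # last 3 clean readings
    t_ref: np.datetime64 | None = None
    in_transient = False
    ref_med = np.nan
    t_drop: np.datetime64 | None = None
    for i in range(len(s)):
        if not valid[i]:
            continue
        if in_transient:
            elapsed = (ts[i] - t_drop) / np.timedelta64(1, "h")
            if abs(temp[i] - ref_med) <= RECOVERY_TOL or elapsed >= recovery_limit:
                in_transient = False
            else:
                flagged[i] = True
                continue
        fresh = t_ref is not None and \
            (ts[i] - t_ref) / np.timedelta64(1, "h") <= recovery_limit
        if len(recent) == 3 and fresh:
            med = float(np.median(recent))
            if med - temp[i] >= drop_threshold:
                flagged[i] = True
                in_transient = True
                ref_med = med
                t_drop = ts[i]
                continue
        recent.append(temp[i])
        t_ref = ts[i]
        if len(recent) > 3:
            recent.pop(0)
    s["valid"] = valid & ~flagged
    s["water_flagged"] = flagged
    return s


def _trailing_stats(values: np.ndarray, mask: np.ndarray,
                    window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, population SD, and count over the previous ``window`` slots,
    excluding the current slot (half-open window)."""
    # center on the global mean before accumulating: cancellation in
    # sum(x^2)/n - mean^2 otherwise leaves ~1e-6 artifacts on flat series
    shift = float(np.nanmean(np.where(mask, values, np.nan))) if mask.any() else 0.0
    values = values - shift
    v = np.where(mask, values, 0.0)
    v2 = np.where(mask, values * values, 0.0)
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v2)])
    cn = np.concatenate([[0.0], np.cumsum(mask.astype(float))])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - window, 0)
    s1 = c1[idx] - c1[lo]
    s2 = c2[idx] - c2[lo]
    cnt = cn[idx] - cn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = s2 / cnt - mean * mean
    sd = np.sqrt(np.clip(var, 0.0, None))
    return mean + shift, sd, cnt.astype(int)


def rolling_baseline(series: pd.DataFrame, window_h: int = 120,
                     min_window_points: int = 90,
                     hour_matched: bool = False) -> pd.DataFrame:
    """Trailing-window baseline mean/SD per timestamp.

    Default pools all valid readings in [t-120 h, t); with
    ``hour_matched=True`` only the previous 5 readings at the same hour of
    day are used (min_window_points then counts those, at most 5). SD uses
    the population convention (divide by n). Baseline is NaN where fewer than
    ``min_window_points`` valid readings fall in the window.

    The input must be on a complete hourly grid (see
    :func:`ensure_hourly_grid`).
    """
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    s = series.reset_index(drop=True)
    temp = s["temp_c"].to_numpy(dtype=float)
    mask = s["valid"].to_numpy(dtype=bool) & ~np.isnan(temp)
    if hour_matched:
        n = len(s)
        lags = window_h // 24
        stack = np.full((lags, n), np.nan)
        mstack = np.zeros((lags, n), dtype=bool)
        for k in range(1, lags + 1):
            stack[k - 1, 24 * k:] = temp[:-24 * k]
            mstack[k - 1, 24 * k:] = mask[:-24 * k]
        cnt = mstack.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(mstack, stack, 0.0).sum(axis=0) / cnt
            var = np.where(mstack, stack * stack, 0.0).sum(axis=0) / cnt - mean ** 2
        sd = np.sqrt(np.clip(var, 0.0, None))
        min_pts = min(min_window_points, lags)
    else:
        mean, sd, cnt = _trailing_stats(temp, mask, window_h)
        min_pts = min_window_points
    defined = cnt >= min_pts
    out = pd.DataFrame({"timestamp": s["timestamp"],
                        "baseline_mean": np.where(defined, mean, np.nan),
                        "baseline_sd": np.where(defined, sd, np.nan),
                        "n_used": cnt})
    if "cow_id" in s.columns:
        out.insert(0, "cow_id", s["cow_id"])
    return out


def standardize(series: pd.DataFrame, baseline: pd.DataFrame,
                sd_floor: float = 0.05) -> pd.DataFrame:
    """Standardized change score z = (temp - mean) / max(sd, sd_floor).

    NaN wherever the reading is invalid or the baseline undefined. The floor
    guards division by zero on flat stretches.
    """
    merged = series.merge(
        baseline[["timestamp", "baseline_mean", "baseline_sd"]],
        on="timestamp", how="left")
    sd = np.maximum(merged["baseline_sd"].to_numpy(dtype=float), sd_floor)
    z = (merged["temp_c"].to_numpy(dtype=float)
         - merged["baseline_mean"].to_numpy(dtype=float)) / sd
    z = np.where(merged["valid"].to_numpy(dtype=bool), z, np.nan)
    out = pd.DataFrame({"timestamp": merged["timestamp"], "z": z})
    if "cow_id" in series.columns:
        out.insert(0, "cow_id", merged["cow_id"])
    return out


def preprocess_cow(series: pd.DataFrame, drop_threshold: float = 0.8,
                   recovery_limit: float = 3.0, window_h: int = 120,
                   min_window_points: int = 90, sd_floor: float = 0.05,
                   hour_matched: bool = False
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Grid -> water-correct -> baseline -> z for one cow.

    Returns ``(clean, baseline, zscores)``.
    """
    clean = correct_water_intake(ensure_hourly_grid(series),
                                 drop_threshold=drop_threshold,
                                 recovery_limit=recovery_limit)
    base = rolling_baseline(clean, window_h=window_h,
                            min_window_points=min_window_points,
                            hour_matched=hour_matched)
    z = standardize(clean, base, sd_floor=sd_floor)
    return clean, base, z
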