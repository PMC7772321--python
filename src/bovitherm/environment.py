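"""Temperature-humidity index (THI) and heat-stress categorisation.

THI combines air temperature and relative humidity into a heat-load index:

    THI = 0.8*T + (RH/100) * (T - 14.3) + 46.4

with T in degrees Celsius and RH in percent. The day is split into three
fixed periods — early morning (00:00-07:59), morning (08:00-15:59) and
evening (16:00-23:59) — and each date x period is labelled "high" when its
maximum hourly THI strictly exceeds 72, the conventional heat-stress onset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

THI_CUTOFF = 72.0
PERIODS = ("early_morning", "morning", "evening")


def thi(air_temp_c, rel_humidity):
    """THI from air temperature (degC) and relative humidity (%).

    Accepts scalars or array-likes; humidity outside [0, 100] is rejected.
    At T = 14.3 degC the humidity term vanishes and THI is 57.84 regardless
    of RH.
    """
    t = np.asarray(air_temp_c, dtype=float)
    rh = np.asarray(rel_humidity, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    out = 0.8 * t + (rh / 100.0) * (t - 14.3) + 46.4
    if np.isscalar(air_temp_c) and np.isscalar(rel_humidity):
        return float(out)
    return out


def period_of(ts: pd.Timestamp) -> str:
    """Day period containing ``ts`` (half-open at each boundary)."""
    h = ts.hour
    if h < 8:
        return "early_morning"
    if h < 16:
        return "morning"
    return "evening"


def period_max_thi(weather: pd.DataFrame, cutoff: float = THI_CUTOFF) -> pd.DataFrame:
    """Per date x period maximum THI with the high/low label.

    ``weather`` needs columns ``timestamp, air_temp_c, rel_humidity``; periods
    with no readings emit no row. Returns ``date, period, max_thi, category``.
    """
    if weather.empty:
        return pd.DataFrame(columns=["date", "period", "max_thi", "category"])
    w = weather.copy()
    w["thi"] = thi(w["air_temp_c"].to_numpy(), w["rel_humidity"].to_numpy())
    w["date"] = w["timestamp"].dt.date
    w["period"] = pd.cut(w["timestamp"].dt.hour, bins=[-1, 7, 15, 23],
                         labels=PERIODS).astype(str)
    out = (w.groupby(["date", "period"], sort=True)["thi"].max()
             .rename("max_thi").reset_index())
    out["category"] = np.where(out["max_thi"] > cutoff, "high", "low")
    # stable period ordering within each date
    out["period"] = pd.Categorical(out["period"], categories=PERIODS, ordered=True)
    return out.sort_values(["date", "period"]).reset_index(drop=True)


def thi_at_event(event_time: pd.Timestamp, period_table: pd.DataFrame) -> str:
    """High/low THI label of the period containing ``event_time``.

    Returns ``"thi_unknown"`` when the period table has no row for that
    date/period (missing weather).
    """
    if event_time is None or pd.isna(event_time):
        return "thi_unknown"
    event_time = pd.Timestamp(event_time)
    row = period_table[
        (period_table["date"] == event_time.date())
        & (period_table["period"].astype(str) == period_of(event_time))]
    if row.empty:
        return "thi_unknown"
    return str(row["category"].iloc[0])
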