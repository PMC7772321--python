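"""Event accounting, median splits, and descriptive group means.

The ledger reproduces the study's event bookkeeping: of all AAM-alerted
episodes, false alerts (no pre-ovulatory follicle), events missing more than
25% of hourly temperature points in either analysis window, and events
without a timed ovulation (failed, late, or undetermined) are removed;
the remainder are analyzed. Group means are plain descriptive cell
statistics (n, mean, SD, SE) by sampling time x estrous-expression category
x THI category — deliberately not model-adjusted least-squares means, so
they track direction rather than published magnitudes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .environment import thi_at_event


def account_events(episodes: pd.DataFrame, ovulations: pd.DataFrame,
                   features: pd.DataFrame) -> dict:
    """Event ledger with counts, percentages and per-event reason codes.

    Identity: n_analyzed = n_alerted_total - n_false - n_no_ovulation
    - n_missing_excluded, where n_no_ovulation bundles failed and late
    ovulations and undetermined events (none of which have a timed
    ovulation). Percentages are relative to the total alerted count.
    """
    ov = ovulations.set_index("episode_id")
    reasons: dict[int, str] = {}
    n_false = n_no_ov = n_failed = n_late = n_missing = n_analyzed = 0
    excluded_ids = set(features.loc[features["excluded"], "episode_id"]
                       .astype(int)) if len(features) else set()
    for _, ep in episodes.iterrows():
        eid = int(ep["episode_id"])
        if eid not in ov.index:
            raise ValueError(f"episode {eid} missing from ovulation table")
        status = ov.loc[eid, "status"]
        if not ep["is_true_estrus"]:
            n_false += 1
            reasons[eid] = "false_alert"
        elif status != "ovulated":
            n_no_ov += 1
            n_failed += status == "failed"
            n_late += status == "late"
            reasons[eid] = f"no_ovulation_{status}"
        elif eid in excluded_ids:
            n_missing += 1
            reasons[eid] = "missing_data"
        else:
            n_analyzed += 1
            reasons[eid] = "analyzed"
    total = len(episodes)
    pct = (lambda n: 100.0 * n / total) if total else (lambda n: 0.0)
    return {"n_alerted_total": total, "n_false": n_false,
            "n_no_ovulation": n_no_ov, "n_failed_ovulation": n_failed,
            "n_late_ovulation": n_late, "n_missing_excluded": n_missing,
            "n_analyzed": n_analyzed,
            "pct_false": pct(n_false), "pct_no_ovulation": pct(n_no_ov),
            "pct_missing_excluded": pct(n_missing),
            "pct_analyzed": pct(n_analyzed), "reasons": reasons}


def attach_thi_labels(features: pd.DataFrame, episodes: pd.DataFrame,
                      ovulations: pd.DataFrame,
                      period_table: pd.DataFrame) -> pd.DataFrame:
    """THI category per feature row: estrus windows take the label of the
    period containing the episode onset, ovulation windows that of the
    ovulation time."""
    eps = episodes.set_index("episode_id")
    ov = ovulations.set_index("episode_id")
    labels = []
    for _, row in features.iterrows():
        eid = int(row["episode_id"])
        t = eps.loc[eid, "onset"] if row["window_kind"] == "estrus" \
            else ov.loc[eid, "ovulation_time"]
        labels.append(thi_at_event(t, period_table))
    out = features.copy()
    out["thi_category"] = labels
    return out


def group_means(features: pd.DataFrame, episodes: pd.DataFrame,
                grouping: str = "peak_category",
                value_cols: tuple[str, ...] = ("auc", "ptc", "ntc")
                ) -> pd.DataFrame:
    """Descriptive cell means by window_kind x expression category x THI.

    ``grouping`` is ``peak_category`` or ``duration_category``; ``features``
    must already carry ``thi_category`` (see :func:`attach_thi_labels`).
    Excluded events are dropped; empty cells emit a row with n=0 and NaN
    statistics. SD uses the sample convention, SE = SD/sqrt(n).
    """
    if grouping not in ("peak_category", "duration_category"):
        raise ValueError("grouping must be peak_category or duration_category")
    f = features[~features["excluded"]].merge(
        episodes[["episode_id", grouping]], on="episode_id", how="left")
    kinds = ("estrus", "ovulation")
    cats = ("high", "low") if grouping == "peak_category" else ("long", "short")
    this = ("high", "low")
    rows = []
    for kind in kinds:
        for cat in cats:
            for thi_cat in this:
                cell = f[(f["window_kind"] == kind) & (f[grouping] == cat)
                         & (f["thi_category"] == thi_cat)]
                row = {"window_kind": kind, grouping: cat,
                       "thi_category": thi_cat, "n": len(cell)}
                for c in value_cols:
                    v = cell[c].dropna()
                    row[f"{c}_mean"] = v.mean() if len(v) else np.nan
                    row[f"{c}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
                    row[f"{c}_se"] = (v.std(ddof=1) / np.sqrt(len(v))
                                      if len(v) > 1 else np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def compute_median_cuts(episodes: pd.DataFrame) -> tuple[float, float]:
    """Empirical medians of peak index and duration over true-estrus episodes.

    Reported alongside the fixed categorisation cuts (80 index, 12 h), which
    remain the defaults for reproducibility.
    """
    true_eps = episodes[episodes["is_true_estrus"]] \
        if "is_true_estrus" in episodes.columns else episodes
    if not len(true_eps):
        raise ValueError("no true-estrus episodes")
    return (float(true_eps["peak_index"].median()),
            float(true_eps["duration_h"].median()))
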