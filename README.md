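# bovitherm

Rumen-reticular temperature (RRT) analysis around estrus and ovulation in
dairy cows.

Collar-mounted automated activity monitors (AAM) detect estrus from a 0–100
activity index (alert at ≥ 35), but insemination timing depends on
ovulation, which follows the activity peak by roughly a day. An ingested
bolus thermometer reports RRT hourly, and body temperature rises around
estrus and dips around ovulation. `bovitherm` implements the full analysis
chain for asking whether those thermal signatures can time either event:

* a **ground-truthed synthetic herd generator** (hourly RRT with circadian
  rhythm, noise and drinking transients; 2 h activity blocks; twice-daily
  ovarian ultrasound records; hourly weather), so every stage is testable
  against known injected signals;
* **preprocessing** — water-intake correction (drop/recovery heuristic,
  readings flagged, never modified), a trailing 5-day (120 h) hourly
  baseline mean/SD, and the standardized change score
  z = (T − baseline) / SD;
* **episode building** — activity-run detection, true-estrus classification
  (follicle > 15 mm, no CL > 20 mm), ovulation timed at the midpoint of the
  exam pair across which the dominant follicle disappears, late/failed
  resolution from the day-7 CL;
* **thermal features** per event over the estrus and peri-ovulatory
  windows, relative to baseline: positive AUC (trapezoidal integral of
  max(y, 0), °C·h), PTC = max(y), NTC = min(y), with exclusion of events
  missing > 25 % of hourly points;
* **THI** (temperature-humidity index, `0.8·T + (RH/100)(T−14.3) + 46.4`)
  with per-day-period maxima and the > 72 heat-stress category;
* **alerting** — two consecutive hourly z readings beyond ± {0.5 … 3} STD
  inside [AAM alert − 12 h, ovulation + 12 h], first-alert rule, and
  detection-interval summaries (% alerted, mean, SD, min, max);
* **reporting** — event ledger (false alerts / no-ovulation /
  missing-data removals), empirical median cuts, and descriptive group
  means by sampling time × estrous expression × THI.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from bovitherm import HerdConfig, PipelineConfig, run_pipeline

config = PipelineConfig(herd=HerdConfig(n_cows=30, seed=3))
manifest = run_pipeline(config, "herd_run")
```

This simulates a 30-cow herd and writes every stage artifact (CSV tables
plus `ledger.json` and `manifest.json`) into `herd_run/`. Inspecting the
results:

```python
import pandas as pd, json
feats = pd.read_csv("herd_run/features.csv")
print(feats[~feats.excluded].groupby("window_kind")[["auc", "ptc", "ntc"]].mean())
```

```
                  auc       ptc       ntc
window_kind
estrus       4.150667  0.778508 -0.194929
ovulation    0.500225  0.239974 -0.714881
```

Mean positive AUC and PTC are several-fold larger during estrus than around
ovulation, while the deepest drop below baseline (NTC) occurs around
ovulation — the thermal asymmetry the alerting system exploits. The alert
summary shows the detection ladder:

```python
s = pd.read_csv("herd_run/alert_summary.csv")
print(s[s.direction == "estrus"][["threshold", "pct_alerted",
                                  "aam_to_alert_mean", "aam_to_alert_min"]])
```

```
    threshold  pct_alerted  aam_to_alert_mean  aam_to_alert_min
0         0.5     100.0000            -5.3636             -12.0
2         1.0     100.0000            -0.2727             -12.0
4         1.5     100.0000             2.3182             -11.0
6         2.0      90.9091             3.7000               2.0
8         2.5      77.2727             4.4706               2.0
10        3.0      63.6364             4.9286               2.0
```

The alerted percentage falls monotonically as the threshold rises (alerts
at a higher threshold are a subset of those at any lower one), and no
AAM-anchored interval precedes the −12 h search-window start.

The same pipeline is available from the shell:

```bash
bovitherm all --dir herd_run --seed 3
bovitherm alerts --dir herd_run --thresholds 1,2,3
```

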