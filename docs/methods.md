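# Methods

## The problem

In dairy herds, estrus (behavioural heat) is routinely detected by
collar-mounted automated activity monitors (AAM) that emit a 0–100 activity
index in 2 h blocks; an index of 35 or more raises an estrus alert. Optimal
insemination timing, however, depends on ovulation, which follows the
activity peak by roughly a day and is only observable directly by serial
ultrasound. Rumen-reticular temperature (RRT), measured hourly by an
ingested bolus thermometer, rises around estrus and dips around ovulation,
so a bolus already in place for health monitoring could in principle time
both events. This package implements that analysis end to end — baseline
construction, thermal feature extraction, heat-stress context, and a
standard-deviation-threshold alerting system — and ships a fully
ground-truthed synthetic herd generator so every stage is testable without
animal data.

## Signal model and generator

One cow's hourly RRT is simulated as

    temp(t) = basal + circadian(t) + noise(t) + drink(t) + rise(t) + dip(t)

with defaults: basal 38.6 °C; a 24 h sinusoidal circadian term of amplitude
0.15 °C peaking at 18:00; iid Gaussian noise with SD 0.15 °C; drinking
bouts; an estrus-associated raised-cosine rise of amplitude 0.55 °C
spanning the activity episode; and a raised-cosine dip of amplitude
−0.60 °C over 6 h centred on the hour nearest ovulation. Raised cosines
were chosen because the sampled peak equals the configured amplitude
exactly when the centre lands on the hourly grid (the generator snaps it),
which gives downstream tests closed-form expectations.

Drinking bouts occur at Poisson times within 05:00–22:00 (0.5 detectable
bouts/day), depress RRT by 2.0 °C at the first hourly sample at or after
the bout — the bolus samples hourly, so the recovery clock starts at that
sample — and recover exponentially with a 0.8 h time constant. Published
bolus studies report drinking depressions of 1–3 °C with recovery within
the hour, which these defaults emulate. Hours whose drink-induced deficit
exceeds 0.2 °C are recorded as ground-truth transients for
correction-recovery tests. The bout rate counts only *detectable* bouts
(deep, sharp depressions); cows drink more often than this, but shallow
bouts are indistinguishable from noise and are not modelled.

Activity is drawn uniform 5–30 per 2 h block outside episodes (never
false-triggering the 35 threshold) and shaped inside the episode so that
every block from onset to end is ≥ 35 with the maximum exactly the injected
peak. Peaks are drawn N(80, 12) clipped to 40–100 and durations from
{8, 10, 12, 14, 16} h, reproducing the field-scale medians of 80 index and
12 h. Ovulation falls 24–32 h after episode onset. Exams run twice daily at
08:00/17:00 from the alert, at most six, plus a day-7 confirmation scan;
the pre-ovulatory follicle (16.5–19.5 mm, growing 0.3 mm per exam)
disappears across the exam pair bracketing the true ovulation. Configurable
fractions of episodes are false alerts (no dominant follicle, no thermal
signature — an AAM alert without underlying estrus physiology), failed
ovulations (follicle persists, no day-7 CL) and late ovulations (follicle
persists, new day-7 CL).

Weather is hourly with a diurnal cycle; a configurable fraction of days are
"summer" days constructed to exceed THI 72 at their maximum (the rest are
bounded below it). On days whose maximum THI exceeds 72 the estrus rise
amplitude is multiplied by (1 + thi_coupling), default gain 0.4,
reproducing the direction of the observed heat-stress × estrous-expression
interaction.

All randomness derives from one seed through spawned generator streams;
fixed seed ⇒ byte-identical output tables.

## Preprocessing

Readings are placed on a strict hourly grid; gaps and physiologically
impossible values (outside 30–45 °C) are marked invalid, never imputed.

**Water-intake correction.** The commercial correction is proprietary, so a
fully documented heuristic replaces it: a valid reading starts a transient
when it sits ≥ 0.8 °C below the median of the previous three clean
readings; subsequent readings stay flagged until one returns within 0.2 °C
of that median or 3 h elapse. The reference median is only trusted while
its newest reading is at most 3 h old, which makes the correction
idempotent (re-correcting a corrected series flags nothing new).
Temperatures are only ever flagged, never modified. Note one consequence:
flagged hours count as missing in the analysis windows below, whereas the
commercial system corrected them in place — so the synthetic herd loses
more events to the missing-data rule (typically 10–15 %) than a real
telemetry stream would.

**Baseline.** For each timestamp t the baseline is the mean and population
SD of the valid readings in the half-open trailing window [t−120 h, t) —
the previous five days, all hours pooled. A per-hour-of-day variant (the
previous five same-hour readings) is available behind a switch but is far
noisier with only five points and is not the default. The current reading
never enters its own baseline, so the estrus rise cannot inflate the
baseline at onset; the early hours of a long episode do leak into baselines
used later in that same episode, a limitation inherent to any trailing
baseline (see "Numerical choices" for the leak-free freeze option).
Baselines with fewer than 90 of 120 possible points (75 %, mirroring the
25 % missingness tolerance) are undefined.

**Standardisation.** z_t = (temp_t − baseline_mean_t) / max(baseline_sd_t,
0.05 °C). The floor prevents unbounded z on flat stretches; 0.05 °C is the
bolus quantisation scale.

## Episodes, classification, ovulation timing

Episodes are maximal runs of blocks ≥ 35, with runs separated by fewer than
three quiet blocks (6 h) merged so single-block dropouts do not split one
estrus. Peak = run maximum; duration = last-block start − onset + 2 h
(contiguous-run convention). An episode is true estrus when the alert exam
shows a follicle > 15 mm and no CL > 20 mm. The dominant follicle (largest
at the first exam) is tracked across exams by nearest diameter within
± 25 %; the first exam with no match marks disappearance, and ovulation is
timed at the midpoint of that exam pair. Follicles persisting through all
six exams are resolved by the day-7 scan: new CL ⇒ late ovulation, none ⇒
failed. Median splits: peak ≥ 80 is high (the 80–100 range belongs to the
upper class), duration ≥ 12 h is long (tie resolved upward to mirror the
peak rule).

## Thermal features

For each analyzed event, two windows: estrus (onset through the end of the
above-threshold span) and ovulation (the bracketing exam pair). Within a
window, y_t = temp_t − baseline_mean_t at the valid hourly points, and

* **positive AUC** (°C·h): trapezoidal integral of max(y, 0) over the
  observed time stamps (hours to the nearest second). Clamping precedes
  integration, so the result equals the area under the clamped linear
  interpolant exactly — order-independent, and verified against a
  1-second-grid Riemann oracle to < 1e-6. The field sometimes labels this
  quantity "°C²"; time × temperature is dimensionally °C·h and the columns
  are labelled accordingly.
* **PTC / NTC** (°C): max(y) / min(y), both unclamped — a window wholly
  below baseline yields a negative PTC rather than zero, preserving
  information; summaries may clamp if desired.

Events missing more than 25 % of expected hourly points in either window
are excluded. Expected points are floor(t_end − t_start) + 1 hourly slots,
endpoints inclusive.

## Alerting and intervals

An alert is two consecutive hourly z readings both ≥ +thr (estrus) or both
≤ −thr (ovulation), thr ∈ {0.5, 1, 1.5, 2, 2.5, 3} STD, searched from 12 h
before the AAM alert to 12 h after ovulation. One alert per maximal
qualifying run, timed at the run's first reading ("exceeded" is read
inclusively; the earliest actionable time is reported). Only the first
alert per event × threshold × direction enters the interval statistics.
Alerts nest across thresholds by construction, which forces the alerted
percentage to be non-increasing from 0.5 to 3 STD.

Intervals are alert − anchor: AAM-anchored intervals are bounded below by
−12 h (the window start) and ovulation-anchored intervals are negative when
the alert precedes ovulation. Summaries report % alerted (over eligible
events: true estrus, ovulated, non-excluded) and mean / sample SD (n−1) /
min / max per threshold and direction.

## Reporting

The event ledger reproduces the study bookkeeping: total AAM alerts minus
false alerts, minus events without a timed ovulation (failed + late +
undetermined, bundled because none can contribute an ovulation window),
minus missing-data exclusions, equals analyzed events — an identity
asserted on every run. Group means are plain descriptive cell statistics
(n, mean, SD, SE) by sampling time × expression category × THI category.
They are deliberately not mixed-model least-squares means: published
magnitudes from repeated-measures models are covariate-adjusted and not
directly comparable, so only directions should be compared.

## Numerical choices

* SD conventions: population (÷ n) for the rolling baseline, sample (÷ n−1)
  for descriptive summaries. Both arbitrary but fixed.
* Exactly-72 THI is "low" (the heat-stress class is "maximum THI > 72");
  period intervals are half-open.
* `freeze_baseline` option in feature extraction: holds both windows'
  baseline at its value at episode onset — the last instant guaranteed free
  of the episode's own thermal signature. Default off (the rolling baseline
  is the method); used by closed-form tests and available as a sensitivity
  control. The closed-form checks are exact only with the freeze: against
  the rolling baseline the pulse's own early hours bias PTC low by
  ~0.01–0.03 °C, and the Monte-Carlo recovery oracle models exactly that
  contamination.
* Degenerate inputs: < 2 points in a window ⇒ AUC undefined (NaN), event
  flagged rather than dropped; < 3 valid readings ⇒ water correction skipped
  with a warning; empty activity ⇒ no episodes.

## What passing tests do and do not show

The generator reproduces the statistical skeleton the analysis assumes —
circadian + noise + transients, episode-locked pulses with known
amplitudes, exam bracketing, heat-stress coupling. It does not model
sensor drift, feed-intake thermal effects, hormone dynamics, milk-yield or
body-condition trajectories, inter-cow amplitude heterogeneity beyond the
THI gain, or autocorrelated noise. Tests passing on this herd therefore
demonstrate correctness of the computations and the qualitative behaviour
of the alerting system, not field-level detection performance; the default
problem sizes (150-cow herd for qualitative checks, 500 events for
extreme-statistic recovery, 1000 random series for the AUC oracle) were
chosen to make sampling noise small relative to the asserted effects.

## Known limitations

* The trailing baseline leaks long episodes into their own reference
  (documented above); whether the original analysis excluded the estrus
  window from its baseline is unknowable from the published description.
* The water-intake heuristic's constants (0.8 °C drop, 0.2 °C recovery
  band, 3 h limit) are plausible but unvalidated against the proprietary
  algorithm they replace.
* Alerted-percentage magnitudes on synthetic defaults run higher than field
  values at low thresholds (the generator's signal-to-noise is favourable);
  only the ordering and nesting structure are asserted.
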