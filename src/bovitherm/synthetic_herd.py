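"""Ground-truthed synthetic herd generator.

Emulates the data streams of a precision-livestock estrus study: hourly
rumen-reticular temperature (RRT) from bolus thermometers, a 0-100 activity
index in 2 h blocks from collar-mounted automated activity monitors (AAM),
twice-daily ovarian ultrasound exams, and hourly weather. Every stochastic
component is driven by a single seed and every injected event is recorded in
a truth table, so downstream feature extraction and alerting can be tested
against known answers.

Signal model for one cow's RRT (hourly, degrees Celsius):

    temp(t) = basal + circadian(t) + noise(t) + drink(t) + rise(t) + dip(t)

* circadian: 24 h sinusoid with an early-evening acrophase;
* noise: iid Gaussian;
* drink: drinking bouts depress RRT sharply with exponential recovery;
* rise: a raised-cosine pulse spanning the estrus episode (peak equals the
  injected amplitude exactly at the hourly sample nearest the centre);
* dip: a raised-cosine trough centred on the hour nearest ovulation.

On days whose maximum THI exceeds 72 the estrus rise amplitude is multiplied
by (1 + thi_coupling), reproducing the direction of the heat-stress by
estrous-expression interaction seen in the field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .environment import thi

HOUR = pd.Timedelta(hours=1)
BLOCK_H = 2  # AAM reporting resolution, hours

#: hours with drink-induced deficit above this are ground-truth transients
DRINK_TRUTH_TOL = 0.2


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SignalParams:
    """Tunable components of the simulated RRT / activity signal.

    Amplitudes in degrees Celsius, durations in hours. ``drink_depth`` and
    ``ovulation_dip_amp`` are non-positive (a value of 0 switches the term
    off). ``thi_coupling`` is the dimensionless gain applied to the estrus
    rise on heat-stress days (day max THI > 72).
    """

    basal_temp: float = 38.6
    circadian_amplitude: float = 0.15
    circadian_acrophase_h: float = 18.0
    noise_sd: float = 0.15
    drink_rate: float = 0.5          # detectable bouts per day
    drink_depth: float = -2.0
    drink_recovery: float = 0.8      # exponential time constant, h
    estrus_rise_amp: float = 0.55
    estrus_rise_duration: float = 12.0
    ovulation_dip_amp: float = -0.60
    ovulation_dip_duration: float = 6.0
    thi_coupling: float = 0.4

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.estrus_rise_duration <= 0:
            raise ValueError("estrus_rise_duration must be > 0")
        if self.drink_depth > 0:
            raise ValueError("drink_depth must be <= 0")
        if self.ovulation_dip_amp > 0:
            raise ValueError("ovulation_dip_amp must be <= 0")
        if self.drink_rate < 0:
            raise ValueError("drink_rate must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth for one injected estrus episode."""

    cow_id: str
    episode_onset: pd.Timestamp
    episode_end: pd.Timestamp       # exclusive end of the above-threshold span
    true_peak_index: int
    ovulation_time: pd.Timestamp | None
    ovulated: bool
    injected_rise_amp: float
    injected_dip_amp: float
    is_false_alert: bool = False
    status: str = "ovulated"        # ovulated | late | failed | false

    def __post_init__(self) -> None:
        if self.episode_onset >= self.episode_end:
            raise ValueError("episode_onset must precede episode_end")
        if self.ovulated and self.ovulation_time is not None:
            if self.ovulation_time <= self.episode_onset:
                raise ValueError("ovulation_time must follow episode_onset")


@dataclass
class HerdConfig:
    """Study-scale configuration for :func:`simulate_herd`."""

    n_cows: int = 150
    n_days: int = 21
    start: str = "2021-06-01"
    seed: int = 0
    summer_fraction: float = 0.5
    episodes_per_cow: int = 1
    false_fraction: float = 0.129    # false AAM alerts (no pre-ovulatory follicle)
    failed_fraction: float = 0.03    # follicle persists, no day-7 CL
    late_fraction: float = 0.03      # follicle persists, new day-7 CL
    missing_rate: float = 0.02       # random dropped hourly readings
    heavy_missing_fraction: float = 0.026  # events with >25% of estrus hours dropped
    duration_choices: tuple[int, ...] = (8, 10, 12, 14, 16)
    signal: SignalParams = field(default_factory=SignalParams)

    def __post_init__(self) -> None:
        if self.n_cows < 1:
            raise ValueError("n_cows must be >= 1")
        if self.episodes_per_cow < 0:
            raise ValueError("episodes_per_cow must be >= 0")
        for name in ("false_fraction", "failed_fraction", "late_fraction",
                     "missing_rate", "heavy_missing_fraction", "summer_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class HerdData:
    """In-memory bundle of the generated tables."""

    weather: pd.DataFrame
    rrt: pd.DataFrame
    activity: pd.DataFrame
    exams: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iso = "%Y-%m-%dT%H:%M:%S"
        w = self.weather.copy()
        w["air_temp_c"] = w["air_temp_c"].round(2)
        w["rel_humidity"] = w["rel_humidity"].round(1)
        w.to_csv(out / "weather.csv", index=False, date_format=iso)
        r = self.rrt.copy()
        r["temp_c"] = r["temp_c"].round(2)
        r.to_csv(out / "rrt.csv", index=False, date_format=iso)
        self.activity.to_csv(out / "activity.csv", index=False, date_format=iso)
        self.exams.to_csv(out / "exams.csv", index=False, date_format=iso)
        self.truth.to_csv(out / "truth.csv", index=False, date_format=iso)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def simulate_weather(n_days: int, seed: int, summer_fraction: float = 0.5,
                     start: str | pd.Timestamp = "2021-06-01") -> pd.DataFrame:
    """Hourly weather with a diurnal cycle; ``round(n_days*summer_fraction)``
    randomly placed "summer" days reach THI > 72 at their daily maximum, the
    remaining days stay below 72 at every hour (bounded noise guarantees it).

    Returns columns ``timestamp, air_temp_c, rel_humidity``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0 <= summer_fraction <= 1:
        raise ValueError("summer_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_summer = round(n_days * summer_fraction)
    summer_days = set(rng.choice(n_days, size=n_summer, replace=False).tolist())

    times = pd.date_range(pd.Timestamp(start), periods=n_days * 24, freq="h")
    hod = times.hour.to_numpy()
    day = np.arange(n_days * 24) // 24
    shape = np.cos(2 * np.pi * (hod - 14) / 24)  # warmest mid-afternoon
    is_summer = np.isin(day, list(summer_days))
    mean_t = np.where(is_summer, 24.0, 12.0)
    amp_t = np.where(is_summer, 7.0, 5.0)
    temp = mean_t + amp_t * shape + rng.uniform(-0.5, 0.5, size=len(times))
    rh = np.where(is_summer, 55.0, 60.0) + rng.uniform(-5, 5, size=len(times))
    rh = np.clip(rh, 0.0, 100.0)
    return pd.DataFrame({"timestamp": times, "air_temp_c": temp,
                         "rel_humidity": rh})


def _high_thi_dates(weather: pd.DataFrame, cutoff: float = 72.0) -> set:
    """Dates whose maximum hourly THI exceeds the cutoff."""
    vals = thi(weather["air_temp_c"].to_numpy(), weather["rel_humidity"].to_numpy())
    daily = pd.Series(vals).groupby(weather["timestamp"].dt.date).max()
    return set(daily.index[daily > cutoff])


# ---------------------------------------------------------------------------
# one cow
# ---------------------------------------------------------------------------

def _raised_cosine(hours_from_center: np.ndarray, amp: float,
                   duration: float) -> np.ndarray:
    """amp/2 * (1 + cos(2*pi*x/duration)) on |x| <= duration/2, else 0."""
    out = np.zeros_like(hours_from_center, dtype=float)
    if amp == 0 or duration <= 0:
        return out
    mask = np.abs(hours_from_center) <= duration / 2
    out[mask] = amp / 2 * (1 + np.cos(2 * np.pi * hours_from_center[mask] / duration))
    return out


def simulate_cow(params: SignalParams,
                 truth: TruthRecord | Sequence[TruthRecord],
                 seed: int,
                 start: str | pd.Timestamp = "2021-06-01",
                 n_days: int = 21) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cow's hourly RRT and 2 h-block activity.

    ``truth`` may be one record or several non-overlapping records; injected
    amplitudes are taken from the truth records (the herd generator applies
    THI coupling there). Returns ``(rrt, activity)`` where ``rrt`` carries a
    ground-truth ``drink_transient`` column (hours whose drink-induced deficit
    exceeds 0.2 degC) for correction-recovery tests.

    Raises ``ValueError`` on overlapping episodes or truth times outside the
    simulated horizon.
    """
    truths = [truth] if isinstance(truth, TruthRecord) else sorted(
        truth, key=lambda t: t.episode_onset)
    start = pd.Timestamp(start)
    horizon_end = start + pd.Timedelta(hours=n_days * 24)
    for a, b in zip(truths, truths[1:]):
        if b.episode_onset < a.episode_end:
            raise ValueError(f"overlapping estrus episodes for cow {a.cow_id}")
    for t in truths:
        if not (start <= t.episode_onset and t.episode_end <= horizon_end):
            raise ValueError("truth episode outside simulated horizon")
        if t.ovulation_time is not None and not (
                start <= t.ovulation_time <= horizon_end):
            raise ValueError("ovulation_time outside simulated horizon")

    rng = np.random.default_rng(seed)
    times = pd.date_range(start, periods=n_days * 24, freq="h")
    hrs = ((times - start) / HOUR).to_numpy(dtype=float)
    hod = times.hour.to_numpy()

    temp = np.full(len(times), params.basal_temp, dtype=float)
    temp += params.circadian_amplitude * np.cos(
        2 * np.pi * (hod - params.circadian_acrophase_h) / 24)
    if params.noise_sd > 0:
        temp += rng.normal(0.0, params.noise_sd, size=len(times))

    # drinking bouts: full depth at the first hourly sample at/after the bout,
    # exponential recovery from that sample onward
    deficit = np.zeros(len(times))
    if params.drink_rate > 0 and params.drink_depth < 0:
        for d in range(n_days):
            for _ in range(rng.poisson(params.drink_rate)):
                bout_h = d * 24 + rng.uniform(5.0, 22.0)
                i0 = int(np.ceil(bout_h))
                if i0 >= len(times):
                    continue
                span = np.arange(i0, min(i0 + 9, len(times)))
                deficit[span] += params.drink_depth * np.exp(
                    -(span - i0) / params.drink_recovery)
    temp += deficit
    drink_transient = np.abs(deficit) > DRINK_TRUTH_TOL

    # estrus rises and ovulation dips
    for t in truths:
        dur = (t.episode_end - t.episode_onset) / HOUR
        center = (t.episode_onset - start) / HOUR + dur / 2
        center = round(center)  # land the peak on an hourly sample
        temp += _raised_cosine(hrs - center, t.injected_rise_amp, dur)
        if t.ovulation_time is not None and t.injected_dip_amp != 0:
            c_ov = round((t.ovulation_time - start) / HOUR)
            temp += _raised_cosine(hrs - c_ov, t.injected_dip_amp,
                                   params.ovulation_dip_duration)

    rrt = pd.DataFrame({"cow_id": truths[0].cow_id if truths else "cow",
                        "timestamp": times, "temp_c": temp,
                        "drink_transient": drink_transient})

    # activity: 2 h blocks, quiescent baseline uniform 5-30, episodes shaped
    # so blocks starting in [onset, end) are >= 35 with maximum exactly the
    # injected peak
    block_starts = pd.date_range(start, periods=n_days * 24 // BLOCK_H,
                                 freq=f"{BLOCK_H}h")
    index = rng.uniform(5, 30, size=len(block_starts)).round().astype(int)
    for t in truths:
        in_ep = (block_starts >= t.episode_onset) & (block_starts < t.episode_end)
        idx = np.flatnonzero(in_ep)
        m = len(idx)
        if m == 0:
            continue
        if m == 1:
            index[idx] = t.true_peak_index
        else:
            j = np.arange(m, dtype=float)
            tri = 1 - np.abs(j - (m - 1) / 2) / ((m - 1) / 2)
            prof = np.round(35 + (t.true_peak_index - 35) * tri).astype(int)
            prof = np.clip(prof, 35, t.true_peak_index)
            prof[int((m - 1) // 2)] = t.true_peak_index
            index[idx] = prof
    activity = pd.DataFrame({"cow_id": truths[0].cow_id if truths else "cow",
                             "block_start": block_starts, "index": index})
    return rrt, activity


# ---------------------------------------------------------------------------
# herd
# ---------------------------------------------------------------------------

def _exam_times_after(t: pd.Timestamp, n: int) -> list[pd.Timestamp]:
    """First ``n`` twice-daily exam slots (08:00 / 17:00) at/after ``t``."""
    slots: list[pd.Timestamp] = []
    day = t.normalize()
    while len(slots) < n:
        for h in (8, 17):
            s = day + pd.Timedelta(hours=h)
            if s >= t:
                slots.append(s)
                if len(slots) == n:
                    break
        day += pd.Timedelta(days=1)
    return slots


def _fmt_diams(diams: Sequence[float]) -> str:
    return ";".join(f"{d:.1f}" for d in diams)


def simulate_herd(config: HerdConfig,
                  out_dir: str | Path | None = None) -> HerdData:
    """Generate the full herd dataset (weather, RRT, activity, exams, truth).

    Episode statuses are assigned by the configured fractions: false alerts
    carry no pre-ovulatory follicle and no thermal signature; ovulated events
    get an ovulation time 24-32 h after episode onset, bracketed by the exam
    pair around it; late/failed events keep their follicle through all six
    exams and differ only in the day-7 CL. When ``out_dir`` is given the five
    CSV tables are written there.
    """
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.n_cows + 2)
    rng = np.random.default_rng(child[0])
    weather = simulate_weather(config.n_days, seed=child[1],
                               summer_fraction=config.summer_fraction,
                               start=config.start)
    hot_dates = _high_thi_dates(weather)
    start = pd.Timestamp(config.start)
    p = config.signal

    rrt_parts, act_parts, exam_rows, truth_rows = [], [], [], []
    for i in range(config.n_cows):
        cow_rng = np.random.default_rng(child[i + 2])
        cow_id = f"cow{i + 1:04d}"
        truths: list[TruthRecord] = []
        last_end_day = 5
        for _ in range(config.episodes_per_cow):
            day0 = int(cow_rng.integers(max(6, last_end_day + 1),
                                        max(7, config.n_days - 10)))
            onset = start + pd.Timedelta(days=day0,
                                         hours=int(cow_rng.integers(0, 12)) * 2)
            dur = int(cow_rng.choice(config.duration_choices))
            end = onset + pd.Timedelta(hours=dur)
            peak = int(np.clip(round(cow_rng.normal(80, 12)), 40, 100))

            u = cow_rng.random()
            if u < config.false_fraction:
                status = "false"
            elif u < config.false_fraction + config.failed_fraction:
                status = "failed"
            elif u < (config.false_fraction + config.failed_fraction
                      + config.late_fraction):
                status = "late"
            else:
                status = "ovulated"

            ovulated = status == "ovulated"
            ov_time = (onset + pd.Timedelta(hours=float(cow_rng.uniform(24, 32)))
                       if ovulated else None)
            rise = 0.0 if status == "false" else p.estrus_rise_amp
            if rise and onset.date() in hot_dates:
                rise *= 1 + p.thi_coupling
            dip = p.ovulation_dip_amp if ovulated else 0.0
            truths.append(TruthRecord(
                cow_id=cow_id, episode_onset=onset, episode_end=end,
                true_peak_index=peak, ovulation_time=ov_time,
                ovulated=ovulated, injected_rise_amp=rise,
                injected_dip_amp=dip, is_false_alert=status == "false",
                status=status))
            last_end_day = day0 + 2

        rrt, act = simulate_cow(p, truths, seed=int(cow_rng.integers(2**31)),
                                start=start, n_days=config.n_days)

        # missingness: drop rows entirely (gaps, carried not imputed)
        drop = cow_rng.random(len(rrt)) < config.missing_rate
        for t in truths:
            if cow_rng.random() < config.heavy_missing_fraction:
                win = (rrt["timestamp"] >= t.episode_onset) & \
                      (rrt["timestamp"] <= t.episode_end)
                heavy = cow_rng.random(len(rrt)) < 0.40
                drop |= (win.to_numpy() & heavy)
        rrt = rrt.loc[~drop]
        rrt_parts.append(rrt)
        act_parts.append(act)

        # ultrasound exams
        for t in truths:
            slots = _exam_times_after(t.episode_onset, 6)
            fol = float(cow_rng.uniform(16.5, 19.5))
            old_cl = float(cow_rng.uniform(6, 12))
            disappeared = False
            for k, s in enumerate(slots):
                if t.status == "false":
                    fols = [float(cow_rng.uniform(8, 13)),
                            float(cow_rng.uniform(5, 8))]
                    exam_rows.append((cow_id, s, _fmt_diams(sorted(fols, reverse=True)),
                                      _fmt_diams([old_cl]), False))
                    break  # classified false at the alert exam; no follow-up
                if t.ovulated and t.ovulation_time is not None and s > t.ovulation_time:
                    disappeared = True
                    fols = [float(cow_rng.uniform(8, 11)),
                            float(cow_rng.uniform(5, 8))]
                else:
                    fols = [fol + 0.3 * k, float(cow_rng.uniform(8, 12)),
                            float(cow_rng.uniform(5, 8))]
                exam_rows.append((cow_id, s, _fmt_diams(fols),
                                  _fmt_diams([old_cl]), False))
                if disappeared:
                    break
            # day-7 confirmation scan after the last scheduled scan
            if t.status != "false":
                day7 = slots[-1] + pd.Timedelta(days=7)
                cl = [float(cow_rng.uniform(22, 28))] if t.status in (
                    "ovulated", "late") else []
                exam_rows.append((cow_id, day7, _fmt_diams(
                    [float(cow_rng.uniform(8, 12))]), _fmt_diams(cl), True))
        truth_rows.extend(truths)

    truth = pd.DataFrame([{
        "cow_id": t.cow_id, "episode_onset": t.episode_onset,
        "episode_end": t.episode_end, "true_peak_index": t.true_peak_index,
        "ovulation_time": t.ovulation_time, "ovulated": t.ovulated,
        "injected_rise_amp": t.injected_rise_amp,
        "injected_dip_amp": t.injected_dip_amp,
        "is_false_alert": t.is_false_alert, "status": t.status,
    } for t in truth_rows])
    exams = pd.DataFrame(exam_rows, columns=[
        "cow_id", "exam_time", "follicle_diams", "cl_diams", "day7"])
    data = HerdData(weather=weather,
                    rrt=pd.concat(rrt_parts, ignore_index=True),
                    activity=pd.concat(act_parts, ignore_index=True),
                    exams=exams.sort_values(["cow_id", "exam_time"],
                                            kind="stable").reset_index(drop=True),
                    truth=truth)
    if out_dir is not None:
        data.write(out_dir)
    return data
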