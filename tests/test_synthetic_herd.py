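"""Generator contracts: determinism, injected-signal recovery, bracketing."""

import numpy as np
import pandas as pd
import pytest

from bovitherm import (HerdConfig, SignalParams, TruthRecord, simulate_cow,
                       simulate_herd, simulate_weather, thi)

START = pd.Timestamp("2021-06-01")


def quiet_params(**kw):
    base = dict(circadian_amplitude=0.0, noise_sd=0.0, drink_rate=0.0,
                estrus_rise_amp=0.0, ovulation_dip_amp=0.0)
    base.update(kw)
    return SignalParams(**base)


def one_truth(rise=0.0, dip=0.0, peak=85, ovulated=False):
    onset = START + pd.Timedelta(days=6)
    return TruthRecord(
        cow_id="c1", episode_onset=onset,
        episode_end=onset + pd.Timedelta(hours=12), true_peak_index=peak,
        ovulation_time=onset + pd.Timedelta(hours=28) if ovulated else None,
        ovulated=ovulated, injected_rise_amp=rise, injected_dip_amp=dip)


class TestWeather:
    def test_no_summer_days_stay_below_heat_stress(self):
        w = simulate_weather(1, seed=0, summer_fraction=0.0)
        assert len(w) == 24
        assert (thi(w["air_temp_c"].to_numpy(),
                    w["rel_humidity"].to_numpy()) < 72).all()

    def test_summer_fraction_sets_count_of_hot_days(self):
        w = simulate_weather(10, seed=1, summer_fraction=0.5)
        vals = thi(w["air_temp_c"].to_numpy(), w["rel_humidity"].to_numpy())
        daily_max = pd.Series(vals).groupby(w["timestamp"].dt.date).max()
        assert (daily_max > 72).sum() == 5

    def test_deterministic_under_fixed_seed(self):
        a = simulate_weather(5, seed=42, summer_fraction=0.3)
        b = simulate_weather(5, seed=42, summer_fraction=0.3)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_nonpositive_days(self):
        with pytest.raises(ValueError):
            simulate_weather(0, seed=0)


class TestSignalParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SignalParams(noise_sd=-0.1)
        with pytest.raises(ValueError):
            SignalParams(estrus_rise_duration=0)
        with pytest.raises(ValueError):
            SignalParams(drink_depth=0.5)
        with pytest.raises(ValueError):
            SignalParams(ovulation_dip_amp=0.1)


class TestSimulateCow:
    def test_all_terms_off_gives_constant_basal(self):
        rrt, _ = simulate_cow(quiet_params(), one_truth(), seed=0, start=START)
        assert np.allclose(rrt["temp_c"], 38.6)

    def test_noiseless_rise_peaks_at_injected_amplitude(self):
        rrt, _ = simulate_cow(quiet_params(), one_truth(rise=0.5), seed=0,
                              start=START)
        t = one_truth()
        win = rrt[(rrt["timestamp"] >= t.episode_onset)
                  & (rrt["timestamp"] <= t.episode_end)]
        assert win["temp_c"].max() - 38.6 == pytest.approx(0.5, abs=1e-12)
        outside = rrt[rrt["timestamp"] > t.episode_end + pd.Timedelta(hours=1)]
        assert np.allclose(outside["temp_c"], 38.6)

    def test_activity_peak_equals_injected_and_bounded_to_episode(self):
        _, act = simulate_cow(quiet_params(), one_truth(peak=85), seed=3,
                              start=START)
        t = one_truth()
        inside = act[(act["block_start"] >= t.episode_onset)
                     & (act["block_start"] < t.episode_end)]
        outside = act.drop(inside.index)
        assert inside["index"].max() == 85
        assert (inside["index"] >= 35).all()
        assert (outside["index"] < 35).all()

    def test_overlapping_episodes_rejected(self):
        a = one_truth()
        b = TruthRecord(cow_id="c1",
                        episode_onset=a.episode_onset + pd.Timedelta(hours=6),
                        episode_end=a.episode_end + pd.Timedelta(hours=12),
                        true_peak_index=60, ovulation_time=None,
                        ovulated=False, injected_rise_amp=0.0,
                        injected_dip_amp=0.0)
        with pytest.raises(ValueError, match="overlapping"):
            simulate_cow(quiet_params(), [a, b], seed=0, start=START)

    def test_truth_outside_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            simulate_cow(quiet_params(), one_truth(), seed=0, start=START,
                         n_days=5)


class TestSimulateHerd:
    def test_truth_rows_match_episode_count_and_all_ovulate(self):
        cfg = HerdConfig(n_cows=5, seed=1, false_fraction=0.0,
                         failed_fraction=0.0, late_fraction=0.0)
        data = simulate_herd(cfg)
        assert len(data.truth) == 5
        assert data.truth["ovulated"].all()

    def test_false_fraction_scales_false_episode_count(self):
        cfg = HerdConfig(n_cows=100, seed=2, false_fraction=0.2,
                         failed_fraction=0.0, late_fraction=0.0)
        data = simulate_herd(cfg)
        n_false = data.truth["is_false_alert"].sum()
        assert 10 <= n_false <= 30  # binomial(100, 0.2) within 2.5 sd

    def test_every_ovulation_bracketed_by_follicle_disappearance(self):
        cfg = HerdConfig(n_cows=20, seed=5, false_fraction=0.0,
                         failed_fraction=0.0, late_fraction=0.0)
        data = simulate_herd(cfg)
        serial = data.exams[~data.exams["day7"]]
        for _, t in data.truth.iterrows():
            ex = serial[serial["cow_id"] == t["cow_id"]].sort_values("exam_time")
            before = ex[ex["exam_time"] < t["ovulation_time"]]
            after = ex[ex["exam_time"] > t["ovulation_time"]]
            assert len(before) and len(after)
            # dominant follicle (>15 mm) present right before, gone right after
            last_before = str(before.iloc[-1]["follicle_diams"])
            first_after = str(after.iloc[0]["follicle_diams"])
            assert max(float(x) for x in last_before.split(";")) > 15
            assert max(float(x) for x in first_after.split(";")) < 15

    def test_fixed_seed_gives_byte_identical_tables(self, tmp_path):
        cfg = HerdConfig(n_cows=4, seed=9)
        simulate_herd(cfg, out_dir=tmp_path / "a")
        simulate_herd(cfg, out_dir=tmp_path / "b")
        for name in ("weather", "rrt", "activity", "exams", "truth"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == \
                (tmp_path / "b" / f"{name}.csv").read_bytes()
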