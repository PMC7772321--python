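"""Water-intake correction, trailing baseline, and standardisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bovitherm import (HerdConfig, SignalParams, correct_water_intake,
                       ensure_hourly_grid, rolling_baseline, simulate_cow,
                       simulate_herd, standardize)
from tests.test_synthetic_herd import START, one_truth, quiet_params


def series_of(temps, start="2021-06-01"):
    ts = pd.date_range(start, periods=len(temps), freq="h")
    return ensure_hourly_grid(pd.DataFrame({"timestamp": ts,
                                            "temp_c": list(temps)}))


class TestWaterCorrection:
    def test_constant_series_flags_nothing(self):
        out = correct_water_intake(series_of([38.6] * 10))
        assert not out["water_flagged"].any()

    def test_drop_and_partial_recovery_flagged_full_recovery_kept(self):
        out = correct_water_intake(
            series_of([38.6, 38.6, 38.6, 37.0, 37.9, 38.6, 38.6]),
            drop_threshold=0.8)
        assert out["water_flagged"].tolist() == [False, False, False, True,
                                                 True, False, False]
        # temperatures untouched, only flags set
        assert out["temp_c"].tolist()[3] == 37.0

    def test_drop_below_threshold_untouched(self):
        out = correct_water_intake(
            series_of([38.6, 38.6, 38.6, 38.1, 38.6]), drop_threshold=0.8)
        assert not out["water_flagged"].any()

    def test_recovery_limit_ends_transient(self):
        # never returns near baseline: flags stop once 3 h have elapsed
        out = correct_water_intake(
            series_of([38.6, 38.6, 38.6, 37.0, 37.1, 37.2, 37.3, 37.3]),
            drop_threshold=0.8, recovery_limit=3.0)
        assert out["water_flagged"].tolist()[3:6] == [True, True, True]
        assert not out["water_flagged"].tolist()[6]

    @pytest.mark.parametrize("temps", [
        [38.6, 38.6, 38.6, 37.0, 37.9, 38.6, 38.6],
        [38.6, 38.6, 38.6, 37.0, 37.1, 37.2, 37.3, 37.3],  # timeout release
    ])
    def test_idempotent(self, temps):
        first = correct_water_intake(series_of(temps))
        second = correct_water_intake(first)
        assert not second["water_flagged"].any()
        pd.testing.assert_series_equal(first["valid"], second["valid"])

    def test_too_few_valid_readings_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = correct_water_intake(series_of([38.6, 38.5]))
        assert out["valid"].sum() == 2

    def test_recovers_most_injected_transients_on_synthetic_cow(self):
        # default noise/drinking parameters over a long horizon
        params = SignalParams(estrus_rise_amp=0.0, ovulation_dip_amp=0.0)
        rrt, _ = simulate_cow(params, one_truth(), seed=11, start=START,
                              n_days=90)
        out = correct_water_intake(ensure_hourly_grid(rrt))
        truth = rrt.set_index("timestamp")["drink_transient"]
        flagged = out.set_index("timestamp")["water_flagged"]
        recall = flagged[truth[truth].index].mean()
        assert truth.sum() > 20
        assert recall >= 0.90


class TestRollingBaseline:
    def test_constant_series_recovers_constant_with_zero_sd(self):
        b = rolling_baseline(series_of([38.6] * 144))
        defined = b.dropna(subset=["baseline_mean"])
        assert len(defined) > 0
        assert np.allclose(defined["baseline_mean"], 38.6)
        assert np.allclose(defined["baseline_sd"], 0.0)

    def test_alternating_series_population_sd(self):
        temps = [38.5 if i % 2 == 0 else 38.7 for i in range(121)]
        b = rolling_baseline(series_of(temps), min_window_points=120)
        assert b["baseline_mean"].iloc[120] == pytest.approx(38.6)
        assert b["baseline_sd"].iloc[120] == pytest.approx(0.1)

    def test_undefined_before_min_window_points(self):
        b = rolling_baseline(series_of([38.6] * 130), min_window_points=120)
        assert b["baseline_mean"].iloc[:120].isna().all()
        assert b["baseline_mean"].iloc[120:].notna().all()

    def test_window_excludes_current_reading(self):
        temps = [38.6] * 120 + [40.0]
        b = rolling_baseline(series_of(temps), min_window_points=120)
        assert b["baseline_mean"].iloc[120] == pytest.approx(38.6)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            rolling_baseline(series_of([38.6] * 10), window_h=0)

    def test_hour_matched_variant_on_constant_series(self):
        b = rolling_baseline(series_of([38.6] * (24 * 7)), hour_matched=True,
                             min_window_points=5)
        defined = b.dropna(subset=["baseline_mean"])
        assert np.allclose(defined["baseline_mean"], 38.6)
        assert defined["n_used"].max() == 5


class TestStandardize:
    @pytest.mark.parametrize("temp,mean,sd,expect", [
        (39.2, 38.6, 0.3, 2.0),    # plain arithmetic
        (38.6, 38.6, 0.3, 0.0),    # reading equals baseline
        (38.7, 38.6, 0.0, 2.0),    # sd floor (0.05) engages
    ])
    def test_z_score_arithmetic(self, temp, mean, sd, expect):
        s = series_of([temp])
        b = pd.DataFrame({"timestamp": s["timestamp"],
                          "baseline_mean": [mean], "baseline_sd": [sd]})
        z = standardize(s, b, sd_floor=0.05)
        assert z["z"].iloc[0] == pytest.approx(expect)

    def test_invalid_readings_propagate_nan(self):
        s = series_of([38.6, np.nan, 38.6])
        b = pd.DataFrame({"timestamp": s["timestamp"],
                          "baseline_mean": 38.0, "baseline_sd": 0.2})
        z = standardize(s, b)
        assert np.isnan(z["z"].iloc[1]) and z["z"].notna().sum() == 2

    @given(shift=st.floats(-5, 5), seed=st.integers(0, 100))
    @settings(max_examples=20, deadline=None)
    def test_shift_invariance(self, shift, seed):
        """Adding a constant to the whole series leaves z unchanged."""
        rng = np.random.default_rng(seed)
        temps = 38.6 + rng.normal(0, 0.2, size=150)
        s1 = series_of(temps)
        s2 = series_of(temps + shift)
        z1 = standardize(s1, rolling_baseline(s1))
        z2 = standardize(s2, rolling_baseline(s2))
        np.testing.assert_allclose(z1["z"], z2["z"], atol=1e-9)
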