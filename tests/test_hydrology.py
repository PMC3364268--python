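"""Flooding arithmetic and the two-condition subsidy classification."""

import numpy as np
import pandas as pd
import pytest

from marshpulse.hydrology import (PulseWindow, classify_sample,
                                  classify_samples, depth_at,
                                  flooded_fraction, inflow_daily_mean_depth,
                                  reference_max_mean_depth)
from marshpulse.synthetic import (default_community_config,
                                  default_hydro_config,
                                  default_pulse_windows,
                                  generate_sampling_campaign,
                                  generate_water_levels)

from conftest import make_series


class TestDepthAt:
    def test_stage_at_marsh_elevation_is_dry(self):
        s = make_series([100.0, 100.0, 100.0], elev=100.0)
        assert depth_at(s, s.times[1]) == 0.0

    def test_constant_offset(self):
        s = make_series([350.0] * 5, elev=100.0)
        assert depth_at(s, s.times[2]) == 250.0

    def test_halfway_tie_goes_to_earlier_reading(self):
        s = make_series([100.0, 300.0], elev=0.0)
        midpoint = s.times[0] + pd.Timedelta(minutes=30)
        assert depth_at(s, midpoint) == 100.0

    def test_nearest_reading_lookup(self):
        s = make_series([100.0, 300.0], elev=0.0)
        assert depth_at(s, s.times[0] + pd.Timedelta(minutes=40)) == 300.0
        assert depth_at(s, s.times[0] + pd.Timedelta(minutes=20)) == 100.0

    def test_outside_span_raises(self):
        s = make_series([100.0, 100.0], elev=0.0)
        with pytest.raises(ValueError, match="outside"):
            depth_at(s, s.times[0] - pd.Timedelta(hours=2))


class TestFloodedFraction:
    def test_all_above(self, two_day_window):
        s = make_series([10.0] * 48, elev=0.0)
        assert flooded_fraction(s, two_day_window) == 100.0

    def test_all_below(self, two_day_window):
        s = make_series([-10.0] * 48, elev=0.0)
        assert flooded_fraction(s, two_day_window) == 0.0

    def test_toy_count(self):
        # 10 hourly readings, 3 flooded -> 30.0%
        stages = [-1.0] * 7 + [1.0] * 3
        s = make_series(stages, elev=0.0)
        w = PulseWindow("w", s.times[0], s.times[-1] + pd.Timedelta(hours=1))
        assert flooded_fraction(s, w) == pytest.approx(30.0)

    def test_window_is_half_open(self):
        s = make_series([-1.0] * 10 + [1.0], elev=0.0)
        w = PulseWindow("w", s.times[0], s.times[10])  # excludes flooded hour
        assert flooded_fraction(s, w) == 0.0

    def test_empty_window_raises(self):
        s = make_series([0.0] * 10, elev=0.0)
        w = PulseWindow("w", pd.Timestamp("2010-01-01"),
                        pd.Timestamp("2010-01-02"))
        with pytest.raises(ValueError):
            flooded_fraction(s, w)


class TestReferenceMaxMeanDepth:
    def test_never_flooded_is_undefined(self, two_day_window):
        s = make_series([-5.0] * 48, elev=0.0)
        assert reference_max_mean_depth(s, two_day_window) is None

    def test_constant_depth(self, two_day_window):
        s = make_series([70.0] * 48, elev=0.0)
        assert reference_max_mean_depth(s, two_day_window) == pytest.approx(70.0)

    def test_daily_means_over_flooded_readings_only(self, two_day_window):
        # day 1 flooded readings {100, 300} -> 200; day 2 {50} -> 50
        stages = [100.0, 300.0] + [-10.0] * 22 + [50.0] + [-10.0] * 23
        s = make_series(stages, elev=0.0)
        assert reference_max_mean_depth(s, two_day_window) == pytest.approx(200.0)


class TestInflowDailyMean:
    def test_dry_readings_count_as_zero(self):
        stages = [200.0] * 12 + [-50.0] * 12
        s = make_series(stages, elev=0.0)
        assert inflow_daily_mean_depth(s, s.times[3]) == pytest.approx(100.0)

    def test_flooded_only_convention(self):
        stages = [200.0] * 12 + [-50.0] * 12
        s = make_series(stages, elev=0.0)
        assert inflow_daily_mean_depth(
            s, s.times[3], convention="flooded_only") == pytest.approx(200.0)


class TestClassifySample:
    def test_reference_never_flooded_gives_condition_1(self, two_day_window):
        ref = make_series([-5.0] * 48, elev=0.0, area="reference")
        inflow = make_series([100.0] * 48, elev=0.0, area="inflow")
        c = classify_sample("s1", inflow.times[10], inflow, ref,
                            two_day_window)
        assert c.subsidized and c.condition == 1
        assert c.reference_max_mean_depth is None

    def test_condition_2_when_inflow_day_exceeds_reference_max(
            self, two_day_window):
        ref = make_series([200.0] * 48, elev=0.0, area="reference")
        inflow = make_series([350.0] * 48, elev=0.0, area="inflow")
        c = classify_sample("s1", inflow.times[10], inflow, ref,
                            two_day_window)
        assert c.subsidized and c.condition == 2
        assert c.inflow_daily_mean_depth == pytest.approx(350.0)
        assert c.reference_max_mean_depth == pytest.approx(200.0)

    def test_identical_series_with_flooded_reference_is_unsubsidized(
            self, two_day_window):
        # daily mean over all readings can never strictly exceed the window
        # maximum of flooded-only daily means of the same series
        stages = ([-50.0, 150.0] * 12) + [100.0] * 24
        ref = make_series(stages, elev=0.0, area="reference")
        inflow = make_series(stages, elev=0.0, area="inflow")
        for i in range(0, 48, 5):
            if ref.depth[i] <= 0:
                continue
            c = classify_sample("s", ref.times[i], inflow, ref,
                                two_day_window)
            assert not c.subsidized

    def test_sample_outside_window_raises(self, two_day_window):
        s = make_series([100.0] * 72, elev=0.0)
        with pytest.raises(ValueError, match="outside"):
            classify_sample("s1", s.times[60], s, s, two_day_window)


@pytest.fixture(scope="module")
def campaign():
    hydro = generate_water_levels(default_hydro_config(seed=7))
    windows = default_pulse_windows()
    samples, _, _ = generate_sampling_campaign(
        default_community_config(seed=8), hydro, windows)
    return hydro, windows, samples


class TestClassificationProperties:
    def test_order_independence(self, campaign):
        (inflow, ref), windows, samples = campaign
        a = classify_samples(samples, inflow, ref, windows)
        b = classify_samples(samples.iloc[::-1], inflow, ref, windows)
        merged = a.merge(b, on="sample_id", suffixes=("_a", "_b"))
        assert (merged["subsidized_a"] == merged["subsidized_b"]).all()

    def test_monotone_in_uniform_inflow_raise(self, campaign):
        (inflow, ref), windows, samples = campaign
        base = classify_samples(samples, inflow, ref, windows)
        for dz in (25.0, 100.0, 400.0):
            raised = classify_samples(samples, inflow.shifted(dz), ref,
                                      windows)
            m = base.merge(raised, on="sample_id", suffixes=("_lo", "_hi"))
            # raising the inflow stage can only create subsidized samples
            assert not ((m["subsidized_lo"]) & (~m["subsidized_hi"])).any()

    def test_subsidized_share_in_field_consistent_band(self):
        # default configuration: pooled subsidized-sample share sits in the
        # 85-95% band typical of marsh flooding driven by a river pulse
        shares = []
        for seed in range(5):
            inflow, ref = generate_water_levels(default_hydro_config(seed))
            windows = default_pulse_windows()
            samples, _, _ = generate_sampling_campaign(
                default_community_config(seed + 101), (inflow, ref), windows)
            cls = classify_samples(samples, inflow, ref, windows)
            shares.append(100.0 * cls["subsidized"].mean())
        assert 85.0 <= np.mean(shares) <= 95.0
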