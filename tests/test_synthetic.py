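"""Generator contracts: hydrographs, campaigns, weighings, pellets."""

import numpy as np
import pandas as pd
import pytest

from marshpulse.hydrology import PulseWindow, flooded_fraction
from marshpulse.synthetic import (AllometryTruth, CalorimetryTruth,
                                  CommunityConfig, HydroConfig,
                                  SpeciesAllometryTruth,
                                  SpeciesCalorimetryTruth, SpeciesConfig,
                                  default_allometry_truth,
                                  default_community_config,
                                  default_hydro_config,
                                  default_pulse_windows,
                                  generate_pellets,
                                  generate_sampling_campaign,
                                  generate_water_levels,
                                  generate_wet_dry_individuals,
                                  residual_sd_for_r2)

WEEK = (pd.Timestamp("2005-02-01"), pd.Timestamp("2005-02-08"))


def quiet_config(**kw):
    base = dict(window_start=WEEK[0], window_end=WEEK[1],
                tidal_amplitude=0.0, met_sd=0.0, noise_sd=0.0,
                mean_stage_offset_reference=-100.0, pulse_windows=())
    base.update(kw)
    return HydroConfig(**base)


class TestWaterLevels:
    def test_all_stochastic_terms_off_gives_constant_dry_series(self):
        inflow, ref = generate_water_levels(quiet_config())
        assert np.ptp(inflow.stage) == 0 and np.ptp(ref.stage) == 0
        assert (inflow.depth < 0).all() and (ref.depth < 0).all()

    def test_forced_plateau_depth(self):
        w = (pd.Timestamp("2005-02-03"), pd.Timestamp("2005-02-05"))
        cfg = quiet_config(pulse_windows=(w,), pulse_plateau_depth=300.0,
                           pulse_ramp_hours=0.0)
        inflow, _ = generate_water_levels(cfg)
        inside = (inflow.times >= w[0]) & (inflow.times < w[1])
        assert inflow.depth[inside] == pytest.approx(300.0)
        assert (inflow.depth[~inside] < 0).all()

    def test_pure_sinusoid_floods_half_the_time(self):
        # oracle: a sinusoid about the marsh elevation is positive for half
        # of each period; count the sampled hours with sin > 0
        period = 12.42  # hourly sampling never hits an exact zero crossing
        n_hours = 1242  # 100 whole periods
        cfg = quiet_config(window_end=WEEK[0] + pd.Timedelta(hours=n_hours),
                           mean_stage_offset_reference=0.0,
                           tidal_amplitude=80.0, tidal_period=period)
        _, ref = generate_water_levels(cfg)
        w = PulseWindow("all", cfg.window_start, cfg.window_end)
        hours = np.arange(n_hours)
        oracle = 100.0 * np.mean(np.sin(2 * np.pi * hours / period) > 0)
        assert flooded_fraction(ref, w) == pytest.approx(oracle)
        assert flooded_fraction(ref, w) == pytest.approx(50.0, abs=2.0)

    def test_fixed_seed_bit_identical(self):
        cfg = default_hydro_config(seed=42)
        a = generate_water_levels(cfg)
        b = generate_water_levels(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.stage, y.stage)
            assert (x.times == y.times).all()

    def test_reference_flooding_monotone_in_offset(self):
        w = PulseWindow("feb", pd.Timestamp("2005-02-14"),
                        pd.Timestamp("2005-03-01"))
        fracs = []
        for offset in (-150.0, -75.0, 0.0, 75.0):
            cfg = default_hydro_config(seed=3)
            cfg = HydroConfig(**{**cfg.__dict__,
                                 "mean_stage_offset_reference": offset})
            _, ref = generate_water_levels(cfg)
            fracs.append(flooded_fraction(ref, w))
        assert fracs == sorted(fracs)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            HydroConfig(window_start=WEEK[1], window_end=WEEK[0])

    def test_nonpositive_tidal_period_raises(self):
        with pytest.raises(ValueError):
            quiet_config(tidal_period=0.0)


def flooded_campaign_hydro(days=10, depth=300.0):
    """Constantly flooded inflow at a fixed depth; reference dry."""
    cfg = quiet_config(window_end=WEEK[0] + pd.Timedelta(days=days),
                       pulse_windows=((WEEK[0],
                                       WEEK[0] + pd.Timedelta(days=days)),),
                       pulse_plateau_depth=depth, pulse_ramp_hours=0.0)
    return generate_water_levels(cfg), PulseWindow(
        "p", WEEK[0], WEEK[0] + pd.Timedelta(days=days))


class TestSamplingCampaign:
    def test_zero_density_gives_empty_catches(self):
        hydro, w = flooded_campaign_hydro()
        cfg = CommunityConfig(species=(SpeciesConfig(
            "sp", 0.0, 1.0, 3.0, 0.2, 1e-5, 3.0),), seed=1)
        samples, catches, _ = generate_sampling_campaign(cfg, hydro, [w])
        assert len(samples) > 0
        assert catches == []

    def test_counts_match_negative_binomial_moments(self):
        # ~1000 samples at fixed depth: mean total count within 3 SE of the
        # configured mean (depth = reference depth, so scale is 1)
        hydro, w = flooded_campaign_hydro(days=42, depth=200.0)
        sp = SpeciesConfig("sp", 12.0, 0.5, 3.0, 0.2, 1e-5, 3.0)
        cfg = CommunityConfig(species=(sp,), samples_per_day=24,
                              reference_depth_mm=200.0,
                              saturation_depth_mm=200.0, seed=2)
        samples, catches, _ = generate_sampling_campaign(cfg, hydro, [w])
        per_sample = pd.Series(0, index=samples.sample_id, dtype=float)
        for c in catches:
            per_sample[c.sample_id] += c.count
        n = len(per_sample)
        assert n >= 900
        var = 12.0 + 12.0 ** 2 / 0.5  # negative-binomial moments
        se = np.sqrt(var / n)
        assert abs(per_sample.mean() - 12.0) < 3 * se

    def test_never_flooded_window_warns_and_yields_no_samples(self, caplog):
        cfg = quiet_config()
        hydro = generate_water_levels(cfg)
        w = PulseWindow("dry", WEEK[0], WEEK[1])
        with caplog.at_level("WARNING"):
            samples, catches, truth = generate_sampling_campaign(
                default_community_config(1), hydro, [w])
        assert len(samples) == 0 and catches == []
        assert "never flooded" in caplog.text

    def test_default_campaign_is_field_scale(self):
        hydro = generate_water_levels(default_hydro_config(seed=5))
        windows = default_pulse_windows()
        samples, catches, truth = generate_sampling_campaign(
            default_community_config(seed=6), hydro, windows)
        n = samples.groupby("pulse_id").size()
        # same order as the field campaigns (n = 66 and 75)
        assert 50 <= n["February"] <= 95
        assert 50 <= n["March"] <= 95
        assert set(truth.subsidized) == set(samples.sample_id)

    def test_dominant_species_share(self):
        cfg = default_community_config(seed=9)
        dom_expected = sum(
            v for k, v in cfg.relative_abundances.items()
            if k in {"Palaemonetes paludosus", "Heterandria formosa",
                     "Gambusia affinis", "Lucania parva",
                     "Poecilia latipinna", "Cyprinodon variegatus"})
        hydro, w = flooded_campaign_hydro(days=30)
        _, catches, _ = generate_sampling_campaign(cfg, hydro, [w])
        counts = {}
        for c in catches:
            counts[c.species] = counts.get(c.species, 0) + c.count
        dom = sum(v for k, v in counts.items()
                  if k in {"Palaemonetes paludosus", "Heterandria formosa",
                           "Gambusia affinis", "Lucania parva",
                           "Poecilia latipinna", "Cyprinodon variegatus"})
        share = dom / sum(counts.values())
        assert share >= dom_expected - 0.03  # binomial slack
        assert dom_expected >= 0.90

    def test_fixed_seed_bit_identical(self):
        hydro = generate_water_levels(default_hydro_config(seed=5))
        windows = default_pulse_windows()
        cfg = default_community_config(seed=6)
        s1, c1, t1 = generate_sampling_campaign(cfg, hydro, windows)
        s2, c2, t2 = generate_sampling_campaign(cfg, hydro, windows)
        pd.testing.assert_frame_equal(s1, s2)
        assert c1 == c2
        assert t1.subsidized == t2.subsidized


class TestWetDryGenerator:
    def test_noise_off_exact_line(self):
        truth = AllometryTruth(species=(SpeciesAllometryTruth(
            "sp", 0.2, 0.0, 0.0, 5, ww_min=1.0, ww_max=1.0000001),), seed=3)
        recs = generate_wet_dry_individuals(truth)
        for r in recs:
            assert r.dry_g == pytest.approx(0.2 * r.wet_g, rel=1e-6)

    def test_all_dry_below_wet(self):
        truth = default_allometry_truth(seed=4)
        for seed in range(3):
            recs = generate_wet_dry_individuals(truth, seed=seed)
            assert all(0 < r.dry_g < r.wet_g for r in recs)

    def test_fixed_seed_bit_identical(self):
        truth = default_allometry_truth(seed=4)
        assert generate_wet_dry_individuals(truth) == \
            generate_wet_dry_individuals(truth)

    def test_too_few_individuals_raises(self):
        truth = AllometryTruth(species=(SpeciesAllometryTruth(
            "sp", 0.2, 0.0, 0.01, 2),))
        with pytest.raises(ValueError, match=">= 3"):
            generate_wet_dry_individuals(truth)

    def test_slope_recovery_near_truth(self):
        # regeneration + refit recovers the configured line
        from marshpulse.allometry import fit_wet_dry
        truth = default_allometry_truth(seed=10)
        recs = generate_wet_dry_individuals(truth)
        target = truth.by_name()["Poecilia latipinna"]
        sp_recs = [r for r in recs if r.species == "Poecilia latipinna"]
        m = fit_wet_dry(sp_recs)
        assert m.slope == pytest.approx(target.true_slope, abs=0.02)


class TestPelletGenerator:
    def test_zero_sd_exact(self):
        truth = CalorimetryTruth(species=(SpeciesCalorimetryTruth(
            "sp", 6141.85, 0.0, 3),))
        recs = generate_pellets(truth)
        assert [r.energy for r in recs] == [6141.85] * 3

    def test_many_pellets_mean_within_3se(self):
        truth = CalorimetryTruth(species=(SpeciesCalorimetryTruth(
            "sp", 6141.85, 127.3, 500),), seed=6)
        vals = np.array([r.energy for r in generate_pellets(truth)])
        assert abs(vals.mean() - 6141.85) < 3 * 127.3 / np.sqrt(500)

    def test_single_pellet(self):
        truth = CalorimetryTruth(species=(SpeciesCalorimetryTruth(
            "sp", 5421.80, 20.0, 1),), seed=7)
        recs = generate_pellets(truth)
        assert len(recs) == 1 and recs[0].energy > 0

    def test_fixed_seed_bit_identical(self):
        truth = default_calorimetry_truth = None
        from marshpulse.synthetic import default_calorimetry_truth as dct
        truth = dct(seed=8)
        assert generate_pellets(truth) == generate_pellets(truth)


def test_residual_sd_matches_target_r2():
    # generated data refit at scale should show roughly the requested r²
    from marshpulse.allometry import fit_wet_dry
    sd = residual_sd_for_r2(0.2, 0.05, 1.0, 0.9)
    truth = AllometryTruth(species=(SpeciesAllometryTruth(
        "sp", 0.2, 0.0, sd, 3000, ww_min=0.05, ww_max=1.0),), seed=12)
    m = fit_wet_dry(generate_wet_dry_individuals(truth))
    assert m.r_squared == pytest.approx(0.9, abs=0.05)
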