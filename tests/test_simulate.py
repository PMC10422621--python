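"""Synthetic stands, disturbance bookkeeping, and the survey simulator."""

import numpy as np
import pytest
from scipy import stats

from necroscan import (
    DisturbanceParams,
    GridSpec,
    SensorParams,
    StandParams,
    apply_disturbance,
    compute_grid_metrics,
    normalize_heights,
    simulate_stand,
    simulate_survey,
)
from necroscan.simulate import crown_radius


class TestStand:
    def test_same_seed_identical_stand(self):
        params = StandParams(seed=7, extent=(50.0, 50.0))
        a = simulate_stand(params)
        b = simulate_stand(params)
        assert a.trees.equals(b.trees)

    def test_stem_count_in_poisson_interval(self):
        """Realized counts on 1 ha stay within the 99% Poisson band of the
        requested density across many replicates."""
        lam = 1000.0
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        counts = [
            len(simulate_stand(StandParams(stems_per_ha=lam, extent=(100.0, 100.0),
                                           seed=s)))
            for s in range(60)
        ]
        inside = sum(lo <= c <= hi for c in counts)
        assert inside >= 57  # ~99% of 60, allowing a single excursion

    def test_pure_species_mix(self):
        stand = simulate_stand(StandParams(species_mix=(1.0, 0.0, 0.0), seed=3,
                                           extent=(50.0, 50.0)))
        assert (stand.trees["species"] == "red").all()

    def test_dbh_truncated_at_census_threshold(self):
        stand = simulate_stand(StandParams(seed=11, extent=(50.0, 50.0)))
        assert (stand.trees["dbh"] >= 5.0).all()

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            StandParams(species_mix=(0.5, 0.2, 0.2))


class TestDisturbance:
    def test_zero_mortality_no_necromass(self):
        stand = simulate_stand(StandParams(seed=5, extent=(50.0, 50.0)))
        out = apply_disturbance(stand, DisturbanceParams(mortality_fraction=0.0, seed=5))
        assert out.true_masses().agn == 0.0

    def test_full_mortality_converts_all_biomass(self):
        stand = simulate_stand(StandParams(seed=5, extent=(50.0, 50.0)))
        before = stand.true_masses()
        out = apply_disturbance(stand, DisturbanceParams(mortality_fraction=1.0, seed=5))
        after = out.true_masses()
        assert after.agb == 0.0
        assert after.agn == pytest.approx(before.agb, rel=1e-12)

    def test_total_mass_conserved_exactly(self):
        stand = simulate_stand(StandParams(seed=9, extent=(60.0, 60.0)))
        before = stand.true_masses()
        out = apply_disturbance(stand, DisturbanceParams(mortality_fraction=0.4, seed=9))
        after = out.true_masses()
        assert after.agb + after.agn == pytest.approx(before.agb, rel=1e-12)

    def test_mortality_29pct_gives_matching_mass_fraction(self):
        """Killing 29% of stems at random converts roughly 29% of total
        mass to necromass on a large stand (law of large numbers)."""
        stand = simulate_stand(StandParams(seed=2, extent=(150.0, 150.0)))
        out = apply_disturbance(stand, DisturbanceParams(mortality_fraction=0.29, seed=2))
        m = out.true_masses()
        assert m.agn / m.agtm == pytest.approx(0.29, abs=0.06)

    def test_exact_dead_count(self):
        stand = simulate_stand(StandParams(seed=5, extent=(50.0, 50.0)))
        out = apply_disturbance(stand, DisturbanceParams(mortality_fraction=0.3, seed=1))
        assert (out.trees["status"] == "dead").sum() == int(0.3 * len(stand))


class TestSurvey:
    def test_same_seed_byte_identical_cloud(self):
        stand = simulate_stand(StandParams(seed=4, extent=(40.0, 40.0)))
        sensor = SensorParams(pulses_per_m2=8.0, seed=4)
        a = simulate_survey(stand, sensor)
        b = simulate_survey(stand, sensor)
        assert a.points.equals(b.points)

    def test_treeless_ground_has_no_canopy_returns(self):
        stand = simulate_stand(StandParams(stems_per_ha=1e-6, seed=1,
                                           extent=(40.0, 40.0)))
        stand.trees = stand.trees.iloc[0:0]
        cloud = simulate_survey(stand, SensorParams(pulses_per_m2=4.0, seed=1))
        assert cloud.points["ground"].all()

    def test_closed_canopy_fcover_near_one(self):
        stand = simulate_stand(StandParams(seed=6, extent=(52.0, 52.0)))
        cloud = simulate_survey(stand, SensorParams(pulses_per_m2=12.0, seed=6))
        norm = normalize_heights(cloud, ground="classified_returns")
        grid = GridSpec.from_extent(0, 0, 52, 52, 13.0)
        fc = compute_grid_metrics(norm, grid)["FCover"].values
        assert np.nanmean(fc) > 0.85

    def test_return_volume_matches_survey_magnitudes(self):
        """At the default pulse density, a closed-canopy 10 x 10 m plot
        yields several thousand returns, the magnitude of real plot
        extractions (~1600-5000 per plot)."""
        from necroscan import clip_rectangle

        stand = simulate_stand(StandParams(seed=8, extent=(40.0, 40.0)))
        cloud = simulate_survey(stand, SensorParams(seed=8))
        plot = clip_rectangle(cloud, (20.0, 20.0), side=10.0)
        assert 1500 <= len(plot) <= 6000

    def test_defoliation_shifts_profile_downward(self):
        """Post-storm return-height distribution has a lower first moment."""
        from necroscan import vertical_profile

        stand = simulate_stand(StandParams(seed=10, extent=(40.0, 40.0)))
        dist = DisturbanceParams(mortality_fraction=0.5, defoliation_fraction=0.9,
                                 seed=10)
        disturbed = apply_disturbance(stand, dist)
        sensor = SensorParams(pulses_per_m2=8.0, seed=10)
        pre = normalize_heights(simulate_survey(stand, sensor),
                                ground="classified_returns")
        post = normalize_heights(simulate_survey(disturbed, sensor, dist),
                                 ground="classified_returns")

        def first_moment(cloud):
            prof = vertical_profile(cloud, 1.0)
            mid = (prof["bin_low"] + prof["bin_high"]) / 2
            return np.average(mid, weights=prof["count"])

        assert first_moment(post) < first_moment(pre)

    def test_fcover_decreases_with_mortality(self):
        """Mean post-storm F-Cover falls strictly as imposed mortality
        rises, averaged over seeds."""
        mortalities = [0.1, 0.3, 0.5, 0.7]
        means = []
        for m in mortalities:
            vals = []
            for seed in (21, 22, 23):
                stand = simulate_stand(StandParams(seed=seed, extent=(39.0, 39.0)))
                dist = DisturbanceParams(mortality_fraction=m,
                                         defoliation_fraction=0.9, seed=seed)
                disturbed = apply_disturbance(stand, dist)
                cloud = simulate_survey(
                    disturbed, SensorParams(pulses_per_m2=8.0, seed=seed), dist
                )
                norm = normalize_heights(cloud, ground="classified_returns")
                grid = GridSpec.from_extent(0, 0, 39, 39, 13.0)
                fc = compute_grid_metrics(norm, grid)["FCover"].values
                vals.append(np.nanmean(fc))
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_sensor_stream_independent_of_stand_stream(self):
        """Changing only the sensor seed leaves the stand unchanged."""
        params = StandParams(seed=12, extent=(40.0, 40.0))
        stand = simulate_stand(params)
        a = simulate_survey(stand, SensorParams(pulses_per_m2=4.0, seed=1))
        b = simulate_survey(stand, SensorParams(pulses_per_m2=4.0, seed=2))
        assert not a.points.equals(b.points)
        assert simulate_stand(params).trees.equals(stand.trees)

    def test_crown_radius_monotone_in_dbh(self):
        d = np.array([5.0, 20.0, 60.0])
        r = crown_radius(d)
        assert (np.diff(r) > 0).all()
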