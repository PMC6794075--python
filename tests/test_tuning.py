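"""Direction tuning, selectivity gating, interpolation, population curves."""

import numpy as np
import pytest

from reachprior import tuning as T


class TestDTV:
    def test_symmetric_rates_zero_vector(self):
        vec, ang = T.directional_tuning_vector(np.array([10.0, 10, 10, 10]))
        assert np.allclose(vec, 0.0)
        assert ang is None

    def test_single_direction(self):
        vec, ang = T.directional_tuning_vector(np.array([10.0, 0, 0, 0]))
        np.testing.assert_allclose(vec, [10.0, 0.0], atol=1e-12)
        assert ang == pytest.approx(0.0)

    def test_vector_sum_example(self):
        vec, ang = T.directional_tuning_vector(np.array([8.0, 4, 2, 4]))
        np.testing.assert_allclose(vec, [6.0, 0.0], atol=1e-12)
        assert ang == pytest.approx(0.0)

    def test_pd_max_tie_broken_toward_dtv(self):
        # 0 and 90 tie for the max; the DTV points between, nearer 90
        rates = np.array([10.0, 10.0, 0.0, 6.0])
        vec, ang = T.directional_tuning_vector(rates)
        pdm = T.pd_max_of(rates, ang)
        assert pdm == (0.0 if ang < 45 else 90.0)


class TestSelectivity:
    def test_degenerate_equal_values(self):
        groups = [np.full(5, 3.0) for _ in range(4)]
        assert T.selectivity_test(groups) == 1.0

    def test_insufficient_trials_gated_out(self):
        groups = [np.array([1.0]), np.ones(3), np.ones(3), np.ones(3)]
        assert T.selectivity_test(groups) is None

    def test_type_i_rate(self, rng):
        """Under exchangeable groups the Kruskal-Wallis test rejects at
        roughly the nominal rate."""
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = [rng.normal(10, 2, 8) for _ in range(4)]
            if T.selectivity_test(groups) < 0.05:
                hits += 1
        assert abs(hits / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_power_with_shifted_group(self, rng):
        """A +20 Hz shift in one direction at 12 trials/group is detected at
        p < 0.01 nearly always."""
        hits = 0
        for _ in range(50):
            groups = [rng.normal(10, 3, 12) for _ in range(3)]
            groups.append(rng.normal(30, 3, 12))
            if T.selectivity_test(groups) < 0.01:
                hits += 1
        assert hits >= 45


class TestInterpolation:
    def test_constant(self):
        theta = np.linspace(0, 360, 100)
        np.testing.assert_allclose(
            T.interpolate_tuning(np.full(4, 5.0), theta), 5.0, atol=1e-12
        )

    def test_cosine_reconstruction(self):
        """Samples of cos(theta) reconstruct cos(theta) everywhere."""
        theta = np.linspace(0, 360, 721)
        vals = T.interpolate_tuning(np.array([1.0, 0.0, -1.0, 0.0]), theta)
        np.testing.assert_allclose(vals, np.cos(np.deg2rad(theta)), atol=1e-12)

    def test_passes_through_samples(self, rng):
        for _ in range(20):
            r = rng.uniform(0, 30, 4)
            vals = T.interpolate_tuning(r, np.array([0.0, 90.0, 180.0, 270.0]))
            np.testing.assert_allclose(vals, r, atol=1e-9)


class TestGating:
    def test_gate_separates_classes(self, small_session):
        """Tuned synthetic units pass the motor-goal gate; untuned units and
        low-rate units fail."""
        gated = T.gate_motor_goal_units(small_session)
        by_class = gated.groupby("truth_klass")["is_motor_goal"].mean()
        assert by_class["untuned"] == 0.0
        assert by_class["UR"] > 0.9
        assert by_class["DR"] > 0.9

    def test_rate_gate(self, small_session):
        gated = T.gate_motor_goal_units(small_session, rate_gate_hz=1e6)
        assert not gated["is_motor_goal"].any()

    def test_estimated_pd_matches_truth(self, small_session):
        gated = T.gate_motor_goal_units(small_session)
        g = gated[gated["is_motor_goal"]]
        assert (g["pd_max"] == g["truth_pd"]).mean() > 0.95


class TestPopulationTuning:
    def test_normalization_anchor(self, small_session):
        """The full-prior population curve peaks at 1 at the aligned PD."""
        gated = T.gate_motor_goal_units(small_session)
        cond = T.planning_rate_conditions(small_session, gated)
        # restrict to UR units, which carry a single PD lobe at full prior
        ur = gated[(gated["is_motor_goal"]) & (gated["truth_klass"] == "UR")]
        sub = cond[cond["unit_id"].isin(ur["unit_id"])]
        dirs, mean, se, n = T.population_tuning(sub, 0.75)
        assert mean[0] == pytest.approx(1.0, abs=1e-9)
        assert mean[0] == mean.max()

    def test_dr_zero_prior_bilobed(self, small_session):
        """DR population tuning in zero-prior trials has lobes at 0 and 180
        degrees above the orthogonal directions (choice-set co-encoding)."""
        gated = T.gate_motor_goal_units(small_session)
        cond = T.planning_rate_conditions(small_session, gated)
        dr = gated[(gated["is_motor_goal"]) & (gated["truth_klass"] == "DR")]
        sub = cond[cond["unit_id"].isin(dr["unit_id"])]
        dirs, mean, se, n = T.population_tuning(sub, 0.0)
        assert mean[0] > mean[1] and mean[0] > mean[3]
        assert mean[2] > mean[1] and mean[2] > mean[3]

    def test_single_unit_population_is_own_curve(self, small_session):
        gated = T.gate_motor_goal_units(small_session)
        cond = T.planning_rate_conditions(small_session, gated)
        uid = cond["unit_id"].iloc[0]
        sub = cond[cond["unit_id"] == uid]
        dirs, mean, se, n = T.population_tuning(sub, 0.75)
        assert n == 1
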