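"""Generator contracts: block design, behavior, rate profiles, spiking."""

import numpy as np
import pandas as pd
import pytest

from reachprior.synthetic import (
    BehaviorParams,
    SimConfig,
    child_rngs,
    generate_behavior,
    generate_spikes,
    lobe,
    plan_trials,
    rate_profile,
    simulate_selection_traces,
)


def _skeleton_trial(level_ratio=(5, 1), loc=90.0, reach=180.0):
    return {
        "precue_location": loc,
        "prior_ccw": level_ratio[0],
        "prior_cw": level_ratio[1],
        "reach_direction": reach,
        "t_precue_on": 700.0,
        "t_rulecue_on": 2000.0,
    }


def _truth(klass, pd=180.0, slope=1.0):
    return {
        "truth_klass": klass,
        "truth_pd": pd,
        "truth_baseline_rate": 10.0,
        "truth_tuning_gain": 20.0 if klass != "untuned" else 0.0,
        "truth_tuning_width": 4.0,
        "truth_prior_slope": slope,
        "truth_selection_latency": 150.0,
    }


class TestPlanTrials:
    def test_block_structure(self, rng):
        cfg = SimConfig(n_blocks=28, n_subjects=1, seed=0)
        trials = plan_trials(cfg, rng)
        assert len(trials) == 28 * 8
        for _, block in trials.groupby(trials["trial_id"].str[:-3]):
            assert (block["trial_type"] == "free_choice").sum() == 2
            assert (block["trial_type"] == "instructed").sum() == 6
            k_ccw = int(block["prior_ccw"].iloc[0])
            assert (block["instructed_rule"] == "ccw").sum() == k_ccw
            assert (block["instructed_rule"] == "cw").sum() == 6 - k_ccw

    def test_full_prior_block_all_one_rule(self, rng):
        cfg = SimConfig(n_blocks=28, n_subjects=1, seed=3)
        trials = plan_trials(cfg, rng)
        full = trials[(trials["prior_ccw"] == 6) & (trials["trial_type"] == "instructed")]
        assert len(full) and (full["instructed_rule"] == "ccw").all()

    def test_same_seed_identical(self):
        cfg = SimConfig(n_blocks=8, seed=9)
        a = plan_trials(cfg, np.random.default_rng(1))
        b = plan_trials(cfg, np.random.default_rng(1))
        pd.testing.assert_frame_equal(a, b)


class TestBehavior:
    def _choices(self, slope, n_blocks=120, seed=4):
        cfg = SimConfig(n_blocks=n_blocks, seed=seed)
        rngs = child_rngs(seed, "trials", "behavior")
        trials = plan_trials(cfg, rngs["trials"])
        params = BehaviorParams(choice_bias_slope=slope)
        return generate_behavior(trials, params, rngs["behavior"])

    def test_null_slope_choice_probability_half(self):
        done = self._choices(0.0)
        free = done[(done["trial_type"] == "free_choice") & (done["prior_level"] > 0)]
        p = (free["congruency"] == "follow").mean()
        n = len(free)
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_strong_slope_saturates(self):
        """At the strongest prior, a steep configured bias drives choices
        close to the logistic prediction."""
        done = self._choices(6.0)
        free = done[
            (done["trial_type"] == "free_choice") & (done["prior_level"] == 0.75)
        ]
        expect = 1 / (1 + np.exp(-6.0 * 0.75))
        p = (free["congruency"] == "follow").mean()
        assert abs(p - expect) < 3 * np.sqrt(expect * (1 - expect) / len(free))

    def test_zero_rt_effect_equal_means(self):
        cfg = SimConfig(n_blocks=120, seed=6)
        rngs = child_rngs(6, "trials", "behavior")
        trials = plan_trials(cfg, rngs["trials"])
        done = generate_behavior(
            trials, BehaviorParams(rt_congruency_effect=0.0), rngs["behavior"]
        )
        nz = done[done["prior_level"] > 0]
        f = nz.loc[nz["congruency"] == "follow", "rt"]
        a = nz.loc[nz["congruency"] == "against", "rt"]
        se = np.sqrt(f.var() / len(f) + a.var() / len(a))
        assert abs(f.mean() - a.mean()) < 3 * se


class TestRateProfile:
    def test_dr_zero_prior_symmetric_lobes(self):
        """DR planning rate is identical whichever PD-axis goal carries the
        pre-cue in the zero-prior condition."""
        t = np.arange(1700.0, 2000.0)
        r1 = rate_profile(_truth("DR"), _skeleton_trial((3, 3), 90.0), t)
        r2 = rate_profile(_truth("DR"), _skeleton_trial((3, 3), 270.0), t)
        np.testing.assert_allclose(r1, r2)

    def test_ur_zero_prior_untuned(self):
        """UR units carry no lobe in zero-prior trials: planning rate is
        baseline at every pre-cue location."""
        t = np.arange(1700.0, 2000.0)
        for loc in (0.0, 90.0, 180.0, 270.0):
            r = rate_profile(_truth("UR"), _skeleton_trial((3, 3), loc), t)
            np.testing.assert_allclose(r, 10.0, atol=0.05)

    def test_dr_od_lobe_suppressed_by_prior(self):
        """With the prior pointing away from the PD, the DR planning rate
        drops below the zero-prior level by slope x level x gain."""
        t = np.arange(1700.0, 2000.0)
        zero = rate_profile(_truth("DR"), _skeleton_trial((3, 3), 90.0), t).mean()
        # pre-cue 90, cw-heavy ratio 0:6 -> high prior at 0 (away from PD 180)
        away = rate_profile(_truth("DR"), _skeleton_trial((0, 6), 90.0), t).mean()
        assert away == pytest.approx(zero - 20.0 * 1.0 * 0.75, rel=1e-3)

    def test_orth_goals_no_prior_modulation(self):
        """Response lobes vanish at 90 degrees, so conditions with both goals
        orthogonal to the PD axis carry no prior modulation at any level."""
        t = np.arange(1700.0, 2000.0)
        for klass in ("UR", "DR"):
            rates = [
                rate_profile(
                    _truth(klass, pd=0.0), _skeleton_trial(r, 0.0, 90.0), t
                ).mean()
                for r in ((3, 3), (4, 2), (6, 0), (0, 6))
            ]
            assert np.ptp(rates) < 1e-9

    def test_lobe_shape(self):
        assert lobe(0.0, 4.0) == pytest.approx(1.0)
        assert lobe(90.0, 4.0) == pytest.approx(0.0, abs=1e-12)
        assert lobe(180.0, 4.0) == 0.0
        assert lobe(45.0, 4.0) > 0.0


class TestSpikes:
    def test_constant_rate_count_within_3_sigma(self, rng):
        """A 50 Hz unit over 100 s yields a spike count within 3 sigma of
        5000 (Poisson statistics)."""
        units = pd.DataFrame(
            [
                {
                    "unit_id": "u0",
                    "session_id": "s",
                    "subject_id": "m",
                    "area": "PMd",
                    **{k: v for k, v in _truth("untuned").items()},
                }
            ]
        )
        units.loc[0, "truth_baseline_rate"] = 50.0
        trials = pd.DataFrame(
            [
                {
                    "trial_id": f"t{i}",
                    "session_id": "s",
                    "precue_location": 90.0,
                    "prior_ccw": 3,
                    "prior_cw": 3,
                    "reach_direction": np.nan,
                    "t_precue_on": 1e9,  # keep the whole trial at baseline
                    "t_rulecue_on": 2e9,
                    "t_movement_off": 10_000.0 - 100.0,
                }
                for i in range(10)
            ]
        )
        spikes = generate_spikes(units, trials, rng)
        assert abs(len(spikes) - 5000) < 3 * np.sqrt(5000)

    def test_zero_rate_no_spikes(self, rng):
        units = pd.DataFrame(
            [
                {
                    "unit_id": "u0",
                    "session_id": "s",
                    "subject_id": "m",
                    "area": "PMd",
                    **_truth("untuned"),
                }
            ]
        )
        units.loc[0, "truth_baseline_rate"] = 1e-12
        trials = pd.DataFrame(
            [
                {
                    "trial_id": "t0",
                    "session_id": "s",
                    "precue_location": 90.0,
                    "prior_ccw": 3,
                    "prior_cw": 3,
                    "reach_direction": np.nan,
                    "t_precue_on": 1e9,
                    "t_rulecue_on": 2e9,
                    "t_movement_off": 1000.0,
                }
            ]
        )
        assert len(generate_spikes(units, trials, rng)) == 0

    def test_seed_reproducibility(self):
        from reachprior.synthetic import simulate_session

        a = simulate_session(SimConfig(n_units_per_area=2, n_blocks=2, seed=11))
        b = simulate_session(SimConfig(n_units_per_area=2, n_blocks=2, seed=11))
        pd.testing.assert_frame_equal(a.spikes, b.spikes)
        pd.testing.assert_frame_equal(a.trials, b.trials)


class TestSelectionTraces:
    def test_latency_controls_divergence(self, rng):
        t, a, b = simulate_selection_traces(
            40, 200.0, rng, n_trials=40, latency_jitter_sd=0.0
        )
        diff = (a - b).mean(axis=0)
        # conditions match before the latency, diverge after
        pre = abs(diff[(t > -250) & (t < 0)].mean())
        post = diff[t > 350].mean()
        assert pre < 1.0 and post > 15.0


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_units_per_area=0).validate()
    with pytest.raises(ValueError):
        SimConfig(class_mixture={"UR": 0.5, "DR": 0.2, "untuned": 0.2}).validate()
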