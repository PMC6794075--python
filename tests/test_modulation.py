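"""Modulation fits, UR/DR classification, and the dip test."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))
from dip_oracle import dip_oracle  # noqa: E402

from reachprior.modulation import (  # noqa: E402
    classify_modulation,
    dip_null_table,
    dip_statistic,
    dip_test,
    fit_unit_modulation,
    modulation_angle,
    population_modulation_test,
)


class TestDipStatistic:
    def test_two_point_masses(self):
        """Equal point masses at 0 and 1: the closest unimodal CDF is the
        straight line, at sup-distance exactly 1/4."""
        assert dip_statistic([0.0, 0.0, 1.0, 1.0]) == pytest.approx(0.25, abs=1e-12)

    def test_identical_values_degenerate(self):
        """A point mass is itself unimodal: minimal dip."""
        assert dip_statistic(np.ones(10)) == pytest.approx(0.0, abs=1e-12)

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0, 2.0, 3.0])

    def test_oracle_equivalence_small_n(self, rng):
        """Exact agreement with the brute-force LP oracle for n <= 12,
        including tied samples."""
        for trial in range(120):
            n = int(rng.integers(4, 13))
            kind = trial % 4
            if kind == 0:
                x = rng.uniform(0, 1, n)
            elif kind == 1:
                x = rng.integers(0, 4, n).astype(float)
            elif kind == 2:
                x = np.r_[rng.normal(0, 0.05, n // 2), rng.normal(1, 0.05, n - n // 2)]
            else:
                x = np.round(rng.uniform(0, 1, n), 1)
            assert dip_statistic(x) == pytest.approx(dip_oracle(x), abs=1e-12)

    def test_bimodal_exceeds_unimodal(self, rng):
        uni = dip_statistic(rng.normal(0, 1, 300))
        bi = dip_statistic(np.r_[rng.normal(0, 0.1, 150), rng.normal(3, 0.1, 150)])
        assert bi > 5 * uni


class TestDipTest:
    def test_power_on_separated_modes(self, rng):
        """Two well-separated Gaussians, n=200: p < 0.005."""
        x = np.r_[rng.normal(0, 0.1, 100), rng.normal(3, 0.1, 100)]
        res = dip_test(x, n_boot=400, rng=rng)
        assert res.p < 0.005

    def test_null_table_reuse(self, rng):
        table = dip_null_table(50, 200, rng)
        res = dip_test(rng.uniform(0, 1, 50), null_table=table)
        assert 0.0 <= res.p <= 1.0
        assert res.n_boot == 200

    def test_zero_boot_rejected(self, rng):
        with pytest.raises(ValueError):
            dip_null_table(50, 0, rng)


class TestAngleAndClass:
    def test_angle_quadrant(self):
        assert modulation_angle(1.0, 0.0) == pytest.approx(np.pi / 2)
        assert modulation_angle(0.0, -1.0) == pytest.approx(0.0)
        assert modulation_angle(1.0, -1.0) == pytest.approx(np.pi / 4)
        # wrong-sign slopes clip onto the axes
        assert modulation_angle(-0.5, -1.0) == pytest.approx(0.0)
        assert modulation_angle(0.5, 1.0) == pytest.approx(np.pi / 2)

    def test_classification_rules(self):
        assert classify_modulation(1.0, 0.0, 0.001, 0.9) == "UR"
        assert classify_modulation(0.0, -1.0, 0.9, 0.001) == "DR"
        assert classify_modulation(1.0, -1.0, 0.001, 0.001) == "both"
        assert classify_modulation(1.0, -1.0, 0.2, 0.2) == "none"
        # significance requires the expected sign
        assert classify_modulation(-1.0, -1.0, 0.001, 0.2) == "none"


def _role_rates(rng, slope_pd, slope_od, n_per_cell=20, noise=0.15):
    rows = []
    for level in (0.0, 0.25, 0.5, 0.75):
        for role, slope in (("PD", slope_pd), ("OD", slope_od)):
            mu = 1.0 + slope * level
            rows.extend(
                {"role": role, "prior_level": level,
                 "norm_rate": mu + noise * rng.standard_normal()}
                for _ in range(n_per_cell)
            )
    return pd.DataFrame(rows)


class TestUnitFit:
    def test_recovers_ur(self, rng):
        """True slopes (+0.8, 0) recover within CI and classify UR."""
        res = fit_unit_modulation(_role_rates(rng, 0.8, 0.0), "u", "PMd")
        assert res.klass == "UR"
        assert res.slope_pd == pytest.approx(0.8, abs=0.15)
        assert abs(res.slope_od) < 0.15

    def test_recovers_dr(self, rng):
        res = fit_unit_modulation(_role_rates(rng, 0.0, -0.8), "u", "PMd")
        assert res.klass == "DR"
        assert res.slope_od == pytest.approx(-0.8, abs=0.15)

    def test_null_units_rarely_classified(self, rng):
        hits = sum(
            fit_unit_modulation(_role_rates(rng, 0.0, 0.0), "u", "PMd").klass
            != "none"
            for _ in range(100)
        )
        # two alpha=0.05 gates; expected false-positive rate ~< 10%
        assert hits <= 18

    def test_single_level_unfittable(self, rng):
        df = _role_rates(rng, 1.0, 0.0)
        assert fit_unit_modulation(df[df["prior_level"] == 0.5], "u", "") is None

    def test_scale_invariant_classification(self, rng):
        """Uniformly rescaling a unit's rates does not change its class."""
        df = _role_rates(rng, 0.8, -0.1)
        a = fit_unit_modulation(df, "u", "")
        df2 = df.assign(norm_rate=df["norm_rate"] * 3.7)
        b = fit_unit_modulation(df2, "u", "")
        assert a.klass == b.klass
        assert b.slope_pd == pytest.approx(3.7 * a.slope_pd, rel=1e-9)


class TestPopulationTest:
    def _unit_table(self, rng, n_units, slope_pd, slope_od):
        frames = []
        for u in range(n_units):
            df = _role_rates(rng, slope_pd, slope_od, n_per_cell=10)
            df["unit_id"] = f"u{u}"
            df["hi_dir"] = np.where(df["role"] == "PD", 0.0, 180.0)
            df["pd_max"] = 0.0
            df["rate"] = df["norm_rate"]
            frames.append(df.drop(columns=["role"]))
        return pd.concat(frames, ignore_index=True)

    def test_ur_population_signature(self, rng):
        cond = self._unit_table(rng, 12, 0.8, 0.0)
        rep = population_modulation_test(cond)
        s = rep.slopes.set_index("role")
        assert s.loc["PD", "p"] < 0.001 and s.loc["PD", "mean_slope"] > 0
        assert s.loc["OD", "p"] > 0.01

    def test_permuted_levels_null(self, rng):
        """Shuffling prior levels destroys the population slope."""
        cond = self._unit_table(rng, 12, 0.8, -0.8)
        cond["rate"] = rng.permutation(cond["rate"].to_numpy())
        rep = population_modulation_test(cond)
        s = rep.slopes.set_index("role")
        # slopes collapse to a small fraction of the injected +-0.8 effect
        assert abs(s.loc["PD", "mean_slope"]) < 0.15
        assert abs(s.loc["OD", "mean_slope"]) < 0.15

    def test_posthoc_structure(self, rng):
        cond = self._unit_table(rng, 8, 1.0, 0.0)
        rep = population_modulation_test(cond)
        ph = rep.posthoc
        assert set(ph["role"]) <= {"PD", "OD", "Orth"}
        pd_rows = ph[ph["role"] == "PD"]
        assert list(zip(pd_rows["level_a"], pd_rows["level_b"])) == [
            (0.0, 0.25), (0.25, 0.5), (0.5, 0.75)
        ]
        assert (ph["p_corrected"] >= ph["p"] - 1e-15).all()

    def test_mixed_method_agrees_in_sign(self, rng):
        cond = self._unit_table(rng, 8, 0.8, -0.8)
        rep = population_modulation_test(cond, method="mixed")
        s = rep.slopes.set_index("role")
        assert s.loc["PD", "mean_slope"] > 0 > s.loc["OD", "mean_slope"]
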