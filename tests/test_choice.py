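"""Choice sorting, ROC discriminability, and signal correlations."""

import numpy as np
import pandas as pd
import pytest

from reachprior.choice import (
    auroc,
    choice_roc_suite,
    pd_distance,
    signal_correlations,
    sort_choice_trials,
    unit_choice_rocs,
)


def _pairwise_auc(a, b):
    """Exhaustive pair-counting oracle."""
    a = np.asarray(a)[:, None]
    b = np.asarray(b)[None, :]
    return ((a > b).sum() + 0.5 * (a == b).sum()) / (a.size * b.size)


class TestAuroc:
    def test_identical_samples_half(self):
        x = np.array([1.0, 2.0, 3.0])
        assert auroc(x, x) == pytest.approx(0.5)

    def test_full_separation(self):
        assert auroc([5.0, 6.0], [1.0, 2.0]) == 1.0
        assert auroc([1.0, 2.0], [5.0, 6.0]) == 0.0

    def test_matches_pair_counting_oracle(self, rng):
        """Exact agreement with the exhaustive oracle up to n=50 per class,
        with ties."""
        for _ in range(60):
            na, nb = rng.integers(2, 51, size=2)
            a = rng.integers(0, 12, na).astype(float)
            b = rng.integers(0, 12, nb).astype(float)
            assert auroc(a, b) == pytest.approx(_pairwise_auc(a, b), abs=1e-12)

    def test_complement_symmetry(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=15)
        assert auroc(a, b) + auroc(b, a) == pytest.approx(1.0)

    def test_min_trials(self):
        assert auroc([1.0], [2.0, 3.0], min_n=2) is None


def _free_choice_table(rng, n_per_cell=12, premature=False, pd_max=0.0):
    """Free-choice planning rates of one co-encoding (DR-like) unit.

    Rates depend on the prior direction (down-modulation of the devalued
    option) but, unless ``premature`` is set, not on the upcoming choice.
    """
    rows = []
    for level in (0.25, 0.5, 0.75):
        for hi_dir, prior_role in ((0.0, "in"), (180.0, "out")):
            for reach, n in ((0.0, n_per_cell), (180.0, n_per_cell)):
                for _ in range(n):
                    mu = 20.0 if hi_dir == 0.0 else 20.0 - 12.0 * level
                    if premature and reach == 0.0:
                        mu += 8.0
                    rows.append(
                        {
                            "prior_level": level,
                            "hi_dir": hi_dir,
                            "reach_direction": reach,
                            "rate": mu + rng.normal(0, 2.0),
                        }
                    )
    return pd.DataFrame(rows)


class TestChoiceSort:
    def test_role_definitions(self):
        df = pd.DataFrame(
            {
                "prior_level": [0.5, 0.5, 0.5, 0.0],
                "hi_dir": [0.0, 180.0, 90.0, 0.0],
                "reach_direction": [0.0, 0.0, 90.0, 180.0],
            }
        )
        out = sort_choice_trials(df, pd_max=0.0)
        assert list(out["prior_role"]) == ["Prior-in", "Prior-out", "Orth", "Zero"]
        assert list(out["reach_role"]) == [
            "Reach-in", "Reach-in", "Orth", "Reach-out"
        ]

    def test_follow_against_combinations(self):
        """Prior-in + Reach-in and Prior-out + Reach-out are follow trials;
        the cross combinations are against trials."""
        df = pd.DataFrame(
            {
                "prior_level": [0.5] * 4,
                "hi_dir": [0.0, 180.0, 0.0, 180.0],
                "reach_direction": [0.0, 180.0, 180.0, 0.0],
            }
        )
        out = sort_choice_trials(df, pd_max=0.0)
        follow = (
            ((out["prior_role"] == "Prior-in") & (out["reach_role"] == "Reach-in"))
            | ((out["prior_role"] == "Prior-out") & (out["reach_role"] == "Reach-out"))
        )
        assert list(follow) == [True, True, False, False]


class TestRocSuite:
    def test_co_encoding_unit_rocs(self, rng):
        """Without premature commitment, planning activity separates prior
        directions (between-condition AUC >> 0.5) but not upcoming choices
        (within-condition AUC ~ 0.5)."""
        df = _free_choice_table(rng)
        st = sort_choice_trials(df, 0.0)
        rocs = pd.DataFrame([r.__dict__ for r in unit_choice_rocs(st, "u")])
        within = rocs[rocs["comparison"].str.startswith("within")]
        between = rocs[rocs["comparison"] == "between_prior"]
        assert abs(within["auc"].mean() - 0.5) < 0.08
        assert between["auc"].mean() > 0.8

    def test_premature_commitment_detected(self, rng):
        """A choice-tied planning rate yields within-condition AUC >> 0.5."""
        df = _free_choice_table(rng, premature=True)
        st = sort_choice_trials(df, 0.0)
        rocs = pd.DataFrame([r.__dict__ for r in unit_choice_rocs(st, "u")])
        within = rocs[rocs["comparison"].str.startswith("within")]
        assert within["auc"].mean() > 0.8

    def test_shuffled_choices_null(self, rng):
        df = _free_choice_table(rng, premature=True)
        df["reach_direction"] = rng.permutation(df["reach_direction"].to_numpy())
        st = sort_choice_trials(df, 0.0)
        rocs = pd.DataFrame([r.__dict__ for r in unit_choice_rocs(st, "u")])
        within = rocs[rocs["comparison"].str.startswith("within")]
        assert abs(within["auc"].mean() - 0.5) < 0.1

    def test_suite_over_units(self, rng):
        frames = []
        for u in range(4):
            df = _free_choice_table(rng)
            df["unit_id"] = f"u{u}"
            df["pd_max"] = 0.0
            frames.append(df)
        cond = pd.concat(frames, ignore_index=True)
        roc_df, rep = choice_roc_suite(cond)
        assert roc_df["unit_id"].nunique() == 4
        assert len(rep) == 1 and rep["term"].iloc[0] == "REACHDIR"


class TestCorrelations:
    def test_pd_distance_folding(self):
        assert pd_distance(0.0, 270.0) == 90.0
        assert pd_distance(0.0, 180.0) == 180.0
        assert pd_distance(90.0, 90.0) == 0.0

    def _session(self, rng, anti=True):
        rows = []
        for t in range(40):
            for level in (0.0, 0.5):
                shared = rng.normal(0, 5)
                tid = f"t{t}-{level}"
                rows.append({"session_id": "s", "unit_id": "a", "trial_id": tid,
                             "prior_level": level, "pd_max": 0.0,
                             "rate": 20 + shared})
                sign = -1.0 if anti else 1.0
                rows.append({"session_id": "s", "unit_id": "b", "trial_id": tid,
                             "prior_level": level, "pd_max": 180.0,
                             "rate": 20 + sign * shared})
        return pd.DataFrame(rows)

    def test_antiphase_pair(self, rng):
        corr = signal_correlations(self._session(rng, anti=True))
        assert (corr["pd_distance"] == 180.0).all()
        assert (corr["r"] < -0.95).all()

    def test_duplicated_unit_r_one(self, rng):
        corr = signal_correlations(self._session(rng, anti=False))
        assert (corr["r"] > 0.95).all()

    def test_affine_rescale_invariance(self, rng):
        df = self._session(rng)
        a = signal_correlations(df)
        df2 = df.copy()
        df2.loc[df2["unit_id"] == "a", "rate"] = (
            3.0 * df2.loc[df2["unit_id"] == "a", "rate"] + 7.0
        )
        b = signal_correlations(df2)
        np.testing.assert_allclose(a["r"], b["r"], atol=1e-12)
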