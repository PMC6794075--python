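"""Choice-predictive activity (ROC) and pairwise signal correlations.

Free-choice trials are sorted per unit by the direction of the higher prior
relative to the unit's PD_max (Prior-in / Prior-out / Orth) and by the
executed reach (Reach-in / Reach-out).  Prior-in followed by Reach-in and
Prior-out followed by Reach-out are follow trials; the cross combinations
are against trials.

Discriminability is the area under the ROC curve of trial-by-trial planning
activity (0.5 chance, 1.0 perfect), computed rank-based (the probability
that a random draw from one class exceeds one from the other, ties counted
half).  The within-condition ROC (Reach-in vs Reach-out separately in
Prior-in and Prior-out trials) asks whether planning activity predicts the
upcoming choice; the between-condition ROC (Prior-in vs Prior-out) asks how
reliably it reflects the prior direction.

Signal correlations are Pearson coefficients of planning rates across
trials for simultaneously recorded unit pairs, binned by the distance
between the units' PD_max (0, 90, 180 degrees; 270 folds to 90) and
computed per prior level; co-encoding of both goals predicts that the
anti-correlation of opposite-PD pairs weakens as the prior decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modulation import role_relative_to_pd


@dataclass
class RocResult:
    unit_id: str
    prior_level: float
    comparison: str  # within_prior_in | within_prior_out | between_prior
    auc: float
    n_a: int
    n_b: int


def auroc(class_a: np.ndarray, class_b: np.ndarray, min_n: int = 1) -> float | None:
    """Rank-based AUC: P(a > b) + 0.5 P(a == b).

    Returns None when either class holds fewer than ``min_n`` values.
    """
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if len(a) < min_n or len(b) < min_n:
        return None
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0
    return float(u / (len(a) * len(b)))


def sort_choice_trials(unit_trials: pd.DataFrame, pd_max: float) -> pd.DataFrame:
    """Assign prior roles and reach roles to a unit's free-choice trials.

    Adds ``prior_role`` (Prior-in / Prior-out / Orth; zero-prior trials get
    the neutral ``Zero`` label and are excluded from between-prior ROCs) and
    ``reach_role`` (Reach-in / Reach-out for reaches on the unit's PD axis).
    """
    df = unit_trials.copy()
    role = role_relative_to_pd(df["hi_dir"].to_numpy(), pd_max)
    prior_role = np.where(
        df["prior_level"].to_numpy(dtype=float) == 0.0,
        "Zero",
        np.where(role == "PD", "Prior-in", np.where(role == "OD", "Prior-out", "Orth")),
    )
    delta = np.mod(df["reach_direction"].to_numpy(dtype=float) - pd_max, 360.0)
    reach_role = np.where(
        delta == 0.0, "Reach-in", np.where(delta == 180.0, "Reach-out", "Orth")
    )
    df["prior_role"] = prior_role
    df["reach_role"] = reach_role
    return df


def unit_choice_rocs(
    sorted_trials: pd.DataFrame,
    unit_id: str = "",
    min_trials: int = 5,
    rate_column: str = "rate",
) -> list[RocResult]:
    """Within- and between-condition AUCs per prior level for one unit."""
    out: list[RocResult] = []
    df = sorted_trials[sorted_trials["prior_role"].isin(["Prior-in", "Prior-out"])]
    for level, grp in df.groupby("prior_level", sort=True):
        for role, name in (
            ("Prior-in", "within_prior_in"),
            ("Prior-out", "within_prior_out"),
        ):
            g = grp[grp["prior_role"] == role]
            a = g.loc[g["reach_role"] == "Reach-in", rate_column].to_numpy()
            b = g.loc[g["reach_role"] == "Reach-out", rate_column].to_numpy()
            if len(a) >= min_trials and len(b) >= min_trials:
                out.append(
                    RocResult(unit_id, float(level), name,
                              auroc(a, b), len(a), len(b))
                )
        a = grp.loc[grp["prior_role"] == "Prior-in", rate_column].to_numpy()
        b = grp.loc[grp["prior_role"] == "Prior-out", rate_column].to_numpy()
        if len(a) >= min_trials and len(b) >= min_trials:
            out.append(
                RocResult(unit_id, float(level), "between_prior",
                          auroc(a, b), len(a), len(b))
            )
    return out


def choice_roc_suite(
    cond: pd.DataFrame,
    min_trials: int = 5,
    rate_column: str = "rate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit choice ROCs plus a population REACHDIR fixed-effect test.

    ``cond`` is a planning-rate condition table restricted to free-choice
    trials (columns: unit_id, pd_max, rate, prior_level, hi_dir,
    reach_direction).  Returns (roc_table, reachdir_report).  The REACHDIR
    test is two-stage: per unit, OLS of activity on PRIOR, PRIORDIR,
    REACHDIR and interactions; the REACHDIR coefficients are then tested
    across units.
    """
    rocs: list[RocResult] = []
    coefs = []
    for unit_id, grp in cond.groupby("unit_id", sort=False):
        pdm = float(grp["pd_max"].iloc[0])
        st = sort_choice_trials(grp, pdm)
        rocs.extend(unit_choice_rocs(st, unit_id, min_trials, rate_column))
        axis = st[
            st["prior_role"].isin(["Prior-in", "Prior-out", "Zero"])
            & st["reach_role"].isin(["Reach-in", "Reach-out"])
        ]
        if len(axis) >= 8:
            level = axis["prior_level"].to_numpy(dtype=float)
            pdir = np.where(axis["prior_role"] == "Prior-in", 0.5,
                            np.where(axis["prior_role"] == "Prior-out", -0.5, 0.0))
            rdir = np.where(axis["reach_role"] == "Reach-in", 0.5, -0.5)
            X = np.column_stack(
                [np.ones_like(level), level, pdir, rdir,
                 level * pdir, level * rdir, pdir * rdir]
            )
            y = axis[rate_column].to_numpy(dtype=float)
            if np.linalg.matrix_rank(X) == X.shape[1]:
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                coefs.append({"unit_id": unit_id, "reachdir": beta[3]})
    roc_df = pd.DataFrame([r.__dict__ for r in rocs])
    rep_rows = []
    if coefs:
        cdf = pd.DataFrame(coefs)
        vals = cdf["reachdir"].to_numpy()
        if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            t, p = stats.ttest_1samp(vals, 0.0)
        else:
            t, p = np.nan, 1.0
        rep_rows.append(
            {"term": "REACHDIR", "estimate": float(vals.mean()),
             "t": float(t), "p": float(p), "n_units": len(vals)}
        )
    return roc_df, pd.DataFrame(rep_rows)


# ---------------------------------------------------------------------------
# pairwise signal correlations

def pd_distance(pd_a: float, pd_b: float) -> float:
    """Distance between two PD_max values, folded to {0, 90, 180}."""
    d = abs((pd_a - pd_b) % 360.0)
    return float(min(d, 360.0 - d))


def signal_correlations(
    cond: pd.DataFrame,
    rate_column: str = "rate",
    min_trials: int = 8,
) -> pd.DataFrame:
    """Pearson correlation of planning rates per simultaneous unit pair.

    Pairs are formed within sessions; the correlation is computed across
    trials pooled within each prior level.  Pairs with a zero-variance
    member in a cell are skipped for that cell.
    """
    rows = []
    for session, sgrp in cond.groupby("session_id", sort=False):
        units = sorted(sgrp["unit_id"].unique())
        wide = sgrp.pivot_table(
            index="trial_id", columns="unit_id", values=rate_column
        )
        meta = sgrp.drop_duplicates("trial_id").set_index("trial_id")["prior_level"]
        pdm = sgrp.drop_duplicates("unit_id").set_index("unit_id")["pd_max"]
        for i, ua in enumerate(units):
            for ub in units[i + 1 :]:
                for level in sorted(sgrp["prior_level"].unique()):
                    trial_ids = meta.index[meta == level]
                    sub = wide.loc[wide.index.intersection(trial_ids), [ua, ub]].dropna()
                    if len(sub) < min_trials:
                        continue
                    a = sub[ua].to_numpy()
                    b = sub[ub].to_numpy()
                    if np.std(a) == 0 or np.std(b) == 0:
                        continue
                    r = float(np.corrcoef(a, b)[0, 1])
                    rows.append(
                        {
                            "session_id": session,
                            "unit_a": ua,
                            "unit_b": ub,
                            "pd_distance": pd_distance(
                                float(pdm[ua]), float(pdm[ub])
                            ),
                            "prior_level": float(level),
                            "r": r,
                            "n_trials": len(sub),
                        }
                    )
    return pd.DataFrame(rows)


def correlation_prior_trend(
    pair_corr: pd.DataFrame, pd_distance_deg: float = 180.0
) -> dict:
    """Prior trend of signal correlations in one PD-distance bin.

    Two-stage analogue of the CorrCoef ~ PRIOR | PAIRS model: per-pair OLS
    slope of r on prior level, then a one-sample t-test across pairs.
    """
    sel = pair_corr[pair_corr["pd_distance"] == pd_distance_deg]
    slopes = []
    for (ua, ub), grp in sel.groupby(["unit_a", "unit_b"]):
        if grp["prior_level"].nunique() < 2:
            continue
        slopes.append(
            np.polyfit(grp["prior_level"].to_numpy(), grp["r"].to_numpy(), 1)[0]
        )
    if len(slopes) < 2:
        return {"slope": np.nan, "t": np.nan, "p": np.nan, "n_pairs": len(slopes)}
    s = np.asarray(slopes)
    t, p = stats.ttest_1samp(s, 0.0)
    return {
        "slope": float(s.mean()),
        "t": float(t),
        "p": float(p),
        "n_pairs": len(s),
    }
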