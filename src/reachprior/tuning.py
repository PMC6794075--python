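"""Direction selectivity, motor-goal gating, and population tuning.

Selectivity of a unit is quantified with a directional tuning vector (DTV),
the vector sum of the four cardinal unit vectors weighted by the mean firing
rate per direction, and tested with a Kruskal-Wallis test over the four
direction groups (alpha = 0.01).  Units qualify as motor-goal neurons when
they fire above 5 Hz in at least one analysis epoch and are direction
selective for the reach goal during planning in full-prior instructed trials
(where the pre-cue announces the goal unambiguously).

Continuous tuning curves are reconstructed from the four sampled directions
by trigonometric (ideal low-pass) interpolation; this reconstruction is
presentation-layer only — statistics run on the four sampled directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset
from .records import (
    CARDINAL_DIRECTIONS,
    EPOCHS,
    derive_prior_level,
    rule_goal,
    wrap_degrees,
)


@dataclass
class TuningResult:
    unit_id: str
    epoch: str
    direction_means: np.ndarray  # Hz at (0, 90, 180, 270)
    dtv: np.ndarray  # 2-vector
    pd_continuous: float | None  # degrees, None when DTV is degenerate
    pd_max: float
    kw_p: float

    @property
    def is_selective(self) -> bool:
        return self.kw_p < 0.01


def directional_tuning_vector(
    direction_means: np.ndarray,
) -> tuple[np.ndarray, float | None]:
    """Rate-weighted vector sum over the four cardinal directions.

    Returns the 2-vector and its angle in degrees, or ``None`` for the angle
    when the vector is degenerate (all direction means equal).
    """
    rates = np.asarray(direction_means, dtype=float)
    if rates.shape != (4,):
        raise ValueError("expected 4 direction means")
    ang = np.deg2rad(CARDINAL_DIRECTIONS)
    vec = np.array([np.sum(rates * np.cos(ang)), np.sum(rates * np.sin(ang))])
    if np.allclose(vec, 0.0):
        return vec, None
    return vec, float(wrap_degrees(np.degrees(np.arctan2(vec[1], vec[0]))))


def pd_max_of(direction_means: np.ndarray, pd_continuous: float | None) -> float:
    """Direction of maximal mean response; ties broken toward the DTV angle."""
    rates = np.asarray(direction_means, dtype=float)
    top = np.flatnonzero(rates == rates.max())
    if len(top) == 1 or pd_continuous is None:
        return float(CARDINAL_DIRECTIONS[top[0]])
    cands = np.array([CARDINAL_DIRECTIONS[i] for i in top], dtype=float)
    delta = np.abs((cands - pd_continuous + 180.0) % 360.0 - 180.0)
    return float(cands[np.argmin(delta)])


def selectivity_test(rates_by_direction: list[np.ndarray]) -> float | None:
    """Kruskal-Wallis p-value over direction groups.

    Returns ``None`` (gated out) when any direction has fewer than 2 trials;
    returns 1.0 for the degenerate all-identical input.
    """
    groups = [np.asarray(g, dtype=float) for g in rates_by_direction]
    if any(len(g) < 2 for g in groups):
        return None
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


# ---------------------------------------------------------------------------
# per-trial epoch rates

def epoch_rate_table(ds: Dataset, epoch: str) -> pd.DataFrame:
    """Per-(unit, trial) firing rate in one analysis epoch, vectorized.

    Only trials with the epoch's anchor events present are included.
    """
    win = EPOCHS[epoch]
    tr = ds.trials
    anchor = tr[f"t_{win.anchor_event}"].astype(float)
    if win.end_event is None:
        start = anchor + win.offset_start
        end = anchor + win.offset_end
    else:
        start = anchor + (win.offset_start or 0.0)
        end = tr[f"t_{win.end_event}"].astype(float)
    bounds = pd.DataFrame(
        {
            "trial_id": tr["trial_id"],
            "session_id": tr["session_id"],
            "_start": start,
            "_end": end,
        }
    ).dropna(subset=["_start", "_end"])
    units = ds.units[["unit_id", "session_id"]]
    # every unit x every trial of its session
    pairs = units.merge(bounds, on="session_id")
    sp = ds.spikes.merge(bounds, on="trial_id", how="inner")
    inside = sp[(sp["time_ms"] >= sp["_start"]) & (sp["time_ms"] < sp["_end"])]
    counts = (
        inside.groupby(["unit_id", "trial_id"], sort=False)
        .size()
        .rename("n_spikes")
        .reset_index()
    )
    out = pairs.merge(counts, on=["unit_id", "trial_id"], how="left")
    out["n_spikes"] = out["n_spikes"].fillna(0.0)
    out["rate"] = out["n_spikes"] / ((out["_end"] - out["_start"]) / 1000.0)
    return out[["unit_id", "trial_id", "rate"]]


def _full_prior_goal_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct full-prior instructed trials, with the (unambiguous) goal."""
    lev = trials["prior_level"].astype(float)
    sel = trials[
        (lev == 0.75)
        & (trials["trial_type"] == "instructed")
        & (trials["outcome"] == "correct")
    ].copy()
    return sel


def unit_tuning(
    ds: Dataset,
    epoch: str = "planning",
    rate_table: pd.DataFrame | None = None,
) -> list[TuningResult]:
    """Per-unit direction tuning in an epoch, on full-prior instructed trials
    (direction coordinate: reach goal for planning/movement epochs, pre-cue
    location for baseline/pre-cue epochs)."""
    rates = rate_table if rate_table is not None else epoch_rate_table(ds, epoch)
    trials = _full_prior_goal_trials(ds.trials)
    coord = (
        "reach_direction" if epoch in ("planning", "movement") else "precue_location"
    )
    merged = rates.merge(
        trials[["trial_id", coord]].rename(columns={coord: "direction"}),
        on="trial_id",
        how="inner",
    )
    results = []
    for unit_id, grp in merged.groupby("unit_id", sort=False):
        by_dir = [
            grp.loc[grp["direction"] == d, "rate"].to_numpy()
            for d in CARDINAL_DIRECTIONS
        ]
        means = np.array([g.mean() if len(g) else np.nan for g in by_dir])
        if np.any(np.isnan(means)):
            continue
        vec, ang = directional_tuning_vector(means)
        p = selectivity_test(by_dir)
        results.append(
            TuningResult(
                unit_id=unit_id,
                epoch=epoch,
                direction_means=means,
                dtv=vec,
                pd_continuous=ang,
                pd_max=pd_max_of(means, ang),
                kw_p=p if p is not None else np.nan,
            )
        )
    return results


def gate_motor_goal_units(
    ds: Dataset,
    rate_gate_hz: float = 5.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Motor-goal neuron gate: epoch mean rate > gate in any analysis window
    AND planning-epoch goal selectivity (Kruskal-Wallis p < alpha) on
    full-prior instructed trials.

    Returns a per-unit table with epoch rates, tuning fields, and the
    ``is_motor_goal`` flag.
    """
    if not len(_full_prior_goal_trials(ds.trials)):
        raise ValueError("no full-prior instructed trials: cannot gate units")
    epoch_means = {}
    planning_table = None
    for epoch in EPOCHS:
        tbl = epoch_rate_table(ds, epoch)
        if epoch == "planning":
            planning_table = tbl
        epoch_means[epoch] = tbl.groupby("unit_id")["rate"].mean()
    tunings = unit_tuning(ds, "planning", rate_table=planning_table)
    tune_df = pd.DataFrame(
        {
            "unit_id": [t.unit_id for t in tunings],
            "kw_p": [t.kw_p for t in tunings],
            "pd_max": [t.pd_max for t in tunings],
            "pd_continuous": [t.pd_continuous for t in tunings],
            "mean_0": [t.direction_means[0] for t in tunings],
            "mean_90": [t.direction_means[1] for t in tunings],
            "mean_180": [t.direction_means[2] for t in tunings],
            "mean_270": [t.direction_means[3] for t in tunings],
        }
    )
    out = ds.units.merge(tune_df, on="unit_id", how="left")
    for epoch, means in epoch_means.items():
        out[f"rate_{epoch}"] = out["unit_id"].map(means)
    rate_cols = [f"rate_{e}" for e in EPOCHS]
    out["passes_rate_gate"] = out[rate_cols].max(axis=1) > rate_gate_hz
    out["is_selective"] = out["kw_p"] < alpha
    out["is_motor_goal"] = out["passes_rate_gate"] & out["is_selective"]
    return out


# ---------------------------------------------------------------------------
# interpolation and population tuning

def interpolate_tuning(
    direction_means: np.ndarray, theta_deg: np.ndarray
) -> np.ndarray:
    """Trigonometric (ideal low-pass) interpolation of four cardinal samples.

    Keeps the mean, the first harmonic, and the Nyquist cosine term at half
    weight (the standard even-N trigonometric interpolant); passes exactly
    through the four samples.
    """
    r = np.asarray(direction_means, dtype=float)
    if r.shape != (4,):
        raise ValueError("expected 4 samples")
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    m = r.mean()
    a1 = (r[0] - r[2]) / 2.0
    b1 = (r[1] - r[3]) / 2.0
    c2 = (r[0] - r[1] + r[2] - r[3]) / 4.0
    return m + a1 * np.cos(th) + b1 * np.sin(th) + c2 * np.cos(2.0 * th)


def high_prior_direction(trials: pd.DataFrame) -> pd.Series:
    """Direction of the higher-prior goal per trial (cw-rule goal in the
    zero-prior condition, by the presentation convention)."""
    out = []
    for row in trials.itertuples(index=False):
        _, hi = derive_prior_level((int(row.prior_ccw), int(row.prior_cw)))
        rule = "cw" if hi == "tie" else hi
        out.append(rule_goal(float(row.precue_location), rule))
    return pd.Series(out, index=trials.index, name="hi_dir")


def planning_rate_conditions(
    ds: Dataset,
    gated: pd.DataFrame,
    trial_types: tuple[str, ...] = ("instructed",),
    correct_only: bool = True,
) -> pd.DataFrame:
    """Per-trial planning rates of gated units, annotated with prior level
    and the high-prior direction (the tuning coordinate during planning)."""
    rates = epoch_rate_table(ds, "planning")
    keep = gated.loc[
        gated["is_motor_goal"], ["unit_id", "session_id", "area", "pd_max"]
    ]
    tr = ds.trials
    mask = tr["trial_type"].isin(trial_types)
    if correct_only:
        mask &= tr["outcome"] == "correct"
    tr = tr.loc[mask].copy()
    tr["hi_dir"] = high_prior_direction(tr)
    merged = rates.merge(keep, on="unit_id").merge(
        tr[["trial_id", "prior_level", "precue_location", "hi_dir",
            "reach_direction", "trial_type", "congruency"]],
        on="trial_id",
    )
    return merged


def population_tuning(
    cond: pd.DataFrame, prior_level: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """PD-aligned, normalized population tuning at one prior level.

    Each unit's four-direction planning tuning (coordinate: high-prior
    direction) is rotated so its PD_max maps to 0 degrees, divided by the
    unit's full-prior PD response, then averaged across units.

    Returns (aligned_directions_deg, mean, se, n_units).
    """
    dirs = np.array(CARDINAL_DIRECTIONS, dtype=float)
    curves = []
    for unit_id, grp in cond.groupby("unit_id", sort=False):
        pdm = float(grp["pd_max"].iloc[0])
        full = grp[(grp["prior_level"] == 0.75) & (grp["hi_dir"] == pdm)]
        if not len(full) or full["rate"].mean() <= 0:
            continue
        anchor = full["rate"].mean()
        at_level = grp[grp["prior_level"] == prior_level]
        means = []
        for d in dirs:
            sel = at_level[at_level["hi_dir"] == wrap_degrees(pdm + d)]
            means.append(sel["rate"].mean() if len(sel) else np.nan)
        if np.any(np.isnan(means)):
            continue
        curves.append(np.asarray(means) / anchor)
    if not curves:
        raise ValueError(f"no units with complete tuning at level {prior_level}")
    arr = np.vstack(curves)
    return dirs, arr.mean(axis=0), arr.std(axis=0, ddof=1) / np.sqrt(len(arr)), len(arr)
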