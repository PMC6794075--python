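"""Task-faithful synthetic sessions: behavior and Poisson spike trains.

The generator emulates the rule-guided reach-selection task: blocks of eight
successful trials (six instructed, two free-choice) at a fixed likelihood
ratio and pre-cue location, seven ratios {6:0 .. 0:6}, four cardinal pre-cue
locations, and the trial timeline (500-1000 ms fixation, 500 ms pre-cue,
500-1500 ms memory period, rule-cue with simultaneous go signal).

Neural ground truth follows the two empirically motivated unit classes:

UR (up-regulating)
    carries a single von-Mises-shaped response lobe at the high-prior goal,
    with gain growing linearly in prior level; untuned in zero-prior trials.
DR (down-regulating)
    carries lobes at both potential goals (choice-set co-encoding); the lobe
    of the devalued (low-prior) goal shrinks linearly with prior level.

Response lobes are exactly zero at and beyond 90 degrees from their center,
so conditions whose potential goals are orthogonal to a unit's preferred
axis show no prior modulation by construction.  After the rule-cue, each
unit transitions to single-goal movement coding at its own selection
latency (an area offset plus a class offset plus jitter), which is what the
latency stage is asked to recover.

Spiking is an inhomogeneous Poisson process sampled on a 1 ms grid.  A
single root seed spawns named child streams (units, trials, behavior,
spikes) so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import Dataset
from .records import (
    CARDINAL_DIRECTIONS,
    PRIOR_RATIOS,
    congruency_of,
    derive_prior_level,
    rule_goal,
    wrap_degrees,
)


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioral bias parameters (shapes mirror the empirical patterns:
    graded choice bias, follow/against RT and error-rate asymmetries)."""

    #: logistic slope of P(follow high prior) per unit prior level
    choice_bias_slope: float = 2.8
    rt_base: float = 420.0  # ms
    #: RT shift in ms per unit prior level (+ for against, - for follow)
    rt_congruency_effect: float = 60.0
    rt_noise_sd: float = 0.12  # log-scale sd of the multiplicative RT noise
    error_base: float = 0.05
    #: error-rate change per unit prior level (+ against, - follow)
    error_congruency_slope: float = 0.25


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    n_units_per_area: int = 48  # total per area, split across subjects
    #: successful 8-trial blocks per session; 84 = three repetitions of each
    #: of the 28 ratio x location combinations (balanced design)
    n_blocks: int = 84
    seed: int = 0
    n_subjects: int = 2
    class_mixture: dict = field(
        default_factory=lambda: {"UR": 0.3, "DR": 0.3, "untuned": 0.4}
    )
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    #: base selection latency per area, ms after rule-cue onset
    area_latency: dict = field(default_factory=lambda: {"PMd": 160.0, "PRR": 200.0})
    #: class-specific latency offset, ms (DR selection signals lead)
    class_latency: dict = field(
        default_factory=lambda: {"UR": 15.0, "DR": -15.0, "untuned": 0.0}
    )
    latency_jitter_sd: float = 5.0
    baseline_range: tuple = (6.0, 14.0)
    gain_range: tuple = (16.0, 30.0)
    tuning_kappa: float = 4.0
    prior_slope_range: tuple = (0.8, 1.2)
    #: task timing (ms): uniform fixation, fixed pre-cue, uniform memory
    fixation_range: tuple = (500.0, 1000.0)
    precue_ms: float = 500.0
    memory_range: tuple = (500.0, 1500.0)
    rulecue_ms: float = 250.0
    movement_ms: float = 300.0

    def validate(self) -> "SimConfig":
        if self.n_units_per_area < 1 or self.n_blocks < 1:
            raise ValueError("n_units_per_area and n_blocks must be >= 1")
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        if self.fixation_range != (500.0, 1000.0) and self.fixation_range[0] > self.fixation_range[1]:
            raise ValueError("bad fixation range")
        return self


def child_rngs(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Named independent random streams spawned from one root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# units

def generate_units(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw unit tables with ground-truth tuning/class parameters."""
    rows = []
    subjects = [f"S{i + 1}" for i in range(config.n_subjects)]
    for area in ("PMd", "PRR"):
        per_subject = np.array_split(np.arange(config.n_units_per_area), config.n_subjects)
        for subj, idx in zip(subjects, per_subject):
            session = f"{subj}-sess1"
            for i in idx:
                klass = rng.choice(
                    list(config.class_mixture), p=list(config.class_mixture.values())
                )
                gain = 0.0 if klass == "untuned" else rng.uniform(*config.gain_range)
                latency = (
                    config.area_latency[area]
                    + config.class_latency[klass]
                    + rng.normal(0.0, config.latency_jitter_sd)
                )
                rows.append(
                    {
                        "unit_id": f"{area}-{subj}-{i:03d}",
                        "session_id": session,
                        "subject_id": subj,
                        "area": area,
                        "truth_klass": klass,
                        "truth_pd": float(rng.choice(CARDINAL_DIRECTIONS)),
                        "truth_baseline_rate": rng.uniform(*config.baseline_range),
                        "truth_tuning_gain": gain,
                        "truth_tuning_width": config.tuning_kappa,
                        "truth_prior_slope": rng.uniform(*config.prior_slope_range),
                        "truth_selection_latency": latency,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trials

def plan_trials(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plan trial skeletons: block structure, cues, timing; no behavior yet.

    Each 8-trial block holds the prior ratio and pre-cue location constant
    and contains exactly two free-choice and six instructed trials, the
    instructed rules drawn in exact proportion to the likelihood ratio.
    """
    config.validate()
    combos = [(r, loc) for r in PRIOR_RATIOS for loc in CARDINAL_DIRECTIONS]
    rows = []
    for s in range(config.n_subjects):
        subj = f"S{s + 1}"
        session = f"{subj}-sess1"
        reps = int(np.ceil(config.n_blocks / len(combos)))
        schedule = [c for _ in range(reps) for c in combos][: config.n_blocks]
        order = rng.permutation(len(schedule))
        for b, k in enumerate(order):
            (k_ccw, k_cw), loc = schedule[k]
            kinds = ["free_choice"] * 2 + ["instructed"] * 6
            rules = ["none"] * 2 + ["ccw"] * k_ccw + ["cw"] * k_cw
            pos = rng.permutation(8)
            level, _ = derive_prior_level((k_ccw, k_cw))
            for j, p in enumerate(pos):
                fix = rng.uniform(*config.fixation_range)
                memory = rng.uniform(*config.memory_range)
                t_precue_on = fix
                t_precue_off = t_precue_on + config.precue_ms
                t_rulecue_on = t_precue_off + memory
                rows.append(
                    {
                        "trial_id": f"{session}-b{b:03d}-t{j}",
                        "session_id": session,
                        "subject_id": subj,
                        "precue_location": float(loc),
                        "prior_ccw": k_ccw,
                        "prior_cw": k_cw,
                        "prior_level": level,
                        "trial_type": kinds[p],
                        "instructed_rule": rules[p],
                        "chosen_rule": "none",
                        "reach_direction": np.nan,
                        "congruency": "none",
                        "rt": np.nan,
                        "outcome": "correct",
                        "t_fixation_on": 0.0,
                        "t_precue_on": t_precue_on,
                        "t_precue_off": t_precue_off,
                        "t_rulecue_on": t_rulecue_on,
                        "t_go": t_rulecue_on,
                        "t_movement_on": np.nan,
                        "t_movement_off": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def generate_behavior(
    trials: pd.DataFrame, params: BehaviorParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill choices, outcomes and reaction times into planned trials.

    Free-choice trials follow the high-prior rule with logistic probability
    sigma(slope * level); instructed trials err with a congruency-dependent
    Bernoulli rate; RTs are drawn from a shifted log-normal whose mean moves
    with congruency x prior.  Free-choice rewards are 1.5 or 0.5 units with
    equal probability; instructed correct reaches earn 1 unit.
    """
    trials = trials.copy()
    chosen, outcome, rts, rewards = [], [], [], []
    t_mov_on, t_mov_off, congr, reach = [], [], [], []
    for row in trials.itertuples(index=False):
        ratio = (int(row.prior_ccw), int(row.prior_cw))
        level, hi_rule = derive_prior_level(ratio)
        if row.trial_type == "free_choice":
            p_follow = 1.0 / (1.0 + np.exp(-params.choice_bias_slope * level))
            if hi_rule == "tie":
                rule = "cw" if rng.random() < 0.5 else "ccw"
            else:
                lo_rule = "cw" if hi_rule == "ccw" else "ccw"
                rule = hi_rule if rng.random() < p_follow else lo_rule
            out = "correct"
            rewards.append(1.5 if rng.random() < 0.5 else 0.5)
        else:
            instructed = row.instructed_rule
            instr_goal = rule_goal(row.precue_location, instructed)
            instr_congr = congruency_of(ratio, row.precue_location, instr_goal)
            sgn = 1.0 if instr_congr == "against" else -1.0
            p_err = float(
                np.clip(
                    params.error_base + sgn * params.error_congruency_slope * level,
                    0.005,
                    0.995,
                )
            )
            if rng.random() < p_err:
                rule = "cw" if instructed == "ccw" else "ccw"
                out = "error"
                rewards.append(0.0)
            else:
                rule = instructed
                out = "correct"
                rewards.append(1.0)
        goal = rule_goal(row.precue_location, rule)
        cg = congruency_of(ratio, row.precue_location, goal)
        sgn = 1.0 if cg == "against" else -1.0
        mean_rt = params.rt_base + sgn * params.rt_congruency_effect * level
        rt = mean_rt * np.exp(
            params.rt_noise_sd * rng.standard_normal() - params.rt_noise_sd**2 / 2
        )
        rt = float(np.clip(rt, 150.0, 799.0))
        chosen.append(rule)
        outcome.append(out)
        rts.append(rt)
        reach.append(goal)
        congr.append(cg)
        t_mov_on.append(row.t_go + rt)
        t_mov_off.append(row.t_go + rt + 300.0)
    trials["chosen_rule"] = chosen
    trials["outcome"] = outcome
    trials["rt"] = rts
    trials["reach_direction"] = reach
    trials["congruency"] = congr
    trials["reward"] = rewards
    trials["t_movement_on"] = t_mov_on
    trials["t_movement_off"] = t_mov_off
    return trials


# ---------------------------------------------------------------------------
# rates and spikes

def lobe(delta_deg: np.ndarray, kappa: float) -> np.ndarray:
    """Von-Mises-shaped response lobe, 1 at its center and exactly 0 at and
    beyond +-90 degrees (baseline-clipped circular bump)."""
    d = np.deg2rad(np.asarray(delta_deg, dtype=float))
    raw = (np.exp(kappa * (np.cos(d) - 1.0)) - np.exp(-kappa)) / (1.0 - np.exp(-kappa))
    return np.clip(raw, 0.0, None)


def _goal_weights(
    klass: str, prior_slope: float, level: float, hi_dir: float | None,
    goals: tuple[float, float],
) -> dict[float, float]:
    """Per-goal lobe weights during planning for one trial."""
    if klass == "UR":
        if hi_dir is None or level == 0.0:
            return {g: 0.0 for g in goals}
        return {g: prior_slope * level if g == hi_dir else 0.0 for g in goals}
    if klass == "DR":
        w = {}
        for g in goals:
            if hi_dir is None or level == 0.0 or g == hi_dir:
                w[g] = 1.0
            else:
                w[g] = max(0.0, 1.0 - prior_slope * level)
        return w
    return {g: 0.0 for g in goals}


def rate_profile(truth: pd.Series | dict, trial: pd.Series | dict, t: np.ndarray) -> np.ndarray:
    """Instantaneous firing rate (Hz) of one unit in one trial at times ``t``.

    Baseline before the pre-cue; a prior-weighted planning profile from
    pre-cue onset; a transition to single-goal movement coding at the unit's
    selection latency after rule-cue onset.  Transitions are smooth logistic
    blends (20 ms time constant) so the selection latency is well defined as
    the inflection of the transition.
    """
    g = truth.get if hasattr(truth, "get") else truth.__getitem__
    tr = trial.get if hasattr(trial, "get") else trial.__getitem__
    t = np.asarray(t, dtype=float)
    base = float(g("truth_baseline_rate"))
    gain = float(g("truth_tuning_gain"))
    kappa = float(g("truth_tuning_width"))
    pd_deg = float(g("truth_pd"))
    klass = g("truth_klass")
    slope = float(g("truth_prior_slope"))

    loc = float(tr("precue_location"))
    goals = (wrap_degrees(loc - 90.0), wrap_degrees(loc + 90.0))
    level, hi_rule = derive_prior_level((int(tr("prior_ccw")), int(tr("prior_cw"))))
    hi_dir = None if hi_rule == "tie" else rule_goal(loc, hi_rule)

    weights = _goal_weights(klass, slope, level, hi_dir, goals)
    plan_rate = base + gain * sum(
        w * float(lobe(gl - pd_deg, kappa)) for gl, w in weights.items()
    )

    reach = tr("reach_direction")
    if reach is None or (isinstance(reach, float) and np.isnan(reach)) or gain == 0.0:
        move_rate = base if gain == 0.0 else plan_rate
    else:
        move_rate = base + 1.2 * gain * float(lobe(float(reach) - pd_deg, kappa))

    t_visual = float(tr("t_precue_on")) + 60.0
    t_select = float(tr("t_rulecue_on")) + float(g("truth_selection_latency"))
    s1 = expit((t - t_visual) / 20.0)
    s2 = expit((t - t_select) / 20.0)
    rate = base + (plan_rate - base) * s1 + (move_rate - plan_rate) * s2
    return np.clip(rate, 0.0, None)


def generate_spikes(
    units: pd.DataFrame,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    dt_ms: float = 1.0,
) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike tables for every unit on its session's
    trials, sampled on a ``dt_ms`` grid (per-bin Poisson counts, spike times
    jittered uniformly within their bin)."""
    out_unit, out_trial, out_time = [], [], []
    trials_by_session = dict(tuple(trials.groupby("session_id", sort=False)))
    for unit in units.itertuples(index=False):
        sess_trials = trials_by_session.get(unit.session_id)
        if sess_trials is None:
            continue
        truth = {f: getattr(unit, f) for f in units.columns}
        for trial in sess_trials.itertuples(index=False):
            tr = {f: getattr(trial, f) for f in trials.columns}
            t_end = tr["t_movement_off"]
            if t_end is None or (isinstance(t_end, float) and np.isnan(t_end)):
                t_end = tr["t_rulecue_on"] + 800.0
            grid = np.arange(0.0, float(t_end) + 100.0, dt_ms) + dt_ms / 2.0
            rate = rate_profile(truth, tr, grid)
            if np.any(rate < -1e-9):
                raise ValueError(f"negative rate for unit {unit.unit_id}")
            counts = rng.poisson(rate * dt_ms / 1000.0)
            nz = np.nonzero(counts)[0]
            if len(nz) == 0:
                continue
            reps = np.repeat(grid[nz], counts[nz])
            times = reps + rng.uniform(-dt_ms / 2.0, dt_ms / 2.0, size=len(reps))
            times = np.sort(np.clip(times, 0.0, None))
            out_unit.append(np.full(len(times), unit.unit_id))
            out_trial.append(np.full(len(times), tr["trial_id"]))
            out_time.append(times)
    if not out_unit:
        return pd.DataFrame(columns=["unit_id", "trial_id", "time_ms"])
    return pd.DataFrame(
        {
            "unit_id": np.concatenate(out_unit),
            "trial_id": np.concatenate(out_trial),
            "time_ms": np.concatenate(out_time),
        }
    )


def simulate_session(config: SimConfig) -> Dataset:
    """Full synthetic dataset: units, behavior-completed trials, spikes."""
    config.validate()
    rngs = child_rngs(config.seed, "units", "trials", "behavior", "spikes")
    units = generate_units(config, rngs["units"])
    trials = plan_trials(config, rngs["trials"])
    trials = generate_behavior(trials, config.behavior, rngs["behavior"])
    spikes = generate_spikes(units, trials, rngs["spikes"])
    return Dataset(units=units, trials=trials, spikes=spikes)


# ---------------------------------------------------------------------------
# focused selection-latency population (used for latency calibration studies)

def simulate_selection_traces(
    n_units: int,
    selection_latency_ms: float,
    rng: np.random.Generator,
    n_trials: int = 20,
    t_start: float = -300.0,
    t_end: float = 600.0,
    baseline: float = 10.0,
    gain: float = 20.0,
    latency_jitter_sd: float = 5.0,
    dt_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-averaged spike-count traces for two opposing-goal conditions.

    Each unit co-encodes both goals during planning, then transitions to
    single-goal coding (preferred condition up to baseline+gain, the other
    down to baseline) at the population latency plus per-unit jitter.
    Returns ``(t, traces_a, traces_b)`` with traces of shape
    ``(n_units, n_t)`` in Hz, Poisson-sampled over ``n_trials`` trials.

    This is the controlled population used to calibrate the neural-distance
    latency estimators (recovery of an injected latency offset, permutation
    power and type-I error).
    """
    t = np.arange(t_start, t_end, dt_ms) + dt_ms / 2.0
    lat = selection_latency_ms + rng.normal(0.0, latency_jitter_sd, size=n_units)
    s = expit((t[None, :] - lat[:, None]) / 20.0)
    plan = baseline + 0.5 * gain
    rate_up = plan + (baseline + gain - plan) * s
    rate_dn = plan + (baseline - plan) * s
    traces = []
    for rate in (rate_up, rate_dn):
        lam = np.repeat(rate[:, None, :], n_trials, axis=1) * dt_ms / 1000.0
        counts = rng.poisson(lam)
        traces.append(counts.mean(axis=1) / (dt_ms / 1000.0))
    return t, traces[0], traces[1]
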