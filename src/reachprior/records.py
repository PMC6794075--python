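"""Shared data model for the rule-guided reach-selection task.

The task: a monkey fixates, a probabilistic pre-cue flashes at one of four
cardinal locations, and the two potential reach goals lie 90 degrees clockwise
(cw) and counter-clockwise (ccw) from the pre-cue.  The relative sizes of the
pre-cue arrowheads announce the likelihood ratio with which the cw or ccw rule
will later be instructed.  Ratios are drawn from {6:0, 5:1, 4:2, 3:3, 2:4,
1:5, 0:6} (ccw:cw) and are held constant within blocks of eight successful
trials (six instructed, two free-choice).  A colored rule-cue resolves
instructed trials; a white rule-cue signals a free choice with symmetric
reward.

This module fixes the numeric conventions every downstream stage relies on:
angles in degrees with 0 = rightward and counter-clockwise positive, times in
milliseconds from trial start, analysis windows half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Cardinal directions used for pre-cues and reach goals (degrees).
CARDINAL_DIRECTIONS = (0, 90, 180, 270)

#: Likelihood ratios (ccw:cw) used to manipulate the action prior.
PRIOR_RATIOS = ((6, 0), (5, 1), (4, 2), (3, 3), (2, 4), (1, 5), (0, 6))

#: Normalized prior strengths realised by the seven ratios.
PRIOR_LEVELS = (0.0, 0.25, 0.5, 0.75)

#: Ordered trial events; ``t_go`` may coincide with ``t_rulecue_on`` (the go
#: signal is given simultaneously with the rule-cue), all other pairs are
#: strictly ordered.
EVENT_ORDER = (
    "fixation_on",
    "precue_on",
    "precue_off",
    "rulecue_on",
    "go",
    "movement_on",
    "movement_off",
)

AREAS = ("PMd", "PRR")

MAX_RT_MS = 800.0


class SchemaError(ValueError):
    """A dataset row violates the task schema or an invariant."""


def wrap_degrees(angle: float) -> float:
    """Map an angle to [0, 360)."""
    return float(np.mod(angle, 360.0))


def rule_goal(precue_location: float, rule: str) -> float:
    """Reach goal implied by a transformation rule at a pre-cue location.

    The cw rule rotates the pre-cue location -90 degrees, the ccw rule +90
    (counter-clockwise positive convention).
    """
    if rule == "cw":
        return wrap_degrees(precue_location - 90.0)
    if rule == "ccw":
        return wrap_degrees(precue_location + 90.0)
    raise ValueError(f"unknown rule {rule!r}")


def goal_rule(precue_location: float, reach_direction: float) -> str:
    """Inverse of :func:`rule_goal`: which rule produces this reach."""
    if wrap_degrees(precue_location - 90.0) == wrap_degrees(reach_direction):
        return "cw"
    if wrap_degrees(precue_location + 90.0) == wrap_degrees(reach_direction):
        return "ccw"
    raise ValueError(
        f"reach {reach_direction} is not +-90 deg from pre-cue {precue_location}"
    )


def derive_prior_level(prior_ratio: tuple[int, int]) -> tuple[float, str]:
    """Normalized prior strength and high-prior rule for a likelihood ratio.

    Between pre-cue and rule-cue each rule carries an initial expected value
    (iEV).  In a block of eight trials, six are instructed (split k:(6-k)
    between the rules) and two are free choices worth half an expected unit to
    either rule, so the iEV of the rule with k instructed trials is
    ``(6/8)*(k/6) + (2/8)*(1/2) = k/8 + 1/8``.  This reproduces the iEV pairs
    {0.875:0.125, 0.75:0.25, 0.625:0.375, 0.5:0.5} for ratios 6:0 .. 3:3.

    The prior level is the absolute normalized iEV difference
    ``|iEV_hi - iEV_lo| / (iEV_hi + iEV_lo)``, giving {0, 0.25, 0.5, 0.75}.

    Parameters
    ----------
    prior_ratio : (int, int)
        Instructed-trial counts per block for the (ccw, cw) rules; must be
        non-negative and sum to 6.

    Returns
    -------
    level : float
    high_prior_rule : {"ccw", "cw", "tie"}
    """
    k_ccw, k_cw = prior_ratio
    if k_ccw < 0 or k_cw < 0 or k_ccw + k_cw != 6:
        raise ValueError(f"invalid prior ratio {prior_ratio!r}: must sum to 6")
    iev_ccw = k_ccw / 8.0 + 1.0 / 8.0
    iev_cw = k_cw / 8.0 + 1.0 / 8.0
    level = abs(iev_ccw - iev_cw) / (iev_ccw + iev_cw)
    if k_ccw > k_cw:
        rule = "ccw"
    elif k_cw > k_ccw:
        rule = "cw"
    else:
        rule = "tie"
    return level, rule


def iev_pair(prior_ratio: tuple[int, int]) -> tuple[float, float]:
    """Initial expected values (ccw, cw) for a likelihood ratio."""
    k_ccw, k_cw = prior_ratio
    if k_ccw < 0 or k_cw < 0 or k_ccw + k_cw != 6:
        raise ValueError(f"invalid prior ratio {prior_ratio!r}: must sum to 6")
    return k_ccw / 8.0 + 1.0 / 8.0, k_cw / 8.0 + 1.0 / 8.0


def congruency_of(
    prior_ratio: tuple[int, int],
    precue_location: float,
    reach_direction: float,
) -> str:
    """Follow/against label of a reach relative to the high-prior direction.

    ``follow`` means the reach went toward the goal of the higher-prior rule.
    In the zero-prior condition (3:3) cw reaches are arbitrarily labelled
    ``follow`` (presentation convention only).
    """
    _, hi_rule = derive_prior_level(prior_ratio)
    rule = goal_rule(precue_location, reach_direction)
    if hi_rule == "tie":
        return "follow" if rule == "cw" else "against"
    return "follow" if rule == hi_rule else "against"


@dataclass(frozen=True)
class EpochWindow:
    """Half-open analysis window ``[offset_start, offset_end)`` in ms,
    anchored to a named trial event."""

    name: str
    anchor_event: str
    offset_start: float | None
    offset_end: float | None
    #: event supplying the end bound when ``offset_end`` is None
    end_event: str | None = None

    def resolve(self, event_times: Mapping[str, float]) -> tuple[float, float]:
        """Absolute (start, end) in trial time, or raise ``KeyError``."""
        if self.anchor_event not in event_times:
            raise KeyError(f"missing event {self.anchor_event!r}")
        anchor = event_times[self.anchor_event]
        start = anchor + (self.offset_start or 0.0)
        if self.end_event is not None:
            if self.end_event not in event_times:
                raise KeyError(f"missing event {self.end_event!r}")
            end = event_times[self.end_event]
        else:
            end = anchor + self.offset_end
        return start, end


#: The four analysis windows: 300 ms before pre-cue onset (baseline), 300 ms
#: after pre-cue onset (pre-cue), last 300 ms before the rule/go-signal
#: (planning), and reach onset to offset (movement).
EPOCHS: dict[str, EpochWindow] = {
    "baseline": EpochWindow("baseline", "precue_on", -300.0, 0.0),
    "precue": EpochWindow("precue", "precue_on", 0.0, 300.0),
    "planning": EpochWindow("planning", "rulecue_on", -300.0, 0.0),
    "movement": EpochWindow(
        "movement", "movement_on", 0.0, None, end_event="movement_off"
    ),
}


def epoch_rate(
    spike_times: np.ndarray,
    window: EpochWindow,
    event_times: Mapping[str, float],
) -> float:
    """Firing rate (Hz) of one trial's spikes in an analysis window.

    Spikes falling exactly on the end bound are excluded (half-open window).
    """
    start, end = window.resolve(event_times)
    if end <= start:
        raise ValueError(f"empty window [{start}, {end})")
    t = np.asarray(spike_times, dtype=float)
    n = int(np.count_nonzero((t >= start) & (t < end)))
    return n / ((end - start) / 1000.0)


@dataclass(frozen=True)
class SyntheticUnitTruth:
    """Ground-truth generative parameters of a synthetic unit.

    klass
        "UR" (up-regulating: preferred-direction response grows with prior
        toward the PD), "DR" (down-regulating: response shrinks with prior
        toward the opposite direction), or "untuned".
    pd
        Preferred direction in degrees.
    prior_slope
        Modulation strength in normalized response units per unit prior
        level; applied with positive sign at the PD for UR units and as a
        suppression of the devalued option for DR units.
    selection_latency
        Offset (ms after rule-cue onset) at which the unit's activity
        transitions to single-goal movement coding.
    """

    klass: str
    pd: float
    baseline_rate: float
    tuning_gain: float
    tuning_width: float
    prior_slope: float
    selection_latency: float

    def __post_init__(self) -> None:
        if self.klass not in ("UR", "DR", "untuned"):
            raise ValueError(f"unknown unit class {self.klass!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.klass == "untuned" and self.tuning_gain != 0:
            raise ValueError("untuned units must have tuning_gain = 0")


@dataclass(frozen=True)
class UnitRecord:
    unit_id: str
    session_id: str
    subject_id: str
    area: str
    ground_truth: SyntheticUnitTruth | None = None

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValueError(f"area must be one of {AREAS}, got {self.area!r}")


@dataclass
class TrialRecord:
    """One task trial; see module docstring for the task structure."""

    trial_id: str
    session_id: str
    subject_id: str
    precue_location: float
    prior_ratio: tuple[int, int]
    trial_type: str  # instructed | free_choice
    instructed_rule: str  # cw | ccw | none
    chosen_rule: str  # cw | ccw | none
    outcome: str  # correct | error | aborted
    event_times: dict[str, float] = field(default_factory=dict)
    rt: float | None = None

    @property
    def prior_level(self) -> float:
        return derive_prior_level(self.prior_ratio)[0]

    @property
    def high_prior_rule(self) -> str:
        return derive_prior_level(self.prior_ratio)[1]

    @property
    def reach_direction(self) -> float | None:
        if self.chosen_rule in ("cw", "ccw"):
            return rule_goal(self.precue_location, self.chosen_rule)
        return None

    @property
    def congruency(self) -> str | None:
        if self.reach_direction is None:
            return None
        return congruency_of(
            self.prior_ratio, self.precue_location, self.reach_direction
        )

    def validate(self) -> None:
        if self.precue_location not in CARDINAL_DIRECTIONS:
            raise SchemaError(
                f"trial {self.trial_id}: pre-cue location "
                f"{self.precue_location} not cardinal"
            )
        derive_prior_level(self.prior_ratio)  # raises on bad ratio
        if self.trial_type not in ("instructed", "free_choice"):
            raise SchemaError(f"trial {self.trial_id}: bad trial_type")
        if self.trial_type == "free_choice" and self.instructed_rule != "none":
            raise SchemaError(
                f"trial {self.trial_id}: free-choice trial with an instruction"
            )
        if self.trial_type == "instructed" and self.instructed_rule not in (
            "cw",
            "ccw",
        ):
            raise SchemaError(f"trial {self.trial_id}: instructed without rule")
        present = [e for e in EVENT_ORDER if e in self.event_times]
        times = [self.event_times[e] for e in present]
        for (ea, ta), (eb, tb) in zip(
            zip(present, times), zip(present[1:], times[1:])
        ):
            ok = ta <= tb if (ea, eb) == ("rulecue_on", "go") else ta < tb
            if not ok:
                raise SchemaError(
                    f"trial {self.trial_id}: events out of order "
                    f"({ea}={ta} !< {eb}={tb})"
                )
        if (
            self.outcome != "aborted"
            and "go" in self.event_times
            and "movement_on" in self.event_times
        ):
            rt = self.event_times["movement_on"] - self.event_times["go"]
            if rt > MAX_RT_MS:
                raise SchemaError(
                    f"trial {self.trial_id}: rt {rt} ms exceeds {MAX_RT_MS}"
                )
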