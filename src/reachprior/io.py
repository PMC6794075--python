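"""Tabular dataset interchange: units / trials / spikes CSV bundles.

The on-disk layout is three plain CSV files:

``units.csv``
    unit_id, session_id, subject_id, area and, for synthetic units, the
    ground-truth columns ``truth_klass, truth_pd, truth_baseline_rate,
    truth_tuning_gain, truth_tuning_width, truth_prior_slope,
    truth_selection_latency``.
``trials.csv``
    One row per trial with the behavioral fields and one ``t_<event>`` column
    per trial event (ms from trial start).
``spikes.csv``
    unit_id, trial_id, time_ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    CARDINAL_DIRECTIONS,
    EVENT_ORDER,
    MAX_RT_MS,
    AREAS,
    SchemaError,
    congruency_of,
    derive_prior_level,
    rule_goal,
)

UNIT_COLUMNS = ["unit_id", "session_id", "subject_id", "area"]
TRUTH_COLUMNS = [
    "truth_klass",
    "truth_pd",
    "truth_baseline_rate",
    "truth_tuning_gain",
    "truth_tuning_width",
    "truth_prior_slope",
    "truth_selection_latency",
]
TRIAL_COLUMNS = [
    "trial_id",
    "session_id",
    "subject_id",
    "precue_location",
    "prior_ccw",
    "prior_cw",
    "prior_level",
    "trial_type",
    "instructed_rule",
    "chosen_rule",
    "reach_direction",
    "congruency",
    "rt",
    "outcome",
] + [f"t_{e}" for e in EVENT_ORDER]
SPIKE_COLUMNS = ["unit_id", "trial_id", "time_ms"]

_ID_DTYPES = {"unit_id": str, "trial_id": str, "session_id": str, "subject_id": str}


@dataclass
class Dataset:
    """In-memory bundle of the three tables, validated on construction."""

    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame

    def validate(self) -> "Dataset":
        validate_dataset(self)
        return self

    def spikes_by_unit_trial(self) -> dict[tuple[str, str], np.ndarray]:
        """Spike-time arrays keyed by (unit_id, trial_id)."""
        out: dict[tuple[str, str], np.ndarray] = {}
        if len(self.spikes) == 0:
            return out
        for key, grp in self.spikes.groupby(["unit_id", "trial_id"], sort=False):
            out[key] = grp["time_ms"].to_numpy(dtype=float)
        return out


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def validate_dataset(ds: Dataset) -> None:
    """Check schema, foreign keys, and trial invariants; raise SchemaError."""
    _require_columns(ds.units, UNIT_COLUMNS, "units")
    _require_columns(ds.trials, TRIAL_COLUMNS, "trials")
    _require_columns(ds.spikes, SPIKE_COLUMNS, "spikes")

    if ds.units["unit_id"].duplicated().any():
        dup = ds.units.loc[ds.units["unit_id"].duplicated(), "unit_id"].iloc[0]
        raise SchemaError(f"units: duplicate unit_id {dup!r}")
    bad_area = ~ds.units["area"].isin(AREAS)
    if bad_area.any():
        raise SchemaError(
            f"units: unknown area {ds.units.loc[bad_area, 'area'].iloc[0]!r}"
        )
    if ds.trials["trial_id"].duplicated().any():
        dup = ds.trials.loc[ds.trials["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise SchemaError(f"trials: duplicate trial_id {dup!r}")

    tr = ds.trials
    for i, row in tr.iterrows():
        tid = row["trial_id"]
        if row["precue_location"] not in CARDINAL_DIRECTIONS:
            raise SchemaError(f"trial {tid}: non-cardinal pre-cue location")
        level, _ = derive_prior_level((int(row["prior_ccw"]), int(row["prior_cw"])))
        if abs(level - float(row["prior_level"])) > 1e-9:
            raise SchemaError(f"trial {tid}: prior_level inconsistent with ratio")
        if row["trial_type"] == "free_choice" and row["instructed_rule"] != "none":
            raise SchemaError(f"trial {tid}: free-choice trial with instruction")
        if not pd.isna(row["reach_direction"]):
            reach = float(row["reach_direction"])
            goal = {
                rule_goal(row["precue_location"], "cw"),
                rule_goal(row["precue_location"], "ccw"),
            }
            if reach not in goal:
                raise SchemaError(
                    f"trial {tid}: reach {reach} not +-90 deg from pre-cue"
                )
            want = congruency_of(
                (int(row["prior_ccw"]), int(row["prior_cw"])),
                float(row["precue_location"]),
                reach,
            )
            if row["congruency"] != want:
                raise SchemaError(f"trial {tid}: congruency should be {want!r}")
        present = [e for e in EVENT_ORDER if not pd.isna(row.get(f"t_{e}"))]
        for ea, eb in zip(present, present[1:]):
            ta, tb = float(row[f"t_{ea}"]), float(row[f"t_{eb}"])
            ok = ta <= tb if (ea, eb) == ("rulecue_on", "go") else ta < tb
            if not ok:
                raise SchemaError(
                    f"trial {tid}: events out of order ({ea}={ta}, {eb}={tb})"
                )
        if row["outcome"] != "aborted" and not pd.isna(row.get("rt")):
            rt = float(row["rt"])
            if not pd.isna(row.get("t_go")) and not pd.isna(row.get("t_movement_on")):
                if abs(rt - (row["t_movement_on"] - row["t_go"])) > 1e-6:
                    raise SchemaError(f"trial {tid}: rt != movement_on - go")
            if rt > MAX_RT_MS:
                raise SchemaError(f"trial {tid}: rt {rt} exceeds {MAX_RT_MS} ms")

    if len(ds.spikes):
        known_units = set(ds.units["unit_id"])
        known_trials = set(ds.trials["trial_id"])
        bad = ~ds.spikes["unit_id"].isin(known_units)
        if bad.any():
            raise SchemaError(
                f"spikes: dangling unit_id {ds.spikes.loc[bad, 'unit_id'].iloc[0]!r}"
            )
        bad = ~ds.spikes["trial_id"].isin(known_trials)
        if bad.any():
            raise SchemaError(
                f"spikes: dangling trial_id "
                f"{ds.spikes.loc[bad, 'trial_id'].iloc[0]!r}"
            )
        if (ds.spikes["time_ms"] < 0).any():
            raise SchemaError("spikes: negative spike time")


def read_dataset(directory: str | Path) -> Dataset:
    """Read and validate a units/trials/spikes CSV bundle from a directory."""
    directory = Path(directory)
    paths = {name: directory / f"{name}.csv" for name in ("units", "trials", "spikes")}
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing {name} table: {p}")
    units = pd.read_csv(paths["units"], dtype=_ID_DTYPES,
                        float_precision="round_trip")
    trials = pd.read_csv(paths["trials"], dtype=_ID_DTYPES,
                         float_precision="round_trip")
    spikes = pd.read_csv(paths["spikes"], dtype=_ID_DTYPES,
                         float_precision="round_trip")
    # canonical numeric dtypes (integers written without a decimal point
    # would otherwise come back as int columns)
    for col in TRUTH_COLUMNS:
        if col in units.columns and col != "truth_klass":
            units[col] = units[col].astype(float)
    for col in trials.columns:
        if col.startswith("t_") or col in (
            "precue_location", "prior_level", "reach_direction", "rt", "reward"
        ):
            trials[col] = trials[col].astype(float)
    for col in ("prior_ccw", "prior_cw"):
        trials[col] = trials[col].astype(int)
    if "time_ms" in spikes.columns:
        spikes["time_ms"] = spikes["time_ms"].astype(float)
    ds = Dataset(units=units, trials=trials, spikes=spikes)
    ds.validate()
    return ds


def write_dataset(ds: Dataset, directory: str | Path) -> None:
    """Write a validated bundle as units/trials/spikes CSVs."""
    ds.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # %.17g: float columns survive the text round trip bit-exactly
    ds.units.to_csv(directory / "units.csv", index=False, float_format="%.17g")
    ds.trials.to_csv(directory / "trials.csv", index=False, float_format="%.17g")
    ds.spikes.to_csv(directory / "spikes.csv", index=False, float_format="%.17g")
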