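"""Run configuration: every tunable of the pipeline in one validated object.

Defaults are the analysis constants used throughout: EPSP kernel rise/decay
2/50 ms, Gaussian width 50 ms, 1 ms grid, selectivity alpha 0.01, 5 Hz rate
gate, modulation alpha 0.05, bootstrap N=1000 (90% CIs), permutation
N=10,000, ND velocity threshold 0.3, MVT search window 0-600 ms after the
rule-cue.  Configs load from YAML mappings; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import BehaviorParams, SimConfig


@dataclass(frozen=True)
class AnalysisConfig:
    tau_g_ms: float = 2.0
    tau_d_ms: float = 50.0
    sigma_ms: float = 50.0
    dt_ms: float = 1.0
    alpha_select: float = 0.01
    rate_gate_hz: float = 5.0
    alpha_modulation: float = 0.05
    n_boot: int = 1000
    ci_level: float = 90.0
    n_perm: int = 10000
    dip_n_boot: int = 10000
    velocity_threshold: float = 0.3
    mvt_window_ms: tuple = (0.0, 600.0)
    roc_min_trials: int = 5
    #: prior ratios used for cross-class latency comparisons (zero prior and
    #: one high-prior level; full-prior against trials are too scarce)
    latency_prior_levels: tuple = (0.0, 0.5)

    def validate(self) -> "AnalysisConfig":
        if self.tau_g_ms <= 0 or self.tau_d_ms <= 0 or self.sigma_ms <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        for a in (self.alpha_select, self.alpha_modulation):
            if not 0 < a < 1:
                raise ValueError("alpha out of range")
        if self.n_boot < 1 or self.n_perm < 1 or self.dip_n_boot < 1:
            raise ValueError("resampling counts must be >= 1")
        if self.mvt_window_ms[0] >= self.mvt_window_ms[1]:
            raise ValueError("bad MVT search window")
        return self


@dataclass(frozen=True)
class RunConfig:
    simulation: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if f.name == "behavior" and isinstance(value, dict):
            value = _build(BehaviorParams, value, f"{path}.behavior")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def validate_config(data: dict | None) -> RunConfig:
    """Normalize a (possibly partial) mapping into a RunConfig.

    Missing keys take the defaults; unknown keys and out-of-range values
    raise named errors before any stage runs.
    """
    data = data or {}
    unknown = set(data) - {"simulation", "analysis"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    sim = _build(SimConfig, data.get("simulation") or {}, "simulation")
    ana = _build(AnalysisConfig, data.get("analysis") or {}, "analysis")
    sim.validate()
    ana.validate()
    return RunConfig(simulation=sim, analysis=ana)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file (or defaults when ``path`` is None)."""
    if path is None:
        return validate_config({})
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return validate_config(data)
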