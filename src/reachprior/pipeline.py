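"""End-to-end orchestration: simulate -> density -> tuning -> classify ->
behavior -> latency -> roc, with a manifest and a human-readable report.

Every stage is a pure function of (inputs, config, seed); the manifest
records the config snapshot, per-stage seeds, counts, wall-clock, and
output-file digests, so deleting intermediate files and re-running
reproduces them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import choice as choice_mod
from . import latency as latency_mod
from . import modulation as modulation_mod
from . import tuning as tuning_mod
from .config import RunConfig
from .density import KernelSpec, density
from .io import Dataset, read_dataset
from .records import wrap_degrees
from .synthetic import simulate_session


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# condition-averaged densities for the latency stage

def unit_condition_traces(
    ds: Dataset,
    unit_ids: list[str],
    cfg: RunConfig,
    t_start: float = -300.0,
    t_end: float = 600.0,
) -> tuple[np.ndarray, dict]:
    """Per-unit condition-averaged Gaussian spike densities aligned to the
    rule-cue, for opposing-goal trial groups.

    Conditions are (prior_level, pre-cue location, reach goal) cells built
    from correct instructed trials at the configured latency prior levels;
    at zero prior the two opposing goals at a location are simply the cw and
    ccw reaches.  Traces are normalized per unit by its full-prior PD_max
    planning response (units without a positive anchor are dropped by the
    caller).

    Returns (t, traces) with ``traces[(level, location, goal)]`` an
    (n_units, n_t) array in normalized rate units.
    """
    spec = KernelSpec(kind="gaussian", sigma=cfg.analysis.sigma_ms, dt=cfg.analysis.dt_ms)
    tr = ds.trials
    sel = tr[
        (tr["trial_type"] == "instructed")
        & (tr["outcome"] == "correct")
        & (tr["prior_level"].astype(float).isin(cfg.analysis.latency_prior_levels))
    ]
    spikes_by_ut = ds.spikes_by_unit_trial()
    align = tr.set_index("trial_id")["t_rulecue_on"]
    unit_sessions = ds.units.set_index("unit_id")["session_id"]

    t_axis = None
    traces: dict[tuple, list] = {}
    keys = []
    for level, lgrp in sel.groupby(sel["prior_level"].astype(float)):
        for loc, grp in lgrp.groupby("precue_location"):
            for goal in (wrap_degrees(loc - 90.0), wrap_degrees(loc + 90.0)):
                cell = grp[grp["reach_direction"].astype(float) == goal]
                keys.append(((float(level), float(loc), float(goal)), cell))
    for key, cell in keys:
        traces[key] = []
    for uid in unit_ids:
        sess = unit_sessions[uid]
        for key, cell in keys:
            ids = cell.loc[cell["session_id"] == sess, "trial_id"]
            pooled = []
            for tid in ids:
                st = spikes_by_ut.get((uid, tid))
                t0 = align[tid]
                if st is not None:
                    pooled.append(st - t0)
                else:
                    pooled.append(np.empty(0))
            if not pooled:
                traces[key].append(np.full(1, np.nan))
                continue
            allspk = np.concatenate(pooled) if pooled else np.empty(0)
            t_axis, vals = density(allspk, spec, t_start, t_end)
            traces[key].append(vals / len(pooled))
    out = {k: np.vstack(v) for k, v in traces.items()}
    return t_axis, out


def _normalized_traces(
    traces: dict, anchors: pd.Series, unit_ids: list[str]
) -> tuple[list[str], dict]:
    """Divide each unit's traces by its anchor; drop units without one."""
    keep = [i for i, u in enumerate(unit_ids) if anchors.get(u, 0.0) > 0]
    kept_ids = [unit_ids[i] for i in keep]
    scale = np.array([anchors[u] for u in kept_ids])[:, None]
    return kept_ids, {k: v[keep] / scale for k, v in traces.items()}


def opposing_goal_pairs(traces: dict, level: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """The four pre-cue-location opposing-goal trace pairs at one level."""
    pairs = []
    locs = sorted({k[1] for k in traces if k[0] == level})
    for loc in locs:
        a = traces[(level, loc, wrap_degrees(loc - 90.0))]
        b = traces[(level, loc, wrap_degrees(loc + 90.0))]
        pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# the pipeline

def run_pipeline(
    cfg: RunConfig,
    out_dir: str | Path,
    in_dir: str | Path | None = None,
    write_spikes: bool = True,
) -> dict:
    """Execute all stages and write artifacts plus report.md / manifest.json.

    Returns the manifest dict.  ``in_dir`` may point at an existing dataset
    bundle; otherwise a synthetic session is generated from the config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "stages": {},
        "outputs": {},
    }
    report_lines: list[str] = ["# reachprior pipeline report", ""]

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time()}

    def done(name, **counts):
        st = manifest["stages"][name]
        st["seconds"] = round(time.time() - st.pop("t_start"), 2)
        st.update(counts)

    # --- simulate / load -------------------------------------------------
    stage("simulate")
    if in_dir is not None:
        ds = read_dataset(in_dir)
    else:
        ds = simulate_session(cfg.simulation)
        # %.17g keeps float columns exact across a write/read cycle
        ds.units.to_csv(out_dir / "units.csv", index=False, float_format="%.17g")
        ds.trials.to_csv(out_dir / "trials.csv", index=False, float_format="%.17g")
        if write_spikes:
            ds.spikes.to_csv(out_dir / "spikes.csv", index=False,
                             float_format="%.17g")
    done("simulate", n_units=len(ds.units), n_trials=len(ds.trials),
         n_spikes=len(ds.spikes))

    # --- tuning / gating -------------------------------------------------
    stage("tuning")
    gated = tuning_mod.gate_motor_goal_units(
        ds, cfg.analysis.rate_gate_hz, cfg.analysis.alpha_select
    )
    gated.to_csv(out_dir / "gating.csv", index=False)
    counts = gated.groupby("area")["is_motor_goal"].agg(["sum", "size"])
    for area, row in counts.iterrows():
        report_lines.append(
            f"- {area}: {int(row['sum'])}/{int(row['size'])} motor-goal neurons"
        )
    cond = tuning_mod.planning_rate_conditions(ds, gated)
    pop_rows = []
    for level in sorted(cond["prior_level"].unique()):
        try:
            dirs, mean, se, n = tuning_mod.population_tuning(cond, float(level))
        except ValueError:
            continue
        for d, m, s in zip(dirs, mean, se):
            pop_rows.append({"prior_level": level, "aligned_direction": d,
                             "mean": m, "se": s, "n_units": n})
    pd.DataFrame(pop_rows).to_csv(out_dir / "population_tuning.csv", index=False)
    done("tuning", n_motor_goal=int(gated["is_motor_goal"].sum()))

    # --- classify --------------------------------------------------------
    stage("classify")
    results = modulation_mod.unit_modulation_results(
        cond, alpha=cfg.analysis.alpha_modulation
    )
    mod_df = pd.DataFrame([r.__dict__ for r in results])
    mod_df.to_csv(out_dir / "modulation.csv", index=False)
    rng_dip = np.random.default_rng(
        np.random.SeedSequence([cfg.simulation.seed, 1]).generate_state(1)[0]
    )
    dip_summary = {}
    class_counts = {}
    for area, grp in mod_df.groupby("area"):
        graded = grp[grp["klass"].isin(["UR", "DR"])]
        class_counts[area] = grp["klass"].value_counts().to_dict()
        if len(graded) >= 4:
            res = modulation_mod.dip_test(
                graded["angle"].to_numpy(),
                n_boot=cfg.analysis.dip_n_boot,
                rng=rng_dip,
            )
            dip_summary[area] = {"dip": res.dip, "p": res.p, "n": res.n}
            report_lines.append(
                f"- {area} modulation-angle dip test: dip={res.dip:.4f}, "
                f"p={res.p:.4g} (n={res.n})"
            )
    with open(out_dir / "modulation_summary.json", "w") as fh:
        json.dump({"class_counts": class_counts, "dip": dip_summary}, fh,
                  indent=2, default=_json_default)

    # population fixed-effect tests per recovered class
    norm_cond = modulation_mod.normalize_rates(cond)
    pop_tests = {}
    for klass in ("UR", "DR"):
        ids = mod_df.loc[mod_df["klass"] == klass, "unit_id"]
        sub = norm_cond[norm_cond["unit_id"].isin(ids)]
        if sub["unit_id"].nunique() >= 2:
            rep = modulation_mod.population_modulation_test(
                sub, rate_column="norm_rate"
            )
            pop_tests[klass] = rep.slopes.to_dict("records")
    with open(out_dir / "population_modulation.json", "w") as fh:
        json.dump(pop_tests, fh, indent=2, default=_json_default)
    done("classify", n_classified=len(mod_df))

    # --- behavior --------------------------------------------------------
    stage("behavior")
    summary = behavior_mod.summarize_behavior(ds.trials)
    summary.error_rates.to_csv(out_dir / "behavior_error_rates.csv", index=False)
    summary.rts.to_csv(out_dir / "behavior_rts.csv", index=False)
    summary.choice_probabilities.to_csv(
        out_dir / "behavior_choice_probabilities.csv", index=False
    )
    fits = behavior_mod.fit_behavior_models(ds.trials)
    with open(out_dir / "behavior_models.json", "w") as fh:
        json.dump(
            [
                {"model_id": f.model_id, "method": f.method,
                 "fallback": f.fallback, "terms": f.terms.to_dict("records")}
                for f in fits
            ],
            fh, indent=2, default=_json_default,
        )
    cp = summary.choice_probabilities
    top = cp.loc[cp["prior_level"].idxmax()]
    report_lines.append(
        f"- choice probability at the strongest prior: "
        f"{top['choice_probability']:.2f} (n={int(top['n'])})"
    )
    done("behavior", n_model_fits=len(fits))

    # --- latency ---------------------------------------------------------
    stage("latency")
    anchors = {}
    for uid, grp in norm_cond.groupby("unit_id"):
        pdm = float(grp["pd_max"].iloc[0])
        full = grp[(grp["prior_level"] == 0.75) & (grp["hi_dir"] == pdm)]
        anchors[uid] = full["rate"].mean() if len(full) else 0.0
    anchors = pd.Series(anchors)

    latency_report: dict = {}
    mvts: dict[tuple, float] = {}
    rng_lat = np.random.default_rng(
        np.random.SeedSequence([cfg.simulation.seed, 2]).generate_state(1)[0]
    )
    pop_traces: dict[tuple, dict] = {}
    t_axis = None
    area_class = mod_df[mod_df["klass"].isin(["UR", "DR"])]
    for (area, klass), grp in area_class.groupby(["area", "klass"]):
        ids = grp["unit_id"].tolist()
        if len(ids) < 3:
            continue
        t_axis, traces = unit_condition_traces(ds, ids, cfg)
        kept, ntraces = _normalized_traces(traces, anchors, ids)
        if len(kept) < 3:
            continue
        pop_traces[(area, klass)] = ntraces
        for level in cfg.analysis.latency_prior_levels:
            pairs = opposing_goal_pairs(ntraces, float(level))
            if not pairs:
                continue
            point, _ = latency_mod.bootstrap_nd(
                pairs, t_axis,
                n_boot=cfg.analysis.n_boot, rng=rng_lat,
                ci_level=cfg.analysis.ci_level,
                search_window=cfg.analysis.mvt_window_ms,
                velocity_threshold=cfg.analysis.velocity_threshold,
            )
            key = f"{area}-{klass}-level{level}"
            latency_report[key] = {
                "mvt": point.mvt, "pt": point.pt,
                "mvt_ci": point.mvt_ci, "pt_ci": point.pt_ci,
                "n_units": len(kept),
            }
            if point.mvt is not None:
                mvts[(area, klass, float(level))] = point.mvt

    # between-area permutation tests within class, at the higher level
    perm_level = float(cfg.analysis.latency_prior_levels[-1])
    for klass in ("UR", "DR"):
        ka, kb = ("PMd", klass), ("PRR", klass)
        if ka in pop_traces and kb in pop_traces:
            pa = opposing_goal_pairs(pop_traces[ka], perm_level)
            pb = opposing_goal_pairs(pop_traces[kb], perm_level)
            if pa and pb:
                diff, p = latency_mod.permutation_area_test(
                    pa, pb, t_axis, n_perm=cfg.analysis.n_perm, rng=rng_lat,
                    search_window=cfg.analysis.mvt_window_ms,
                )
                latency_report[f"perm-PMd-vs-PRR-{klass}"] = {
                    "mvt_difference_ms": diff, "p": p,
                }
    with open(out_dir / "latency_report.json", "w") as fh:
        json.dump(latency_report, fh, indent=2, default=_json_default)
    done("latency", n_populations=len(pop_traces))

    # --- choice ROC + correlations --------------------------------------
    stage("roc")
    free_cond = tuning_mod.planning_rate_conditions(
        ds, gated, trial_types=("free_choice",)
    )
    roc_df, reach_rep = choice_mod.choice_roc_suite(
        free_cond, min_trials=cfg.analysis.roc_min_trials
    )
    roc_df.to_csv(out_dir / "choice_roc.csv", index=False)
    corr = choice_mod.signal_correlations(cond)
    corr.to_csv(out_dir / "signal_correlations.csv", index=False)
    trend = choice_mod.correlation_prior_trend(corr, 180.0)
    with open(out_dir / "choice_summary.json", "w") as fh:
        json.dump(
            {"reachdir_test": reach_rep.to_dict("records"),
             "opposite_pd_prior_trend": trend},
            fh, indent=2, default=_json_default,
        )
    if len(roc_df):
        for comp, grp in roc_df.groupby("comparison"):
            report_lines.append(
                f"- mean {comp} AUC: {grp['auc'].mean():.3f} "
                f"(n={grp['unit_id'].nunique()} units)"
            )
    done("roc", n_roc=len(roc_df), n_pairs=corr["unit_a"].nunique() if len(corr) else 0)

    # --- report assertions ----------------------------------------------
    # the six population slope tests form one check family; Bonferroni
    # keeps the family-wise false-alarm rate of the null assertions at alpha
    checks = {}
    alpha = cfg.analysis.alpha_modulation / 6.0
    if "UR" in pop_tests:
        s = {r["role"]: r for r in pop_tests["UR"]}
        checks["ur_pd_upregulation"] = bool(
            s["PD"]["mean_slope"] > 0 and s["PD"]["p"] < alpha
        )
        checks["ur_od_null"] = bool(s["OD"]["p"] >= alpha)
        if "Orth" in s:
            checks["ur_orth_null"] = bool(s["Orth"]["p"] >= alpha)
    if "DR" in pop_tests:
        s = {r["role"]: r for r in pop_tests["DR"]}
        checks["dr_od_downregulation"] = bool(
            s["OD"]["mean_slope"] < 0 and s["OD"]["p"] < alpha
        )
        checks["dr_pd_null"] = bool(s["PD"]["p"] >= alpha)
        if "Orth" in s:
            checks["dr_orth_null"] = bool(s["Orth"]["p"] >= alpha)
    lv = perm_level
    quad = {k: v for k, v in mvts.items() if k[2] == lv}
    if len(quad) == 4:
        earliest = min(quad, key=quad.get)
        checks["pmd_dr_earliest_mvt"] = bool(earliest[:2] == ("PMd", "DR"))
        report_lines.append(
            "- MVTs (ms after rule-cue, level "
            f"{lv}): "
            + ", ".join(f"{a}-{k}: {quad[(a, k, lv)]:.0f}"
                        for a, k in sorted({q[:2] for q in quad}))
        )
    for area, d in dip_summary.items():
        checks[f"bimodal_angles_{area}"] = bool(d["p"] < 0.05)
    manifest["checks"] = checks
    report_lines.append("")
    report_lines.append("## Checks")
    for name, ok in checks.items():
        report_lines.append(f"- {name}: {'PASS' if ok else 'FAIL'}")

    (out_dir / "report.md").write_text("\n".join(report_lines) + "\n")
    for p in sorted(out_dir.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _digest(p)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest
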