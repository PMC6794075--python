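"""Behavioral bias summaries and regression models.

Error rates (instructed trials only), reaction times, and free-choice
probabilities are summarized by prior level and congruency.  The biasing
effect of the prior is quantified with two regression models:

M1 (errors, RTs)
    response ~ PRIOR + PRIOR:CONGRUENCY with per-subject random slopes;
    PRIOR enters as the continuous normalized level {0, 0.25, 0.5, 0.75}.
M2 (choice)
    binomial follow/against ~ PRIOR with a per-subject random slope.

With only a handful of subjects a full mixed fit is often singular, so the
default estimation route is a precisely defined two-stage procedure:
per-subject GLM fits pooled across subjects by inverse-variance weighting.
A linear mixed model is attempted first for the RT model when requested;
failures fall back to two-stage and are flagged.  Post-hoc tests compare
successive prior levels with Bonferroni-corrected t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BehaviorSummary:
    """Condition-level behavioral summaries."""

    #: per (prior_level, congruency): error rate and n, instructed trials
    error_rates: pd.DataFrame
    #: per (prior_level, congruency, trial_type): mean RT, SE, n
    rts: pd.DataFrame
    #: per prior_level: fraction of free choices toward the high prior
    choice_probabilities: pd.DataFrame


@dataclass
class ModelFitReport:
    model_id: str  # M1_error | M1_rt | M2_choice
    terms: pd.DataFrame  # term, estimate, se, t, p
    method: str  # "two_stage" | "mixed"
    fallback: bool = False
    notes: list = field(default_factory=list)


def summarize_behavior(trials: pd.DataFrame) -> BehaviorSummary:
    """Error rates, RTs and choice probabilities by prior and congruency.

    Error rates are reported for instructed trials only (both goals are
    valid in free-choice trials).  The congruency of an instructed trial is
    judged from the instruction (follow = the rule-cue matched the
    high-prior direction), so error trials count against the instructed
    condition they came from.  Choice probability at prior level 0 uses the
    cw-equals-follow presentation convention.
    """
    done = trials[trials["outcome"] != "aborted"].copy()

    instr = done[done["trial_type"] == "instructed"].copy()
    # congruency of the *instruction*: on correct trials it equals the reach
    # congruency; on error trials it is the opposite label
    instr_congr = np.where(
        instr["outcome"] == "correct",
        instr["congruency"],
        np.where(instr["congruency"] == "follow", "against", "follow"),
    )
    instr["instr_congruency"] = instr_congr
    err = (
        instr.groupby(["prior_level", "instr_congruency"], observed=True)
        .agg(
            n=("outcome", "size"),
            n_errors=("outcome", lambda s: int((s == "error").sum())),
        )
        .reset_index()
        .rename(columns={"instr_congruency": "congruency"})
    )
    err["error_rate"] = err["n_errors"] / err["n"]

    rts = (
        done.dropna(subset=["rt"])
        .groupby(["prior_level", "congruency", "trial_type"], observed=True)["rt"]
        .agg(["mean", "sem", "size"])
        .reset_index()
        .rename(columns={"mean": "rt_mean", "sem": "rt_se", "size": "n"})
    )

    free = done[(done["trial_type"] == "free_choice")].copy()
    cp = (
        free.groupby("prior_level", observed=True)["congruency"]
        .agg(n="size", n_follow=lambda s: int((s == "follow").sum()))
        .reset_index()
    )
    cp["choice_probability"] = cp["n_follow"] / cp["n"]

    return BehaviorSummary(error_rates=err, rts=rts, choice_probabilities=cp)


# ---------------------------------------------------------------------------
# model fits

def _per_subject_glm(
    df: pd.DataFrame, response: str, binomial: bool
) -> pd.DataFrame | None:
    """Per-subject GLM of response on PRIOR and PRIOR:CONGRUENCY."""
    import statsmodels.api as sm

    rows = []
    for subj, grp in df.groupby("subject_id", sort=False):
        y = grp[response].to_numpy(dtype=float)
        level = grp["prior_level"].to_numpy(dtype=float)
        if "congruency" in grp and grp["congruency"].nunique() > 1:
            sgn = np.where(grp["congruency"] == "against", 0.5, -0.5)
            X = np.column_stack([np.ones_like(level), level, level * sgn])
            names = ["intercept", "PRIOR", "PRIOR:CONGRUENCY"]
        else:
            X = np.column_stack([np.ones_like(level), level])
            names = ["intercept", "PRIOR"]
        try:
            if binomial:
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            else:
                fit = sm.OLS(y, X).fit()
        except Exception:
            continue
        for name, est, se in zip(names, fit.params, fit.bse):
            if np.isfinite(se) and se > 0:
                rows.append(
                    {"subject_id": subj, "term": name, "estimate": est, "se": se}
                )
    if not rows:
        return None
    return pd.DataFrame(rows)


def _pool_inverse_variance(per_subject: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for term, grp in per_subject.groupby("term", sort=False):
        w = 1.0 / grp["se"] ** 2
        est = float(np.sum(w * grp["estimate"]) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        z = est / se
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": se,
                "t": z,
                "p": float(2 * stats.norm.sf(abs(z))),
                "n_subjects": len(grp),
            }
        )
    return pd.DataFrame(rows)


def fit_behavior_models(
    trials: pd.DataFrame, try_mixed_rt: bool = False
) -> list[ModelFitReport]:
    """Fit M1 for errors and RTs and M2 for choice.

    Single-subject inputs automatically use the (flagged) fallback: the
    per-subject fit is then the pooled fit.
    """
    done = trials[trials["outcome"] != "aborted"].copy()
    reports: list[ModelFitReport] = []
    single_subject = done["subject_id"].nunique() < 2

    # --- M1 errors (instructed only, binomial)
    instr = done[done["trial_type"] == "instructed"].copy()
    instr["is_error"] = (instr["outcome"] == "error").astype(float)
    instr_congr = np.where(
        instr["outcome"] == "correct",
        instr["congruency"],
        np.where(instr["congruency"] == "follow", "against", "follow"),
    )
    instr["congruency"] = instr_congr
    per = _per_subject_glm(instr, "is_error", binomial=True)
    if per is not None:
        rep = ModelFitReport(
            model_id="M1_error",
            terms=_pool_inverse_variance(per),
            method="two_stage",
            fallback=single_subject,
        )
        if single_subject:
            rep.notes.append("single subject: no random-effect structure")
        reports.append(rep)

    # --- M1 RTs (all completed reaches)
    rt_df = done.dropna(subset=["rt"]).copy()
    mixed_done = False
    if try_mixed_rt and not single_subject:
        try:
            import statsmodels.formula.api as smf

            d = rt_df.copy()
            d["sgn"] = np.where(d["congruency"] == "against", 0.5, -0.5)
            d["px"] = d["prior_level"] * d["sgn"]
            fit = smf.mixedlm(
                "rt ~ prior_level + px", d, groups=d["subject_id"],
                re_formula="~px",
            ).fit(method="lbfgs", maxiter=200)
            if fit.converged:
                fe = fit.fe_params
                terms = pd.DataFrame(
                    {
                        "term": ["intercept", "PRIOR", "PRIOR:CONGRUENCY"],
                        "estimate": fe.to_numpy(),
                        "se": fit.bse[: len(fe)].to_numpy(),
                    }
                )
                terms["t"] = terms["estimate"] / terms["se"]
                terms["p"] = 2 * stats.norm.sf(np.abs(terms["t"]))
                terms["n_subjects"] = d["subject_id"].nunique()
                reports.append(
                    ModelFitReport(model_id="M1_rt", terms=terms, method="mixed")
                )
                mixed_done = True
        except Exception:
            mixed_done = False
    if not mixed_done:
        per = _per_subject_glm(rt_df, "rt", binomial=False)
        if per is not None:
            rep = ModelFitReport(
                model_id="M1_rt",
                terms=_pool_inverse_variance(per),
                method="two_stage",
                fallback=try_mixed_rt or single_subject,
            )
            reports.append(rep)

    # --- M2 choice (free-choice trials, non-zero prior)
    free = done[
        (done["trial_type"] == "free_choice") & (done["prior_level"] > 0)
    ].copy()
    if len(free):
        free["is_follow"] = (free["congruency"] == "follow").astype(float)
        free = free.drop(columns=["congruency"])  # M2 has no congruency term
        per = _per_subject_glm(free, "is_follow", binomial=True)
        if per is not None:
            rep = ModelFitReport(
                model_id="M2_choice",
                terms=_pool_inverse_variance(per),
                method="two_stage",
                fallback=single_subject,
            )
            reports.append(rep)
    return reports


def posthoc_successive(
    values: pd.DataFrame,
    value_column: str,
    group_columns: list[str] | None = None,
    n_families: int | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected t-tests between successive prior levels.

    ``values`` holds trial-level rows with ``prior_level`` plus the measure;
    comparisons run within each combination of ``group_columns``.  The
    Bonferroni factor defaults to the number of comparisons per family.
    """
    group_columns = group_columns or []
    rows = []
    grouper = values.groupby(group_columns, observed=True) if group_columns else [((), values)]
    for key, grp in grouper:
        levels = sorted(grp["prior_level"].unique())
        k = n_families or max(1, len(levels) - 1)
        for la, lb in zip(levels, levels[1:]):
            a = grp.loc[grp["prior_level"] == la, value_column].to_numpy(dtype=float)
            b = grp.loc[grp["prior_level"] == lb, value_column].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                continue
            if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
                t, p = (np.nan, 1.0)
            else:
                t, p = stats.ttest_ind(b, a, equal_var=False)
            row = {c: v for c, v in zip(group_columns, key if isinstance(key, tuple) else (key,))}
            row.update(
                {
                    "level_a": la,
                    "level_b": lb,
                    "t": float(t),
                    "p": float(p),
                    "p_corrected": float(min(1.0, p * k)),
                    "significant_05": bool(p < 0.05 / k),
                    "significant_01": bool(p < 0.01 / k),
                    "significant_001": bool(p < 0.001 / k),
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)
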