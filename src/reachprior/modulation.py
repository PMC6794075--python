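"""Per-unit graded prior modulation, Hartigans' dip test, UR/DR classes.

For every motor-goal neuron the planning-period rates are normalized to the
unit's full-prior preferred-direction response and regressed on prior level
separately for trials in which the higher prior points toward the preferred
direction (PD_max role) and toward the opposite direction (OD role), with a
PRIOR x PRIORDIR interaction model.  The pair of slopes maps each unit to an
angular coordinate

    angle = arctan2(max(slope_pd, 0), max(-slope_od, 0))  in [0, pi/2],

with up-regulation on the y-axis and down-regulation magnitude on the x-axis
(wrong-sign slopes fall onto an axis rather than outside the quadrant).
Units with significant expected-sign modulation split into up-regulating
(UR, angle > pi/4) and down-regulating (DR, angle < pi/4) classes; units
significant on both axes are labelled "both" and excluded from the
dichotomy.  Bimodality of the angle distribution is established with
Hartigans' dip test of unimodality.

The dip statistic is computed exactly: dip(F) is the smallest d such that
some unimodal distribution function stays within a band of half-width d
around the empirical CDF (equivalently the minimax sup-norm distance to the
unimodal class, atoms permitted at the mode).  Feasibility of a band
half-width is decided by a convex-corridor sweep — a convex nondecreasing
function through the corridor exists iff the greatest convex minorant of the
upper bounds clears every lower bound — run from the left for the rising
flank and from the right (mirrored) for the falling flank; the statistic is
found by bisection to machine precision.  P-values are Monte-Carlo
calibrated against uniform(0, 1) null samples of matched size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

try:  # optional JIT; the pure-Python path is identical
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


ALPHA_MODULATION = 0.05


# ---------------------------------------------------------------------------
# Hartigans' dip statistic

@njit(cache=False)
def _flank_min(v: np.ndarray, c: np.ndarray, n: float, d: float):
    """Rising-flank analysis of the band of half-width ``d`` around the ECDF
    over unique points v with cumulative counts c.

    Point j carries the corridor [c[j]/n - d, c[j-1]/n + d].  Convexity of
    the rising flank propagates forced values forward: once a lower bound
    pulls the function up, the chord from any earlier upper bound fixes a
    minimal slope that persists.  The DP tracks Gmin[k], the smallest value
    any feasible convex nondecreasing flank can take at v[k], and S[k], the
    smallest admissible slope beyond v[k].

    Returns (prefix_ok, a_min): prefix_ok[m] says the corridors at
    0..m-1 admit a convex flank ending at v[m] within the (weaker,
    pre-jump) terminal corridor; a_min[m] is the smallest admissible
    terminal value there (the flank may end in an atom at the mode, so the
    terminal point only needs the pre-jump corridor).
    """
    K = len(v)
    eps = 1e-13
    lo = np.empty(K)
    hi = np.empty(K)
    for j in range(K):
        prev = c[j - 1] if j > 0 else 0.0
        lo[j] = c[j] / n - d
        hi[j] = prev / n + d
    gmin = np.empty(K)
    slope = np.empty(K)
    reach = np.empty(K)  # max over earlier forced lines, excluding own lo
    prefix_ok = np.empty(K, dtype=np.bool_)
    a_min = np.empty(K)
    ok = True
    for k in range(K):
        r = -1e300
        for j in range(k):
            val = gmin[j] + slope[j] * (v[k] - v[j])
            if val > r:
                r = val
        reach[k] = r
        prefix_ok[k] = ok
        lo_a = (c[k - 1] if k > 0 else 0.0) / n - d
        a_min[k] = max(lo_a, r)
        if a_min[k] > hi[k] + eps:
            prefix_ok[k] = False
        gmin[k] = max(lo[k], r)
        if gmin[k] > hi[k] + eps:
            ok = False
        s = 0.0
        for i in range(k):
            si = (gmin[k] - hi[i]) / (v[k] - v[i])
            if si > s:
                s = si
        slope[k] = s
    return prefix_ok, a_min


@njit(cache=False)
def _dip_feasible(v: np.ndarray, c: np.ndarray, n: float, d: float) -> bool:
    """Does a unimodal df exist within sup-distance ``d`` of the ECDF?

    The rising (convex) flank is analysed left-to-right, the falling
    (concave) flank on the mirrored ECDF (x -> -x, F -> 1 - F maps it onto a
    rising convex flank); the two flanks meet at a mode point where an atom
    may absorb the gap, so feasibility at mode m additionally needs the
    left flank's minimal end value not to exceed the right flank's maximal
    start value.
    """
    K = len(v)
    left_ok, a_min = _flank_min(v, c, n, d)
    cnt = np.empty(K)
    cnt[0] = c[0]
    for j in range(1, K):
        cnt[j] = c[j] - c[j - 1]
    vm = np.empty(K)
    cm = np.empty(K)
    acc = 0.0
    for j in range(K):
        vm[j] = -v[K - 1 - j]
        acc += cnt[K - 1 - j]
        cm[j] = acc
    right_ok_m, b_comp = _flank_min(vm, cm, n, d)
    eps = 1e-13
    for m in range(K):
        mm = K - 1 - m  # mirrored index of v[m]
        if left_ok[m] and right_ok_m[mm]:
            b_max = 1.0 - b_comp[mm]
            if a_min[m] <= b_max + eps:
                return True
    return False


def dip_statistic(sample: np.ndarray) -> float:
    """Hartigans' dip: sup-norm distance from the ECDF to the closest
    unimodal distribution function.

    Requires n >= 4 (undefined below that).  Computed by bisection on the
    exact band-feasibility criterion; accurate to ~1e-15.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("dip statistic requires n >= 4")
    v, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts).astype(float)
    if len(v) == 1:
        return 0.0
    lo, hi = 0.0, 0.26
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _dip_feasible(v, c, float(n), mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class DipResult:
    dip: float
    p: float
    n: int
    n_boot: int


def dip_null_table(
    n: int, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo null distribution of the dip for uniform samples of size n."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    return np.array([dip_statistic(rng.uniform(0, 1, n)) for _ in range(n_boot)])


def dip_test(
    sample: np.ndarray,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    null_table: np.ndarray | None = None,
) -> DipResult:
    """Dip statistic with a Monte-Carlo uniform-null p-value.

    ``null_table`` may carry a precomputed null distribution (matched n) to
    amortize calibration across repeated tests.
    """
    x = np.asarray(sample, dtype=float)
    d = dip_statistic(x)
    if null_table is None:
        if rng is None:
            raise ValueError("need rng (or null_table) for the Monte-Carlo null")
        null_table = dip_null_table(len(x), n_boot, rng)
    p = float(np.mean(null_table >= d))
    return DipResult(dip=d, p=p, n=len(x), n_boot=len(null_table))


# ---------------------------------------------------------------------------
# per-unit modulation fits (PRIOR x PRIORDIR linear model)

@dataclass
class ModulationResult:
    unit_id: str
    area: str
    slope_pd: float
    slope_od: float
    p_pd: float
    p_od: float
    angle: float
    klass: str  # UR | DR | both | none
    n_trials: int


def modulation_angle(slope_pd: float, slope_od: float) -> float:
    """Angular coordinate of (down-regulation magnitude, up-regulation)."""
    return float(np.arctan2(max(slope_pd, 0.0), max(-slope_od, 0.0)))


def classify_modulation(
    slope_pd: float, slope_od: float, p_pd: float, p_od: float,
    alpha: float = ALPHA_MODULATION,
) -> str:
    """UR/DR/both/none from expected-sign significant slopes and the angle."""
    sig_pd = p_pd < alpha and slope_pd > 0
    sig_od = p_od < alpha and slope_od < 0
    if sig_pd and sig_od:
        return "both"
    angle = modulation_angle(slope_pd, slope_od)
    if sig_pd and angle > np.pi / 4:
        return "UR"
    if sig_od and angle < np.pi / 4:
        return "DR"
    return "none"


def role_relative_to_pd(hi_dir: np.ndarray, pd_max: float) -> np.ndarray:
    """PD/OD/Orth role of the high-prior direction relative to pd_max."""
    delta = np.mod(np.asarray(hi_dir, dtype=float) - pd_max, 360.0)
    out = np.where(delta == 0.0, "PD", np.where(delta == 180.0, "OD", "Orth"))
    return out


def prior_role_table(unit_cond: pd.DataFrame, pd_max: float) -> pd.DataFrame:
    """Per-trial (rate, prior_level, role) rows for the modulation fit.

    Zero-prior trials whose potential goals span the unit's PD axis anchor
    both regression lines, so they enter once per role.
    """
    df = unit_cond.copy()
    df["role"] = role_relative_to_pd(df["hi_dir"].to_numpy(), pd_max)
    nz = df[df["prior_level"] > 0]
    z = df[df["prior_level"] == 0]
    z_axis = z[z["role"].isin(["PD", "OD"])]
    rows = [nz[nz["role"].isin(["PD", "OD"])]]
    for role in ("PD", "OD"):
        dup = z_axis.copy()
        dup["role"] = role
        rows.append(dup)
    both = pd.concat(rows, ignore_index=True)
    orth = pd.concat([nz[nz["role"] == "Orth"], z[z["role"] == "Orth"]],
                     ignore_index=True)
    orth["role"] = "Orth"
    return pd.concat([both, orth], ignore_index=True)


def fit_unit_modulation(
    role_table: pd.DataFrame,
    unit_id: str = "",
    area: str = "",
    alpha: float = ALPHA_MODULATION,
    rate_column: str = "norm_rate",
) -> ModulationResult | None:
    """OLS fit of normalized planning rate on PRIOR, PRIORDIR and their
    interaction; marginal prior slopes per role with two-sided p-values.

    Returns None (unfittable) when fewer than two prior levels are present
    in either role.
    """
    import statsmodels.api as sm

    df = role_table[role_table["role"].isin(["PD", "OD"])]
    for role in ("PD", "OD"):
        if df.loc[df["role"] == role, "prior_level"].nunique() < 2:
            return None
    y = df[rate_column].to_numpy(dtype=float)
    level = df["prior_level"].to_numpy(dtype=float)
    dircode = np.where(df["role"] == "PD", 0.5, -0.5)
    X = np.column_stack([np.ones_like(level), level, dircode, level * dircode])
    fit = sm.OLS(y, X).fit()
    t_pd = fit.t_test([0.0, 1.0, 0.0, 0.5])
    t_od = fit.t_test([0.0, 1.0, 0.0, -0.5])
    slope_pd = float(np.squeeze(t_pd.effect))
    slope_od = float(np.squeeze(t_od.effect))
    p_pd = float(np.squeeze(t_pd.pvalue))
    p_od = float(np.squeeze(t_od.pvalue))
    return ModulationResult(
        unit_id=unit_id,
        area=area,
        slope_pd=slope_pd,
        slope_od=slope_od,
        p_pd=p_pd,
        p_od=p_od,
        angle=modulation_angle(slope_pd, slope_od),
        klass=classify_modulation(slope_pd, slope_od, p_pd, p_od, alpha),
        n_trials=len(df),
    )


def normalize_rates(cond: pd.DataFrame) -> pd.DataFrame:
    """Add ``norm_rate``: planning rate divided by the unit's full-prior
    response with the high prior at its PD_max (the population-tuning
    anchor).  Units with a non-positive anchor are dropped."""
    out = []
    for unit_id, grp in cond.groupby("unit_id", sort=False):
        pdm = float(grp["pd_max"].iloc[0])
        anchor_rows = grp[(grp["prior_level"] == 0.75) & (grp["hi_dir"] == pdm)]
        if not len(anchor_rows):
            continue
        anchor = anchor_rows["rate"].mean()
        if anchor <= 0:
            continue
        g = grp.copy()
        g["norm_rate"] = g["rate"] / anchor
        out.append(g)
    if not out:
        return cond.iloc[0:0].assign(norm_rate=[])
    return pd.concat(out, ignore_index=True)


def unit_modulation_results(
    cond: pd.DataFrame, alpha: float = ALPHA_MODULATION
) -> list[ModulationResult]:
    """Fit modulation for every unit in a planning-rate condition table
    (output of tuning.planning_rate_conditions, normalized)."""
    normed = normalize_rates(cond)
    results = []
    for unit_id, grp in normed.groupby("unit_id", sort=False):
        pdm = float(grp["pd_max"].iloc[0])
        area = grp["area"].iloc[0] if "area" in grp else ""
        roles = prior_role_table(grp, pdm)
        res = fit_unit_modulation(roles, unit_id=unit_id, area=area, alpha=alpha)
        if res is not None:
            results.append(res)
    return results


# ---------------------------------------------------------------------------
# population-level fixed-effect tests (PRIOR x PRIORDIR across units)

@dataclass
class PopulationModulationReport:
    slopes: pd.DataFrame  # per role: mean slope, t, p, n_units
    posthoc: pd.DataFrame  # successive prior-level contrasts per role
    method: str  # "two_stage" | "mixed"
    fallback: bool = False


def _two_stage_population(rate_roles: pd.DataFrame, rate_column: str):
    per_unit = []
    for (unit_id, role), grp in rate_roles.groupby(["unit_id", "role"], sort=False):
        if grp["prior_level"].nunique() < 2:
            continue
        x = grp["prior_level"].to_numpy(dtype=float)
        y = grp[rate_column].to_numpy(dtype=float)
        slope = np.polyfit(x, y, 1)[0]
        per_unit.append({"unit_id": unit_id, "role": role, "slope": slope})
    per_unit = pd.DataFrame(per_unit)
    rows = []
    for role, grp in per_unit.groupby("role"):
        s = grp["slope"].to_numpy()
        if len(s) >= 2 and np.std(s, ddof=1) > 0:
            t, p = stats.ttest_1samp(s, 0.0)
        else:
            t, p = np.nan, 1.0
        rows.append(
            {"role": role, "mean_slope": s.mean(), "t": float(t),
             "p": float(p), "n_units": len(s)}
        )
    return pd.DataFrame(rows), per_unit


def _mixed_population(rate_roles: pd.DataFrame, rate_column: str):
    import statsmodels.formula.api as smf

    df = rate_roles[rate_roles["role"].isin(["PD", "OD"])].copy()
    df["dircode"] = np.where(df["role"] == "PD", 0.5, -0.5)
    df = df.rename(columns={rate_column: "activity"})
    model = smf.mixedlm(
        "activity ~ prior_level * dircode",
        df,
        groups=df["unit_id"],
        re_formula="~prior_level * dircode",
    )
    fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    if not fit.converged:
        raise RuntimeError("mixed model did not converge")
    c_pd = np.array([0.0, 1.0, 0.0, 0.5])
    c_od = np.array([0.0, 1.0, 0.0, -0.5])
    rows = []
    fe = fit.fe_params.to_numpy()
    cov = fit.cov_params().to_numpy()[: len(fe), : len(fe)]
    for role, cvec in (("PD", c_pd), ("OD", c_od)):
        est = float(cvec @ fe)
        se = float(np.sqrt(cvec @ cov @ cvec))
        z = est / se
        rows.append(
            {"role": role, "mean_slope": est, "t": z,
             "p": float(2 * stats.norm.sf(abs(z))), "n_units": df["unit_id"].nunique()}
        )
    return pd.DataFrame(rows)


def population_modulation_test(
    cond: pd.DataFrame,
    rate_column: str = "rate",
    method: str = "two_stage",
) -> PopulationModulationReport:
    """Population prior-slope tests at PD_max, OD and Orth.

    Default is the precisely defined two-stage route (per-unit OLS slopes,
    then one-sample t-tests across units); ``method="mixed"`` fits a linear
    mixed model with per-unit random PRIOR x PRIORDIR effects and falls back
    to two-stage (flagged) if the fit fails.  Post-hoc output holds
    Bonferroni-corrected paired t-tests between successive prior levels of
    the per-unit mean rates within each role.
    """
    if cond["unit_id"].nunique() < 2:
        raise ValueError("population test needs >= 2 units")
    roles = []
    for unit_id, grp in cond.groupby("unit_id", sort=False):
        pdm = float(grp["pd_max"].iloc[0])
        roles.append(prior_role_table(grp, pdm))
    rate_roles = pd.concat(roles, ignore_index=True)

    fallback = False
    used = method
    if method == "mixed":
        try:
            slopes = _mixed_population(rate_roles, rate_column)
            # Orth slope still comes from the two-stage route
            two, _ = _two_stage_population(
                rate_roles[rate_roles["role"] == "Orth"], rate_column
            )
            slopes = pd.concat([slopes, two], ignore_index=True)
        except Exception:
            fallback = True
            used = "two_stage"
            slopes, _ = _two_stage_population(rate_roles, rate_column)
    else:
        slopes, _ = _two_stage_population(rate_roles, rate_column)

    # successive prior-level contrasts on per-unit mean rates
    cell = (
        rate_roles.groupby(["unit_id", "role", "prior_level"])[rate_column]
        .mean()
        .reset_index()
    )
    posthoc_rows = []
    for role, grp in cell.groupby("role"):
        levels = sorted(grp["prior_level"].unique())
        k = max(1, len(levels) - 1)
        for la, lb in zip(levels, levels[1:]):
            wide = grp.pivot(index="unit_id", columns="prior_level",
                             values=rate_column)[[la, lb]].dropna()
            if len(wide) < 2:
                continue
            diffs = wide[lb] - wide[la]
            if np.std(diffs, ddof=1) == 0:
                t, p = np.nan, 1.0
            else:
                t, p = stats.ttest_rel(wide[lb], wide[la])
            posthoc_rows.append(
                {"role": role, "level_a": la, "level_b": lb, "t": float(t),
                 "p": float(p), "p_corrected": float(min(1.0, p * k)),
                 "n_units": len(wide)}
            )
    return PopulationModulationReport(
        slopes=slopes,
        posthoc=pd.DataFrame(posthoc_rows),
        method=used,
        fallback=fallback,
    )
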