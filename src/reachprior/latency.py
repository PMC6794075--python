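"""Neural-distance trajectories and selection-signal latencies.

The neural distance (ND) between two task conditions is the Euclidean
distance in the state space spanned by all units — no dimensionality
reduction — computed per time bin from condition-averaged spike densities:

    ND(t) = sqrt( sum_units (r_A,unit(t) - r_B,unit(t))^2 )

For selection-signal latencies the two conditions are trials reaching the
two opposing goals of a pre-cue location; the final trajectory averages the
four pre-cue-location trajectories.  Because planning activity already
differs between prior conditions, a non-zero ND is not itself evidence of
commitment; instead the latency is the time after rule-cue/go onset at
which the ND's rate of change peaks (maximal velocity time, MVT), with the
plateau time (PT) — the first bin after MVT where the velocity drops below
a threshold — as a threshold-robust companion.  Velocity is a centered
finite difference of the Gaussian-smoothed trajectory; the earliest bin
wins ties.

Uncertainty is estimated by resampling units with replacement (bootstrap,
percentile CIs) and between-population latency differences are tested by
permuting unit-to-population assignment at matched sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LatencyResult:
    mvt: float | None  # ms
    pt: float | None  # ms
    mvt_ci: tuple[float, float] | None = None
    pt_ci: tuple[float, float] | None = None
    condition: str = ""


def neural_distance(
    traces_a: np.ndarray, traces_b: np.ndarray
) -> np.ndarray:
    """Euclidean ND per time bin between two (n_units, n_t) trace stacks."""
    a = np.atleast_2d(np.asarray(traces_a, dtype=float))
    b = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition trace stacks must share shape")
    return np.sqrt(np.sum((a - b) ** 2, axis=0))


def average_location_nd(pairs: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Mean of the per-pre-cue-location ND trajectories."""
    if not pairs:
        raise ValueError("no location pairs")
    return np.mean([neural_distance(a, b) for a, b in pairs], axis=0)


def nd_velocity(nd: np.ndarray, dt_ms: float = 1.0) -> np.ndarray:
    """Centered finite difference of ND per ms (one-sided at the edges)."""
    return np.gradient(np.asarray(nd, dtype=float), dt_ms)


def latency_estimates(
    nd: np.ndarray,
    t: np.ndarray,
    search_window: tuple[float, float] = (0.0, 600.0),
    velocity_threshold: float = 0.3,
    dt_ms: float = 1.0,
) -> LatencyResult:
    """MVT and PT of one ND trajectory.

    MVT is the earliest time of the maximal positive velocity inside the
    search window; PT is the first bin after MVT where the velocity falls
    below ``velocity_threshold``.  A flat or monotonically falling
    trajectory yields ``mvt=None`` (no-latency flag).
    """
    t = np.asarray(t, dtype=float)
    nd = np.asarray(nd, dtype=float)
    vel = nd_velocity(nd, dt_ms)
    mask = (t >= search_window[0]) & (t <= search_window[1])
    if not np.any(mask):
        raise ValueError("search window outside trajectory")
    vw = vel[mask]
    tw = t[mask]
    vmax = vw.max()
    if vmax <= 0:
        return LatencyResult(mvt=None, pt=None)
    # earliest tie wins; ties are judged with a relative tolerance so that
    # float rounding on a constant-velocity stretch cannot hide the tie
    tol = abs(vmax) * 1e-9
    i = int(np.flatnonzero(vw >= vmax - tol)[0])
    mvt = float(tw[i])
    after = np.flatnonzero((tw > mvt) & (vw < velocity_threshold))
    pt = float(tw[after[0]]) if len(after) else float(tw[-1])
    return LatencyResult(mvt=mvt, pt=pt)


def bootstrap_nd(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    t: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    ci_level: float = 90.0,
    search_window: tuple[float, float] = (0.0, 600.0),
    velocity_threshold: float = 0.3,
) -> tuple[LatencyResult, np.ndarray]:
    """Point estimate plus unit-resampled bootstrap CIs for MVT and PT.

    Units are resampled with replacement jointly across the location pairs
    (the unit axis is shared).  Returns the point-estimate LatencyResult
    with percentile CIs attached, and the (n_boot, n_t) ND band.
    """
    if rng is None:
        raise ValueError("bootstrap needs an rng")
    n_units = pairs[0][0].shape[0]
    if any(p[0].shape[0] != n_units for p in pairs):
        raise ValueError("location pairs must share the unit axis")
    point = latency_estimates(
        average_location_nd(pairs), t,
        search_window=search_window, velocity_threshold=velocity_threshold,
    )
    # squared per-unit differences per location; resampling sums rows
    d2 = [
        (np.atleast_2d(a) - np.atleast_2d(b)) ** 2 for a, b in pairs
    ]
    nd_boot = np.empty((n_boot, len(t)))
    mvts, pts = [], []
    for k in range(n_boot):
        idx = rng.integers(0, n_units, size=n_units)
        nd_k = np.mean([np.sqrt(m[idx].sum(axis=0)) for m in d2], axis=0)
        nd_boot[k] = nd_k
        res = latency_estimates(
            nd_k, t, search_window=search_window,
            velocity_threshold=velocity_threshold,
        )
        if res.mvt is not None:
            mvts.append(res.mvt)
            pts.append(res.pt)
    lo = (100.0 - ci_level) / 2.0
    hi = 100.0 - lo
    if mvts:
        point.mvt_ci = tuple(np.percentile(mvts, [lo, hi]))
        point.pt_ci = tuple(np.percentile(pts, [lo, hi]))
    return point, nd_boot


def _mvt_from_squared_diffs(
    d2_sum: np.ndarray, t: np.ndarray, mask: np.ndarray, dt_ms: float
) -> np.ndarray:
    """Vectorized MVT for stacked squared-difference sums (n_samples, n_t)."""
    nd = np.sqrt(d2_sum)
    vel = np.gradient(nd, dt_ms, axis=1)
    vw = vel[:, mask]
    tw = t[mask]
    idx = np.argmax(vw, axis=1)  # argmax returns the earliest maximum
    return tw[idx]


def permutation_area_test(
    pairs_a: list[tuple[np.ndarray, np.ndarray]],
    pairs_b: list[tuple[np.ndarray, np.ndarray]],
    t: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    search_window: tuple[float, float] = (0.0, 600.0),
    dt_ms: float = 1.0,
) -> tuple[float, float]:
    """Permutation test of the |MVT_A - MVT_B| latency difference.

    Units are randomly reassigned between the two populations at matched
    sample sizes; the p-value is the fraction of permutations whose absolute
    latency difference is at least the observed one.

    Returns (observed difference in ms, p-value).
    """
    if rng is None:
        raise ValueError("permutation test needs an rng")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives very coarse p-value resolution")
    if len(pairs_a) != len(pairs_b):
        raise ValueError("populations must share the location-pair structure")
    t = np.asarray(t, dtype=float)
    mask = (t >= search_window[0]) & (t <= search_window[1])
    n_a = pairs_a[0][0].shape[0]
    n_b = pairs_b[0][0].shape[0]

    # per-location pooled squared diffs, rows = units of A then B
    d2 = [
        np.vstack(
            [
                (np.atleast_2d(aa) - np.atleast_2d(ab)) ** 2,
                (np.atleast_2d(ba) - np.atleast_2d(bb)) ** 2,
            ]
        )
        for (aa, ab), (ba, bb) in zip(pairs_a, pairs_b)
    ]
    n_tot = n_a + n_b

    def mvt_of(idx_a: np.ndarray, idx_b: np.ndarray) -> tuple[float, float]:
        nd_a = np.mean([np.sqrt(m[idx_a].sum(axis=0)) for m in d2], axis=0)
        nd_b = np.mean([np.sqrt(m[idx_b].sum(axis=0)) for m in d2], axis=0)
        m_a = _mvt_from_squared_diffs(nd_a[None, :] ** 2, t, mask, dt_ms)[0]
        m_b = _mvt_from_squared_diffs(nd_b[None, :] ** 2, t, mask, dt_ms)[0]
        return m_a, m_b

    obs_a, obs_b = mvt_of(np.arange(n_a), np.arange(n_a, n_tot))
    observed = abs(obs_a - obs_b)

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        pa, pb = mvt_of(perm[:n_a], perm[n_a:])
        if abs(pa - pb) >= observed:
            count += 1
    return float(observed), count / n_perm
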