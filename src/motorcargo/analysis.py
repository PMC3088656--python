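"""Estimators and summaries computed from protocol outputs."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def l80(run_lengths) -> float:
    """20th-percentile run length: the distance that 80% of cargos
    travel at least.

    Uses the inverted-ECDF (type-1) order statistic — the smallest
    sample value x with ECDF(x) >= 0.2 — since "20th percentile" is
    otherwise convention-dependent.
    """
    x = np.asarray(run_lengths, dtype=float)
    if x.size == 0:
        raise ValueError("empty run-length sample")
    return float(np.quantile(x, 0.2, method="inverted_cdf"))


def windowed_velocity(t, y, tau: float, plus_dir: int = 1) -> np.ndarray:
    """Per-window velocities over non-overlapping windows of duration tau.

    ``t`` must be evenly sampled with spacing <= tau; each window's
    velocity is its net axial displacement divided by tau.  Returns an
    (n_windows, 2) array of (window start time, velocity); minus-end
    displacement gives negative velocity.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2:
        return np.empty((0, 2))
    dt_s = t[1] - t[0]
    if tau < dt_s - 1e-12:
        raise ValueError("window tau shorter than the sampling interval")
    k = max(int(round(tau / dt_s)), 1)
    n_win = (t.size - 1) // k
    if n_win == 0:
        return np.empty((0, 2))
    starts = t[: n_win * k : k]
    disp = y[k : n_win * k + 1 : k] - y[: n_win * k : k]
    v = plus_dir * disp / (k * dt_s)
    return np.column_stack([starts, v])


def poisson_fit(engaged_counts, weights=None) -> Tuple[float, dict]:
    """Fit a Poisson distribution to an engaged-motor census.

    The single parameter is the sample mean (the simulation's own
    time-averaged engaged count).  Goodness of fit is a chi-square
    statistic of observed vs. Poisson(λ) frequencies over the occupied
    bins.  ``engaged_counts`` may be raw draws, or bin values with
    time-weights in ``weights``.
    """
    x = np.asarray(engaged_counts, dtype=float)
    if weights is None:
        values, w = np.unique(x.astype(int), return_counts=True)
        w = w.astype(float)
    else:
        values = x.astype(int)
        w = np.asarray(weights, dtype=float)
        keep = w > 0
        values, w = values[keep], w[keep]
    total = w.sum()
    if total <= 0:
        raise ValueError("no observations")
    lam = float((values * w).sum() / total)
    if lam == 0.0 or len(values) < 2:
        return lam, {"chi2": np.inf, "dof": 0, "chi2_per_dof": np.inf,
                     "pvalue": 0.0}
    pmf = stats.poisson.pmf(values, lam)
    pmf = pmf / pmf.sum()          # condition on the occupied bins
    expected = total * pmf
    chi2 = float(((w - expected) ** 2 / expected).sum())
    dof = max(len(values) - 2, 1)  # one parameter estimated
    pvalue = float(stats.chi2.sf(chi2, dof))
    return lam, {"chi2": chi2, "dof": dof, "chi2_per_dof": chi2 / dof,
                 "pvalue": pvalue}


def power_law_fit(x, y) -> Tuple[float, float]:
    """Fit y ∝ x^(−b) by least squares on log-log axes.

    Returns (b, standard error of b).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive data")
    res = stats.linregress(np.log(x), np.log(y))
    return -float(res.slope), float(res.stderr)


def binding_summary(trials: pd.DataFrame,
                    t_grid: Optional[np.ndarray] = None) -> dict:
    """Empirical fraction-bound-by-t curve with explicit censoring.

    ``trials`` needs columns ``success`` (bool) and ``t_bind`` (s, NaN
    for failures).  The curve is the fraction of *all* trials bound by
    each time (failures never bind), the Kaplan-style estimate for this
    design where every trial is followed to its end.
    """
    n = len(trials)
    if n == 0:
        raise ValueError("no trials")
    success = trials["success"].to_numpy(dtype=bool) if "success" in trials \
        else trials["bound"].to_numpy(dtype=bool)
    times = trials["t_bind"].to_numpy(dtype=float)
    bound_times = np.sort(times[success])
    if t_grid is None:
        top = bound_times[-1] if bound_times.size else 1.0
        t_grid = np.linspace(0.0, top, 200)
    frac = np.searchsorted(bound_times, t_grid, side="right") / n
    mean = float(bound_times.mean()) if bound_times.size else None
    return {
        "t": np.asarray(t_grid),
        "fraction_bound": frac,
        "mean_time_bound": mean,
        "n_trials": n,
        "n_bound": int(success.sum()),
        "n_censored": int(n - success.sum()),
    }


def bootstrap_mean_ci(x, n_boot: int = 1000, alpha: float = 0.05,
                      rng: Optional[np.random.Generator] = None
                      ) -> Tuple[float, float, float]:
    """Mean with a bootstrap (1−alpha) percentile CI."""
    x = np.asarray(x, dtype=float)
    rng = rng or np.random.default_rng(0)
    means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(x.mean()), float(lo), float(hi)
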