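"""Inference of (alpha, beta, D) from per-condition velocity statistics.

The observables are the normalized mean upstream and transverse velocities
measured at several shear conditions; the forward model is the stationary
Fokker-Planck quadrature of :mod:`rheotaxis.model`.  Both a systematic grid
scan of the weighted least-squares objective and a bounded local refinement
are provided.

Identifiability caveat: the stationary angle density depends on the
parameters only through gamma_dot*alpha/D and gamma_dot*chi*beta/D, so
stationary velocity statistics constrain the *ratios* alpha/D and beta/D;
the objective is exactly flat along (alpha, beta, D) -> (c alpha, c beta,
c D).  The overall scale (the time scale of the dynamics) is set by the
initial guess, whose default is the centre of the plausible parameter box;
pinning it from data requires dynamical observables such as the reversal
response time.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import ModelParams, predicted_mean_velocities
from .stats import VelocityStats

__all__ = ["FitResult", "ScanResult", "fit_parameters", "parameter_scan"]

#: default box constraints for (alpha, beta, D)
DEFAULT_BOUNDS = ((0.02, 1.0), (0.0, 0.5), (0.02, 1.0))
#: default initial guess: centre of the plausible ranges for mammalian sperm
DEFAULT_X0 = (0.3, 0.075, 0.25)


@dataclass
class FitResult:
    """Point estimates, optional bootstrap CIs, and the fit diagnostics."""

    alpha: float
    beta: float
    D: float
    objective: float
    converged: bool
    n_conditions: int
    ci: dict[str, tuple[float, float]] | None = None
    scan_surface: pd.DataFrame | None = None


@dataclass
class ScanResult:
    """Objective surface over a parameter grid and its minimizing node."""

    surface: pd.DataFrame
    best: tuple[float, float, float]
    best_objective: float


def _observations(stats_by_condition) -> list[tuple[float, int, float, VelocityStats]]:
    obs = []
    for key, st in stats_by_condition.items():
        gamma_dot, sigma, v0 = key
        vals = [st.mean_upstream, st.mean_transverse, st.se_upstream, st.se_transverse]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite statistics for condition {key}")
        obs.append((float(gamma_dot), int(sigma), float(v0), st))
    return obs


def _objective_fn(obs, V, A, h_adv, chi, n_grid=1024):
    def objective(theta) -> float:
        alpha, beta, D = theta
        try:
            params = ModelParams(V=V, alpha=alpha, beta=beta, chi=chi, D=D,
                                 A=A, h_adv=h_adv)
        except ValueError:
            return np.inf
        if D <= 0:
            return np.inf
        total = 0.0
        for gamma_dot, sigma, v0, st in obs:
            vx, vy = predicted_mean_velocities(params, sigma, gamma_dot,
                                               n_grid=n_grid)
            pred_up = -sigma * vy / v0
            pred_tr = vx / v0
            w_up = 1.0 / max(st.se_upstream, 1e-9) ** 2
            w_tr = 1.0 / max(st.se_transverse, 1e-9) ** 2
            total += w_up * (pred_up - st.mean_upstream) ** 2
            total += w_tr * (pred_tr - st.mean_transverse) ** 2
        return total

    return objective


def parameter_scan(
    stats_by_condition,
    alphas,
    betas,
    Ds,
    V: float = 50.0,
    A: float = 10.0,
    h_adv: float = 10.0,
    chi: int = +1,
) -> ScanResult:
    """Evaluate the weighted-RSS objective on a full (alpha, beta, D) grid.

    ``stats_by_condition`` maps ``(gamma_dot, sigma, v0)`` to
    :class:`~rheotaxis.stats.VelocityStats`.  Returns the surface as a tidy
    DataFrame (columns alpha, beta, D, objective) plus the argmin node.
    """
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    Ds = np.atleast_1d(np.asarray(Ds, dtype=float))
    if alphas.size == 0 or betas.size == 0 or Ds.size == 0:
        raise ValueError("empty parameter grid")
    obs = _observations(stats_by_condition)
    objective = _objective_fn(obs, V, A, h_adv, chi)
    rows = []
    for a in alphas:
        for b in betas:
            for d in Ds:
                rows.append((a, b, d, objective((a, b, d))))
    surface = pd.DataFrame(rows, columns=["alpha", "beta", "D", "objective"])
    i = int(surface["objective"].idxmin())
    best = (
        float(surface.at[i, "alpha"]),
        float(surface.at[i, "beta"]),
        float(surface.at[i, "D"]),
    )
    return ScanResult(surface=surface, best=best,
                      best_objective=float(surface.at[i, "objective"]))


def fit_parameters(
    stats_by_condition,
    V: float = 50.0,
    A: float = 10.0,
    h_adv: float = 10.0,
    chi: int = +1,
    bounds=DEFAULT_BOUNDS,
    x0=DEFAULT_X0,
    pre_scan: bool = False,
    pre_scan_size: int = 5,
    n_boot: int = 0,
    seed=None,
    ci_level: float = 0.95,
) -> FitResult:
    """Fit (alpha, beta, D) to normalized mean velocities across conditions.

    Minimizes the inverse-variance-weighted squared error between the
    quadrature-predicted and observed normalized mean upstream/transverse
    velocities, by bounded local optimization (L-BFGS-B) from ``x0``,
    optionally preceded by a coarse grid pre-scan within ``bounds``.
    Deterministic given its inputs (including ``seed``).

    Confidence intervals (when ``n_boot > 0``) come from a parametric
    bootstrap: the observed condition means are resampled from
    Gaussian(mean, se) and refit; percentile intervals at ``ci_level``.
    """
    obs = _observations(stats_by_condition)
    if len({g for g, _, _, _ in obs}) < 3:
        raise ValueError("need at least 3 distinct shear conditions")
    objective = _objective_fn(obs, V, A, h_adv, chi)
    if not all(np.isfinite(b) for lo_hi in bounds for b in lo_hi):
        raise ValueError("bounds must be finite")

    start = np.asarray(x0, dtype=float)
    if pre_scan:
        grids = [np.linspace(max(lo, 1e-3 if i != 1 else 0.0), hi, pre_scan_size)
                 for i, (lo, hi) in enumerate(bounds)]
        scan = parameter_scan(stats_by_condition, *grids, V=V, A=A,
                              h_adv=h_adv, chi=chi)
        start = np.asarray(scan.best)

    def _refine(fn, x_start):
        res = minimize(fn, x_start, method="L-BFGS-B", bounds=bounds)
        return res

    res = _refine(objective, start)
    alpha_hat, beta_hat, d_hat = (float(v) for v in res.x)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_boot, 3))
        for b in range(n_boot):
            boot_stats = {}
            for gamma_dot, sigma, v0, st in obs:
                perturbed = VelocityStats(
                    mean_upstream=st.mean_upstream
                    + rng.normal(0.0, st.se_upstream),
                    mean_transverse=st.mean_transverse
                    + rng.normal(0.0, st.se_transverse),
                    se_upstream=st.se_upstream,
                    se_transverse=st.se_transverse,
                    sd_upstream=st.sd_upstream,
                    sd_transverse=st.sd_transverse,
                    hist_upstream=None,
                    hist_transverse=None,
                    n_samples=st.n_samples,
                    n_tracks=st.n_tracks,
                    v0=st.v0,
                )
                boot_stats[(gamma_dot, sigma, v0)] = perturbed
            fn = _objective_fn(_observations(boot_stats), V, A, h_adv, chi)
            draws[b] = _refine(fn, res.x).x
        q = 100.0 * (1.0 - ci_level) / 2.0
        ci = {
            name: (float(np.percentile(draws[:, i], q)),
                   float(np.percentile(draws[:, i], 100.0 - q)))
            for i, name in enumerate(("alpha", "beta", "D"))
        }

    return FitResult(
        alpha=alpha_hat,
        beta=beta_hat,
        D=d_hat,
        objective=float(res.fun),
        converged=bool(res.success),
        n_conditions=len(obs),
        ci=ci,
    )
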