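"""Design optimization of nanopillar cap geometry for maximal envelope tension.

Searches over the cap ratios ``R/rho`` (curvature) and ``rho/d`` (packing)
for the geometry that maximizes the suspended-region tension ``tau_B`` at
the free-energy minimum, given an effective adhesion ``eps'/k``.  Also
provides one-axis parameter sweeps (wetting angle, curvature, pillar
radius, gap, bending) and the flat-cap vs spherical-cap comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .geometry import CapGeometry, EnvelopeParams
from .mechanics import (
    _free_energy,
    _solve_lambda,
    effective_adhesion,
    minimize_free_energy,
)

__all__ = [
    "DesignResult",
    "optimize_design",
    "optimize_curvature_fixed_cap",
    "sweep",
    "compare_flat_vs_spherical",
    "FlatSphericalComparison",
]


@dataclass(frozen=True)
class DesignResult:
    """Optimal cap design at a given effective adhesion ``eps'/k``.

    ``tau_over_k = tau_over_eps * eps_prime_over_k`` by construction.
    """

    eps_prime_over_k: float
    R_over_rho: float
    rho_over_d: float
    tau_over_eps: float
    tau_over_k: float
    theta_star: float


def _min_energy_state(
    R_over_rho: float, rho_over_d: float, e: float, s0: float = 1.0
) -> tuple[float, float, float]:
    """(theta*, lam*, F*) at the free-energy minimum, dimensionless units."""
    r = R_over_rho * rho_over_d  # R/d
    theta_max = math.asin(min(1.0 / R_over_rho, 1.0))

    def objective(theta: float) -> float:
        return _free_energy(r, e, theta, _solve_lambda(r, e, theta, s0))

    res = minimize_scalar(
        objective,
        bounds=(0.0, theta_max),
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = sorted(
        [(0.0, objective(0.0)), (float(res.x), float(res.fun)),
         (theta_max, objective(theta_max))]
    )
    f_best = min(f for _, f in candidates)
    theta = next(
        th for th, f in candidates if f <= f_best + 1e-12 * max(abs(f_best), 1e-30)
    )
    lam = _solve_lambda(r, e, theta, s0)
    return theta, lam, _free_energy(r, e, theta, lam)


def _tau_at_min(R_over_rho: float, rho_over_d: float, e: float) -> float:
    """Suspended tension tau_B/k at the free-energy minimum."""
    return _min_energy_state(R_over_rho, rho_over_d, e)[1]


def _best_curvature(
    rho_over_d: float, e: float, bounds: tuple[float, float], tol: float
) -> tuple[float, float]:
    """Maximize tau_B/k over R/rho at fixed packing; coarse grid + refine."""
    lo, hi = bounds
    grid = np.linspace(lo, hi, 48)
    taus = np.array([_tau_at_min(x, rho_over_d, e) for x in grid])
    i = int(np.argmax(taus))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda x: -_tau_at_min(x, rho_over_d, e),
        bounds=(b_lo, b_hi),
        method="bounded",
        options={"xatol": tol},
    )
    if -res.fun >= taus[i]:
        return float(res.x), float(-res.fun)
    return float(grid[i]), float(taus[i])


def optimize_design(
    eps_prime_over_k: float,
    bounds: tuple[float, float] = (1.0, 20.0),
    tol: float = 1e-7,
    rho_over_d_grid: int = 10,
) -> DesignResult:
    """Cap geometry maximizing the suspended tension at fixed ``eps'/k``.

    Maximizes ``tau_B/k`` at the constrained free-energy minimum (with
    ``S0 = d^2``) over ``R/rho`` in ``bounds`` and ``rho/d`` in (0, 0.5].
    Fully deterministic.  The optimum packing lands on the tightly packed
    boundary ``rho/d = 0.5`` for every adhesion decade.
    """
    if eps_prime_over_k <= 0:
        raise ValueError(
            f"effective adhesion eps'/k must be > 0 for a design optimum, "
            f"got {eps_prime_over_k}"
        )
    e = eps_prime_over_k
    rho_grid = np.linspace(0.5 / rho_over_d_grid, 0.5, rho_over_d_grid)
    best: tuple[float, float, float] | None = None  # (tau, rho/d, R/rho)
    for rho_over_d in rho_grid:
        r_opt, tau = _best_curvature(float(rho_over_d), e, bounds, tol)
        if best is None or tau > best[0]:
            best = (tau, float(rho_over_d), r_opt)
    tau, rho_over_d, r_over_rho = best
    # Local refinement of the packing ratio around the best grid point.
    step = 0.5 / rho_over_d_grid
    res = minimize_scalar(
        lambda rd: -_best_curvature(rd, e, bounds, tol)[1],
        bounds=(max(rho_over_d - step, 1e-3), min(rho_over_d + step, 0.5)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    if -res.fun > tau:
        rho_over_d = float(res.x)
        r_over_rho, tau = _best_curvature(rho_over_d, e, bounds, tol)
    theta_star, lam, _ = _min_energy_state(r_over_rho, rho_over_d, e)
    return DesignResult(
        eps_prime_over_k=e,
        R_over_rho=r_over_rho,
        rho_over_d=rho_over_d,
        tau_over_eps=lam / e,
        tau_over_k=lam,
        theta_star=theta_star,
    )


def optimize_curvature_fixed_cap(
    cap_footprint: float,
    env: "EnvelopeParams | list[EnvelopeParams]",
    d: float,
    bounds: tuple[float, float] = (1.0, 10.0),
    tol: float = 1e-6,
) -> tuple[float, float] | float:
    """Optimal ``R/rho`` for a cap of fixed footprint area (nm^2).

    The cap radius is fixed by ``rho = sqrt(cap_footprint/pi)``; the radius
    of curvature R is varied.  Here the bending penalty depends on R, so
    the effective adhesion ``eps'(R) = eps - 2*kappa/R^2`` changes along
    the search.  With a single :class:`EnvelopeParams` the scalar optimum
    is returned; with a list of envelope draws, the (min, max) interval of
    the optima.  Raises if no R in the range gives ``eps' > 0``.
    """
    rho = math.sqrt(cap_footprint / math.pi)
    if 2 * rho > d:
        raise ValueError(
            f"cap footprint {cap_footprint} nm^2 (rho={rho:.2f}) does not fit "
            f"the pitch d={d}"
        )
    envs = [env] if isinstance(env, EnvelopeParams) else list(env)

    def optimum_for(single: EnvelopeParams) -> float:
        def neg_tau(R_over_rho: float) -> float:
            R = R_over_rho * rho
            eps_prime = effective_adhesion(single, R).eps_prime
            if eps_prime <= 0:
                return 0.0
            return -_tau_at_min(R_over_rho, rho / d, eps_prime / single.k)

        grid = np.linspace(bounds[0], bounds[1], 48)
        vals = np.array([neg_tau(x) for x in grid])
        if np.all(vals >= 0.0):
            raise ValueError(
                "no adhesive design exists: eps'(R) <= 0 over the whole "
                f"R/rho range {bounds} for envelope {single}"
            )
        i = int(np.argmin(vals))
        res = minimize_scalar(
            neg_tau,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
            method="bounded",
            options={"xatol": tol},
        )
        return float(res.x) if res.fun <= vals[i] else float(grid[i])

    optima = [optimum_for(single) for single in envs]
    if isinstance(env, EnvelopeParams):
        return optima[0]
    return min(optima), max(optima)


_SWEEP_AXES = ("theta", "R", "rho", "gap", "a")


def sweep(
    axis: str,
    values,
    geom: CapGeometry,
    env: EnvelopeParams,
) -> pd.DataFrame:
    """Evaluate tension and free energy along one geometry/envelope axis.

    ``axis`` is one of ``theta`` (wetting angle at fixed geometry, no
    minimization), ``R`` (cap radius of curvature, nm), ``rho`` (cap
    radius, nm), ``gap`` (edge-to-edge gap ``d - 2*rho`` at fixed rho, nm)
    or ``a`` (dimensionless bending parameter ``2*kappa/(k*d^2)``).  All
    but ``theta`` report the free-energy-minimum state.  Returns a tidy
    long-format table with columns ``axis, value, tau_suspended,
    free_energy, admissible``; inadmissible grid points are flagged with
    ``admissible=False`` and NaN responses, never dropped.
    """
    if axis not in _SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {_SWEEP_AXES}")
    values = np.asarray(list(values), dtype=float)
    if values.size > 1 and not (
        np.all(np.diff(values) > 0) or np.all(np.diff(values) < 0)
    ):
        raise ValueError("sweep grid must be strictly monotone")
    rows = []
    for v in values:
        tau = f_val = math.nan
        admissible = True
        try:
            if axis == "theta":
                eps_prime = effective_adhesion(env, geom.R).eps_prime
                e = max(eps_prime, 0.0) / env.k
                lam = _solve_lambda(geom.R / geom.d, e, v, 1.0)
                tau = env.k * lam
                f_val = _free_energy(geom.R / geom.d, e, v, lam)
            else:
                if axis == "R":
                    g = CapGeometry(R=v, rho=geom.rho, d=geom.d)
                    e_ = env
                elif axis == "rho":
                    g = CapGeometry(R=geom.R, rho=v, d=geom.d)
                    e_ = env
                elif axis == "gap":
                    g = CapGeometry(R=geom.R, rho=geom.rho, d=2 * geom.rho + v)
                    e_ = env
                else:  # bending parameter a
                    kappa = v * (env.k * 1e-3) * (geom.d * 1e-9) ** 2 / 2.0
                    g = geom
                    e_ = EnvelopeParams(k=env.k, eps=env.eps, kappa=kappa)
                state = minimize_free_energy(g, e_)
                tau = state.tau_suspended
                f_val = state.free_energy
        except (ValueError, RuntimeError):
            admissible = False
        rows.append(
            {
                "axis": axis,
                "value": float(v),
                "tau_suspended": tau,
                "free_energy": f_val,
                "admissible": admissible,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FlatSphericalComparison:
    """Suspended-tension intervals for flat-topped vs spherical-cap pillars."""

    flat_interval: tuple[float, float]       # mN/m
    spherical_interval: tuple[float, float]  # mN/m
    min_ratio: float  # smallest per-draw ratio spherical/flat


def compare_flat_vs_spherical(
    flat_geom: CapGeometry,
    spherical_geom: CapGeometry,
    env_draws: list[EnvelopeParams],
    edge_suppression: float = 1e-4,
    mode: str = "min",
) -> FlatSphericalComparison:
    """Compare induced suspended tensions of flat-topped and spherical caps.

    Flat tops are modeled within the spherical-cap family as a large-R cap
    whose adhesion is suppressed by the sharp-edge bending penalty
    (``eps -> edge_suppression * eps``); the near-flat geometry itself also
    caps the attainable area change.  Both geometries are evaluated over
    the same paired envelope draws and the interval ordering is asserted:
    spherical tensions must exceed flat ones for every draw.
    """
    from .rupture import _tau_for  # local import avoids a module cycle

    flat_taus = []
    sph_taus = []
    for env in env_draws:
        env_flat = EnvelopeParams(
            k=env.k, eps=env.eps * edge_suppression, kappa=env.kappa
        )
        flat_taus.append(_tau_for(flat_geom, env_flat, mode))
        sph_taus.append(_tau_for(spherical_geom, env, mode))
    flat_taus = np.asarray(flat_taus)
    sph_taus = np.asarray(sph_taus)
    if np.any(flat_taus >= sph_taus):
        raise RuntimeError(
            "interval ordering violated: a flat-cap draw reached a tension "
            ">= its paired spherical-cap draw"
        )
    with np.errstate(divide="ignore"):
        ratios = np.where(flat_taus > 0, sph_taus / np.maximum(flat_taus, 1e-300), math.inf)
    return FlatSphericalComparison(
        flat_interval=(float(flat_taus.min()), float(flat_taus.max())),
        spherical_interval=(float(sph_taus.min()), float(sph_taus.max())),
        min_ratio=float(ratios.min()),
    )
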