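"""Constrained free-energy model of a cell envelope on spherical-cap pillars.

The envelope over one lattice unit cell splits into an adhering region A
(in contact with the cap, spherical-cap area ``2*pi*R^2*(1-cos theta)``)
and a suspended region B (flat, area ``d^2 - pi*R^2*sin^2 theta``).  Each
region is uniformly stretched; the stretch is set by a Lagrange multiplier
``lam`` that conserves the initial envelope area ``S0``:

    S0 = A_cap/(lam + 1 - e)^2 + A_sus/(lam + 1)^2,        e = eps'/k

where ``eps'`` is the effective adhesion energy density (adhesion reduced
by the Helfrich bending cost of conforming to the cap, ``eps' = eps -
2*kappa/R^2``).  The free energy of the configuration, in units of k,

    F = A_cap * [(lam - e)^2 - e]/(lam + 1 - e)^2
        + A_sus * lam^2/(lam + 1)^2,

is minimized over the wetting angle ``theta in [0, theta_max]``.  The
resulting tensions are ``tau_B = k*lam`` in the suspended region and
``tau_A = k*lam - eps'`` on the cap; ``tau = -k`` is the membrane-collapse
bound, so admissible solutions keep both denominators positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq, minimize_scalar

from .geometry import CapGeometry, EnvelopeParams

__all__ = [
    "EffectiveAdhesion",
    "MechanicalState",
    "CollapseError",
    "SolverError",
    "effective_adhesion",
    "solve_lambda",
    "free_energy",
    "tensions",
    "minimize_free_energy",
    "maximal_cover_state",
]

#: Relative tolerance on the area-conservation residual of returned states.
RESIDUAL_TOL = 1e-9
#: Absolute tolerance (rad) on the minimizing wetting angle.
THETA_TOL = 1e-8


class SolverError(RuntimeError):
    """No admissible Lagrange multiplier exists for the requested state."""


class CollapseError(ValueError):
    """A denominator ``lam + 1`` or ``lam + 1 - e`` is non-positive
    (tension at or below the collapse bound ``tau = -k``)."""


@dataclass(frozen=True)
class EffectiveAdhesion:
    """Adhesion energy density corrected for cap-curvature bending cost."""

    eps_prime: float  # mN/m
    adhesive: bool    # True iff eps_prime > 0


@dataclass(frozen=True)
class MechanicalState:
    """A solved envelope configuration on one unit cell.

    Tensions are in the same units as the stiffness ``k`` passed to the
    solver (mN/m for physical input); ``free_energy`` is in units of
    ``k*d^2``; areas are deformed areas in nm^2 for physical input.
    """

    theta: float
    lam: float
    tau_suspended: float
    tau_adhering: float
    free_energy: float
    area_adhered: float
    area_suspended: float
    constraint_residual: float


def effective_adhesion(env: EnvelopeParams, R: float) -> EffectiveAdhesion:
    """Effective adhesion ``eps' = eps - 2*kappa/R^2`` for a cap of radius R (nm).

    Bending only ever reduces adhesion; ``eps' <= 0`` means the envelope
    does not adhere to the cap at all (a valid outcome, not an error).
    """
    if R <= 0:
        raise ValueError(f"cap radius of curvature must be > 0, got {R}")
    eps_prime = env.eps - env.kappa_per_area(R)
    return EffectiveAdhesion(eps_prime=eps_prime, adhesive=eps_prime > 0.0)


# ---------------------------------------------------------------------------
# Dimensionless core: lengths in units of d, energies per area in units of k.
# ---------------------------------------------------------------------------

def _areas(R_over_d: float, theta: float) -> tuple[float, float]:
    a_cap = 2.0 * math.pi * R_over_d**2 * (1.0 - math.cos(theta))
    a_sus = 1.0 - math.pi * R_over_d**2 * math.sin(theta) ** 2
    return a_cap, a_sus


def _solve_lambda(R_over_d: float, e: float, theta: float, s0: float = 1.0) -> float:
    """Root of the area-conservation constraint, in the admissible region.

    The constraint RHS is strictly decreasing in lam for
    ``lam > max(-1, -1 + e)`` and diverges at that bound, so the admissible
    root is unique; it is bracketed and polished with Brent's method.
    """
    if s0 <= 0:
        raise SolverError(f"initial area S0 must be > 0, got {s0}")
    a_cap, a_sus = _areas(R_over_d, theta)
    if a_sus < 0:
        raise SolverError(
            f"cap footprint exceeds the unit cell at theta={theta}"
        )
    if a_cap <= 0.0:
        # theta = 0: only the suspended term survives; closed form.
        return math.sqrt(a_sus / s0) - 1.0

    lo_bound = max(-1.0, -1.0 + e)

    def residual(lam: float) -> float:
        return a_cap / (lam + 1.0 - e) ** 2 + a_sus / (lam + 1.0) ** 2 - s0

    lo = lo_bound + 1e-13 * (1.0 + abs(lo_bound))
    if residual(lo) < 0.0:
        # Root is pinched against the collapse/adhesion bound.
        raise SolverError(
            f"no admissible Lagrange multiplier for S0={s0} at theta={theta}"
        )
    hi = max(1.0, lo + 1.0)
    for _ in range(200):
        if residual(hi) < 0.0:
            break
        hi = 2.0 * hi + 1.0
    else:
        raise SolverError(f"could not bracket constraint root for S0={s0}")
    return brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16)


def _free_energy(R_over_d: float, e: float, theta: float, lam: float) -> float:
    a_cap, a_sus = _areas(R_over_d, theta)
    den_a = lam + 1.0 - e
    den_b = lam + 1.0
    if den_b <= 0.0 or (a_cap > 0.0 and den_a <= 0.0):
        raise CollapseError(
            f"state lam={lam}, e={e} at or below the collapse bound tau=-k"
        )
    cap_term = a_cap * ((lam - e) ** 2 - e) / den_a**2 if a_cap > 0.0 else 0.0
    return cap_term + a_sus * lam**2 / den_b**2


def _state(
    geom: CapGeometry,
    k: float,
    eps_prime: float,
    theta: float,
    S0: float,
) -> MechanicalState:
    """Assemble a MechanicalState at a given wetting angle (physical units)."""
    r = geom.R / geom.d
    e = eps_prime / k
    s0 = S0 / geom.d**2
    lam = _solve_lambda(r, e, theta, s0)
    f = _free_energy(r, e, theta, lam)
    a_cap, a_sus = _areas(r, theta)
    residual = abs(
        (a_cap / (lam + 1.0 - e) ** 2 if a_cap > 0 else 0.0)
        + a_sus / (lam + 1.0) ** 2
        - s0
    ) / s0
    tau_b, tau_a = tensions(lam, k, eps_prime)
    return MechanicalState(
        theta=theta,
        lam=lam,
        tau_suspended=tau_b,
        tau_adhering=tau_a,
        free_energy=f,
        area_adhered=a_cap * geom.d**2,
        area_suspended=a_sus * geom.d**2,
        constraint_residual=residual,
    )


# ---------------------------------------------------------------------------
# Public, physical-unit surface.
# ---------------------------------------------------------------------------

def solve_lambda(
    geom: CapGeometry,
    eps_prime_over_k: float,
    theta: float,
    S0: float | None = None,
) -> float:
    """Lagrange multiplier conserving the initial area S0 (default ``d^2``)."""
    if not 0.0 <= theta <= geom.theta_max + 1e-12:
        raise ValueError(f"theta={theta} outside [0, theta_max={geom.theta_max}]")
    s0 = 1.0 if S0 is None else S0 / geom.d**2
    return _solve_lambda(geom.R / geom.d, eps_prime_over_k, theta, s0)


def free_energy(
    geom: CapGeometry,
    eps_prime_over_k: float,
    theta: float,
    lam: float,
) -> float:
    """Free energy of the (theta, lam) configuration in units of ``k*d^2``."""
    return _free_energy(geom.R / geom.d, eps_prime_over_k, theta, lam)


def tensions(lam: float, k: float, eps_prime: float) -> tuple[float, float]:
    """Suspended and adhering tensions ``(k*lam, k*lam - eps')``.

    The difference is exactly ``eps'``: adhesion compresses the envelope on
    the cap relative to the stretched suspended membrane.
    """
    tau_suspended = k * lam
    return tau_suspended, tau_suspended - eps_prime


def minimize_free_energy(
    geom: CapGeometry,
    env: EnvelopeParams,
    S0: float | None = None,
) -> MechanicalState:
    """State at the free-energy minimum over the wetting angle.

    Minimizes ``F(theta, lam(theta))`` over ``theta in [0, theta_max]``
    with ``lam(theta)`` from the area constraint.  For a non-adhesive
    envelope (``eps' <= 0``) the undeformed reference state ``theta=0,
    lam=0, F=0`` is returned.  Ties are broken toward the smallest theta.
    """
    eps_prime = effective_adhesion(env, geom.R).eps_prime
    s0_phys = geom.d**2 if S0 is None else S0
    if eps_prime <= 0.0:
        return _state(geom, env.k, eps_prime=0.0, theta=0.0, S0=s0_phys)
    e = eps_prime / env.k
    r = geom.R / geom.d
    s0 = s0_phys / geom.d**2
    theta_max = geom.theta_max

    def objective(theta: float) -> float:
        return _free_energy(r, e, theta, _solve_lambda(r, e, theta, s0))

    res = minimize_scalar(
        objective,
        bounds=(0.0, theta_max),
        method="bounded",
        options={"xatol": THETA_TOL},
    )
    # Candidate minima: interior optimum plus both interval endpoints; pick
    # the smallest theta among values tied within the energy resolution.
    candidates = sorted(
        [(0.0, objective(0.0)), (float(res.x), float(res.fun)),
         (theta_max, objective(theta_max))]
    )
    f_best = min(f for _, f in candidates)
    f_scale = max(abs(f_best), 1e-30)
    theta_star = next(
        th for th, f in candidates if f <= f_best + 1e-12 * f_scale
    )
    return _state(geom, env.k, eps_prime, theta_star, s0_phys)


def maximal_cover_state(
    geom: CapGeometry,
    env: EnvelopeParams,
    S0: float | None = None,
) -> MechanicalState:
    """State evaluated at full cap coverage ``theta = theta_max`` (no minimization).

    This is the upper envelope-deformation scenario; for an adhesive
    envelope its suspended tension is at least that of the free-energy
    minimum.
    """
    eps_prime = effective_adhesion(env, geom.R).eps_prime
    s0_phys = geom.d**2 if S0 is None else S0
    if eps_prime <= 0.0:
        return _state(geom, env.k, eps_prime=0.0, theta=0.0, S0=s0_phys)
    return _state(geom, env.k, eps_prime, geom.theta_max, s0_phys)
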