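"""Bactericidal rupture assessment from solved envelope tensions.

Propagates uncertainty in the envelope parameters (stiffness k, adhesion
eps, bending rigidity kappa) through the mechanical model to an interval
of suspended tensions, then classifies the interval against the critical
rupture-tension window (literature default 30-75 mN/m): rupture in the
suspended region is taken as the lysis mechanism, so a surface is called
bactericidal only when even its lowest attainable tension exceeds the
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import CapGeometry, EnvelopeParams
from .mechanics import maximal_cover_state, minimize_free_energy

__all__ = [
    "ParameterBox",
    "TensionInterval",
    "RuptureVerdict",
    "DEFAULT_CRITICAL_WINDOW",
    "DEFAULT_ENVELOPE_BOX",
    "tension_interval",
    "classify",
    "relative_tension_change",
]

#: Critical membrane-rupture tension window (mN/m), literature range.
DEFAULT_CRITICAL_WINDOW: tuple[float, float] = (30.0, 75.0)

_MODES = ("min", "maxcover")


@dataclass(frozen=True)
class ParameterBox:
    """Axis-aligned box of envelope parameters (point axes allowed).

    ``k`` in mN/m, ``eps`` in mN/m, ``kappa`` in J; each a (lo, hi) pair.
    """

    k: tuple[float, float]
    eps: tuple[float, float]
    kappa: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("k", self.k), ("eps", self.eps), ("kappa", self.kappa)):
            if hi < lo:
                raise ValueError(f"inverted {name} range ({lo}, {hi})")

    def grid(self, points_per_axis: int = 16) -> list[EnvelopeParams]:
        axes = [
            np.linspace(lo, hi, points_per_axis) if hi > lo else np.array([lo])
            for lo, hi in (self.k, self.eps, self.kappa)
        ]
        return [
            EnvelopeParams(k=float(k), eps=float(e), kappa=float(kp))
            for k in axes[0]
            for e in axes[1]
            for kp in axes[2]
        ]


#: Default envelope-parameter box: stiff bacterial envelopes (k 0.7-2.5 N/m,
#: i.e. cell-wall Young's modulus of tens of MPa times a 20-30 nm wall),
#: weak nonspecific adhesion (0.3-1 mJ/m^2) and membrane-scale bending
#: rigidities (0.01-0.1 aJ, a few to tens of kT).
DEFAULT_ENVELOPE_BOX = ParameterBox(
    k=(700.0, 2500.0), eps=(0.3, 1.0), kappa=(1e-20, 1e-19)
)


@dataclass(frozen=True)
class TensionInterval:
    """Range of suspended tensions (mN/m) over an envelope-parameter box."""

    tau_min: float
    tau_max: float
    mode: str  # "min" (free-energy minimum) or "maxcover"

    def __post_init__(self) -> None:
        if self.tau_min > self.tau_max:
            raise ValueError("tau_min > tau_max")


@dataclass(frozen=True)
class RuptureVerdict:
    """Classification of a tension interval against the critical window."""

    verdict: str  # "bactericidal" | "non-bactericidal" | "uncertain"
    critical_window: tuple[float, float] = DEFAULT_CRITICAL_WINDOW


def _tau_for(geom: CapGeometry, env: EnvelopeParams, mode: str) -> float:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    solver = minimize_free_energy if mode == "min" else maximal_cover_state
    return solver(geom, env).tau_suspended


def tension_interval(
    geom: CapGeometry,
    box: ParameterBox,
    mode: str = "min",
    grid_points: int = 16,
    refine: bool = True,
) -> TensionInterval:
    """Min/max suspended tension over a (k, eps, kappa) parameter box.

    Evaluates a deterministic grid (``grid_points`` per non-degenerate
    axis) and refines both endpoints by bounded local search from the grid
    arg-extrema; the tension is smooth but not monotone in kappa (via the
    effective adhesion and the optimal wetting angle), so endpoint search
    rather than interval arithmetic is required.  If no point of the box
    is adhesive, the degenerate interval [0, 0] is returned with a warning.
    """
    envs = box.grid(grid_points)
    taus = np.array([_tau_for(geom, env, mode) for env in envs])
    if np.all(taus <= 0.0):
        warnings.warn(
            "envelope box is entirely non-adhesive (eps' <= 0 everywhere): "
            "tension interval collapses to [0, 0]",
            stacklevel=2,
        )
        return TensionInterval(tau_min=0.0, tau_max=0.0, mode=mode)

    lo_env = envs[int(np.argmin(taus))]
    hi_env = envs[int(np.argmax(taus))]
    tau_lo = float(taus.min())
    tau_hi = float(taus.max())
    if refine:
        # Search in unit-cube coordinates so the wildly different parameter
        # scales (k ~ 1e3 mN/m, kappa ~ 1e-19 J) are weighted evenly.
        los = np.array([box.k[0], box.eps[0], box.kappa[0]])
        his = np.array([box.k[1], box.eps[1], box.kappa[1]])
        span = his - los  # zero span pins a degenerate axis

        def tau_at(u: np.ndarray) -> float:
            x = los + np.clip(u, 0.0, 1.0) * span
            env = EnvelopeParams(k=float(x[0]), eps=float(x[1]), kappa=float(x[2]))
            return _tau_for(geom, env, mode)

        for sign, start in ((1.0, lo_env), (-1.0, hi_env)):
            u0 = np.divide(
                np.array([start.k, start.eps, start.kappa]) - los,
                span,
                out=np.zeros(3),
                where=span > 0,
            )
            res = minimize(
                lambda u: sign * tau_at(u),
                x0=np.clip(u0, 0.0, 1.0),
                method="Nelder-Mead",
                options={"maxiter": 120, "xatol": 1e-4, "fatol": 1e-10},
            )
            if sign > 0:
                tau_lo = min(tau_lo, float(res.fun))
            else:
                tau_hi = max(tau_hi, float(-res.fun))
    return TensionInterval(tau_min=tau_lo, tau_max=tau_hi, mode=mode)


def classify(
    interval: TensionInterval,
    window: tuple[float, float] = DEFAULT_CRITICAL_WINDOW,
) -> RuptureVerdict:
    """Verdict of a tension interval against the rupture window.

    ``bactericidal`` when even the lowest tension reaches the window's
    upper bound; ``non-bactericidal`` when even the highest tension stays
    below the lower bound; ``uncertain`` otherwise.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"inverted critical window ({lo}, {hi})")
    if interval.tau_min >= hi:
        verdict = "bactericidal"
    elif interval.tau_max < lo:
        verdict = "non-bactericidal"
    else:
        verdict = "uncertain"
    return RuptureVerdict(verdict=verdict, critical_window=(lo, hi))


def relative_tension_change(
    geom_a: CapGeometry,
    geom_b: CapGeometry,
    box: ParameterBox,
    mode: str = "min",
    grid_points: int = 8,
) -> tuple[float, float]:
    """Percent change interval of tension from geometry A to geometry B.

    Evaluates ``100*(tau_b - tau_a)/tau_a`` on paired envelope draws over
    the box grid; draws where geometry A is non-adhesive (``tau_a = 0``)
    are excluded with a warning.
    """
    changes = []
    skipped = 0
    for env in box.grid(grid_points):
        tau_a = _tau_for(geom_a, env, mode)
        if tau_a == 0.0:
            skipped += 1
            continue
        tau_b = _tau_for(geom_b, env, mode)
        changes.append(100.0 * (tau_b - tau_a) / tau_a)
    if skipped:
        warnings.warn(
            f"excluded {skipped} envelope draws with zero reference tension",
            stacklevel=2,
        )
    if not changes:
        raise ValueError("reference geometry non-adhesive on every draw")
    return float(min(changes)), float(max(changes))
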