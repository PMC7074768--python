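"""Geometry of spherical-cap nanopillar lattices and unit handling.

A "cotton swab" (CS) nanopillar is a rigid pillar topped by a spherical cap
of radius of curvature ``R`` and cap radius ``rho``, arranged on a square
lattice with center-to-center pitch ``d`` (one pillar per ``d x d`` unit
cell).  All lengths are in nanometres at the user-facing surface; the
mechanical solver operates on the dimensionless ratios ``R/rho``, ``rho/d``,
``eps/k`` and the bending group ``a = 2*kappa/(k*d^2)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "CapGeometry",
    "EnvelopeParams",
    "GeometryError",
    "max_wetting_angle",
    "cap_area",
    "suspended_area",
    "edge_bending_dominance",
    "nondimensionalize",
    "redimensionalize",
    "load_geometry",
    "load_geometry_batch",
]

#: 1 mN/m expressed in J/nm^2 (1 mN/m = 1e-3 J/m^2 = 1e-21 J/nm^2).
MN_PER_M_IN_J_PER_NM2 = 1e-21


class GeometryError(ValueError):
    """Raised for invalid or inconsistent cap/lattice geometry."""


@dataclass(frozen=True)
class CapGeometry:
    """One spherical pillar cap plus its square-lattice unit cell.

    Parameters
    ----------
    R : float
        Cap radius of curvature (nm).
    rho : float
        Cap radius, i.e. half the cap width seen from the top (nm).
    d : float
        Center-to-center pitch of the square lattice (nm).
    """

    R: float
    rho: float
    d: float

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.rho > 0 and self.d > 0):
            raise GeometryError(
                f"R, rho, d must all be positive; got R={self.R}, "
                f"rho={self.rho}, d={self.d}"
            )
        if self.rho > self.R * (1 + 1e-12):
            raise GeometryError(
                f"cap radius rho={self.rho} exceeds radius of curvature "
                f"R={self.R}: a spherical cap cannot be wider than its sphere"
            )
        if 2 * self.rho > self.d * (1 + 1e-12):
            raise GeometryError(
                f"caps overlap: 2*rho={2 * self.rho} > pitch d={self.d}"
            )

    @property
    def theta_max(self) -> float:
        """Largest admissible wetting angle, ``arcsin(rho/R)`` (rad)."""
        return max_wetting_angle(self)

    @property
    def gap(self) -> float:
        """Edge-to-edge gap between adjacent caps, ``d - 2*rho`` (nm)."""
        return self.d - 2 * self.rho


@dataclass(frozen=True)
class EnvelopeParams:
    """Mechanical description of the bacterial cell envelope.

    The envelope is treated as a thin, linear-elastic, isotropic sheet with
    area-stretch stiffness ``k`` (tension tensor T = k E), an adhesion
    energy density ``eps`` towards the pillar surface, and a Helfrich
    bending rigidity ``kappa``.

    Parameters
    ----------
    k : float
        Envelope stiffness (mN/m).
    eps : float
        Adhesion energy density (mN/m, equivalently mJ/m^2).
    kappa : float
        Bending rigidity (J).  Typical membrane values are tens of kT,
        i.e. ~1e-19 J.
    """

    k: float
    eps: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"envelope stiffness k must be > 0, got {self.k}")
        if self.eps < 0:
            raise ValueError(f"adhesion energy eps must be >= 0, got {self.eps}")
        if self.kappa < 0:
            raise ValueError(f"bending rigidity kappa must be >= 0, got {self.kappa}")

    def bending_parameter(self, d_nm: float) -> float:
        """Dimensionless bending group ``a = 2*kappa/(k*d^2)``."""
        d_m = d_nm * 1e-9
        k_si = self.k * 1e-3  # mN/m -> N/m
        return 2.0 * self.kappa / (k_si * d_m**2)

    def kappa_per_area(self, R_nm: float) -> float:
        """Bending energy density ``2*kappa/R^2`` of a sphere of radius R, in mN/m."""
        R_m = R_nm * 1e-9
        return (2.0 * self.kappa / R_m**2) * 1e3  # J/m^2 -> mN/m


def max_wetting_angle(geom: CapGeometry) -> float:
    """Upper bound ``theta_max = arcsin(rho/R)`` on the wetting angle (rad).

    The envelope cannot wrap past the cap equator/edge: the sharp edge at
    the cap rim carries a bending-energy cost far exceeding any adhesion
    gain (see :func:`edge_bending_dominance`).
    """
    ratio = geom.rho / geom.R
    if ratio > 1 + 1e-12:
        raise GeometryError(f"rho/R = {ratio} > 1: invalid spherical cap")
    return math.asin(min(ratio, 1.0))


def cap_area(R: float, theta: float) -> float:
    """Area ``2*pi*R^2*(1 - cos(theta))`` of a spherical cap of half-angle theta."""
    if not 0.0 <= theta <= math.pi / 2 + 1e-12:
        raise ValueError(f"wetting angle theta={theta} outside [0, pi/2]")
    return 2.0 * math.pi * R**2 * (1.0 - math.cos(theta))


def suspended_area(geom: CapGeometry, theta: float) -> float:
    """Flat suspended area ``d^2 - pi*R^2*sin^2(theta)`` of one unit cell.

    This is the part of the unit cell not covered by the cap's circular
    footprint; the suspended membrane between caps is assumed flat.
    """
    if not 0.0 <= theta <= geom.theta_max + 1e-12:
        raise ValueError(
            f"theta={theta} outside [0, theta_max={geom.theta_max}]"
        )
    area = geom.d**2 - math.pi * geom.R**2 * math.sin(theta) ** 2
    if area <= 0:
        raise GeometryError(
            f"cap footprint exceeds unit cell at theta={theta}: "
            f"pi*R^2*sin^2(theta) = {geom.d**2 - area} >= d^2 = {geom.d**2}"
        )
    return area


def edge_bending_dominance(geom: CapGeometry, r_edge: float) -> float:
    """Order-of-magnitude ratio of edge to cap bending energy.

    The rim of a cap has a small local radius of curvature ``r_edge``; its
    bending energy scales as ``kappa*rho/r_edge`` while the cap's scales as
    ``kappa*(rho/R)^2``, so the ratio is ``R^2/(rho*r_edge)`` (proportionality
    constants taken as 1).  Values >> 1 justify capping the wetting angle at
    ``theta_max`` instead of letting the envelope wrap around the rim.
    """
    if r_edge <= 0:
        raise ValueError(f"edge radius must be > 0, got {r_edge}")
    return geom.R**2 / (geom.rho * r_edge)


def nondimensionalize(geom: CapGeometry, env: EnvelopeParams) -> dict[str, float]:
    """Reduce (geometry, envelope) to the solver's dimensionless groups.

    Returns ``R_over_rho``, ``rho_over_d``, ``eps_over_k`` and
    ``a = 2*kappa/(k*d^2)``.  Round-trips exactly with
    :func:`redimensionalize` given the same ``d`` and ``k``.
    """
    return {
        "R_over_rho": geom.R / geom.rho,
        "rho_over_d": geom.rho / geom.d,
        "eps_over_k": env.eps / env.k,
        "a": env.bending_parameter(geom.d),
    }


def redimensionalize(
    params: dict[str, float], d_nm: float, k_mN_per_m: float
) -> tuple[CapGeometry, EnvelopeParams]:
    """Inverse of :func:`nondimensionalize` given the two scale choices."""
    rho = params["rho_over_d"] * d_nm
    R = params["R_over_rho"] * rho
    eps = params["eps_over_k"] * k_mN_per_m
    kappa = params["a"] * (k_mN_per_m * 1e-3) * (d_nm * 1e-9) ** 2 / 2.0
    return CapGeometry(R=R, rho=rho, d=d_nm), EnvelopeParams(
        k=k_mN_per_m, eps=eps, kappa=kappa
    )


_GEOM_KEYS = ("R_nm", "rho_nm", "d_nm")


def _geometry_from_mapping(data: dict) -> CapGeometry:
    missing = [key for key in _GEOM_KEYS if key not in data]
    if missing:
        raise GeometryError(
            f"geometry config missing required keys {missing}; "
            f"expected {list(_GEOM_KEYS)}"
        )
    try:
        values = {key: float(data[key]) for key in _GEOM_KEYS}
    except (TypeError, ValueError) as exc:
        raise GeometryError(f"non-numeric geometry value: {exc}") from exc
    return CapGeometry(R=values["R_nm"], rho=values["rho_nm"], d=values["d_nm"])


def load_geometry(path: str | Path) -> CapGeometry:
    """Load a single cap geometry from a YAML or JSON config file.

    The file must define the keys ``R_nm``, ``rho_nm`` and ``d_nm``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise GeometryError(f"{path}: expected a mapping with keys {list(_GEOM_KEYS)}")
    return _geometry_from_mapping(data)


def load_geometry_batch(path: str | Path) -> list[CapGeometry]:
    """Load one geometry per row from a CSV with columns R_nm, rho_nm, d_nm."""
    table = pd.read_csv(path)
    missing = [key for key in _GEOM_KEYS if key not in table.columns]
    if missing:
        raise GeometryError(f"{path}: CSV missing required columns {missing}")
    return [
        _geometry_from_mapping(row._asdict())
        for row in table[list(_GEOM_KEYS)].itertuples(index=False)
    ]
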