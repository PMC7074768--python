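import numpy as np
import pytest

from nanocap import CapGeometry, EnvelopeParams


@pytest.fixture
def hemispheres() -> CapGeometry:
    """Tightly packed hemispherical caps: R = rho = d/2."""
    return CapGeometry(R=45.0, rho=45.0, d=90.0)


@pytest.fixture
def cs_geometry() -> CapGeometry:
    """A cotton-swab cap close to the 100 nm-deposition surface."""
    return CapGeometry(R=42.9, rho=39.0, d=86.0)


@pytest.fixture
def soft_envelope() -> EnvelopeParams:
    return EnvelopeParams(k=300.0, eps=0.5, kappa=0.0)


def brute_force_lambda(a_cap, a_sus, e, s0=1.0, iters=100):
    """Vectorized bisection oracle for the area-conservation constraint.

    Independent of the production Brent solver: plain interval halving on
    the admissible region, broadcast over numpy arrays of cap/suspended
    areas (one per wetting angle).
    """
    a_cap = np.asarray(a_cap, dtype=float)
    a_sus = np.asarray(a_sus, dtype=float)

    def g(lam):
        cap = np.where(a_cap > 0, a_cap / (lam + 1.0 - e) ** 2, 0.0)
        return cap + a_sus / (lam + 1.0) ** 2 - s0

    lo_bound = max(-1.0, -1.0 + e)
    lo = np.full(a_cap.shape, lo_bound + 1e-12)
    hi = np.full(a_cap.shape, 1.0)
    for _ in range(80):  # expand upper bracket
        mask = g(hi) > 0
        if not mask.any():
            break
        hi = np.where(mask, 2 * hi + 1, hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        above = g(mid) > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return 0.5 * (lo + hi)


def brute_force_min_state(R_over_d, theta_max, e, n_grid=10_000, s0=1.0):
    """Dense-grid free-energy minimum oracle (theta*, lam*, F*)."""
    thetas = np.linspace(0.0, theta_max, n_grid)
    a_cap = 2 * np.pi * R_over_d**2 * (1 - np.cos(thetas))
    a_sus = 1 - np.pi * R_over_d**2 * np.sin(thetas) ** 2
    lams = brute_force_lambda(a_cap, a_sus, e, s0)
    cap_term = np.where(
        a_cap > 0, a_cap * ((lams - e) ** 2 - e) / (lams + 1 - e) ** 2, 0.0
    )
    F = cap_term + a_sus * lams**2 / (lams + 1) ** 2
    i = int(np.argmin(F))
    return thetas[i], lams[i], F[i]
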