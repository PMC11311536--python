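"""Independent collision-integral oracle for central potentials.

For a spherically symmetric potential V(r) the classical deflection angle
has the closed-form quadrature

    χ(E, b) = π − 2b ∫_{r₀}^∞ dr / (r² √(1 − b²/r² − V(r)/E))

with r₀ the outermost turning point, and the transport cross section and
temperature-averaged collision integral follow by two more quadratures:

    Q⁽¹⁾(E) = 2π ∫ (1 − cos χ) b db,
    Ω⁽¹·¹⁾(T) = (1/2) ∫ x² e^(−x) Q⁽¹⁾(x·kT) dx.

This module is a verification tool: it shares no code with the Monte-Carlo
trajectory engine, so agreement between the two is a meaningful check.
In the classical-orbiting regime (near-degenerate turning point) the
deflection factor 1 − cos χ is replaced by its random-phase average 1;
this only matters deep in the attractive low-energy tail.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import roots_genlaguerre, roots_legendre

from .constants import R_KJ

__all__ = ["spherical_ccs_oracle", "transport_cross_section"]


def _turning_point(potential, E: float, b: float, r_far: float) -> float | None:
    """Outermost root of 1 − b²/r² − V(r)/E; None signals orbiting."""
    def g(r):
        return 1.0 - (b / r) ** 2 - potential(r) / E

    r_lo = min(1e-3, 0.1 * b) if b > 0 else 1e-3
    grid = np.geomspace(max(r_far, 5.0 * b), r_lo, 800)
    with np.errstate(over="ignore", invalid="ignore"):
        vals = np.array([g(r) for r in grid])
    vals = np.nan_to_num(vals, nan=-np.inf, neginf=-np.inf)
    sign_change = np.where((vals[:-1] > 0) & (vals[1:] <= 0))[0]
    if sign_change.size == 0:
        raise RuntimeError(
            "no classical turning point found; potential may not decay to 0"
        )
    k = sign_change[0]
    r0 = brentq(g, grid[k + 1], grid[k], xtol=1e-14, rtol=1e-14)
    # orbiting: effective-potential barrier makes the root nearly degenerate
    dg = (g(r0 * (1 + 1e-7)) - g(r0 * (1 - 1e-7))) / (2e-7 * r0)
    if abs(dg) * r0 < 1e-6:
        return None
    return r0


def _deflection(potential, E: float, b: float, r_far: float,
                nodes_t, weights_t) -> float | None:
    """χ(E, b) by turning-point-regularized quadrature; None for orbiting."""
    if b == 0.0:
        return np.pi  # head-on against a repulsive core
    r0 = _turning_point(potential, E, b, r_far)
    if r0 is None:
        return None
    u0 = 1.0 / r0
    # u = u0 (1 − t²) removes the inverse-square-root endpoint singularity
    t = nodes_t
    u = u0 * (1.0 - t * t)
    r = 1.0 / np.maximum(u, 1e-300)
    with np.errstate(over="ignore", invalid="ignore"):
        vr = np.array([potential(x) for x in r])
        gg = 1.0 - (b * u) ** 2 - vr / E
    gg = np.maximum(gg, 1e-300)
    integrand = 2.0 * u0 * t / np.sqrt(gg)
    integral = float(np.sum(weights_t * integrand))
    return np.pi - 2.0 * b * integral


def _far_radius(potential, kT: float) -> float:
    r = 1.0
    for _ in range(60):
        with np.errstate(over="ignore"):
            if abs(potential(r)) < 1e-9 * kT:
                return r
        r *= 1.5
    return r


def _b_cut(potential, E: float, r_far: float, nodes_t, weights_t) -> float:
    """Smallest b (by growth search) where |χ| < 10⁻⁴ rad."""
    b = 1.0
    for _ in range(80):
        chi = _deflection(potential, E, b, r_far, nodes_t, weights_t)
        if chi is not None and abs(chi) < 1e-4:
            return b
        b *= 1.3
    return b


def transport_cross_section(potential, E: float, *, n_b: int = 300,
                            n_theta: int = 200) -> float:
    """Q⁽¹⁾(E) (Å²) for a central potential at collision energy E (kJ/mol)."""
    if E <= 0:
        raise ValueError("collision energy must be positive")
    nt, wt = roots_legendre(n_theta)
    nt = 0.5 * (nt + 1.0)  # map to (0, 1)
    wt = 0.5 * wt
    r_far = _far_radius(potential, E)
    bc = _b_cut(potential, E, r_far, nt, wt)
    nb, wb = roots_legendre(n_b)
    bs = 0.5 * bc * (nb + 1.0)
    ws = 0.5 * bc * wb
    total = 0.0
    for b, w in zip(bs, ws):
        chi = _deflection(potential, E, b, r_far, nt, wt)
        factor = 1.0 if chi is None else (1.0 - np.cos(chi))
        total += w * factor * 2.0 * np.pi * b
    return total


def spherical_ccs_oracle(
    potential,
    gas=None,
    T: float = 298.0,
    *,
    n_energy: int = 24,
    n_b: int = 240,
    n_theta: int = 200,
) -> float:
    """Ω⁽¹·¹⁾(T) in Å² for a central potential, by nested quadrature.

    ``potential`` maps r (Å) to energy (kJ/mol) and must decay to zero.
    ``gas`` (a BufferGasModel) only supplies the temperature when given;
    the collision integral is independent of the masses.
    """
    if gas is not None:
        T = gas.temperature
    if T <= 0:
        raise ValueError("temperature must be positive")
    kT = R_KJ * T
    x, wx = roots_genlaguerre(n_energy, 2)  # weight x² e^−x on (0, ∞)
    total = 0.0
    for xi, wi in zip(x, wx):
        q1 = transport_cross_section(potential, xi * kT, n_b=n_b, n_theta=n_theta)
        total += wi * q1
    return 0.5 * total
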