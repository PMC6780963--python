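"""Independent oracles used only by the tests.

The radial oracle solves the same physical problem as the production
solver but with an entirely different method: SciPy's collocation BVP
solver (`solve_bvp`) on a fine mesh, with a plain relaxed fixed point on
the zone boundaries and a *step* (not volume-weighted) zone factor. It
was written before the production solver was trusted and stays
independent of it.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_bvp
from scipy.optimize import brentq

from avatum.model_core import NutrientSpec


def _solve_one(R, spec, Rq, Rn, n_mesh=2001):
    """Collocation solve of (r^2 c')' = (r^2/D) f(r) Vmax c/(Km+c).

    Nondimensionalized (x = r/R, u = c/C_bulk) so the collocation
    solver sees O(1) magnitudes, and solved on [x0, 1] with a tiny
    inner cutoff and symmetry there; c' ~ r near the centre, so the
    truncation perturbs the solution negligibly while avoiding the
    coordinate singularity.
    """

    xq, xn = Rq / R, Rn / R
    phi2 = spec.Vmax * R**2 / (spec.D_tissue * spec.C_bulk)  # Thiele-like
    km = spec.Km / spec.C_bulk

    def zone_factor(x):
        # steps mollified over 0.2% of the radius: collocation cannot
        # refine across a true discontinuity; the perturbation to the
        # solution is far below the comparison tolerance
        w = 2e-3
        f = np.ones_like(x)
        if xq > 0:
            f -= 0.25 * (1.0 - np.tanh((x - xq) / w))
        if xn > 0:
            f -= 0.25 * (1.0 - np.tanh((x - xn) / w))
        return f

    def rhs(x, y):
        u, du = y
        u = np.clip(u, 0.0, None)
        q = zone_factor(x) * phi2 * u / (km + u)
        return np.vstack([du, q - 2.0 * du / x])

    def bc(ya, yb):
        return np.array([ya[1], yb[0] - 1.0])

    x = np.linspace(1e-3, 1.0, n_mesh)
    y0 = np.vstack([np.ones_like(x), np.zeros_like(x)])
    sol = solve_bvp(rhs, bc, x, y0, tol=1e-6, max_nodes=400000)
    if not sol.success:
        raise RuntimeError(f"oracle BVP failed: {sol.message}")
    return sol


def radial_oracle(R, specs, max_iter=300, relax=0.3, n_eval=4001):
    """(r, c_glucose, c_oxygen, Rq, Rn) for the steady two-nutrient
    free-boundary problem; intended for radii without a necrotic core
    (where crossing radii are well-conditioned)."""
    spec_g, spec_o = specs
    Rq = Rn = 0.0
    rr = np.linspace(1e-3 * R, R, n_eval)
    for _ in range(max_iter):
        sol_g = _solve_one(R, spec_g, Rq, Rn)
        sol_o = _solve_one(R, spec_o, Rq, Rn)
        cg = sol_g.sol(rr / R)[0] * spec_g.C_bulk
        co = sol_o.sol(rr / R)[0] * spec_o.C_bulk
        crossings = []
        for c, spec in ((cg, spec_g), (co, spec_o)):
            if spec.C_crit <= 0 or c[0] >= spec.C_crit:
                crossings.append(0.0)
            else:
                fcn = lambda r: np.interp(r, rr, c) - spec.C_crit
                crossings.append(brentq(fcn, 0.0, R, xtol=1e-12 * R))
        Rq_new, Rn_new = max(crossings), min(crossings)
        if abs(Rq_new - Rq) < 1e-7 * R and abs(Rn_new - Rn) < 1e-7 * R:
            return rr, cg, co, Rq_new, Rn_new
        Rq += relax * (Rq_new - Rq)
        Rn += relax * (Rn_new - Rn)
    raise RuntimeError("oracle fixed point did not converge")


def duct_velocity_profile(y, z, half_width, height, n_terms=60):
    """Analytic fully developed rectangular-duct axial velocity (up to a
    multiplicative constant): no-slip at z = 0, H and y = +-W/2,
    evaluated on the given coordinates. Classic Fourier series."""
    b = half_width
    ay = np.minimum(np.abs(y), b)  # clamp outside the wall (solid region)
    u = np.zeros(np.broadcast(y, z).shape)
    for k in range(n_terms):
        n = 2 * k + 1
        lam = n * np.pi / height
        # cosh(lam*y)/cosh(lam*b) via exponentials (cosh overflows)
        ratio = (
            np.exp(lam * (ay - b))
            * (1.0 + np.exp(-2.0 * lam * ay))
            / (1.0 + np.exp(-2.0 * lam * b))
        )
        term = (
            (4.0 / (n * np.pi))
            * np.sin(n * np.pi * z / height)
            * (1.0 - ratio)
            / n**2
        )
        u = u + term
    return u


def stokes_sphere_max_shear(mu, U, a):
    """Classical maximum tangential traction on a rigid sphere in
    uniform Stokes flow: (3/2) mu U / a."""
    return 1.5 * mu * U / a
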