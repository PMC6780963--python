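"""Coupled nutrient transport in the perfused channel.

A single-domain finite-volume solve on the chip grid with piecewise
coefficients: outside the tumor the nutrient is advected by the solved
flow and diffuses with its medium diffusivity (no consumption in the
culture medium); inside the tumor the velocity is identically zero and
the nutrient diffuses with its tissue diffusivity while being consumed
at the zone-dependent Michaelis–Menten rate (full in proliferative
voxels, half in quiescent, zero in necrotic). Concentration and normal
diffusive flux are continuous across the tumor surface because the
discretization is conservative with harmonic-mean face diffusivities.

Boundary conditions: Dirichlet inlet at the feed concentration,
impermeable walls everywhere (the chip surfaces pass no nutrient),
zero-diffusive-flux advective outflow at the outlet.

Because the zone labels depend on the concentrations they control, the
solver iterates {solve both nutrients; reclassify tumor voxels} with a
relaxed per-voxel consumption factor until the fields and factors stop
moving (same free-boundary fixed point as the radial solver, in 3D).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..model_core import NutrientSpec, _ordered_specs, volume_from_radius
from .flow import FlowField
from .geometry import ChipDomain

logger = logging.getLogger(__name__)

__all__ = ["ConcentrationField3D", "TransportError", "solve_transport"]

RESIDUAL_TOL = 1e-3
MAX_OUTER = 150
FACTOR_DAMPING = 0.5
DEFICIENCY_BAND = 0.05  # smoothing band for the zone indicator, x C_crit


class TransportError(RuntimeError):
    """Zone fixed point failed to converge; carries the last label field."""

    def __init__(self, message, labels=None):
        super().__init__(message)
        self.labels = labels


@dataclass
class ConcentrationField3D:
    """Steady nutrient fields with tumor zone labels and zone volumes.

    ``c_glucose`` / ``c_oxygen`` are cell-centred (NaN in solid cells);
    ``labels`` is -1 outside the tumor, else the ZoneLabel integer.
    Zone volumes are full-sphere volumes: the voxel label fractions are
    applied to the analytic sphere volume so that stair-stepping does
    not bias the growth law.
    """

    domain: ChipDomain
    c_glucose: np.ndarray
    c_oxygen: np.ndarray
    labels: np.ndarray
    V: float
    Vq: float
    Vn: float
    n_outer: int = 0

    def surface_concentration_range(self, nutrient: str = "glucose"):
        """(min, max) concentration over fluid voxels adjacent to the tumor."""
        c = self.c_glucose if nutrient == "glucose" else self.c_oxygen
        adj = _tumor_adjacent_fluid(self.domain)
        return float(np.nanmin(c[adj])), float(np.nanmax(c[adj]))


def _tumor_adjacent_fluid(domain: ChipDomain) -> np.ndarray:
    tumor = domain.tumor_mask
    adj = np.zeros_like(tumor)
    for a in range(3):
        for s in (1, -1):
            shifted = np.roll(tumor, s, axis=a)
            sl = [slice(None)] * 3
            sl[a] = 0 if s == 1 else -1
            shifted[tuple(sl)] = False
            adj |= shifted
    return adj & domain.fluid_mask


def _assemble(domain, flow, spec, unknown, num):
    """Upwind advection + harmonic-mean diffusion (sink added later)."""
    shape = domain.shape
    dx, dy, dz = domain.widths
    tumor = domain.tumor_mask
    D_cell = np.where(tumor, spec.D_tissue, spec.D_medium)

    cells = np.argwhere(unknown)
    ci = [cells[:, a] for a in range(3)]
    rown = num[tuple(ci)]
    n = len(rown)
    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows, cols, vals = [], [], []

    widths = (dx, dy, dz)
    face_vel = (flow.u, flow.v, flow.w)
    areas = {
        0: dy[ci[1]] * dz[ci[2]],
        1: dx[ci[0]] * dz[ci[2]],
        2: dx[ci[0]] * dy[ci[1]],
    }
    for a in range(3):
        wa = widths[a]
        A = areas[a]
        for s in (-1, 1):
            ni = [x.copy() for x in ci]
            ni[a] = ni[a] + s
            inb = (ni[a] >= 0) & (ni[a] <= shape[a] - 1)
            # face index along a between cell and neighbour
            fidx = [x.copy() for x in ci]
            fidx[a] = ci[a] + (1 if s > 0 else 0)
            vel = face_vel[a][tuple(fidx)]
            q = vel * A * s  # outward volumetric flux through this face
            n_unknown = np.zeros(n, bool)
            n_unknown[inb] = unknown[tuple(x[inb] for x in ni)]
            # --- interior faces between two unknown cells
            m = n_unknown
            if m.any():
                d1 = 0.5 * wa[ci[a][m]]
                d2 = 0.5 * wa[ni[a][m]]
                D1 = D_cell[tuple(x[m] for x in ci)]
                D2 = D_cell[tuple(x[m] for x in ni)]
                Td = A[m] / (d1 / D1 + d2 / D2)  # harmonic-mean diffusivity
                nn = num[tuple(x[m] for x in ni)]
                # upwind advection: outflow on diagonal, inflow from neighbour
                qm = q[m]
                diag_add = Td + np.maximum(qm, 0.0)
                off = -Td - np.maximum(-qm, 0.0)
                np.add.at(diag, np.nonzero(m)[0], diag_add)
                rows.append(rown[m])
                cols.append(nn)
                vals.append(off)
            # --- domain boundaries along x: inlet / outlet
            if a == 0:
                oob = ~inb
                if s < 0:
                    mio = oob  # inlet: Dirichlet feed concentration
                    if mio.any():
                        Td = A[mio] * spec.D_medium / (0.5 * wa[ci[0][mio]])
                        q_in = -q[mio]  # inflow magnitude
                        np.add.at(diag, np.nonzero(mio)[0], Td)
                        rhs[mio] += (Td + np.maximum(q_in, 0.0)) * spec.C_bulk
                else:
                    moo = oob  # outlet: advective outflow, no diffusion
                    if moo.any():
                        np.add.at(diag, np.nonzero(moo)[0], np.maximum(q[moo], 0.0))
            # solid neighbours / walls / symmetry: no flux (skip)

    rows.append(rown)
    cols.append(rown)
    vals.append(diag)
    A_mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A_mat, rhs


def solve_transport(
    domain: ChipDomain,
    flow: FlowField,
    specs: tuple[NutrientSpec, NutrientSpec],
    max_outer: int = MAX_OUTER,
) -> ConcentrationField3D:
    """Steady coupled transport with the zone free-boundary fixed point.

    The zone factors and the Michaelis–Menten linearization only change
    tumor-voxel diagonal entries between sweeps, so the large fluid
    block is factorized once per call and eliminated; each sweep then
    costs one small dense solve on the tumor voxels. The initial factor
    field comes from the spherically symmetric solution at the same
    radius, which is close to the chip fixed point.
    """
    spec_g, spec_o = _ordered_specs(specs)
    shape = domain.shape
    tumor = domain.tumor_mask
    unknown = domain.fluid_mask | tumor
    n = int(unknown.sum())
    n_t = int(tumor.sum())
    # number unknowns with tumor voxels last (block elimination)
    num = np.full(shape, -1, dtype=np.int64)
    nonturm = unknown & ~tumor
    n_p = int(nonturm.sum())
    num[nonturm] = np.arange(n_p)
    num[tumor] = n_p + np.arange(n_t)

    factor, cg_field, co_field = _radial_warm_start(domain, spec_g, spec_o)
    vols_t = domain.cell_volumes[tumor]

    solvers = []
    for spec, c0 in ((spec_g, cg_field), (spec_o, co_field)):
        A0, b = _assemble(domain, flow, spec, unknown, num)
        solvers.append(_BlockSolver(A0, b, n_p, n_t))

    theta = FACTOR_DAMPING
    prev_move = np.inf
    move = dc = np.nan
    for outer in range(max_outer):
        dc = 0.0
        for spec, cf, solver in (
            (spec_g, cg_field, solvers[0]),
            (spec_o, co_field, solvers[1]),
        ):
            sink = factor[tumor] * spec.Vmax / (spec.Km + cf[tumor]) * vols_t
            x = solver.solve(sink)
            c_new = cf.copy()
            c_new[nonturm] = x[:n_p]
            c_new[tumor] = x[n_p:]
            dc = max(dc, float(np.max(np.abs(c_new[unknown] - cf[unknown]))) / spec.C_bulk)
            cf[...] = c_new
        # reclassify tumor voxels with a smoothed deficiency indicator:
        # a voxel whose concentration sits within a narrow band around
        # C_crit gets a fractional deficiency (a sub-voxel interface
        # position), which keeps the solve -> reclassify map continuous
        # (a necrotic core flattens the binding nutrient's profile at
        # C_crit, where a binary indicator would flip indefinitely)
        dg = _deficiency(cg_field, spec_g)
        do = _deficiency(co_field, spec_o)
        f_target = 1.0 - 0.5 * (dg + do)
        move = float(np.max(np.abs(f_target[tumor] - factor[tumor]))) if n_t else 0.0
        if dc < 1e-6 and move < 1e-3:
            factor = factor + theta * (f_target - factor)
            break
        if move >= prev_move:
            theta = max(theta * 0.7, 0.02)
        else:
            theta = min(theta * 1.3, FACTOR_DAMPING)  # recover when contracting
        prev_move = move
        factor = factor + theta * (f_target - factor)
    else:
        raise TransportError(
            f"zone fixed point did not converge in {max_outer} iterations "
            f"(last label move {move:.3f}, dc {dc:.2e})",
            labels=_labels(domain, cg_field, co_field, spec_g, spec_o),
        )

    if np.nanmin(cg_field[unknown]) < -1e-9 or np.nanmin(co_field[unknown]) < -1e-9:
        raise TransportError("negative concentration in converged transport field")
    for spec, cf, solver in (
        (spec_g, cg_field, solvers[0]),
        (spec_o, co_field, solvers[1]),
    ):
        sink = factor[tumor] * spec.Vmax / (spec.Km + cf[tumor]) * vols_t
        x = np.concatenate([cf[nonturm], cf[tumor]])
        res = solver.residual(sink, x)
        if res > RESIDUAL_TOL:
            raise TransportError(
                f"{spec.name.value} transport residual {res:.2e} above {RESIDUAL_TOL}"
            )

    labels = _labels(domain, cg_field, co_field, spec_g, spec_o)
    V = volume_from_radius(domain.tumor_radius)
    vols = domain.cell_volumes
    vt = vols[tumor].sum()
    if vt > 0:
        # zone fractions from the smoothed indicators (sub-voxel sharp);
        # "at least one deficient" = dg + do - dg*do, "both" = dg*do
        dg = _deficiency(cg_field, spec_g)[tumor]
        do = _deficiency(co_field, spec_o)[tumor]
        vw = vols[tumor]
        q_frac = float(np.sum(vw * (dg + do - dg * do)) / vt)
        n_frac = float(np.sum(vw * dg * do) / vt)
    else:
        q_frac = n_frac = 0.0
    cg_out = np.where(unknown, cg_field, np.nan)
    co_out = np.where(unknown, co_field, np.nan)
    return ConcentrationField3D(
        domain=domain,
        c_glucose=cg_out,
        c_oxygen=co_out,
        labels=labels,
        V=V,
        Vq=V * q_frac,
        Vn=V * n_frac,
        n_outer=outer + 1,
    )


class _BlockSolver:
    """Solves (A0 + diag(sink on tumor rows)) x = b repeatedly.

    A0 is ordered [fluid..., tumor...]; only the tumor diagonal changes
    between calls, so the fluid block is factorized once and the
    problem reduced to a dense Schur complement on the tumor voxels.
    """

    def __init__(self, A0, b, n_p, n_t):
        self.n_p, self.n_t = n_p, n_t
        self.A0 = A0.tocsr()
        A0 = A0.tocsc()
        self.b = b
        if n_t == 0:
            self.lu = spla.splu(A0)
            return
        App = A0[:n_p, :n_p]
        self.Apt = A0[:n_p, n_p:].toarray()
        self.Atp = A0[n_p:, :n_p].tocsr()
        self.Att = A0[n_p:, n_p:].toarray()
        self.lu = spla.splu(App)
        self.W = self.lu.solve(self.Apt)
        self.Vp = self.lu.solve(b[:n_p])
        self.S0 = self.Att - self.Atp @ self.W
        self.rt0 = b[n_p:] - self.Atp @ self.Vp

    def solve(self, sink):
        if self.n_t == 0:
            return self.lu.solve(self.b)
        S = self.S0 + np.diag(sink)
        xt = np.linalg.solve(S, self.rt0)
        xp = self.Vp - self.W @ xt
        return np.concatenate([xp, xt])

    def residual(self, sink, x):
        """Relative inf-norm residual of the nonlinear discrete system."""
        r = self.A0 @ x - self.b
        if self.n_t:
            r[self.n_p :] += sink * x[self.n_p :]
        scale = max(np.max(np.abs(self.b)), 1e-300)
        return float(np.max(np.abs(r)) / scale)


def _radial_warm_start(domain, spec_g, spec_o):
    """Initial zone factors / concentrations from the spherically
    symmetric solution at the same radius (surface held at the feed
    concentration); falls back to all-proliferative on any failure."""
    shape = domain.shape
    factor = np.ones(shape)
    cg = np.full(shape, spec_g.C_bulk)
    co = np.full(shape, spec_o.C_bulk)
    tumor = domain.tumor_mask
    if not tumor.any():
        return factor, cg, co
    try:
        from ..radial_sim import solve_steady_profile

        prof = solve_steady_profile(
            domain.tumor_radius, (spec_g, spec_o), n_nodes=128, refine=False
        )
    except Exception:
        return factor, cg, co
    xc, yc, zc = domain.centers
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    cx, cy, cz = domain.tumor_center
    dist = np.sqrt((X - cx) ** 2 + Y**2 + (Z - cz) ** 2)
    dt = dist[tumor]
    factor_t = np.ones_like(dt)
    factor_t[dt < prof.Rq] = 0.5
    factor_t[dt < prof.Rn] = 0.0
    factor[tumor] = factor_t
    cg[tumor] = np.interp(dt, prof.r, prof.c_glucose)
    co[tumor] = np.interp(dt, prof.r, prof.c_oxygen)
    return factor, cg, co


def _deficiency(c: np.ndarray, spec: NutrientSpec) -> np.ndarray:
    """Smoothed deficiency indicator in [0, 1] (1 = fully deficient).

    Linear ramp over a band of +-DEFICIENCY_BAND/2 x C_crit around the
    critical concentration; zero everywhere when C_crit is zero.
    """
    if spec.C_crit <= 0.0:
        return np.zeros_like(c)
    w = DEFICIENCY_BAND * spec.C_crit
    return np.clip((spec.C_crit - c) / w + 0.5, 0.0, 1.0)


def _labels(domain, cg, co, spec_g, spec_o):
    labels = np.full(domain.shape, -1, dtype=np.int8)
    tumor = domain.tumor_mask
    defic_g = cg < spec_g.C_crit
    defic_o = co < spec_o.C_crit
    labels[tumor] = 0
    labels[tumor & (defic_g ^ defic_o)] = 1
    labels[tumor & defic_g & defic_o] = 2
    return labels


def solute_balance(
    domain: ChipDomain,
    flow: FlowField,
    field_: ConcentrationField3D,
    spec: NutrientSpec,
) -> tuple[float, float]:
    """(net advective influx, consumption integral), mol/s, half-domain.

    At steady state the two agree to solver tolerance (conservation).
    """
    c = field_.c_glucose if spec.name.value == "glucose" else field_.c_oxygen
    _, dy, dz = domain.widths
    area = dy[:, None] * dz[None, :]
    # inlet: advective + diffusive influx; outlet: advective outflow
    cin = spec.C_bulk
    c0 = c[0]
    dx0 = domain.widths[0][0]
    diff_in = np.nansum(spec.D_medium * (cin - c0) / (0.5 * dx0) * area * (~np.isnan(c0)))
    adv_in = np.nansum(flow.u[0] * area * cin)
    adv_out = np.nansum(flow.u[-1] * area * np.nan_to_num(c[-1]))
    influx = adv_in + diff_in - adv_out
    # consumption integral with the converged labels
    factor = np.zeros(domain.shape)
    factor[field_.labels == 0] = 1.0
    factor[field_.labels == 1] = 0.5
    sink = factor * spec.Vmax * np.nan_to_num(c) / (spec.Km + np.nan_to_num(c))
    consumed = float(np.sum(sink[domain.tumor_mask] * domain.cell_volumes[domain.tumor_mask]))
    return float(influx), consumed
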