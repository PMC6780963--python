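"""Steady incompressible flow through the trap channel.

The culture-medium flow is solved on a marker-and-cell (MAC) staggered
rectilinear grid: velocity components live on cell faces, pressure at
cell centres, which makes the discrete divergence exact and the
saddle-point system symmetric. At chip scale the Reynolds number is of
order one or less, so the default drops the convective momentum term
(Stokes); a config switch restores steady Navier–Stokes via Picard
(Oseen) iteration with first-order upwinding.

Boundary conditions: uniform-flux inlet at x = 0, zero-gradient outflow
with a pressure datum p = 0 at x = L, no-slip on the channel floor and
ceiling, the trap walls and the tumor surface (stair-step voxel
surfaces with half-cell wall distances), and free-slip symmetry on both
lateral faces. The tumor is rigid and stationary: interior velocity is
identically zero.

The linear Stokes system is solved with MINRES using a block
preconditioner (exact LU of each velocity Laplacian block, pressure
mass matrix scaled by 1/mu), falling back to a sparse direct solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..model_core import FluidProps
from ..units import pa_to_dyn_cm2
from .geometry import CellType, ChipDomain

logger = logging.getLogger(__name__)

__all__ = ["FlowField", "FlowSolverError", "solve_flow", "max_wall_shear"]

_OUT = -1  # sentinel cell type outside the domain

VELOCITY_RESIDUAL_TOL = 1e-6  # stated convergence criterion for the flow solve


class FlowSolverError(RuntimeError):
    """Flow solve failed to converge; carries the residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or []


@dataclass
class FlowField:
    """Discrete velocity (face-normal components) and pressure fields.

    ``u``, ``v``, ``w`` are face arrays of shape (nx+1, ny, nz) etc.;
    ``p`` is cell-centred (NaN in solid/tumor cells). ``Q_inlet`` is
    the full-channel volumetric flow rate in m^3/s (the meshed symmetry
    half carries Q/2).
    """

    domain: ChipDomain
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    Q_inlet: float
    viscosity: float = np.nan
    residual: float = np.nan
    residual_history: list = field(default_factory=list)

    def cell_velocity(self) -> np.ndarray:
        """Cell-centred velocity vectors, shape (nx, ny, nz, 3)."""
        out = np.empty(self.domain.shape + (3,))
        out[..., 0] = 0.5 * (self.u[:-1] + self.u[1:])
        out[..., 1] = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        out[..., 2] = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return out

    def mass_balance(self) -> tuple[float, float]:
        """(inflow, outflow) through the full channel, m^3/s."""
        _, dy, dz = self.domain.widths
        area = dy[:, None] * dz[None, :]
        q_in = 2.0 * float(np.sum(self.u[0] * area))
        q_out = 2.0 * float(np.sum(self.u[-1] * area))
        return q_in, q_out

    def divergence_max(self) -> float:
        """Max cell divergence flux normalized by the inlet flux."""
        dx, dy, dz = self.domain.widths
        ax = dy[None, :, None] * dz[None, None, :]
        ay = dx[:, None, None] * dz[None, None, :]
        az = dx[:, None, None] * dy[None, :, None]
        div = (
            (self.u[1:] - self.u[:-1]) * ax
            + (self.v[:, 1:] - self.v[:, :-1]) * ay
            + (self.w[:, :, 1:] - self.w[:, :, :-1]) * az
        )
        scale = max(abs(self.Q_inlet) / 2.0, 1e-300)
        return float(np.max(np.abs(div[self.domain.fluid_mask])) / scale)

    def scaled(self, factor: float) -> "FlowField":
        """Linearly rescaled field (Stokes flow is linear in Q)."""
        return FlowField(
            domain=self.domain,
            u=self.u * factor,
            v=self.v * factor,
            w=self.w * factor,
            p=self.p * factor,
            Q_inlet=self.Q_inlet * factor,
            viscosity=self.viscosity,
            residual=self.residual,
            residual_history=list(self.residual_history),
        )


def _face_setup(domain: ChipDomain, d: int, U_in: float):
    """Active mask and fixed values for component ``d`` faces."""
    shape = domain.shape
    sh = list(shape)
    sh[d] += 1
    ct_pad = np.full(tuple(n + 2 for n in shape), _OUT, dtype=np.int8)
    ct_pad[1:-1, 1:-1, 1:-1] = domain.cell_type
    idx = np.indices(sh)
    # padded indices of the minus- and plus-side cells of each face
    cm = [idx[a] + 1 - (1 if a == d else 0) for a in range(3)]
    cp = [idx[a] + 1 for a in range(3)]
    t_cm = ct_pad[tuple(cm)]
    t_cp = ct_pad[tuple(cp)]
    fluid_cm = t_cm == int(CellType.FLUID)
    fluid_cp = t_cp == int(CellType.FLUID)
    active = fluid_cm & fluid_cp
    fixed = np.zeros(sh)
    if d == 0:
        active |= (idx[0] == shape[0]) & fluid_cm  # outlet faces are unknowns
        fixed[(idx[0] == 0) & fluid_cp] = U_in  # uniform-flux inlet
    return np.array(sh), active, fixed, t_cm, t_cp


def _assemble_stokes(domain: ChipDomain, fluid: FluidProps, Q_inlet: float):
    """Assemble the symmetric Stokes saddle system K [U; p] = b."""
    mu = fluid.viscosity
    shape = domain.shape
    widths = domain.widths
    U_in = (Q_inlet / 2.0) / (domain.channel.width / 2.0 * domain.channel.height)

    fluid_mask = domain.fluid_mask
    n_p = int(fluid_mask.sum())
    p_num = np.full(shape, -1, dtype=np.int64)
    p_num[fluid_mask] = np.arange(n_p)

    comp = []
    offset = 0
    for d in range(3):
        sh, active, fixed, t_cm, t_cp = _face_setup(domain, d, U_in)
        num = np.full(tuple(sh), -1, dtype=np.int64)
        n_act = int(active.sum())
        num[active] = offset + np.arange(n_act)
        offset += n_act
        comp.append(dict(d=d, sh=sh, active=active, fixed=fixed, num=num))
    n_u = offset
    n_tot = n_u + n_p

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_tot)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # half-cell CV lengths along each axis at face positions
    dcv = []
    for a in range(3):
        w = widths[a]
        v = np.empty(len(w) + 1)
        v[1:-1] = 0.5 * (w[:-1] + w[1:])
        v[0] = 0.5 * w[0]
        v[-1] = 0.5 * w[-1]
        dcv.append(v)

    solid_like = (int(CellType.SOLID), int(CellType.TUMOR))

    for c in comp:
        d, sh, active, fixed, num = c["d"], c["sh"], c["active"], c["fixed"], c["num"]
        af = np.argwhere(active)  # (n_act, 3) face indices
        n_act = len(af)
        if n_act == 0:
            continue
        fi = [af[:, a] for a in range(3)]
        rown = num[tuple(fi)]
        others = [a for a in range(3) if a != d]
        # cross-section area of the face (normal to d)
        A_f = widths[others[0]][fi[others[0]]] * widths[others[1]][fi[others[1]]]
        diag = np.zeros(n_act)

        for a in range(3):
            for s in (-1, 1):
                if a == d:
                    cc = fi[d] + (0 if s > 0 else -1)  # crossed cell along d
                    valid = (cc >= 0) & (cc <= shape[d] - 1)
                    if not valid.any():
                        continue
                    T = np.zeros(n_act)
                    T[valid] = mu * A_f[valid] / widths[d][cc[valid]]
                    nf = [fi[x].copy() for x in range(3)]
                    nf[d] = fi[d] + s
                    inb = valid & (nf[d] >= 0) & (nf[d] <= sh[d] - 1)
                    nidx = tuple(x[inb] for x in nf)
                    n_active = np.zeros(n_act, bool)
                    n_active[inb] = active[nidx]
                    # off-diagonal to active neighbours
                    m = n_active
                    if m.any():
                        add(rown[m], num[tuple(x[m] for x in nf)], -T[m])
                    # fixed neighbours (inlet value or no-slip zero)
                    mf = inb & ~n_active
                    if mf.any():
                        vals_f = fixed[tuple(x[mf] for x in nf)]
                        rhs[rown[mf]] += T[mf] * vals_f
                    diag += np.where(valid, T, 0.0)
                else:
                    na = fi[a] + s  # tangential neighbour index along a
                    inb = (na >= 0) & (na <= sh[a] - 1)
                    b = [x for x in others if x != a][0] if d in (0, 1, 2) else None
                    third = [x for x in range(3) if x not in (d, a)][0]
                    A_t = dcv[d][fi[d]] * widths[third][fi[third]]
                    T = np.zeros(n_act)
                    # out-of-domain: symmetry (y) or outlet (x, s=+1) -> skip;
                    # wall (z) or inlet (x, s=-1) -> half-cell ghost at 0
                    oob = ~inb
                    if a == 2 or (a == 0 and s < 0):
                        m = oob
                        diag += np.where(
                            m, mu * A_t / (0.5 * widths[a][np.clip(fi[a], 0, None)]), 0.0
                        ) * m
                    # in-bounds neighbours
                    if inb.any():
                        # displaced adjacent cells decide wall vs open
                        ct = domain.cell_type
                        ct_pad = np.full(
                            tuple(n + 2 for n in shape), _OUT, dtype=np.int8
                        )
                        ct_pad[1:-1, 1:-1, 1:-1] = ct
                        cmi = [fi[x] + 1 - (1 if x == d else 0) for x in range(3)]
                        cpi = [fi[x] + 1 for x in range(3)]
                        cmi[a] = cmi[a] + s
                        cpi[a] = cpi[a] + s
                        t_dm = ct_pad[tuple(np.clip(ix, 0, None) for ix in cmi)]
                        t_dp = ct_pad[tuple(np.clip(ix, 0, None) for ix in cpi)]
                        wall = inb & (
                            np.isin(t_dm, solid_like) | np.isin(t_dp, solid_like)
                        )
                        openn = inb & ~wall
                        if wall.any():
                            Tw = mu * A_t[wall] / (0.5 * widths[a][fi[a][wall]])
                            np.add.at(diag, np.nonzero(wall)[0], Tw)
                        if openn.any():
                            dist = 0.5 * (
                                widths[a][fi[a][openn]] + widths[a][na[openn]]
                            )
                            To = mu * A_t[openn] / dist
                            nf = [fi[x].copy() for x in range(3)]
                            nf[a] = na
                            nn = num[tuple(x[openn] for x in nf)]
                            ok = nn >= 0
                            sel = np.nonzero(openn)[0]
                            add(rown[sel[ok]], nn[ok], -To[ok])
                            np.add.at(diag, sel, To)
                            # neighbours that are fixed-zero at full distance
                            # (shouldn't occur for open tangential faces)
        add(rown, rown, diag)

        # pressure gradient: + A p_cp - A p_cm
        cp_idx = [fi[x].copy() for x in range(3)]
        cm_idx = [fi[x].copy() for x in range(3)]
        cm_idx[d] = cm_idx[d] - 1
        in_cp = cp_idx[d] <= shape[d] - 1
        in_cm = cm_idx[d] >= 0
        if in_cp.any():
            pc = p_num[tuple(x[in_cp] for x in cp_idx)]
            ok = pc >= 0
            sel = np.nonzero(in_cp)[0][ok]
            add(rown[sel], n_u + pc[ok], A_f[sel])
        if in_cm.any():
            pc = p_num[tuple(x[in_cm] for x in cm_idx)]
            ok = pc >= 0
            sel = np.nonzero(in_cm)[0][ok]
            add(rown[sel], n_u + pc[ok], -A_f[sel])

    # continuity rows, negated so they are exactly the transpose of the
    # pressure-gradient block (symmetric saddle system for MINRES)
    cells = np.argwhere(fluid_mask)
    ci = [cells[:, a] for a in range(3)]
    prow = n_u + p_num[tuple(ci)]
    for d in range(3):
        c = comp[d]
        num, fixed, active = c["num"], c["fixed"], c["active"]
        others = [a for a in range(3) if a != d]
        A_f = widths[others[0]][ci[others[0]]] * widths[others[1]][ci[others[1]]]
        for s, sign in ((1, 1.0), (0, -1.0)):
            fidx = [ci[x].copy() for x in range(3)]
            fidx[d] = fidx[d] + s
            fnum = num[tuple(fidx)]
            ok = fnum >= 0
            add(prow[ok], fnum[ok], -sign * A_f[ok])
            isfix = ~active[tuple(fidx)]
            if isfix.any():
                fv = fixed[tuple(x[isfix] for x in fidx)]
                rhs[prow[isfix]] += sign * A_f[isfix] * fv

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    K = sp.csr_matrix((vals, (rows, cols)), shape=(n_tot, n_tot))
    sizes = [int(c["active"].sum()) for c in comp]
    return K, rhs, comp, p_num, sizes, n_u, n_p


def solve_flow(
    domain: ChipDomain,
    Q_inlet: float,
    fluid: FluidProps,
    scheme: str = "stokes",
    rtol: float = 1e-9,
    maxiter: int = 2000,
) -> FlowField:
    """Steady flow at full-channel volumetric rate ``Q_inlet`` (m^3/s).

    ``scheme`` is ``"stokes"`` (default; convective term dropped — the
    channel Reynolds number is at most O(1)) or ``"navier_stokes"``
    (Picard/Oseen iteration with first-order upwinding, solved
    directly; intended for modest grids).
    """
    if Q_inlet < 0:
        raise ValueError("Q_inlet must be non-negative")
    if Q_inlet == 0.0:
        zero = FlowField(
            domain=domain,
            u=np.zeros((domain.shape[0] + 1,) + domain.shape[1:]),
            v=np.zeros((domain.shape[0], domain.shape[1] + 1, domain.shape[2])),
            w=np.zeros(domain.shape[:2] + (domain.shape[2] + 1,)),
            p=np.where(domain.fluid_mask, 0.0, np.nan),
            Q_inlet=0.0,
            viscosity=fluid.viscosity,
            residual=0.0,
        )
        return zero

    K, rhs, comp, p_num, sizes, n_u, n_p = _assemble_stokes(domain, fluid, Q_inlet)
    x, res_hist = _solve_saddle(K, rhs, comp, sizes, n_u, n_p, domain, fluid, rtol, maxiter)

    if scheme == "navier_stokes":
        x, res = _picard_navier_stokes(domain, fluid, Q_inlet, K, rhs, comp, n_u, x)
    elif scheme == "stokes":
        res = float(np.linalg.norm(K @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    field_arrays = []
    for c in comp:
        arr = c["fixed"].copy()
        arr[c["active"]] = x[c["num"][c["active"]]]
        field_arrays.append(arr)
    p = np.full(domain.shape, np.nan)
    p[domain.fluid_mask] = x[n_u:]
    flow = FlowField(
        domain=domain,
        u=field_arrays[0],
        v=field_arrays[1],
        w=field_arrays[2],
        p=p,
        Q_inlet=Q_inlet,
        viscosity=fluid.viscosity,
        residual=res,
        residual_history=res_hist,
    )
    if res > VELOCITY_RESIDUAL_TOL:
        raise FlowSolverError(
            f"flow residual {res:.2e} above {VELOCITY_RESIDUAL_TOL}", res_hist
        )
    logger.debug(
        "flow solved: residual=%.2e div_max=%.2e", res, flow.divergence_max()
    )
    return flow


def _solve_saddle(K, rhs, comp, sizes, n_u, n_p, domain, fluid, rtol, maxiter):
    """Pressure Schur-complement CG; sparse-direct fallback.

    The viscous block A is block-diagonal over the three velocity
    components (the vector Laplacian does not couple them) and each
    block is SPD, so it is factorized exactly and eliminated:
    S p = G^T A^{-1} b_u - g with S = G^T A^{-1} G SPD. CG on S with a
    (1/mu)-scaled pressure mass-matrix preconditioner converges nearly
    mesh-independently; each iteration costs three triangular solves.
    """
    n_tot = n_u + n_p
    if n_tot <= 8000:
        return spla.spsolve(K.tocsc(), rhs), []

    lus = []
    start = 0
    for nsz in sizes:
        blk = K[start : start + nsz, start : start + nsz].tocsc()
        lus.append(spla.splu(blk))
        start += nsz

    G = K[:n_u, n_u:].tocsr()
    GT = K[n_u:, :n_u].tocsr()
    b_u = rhs[:n_u]
    g = rhs[n_u:]

    def a_inv(r):
        z = np.empty_like(r)
        s = 0
        for lu, nsz in zip(lus, sizes):
            z[s : s + nsz] = lu.solve(r[s : s + nsz])
            s += nsz
        return z

    def s_mv(p):
        return GT @ a_inv(G @ p)

    S = spla.LinearOperator((n_p, n_p), matvec=s_mv)
    vol = domain.cell_volumes[domain.fluid_mask]
    m_inv = fluid.viscosity / vol  # approximate S^{-1}
    M = spla.LinearOperator((n_p, n_p), matvec=lambda r: m_inv * r)
    rhs_s = GT @ a_inv(b_u) - g

    hist = []

    def cb(xk):
        hist.append(float(np.linalg.norm(s_mv(xk) - rhs_s)))

    p, info = spla.cg(S, rhs_s, M=M, rtol=rtol, atol=0.0, maxiter=maxiter, callback=cb)
    if info != 0:
        logger.warning("Schur CG info=%d; falling back to direct solve", info)
        return spla.spsolve(K.tocsc(), rhs), hist
    u = a_inv(b_u - G @ p)
    return np.concatenate([u, p]), hist


def _picard_navier_stokes(domain, fluid, Q_inlet, K, rhs, comp, n_u, x0, n_iter=8):
    """Oseen (Picard) iterations adding first-order upwind convection.

    The convective matrix is rebuilt from the current velocity estimate
    and the nonsymmetric system solved directly. At chip Reynolds
    numbers the correction to Stokes is small; this path exists to
    verify exactly that.
    """
    rho = fluid.density
    widths = domain.widths
    x = x0.copy()
    n_tot = K.shape[0]
    for _ in range(n_iter):
        rows, cols, vals = [], [], []
        rhs_c = rhs.copy()
        for c in comp:
            d, sh, active, num, fixed = (
                c["d"], c["sh"], c["active"], c["num"], c["fixed"],
            )
            arr = fixed.copy()
            arr[active] = x[num[active]]
            af = np.argwhere(active)
            fi = [af[:, a] for a in range(3)]
            rown = num[tuple(fi)]
            others = [a for a in range(3) if a != d]
            A_f = widths[others[0]][fi[others[0]]] * widths[others[1]][fi[others[1]]]
            # streamwise self-advection rho*u*A*(du/dx) in upwind CV
            # form: diag + |flux|, upstream neighbour - |flux|.  Cross-
            # stream advection is neglected: at chip Reynolds numbers
            # the whole convective term is already a small correction.
            uf = arr[tuple(fi)]
            flux = rho * uf * A_f
            s_up = np.where(uf >= 0, -1, 1)  # upstream side along d
            nf = [ix.copy() for ix in fi]
            nf[d] = nf[d] + s_up
            inb = (nf[d] >= 0) & (nf[d] <= sh[d] - 1)
            rows.append(rown[inb])
            cols.append(rown[inb])
            vals.append(np.abs(flux[inb]))
            nidx = tuple(ix[inb] for ix in nf)
            n_active = active[nidx]
            nn = num[nidx]
            m = np.nonzero(inb)[0][n_active]
            rows.append(rown[m])
            cols.append(nn[n_active])
            vals.append(-np.abs(flux[m]))
            mfix = np.nonzero(inb)[0][~n_active]
            if mfix.size:
                vfix = fixed[tuple(ix[mfix] for ix in nf)]
                np.add.at(rhs_c, rown[mfix], np.abs(flux[mfix]) * vfix)
        C = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_tot, n_tot),
        )
        A = (K + C).tocsc()
        x_new = spla.spsolve(A, rhs_c)
        res = float(
            np.linalg.norm(A @ x_new - rhs_c) / max(np.linalg.norm(rhs_c), 1e-300)
        )
        if np.linalg.norm(x_new - x) <= 1e-8 * max(np.linalg.norm(x), 1e-300):
            return x_new, res
        x = x_new
    return x, res


def max_wall_shear(flow: FlowField, domain: ChipDomain) -> float:
    """Maximum shear stress on the tumor surface, in dyn/cm^2.

    For every fluid cell face-adjacent to a tumor voxel, the tangential
    velocity (cell-centre velocity minus its component along the radius
    from the tumor centre) is sampled at that cell and at one further
    cell outward along the same radial ray, and the surface gradient is
    obtained by a quadratic-through-zero fit — a two-point
    extrapolation that cancels the leading curvature error of a plain
    first difference and regularizes the stair-step voxelization.
    1 Pa = 10 dyn/cm^2.
    """
    return pa_to_dyn_cm2(_max_wall_shear_pa(flow, domain))


def _max_wall_shear_pa(flow: FlowField, domain: ChipDomain) -> float:
    mu = flow.viscosity
    tumor = domain.tumor_mask
    if not tumor.any() or flow.Q_inlet == 0.0:
        return 0.0
    fluid_mask = domain.fluid_mask
    adj = np.zeros_like(tumor)
    for a, sgn in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
        shifted = np.roll(tumor, sgn, axis=a)
        # roll wraps; zero the wrapped slice
        sl = [slice(None)] * 3
        sl[a] = 0 if sgn == 1 else -1
        shifted[tuple(sl)] = False
        adj |= shifted
    cand = adj & fluid_mask
    if not cand.any():
        return 0.0
    xc, yc, zc = domain.centers
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    c0 = np.array(domain.tumor_center)
    R = domain.tumor_radius
    vel = flow.cell_velocity()
    dx, dy, dz = domain.widths
    xe, ye, ze = domain.x_edges, domain.y_edges, domain.z_edges
    tau_max = 0.0
    for i, j, k in np.argwhere(cand):
        h = min(dx[i], dy[j], dz[k])
        pos = np.array([X[i, j, k], Y[i, j, k], Z[i, j, k]])
        rvec = pos - c0
        distc = np.linalg.norm(rvec)
        n = rvec / distc
        # first sample: never closer than the half cell separating the
        # centre from the discrete no-slip face (the sphere may
        # protrude into the cell, while the solver enforced u = 0 only
        # on the voxel face)
        d1 = max(distc - R, 0.5 * h)
        u1 = vel[i, j, k]
        u1t = u1 - u1.dot(n) * n
        # second sample: one local cell further out along the ray
        p2 = c0 + n * (R + d1 + h)
        i2 = int(np.clip(np.searchsorted(xe, p2[0]) - 1, 0, len(xc) - 1))
        j2 = int(np.clip(np.searchsorted(ye, abs(p2[1])) - 1, 0, len(yc) - 1))
        k2 = int(np.clip(np.searchsorted(ze, p2[2]) - 1, 0, len(zc) - 1))
        pos2 = np.array([xc[i2], yc[j2], zc[k2]])
        d2 = np.linalg.norm(pos2 - np.array([c0[0], 0.0, c0[2]])) - R
        if domain.cell_type[i2, j2, k2] == int(CellType.FLUID) and d2 > 1.2 * d1:
            u2 = vel[i2, j2, k2]
            u2t = u2 - u2.dot(n) * n
            # fit u_t(d) = g d + c d^2 through the two samples; g is
            # the surface velocity gradient
            g = (u1t * d2**2 - u2t * d1**2) / (d1 * d2 * (d2 - d1))
            tau = mu * np.linalg.norm(g)
        else:
            tau = mu * np.linalg.norm(u1t) / d1
        tau_max = max(tau_max, tau)
    return tau_max
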