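"""Static unlimited-medium simulator.

Solves the spherically symmetric quasi-steady nutrient problem

    (1/r^2) d/dr ( r^2 dC_i/dr ) = f(r) * Vmax_i C_i / (Km_i + C_i) / D_i

with symmetry at the centre and ``C_i = C_bulk_i`` at the tumor surface
(the medium is unlimited and static, so the surface concentration never
departs from the bulk value). The zone factor ``f`` is 1 in the
proliferative shell, 1/2 in the quiescent shell and 0 in the necrotic
core; since the zones are themselves defined by the concentrations, the
solver iterates solve/classify to a fixed point of the free boundaries.

Growth is advanced with a forward-Euler update of the volume ODE on a
20 h cycle: diffusion equilibrates in minutes while the spheroid doubles
in roughly a day, so the concentration field is re-solved to steady
state at each growth step (quasi-steady coupling).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded

from .model_core import (
    InvariantViolationError,
    KineticParams,
    NutrientSpec,
    TumorState,
    ZoneLabel,
    _ordered_specs,
    classify_point,
    growth_rate,
    radius_from_volume,
    volume_from_radius,
)
from .units import m_to_um, pa_to_dyn_cm2

logger = logging.getLogger(__name__)

__all__ = [
    "RadialProfile",
    "GrowthTrajectory",
    "ConvergenceError",
    "SolverFailureError",
    "solve_steady_profile",
    "detect_boundaries",
    "step",
    "simulate_static",
    "doubling_time",
    "DEFAULT_DT_H",
    "MIN_RADIUS_M",
]

DEFAULT_DT_H = 20.0  # growth-update cycle, h
MIN_RADIUS_M = 8.1e-6  # volume floor: one-cell radius
BOUNDARY_RTOL = 1e-6  # free-boundary fixed-point tolerance, relative to R
RESIDUAL_TOL = 1e-3  # discrete BVP residual criterion
MAX_OUTER_ITER = 100
DAMPING = 0.5  # relaxation on boundary moves between classify sweeps


class ConvergenceError(RuntimeError):
    """Free-boundary fixed point failed to converge; carries last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SolverFailureError(RuntimeError):
    """A converged solution violated a physical bound."""


@dataclass
class RadialProfile:
    """Converged radial concentration profiles and detected zone boundaries.

    ``r`` runs from 0 (centre) to ``R`` (surface); concentrations are in
    mol/m^3 and increase monotonically outward; ``labels`` holds the
    nodewise :class:`ZoneLabel`.
    """

    r: np.ndarray
    c_glucose: np.ndarray
    c_oxygen: np.ndarray
    labels: np.ndarray
    Rq: float
    Rn: float

    @property
    def R(self) -> float:
        return float(self.r[-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "r_um": self.r * 1e6,
                "c_glucose_mM": self.c_glucose,
                "c_oxygen_mM": self.c_oxygen,
                "label": [ZoneLabel(v).name.lower() for v in self.labels],
            }
        )


@dataclass
class GrowthTrajectory:
    """Ordered growth records, one per growth step plus the initial state."""

    records: list = field(default_factory=list)
    extinct: bool = False

    def append(
        self, state: TumorState, max_shear: float | None = None
    ) -> None:
        rec = {
            "t": state.t,
            "R": state.R,
            "V": state.V,
            "Vq": state.Vq,
            "Vn": state.Vn,
            "phase": state.phase,
        }
        if max_shear is not None:
            rec["max_shear"] = max_shear  # Pa
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def final(self) -> dict:
        return self.records[-1]

    def column(self, key: str) -> np.ndarray:
        return np.array([rec[key] for rec in self.records])

    def phase_transition_times(self) -> dict[int, float]:
        """Time stamp of the first record in phase 2 and phase 3."""
        out: dict[int, float] = {}
        for rec in self.records:
            if rec["phase"] not in out and rec["phase"] > 1:
                out[rec["phase"]] = rec["t"]
        return out

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "t_h": self.column("t"),
                "R_um": m_to_um(self.column("R")),
                "V_um3": self.column("V") * 1e18,
                "Vq_um3": self.column("Vq") * 1e18,
                "Vn_um3": self.column("Vn") * 1e18,
                "phase": self.column("phase").astype(int),
            }
        )
        if self.records and "max_shear" in self.records[0]:
            df["max_shear_dyn_cm2"] = pa_to_dyn_cm2(self.column("max_shear"))
        return df


# ---------------------------------------------------------------------------
# steady free-boundary solver


def _make_grid(R: float, n_nodes: int, focus: tuple[float, ...] = ()) -> np.ndarray:
    """Radial node set: uniform base plus geometric clusters near ``focus``.

    Refinement inserts nodes at geometrically shrinking offsets around
    each focus radius (the detected zone boundaries), which sharpens the
    inverse interpolation of the crossings without a global fine grid.
    """
    r = np.linspace(0.0, R, n_nodes)
    if focus:
        h = R / (n_nodes - 1)
        extra = []
        for rf in focus:
            if rf <= 0 or rf >= R:
                continue
            for k in range(1, 5):
                off = h * 0.5**k
                extra.extend((rf - off, rf, rf + off))
        if extra:
            r = np.unique(np.concatenate([r, np.clip(extra, 0.0, R)]))
    return r


def _zone_factor(r: np.ndarray, Rq: float, Rn: float) -> np.ndarray:
    """Consumption factor per control volume, partial-volume weighted.

    Each node's control volume is split by the zone boundaries and the
    factor is the r^2-measure-weighted mix of 0 (necrotic), 1/2
    (quiescent) and 1 (proliferative). The weighting makes the
    solve->reclassify map continuous in (Rq, Rn); a nodewise step
    factor jumps whenever a boundary crosses a node and can leave the
    free-boundary fixed point without a discrete solution.
    """
    rf = 0.5 * (r[:-1] + r[1:])
    a = np.concatenate([[0.0], rf])
    b = np.concatenate([rf, [r[-1]]])
    m = b**3 - a**3
    nec = np.clip(b, 0.0, Rn) ** 3 - np.clip(a, 0.0, Rn) ** 3
    inner_q = np.clip(b, 0.0, Rq) ** 3 - np.clip(a, 0.0, Rq) ** 3
    qui = inner_q - nec
    pro = m - inner_q
    return (0.5 * qui + pro) / m


def _solve_single_nutrient(
    r: np.ndarray, spec: NutrientSpec, f: np.ndarray, c0: np.ndarray | None = None
) -> np.ndarray:
    """Solve the nonlinear BVP for one nutrient on a fixed zone factor.

    Finite-volume tridiagonal system; the Michaelis–Menten sink is
    linearized as ``Vmax c_new / (Km + c_old)`` (positivity-preserving
    M-matrix) and Picard-iterated to convergence.
    """
    n = len(r)
    rf = 0.5 * (r[:-1] + r[1:])  # faces
    # transmissibilities  D * rf^2 / dr  between neighbouring nodes
    trans = spec.D_tissue * rf**2 / np.diff(r)
    # control-volume weights  int r^2 dr  over each node's cell
    edges = np.concatenate([[0.0], rf, [r[-1]]])
    w = np.diff(edges**3) / 3.0

    c = np.full(n, spec.C_bulk) if c0 is None else c0.copy()
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    for _ in range(200):
        k = f * spec.Vmax / (spec.Km + c)  # lagged linearization
        ab[:] = 0.0
        rhs[:] = 0.0
        # interior nodes 0..n-2 (node 0 has only an outer face)
        ab[1, 0] = -trans[0] - k[0] * w[0]
        ab[0, 1] = trans[0]
        # vectorized assembly for nodes 1..n-2
        i = np.arange(1, n - 1)
        ab[1, i] = -(trans[i - 1] + trans[i]) - k[i] * w[i]
        ab[0, i + 1] = trans[i]  # super-diagonal entry for column i+1, row i
        ab[2, i - 1] = trans[i - 1]  # sub-diagonal entry for column i-1, row i
        # Dirichlet surface node
        ab[1, n - 1] = 1.0
        ab[2, n - 2] = 0.0
        rhs[n - 1] = spec.C_bulk
        c_new = solve_banded((1, 1), ab, rhs)
        if np.max(np.abs(c_new - c)) < 1e-12 * spec.C_bulk + 1e-30:
            c = c_new
            break
        c = c_new
    if np.any(c < -1e-12 * spec.C_bulk):
        raise SolverFailureError("negative concentration in converged profile")
    np.clip(c, 0.0, None, out=c)
    return c


def _residual(r: np.ndarray, c: np.ndarray, spec: NutrientSpec, f: np.ndarray) -> float:
    """Relative inf-norm residual of the nonlinear discrete BVP."""
    rf = 0.5 * (r[:-1] + r[1:])
    trans = spec.D_tissue * rf**2 / np.diff(r)
    edges = np.concatenate([[0.0], rf, [r[-1]]])
    w = np.diff(edges**3) / 3.0
    sink = f * spec.Vmax * c / (spec.Km + c) * w
    flux = trans * np.diff(c)  # outward diffusive flux at faces
    res = np.empty_like(c)
    res[0] = flux[0] - sink[0]
    res[1:-1] = flux[1:] - flux[:-1] - sink[1:-1]
    res[-1] = 0.0  # Dirichlet
    # include the natural flux magnitude D*C_bulk*R in the scale so a
    # consumption-free (flat) solution does not divide noise by noise
    scale = max(
        np.max(np.abs(flux)),
        np.max(np.abs(sink)),
        spec.D_tissue * spec.C_bulk * r[-1],
    )
    return float(np.max(np.abs(res)) / scale)


def _crossing_radius(r: np.ndarray, c: np.ndarray, c_crit: float) -> float:
    """Outermost radius where ``c`` crosses ``c_crit`` (0 if never below).

    Profiles are monotone, so the deficient region is the ball
    ``r < r*``; the crossing is located by inverse linear interpolation.
    """
    if c_crit <= 0 or c[0] >= c_crit:
        return 0.0
    below = c < c_crit
    idx = np.nonzero(~below)[0]
    if len(idx) == 0:  # entirely below critical (cannot happen with C_bulk>crit)
        return float(r[-1])
    j = idx[0]  # first node at/above critical
    if j == 0:
        return 0.0
    r0, r1 = r[j - 1], r[j]
    c0, c1 = c[j - 1], c[j]
    return float(r0 + (c_crit - c0) / (c1 - c0) * (r1 - r0))


def _run_bracketed(r, spec_g, spec_o, R, Rq, Rn):
    """Robust fallback for the free-boundary fixed point.

    The quiescent boundary is pinned by Brent root-finding on
    (outermost-crossing - Rq): the map is monotone decreasing in Rq, so
    the root is unique. The necrotic boundary needs a different
    formulation: inside the core neither nutrient is consumed, so the
    binding nutrient's profile is *flat* there and its crossing radius
    is infinitely sensitive — the well-posed condition is that the core
    plateau sits exactly at the critical concentration. Rn is therefore
    the root of (centre concentration - C_crit) of the binding (less
    deficient) nutrient, which is monotone increasing in Rn. The two
    one-dimensional solves are alternated until neither boundary moves.
    """
    from scipy.optimize import brentq

    last = {"cg": None, "co": None}

    def solve_fields(Rq_, Rn_):
        f = _zone_factor(r, Rq_, Rn_)
        cg = _solve_single_nutrient(r, spec_g, f, c0=last["cg"])
        co = _solve_single_nutrient(r, spec_o, f, c0=last["co"])
        last["cg"], last["co"] = cg, co
        return cg, co

    def crossings(cg, co):
        return (
            _crossing_radius(r, cg, spec_g.C_crit),
            _crossing_radius(r, co, spec_o.C_crit),
        )

    xtol = max(1e-12 * R, 5e-17)
    n_evals = 0
    for outer in range(30):
        def hq(b):
            return max(crossings(*solve_fields(b, min(Rn, b)))) - b

        Rq_new = 0.0 if hq(0.0) <= 0.0 else brentq(hq, 0.0, R, xtol=xtol)
        # candidate core: probe with no core at the new quiescent boundary
        rg, ro = crossings(*solve_fields(Rq_new, 0.0))
        if min(rg, ro) <= 0.0:
            Rn_new = 0.0
        else:
            bind_g = rg <= ro  # nutrient whose deficiency bounds the core

            def plateau(b):
                cg_, co_ = solve_fields(Rq_new, b)
                c = cg_ if bind_g else co_
                crit = spec_g.C_crit if bind_g else spec_o.C_crit
                return c[0] - crit

            if plateau(Rq_new) <= 0.0:  # degenerate: core fills the boundary
                Rn_new = Rq_new
            else:
                Rn_new = brentq(plateau, 0.0, Rq_new, xtol=xtol)
        moved = max(abs(Rq_new - Rq), abs(Rn_new - Rn))
        Rq, Rn = Rq_new, Rn_new
        n_evals = outer + 1
        if moved < BOUNDARY_RTOL * R and outer > 0:
            cg, co = solve_fields(Rq, Rn)
            return cg, co, Rq, Rn, MAX_OUTER_ITER + n_evals
    cg, co = solve_fields(Rq, Rn)
    raise ConvergenceError(
        f"free-boundary iteration did not converge (R={m_to_um(R):.2f} um)",
        last_iterate=(r, cg, co, Rq, Rn),
    )


def solve_steady_profile(
    R: float,
    specs: tuple[NutrientSpec, NutrientSpec],
    n_nodes: int = 256,
    refine: bool = True,
) -> RadialProfile:
    """Fixed point of {steady BVP solve; zone reclassification}.

    Iterates the two-nutrient solve with the current zone boundaries,
    re-detects the boundaries from the new profiles, and relaxes the
    boundary move by 0.5 to avoid limit cycles. Terminates when both
    boundaries move by less than ``1e-6 R`` between sweeps. When
    ``refine`` is set, the converged boundaries seed a locally refined
    grid and the fixed point is re-run once on it.
    """
    if R <= 0:
        raise InvariantViolationError("tumor radius must be positive")
    spec_g, spec_o = _ordered_specs(specs)

    def run(r: np.ndarray, Rq0: float, Rn0: float):
        # Relaxed fixed-point iteration on (Rq, Rn). Near the onset of a
        # zone the map oscillates (a tiny half-consumption core removes
        # the deficiency that created it), so the relaxation factor is
        # halved whenever a boundary's move changes sign.
        Rq, Rn = Rq0, Rn0
        theta_q = theta_n = DAMPING
        prev_dq = prev_dn = 0.0
        cg = co = None
        for it in range(MAX_OUTER_ITER):
            f = _zone_factor(r, Rq, Rn)
            cg = _solve_single_nutrient(r, spec_g, f, c0=cg)
            co = _solve_single_nutrient(r, spec_o, f, c0=co)
            rg = _crossing_radius(r, cg, spec_g.C_crit)
            ro = _crossing_radius(r, co, spec_o.C_crit)
            Rq_new, Rn_new = max(rg, ro), min(rg, ro)
            if Rn_new > 0.0:
                # a necrotic core flattens the binding nutrient's profile;
                # the crossing formulation is ill-posed there
                return _run_bracketed(r, spec_g, spec_o, R, Rq_new, Rn_new)
            dq, dn = Rq_new - Rq, Rn_new - Rn
            if abs(dq) < BOUNDARY_RTOL * R and abs(dn) < BOUNDARY_RTOL * R:
                return cg, co, Rq_new, Rn_new, it + 1
            theta_q = (
                max(0.5 * theta_q, 1e-3) if dq * prev_dq < 0
                else min(1.5 * theta_q, DAMPING)
            )
            theta_n = (
                max(0.5 * theta_n, 1e-3) if dn * prev_dn < 0
                else min(1.5 * theta_n, DAMPING)
            )
            prev_dq, prev_dn = dq, dn
            Rq += theta_q * dq
            Rn += theta_n * dn
        return _run_bracketed(r, spec_g, spec_o, R, Rq, Rn)

    r = _make_grid(R, n_nodes)
    cg, co, Rq, Rn, n_it = run(r, 0.0, 0.0)
    if refine and (Rq > 0 or Rn > 0):
        r = _make_grid(R, n_nodes, focus=(Rq, Rn))
        cg, co, Rq, Rn, n_it2 = run(r, Rq, Rn)
        n_it += n_it2

    f = _zone_factor(r, Rq, Rn)
    for spec, c in ((spec_g, cg), (spec_o, co)):
        res = _residual(r, c, spec, f)
        if res > RESIDUAL_TOL:
            raise SolverFailureError(
                f"{spec.name.value} residual {res:.2e} exceeds {RESIDUAL_TOL}"
            )
    labels = np.array(
        [int(classify_point(g, o, (spec_g, spec_o))) for g, o in zip(cg, co)]
    )
    logger.debug(
        "steady profile R=%.2f um converged in %d sweeps: Rq=%.2f um Rn=%.2f um",
        m_to_um(R), n_it, m_to_um(Rq), m_to_um(Rn),
    )
    return RadialProfile(r=r, c_glucose=cg, c_oxygen=co, labels=labels, Rq=Rq, Rn=Rn)


def detect_boundaries(
    profile: RadialProfile, specs: tuple[NutrientSpec, NutrientSpec]
) -> tuple[float, float]:
    """(Rq, Rn) from a radial profile by inverse interpolation.

    ``Rn`` is the outermost radius with both nutrients below critical,
    ``Rq`` the outermost radius with at least one below critical.
    """
    spec_g, spec_o = _ordered_specs(specs)
    for c in (profile.c_glucose, profile.c_oxygen):
        if np.any(np.diff(c) < -1e-9 * max(c.max(), 1e-300)):
            raise InvariantViolationError("radial profile is not monotone")
    rg = _crossing_radius(profile.r, profile.c_glucose, spec_g.C_crit)
    ro = _crossing_radius(profile.r, profile.c_oxygen, spec_o.C_crit)
    return max(rg, ro), min(rg, ro)


# ---------------------------------------------------------------------------
# growth stepping


def step(
    state: TumorState,
    dt: float,
    specs: tuple[NutrientSpec, NutrientSpec],
    params: KineticParams,
    n_nodes: int = 256,
    min_radius: float = MIN_RADIUS_M,
) -> TumorState:
    """One forward-Euler growth update of length ``dt`` hours.

    Solves the steady profile at the current radius, evaluates the
    growth law on the resulting zone volumes, and advances the volume.
    If the volume would fall below the one-cell floor it is clamped
    there. The returned state's zone radii are carried over (clamped to
    the new surface); they are refreshed by the next solve.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    profile = solve_steady_profile(state.R, specs, n_nodes=n_nodes)
    cur = replace(state, Rq=profile.Rq, Rn=profile.Rn)
    rate = growth_rate(cur, params)
    V_new = cur.V + dt * rate
    V_floor = volume_from_radius(min_radius)
    if V_new < V_floor:
        V_new = V_floor
    R_new = radius_from_volume(V_new)
    return TumorState(
        t=state.t + dt,
        R=R_new,
        Rq=min(cur.Rq, R_new),
        Rn=min(cur.Rn, R_new),
    )


def simulate_static(
    initial_radius: float,
    horizon: float,
    specs: tuple[NutrientSpec, NutrientSpec],
    params: KineticParams,
    dt: float = DEFAULT_DT_H,
    n_nodes: int = 256,
    min_radius: float = MIN_RADIUS_M,
) -> GrowthTrajectory:
    """Grow a spheroid in static unlimited medium; deterministic.

    Emits one record per growth step plus the initial state; each
    record's zone radii come from the steady solve at that instant.
    """
    if horizon < dt:
        raise ValueError("horizon must be at least one growth step")
    for s in specs:
        s.validate_runnable()
    traj = GrowthTrajectory()
    state = TumorState(t=0.0, R=initial_radius)
    V_floor = volume_from_radius(min_radius)
    n_steps = int(round(horizon / dt))
    last_phase = 1
    for _ in range(n_steps):
        profile = solve_steady_profile(state.R, specs, n_nodes=n_nodes)
        cur = replace(state, Rq=profile.Rq, Rn=profile.Rn)
        if cur.phase > last_phase:
            logger.info("phase %d begins at t=%.1f h", cur.phase, cur.t)
            last_phase = cur.phase
        traj.append(cur)
        rate = growth_rate(cur, params)
        V_new = cur.V + dt * rate
        if V_new < V_floor:
            V_new = V_floor
            traj.extinct = True
        state = TumorState(t=cur.t + dt, R=radius_from_volume(V_new))
    profile = solve_steady_profile(state.R, specs, n_nodes=n_nodes)
    traj.append(replace(state, Rq=profile.Rq, Rn=profile.Rn))
    return traj


def doubling_time(traj: GrowthTrajectory) -> float:
    """Time (h) for the volume to first reach twice its initial value.

    Log-linear interpolation between the bracketing records; raises if
    the trajectory never doubles.
    """
    t = traj.column("t")
    V = traj.column("V")
    target = 2.0 * V[0]
    idx = np.nonzero(V >= target)[0]
    if len(idx) == 0:
        raise ValueError("trajectory never doubles in volume")
    j = idx[0]
    if j == 0:
        return 0.0
    lv0, lv1 = math.log(V[j - 1]), math.log(V[j])
    frac = (math.log(target) - lv0) / (lv1 - lv0)
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))
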