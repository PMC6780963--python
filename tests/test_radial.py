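"""Radial free-boundary solver and static-medium growth."""

import math
from dataclasses import replace

import numpy as np
import pytest

from avatum.model_core import (
    EMT6RO_GLUCOSE,
    EMT6RO_OXYGEN,
    InvariantViolationError,
    Nutrient,
    NutrientSpec,
    TumorState,
    growth_rate,
    volume_from_radius,
)
from avatum.radial_sim import (
    RadialProfile,
    detect_boundaries,
    doubling_time,
    simulate_static,
    solve_steady_profile,
    step,
)

from .oracles import radial_oracle


def make_spec(name=Nutrient.GLUCOSE, **kw):
    base = dict(
        D_tissue=1e-9, D_medium=1e-9, Vmax=1e-3, Km=1e-2, C_crit=0.0, C_bulk=1.0
    )
    base.update(kw)
    return NutrientSpec(name=name, **base)


class TestSteadyProfile:
    def test_no_consumption_gives_flat_profile(self, specs):
        sp = (
            replace(specs[0], Vmax=0.0),
            replace(specs[1], Vmax=0.0),
        )
        prof = solve_steady_profile(100e-6, sp)
        assert prof.Rq == 0.0 and prof.Rn == 0.0
        np.testing.assert_allclose(prof.c_glucose, sp[0].C_bulk, rtol=1e-12)
        np.testing.assert_allclose(prof.c_oxygen, sp[1].C_bulk, rtol=1e-12)

    def test_saturated_limit_matches_parabolic_closed_form(self):
        """With C >> Km the sink is a constant q0 and the exact solution
        is C_bulk - q0 (R^2 - r^2) / 6 D."""
        R, D, q0, c_bulk = 100e-6, 1e-9, 0.3, 1.0
        tested = make_spec(D_tissue=D, Vmax=q0, Km=1e-6, C_bulk=c_bulk)
        passive = make_spec(name=Nutrient.OXYGEN, Vmax=0.0)
        prof = solve_steady_profile(R, (tested, passive))
        c_center_exact = c_bulk - q0 * R**2 / (6 * D)
        assert c_center_exact >= 10 * tested.Km  # saturation premise holds
        assert prof.c_glucose[0] == pytest.approx(c_center_exact, rel=0.01)
        exact = c_bulk - q0 * (R**2 - prof.r**2) / (6 * D)
        np.testing.assert_allclose(prof.c_glucose, exact, rtol=0.01)

    @pytest.mark.parametrize("R_um", [25.0, 50.0, 100.0, 200.0])
    def test_matches_independent_bvp_oracle(self, R_um, specs):
        """Converged profiles agree with a collocation-BVP oracle built
        on a different discretization, within 0.5% sup-norm."""
        R = R_um * 1e-6
        prof = solve_steady_profile(R, specs)
        rr, cg, co, Rq_o, Rn_o = radial_oracle(R, specs)
        cg_i = np.interp(rr, prof.r, prof.c_glucose)
        co_i = np.interp(rr, prof.r, prof.c_oxygen)
        assert np.max(np.abs(cg_i - cg)) / specs[0].C_bulk < 5e-3
        assert np.max(np.abs(co_i - co)) / specs[1].C_bulk < 5e-3
        assert abs(prof.Rq - Rq_o) <= max(5e-3 * R, 1e-9)

    def test_profiles_monotone_and_bounded(self, specs):
        for R_um in (50.0, 150.0, 300.0):
            prof = solve_steady_profile(R_um * 1e-6, specs)
            for c, spec in ((prof.c_glucose, specs[0]), (prof.c_oxygen, specs[1])):
                assert np.all(np.diff(c) >= -1e-12 * spec.C_bulk)
                assert c[-1] == pytest.approx(spec.C_bulk)
                assert np.all(c >= 0.0) and np.all(c <= spec.C_bulk * (1 + 1e-12))

    def test_zone_monotone_in_bulk_concentration(self, specs):
        """Raising either bulk concentration never enlarges the
        quiescent or necrotic boundary."""
        R = 150e-6
        glc_grid = [0.6, 0.8, 1.0]
        o2_grid = [0.22, 0.28, 0.34]
        rq = np.empty((3, 3))
        rn = np.empty((3, 3))
        for i, g in enumerate(glc_grid):
            for j, o in enumerate(o2_grid):
                sp = (replace(specs[0], C_bulk=g), replace(specs[1], C_bulk=o))
                prof = solve_steady_profile(R, sp)
                rq[i, j], rn[i, j] = prof.Rq, prof.Rn
        tol = 1e-9
        assert np.all(np.diff(rq, axis=0) <= tol)  # more glucose
        assert np.all(np.diff(rq, axis=1) <= tol)  # more oxygen
        assert np.all(np.diff(rn, axis=0) <= tol)
        assert np.all(np.diff(rn, axis=1) <= tol)

    def test_grid_convergence_of_boundaries(self, specs):
        R = 200e-6
        a = solve_steady_profile(R, specs, n_nodes=256)
        b = solve_steady_profile(R, specs, n_nodes=512)
        assert abs(a.Rq - b.Rq) / R < 5e-3
        assert abs(a.Rn - b.Rn) / R < 5e-3

    def test_steady_state_conservation(self, specs):
        """Diffusive influx through the surface balances the volume
        integral of consumption within 0.1% (discrete flux form)."""
        R = 150e-6
        prof = solve_steady_profile(R, specs)
        for c, spec in ((prof.c_glucose, specs[0]), (prof.c_oxygen, specs[1])):
            r = prof.r
            influx = (
                spec.D_tissue
                * r[-1] ** 2
                * (c[-1] - c[-2])
                / (r[-1] - r[-2])
                * 4
                * math.pi
            )
            from avatum.radial_sim import _zone_factor

            f = _zone_factor(r, prof.Rq, prof.Rn)
            rf = 0.5 * (r[:-1] + r[1:])
            edges = np.concatenate([[0.0], rf, [r[-1]]])
            w = np.diff(edges**3) / 3.0
            consumed = 4 * math.pi * np.sum(f * spec.Vmax * c / (spec.Km + c) * w)
            assert influx == pytest.approx(consumed, rel=1e-3)


class TestDetectBoundaries:
    def test_all_above_critical(self, specs):
        r = np.linspace(0, 1e-4, 50)
        prof = RadialProfile(
            r=r,
            c_glucose=np.full_like(r, 0.8),
            c_oxygen=np.full_like(r, 0.28),
            labels=np.zeros_like(r, dtype=int),
            Rq=0.0,
            Rn=0.0,
        )
        assert detect_boundaries(prof, specs) == (0.0, 0.0)

    def test_single_crossing(self, specs):
        """Glucose crosses its 0.06 mM critical level at 50 um while
        oxygen stays above critical: (Rq, Rn) = (50 um, 0)."""
        r = np.linspace(0, 100e-6, 101)
        cg = 0.06 + (r - 50e-6) * 2000.0  # linear, crosses at 50 um
        cg = np.clip(cg, 0.0, None)
        prof = RadialProfile(
            r=r,
            c_glucose=cg,
            c_oxygen=np.full_like(r, 0.28),
            labels=np.zeros_like(r, dtype=int),
            Rq=0.0,
            Rn=0.0,
        )
        rq, rn = detect_boundaries(prof, specs)
        assert rq == pytest.approx(50e-6, rel=1e-6)
        assert rn == 0.0

    def test_synthetic_crossings_round_trip(self, specs):
        """Piecewise-linear profiles built from chosen crossing radii
        return exactly those radii (inverse interpolation is exact on
        linear data)."""
        r = np.linspace(0, 120e-6, 241)
        rq_true, rn_true = 70e-6, 30e-6
        cg = specs[0].C_crit * (r / rq_true)
        co = specs[1].C_crit * (r / rn_true)
        prof = RadialProfile(
            r=r, c_glucose=cg, c_oxygen=co,
            labels=np.zeros_like(r, dtype=int), Rq=0.0, Rn=0.0,
        )
        rq, rn = detect_boundaries(prof, specs)
        assert rq == pytest.approx(rq_true, rel=1e-9)
        assert rn == pytest.approx(rn_true, rel=1e-9)

    def test_non_monotone_rejected(self, specs):
        r = np.linspace(0, 1e-4, 20)
        c = np.linspace(0.8, 0.2, 20)  # decreasing outward: invalid
        prof = RadialProfile(
            r=r, c_glucose=c, c_oxygen=np.full_like(r, 0.28),
            labels=np.zeros_like(r, dtype=int), Rq=0.0, Rn=0.0,
        )
        with pytest.raises(InvariantViolationError):
            detect_boundaries(prof, specs)


class TestStep:
    def test_phase1_euler_factor(self, abundant_specs, kinetics):
        """One 20 h Euler step in phase 1 multiplies the volume by
        1 + 20 (A - Ap) = 1.66."""
        s0 = TumorState(t=0.0, R=24.3e-6)
        s1 = step(s0, 20.0, abundant_specs, kinetics)
        factor = s1.V / s0.V
        expected = 1.0 + 20.0 * (kinetics.A - kinetics.Ap_per_h)
        assert factor == pytest.approx(expected, rel=1e-9)
        assert s1.t == 20.0

    def test_euler_consistency_as_dt_vanishes(self, abundant_specs, kinetics):
        s0 = TumorState(t=0.0, R=30e-6)
        rate = growth_rate(s0, kinetics)
        for dt in (1.0, 0.1, 0.01):
            s1 = step(s0, dt, abundant_specs, kinetics)
            assert (s1.V - s0.V) / dt == pytest.approx(rate, rel=1e-9)

    def test_richardson_halving(self, abundant_specs, kinetics):
        """Two 10 h steps beat one 20 h step against the exact
        exponential, with the global error scaling linearly in dt
        (explicit Euler)."""
        k = kinetics.A - kinetics.Ap_per_h
        s0 = TumorState(t=0.0, R=30e-6)
        exact = s0.V * math.exp(20.0 * k)
        one = step(s0, 20.0, abundant_specs, kinetics).V
        half = step(step(s0, 10.0, abundant_specs, kinetics), 10.0, abundant_specs, kinetics).V
        err_one = abs(one - exact)
        err_half = abs(half - exact)
        assert err_half < err_one
        assert err_one / err_half == pytest.approx(2.0, rel=0.25)


class TestSimulateStatic:
    def test_doubling_time_is_21h(self, abundant_specs, kinetics):
        traj = simulate_static(8.1e-6, 40.0, abundant_specs, kinetics, dt=0.25)
        assert doubling_time(traj) == pytest.approx(21.0, rel=0.01)

    def test_trajectory_structure(self, static_550h):
        traj = static_550h()
        t = traj.column("t")
        assert np.all(np.diff(t) == pytest.approx(20.0))
        phases = traj.column("phase")
        assert np.all(np.diff(phases) >= 0)  # phases never regress
        assert traj.records[0]["phase"] == 1

    def test_more_glucose_larger_final_volume(self, static_550h):
        v_low = static_550h(glc=0.6).final["V"]
        v_high = static_550h(glc=1.0).final["V"]
        assert v_high > v_low

    def test_glucose_more_determinative_than_oxygen(self, static_550h):
        """A 25% glucose increase moves the 550 h volume more than a
        25% oxygen increase (glucose is the limiting nutrient)."""
        base = static_550h(glc=0.8, o2=0.28).final["V"]
        dg = abs(static_550h(glc=1.0, o2=0.28).final["V"] - base)
        do = abs(static_550h(glc=0.8, o2=0.35).final["V"] - base)
        assert dg > do

    def test_final_volume_insensitive_to_initial_radius(self, specs, kinetics):
        """Spheroids started at 8.1-48.6 um converge to the same dormant
        volume (within 5%) once growth has effectively stopped; the
        medium is the radius-sweep condition (0.6 mM glucose, 0.24 mM
        oxygen), and the horizon is long enough to reach dormancy."""
        sp = (replace(specs[0], C_bulk=0.6), replace(specs[1], C_bulk=0.24))
        vols = []
        for r0 in (8.1, 24.3, 48.6):
            traj = simulate_static(r0 * 1e-6, 2400.0, sp, kinetics, n_nodes=128)
            rel_step = (traj.final["V"] - traj.records[-2]["V"]) / traj.final["V"]
            assert rel_step < 0.005  # near-dormant: growth per step < 0.5%
            vols.append(traj.final["V"])
        assert (max(vols) - min(vols)) / min(vols) < 0.05

    def test_deterministic(self, specs, kinetics):
        a = simulate_static(24.3e-6, 100.0, specs, kinetics)
        b = simulate_static(24.3e-6, 100.0, specs, kinetics)
        assert a.column("V").tolist() == b.column("V").tolist()
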