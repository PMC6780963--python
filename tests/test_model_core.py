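"""Zone classification, uptake kinetics, growth law and unit plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avatum.model_core import (
    EMT6RO_GLUCOSE,
    EMT6RO_KINETICS,
    EMT6RO_OXYGEN,
    InvalidInputError,
    InvariantViolationError,
    KineticParams,
    TumorState,
    ZoneLabel,
    classify_point,
    consumption_rate,
    growth_rate,
    radius_from_volume,
    volume_from_radius,
)
from avatum import units

SPECS = (EMT6RO_GLUCOSE, EMT6RO_OXYGEN)


class TestClassifyPoint:
    @pytest.mark.parametrize(
        "glc, o2, expected",
        [
            (0.8, 0.28, ZoneLabel.PROLIFERATIVE),  # the baseline medium
            (0.05, 0.28, ZoneLabel.QUIESCENT),  # glucose below 0.06
            (0.8, 0.01, ZoneLabel.QUIESCENT),  # oxygen below 0.02
            (0.05, 0.01, ZoneLabel.NECROTIC),  # both deficient
            (0.06, 0.02, ZoneLabel.PROLIFERATIVE),  # exact ties -> viable
            (0.06, 0.01, ZoneLabel.QUIESCENT),
        ],
    )
    def test_labels(self, glc, o2, expected):
        assert classify_point(glc, o2, SPECS) is expected

    def test_spec_order_irrelevant(self):
        assert classify_point(0.05, 0.28, (EMT6RO_OXYGEN, EMT6RO_GLUCOSE)) is (
            ZoneLabel.QUIESCENT
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_point(-0.1, 0.28, SPECS)


class TestConsumptionRate:
    def test_half_saturation_identity(self):
        spec = EMT6RO_GLUCOSE
        assert consumption_rate(spec.Km, spec, ZoneLabel.PROLIFERATIVE) == (
            pytest.approx(spec.Vmax / 2)
        )
        assert consumption_rate(spec.Km, spec, ZoneLabel.QUIESCENT) == (
            pytest.approx(spec.Vmax / 4)
        )
        assert consumption_rate(123.0, spec, ZoneLabel.NECROTIC) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(min_value=0.0, max_value=1e3))
    def test_bounded_by_vmax(self, c):
        r = consumption_rate(c, EMT6RO_OXYGEN, ZoneLabel.PROLIFERATIVE)
        assert 0.0 <= r <= EMT6RO_OXYGEN.Vmax


class TestGrowthRate:
    def test_phase1_reduces_to_net_exponential(self):
        V = 6.01e4 * 1e-18  # the 24.3 um sphere
        state = TumorState(t=0.0, R=radius_from_volume(V))
        rate = growth_rate(state, EMT6RO_KINETICS)
        # Ap ~ 4.4e-6/h is negligible next to A = 3.3e-2/h
        assert rate / V == pytest.approx(0.033, rel=2e-4)

    def test_fully_necrotic_shrinks_at_necrosis_rate(self):
        R = 50e-6
        state = TumorState(t=0.0, R=R, Rq=R, Rn=R)
        rate = growth_rate(state, EMT6RO_KINETICS)
        assert rate == pytest.approx(-EMT6RO_KINETICS.An_per_h * state.V)

    def test_phase2_dormancy_condition(self):
        """With no necrosis, dV/dt = 0 exactly when Vq/V = 1 - Ap/A.

        The closed form comes from solving A(V-Vq) = Ap V; it is
        cross-checked here by numeric root finding on the rate."""
        from scipy.optimize import brentq

        p = EMT6RO_KINETICS
        R = 100e-6
        V = volume_from_radius(R)
        frac = 1.0 - p.Ap_per_h / p.A

        def rate_of(fq):
            st_ = TumorState(t=0.0, R=R, Rq=radius_from_volume(fq * V))
            return growth_rate(st_, p)

        assert rate_of(frac) == pytest.approx(0.0, abs=1e-25)
        root = brentq(rate_of, 0.5, 1.0, xtol=1e-15)
        assert root == pytest.approx(frac, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        rq=st.floats(0.0, 1.0),
        rn=st.floats(0.0, 1.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_linear_in_volumes(self, rq, rn, scale):
        """Scaling all radii by s scales the rate by s^3 exactly."""
        R = 80e-6
        rn = min(rn, rq)
        s1 = TumorState(t=0.0, R=R, Rq=rq * R, Rn=rn * R)
        s2 = TumorState(
            t=0.0,
            R=scale ** (1 / 3) * R,
            Rq=scale ** (1 / 3) * rq * R,
            Rn=scale ** (1 / 3) * rn * R,
        )
        r1 = growth_rate(s1, EMT6RO_KINETICS)
        r2 = growth_rate(s2, EMT6RO_KINETICS)
        assert r2 == pytest.approx(scale * r1, rel=1e-9, abs=1e-30)

    def test_inconsistent_volumes_rejected(self):
        with pytest.raises(InvariantViolationError):
            TumorState(t=0.0, R=50e-6, Rq=20e-6, Rn=30e-6)


class TestSphereMaps:
    def test_round_trip(self):
        for R in (0.0, 8.1e-6, 24.3e-6, 1.0):
            assert radius_from_volume(volume_from_radius(R)) == (
                pytest.approx(R, rel=1e-12, abs=1e-30)
            )
        assert radius_from_volume(4 * math.pi / 3) == pytest.approx(1.0, rel=1e-12)

    def test_initial_sphere_volume(self):
        V = volume_from_radius(24.3e-6)
        assert V * 1e18 == pytest.approx(6.01e4, rel=2e-3)

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            radius_from_volume(-1.0)
        with pytest.raises(InvalidInputError):
            volume_from_radius(-1.0)


class TestKineticParams:
    def test_proliferation_constant_matches_doubling_time(self):
        # A is tabulated from a 21 h exponential doubling time
        assert math.log(2) / 21.0 == pytest.approx(EMT6RO_KINETICS.A, abs=5e-4)

    def test_unit_conversions(self):
        p = EMT6RO_KINETICS
        assert p.Ap_per_h == pytest.approx(p.Ap * 3600)
        assert p.An_per_h == pytest.approx(7.2e-3, rel=1e-9)

    def test_no_growth_warns(self):
        with pytest.warns(UserWarning):
            KineticParams(A=1e-9, Ap=1e-3, An=0.0)


class TestPhases:
    def test_phase_logic(self):
        assert TumorState(t=0, R=1e-5).phase == 1
        assert TumorState(t=0, R=1e-5, Rq=5e-6).phase == 2
        assert TumorState(t=0, R=1e-5, Rq=5e-6, Rn=1e-6).phase == 3

    def test_volumes_follow_radii(self):
        s = TumorState(t=0, R=2e-5, Rq=1e-5)
        assert s.V == pytest.approx(volume_from_radius(2e-5))
        assert s.Vq == pytest.approx(volume_from_radius(1e-5))
        assert s.Vn == 0.0


class TestUnits:
    @settings(derandomize=True, max_examples=30)
    @given(x=st.floats(1e-6, 1e6))
    def test_conversions_bijective(self, x):
        assert units.m_to_um(units.um_to_m(x)) == pytest.approx(x, rel=1e-12)
        assert units.m3_s_to_ul_min(units.ul_min_to_m3_s(x)) == (
            pytest.approx(x, rel=1e-12)
        )

    def test_parse_quantity(self):
        assert units.parse_quantity("0.8 mM") == pytest.approx(0.8)
        assert units.parse_quantity("24.3 um") == pytest.approx(24.3e-6)
        assert units.parse_quantity("5 uL/min") == pytest.approx(5e-9 / 60)
        assert units.parse_quantity(0.8, default_unit="mM") == pytest.approx(0.8)
        with pytest.raises(ValueError):
            units.parse_quantity("0.8 furlongs")

    def test_pa_to_dyn(self):
        assert units.pa_to_dyn_cm2(0.1) == pytest.approx(1.0)
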