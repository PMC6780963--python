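"""Shared fixtures.

Long static-medium trajectories are computed once per session and
shared between the ordering tests; everything is deterministic, so
caching cannot mask anything.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

from avatum.model_core import (
    EMT6RO_GLUCOSE,
    EMT6RO_KINETICS,
    EMT6RO_OXYGEN,
    WATER_37C,
)
from avatum.chip.geometry import ChannelSpec, TrapKind, TrapSpec


@pytest.fixture(scope="session")
def specs():
    return (EMT6RO_GLUCOSE, EMT6RO_OXYGEN)


@pytest.fixture(scope="session")
def kinetics():
    return EMT6RO_KINETICS


@pytest.fixture(scope="session")
def fluid():
    return WATER_37C


@pytest.fixture(scope="session")
def abundant_specs():
    """EMT6/Ro uptake but no critical thresholds: pure phase-1 growth."""
    return (
        replace(EMT6RO_GLUCOSE, C_crit=0.0),
        replace(EMT6RO_OXYGEN, C_crit=0.0),
    )


@pytest.fixture(scope="session")
def channel():
    return ChannelSpec(length=3000e-6, width=1200e-6, height=800e-6)


@pytest.fixture(scope="session")
def u_barrier():
    return TrapSpec(TrapKind.U_BARRIER, 700e-6, 700e-6, 250e-6, 50e-6)


@pytest.fixture(scope="session")
def microwell():
    return TrapSpec(TrapKind.MICROWELL, 700e-6, 700e-6, 250e-6, 50e-6)


@pytest.fixture(scope="session")
def static_550h(specs, kinetics):
    """Cache of 550 h static trajectories keyed by (glc, o2, R0_um)."""
    from avatum.radial_sim import simulate_static

    cache = {}

    def get(glc=0.8, o2=0.28, r0_um=24.3):
        key = (glc, o2, r0_um)
        if key not in cache:
            sp = (
                replace(specs[0], C_bulk=glc),
                replace(specs[1], C_bulk=o2),
            )
            cache[key] = simulate_static(r0_um * 1e-6, 550.0, sp, kinetics)
        return cache[key]

    return get
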