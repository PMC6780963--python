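"""Unit conventions and conversions.

Internal convention is SI — metres, seconds, Pa, mol/m^3 — with two
deliberate exceptions that follow common practice in spheroid-growth
work: simulation time stamps are kept in hours (growth happens over
hundreds of hours) and the proliferation constant ``A`` is kept in 1/h.
Concentrations use the happy identity 1 mM = 1 mol/m^3, so "0.8 mM
glucose" is stored as 0.8 with no numeric change.

Config files may attach units to numbers as strings ("0.8 mM",
"24.3 um"); :func:`parse_quantity` normalizes those to the internal
convention.
"""

from __future__ import annotations

import re

UM = 1e-6  # m per micrometre
HOUR = 3600.0  # s per hour
UL_PER_MIN = 1e-9 / 60.0  # m^3/s per uL/min
PA_TO_DYN_CM2 = 10.0  # 1 Pa = 10 dyn/cm^2

#: multiplicative factor taking the stated unit to the internal one
_UNIT_FACTORS: dict[str, float] = {
    # concentration  (internal: mol/m^3)
    "mM": 1.0,
    "mol/m3": 1.0,
    "mol/m^3": 1.0,
    # length (internal: m)
    "m": 1.0,
    "um": UM,
    "µm": UM,
    "mm": 1e-3,
    # time (internal: h for durations/timestamps)
    "h": 1.0,
    "s": 1.0 / HOUR,
    "min": 1.0 / 60.0,
    "day": 24.0,
    # rate constants (internal: value as stated; see KineticParams)
    "1/s": 1.0,
    "1/h": 1.0,
    # diffusivity (internal: m^2/s)
    "m2/s": 1.0,
    "m^2/s": 1.0,
    # volumetric consumption (internal: mol/m^3/s)
    "mol/m3/s": 1.0,
    "mol/m^3/s": 1.0,
    # flow rate (internal: m^3/s)
    "uL/min": UL_PER_MIN,
    "µL/min": UL_PER_MIN,
    "m3/s": 1.0,
    # fluid properties
    "kg/m3": 1.0,
    "kg/m^3": 1.0,
    "Pa.s": 1.0,
    "Pa*s": 1.0,
    "Pa·s": 1.0,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(\S.*?)?\s*$")


def um_to_m(x: float) -> float:
    return x * UM


def m_to_um(x: float) -> float:
    return x / UM


def ul_min_to_m3_s(q: float) -> float:
    return q * UL_PER_MIN


def m3_s_to_ul_min(q: float) -> float:
    return q / UL_PER_MIN


def per_s_to_per_h(k: float) -> float:
    return k * HOUR


def pa_to_dyn_cm2(tau: float) -> float:
    return tau * PA_TO_DYN_CM2


def parse_quantity(value: float | int | str, default_unit: str | None = None) -> float:
    """Normalize a config value to internal units.

    Bare numbers are taken to already carry ``default_unit`` (or the
    internal unit when ``default_unit`` is None). Strings must look like
    ``"<number> <unit>"`` with a recognized unit.
    """
    if isinstance(value, (int, float)):
        if default_unit is not None:
            return float(value) * _UNIT_FACTORS[default_unit]
        return float(value)
    m = _QUANTITY_RE.match(value)
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = m.group(1), m.group(2)
    if unit is None:
        raise ValueError(f"quantity {value!r} has no unit; write e.g. '0.8 mM'")
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(num) * _UNIT_FACTORS[unit]
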