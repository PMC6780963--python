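"""Core domain types, zone classification and the growth law.

The tumor spheroid is partitioned into three concentric zones by the
local concentrations of two diffusible nutrients, glucose and oxygen:

* **proliferative** — both nutrients above their critical value; cells
  divide at the maximal rate and consume nutrient at the full
  Michaelis–Menten rate ``Vmax*C/(Km+C)``;
* **quiescent** — exactly one nutrient below critical; cells survive
  without dividing and consume at half the proliferative rate;
* **necrotic** — both nutrients below critical; cells are dead and
  consume nothing.

Tumor volume evolves by

    dV/dt = A (V - Vq) - Ap (V - Vn) - An Vn

where ``V``, ``Vq``, ``Vn`` are the volumes enclosed by the tumor
surface, the quiescent boundary and the necrotic boundary respectively
(``Vq`` is cumulative: quiescent shell plus necrotic core, so the
proliferation term ``A (V - Vq)`` acts only on the proliferative shell
and apoptosis ``Ap (V - Vn)`` on all viable cells). ``A`` is the
proliferation constant (1/h), ``Ap`` apoptosis and ``An`` necrosis
constants (1/s, converted internally).

Default parameter values are the EMT6/Ro mouse mammary carcinoma
profile shipped in ``data/emt6ro.toml``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace

from .units import HOUR

__all__ = [
    "Nutrient",
    "ZoneLabel",
    "NutrientSpec",
    "KineticParams",
    "FluidProps",
    "TumorState",
    "InvalidInputError",
    "InvariantViolationError",
    "classify_point",
    "consumption_rate",
    "growth_rate",
    "radius_from_volume",
    "volume_from_radius",
    "EMT6RO_GLUCOSE",
    "EMT6RO_OXYGEN",
    "EMT6RO_KINETICS",
    "WATER_37C",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives a physically meaningless input."""


class InvariantViolationError(ValueError):
    """Raised when a domain object violates its structural invariants."""


class Nutrient(enum.Enum):
    GLUCOSE = "glucose"
    OXYGEN = "oxygen"


class ZoneLabel(enum.IntEnum):
    """Cell-state label; the integer order tracks degradation."""

    PROLIFERATIVE = 0
    QUIESCENT = 1
    NECROTIC = 2

    @property
    def consumption_factor(self) -> float:
        return _CONSUMPTION_FACTOR[self]


_CONSUMPTION_FACTOR = {
    ZoneLabel.PROLIFERATIVE: 1.0,
    ZoneLabel.QUIESCENT: 0.5,
    ZoneLabel.NECROTIC: 0.0,
}


@dataclass(frozen=True)
class NutrientSpec:
    """One diffusible species and its transport/uptake constants (SI).

    Attributes
    ----------
    name : Nutrient
    D_tissue : float
        Diffusivity in tumor tissue, m^2/s.
    D_medium : float
        Diffusivity in culture medium (water), m^2/s.
    Vmax : float
        Maximum volumetric consumption rate, mol/m^3/s.
    Km : float
        Michaelis constant, mol/m^3.
    C_crit : float
        Critical concentration below which cells degrade, mol/m^3.
    C_bulk : float
        Bulk medium / inlet concentration, mol/m^3 (1 mM = 1 mol/m^3).
    """

    name: Nutrient
    D_tissue: float
    D_medium: float
    Vmax: float
    Km: float
    C_crit: float
    C_bulk: float

    def __post_init__(self) -> None:
        for field in ("D_tissue", "D_medium", "Km", "C_bulk"):
            if getattr(self, field) <= 0:
                raise InvalidInputError(
                    f"{self.name.value}.{field} must be strictly positive"
                )
        # two idealizations are allowed: Vmax = 0 (non-consumed tracer)
        # and C_crit = 0 (abundant nutrient; strict deficiency never fires)
        if self.Vmax < 0:
            raise InvalidInputError(f"{self.name.value}.Vmax must be non-negative")
        if self.C_crit < 0:
            raise InvalidInputError(f"{self.name.value}.C_crit must be non-negative")

    def validate_runnable(self) -> None:
        """A scenario only makes sense if the medium is above critical."""
        if self.C_crit >= self.C_bulk:
            raise InvariantViolationError(
                f"{self.name.value}: C_crit ({self.C_crit}) must be below "
                f"C_bulk ({self.C_bulk}) for a runnable scenario"
            )

    def with_bulk(self, c_bulk: float) -> "NutrientSpec":
        return replace(self, C_bulk=c_bulk)


@dataclass(frozen=True)
class KineticParams:
    """Growth-law rate constants.

    ``A`` is stored in 1/h (as usually tabulated from a doubling time);
    ``Ap`` and ``An`` in 1/s. Conversions happen once, here.
    """

    A: float  # proliferation, 1/h
    Ap: float  # apoptosis, 1/s
    An: float  # necrosis, 1/s

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise InvalidInputError("proliferation constant A must be > 0")
        if self.Ap < 0 or self.An < 0:
            raise InvalidInputError("apoptosis/necrosis constants must be >= 0")
        if self.A <= self.Ap_per_h:
            warnings.warn(
                "net proliferation A - Ap is non-positive: no growth is possible",
                stacklevel=2,
            )

    @property
    def Ap_per_h(self) -> float:
        return self.Ap * HOUR

    @property
    def An_per_h(self) -> float:
        return self.An * HOUR


@dataclass(frozen=True)
class FluidProps:
    """Culture-medium density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise InvalidInputError("fluid density and viscosity must be positive")


def volume_from_radius(R: float) -> float:
    """Sphere volume (4/3) pi R^3."""
    if R < 0:
        raise InvalidInputError(f"negative radius {R}")
    return 4.0 / 3.0 * math.pi * R**3


def radius_from_volume(V: float) -> float:
    """Radius of the sphere of volume ``V``; inverse of sphere-volume map."""
    if V < 0:
        raise InvalidInputError(f"negative volume {V}")
    return (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class TumorState:
    """Instantaneous tumor configuration.

    ``R``, ``Rq``, ``Rn`` are the tumor surface, quiescent-boundary and
    necrotic-boundary radii (m), with 0 <= Rn <= Rq <= R. Volumes are
    full-sphere volumes derived from the radii (hemispherical meshes
    elsewhere are a numerical convenience only; reporting is always for
    the full spheroid). ``t`` is in hours.
    """

    t: float
    R: float
    Rq: float = 0.0
    Rn: float = 0.0

    def __post_init__(self) -> None:
        if self.R < 0:
            raise InvalidInputError("tumor radius must be non-negative")
        tol = 1e-12 * self.R + 1e-30  # float round-trip slack
        if not (0.0 <= self.Rn <= self.Rq + tol and self.Rq <= self.R + tol):
            raise InvariantViolationError(
                f"zone radii must satisfy 0 <= Rn <= Rq <= R, got "
                f"Rn={self.Rn}, Rq={self.Rq}, R={self.R}"
            )

    @property
    def V(self) -> float:
        return volume_from_radius(self.R)

    @property
    def Vq(self) -> float:
        """Volume enclosed by the quiescent boundary (incl. necrotic core)."""
        return volume_from_radius(self.Rq)

    @property
    def Vn(self) -> float:
        return volume_from_radius(self.Rn)

    @property
    def phase(self) -> int:
        """Growth phase: 1 before quiescence, 2 before necrosis, 3 after."""
        if self.Rn > 0:
            return 3
        if self.Rq > 0:
            return 2
        return 1


def classify_point(
    c_glucose: float,
    c_oxygen: float,
    specs: tuple[NutrientSpec, NutrientSpec],
) -> ZoneLabel:
    """Zone label for a point with the given local concentrations.

    Deficiency is strict: ``C < C_crit``. At exact equality the point
    counts as the more viable class (a measure-zero tie broken
    deterministically). Both nutrients deficient -> necrotic; exactly
    one -> quiescent; none -> proliferative.
    """
    if c_glucose < 0 or c_oxygen < 0:
        raise InvalidInputError(
            f"negative concentration: glucose={c_glucose}, oxygen={c_oxygen}"
        )
    spec_g, spec_o = _ordered_specs(specs)
    deficient = (c_glucose < spec_g.C_crit) + (c_oxygen < spec_o.C_crit)
    if deficient == 2:
        return ZoneLabel.NECROTIC
    if deficient == 1:
        return ZoneLabel.QUIESCENT
    return ZoneLabel.PROLIFERATIVE


def _ordered_specs(
    specs: tuple[NutrientSpec, NutrientSpec],
) -> tuple[NutrientSpec, NutrientSpec]:
    """Return (glucose, oxygen) regardless of the order supplied."""
    a, b = specs
    if a.name is Nutrient.GLUCOSE and b.name is Nutrient.OXYGEN:
        return a, b
    if a.name is Nutrient.OXYGEN and b.name is Nutrient.GLUCOSE:
        return b, a
    raise InvalidInputError("specs must be one glucose and one oxygen NutrientSpec")


def consumption_rate(c: float, spec: NutrientSpec, label: ZoneLabel) -> float:
    """Volumetric uptake (mol/m^3/s): Michaelis–Menten scaled by zone.

    Full rate in the proliferative zone, half in the quiescent zone,
    zero in the necrotic core.
    """
    if c < 0:
        raise InvalidInputError(f"negative concentration {c}")
    return label.consumption_factor * spec.Vmax * c / (spec.Km + c)


def growth_rate(state: TumorState, params: KineticParams) -> float:
    """dV/dt in m^3/h for the three-zone growth law.

    Linear in (V, Vq, Vn); may be negative (shrinkage). In phase 1
    (Vq = Vn = 0) it reduces to ``(A - Ap) V``.
    """
    V, Vq, Vn = state.V, state.Vq, state.Vn
    if Vn > Vq * (1 + 1e-12) or Vq > V * (1 + 1e-12):
        raise InvariantViolationError("volumes must satisfy Vn <= Vq <= V")
    return params.A * (V - Vq) - params.Ap_per_h * (V - Vn) - params.An_per_h * Vn


# --- EMT6/Ro default profile (mouse mammary carcinoma spheroid) -------------
# A = ln 2 / 21 h: exponential doubling time of 21 h.

EMT6RO_GLUCOSE = NutrientSpec(
    name=Nutrient.GLUCOSE,
    D_tissue=4.22e-11,
    D_medium=9.27e-10,
    Vmax=4.36e-2,
    Km=4.0e-2,
    C_crit=0.06,
    C_bulk=0.8,
)

EMT6RO_OXYGEN = NutrientSpec(
    name=Nutrient.OXYGEN,
    D_tissue=1.65e-9,
    D_medium=2.6e-9,
    Vmax=2.74e-2,
    Km=4.64e-3,
    C_crit=0.02,
    C_bulk=0.28,
)

EMT6RO_KINETICS = KineticParams(A=3.3e-2, Ap=1.2153e-9, An=2e-6)

WATER_37C = FluidProps(density=993.3, viscosity=6.92e-4)
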