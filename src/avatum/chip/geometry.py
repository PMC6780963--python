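"""Microchannel + trap geometry on a structured rectilinear grid.

The computational domain is one half of a single-trap unit cell of the
perfusion chip: the channel mid-plane through the tumor centre (y = 0)
and the outer side face are both symmetry planes (the chip carries a
row of identical traps), so only ``0 <= y <= W/2`` is meshed. The flow
axis is x (inlet at x = 0), z is vertical with the channel floor at
z = 0.

Two trap variants hold the spheroid at the centre of the channel floor:

* ``u_barrier`` — a U-shaped wall standing on the floor, opening facing
  upstream so the spheroid inside is directly exposed to the flow;
* ``microwell`` — a rectangular well recessed into the floor (depth =
  trap height), sheltering the spheroid from the flow.

Both variants expose the same length, width, height and cross-section
area by construction (they are built from one shared spec). The tumor
is a full sphere resting tangent to the trap floor.

Cells are classified by their centre into FLUID, SOLID (trap walls,
substrate around the well) and TUMOR; the tumor is rigid and
stationary, so TUMOR cells are no-slip obstacles for the flow but
diffusively coupled in the transport solve. Grid spacing is graded: a
uniform fine region covers the trap and tumor, coarsening by a fixed
factor away from it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from ..units import m_to_um

__all__ = [
    "CellType",
    "TrapKind",
    "ChannelSpec",
    "TrapSpec",
    "ChipDomain",
    "GeometryError",
    "build_domain",
]

COARSENING = 3.0  # coarse/fine spacing ratio outside the trap region
DEFAULT_RESOLUTION = 30e-6  # fine-region cell size, m
FINE_MARGIN = 60e-6  # fine-mesh margin around the trap footprint, m


class GeometryError(ValueError):
    """A geometric containment constraint is violated."""


class CellType(enum.IntEnum):
    FLUID = 0
    SOLID = 1
    TUMOR = 2


class TrapKind(enum.Enum):
    U_BARRIER = "u_barrier"
    MICROWELL = "microwell"


@dataclass(frozen=True)
class ChannelSpec:
    """Channel dimensions (m): length along flow, full width, height."""

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise GeometryError("channel dimensions must be positive")


@dataclass(frozen=True)
class TrapSpec:
    """Trap dimensions (m), shared by both variants.

    ``length`` runs along the flow axis, ``width`` across the channel,
    ``height`` is the barrier height or well depth; ``wall`` is the
    U-barrier wall thickness (unused by the microwell).
    """

    kind: TrapKind
    length: float
    width: float
    height: float
    wall: float = 50e-6

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height, self.wall) <= 0:
            raise GeometryError("trap dimensions must be positive")
        if self.kind is TrapKind.U_BARRIER and 2 * self.wall >= min(
            self.length, self.width
        ):
            raise GeometryError("U-barrier walls leave no interior clearance")

    @property
    def cross_section(self) -> float:
        """Frontal cross-section area (width x height), m^2."""
        return self.width * self.height

    def with_kind(self, kind: TrapKind) -> "TrapSpec":
        from dataclasses import replace

        return replace(self, kind=kind)


def _graded_axis(
    breaks_fine: tuple[float, float],
    lo: float,
    hi: float,
    h_fine: float,
    h_coarse: float,
) -> np.ndarray:
    """Edge coordinates on [lo, hi]: uniform ``h_fine`` inside the fine
    window, uniform ``h_coarse`` outside (each segment rounded to a
    whole number of cells)."""
    a = max(lo, breaks_fine[0])
    b = min(hi, breaks_fine[1])
    edges = [lo]
    for s0, s1, h in ((lo, a, h_coarse), (a, b, h_fine), (b, hi, h_coarse)):
        seg = s1 - s0
        if seg <= 1e-12:
            continue
        n = max(1, int(round(seg / h)))
        edges.extend(np.linspace(s0, s1, n + 1)[1:])
    return np.array(edges)


@dataclass
class ChipDomain:
    """Discretized half-channel with trap and tumor.

    ``cell_type`` has shape (nx, ny, nz) indexed by cell; the edge
    arrays have one more entry per axis. ``z_floor`` is the trap floor
    elevation (0 for the U-barrier, -height for the microwell).
    """

    channel: ChannelSpec
    trap: TrapSpec
    tumor_center: tuple[float, float, float]
    tumor_radius: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    z_edges: np.ndarray
    cell_type: np.ndarray

    # --- derived helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cell_type.shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def widths(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.diff(self.x_edges),
            np.diff(self.y_edges),
            np.diff(self.z_edges),
        )

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
            0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
            0.5 * (self.z_edges[:-1] + self.z_edges[1:]),
        )

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.cell_type == CellType.FLUID

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.cell_type == CellType.TUMOR

    @property
    def cell_volumes(self) -> np.ndarray:
        dx, dy, dz = self.widths
        return dx[:, None, None] * dy[None, :, None] * dz[None, None, :]

    @property
    def inlet_area(self) -> float:
        """Full-channel inlet area (the symmetry half counts double)."""
        return self.channel.width * self.channel.height

    @property
    def z_floor(self) -> float:
        return -self.trap.height if self.trap.kind is TrapKind.MICROWELL else 0.0

    def geometry_audit(self) -> dict[str, float]:
        """Trap metrics shared between the two variants (m / m^2)."""
        return {
            "trap_length": self.trap.length,
            "trap_height": self.trap.height,
            "trap_cross_section": self.trap.cross_section,
        }

    def refine(self) -> "ChipDomain":
        """Bisect every cell along each axis (cell count x 8); cell
        types are re-evaluated from the same analytic geometry."""

        def bisect(e: np.ndarray) -> np.ndarray:
            return np.sort(np.concatenate([e, 0.5 * (e[:-1] + e[1:])]))

        return _classify(
            self.channel,
            self.trap,
            self.tumor_radius,
            bisect(self.x_edges),
            bisect(self.y_edges),
            bisect(self.z_edges),
        )


def _classify(
    channel: ChannelSpec,
    trap: TrapSpec,
    R: float,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    z_edges: np.ndarray,
) -> ChipDomain:
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")

    L, W, H = channel.length, channel.width, channel.height
    x0, x1 = L / 2 - trap.length / 2, L / 2 + trap.length / 2
    half_w = trap.width / 2
    z_floor = -trap.height if trap.kind is TrapKind.MICROWELL else 0.0
    center = (L / 2, 0.0, z_floor + R)

    types = np.full(X.shape, int(CellType.FLUID), dtype=np.int8)
    if trap.kind is TrapKind.U_BARRIER:
        footprint = (X >= x0) & (X <= x1) & (Y <= half_w) & (Z <= trap.height)
        interior = (X <= x1 - trap.wall) & (Y <= half_w - trap.wall)
        types[footprint & ~interior] = int(CellType.SOLID)
    else:  # microwell: substrate below the floor except the well cavity
        below = Z < 0
        well = (X >= x0) & (X <= x1) & (Y <= half_w)
        types[below & ~well] = int(CellType.SOLID)

    dist2 = (X - center[0]) ** 2 + Y**2 + (Z - center[2]) ** 2
    tumor = dist2 < R**2
    if np.any(tumor & (types == int(CellType.SOLID))):
        raise GeometryError("tumor voxels overlap trap walls")
    types[tumor] = int(CellType.TUMOR)

    return ChipDomain(
        channel=channel,
        trap=trap,
        tumor_center=center,
        tumor_radius=R,
        x_edges=x_edges,
        y_edges=y_edges,
        z_edges=z_edges,
        cell_type=types,
    )


def build_domain(
    trap: TrapSpec,
    channel: ChannelSpec,
    tumor_radius: float,
    resolution: float = DEFAULT_RESOLUTION,
) -> ChipDomain:
    """Build the tagged rectilinear half-domain.

    ``resolution`` is the fine-region cell size (m); spacing coarsens by
    a factor of 3 away from the trap. Rebuilding from the same spec is
    bit-identical (pure function of its arguments).

    Raises :class:`GeometryError` naming the violated clearance when
    the tumor does not fit the trap.
    """
    L, W, H = channel.length, channel.width, channel.height
    R = tumor_radius
    if trap.length > L or trap.width > W or trap.height > H:
        raise GeometryError("trap does not fit inside the channel")
    if trap.kind is TrapKind.U_BARRIER:
        clear = min(trap.length / 2 - trap.wall, trap.width / 2 - trap.wall)
        floor = 0.0
    else:
        clear = min(trap.length / 2, trap.width / 2)
        floor = -trap.height
    if R >= clear:
        raise GeometryError(
            f"tumor radius {m_to_um(R):.1f} um exceeds lateral trap clearance "
            f"{m_to_um(clear):.1f} um"
        )
    if floor + 2 * R > H:
        raise GeometryError(
            f"tumor (top at {m_to_um(floor + 2 * R):.1f} um) exceeds channel "
            f"height {m_to_um(H):.1f} um"
        )

    h = resolution
    hc = COARSENING * h
    x0, x1 = L / 2 - trap.length / 2, L / 2 + trap.length / 2
    m = FINE_MARGIN
    x_edges = _graded_axis((x0 - m, x1 + m), 0.0, L, h, hc)
    y_edges = _graded_axis((0.0, trap.width / 2 + m), 0.0, W / 2, h, hc)
    z_fine_top = max(trap.height, floor + 2 * R) + m
    z_edges = _graded_axis((floor, min(H, z_fine_top)), floor, H, h, hc)
    return _classify(channel, trap, R, x_edges, y_edges, z_edges)
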