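"""Coordinate frame, four-imager setup and basic geometry services.

Absolute frame convention: the origin (x = 0, y = 0) is the geometric center
of the A/D imager pair, z = 0 is the beam-axis plane.  The beam travels along
x toward decreasing x (entrance at positive x), y is vertical.  All distances
are mm, energies keV, times ns.

Each Compton imager ("i-TED"-style, 1 scatter + 4 absorber geometry) has one
monolithic 50x50 mm^2 scatter crystal (15 mm thick; 10 mm for imager C) and
four co-planar 50x50x25 mm^3 absorber crystals arranged 2x2 behind it.
Imagers A and B sit on the +z side, D and C on the -z side, front-to-front
(A-D and B-C), with scatter front faces 198 mm apart by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CrystalBox",
    "ImagerGeometry",
    "Phantom",
    "SetupGeometry",
    "build_default_setup",
    "point_in_crystal",
    "segment_plane_intersection",
    "GeometryError",
]

IMAGER_IDS = ("A", "B", "C", "D")

#: full lateral crystal size (x and y), mm
CRYSTAL_WIDTH = 50.0
#: full scatter thickness, mm (imager C is 10 mm)
SCATTER_THICKNESS = 15.0
SCATTER_THICKNESS_C = 10.0
#: full absorber thickness, mm
ABSORBER_THICKNESS = 25.0


class GeometryError(ValueError):
    """Invalid geometry (overlapping crystals, degenerate segments, ...)."""


def _vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


@dataclass(frozen=True)
class CrystalBox:
    """Axis-aligned crystal volume.

    ``role`` is ``"scatter"`` or ``"absorber"``; ``index`` numbers the four
    absorbers (0..3) within an imager, scatter crystals use index 0.
    """

    center: np.ndarray
    half_extents: np.ndarray
    role: str
    imager: str = "?"
    index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "center", _vec(self.center))
        he = _vec(self.half_extents)
        if np.any(he <= 0):
            raise GeometryError("half_extents must be strictly positive")
        object.__setattr__(self, "half_extents", he)
        if self.role not in ("scatter", "absorber"):
            raise GeometryError(f"unknown crystal role {self.role!r}")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.half_extents

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.half_extents

    def contains(self, p) -> bool:
        """Closed-box membership: points exactly on a face count as inside."""
        p = _vec(p)
        return bool(np.all(p >= self.lo) and np.all(p <= self.hi))

    def overlaps(self, other: "CrystalBox") -> bool:
        """Open-interval AABB overlap; shared faces do not count."""
        return bool(np.all(self.lo < other.hi) and np.all(other.lo < self.hi))


@dataclass(frozen=True)
class ImagerGeometry:
    id: str
    scatter: CrystalBox
    absorbers: tuple
    efficiency_scale: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.efficiency_scale <= 1.0):
            raise GeometryError("efficiency_scale must be in (0, 1]")
        if len(self.absorbers) != 4:
            raise GeometryError("an imager has exactly 4 absorber crystals")
        zs = {round(float(a.center[2]), 9) for a in self.absorbers}
        if len(zs) != 1:
            raise GeometryError("absorber crystals must be co-planar")

    @property
    def crystals(self) -> tuple:
        return (self.scatter,) + tuple(self.absorbers)

    @property
    def side(self) -> int:
        """+1 for the +z side, -1 for the -z side."""
        return 1 if self.scatter.center[2] > 0 else -1


@dataclass(frozen=True)
class Phantom:
    """Target volume: graphite cylinder (axis along x) or PE box."""

    kind: str  # "cylinder" | "box"
    material: str
    center: np.ndarray
    #: cylinder: (radius, length_x); box: full (dx, dy, dz)
    dimensions: tuple

    def __post_init__(self):
        object.__setattr__(self, "center", _vec(self.center))
        if self.kind not in ("cylinder", "box"):
            raise GeometryError(f"unknown phantom kind {self.kind!r}")
        if any(d <= 0 for d in self.dimensions):
            raise GeometryError("phantom dimensions must be positive")

    @property
    def x_range(self) -> tuple:
        cx = float(self.center[0])
        if self.kind == "cylinder":
            _, length = self.dimensions
            return (cx - length / 2.0, cx + length / 2.0)
        dx = self.dimensions[0]
        return (cx - dx / 2.0, cx + dx / 2.0)

    def shifted(self, dx: float) -> "Phantom":
        c = self.center.copy()
        c[0] += dx
        return replace(self, center=c)


def graphite_cylinder(x_position: float = 0.0) -> Phantom:
    """25 mm diameter x 50 mm long graphite cylinder centered at x_position."""
    return Phantom("cylinder", "graphite", (x_position, 0.0, 0.0), (12.5, 50.0))


def pe_block(x_position: float = 0.0) -> Phantom:
    """50 x 50 x 180 mm^3 polyethylene block, long axis along the beam."""
    return Phantom("box", "PE", (x_position, 0.0, 0.0), (180.0, 50.0, 50.0))


@dataclass(frozen=True)
class SetupGeometry:
    imagers: dict
    scatter_face_gap: float = 198.0
    lateral_gap: float = 10.0
    scatter_absorber_gap: float = 15.0
    phantom: Phantom | None = None

    def __post_init__(self):
        boxes = self.all_crystals()
        for a, b in itertools.combinations(boxes, 2):
            if a.overlaps(b):
                raise GeometryError(
                    f"crystal volumes overlap: {a.imager}/{a.role}{a.index} "
                    f"and {b.imager}/{b.role}{b.index}"
                )

    def all_crystals(self) -> list:
        out = []
        for im in self.imagers.values():
            out.extend(im.crystals)
        return out

    def imager(self, imager_id: str) -> ImagerGeometry:
        return self.imagers[imager_id]


def _build_imager(imager_id: str, x_center: float, side: int,
                  half_gap: float, scatter_absorber_gap: float,
                  efficiency_scale: float) -> ImagerGeometry:
    thick = SCATTER_THICKNESS_C if imager_id == "C" else SCATTER_THICKNESS
    w2 = CRYSTAL_WIDTH / 2.0
    sc_z = side * (half_gap + thick / 2.0)
    scatter = CrystalBox(
        (x_center, 0.0, sc_z), (w2, w2, thick / 2.0), "scatter", imager_id, 0
    )
    # The four 50x50x25 mm^3 absorbers stand on their sides, 2x2 in (x, y):
    # 25 mm along x, 50 mm along y and z.  This keeps the imager's lateral
    # footprint at 50 mm so neighbouring imagers 60 mm apart do not collide,
    # while the four crystals remain co-planar at one absorber depth.
    a_hx = ABSORBER_THICKNESS / 2.0
    ab_z = side * (half_gap + thick + scatter_absorber_gap + w2)
    absorbers = []
    for k, (ox, oy) in enumerate([(-a_hx, -w2), (a_hx, -w2),
                                  (-a_hx, w2), (a_hx, w2)]):
        absorbers.append(
            CrystalBox((x_center + ox, oy, ab_z),
                       (a_hx, w2, w2), "absorber", imager_id, k)
        )
    return ImagerGeometry(imager_id, scatter, tuple(absorbers), efficiency_scale)


def build_default_setup(scatter_face_gap: float = 198.0,
                        lateral_gap: float = 10.0,
                        scatter_absorber_gap: float = 15.0,
                        phantom: Phantom | None = None,
                        efficiency_scales: dict | None = None) -> SetupGeometry:
    """Four imagers in twofold front-to-front configuration.

    A (+z) faces D (-z) centered at x = 0; B (+z) faces C (-z) shifted
    upstream... downstream along -x by crystal width + lateral gap.  Scatter
    front faces sit at |z| = scatter_face_gap / 2.
    """
    if scatter_face_gap <= 0 or lateral_gap < 0 or scatter_absorber_gap < 0:
        raise GeometryError("gaps must be positive")
    eff = {"A": 1.0, "B": 1.0, "C": 0.93, "D": 1.0}
    if efficiency_scales:
        eff.update(efficiency_scales)
    half_gap = scatter_face_gap / 2.0
    shift = -(CRYSTAL_WIDTH + lateral_gap)
    imagers = {
        "A": _build_imager("A", 0.0, +1, half_gap, scatter_absorber_gap, eff["A"]),
        "B": _build_imager("B", shift, +1, half_gap, scatter_absorber_gap, eff["B"]),
        "C": _build_imager("C", shift, -1, half_gap, scatter_absorber_gap, eff["C"]),
        "D": _build_imager("D", 0.0, -1, half_gap, scatter_absorber_gap, eff["D"]),
    }
    return SetupGeometry(imagers, scatter_face_gap, lateral_gap,
                         scatter_absorber_gap, phantom)


def point_in_crystal(p, crystal: CrystalBox) -> bool:
    """True iff ``p`` lies inside the closed crystal box."""
    return crystal.contains(p)


def segment_plane_intersection(p1, p2, tol: float = 1e-12):
    """Intersection of the infinite line through p1, p2 with the z = 0 plane.

    Returns the intersection point, or ``None`` when the line is parallel to
    the plane (|z1 - z2| below ``tol``).  Raises ``GeometryError`` for a
    degenerate segment (p1 == p2).
    """
    p1 = _vec(p1)
    p2 = _vec(p2)
    if np.array_equal(p1, p2):
        raise GeometryError("degenerate segment: p1 == p2")
    dz = p1[2] - p2[2]
    if abs(dz) < tol:
        return None
    t = p1[2] / dz
    return p1 + t * (p2 - p1)
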