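"""Synthetic bone geometry generators.

The study geometry these meshes stand in for is a Misch type II facial bone:
a dense cortical shell 1.5-2.0 mm thick over a trabecular core, meshed at
1-1.5 mm.  The generators build structured, deterministic hexahedral meshes
with that layering:

* a single verification element,
* a layered (cortical-trabecular-cortical) flat or curved plate,
* a curved arch between two fixed abutments, shaped to reproduce the
  bending-plus-crushing competition a strut-like cheekbone sees under a
  lateral blow,
* the rigid cylindrical impactor (200 mm x Ø40 mm, 2 kg).

All dimensions are configurable; any optional node jitter takes an explicit
seed so generation is reproducible by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .contact import RigidImpactor
from .mesh import Mesh, PHASE_CORTICAL, PHASE_TRABECULAR

__all__ = [
    "PlateSpec",
    "ArchSpec",
    "make_single_element",
    "make_layered_plate",
    "make_zygoma_arch",
    "make_impactor",
]


@dataclass(frozen=True)
class PlateSpec:
    """Layered sandwich plate: cortical skin / trabecular core / cortical skin."""

    span: float = 40.0  # mm, x extent
    width: float = 40.0  # mm, y extent
    cortical_thickness: float = 1.5  # mm per skin (type II range 1.5-2.0)
    core_thickness: float = 7.0  # mm
    element_size: float = 1.5  # mm (study mesh size 1-1.5 mm)
    curvature_radius: float = math.inf  # mm; inf = flat
    # "bridge": fixed on the two edges parallel to the impactor axis (a
    # strut spanning two abutments -> bending + crushing competition, and
    # a through-thickness crush path at the highest study speed);
    # "clamped_edges": whole lateral boundary fixed (stiffer, crush-only)
    support: str = "bridge"
    cortical_bounds: tuple = (1.5, 2.0)
    jitter: float = 0.0  # fraction of element size
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cortical_bounds
        if not (lo <= self.cortical_thickness <= hi):
            raise ValueError(
                f"cortical thickness {self.cortical_thickness} outside configured bounds {self.cortical_bounds}"
            )
        if not self.element_size > 0:
            raise ValueError("element size must be positive")
        if self.span <= 0 or self.width <= 0 or self.core_thickness <= 0:
            raise ValueError("plate dimensions must be positive")

    @property
    def thickness(self) -> float:
        return 2.0 * self.cortical_thickness + self.core_thickness


@dataclass(frozen=True)
class ArchSpec:
    """Curved arch pillar between two abutments, cortical shell over core."""

    radius: float = 30.0  # mm, mid-surface radius
    angle_deg: float = 100.0  # subtended angle
    width: float = 10.0  # mm, out-of-plane
    cortical_thickness: float = 1.5
    core_thickness: float = 7.0
    element_size: float = 1.5
    cortical_bounds: tuple = (1.5, 2.0)

    def __post_init__(self) -> None:
        lo, hi = self.cortical_bounds
        if not (lo <= self.cortical_thickness <= hi):
            raise ValueError("cortical thickness outside configured bounds")
        if self.radius <= 0 or not (0 < self.angle_deg < 180) or self.element_size <= 0:
            raise ValueError("invalid arch dimensions")

    @property
    def thickness(self) -> float:
        return 2.0 * self.cortical_thickness + self.core_thickness


def _layer_grid(cortical: float, core: float, elem: float):
    """z breakpoints and per-element phases through the sandwich thickness."""
    nz_c = max(1, round(cortical / elem))
    nz_core = max(1, round(core / elem))
    z = np.concatenate(
        [
            np.linspace(0.0, cortical, nz_c + 1),
            np.linspace(cortical, cortical + core, nz_core + 1)[1:],
            np.linspace(cortical + core, 2 * cortical + core, nz_c + 1)[1:],
        ]
    )
    phase = np.concatenate(
        [
            np.full(nz_c, PHASE_CORTICAL),
            np.full(nz_core, PHASE_TRABECULAR),
            np.full(nz_c, PHASE_CORTICAL),
        ]
    )
    if nz_c < 2:
        warnings.warn(
            f"only {nz_c} element(s) through each cortical skin at element size {elem} mm",
            stacklevel=3,
        )
    return z, phase


def _structured_hexes(nx: int, ny: int, nz: int) -> np.ndarray:
    """VTK-ordered hex connectivity of an (nx, ny, nz) cell grid."""

    def nid(i, j, k):
        return (k * (ny + 1) + j) * (nx + 1) + i

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    return np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ],
        axis=1,
    )


def make_single_element(size: float = 1.0, phase: int = PHASE_CORTICAL) -> Mesh:
    """One cube hexahedron with face node sets for displacement-driven rigs."""
    if not size > 0:
        raise ValueError("element size must be positive")
    g = np.array([0.0, size])
    z, y, x = np.meshgrid(g, g, g, indexing="ij")
    nodes = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    hexes = _structured_hexes(1, 1, 1)
    sets = {}
    for axis, name in enumerate("xyz"):
        sets[f"{name}0"] = np.nonzero(nodes[:, axis] == 0.0)[0]
        sets[f"{name}1"] = np.nonzero(nodes[:, axis] == size)[0]
    m = Mesh(nodes=nodes, hexes=hexes, phase=np.array([phase]), node_sets=sets)
    m.validate()
    return m


def make_layered_plate(spec: PlateSpec) -> Mesh:
    """Cortical-trabecular-cortical sandwich plate.

    The plate occupies ``[0, span] x [0, width]`` with thickness along z;
    the impact face is the top surface (z = thickness) and the fixed set
    ("fixed") is the full lateral boundary.  A finite ``curvature_radius``
    bends the plate about the x axis, preserving arc length.
    """
    nx = max(1, round(spec.span / spec.element_size))
    ny = max(1, round(spec.width / spec.element_size))
    xs = np.linspace(0.0, spec.span, nx + 1)
    ys = np.linspace(0.0, spec.width, ny + 1)
    zs, phase_col = _layer_grid(spec.cortical_thickness, spec.core_thickness, spec.element_size)
    nz = len(zs) - 1
    # Node numbering must match _structured_hexes: x index fastest, z slowest.
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    hexes = _structured_hexes(nx, ny, nz)
    # Element ordering from _structured_hexes runs the z (layer) index fastest.
    phase = np.tile(phase_col, nx * ny)

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        interior = (
            (nodes[:, 0] > 0)
            & (nodes[:, 0] < spec.span)
            & (nodes[:, 1] > 0)
            & (nodes[:, 1] < spec.width)
            & (nodes[:, 2] > 0)
            & (nodes[:, 2] < spec.thickness)
        )
        nodes[interior] += rng.uniform(
            -spec.jitter * spec.element_size, spec.jitter * spec.element_size, (interior.sum(), 3)
        )

    thickness = spec.thickness
    tol = 1e-9
    x_edges = (np.abs(nodes[:, 0]) < tol) | (np.abs(nodes[:, 0] - spec.span) < tol)
    y_edges = (np.abs(nodes[:, 1]) < tol) | (np.abs(nodes[:, 1] - spec.width) < tol)
    if spec.support == "clamped_edges":
        fixed = x_edges | y_edges
    elif spec.support == "bridge":
        # supported only on the two edges parallel to the impactor axis:
        # a strut spanning two abutments, free to bend between them
        fixed = y_edges
    else:
        raise ValueError(f"unknown support condition {spec.support!r}")
    sets = {
        "fixed": np.nonzero(fixed)[0],
        "impact_face": np.nonzero(np.abs(nodes[:, 2] - thickness) < tol)[0],
        "back_face": np.nonzero(np.abs(nodes[:, 2]) < tol)[0],
    }

    if math.isfinite(spec.curvature_radius):
        r0 = spec.curvature_radius
        y_arc, z_off = nodes[:, 1].copy(), nodes[:, 2].copy()
        theta = (y_arc - spec.width / 2.0) / r0
        rr = r0 + z_off  # offset outward along the curved normal
        nodes[:, 1] = spec.width / 2.0 + rr * np.sin(theta)
        nodes[:, 2] = rr * np.cos(theta) - r0

    mesh = Mesh(nodes=nodes, hexes=hexes, phase=phase, node_sets=sets)
    mesh.validate()
    _check_element_sizes(mesh, spec.element_size)
    return mesh


def make_zygoma_arch(spec: ArchSpec = ArchSpec()) -> Mesh:
    """Curved arch between two fixed abutments (synthetic cheekbone strut).

    Structured grid in (angle, radial, axial) coordinates: the cortical
    shells are the inner and outer radial layers.  Node sets: "abutment_a",
    "abutment_b" (the two fixed ends, together exposed as "fixed") and
    "impact_face" (outer surface of the central third).
    """
    half = math.radians(spec.angle_deg) / 2.0
    arc_len = spec.radius * 2.0 * half
    na = max(2, round(arc_len / spec.element_size))
    nw = max(1, round(spec.width / spec.element_size))
    ts, phase_col = _layer_grid(spec.cortical_thickness, spec.core_thickness, spec.element_size)
    nt = len(ts) - 1

    phis = np.linspace(-half, half, na + 1)
    ws = np.linspace(0.0, spec.width, nw + 1)
    r_in = spec.radius - spec.thickness / 2.0

    # Grid axes map (x=angle index, y=axial index, z=radial index) so the
    # through-thickness phase pattern tiles like the plate.
    nodes = np.empty(((na + 1) * (nw + 1) * (nt + 1), 3))
    idx = 0
    for k in range(nt + 1):
        for j in range(nw + 1):
            for i in range(na + 1):
                r = r_in + ts[k]
                # -sin keeps the (angle, axial, radial) grid right-handed
                nodes[idx] = (ws[j], -r * math.sin(phis[i]), r * math.cos(phis[i]) - r_in)
                idx += 1
    # note: x = axial width, (y, z) = arch plane; crown of the arch at phi=0.
    hexes = _structured_hexes(na, nw, nt)
    phase = np.tile(phase_col, na * nw)

    node_phi = np.tile(phis, (nw + 1) * (nt + 1))
    tol = 1e-9
    a_set = np.nonzero(np.abs(node_phi - phis[0]) < tol)[0]
    b_set = np.nonzero(np.abs(node_phi - phis[-1]) < tol)[0]
    # Outer-surface nodes of the central third of the span.
    node_t = np.repeat(ts, (na + 1) * (nw + 1))
    outer = np.abs(node_t - ts[-1]) < tol
    central = np.abs(node_phi) <= half / 3.0 + tol
    sets = {
        "abutment_a": a_set,
        "abutment_b": b_set,
        "fixed": np.concatenate([a_set, b_set]),
        "impact_face": np.nonzero(outer & central)[0],
        "back_face": np.nonzero((np.abs(node_t - ts[0]) < tol) & central)[0],
    }
    mesh = Mesh(nodes=nodes, hexes=hexes, phase=phase, node_sets=sets)
    mesh.validate()
    return mesh


def _check_element_sizes(mesh: Mesh, target: float, tol: float = 0.2) -> None:
    le = mesh.damage_lengths()
    if np.any(le < (1 - tol) * target) or np.any(le > (1 + tol) * target):
        warnings.warn(
            f"element characteristic lengths [{le.min():.3g}, {le.max():.3g}] mm "
            f"stray more than {tol:.0%} from target {target} mm",
            stacklevel=3,
        )


def make_impactor(
    length: float = 200.0,
    diameter: float = 40.0,
    mass_kg: float = 2.0,
    speed_kmh: float = 0.0,
    aim: np.ndarray = (0.0, 0.0, 0.0),
    position: np.ndarray | None = None,
    axis: np.ndarray = (1.0, 0.0, 0.0),
) -> RigidImpactor:
    """Rigid steel cylinder impactor (defaults: 200 mm x Ø40 mm, 2 kg).

    The velocity vector has magnitude ``speed_kmh`` (converted to mm/s)
    directed from ``position`` toward ``aim``.  When no position is given
    the cylinder axis passes through ``aim`` (speed 0 or pure placement).
    """
    if length <= 0 or diameter <= 0:
        raise ValueError("impactor dimensions must be positive")
    if mass_kg <= 0:
        raise ValueError("impactor mass must be positive")
    if speed_kmh < 0:
        raise ValueError("impactor speed must be non-negative")
    aim = np.asarray(aim, dtype=float)
    center = aim.copy() if position is None else np.asarray(position, dtype=float)
    speed = units.kmh_to_mm_s(speed_kmh)
    if speed > 0 and position is not None:
        direction = aim - center
        nrm = np.linalg.norm(direction)
        if nrm == 0:
            raise ValueError("aim point coincides with impactor position")
        velocity = speed * direction / nrm
    else:
        velocity = np.zeros(3)
        if speed > 0:
            velocity[2] = -speed  # default approach: straight down
    return RigidImpactor(
        length=length,
        radius=diameter / 2.0,
        mass=units.kg_to_tonne(mass_kg),
        center=center,
        axis=np.asarray(axis, dtype=float),
        velocity=velocity,
    )
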