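"""Mesh container, validation, surface bookkeeping and JSON I/O.

A :class:`Mesh` holds first-order solid elements (8-node hexahedra and/or
4-node tetrahedra) over one node array.  Elements are numbered globally with
all hexahedra first, then all tetrahedra; ``phase[e]`` gives the material
phase id of element ``e`` (conventionally 0 = cortical, 1 = trabecular).
Named node sets carry boundary conditions and contact surfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .elements import HEX_FACES, TET_FACES, hex_operators, tet_operators

__all__ = ["Mesh", "MeshError", "merge_tie", "PHASE_CORTICAL", "PHASE_TRABECULAR"]

PHASE_CORTICAL = 0
PHASE_TRABECULAR = 1


class MeshError(ValueError):
    """Invalid mesh topology or geometry."""


@dataclass
class Mesh:
    nodes: np.ndarray  # (nn, 3) mm
    hexes: np.ndarray = field(default_factory=lambda: np.zeros((0, 8), dtype=np.int64))
    tets: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    phase: np.ndarray | None = None  # (ne,) material phase per element
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.hexes = np.asarray(self.hexes, dtype=np.int64).reshape(-1, 8)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        if self.phase is None:
            self.phase = np.zeros(self.n_elements, dtype=np.int64)
        self.phase = np.asarray(self.phase, dtype=np.int64)
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_hexes(self) -> int:
        return self.hexes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    @property
    def n_elements(self) -> int:
        return self.n_hexes + self.n_tets

    def element_nodes(self, e: int) -> np.ndarray:
        if e < self.n_hexes:
            return self.hexes[e]
        return self.tets[e - self.n_hexes]

    def validate(self, n_phases: int | None = None) -> None:
        """Raise :class:`MeshError` on broken connectivity or geometry."""
        for name, conn in (("hex", self.hexes), ("tet", self.tets)):
            if conn.size and (conn.min() < 0 or conn.max() >= self.n_nodes):
                raise MeshError(f"{name} connectivity indexes nonexistent nodes")
        if self.phase.shape[0] != self.n_elements:
            raise MeshError("phase array length must equal the element count")
        if n_phases is not None and self.phase.size and self.phase.max() >= n_phases:
            raise MeshError("element references an undefined material phase")
        vols = self.element_volumes()  # raises on non-positive volumes
        if np.any(~np.isfinite(vols)):
            raise MeshError("non-finite element volume")
        for name, ids in self.node_sets.items():
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise MeshError(f"node set {name!r} indexes nonexistent nodes")

    # -- geometry -----------------------------------------------------------

    def element_volumes(self) -> np.ndarray:
        vols = np.empty(self.n_elements)
        if self.n_hexes:
            try:
                *_, v = hex_operators(self.nodes[self.hexes])
            except ValueError as err:
                raise MeshError(str(err)) from err
            vols[: self.n_hexes] = v
        if self.n_tets:
            try:
                *_, v = tet_operators(self.nodes[self.tets])
            except ValueError as err:
                raise MeshError(str(err)) from err
            vols[self.n_hexes :] = v
        return vols

    def char_lengths(self) -> np.ndarray:
        """Stability characteristic length per element: V / A_max (x3 for tets)."""
        out = np.empty(self.n_elements)
        if self.n_hexes:
            coords = self.nodes[self.hexes]
            *_, vol = hex_operators(coords)
            amax = np.zeros(self.n_hexes)
            for f in HEX_FACES:
                amax = np.maximum(amax, _quad_area(coords[:, f]))
            out[: self.n_hexes] = vol / amax
        if self.n_tets:
            coords = self.nodes[self.tets]
            *_, vol = tet_operators(coords)
            amax = np.zeros(self.n_tets)
            for f in TET_FACES:
                amax = np.maximum(amax, _tri_area(coords[:, f]))
            out[self.n_hexes :] = 3.0 * vol / amax
        return out

    def damage_lengths(self) -> np.ndarray:
        """Softening regularization length per element, L_e = V^(1/3)."""
        return np.cbrt(self.element_volumes())

    def element_centroids(self) -> np.ndarray:
        cent = np.empty((self.n_elements, 3))
        if self.n_hexes:
            cent[: self.n_hexes] = self.nodes[self.hexes].mean(axis=1)
        if self.n_tets:
            cent[self.n_hexes :] = self.nodes[self.tets].mean(axis=1)
        return cent

    # -- surfaces -----------------------------------------------------------

    def exterior_faces(self, alive: np.ndarray | None = None):
        """Boundary faces of the (optionally masked) element set.

        Returns ``(quad_faces (nq, 4), tri_faces (nt, 3))`` in node ids:
        faces that occur exactly once among the selected elements.
        """
        if alive is None:
            alive = np.ones(self.n_elements, dtype=bool)
        quads = []
        if self.n_hexes:
            hx = self.hexes[alive[: self.n_hexes]]
            if hx.size:
                quads = hx[:, HEX_FACES].reshape(-1, 4)
        tris = []
        if self.n_tets:
            tt = self.tets[alive[self.n_hexes :]]
            if tt.size:
                tris = tt[:, TET_FACES].reshape(-1, 3)
        return _unmatched_faces(quads, 4), _unmatched_faces(tris, 3)

    def surface_node_areas(self, alive: np.ndarray | None = None):
        """Tributary area per exterior node of the alive element set.

        Each boundary face spreads its area equally over its nodes.  Returns
        ``(node_ids (m,), areas (m,))``.
        """
        quads, tris = self.exterior_faces(alive)
        acc = np.zeros(self.n_nodes)
        if len(quads):
            a = _quad_area(self.nodes[quads])
            np.add.at(acc, quads.ravel(), np.repeat(a / 4.0, 4))
        if len(tris):
            a = _tri_area(self.nodes[tris])
            np.add.at(acc, tris.ravel(), np.repeat(a / 3.0, 3))
        ids = np.nonzero(acc > 0)[0]
        return ids, acc[ids]

    # -- I/O ----------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "osteoimpact-mesh-v1",
            "nodes": self.nodes.tolist(),
            "hexes": self.hexes.tolist(),
            "tets": self.tets.tolist(),
            "phase": self.phase.tolist(),
            "node_sets": {k: v.tolist() for k, v in self.node_sets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Mesh":
        return cls(
            nodes=np.asarray(d["nodes"], dtype=float),
            hexes=np.asarray(d.get("hexes", []), dtype=np.int64).reshape(-1, 8),
            tets=np.asarray(d.get("tets", []), dtype=np.int64).reshape(-1, 4),
            phase=np.asarray(d["phase"], dtype=np.int64),
            node_sets={k: np.asarray(v) for k, v in d.get("node_sets", {}).items()},
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "Mesh":
        return cls.from_dict(json.loads(Path(path).read_text()))


class SurfaceTracker:
    """Fast exterior-surface extraction for a fixed mesh with dying elements.

    All faces and their areas are enumerated once; per query only a bincount
    over the alive elements' face ids is needed, so the contact surface can
    be refreshed every step during element-deletion bursts.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self._quad = self._build(mesh.hexes, HEX_FACES, _quad_area, 0)
        self._tri = self._build(mesh.tets, TET_FACES, _tri_area, mesh.n_hexes)

    def _build(self, conn, local_faces, area_fn, elem_offset):
        if not len(conn):
            return None
        nf = local_faces.shape[0]
        faces = conn[:, local_faces].reshape(-1, local_faces.shape[1])
        key = np.sort(faces, axis=1)
        # sorted keys identify shared faces; keep a representative in its
        # original cyclic vertex order for the area computation
        _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
        rep = faces[first]
        areas = area_fn(self.mesh.nodes[rep])
        owner = np.repeat(np.arange(len(conn)) + elem_offset, nf)
        return {"inv": inv, "faces": rep, "areas": areas, "owner": owner, "nf": nf}

    def node_areas(self, alive: np.ndarray):
        """Tributary area per exterior node of the alive element set."""
        acc = np.zeros(self.mesh.n_nodes)
        for blk in (self._quad, self._tri):
            if blk is None:
                continue
            sel = alive[blk["owner"]]
            counts = np.bincount(blk["inv"][sel], minlength=len(blk["faces"]))
            boundary = counts == 1
            if not boundary.any():
                continue
            fnodes = blk["faces"][boundary]
            k = fnodes.shape[1]
            np.add.at(acc, fnodes.ravel(), np.repeat(blk["areas"][boundary] / k, k))
        ids = np.nonzero(acc > 0)[0]
        return ids, acc[ids]


def _quad_area(coords: np.ndarray) -> np.ndarray:
    """Area of (possibly warped) quads (..., 4, 3) via the cross-diagonal rule."""
    d1 = coords[..., 2, :] - coords[..., 0, :]
    d2 = coords[..., 3, :] - coords[..., 1, :]
    return 0.5 * np.linalg.norm(np.cross(d1, d2), axis=-1)


def _tri_area(coords: np.ndarray) -> np.ndarray:
    d1 = coords[..., 1, :] - coords[..., 0, :]
    d2 = coords[..., 2, :] - coords[..., 0, :]
    return 0.5 * np.linalg.norm(np.cross(d1, d2), axis=-1)


def _unmatched_faces(faces, width: int) -> np.ndarray:
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, width)
    if not len(faces):
        return faces
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def merge_tie(mesh: Mesh, set_a: str, set_b: str, tolerance: float = 1e-8) -> Mesh:
    """Tie two surfaces by merging their nodes (master = ``set_a``).

    Every node of ``set_b`` must have a ``set_a`` node within ``tolerance``;
    it is snapped onto and merged with that master node, so the constraint is
    exact and preserves rigid-body motion trivially.  Raises
    :class:`MeshError` for unmatched slave nodes.
    """
    a = mesh.node_sets[set_a]
    b = mesh.node_sets[set_b]
    tree = cKDTree(mesh.nodes[a])
    dist, j = tree.query(mesh.nodes[b])
    if np.any(dist > tolerance):
        bad = b[dist > tolerance]
        raise MeshError(
            f"tie failed: {bad.size} nodes of {set_b!r} beyond tolerance "
            f"{tolerance} of {set_a!r} (worst {dist.max():.3g} mm)"
        )
    remap = np.arange(mesh.n_nodes)
    remap[b] = a[j]
    hexes = remap[mesh.hexes] if mesh.n_hexes else mesh.hexes
    tets = remap[mesh.tets] if mesh.n_tets else mesh.tets
    # Drop now-unreferenced nodes and compress indices.
    used = np.zeros(mesh.n_nodes, dtype=bool)
    if hexes.size:
        used[hexes] = True
    if tets.size:
        used[tets] = True
    new_index = -np.ones(mesh.n_nodes, dtype=np.int64)
    new_index[used] = np.arange(used.sum())
    node_sets = {}
    for name, ids in mesh.node_sets.items():
        mapped = new_index[np.unique(remap[ids])]
        node_sets[name] = mapped[mapped >= 0]
    return Mesh(
        nodes=mesh.nodes[used],
        hexes=new_index[hexes] if hexes.size else hexes,
        tets=new_index[tets] if tets.size else tets,
        phase=mesh.phase.copy(),
        node_sets=node_sets,
    )
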