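"""Post-processing: SAE J211 channel filtering, stress fields, fracture maps.

Impact-test force channels are filtered with the SAE J211 channel-frequency-
class filter: a phaseless (forward-backward) pair of 2-pole Butterworth
passes.  Channel class CFC180 corresponds to a -3 dB cutoff of 300 Hz
(cutoff = CFC * 5/3), the class used for head-impact force histories.

Fracture reporting groups deleted elements into face-adjacency connected
components ("fracture lines"), separately maps initiated elements
(omega >= 1), and summarizes how much of the failed volume lies under the
impactor footprint (crush fraction) versus away from it (bending-dominated
failure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .materials import von_mises_voigt
from .mesh import Mesh
from .elements import HEX_FACES, TET_FACES

__all__ = [
    "sae_filter",
    "cfc_cutoff_hz",
    "von_mises",
    "nodal_field",
    "FractureReport",
    "extract_fracture_lines",
]


def cfc_cutoff_hz(channel_class: float) -> float:
    """-3 dB cutoff of a J211 channel class (CFC180 -> 300 Hz)."""
    return channel_class * 5.0 / 3.0


def sae_filter(time: np.ndarray, signal: np.ndarray, channel_class: float = 180.0) -> np.ndarray:
    """Phaseless J211 channel-class filtering of a uniformly sampled signal.

    Two cascaded 2-pole Butterworth passes, forward then backward
    (``filtfilt``), giving zero phase lag and unit DC gain.  Raises if the
    record is too short for the filter warm-up.
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(signal, dtype=float)
    if t.size != x.size:
        raise ValueError("time and signal must have equal length")
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError("time samples must strictly increase")
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("sae_filter needs uniform sampling; resample first")
    fs = 1.0 / dt[0]
    fc = cfc_cutoff_hz(channel_class)
    if fc >= fs / 2:
        raise ValueError(f"cutoff {fc} Hz at or above Nyquist ({fs / 2} Hz)")
    b, a = scipy.signal.butter(2, fc / (fs / 2))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.size <= padlen:
        raise ValueError(
            f"history of {x.size} samples is shorter than the filter warm-up "
            f"({padlen + 1} samples); pad or sample more densely"
        )
    return scipy.signal.filtfilt(b, a, x)


def von_mises(stress) -> np.ndarray:
    """Equivalent stress of Voigt stresses [xx, yy, zz, xy, yz, zx] (MPa)."""
    return von_mises_voigt(stress)


def nodal_field(mesh: Mesh, element_values: np.ndarray, alive: np.ndarray | None = None) -> np.ndarray:
    """Volume-weighted nodal average of a per-element field.

    Deleted elements (``alive`` False) are excluded; nodes attached only to
    deleted elements report 0.
    """
    vals = np.asarray(element_values, dtype=float)
    if alive is None:
        alive = np.ones(mesh.n_elements, dtype=bool)
    vols = mesh.element_volumes()
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    blocks = []
    if mesh.n_hexes:
        blocks.append((mesh.hexes, np.arange(mesh.n_hexes)))
    if mesh.n_tets:
        blocks.append((mesh.tets, np.arange(mesh.n_tets) + mesh.n_hexes))
    for conn, ids in blocks:
        sel = alive[ids]
        c = conn[sel]
        w = vols[ids][sel]
        v = vals[ids][sel]
        np.add.at(num, c.ravel(), np.repeat(w * v, conn.shape[1]))
        np.add.at(den, c.ravel(), np.repeat(w, conn.shape[1]))
    out = np.zeros(mesh.n_nodes)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


@dataclass
class FractureReport:
    """Summary of the final damage state of a run."""

    n_elements: int
    n_initiated: int
    n_deleted: int
    failed_volume: float  # mm^3
    crush_fraction: float  # failed volume under the impactor footprint / total failed
    components: list = field(default_factory=list)  # per fracture component
    initiation_components: int = 0
    omega: np.ndarray | None = None
    damage: np.ndarray | None = None
    deleted: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "n_elements": int(self.n_elements),
            "n_initiated": int(self.n_initiated),
            "n_deleted": int(self.n_deleted),
            "failed_volume_mm3": float(self.failed_volume),
            "crush_fraction": float(self.crush_fraction),
            "initiation_components": int(self.initiation_components),
            "components": self.components,
        }
        return d

    @staticmethod
    def schema() -> dict:
        """Shape of :meth:`to_dict` output (field -> type)."""
        return {
            "n_elements": int,
            "n_initiated": int,
            "n_deleted": int,
            "failed_volume_mm3": float,
            "crush_fraction": float,
            "initiation_components": int,
            "components": list,
        }

    def validate(self) -> None:
        d = self.to_dict()
        for key, typ in self.schema().items():
            if key not in d:
                raise ValueError(f"fracture report missing {key!r}")
            if not isinstance(d[key], typ):
                raise ValueError(f"fracture report field {key!r} is not {typ.__name__}")
        if sum(c["n_elements"] for c in d["components"]) != d["n_deleted"]:
            raise ValueError("component element counts must sum to the deleted count")


def _face_adjacency(mesh: Mesh, mask: np.ndarray) -> sp.csr_matrix:
    """Element adjacency (shared faces) restricted to masked elements."""
    ids = np.nonzero(mask)[0]
    faces = []
    owners = []
    for e in ids:
        if e < mesh.n_hexes:
            local = mesh.hexes[e][HEX_FACES]
        else:
            local = mesh.tets[e - mesh.n_hexes][TET_FACES]
        for f in local:
            faces.append(tuple(sorted(f.tolist())))
            owners.append(e)
    n = mesh.n_elements
    if not faces:
        return sp.csr_matrix((n, n))
    order = np.lexsort(np.asarray(faces).T)
    faces_arr = np.asarray(faces)[order]
    owners_arr = np.asarray(owners)[order]
    same = np.all(faces_arr[1:] == faces_arr[:-1], axis=1)
    i = owners_arr[:-1][same]
    j = owners_arr[1:][same]
    adj = sp.coo_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    return (adj + adj.T).tocsr()


def _components(mesh: Mesh, mask: np.ndarray):
    ids = np.nonzero(mask)[0]
    if ids.size == 0:
        return 0, {}
    adj = _face_adjacency(mesh, mask)
    n_all, labels = connected_components(adj, directed=False)
    groups: dict[int, np.ndarray] = {}
    for lab in np.unique(labels[ids]):
        groups[lab] = ids[labels[ids] == lab]
    return len(groups), groups


def extract_fracture_lines(
    mesh: Mesh,
    omega: np.ndarray,
    damage: np.ndarray,
    deleted: np.ndarray,
    impactor=None,
) -> FractureReport:
    """Build the fracture report from final element fields.

    Deleted elements are grouped into face-adjacent components with element
    counts and bounding extents; initiated elements (omega >= 1) are grouped
    separately.  The crush fraction is the deleted volume whose centroid
    falls inside the impactor's projected footprint (distance to the
    cylinder axis <= radius), over the total deleted volume.
    """
    deleted = np.asarray(deleted, dtype=bool)
    omega = np.asarray(omega, dtype=float)
    vols = mesh.element_volumes()
    cents = mesh.element_centroids()

    n_comp, groups = _components(mesh, deleted)
    components = []
    for lab in sorted(groups, key=lambda k: -groups[k].size):
        ids = groups[lab]
        lo = cents[ids].min(axis=0)
        hi = cents[ids].max(axis=0)
        components.append(
            {
                "n_elements": int(ids.size),
                "volume_mm3": float(vols[ids].sum()),
                "extent_min_mm": lo.tolist(),
                "extent_max_mm": hi.tolist(),
                "element_ids": ids.tolist(),
            }
        )
    n_init_comp, _ = _components(mesh, omega >= 1.0)

    failed_volume = float(vols[deleted].sum())
    crush = 0.0
    if impactor is not None and failed_volume > 0:
        # Footprint = projection of the cylinder along the approach direction:
        # |axial coordinate| <= L/2 and |lateral offset| <= radius, where
        # lateral is perpendicular to both the axis and the approach.
        approach = impactor.velocity
        if np.linalg.norm(approach) < 1e-12:
            approach = np.array([0.0, 0.0, -1.0])
        approach = approach / np.linalg.norm(approach)
        lateral = np.cross(impactor.axis, approach)
        ln = np.linalg.norm(lateral)
        rel = cents[deleted] - impactor.center
        z = rel @ impactor.axis
        if ln < 1e-12:  # axis parallel to approach: use radial distance
            lat = np.linalg.norm(rel - z[:, None] * impactor.axis[None, :], axis=1)
        else:
            lat = np.abs(rel @ (lateral / ln))
        inside = (lat <= impactor.radius) & (np.abs(z) <= impactor.length / 2)
        crush = float(vols[deleted][inside].sum() / failed_volume)

    report = FractureReport(
        n_elements=mesh.n_elements,
        n_initiated=int((omega >= 1.0).sum()),
        n_deleted=int(deleted.sum()),
        failed_volume=failed_volume,
        crush_fraction=crush,
        components=components,
        initiation_components=n_init_comp,
        omega=omega,
        damage=np.asarray(damage, dtype=float),
        deleted=deleted,
    )
    report.validate()
    return report
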