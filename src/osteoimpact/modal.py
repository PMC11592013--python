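"""Linear-elastic verification operations: modal analysis and small statics.

The dynamic model is verified the way head/impact models are in practice —
by its lowest natural frequencies.  Here the assembled linear stiffness
(same B-bar kernels as the explicit solver) and the lumped mass matrix form
the generalized eigenproblem ``K phi = (2 pi f)^2 M phi``, checked in the
tests against closed-form beam frequencies.  A small linear static solve on
the same stiffness supports mesh-convergence checks against thin-plate
theory.  Both are meant for small models (<= ~1e4 DOF).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh
from .solver import _groups_for, lumped_mass_from_groups

__all__ = ["assemble_stiffness", "modal_frequencies", "static_displacement"]


def assemble_stiffness(mesh: Mesh, materials: dict) -> sp.csr_matrix:
    """Assembled linear-elastic stiffness (3n x 3n, CSR)."""
    nn3 = 3 * mesh.n_nodes
    rows, cols, vals = [], [], []
    for g in _groups_for(mesh, materials):
        c = g.card.elastic.stiffness_matrix()
        ke = np.einsum("egik,ij,egjl,eg->ekl", g.bbar, c, g.bbar, g.weights, optimize=True)
        nd = g.dofs.shape[1]
        rows.append(np.repeat(g.dofs, nd, axis=1).ravel())
        cols.append(np.tile(g.dofs, (1, nd)).ravel())
        vals.append(ke.ravel())
    k = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(nn3, nn3)
    )
    return k.tocsr()


def _free_dofs(mesh: Mesh, fixed_set: str | None) -> np.ndarray:
    free = np.ones(3 * mesh.n_nodes, dtype=bool)
    if fixed_set is not None and fixed_set in mesh.node_sets:
        ids = mesh.node_sets[fixed_set]
        free[(3 * ids[:, None] + np.arange(3)).ravel()] = False
    return np.nonzero(free)[0]


def modal_frequencies(mesh: Mesh, materials: dict, fixed_set: str | None = "fixed", k: int = 6) -> np.ndarray:
    """Lowest ``k`` natural frequencies (Hz), ascending.

    An unconstrained model simply reports its (near-zero) rigid-body
    frequencies among the results rather than failing.
    """
    kmat = assemble_stiffness(mesh, materials)
    m = lumped_mass_from_groups(_groups_for(mesh, materials), mesh.n_nodes)
    mvec = np.repeat(m, 3)
    free = _free_dofs(mesh, fixed_set)
    kf = kmat[np.ix_(free, free)]
    mf = sp.diags(mvec[free]).tocsc()
    # Small negative shift keeps the factorization nonsingular for free bodies.
    scale = kf.diagonal().mean()
    vals = spla.eigsh(
        kf.tocsc(), k=min(k, free.size - 1), M=mf, sigma=-1e-6 * scale, return_eigenvectors=False
    )
    vals = np.sort(np.clip(vals, 0.0, None))[:k]
    return np.sqrt(vals) / (2.0 * np.pi)


def static_displacement(mesh: Mesh, materials: dict, loads: np.ndarray, fixed_set: str = "fixed") -> np.ndarray:
    """Linear static displacement field under nodal loads (verification aid)."""
    kmat = assemble_stiffness(mesh, materials)
    free = _free_dofs(mesh, fixed_set)
    f = np.asarray(loads, dtype=float).reshape(-1)
    u = np.zeros(3 * mesh.n_nodes)
    u[free] = spla.spsolve(kmat[np.ix_(free, free)].tocsc(), f[free])
    return u.reshape(-1, 3)
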