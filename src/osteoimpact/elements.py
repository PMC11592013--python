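"""First-order solid element kernels (8-node hexahedron, 4-node tetrahedron).

The hexahedron uses full 2x2x2 Gauss quadrature for the deviatoric response
with a mean-dilatation (B-bar) treatment of the volumetric part, which
removes volumetric locking without introducing hourglass modes.  The
tetrahedron is the standard constant-strain element with a single
integration point.

All kernels are precomputed on the reference configuration (small-strain
formulation): for each element a strain-displacement matrix ``B`` of shape
(ngp, 6, 3*nen) and quadrature weights ``w = det(J) * w_gp`` are stored, so
per-step strain and internal-force evaluations are plain einsums.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "HEX_FACES",
    "TET_FACES",
    "hex_quadrature",
    "hex_operators",
    "tet_operators",
]

# VTK-ordered local faces.
HEX_FACES = np.array(
    [[0, 3, 2, 1], [4, 5, 6, 7], [0, 1, 5, 4], [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]]
)
TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])

_HEX_NAT = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


def hex_quadrature():
    """2x2x2 Gauss points and unit weights in the natural cube."""
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([[sx * g, sy * g, sz * g] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
    return pts, np.ones(8)


def _hex_dshape(natural: np.ndarray) -> np.ndarray:
    """Shape-function gradients dN/dxi at natural points; (ngp, 3, 8)."""
    xi, eta, zeta = natural[:, 0:1], natural[:, 1:2], natural[:, 2:3]
    a = _HEX_NAT
    d = np.empty((natural.shape[0], 3, 8))
    d[:, 0] = a[:, 0] * (1 + eta * a[:, 1]) * (1 + zeta * a[:, 2]) / 8.0
    d[:, 1] = a[:, 1] * (1 + xi * a[:, 0]) * (1 + zeta * a[:, 2]) / 8.0
    d[:, 2] = a[:, 2] * (1 + xi * a[:, 0]) * (1 + eta * a[:, 1]) / 8.0
    return d


def _b_from_grad(grad: np.ndarray) -> np.ndarray:
    """Assemble Voigt B matrices from shape gradients.

    grad : (..., 3, nen) physical gradients -> B : (..., 6, 3*nen) with row
    order [xx, yy, zz, xy, yz, zx] and engineering shear.
    """
    nen = grad.shape[-1]
    lead = grad.shape[:-2]
    b = np.zeros(lead + (6, 3 * nen))
    gx, gy, gz = grad[..., 0, :], grad[..., 1, :], grad[..., 2, :]
    b[..., 0, 0::3] = gx
    b[..., 1, 1::3] = gy
    b[..., 2, 2::3] = gz
    b[..., 3, 0::3] = gy
    b[..., 3, 1::3] = gx
    b[..., 4, 1::3] = gz
    b[..., 4, 2::3] = gy
    b[..., 5, 0::3] = gz
    b[..., 5, 2::3] = gx
    return b


def hex_operators(coords: np.ndarray):
    """Precompute B-bar operators for a batch of hexahedra.

    Parameters
    ----------
    coords : (ne, 8, 3) nodal coordinates in VTK order.

    Returns
    -------
    bbar : (ne, 8, 6, 24) strain-displacement matrices with the volumetric
        part replaced by its element mean.
    grad : (ne, 8, 3, 8) unbarred physical shape gradients (for spin).
    weights : (ne, 8) quadrature weights det(J)*w.
    volume : (ne,) element volumes.
    """
    pts, w = hex_quadrature()
    dnat = _hex_dshape(pts)  # (8gp, 3, 8)
    # Jacobian J[e,g,i,j] = sum_a dnat[g,i,a] coords[e,a,j]
    jac = np.einsum("gia,eaj->egij", dnat, coords)
    detj = np.linalg.det(jac)
    if np.any(detj <= 0):
        bad = np.unique(np.nonzero(detj <= 0)[0])
        raise ValueError(f"non-positive Jacobian in hex elements {bad[:10].tolist()}")
    jinv = np.linalg.inv(jac)
    grad = np.einsum("egji,gja->egia", jinv, dnat)  # physical dN/dx, (ne,8,3,8)
    weights = detj * w  # (ne, 8)
    volume = weights.sum(axis=1)

    b = _b_from_grad(grad)  # (ne, 8, 6, 24)
    # Volumetric row of B: vol[e,g,k] = dN_a/dx_j for dof k=(a,j)
    vol = b[:, :, 0, :] + b[:, :, 1, :] + b[:, :, 2, :]  # (ne, 8, 24)
    vol_mean = np.einsum("eg,egk->ek", weights, vol) / volume[:, None]
    corr = (vol_mean[:, None, :] - vol) / 3.0
    bbar = b.copy()
    bbar[:, :, 0, :] += corr
    bbar[:, :, 1, :] += corr
    bbar[:, :, 2, :] += corr
    return bbar, grad, weights, volume


def tet_operators(coords: np.ndarray):
    """Constant-strain operators for a batch of tetrahedra.

    Returns (b (ne, 1, 6, 12), grad (ne, 1, 3, 4), weights (ne, 1), volume (ne,)).
    """
    x = np.asarray(coords, dtype=float)
    d = x[:, 1:, :] - x[:, 0:1, :]  # (ne, 3, 3) edge vectors
    vol6 = np.linalg.det(d)
    if np.any(vol6 <= 0):
        bad = np.unique(np.nonzero(vol6 <= 0)[0])
        raise ValueError(f"non-positive volume in tet elements {bad[:10].tolist()}")
    volume = vol6 / 6.0
    # Barycentric coordinates satisfy x - x0 = d^T L, so grad_x L_a is the
    # a-th column of d^{-1}.
    dinv = np.linalg.inv(d)
    gradn = np.empty((x.shape[0], 3, 4))
    gradn[:, :, 1:] = dinv
    gradn[:, :, 0] = -gradn[:, :, 1:].sum(axis=2)
    grad = gradn[:, None, :, :]
    b = _b_from_grad(grad)
    weights = volume[:, None]
    return b, grad, weights, volume
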