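"""Trilinear 8-node hexahedron shape functions and quadrature helpers.

Node ordering follows the VTK hexahedron convention: nodes 0-3 are the
bottom face counterclockwise (viewed from +z for an axis-aligned element),
nodes 4-7 the top face in the same order.  Natural coordinates
(xi, eta, zeta) live in [-1, 1]^3.
"""

from __future__ import annotations

import numpy as np

# natural coordinates of the 8 corners, VTK order
HEX_NATURAL = np.array(
    [
        [-1.0, -1.0, -1.0],
        [1.0, -1.0, -1.0],
        [1.0, 1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
        [1.0, -1.0, 1.0],
        [1.0, 1.0, 1.0],
        [-1.0, 1.0, 1.0],
    ]
)

# faces of a hexahedron (outward for positive Jacobian elements)
HEX_FACES = np.array(
    [
        [0, 3, 2, 1],
        [4, 5, 6, 7],
        [0, 1, 5, 4],
        [1, 2, 6, 5],
        [2, 3, 7, 6],
        [3, 0, 4, 7],
    ]
)

_G = 1.0 / np.sqrt(3.0)
GAUSS_2x2x2 = HEX_NATURAL * _G  # (8, 3) Gauss points, unit weights


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """N_a(xi) for points xi of shape (..., 3) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    t = 1.0 + xi[..., None, :] * HEX_NATURAL  # (..., 8, 3)
    return 0.125 * t.prod(axis=-1)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at points xi of shape (..., 3) -> (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    t = 1.0 + xi[..., None, :] * HEX_NATURAL  # (..., 8, 3)
    g = np.empty(t.shape)
    g[..., 0] = HEX_NATURAL[:, 0] * t[..., 1] * t[..., 2]
    g[..., 1] = HEX_NATURAL[:, 1] * t[..., 0] * t[..., 2]
    g[..., 2] = HEX_NATURAL[:, 2] * t[..., 0] * t[..., 1]
    return 0.125 * g


# gradients at the element centre, shared by one-point integration
CENTER_GRADIENTS = shape_gradients(np.zeros(3))  # (8, 3)


def jacobians(elem_coords: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """dx/dxi for element corner coordinates (..., 8, 3) at one point xi -> (..., 3, 3)."""
    g = shape_gradients(xi)  # (8, 3)
    return np.einsum("...ai,aj->...ij", elem_coords, g)


def det_jacobians_at_gauss(elem_coords: np.ndarray) -> np.ndarray:
    """det(dx/dxi) at the 8 Gauss points; elem_coords (..., 8, 3) -> (..., 8)."""
    g = shape_gradients(GAUSS_2x2x2)  # (8, 8, 3): [gauss, node, comp]
    J = np.einsum("...ai,gaj->...gij", elem_coords, g)
    return np.linalg.det(J)


def hex_volumes(elem_coords: np.ndarray) -> np.ndarray:
    """Exact volumes of trilinear hexahedra via 2x2x2 Gauss quadrature."""
    return det_jacobians_at_gauss(elem_coords).sum(axis=-1)


def interpolate(elem_coords: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of nodal values at natural coordinates.

    elem_coords: (..., 8, k); xi: (..., 3) -> (..., k)
    """
    N = shape_functions(xi)  # (..., 8)
    return np.einsum("...a,...ak->...k", N, elem_coords)


def inverse_map(
    elem_coords: np.ndarray,
    points: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve of the inverse isoparametric map, batched.

    Parameters
    ----------
    elem_coords : (n, 8, 3) corner coordinates
    points : (n, 3) physical points, one per element row

    Returns
    -------
    xi : (n, 3) natural coordinates
    converged : (n,) bool
    """
    elem_coords = np.asarray(elem_coords, dtype=float)
    points = np.asarray(points, dtype=float)
    n = len(points)
    xi = np.zeros((n, 3))
    converged = np.zeros(n, dtype=bool)
    scale = np.maximum(
        np.linalg.norm(elem_coords.max(axis=1) - elem_coords.min(axis=1), axis=1),
        1e-30,
    )
    for _ in range(max_iter):
        r = interpolate(elem_coords, xi) - points  # (n, 3)
        res = np.linalg.norm(r, axis=1) / scale
        newly = res < tol
        converged |= newly
        active = ~converged
        if not active.any():
            break
        J = np.einsum(
            "nai,naj->nij", elem_coords[active], shape_gradients(xi[active])
        )
        dxi = np.linalg.solve(J, -r[active][..., None])[..., 0]
        xi[active] += dxi
    # final residual check
    r = interpolate(elem_coords, xi) - points
    converged = np.linalg.norm(r, axis=1) / scale < tol
    return xi, converged
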