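"""Shared finite-element machinery for tet4/tet10 meshes.

Sub-parametric geometry: element Jacobians come from the corner nodes,
which is exact for the straight-sided quadratic elements produced by
``MeshModel.to_quadratic``.  Stiffness integrands are quadratic for tet10,
so the 4-point Gauss rule used here integrates them exactly.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import MeshModel


class SolverError(RuntimeError):
    pass


class SingularSystemError(SolverError):
    pass


class BadMaterialError(SolverError):
    pass


# 4-point degree-2 Gauss rule on the reference tetrahedron (barycentric).
_A, _B = 0.5854101966249685, 0.1381966011250105
TET_QP = np.array([
    [_A, _B, _B, _B],
    [_B, _A, _B, _B],
    [_B, _B, _A, _B],
    [_B, _B, _B, _A],
])
TET_QW = np.full(4, 0.25)


def grad_barycentric(mesh: MeshModel) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the barycentric coordinates and element volumes.

    Returns (n_el, 4, 3) gradients and (n_el,) volumes (mm^3).
    """
    p = mesh.nodes[mesh.elements[:, :4]]
    T = (p[:, 1:] - p[:, :1]).transpose(0, 2, 1)     # columns e1,e2,e3
    det = np.linalg.det(T)
    if np.any(det <= 0):
        raise SolverError("non-positive element Jacobian")
    Tinv = np.linalg.inv(T)
    g123 = Tinv                                       # row i = grad lambda_{i+1}
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), det / 6.0


def shape_gradients(mesh: MeshModel):
    """Physical shape-function gradients at quadrature points.

    Returns (grads, weights_x_vol):
      grads : (n_qp, n_el, n_basis, 3)
      wvol  : (n_qp, n_el) quadrature weight times element volume
    tet4 uses a single point (constant gradients).
    """
    gl, vol = grad_barycentric(mesh)
    if mesh.order == 1:
        return gl[None], vol[None]
    grads = np.empty((len(TET_QP), mesh.n_elements, 10, 3))
    for q, lam in enumerate(TET_QP):
        g = np.empty((mesh.n_elements, 10, 3))
        for i in range(4):
            g[:, i] = (4.0 * lam[i] - 1.0) * gl[:, i]
        from .mesh import TET10_EDGE_NODES
        for (i, j), a in TET10_EDGE_NODES.items():
            g[:, a] = 4.0 * (lam[j] * gl[:, i] + lam[i] * gl[:, j])
        grads[q] = g
    wvol = TET_QW[:, None] * vol[None, :]
    return grads, wvol


def _coo_from_dense_blocks(ke: np.ndarray, dofs: np.ndarray, n_dof: int) -> sp.csr_matrix:
    """Scatter per-element dense blocks ke (n_el, m, m) into a sparse matrix."""
    m = ke.shape[1]
    rows = np.repeat(dofs, m, axis=1).ravel()
    cols = np.tile(dofs, (1, m)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()


def assemble_elasticity(mesh: MeshModel, E: np.ndarray, nu: np.ndarray) -> sp.csr_matrix:
    """Global stiffness for isotropic small-strain elasticity (E in MPa)."""
    E = np.asarray(E, dtype=float)
    nu = np.broadcast_to(np.asarray(nu, dtype=float), E.shape)
    if np.any(~np.isfinite(E)) or np.any(E <= 0):
        raise BadMaterialError("element Young's modulus must be positive and finite")
    if np.any(nu <= -1) or np.any(nu >= 0.5):
        raise BadMaterialError("Poisson ratio out of (-1, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))

    grads, wvol = shape_gradients(mesh)
    n_basis = grads.shape[2]
    n_el = mesh.n_elements
    ke = np.zeros((n_el, n_basis * 3, n_basis * 3))
    eye = np.eye(3)
    for q in range(grads.shape[0]):
        g = grads[q]                      # (n_el, nb, 3)
        w = wvol[q]
        # K[a i, b j] = lam g_ai g_bj + mu g_aj g_bi + mu d_ij (g_a . g_b)
        t1 = np.einsum("e,eai,ebj->eaibj", lam * w, g, g)
        t2 = np.einsum("e,eaj,ebi->eaibj", mu * w, g, g)
        dot = np.einsum("eak,ebk->eab", g, g)
        t3 = np.einsum("e,eab,ij->eaibj", mu * w, dot, eye)
        ke += (t1 + t2 + t3).reshape(n_el, n_basis * 3, n_basis * 3)
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(n_el, -1)
    return _coo_from_dense_blocks(ke, dofs, 3 * mesh.n_nodes)


def assemble_scalar_diffusion(mesh: MeshModel, tensor: np.ndarray) -> sp.csr_matrix:
    """Global matrix for div(beta grad phi) with per-element SPD 3x3 tensors."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape == (3, 3):
        tensor = np.broadcast_to(tensor, (mesh.n_elements, 3, 3))
    grads, wvol = shape_gradients(mesh)
    n_el, n_basis = mesh.n_elements, grads.shape[2]
    ke = np.zeros((n_el, n_basis, n_basis))
    for q in range(grads.shape[0]):
        g = grads[q]
        ke += np.einsum("e,eai,eij,ebj->eab", wvol[q], g, tensor, g)
    return _coo_from_dense_blocks(ke, mesh.elements, mesh.n_nodes)


def traction_load(mesh: MeshModel, facet_pairs: np.ndarray, force: np.ndarray) -> np.ndarray:
    """Nodal load vector for a total force spread uniformly over a patch.

    The resultant equals ``force`` exactly.  tet4 facets: area/3 per corner;
    tet10 facets: the consistent uniform-traction loads of the quadratic
    triangle (zero at corners, area/3 at midsides).
    """
    if len(facet_pairs) == 0:
        raise SolverError("empty load patch")
    areas, _ = mesh.facet_areas_normals(facet_pairs)
    total = areas.sum()
    traction = np.asarray(force, dtype=float) / total
    f = np.zeros((mesh.n_nodes, 3))
    nodes = mesh.facet_all_nodes(facet_pairs)
    if mesh.order == 1:
        w = np.repeat(areas[:, None] / 3.0, 3, axis=1)
    else:
        w = np.hstack([np.zeros((len(areas), 3)), np.repeat(areas[:, None] / 3.0, 3, axis=1)])
    np.add.at(f, nodes.ravel(), np.outer(w.ravel(), traction))
    return f.ravel()


def solve_dirichlet(K: sp.csr_matrix, f: np.ndarray, fixed_dofs: np.ndarray,
                    fixed_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve K u = f with prescribed dofs; returns (u, reactions at fixed dofs).

    Uses a direct sparse LU factorization of the free-free block and checks
    the relative residual to 1e-8.
    """
    n = K.shape[0]
    fixed_dofs = np.asarray(fixed_dofs, dtype=np.int64)
    if len(fixed_dofs) == 0:
        raise SingularSystemError("no Dirichlet constraints: singular system")
    free = np.setdiff1d(np.arange(n), fixed_dofs)
    u = np.zeros(n)
    u[fixed_dofs] = fixed_vals
    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, fixed_dofs] @ u[fixed_dofs]
    try:
        lu = spla.splu(Kff)
        uf = lu.solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - singular factorization
        raise SingularSystemError(str(exc)) from exc
    if not np.all(np.isfinite(uf)):
        raise SingularSystemError("solution contains non-finite entries")
    scale = max(np.linalg.norm(rhs), np.linalg.norm(Kff @ uf), 1e-300)
    resid = np.linalg.norm(Kff @ uf - rhs) / scale
    if resid > 1e-8:
        raise SolverError(f"linear solve residual {resid:.2e} exceeds 1e-8")
    u[free] = uf
    reactions = (K @ u - f)[fixed_dofs]
    return u, reactions
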