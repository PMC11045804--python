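"""Shared P1 finite-element kernels on tetrahedral meshes.

All routines are vectorized over elements and operate on plain numpy
arrays: ``pts`` is ``(n_pts, 3)`` float64, ``tets`` is ``(n_tets, 4)``
int, ``tris`` is ``(n_tris, 3)`` int.  Indices are 0-based.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "tet_volumes",
    "tet_grads",
    "signed_surface_volume",
    "facet_areas_normals",
    "surface_integral_p1",
    "stiffness_matrix",
    "lumped_mass",
    "scaled_jacobians",
    "recover_vertex_gradient",
    "vertex_normals",
    "boundary_vertex_ids",
    "point_triangle_distance",
    "SolverError",
]


class SolverError(RuntimeError):
    """Raised when an iterative linear solve fails to converge."""


def tet_volumes(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of all tetrahedra (positive for right-handed ordering)."""
    v0 = pts[tets[:, 0]]
    e1 = pts[tets[:, 1]] - v0
    e2 = pts[tets[:, 2]] - v0
    e3 = pts[tets[:, 3]] - v0
    return np.einsum("ij,ij->i", np.cross(e1, e2), e3) / 6.0


def tet_grads(pts: np.ndarray, tets: np.ndarray):
    """Volumes and P1 basis gradients.

    Returns ``(vol, grads)`` where ``vol`` is ``(n_tets,)`` signed volumes
    and ``grads`` is ``(n_tets, 4, 3)``: the constant gradient of each of
    the four barycentric basis functions.
    """
    v0 = pts[tets[:, 0]]
    e1 = pts[tets[:, 1]] - v0
    e2 = pts[tets[:, 2]] - v0
    e3 = pts[tets[:, 3]] - v0
    # rows of J map reference simplex edges to physical edges
    J = np.stack([e1, e2, e3], axis=1)  # (M,3,3)
    detJ = np.einsum("ij,ij->i", np.cross(e1, e2), e3)
    vol = detJ / 6.0
    Jinv = np.linalg.inv(J)  # (M,3,3); columns are grad(lambda_1..3)
    g = np.transpose(Jinv, (0, 2, 1))  # (M,3,3): g[:,k,:] = grad lambda_{k+1}
    g0 = -g.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g], axis=1)  # (M,4,3)
    return vol, grads


def signed_surface_volume(pts: np.ndarray, tris: np.ndarray) -> float:
    """Divergence-theorem volume of a closed triangulated surface.

    ``V = (1/3) * sum_f (x_c . n) * area`` with outward orientation;
    negative result signals inward orientation.
    """
    a = pts[tris[:, 0]]
    b = pts[tris[:, 1]]
    c = pts[tris[:, 2]]
    # (x_c . n)*area = (a+b+c)/3 . cross(b-a, c-a)/2
    n2 = np.cross(b - a, c - a)
    xc = (a + b + c) / 3.0
    return float(np.einsum("ij,ij->i", xc, n2).sum() / 6.0)


def facet_areas_normals(pts: np.ndarray, tris: np.ndarray):
    """Areas and unit normals of triangular facets (orientation as stored)."""
    a = pts[tris[:, 0]]
    n2 = np.cross(pts[tris[:, 1]] - a, pts[tris[:, 2]] - a)
    areas = 0.5 * np.linalg.norm(n2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = n2 / (2.0 * areas[:, None])
    normals[areas == 0.0] = 0.0
    return areas, normals


def surface_integral_p1(pts, tris, vertex_values) -> float:
    """Integral over a triangulated surface of a P1 scalar field (exact)."""
    areas, _ = facet_areas_normals(pts, tris)
    vals = vertex_values[tris].mean(axis=1)
    return float((areas * vals).sum())


def stiffness_matrix(pts, tets, coeff=None) -> sp.csr_matrix:
    """Scalar P1 stiffness matrix ``K_ab = sum_e coeff_e vol_e g_a.g_b``.

    ``coeff`` is a per-element scalar (default 1).
    """
    vol, grads = tet_grads(pts, tets)
    if np.any(vol <= 0):
        raise ValueError("stiffness_matrix: mesh contains inverted or flat elements")
    w = vol if coeff is None else vol * np.asarray(coeff)
    ke = np.einsum("e,eak,ebk->eab", w, grads, grads)  # (M,4,4)
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(len(pts), len(pts)))
    return K.tocsr()


def lumped_mass(pts, tets) -> np.ndarray:
    """Row-sum lumped mass: vertex weight = sum of vol/4 of adjacent tets."""
    vol = np.abs(tet_volumes(pts, tets))
    m = np.zeros(len(pts))
    np.add.at(m, tets.reshape(-1), np.repeat(vol / 4.0, 4))
    return m


def scaled_jacobians(pts, tets) -> np.ndarray:
    """Per-element shape quality in (0, 1]; <=0 marks inverted elements.

    Defined as signed volume normalized by the volume of a regular tet
    with the same RMS edge length.
    """
    vol = tet_volumes(pts, tets)
    p = pts[tets]  # (M,4,3)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    e2 = np.stack(
        [((p[:, i] - p[:, j]) ** 2).sum(axis=1) for i, j in pairs], axis=1
    )
    l_rms = np.sqrt(e2.mean(axis=1))
    v_reg = l_rms**3 / (6.0 * np.sqrt(2.0))
    return vol / v_reg


def recover_vertex_gradient(pts, tets, vertex_values) -> np.ndarray:
    """Volume-weighted recovery of the gradient of P1 fields to vertices.

    ``vertex_values`` is ``(n_pts,)`` or ``(n_pts, m)``; the result has one
    3-vector per vertex per field column.
    """
    vals = np.atleast_2d(vertex_values.T).T  # (n_pts, m)
    vol, grads = tet_grads(pts, tets)
    vol = np.abs(vol)
    # element gradient of each field: (M, m, 3)
    ge = np.einsum("eak,eam->emk", grads, vals[tets])
    acc = np.zeros((len(pts), vals.shape[1], 3))
    w = np.zeros(len(pts))
    for a in range(4):
        np.add.at(acc, tets[:, a], ge * vol[:, None, None])
        np.add.at(w, tets[:, a], vol)
    out = acc / w[:, None, None]
    if vertex_values.ndim == 1:
        return out[:, 0, :]
    return out


def vertex_normals(pts, tris, n_pts=None) -> np.ndarray:
    """Area-weighted outward unit normals at the vertices of a facet set."""
    if n_pts is None:
        n_pts = len(pts)
    areas, normals = facet_areas_normals(pts, tris)
    acc = np.zeros((n_pts, 3))
    for a in range(3):
        np.add.at(acc, tris[:, a], normals * areas[:, None])
    nrm = np.linalg.norm(acc, axis=1)
    mask = nrm > 0
    acc[mask] /= nrm[mask, None]
    return acc


def boundary_vertex_ids(tris) -> np.ndarray:
    return np.unique(tris.reshape(-1))


def point_triangle_distance(points, tri_a, tri_b, tri_c) -> np.ndarray:
    """Minimum distance from each point to a set of triangles.

    ``points`` is ``(P,3)``, triangle vertex arrays are ``(T,3)``.
    Memory use is O(P*T) per chunk; the caller sees a flat (P,) result.
    """
    P = len(points)
    out = np.full(P, np.inf)
    chunk = max(1, int(4e6 // max(len(tri_a), 1)))
    for s in range(0, P, chunk):
        p = points[s : s + chunk][:, None, :]  # (p,1,3)
        d2 = _pt_tri_sqdist(p, tri_a[None], tri_b[None], tri_c[None])
        out[s : s + chunk] = np.sqrt(d2.min(axis=1))
    return out


def _pt_tri_sqdist(p, a, b, c):
    # Ericson's real-time-collision-detection region test, vectorized.
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...k,...k->...", ab, ap)
    d2 = np.einsum("...k,...k->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...k,...k->...", ab, bp)
    d4 = np.einsum("...k,...k->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...k,...k->...", ab, cp)
    d6 = np.einsum("...k,...k->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.clip(vb / denom, 0.0, 1.0)
        w = np.clip(vc / denom, 0.0, 1.0)
    v = np.nan_to_num(v)
    w = np.nan_to_num(w)
    closest = a + v[..., None] * ab + w[..., None] * ac

    # vertex regions
    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    t_ab = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
    reg_ab = (~reg_a) & (~reg_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t_ac = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0)
    reg_ac = (~reg_a) & (~reg_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    t_bc = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
    reg_bc = (~reg_b) & (~reg_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    closest = np.where(reg_bc[..., None], b + np.clip(t_bc, 0, 1)[..., None] * (c - b), closest)
    closest = np.where(reg_ac[..., None], a + np.clip(t_ac, 0, 1)[..., None] * ac, closest)
    closest = np.where(reg_ab[..., None], a + np.clip(t_ab, 0, 1)[..., None] * ab, closest)
    closest = np.where(reg_c[..., None], c, closest)
    closest = np.where(reg_b[..., None], b, closest)
    closest = np.where(reg_a[..., None], a, closest)
    diff = p - closest
    return np.einsum("...k,...k->...", diff, diff)


def cg_solve(A, b, tol=1e-9, maxiter=None):
    """Jacobi-preconditioned CG for SPD systems; raises on non-convergence."""
    d = A.diagonal()
    M = sp.diags(1.0 / np.where(d != 0, d, 1.0))
    x, info = spla.cg(A, b, rtol=tol, maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300)
        raise SolverError(f"CG failed to converge (info={info}, rel. residual={res:.3e})")
    return x
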