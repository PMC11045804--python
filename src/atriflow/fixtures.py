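"""Analytic mesh fixtures: boxes, tubes, icospheres.

These meshes have known closed forms (volumes, flow solutions, centerline
lengths) and back the verification suite and the solver benchmarks.  They
are also the building blocks for the appendage-tube geometries used to
validate the centerline extractor.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

__all__ = [
    "boundary_faces",
    "orient_tets",
    "box_mesh",
    "icosphere",
    "tube_mesh",
    "straight_tube_chamber",
    "laa_tube_chamber",
]


def orient_tets(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Reorder tet vertices so all signed volumes are positive."""
    from ._fem import tet_volumes

    tets = tets.copy()
    neg = tet_volumes(pts, tets) < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    return tets


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a positively-oriented tet mesh.

    Faces are emitted with the vertex order induced by the tet (normal
    pointing away from the interior vertex).
    """
    # local faces with outward orientation for a positive tet (0,1,2,3)
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local].reshape(-1, 3)  # (4M, 3)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_s = key[order]
    dup = np.zeros(len(key_s), dtype=bool)
    same = (key_s[1:] == key_s[:-1]).all(axis=1)
    dup[1:] |= same
    dup[:-1] |= same
    keep = order[~dup]
    return faces[keep]


# ----------------------------------------------------------------------
# box
# ----------------------------------------------------------------------

_KUHN_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 7, 5],
        [0, 5, 7, 4],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
    ]
)


def box_mesh(lengths=(1.0, 1.0, 1.0), divisions=(4, 4, 4)):
    """Structured tet mesh of an axis-aligned box (6 tets per cube).

    Returns ``(pts, tets)``; use :func:`boundary_faces` for the surface.
    """
    nx, ny, nz = divisions
    lx, ly, lz = lengths
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corners = np.stack(
        [
            vid(I, J, K),
            vid(I + 1, J, K),
            vid(I, J + 1, K),
            vid(I + 1, J + 1, K),
            vid(I, J, K + 1),
            vid(I + 1, J, K + 1),
            vid(I, J + 1, K + 1),
            vid(I + 1, J + 1, K + 1),
        ],
        axis=1,
    )  # (ncubes, 8)
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)
    return pts, orient_tets(pts, tets)


# ----------------------------------------------------------------------
# icosphere
# ----------------------------------------------------------------------

def icosphere(radius=1.0, refinements=3, center=(0.0, 0.0, 0.0)):
    """Triangulated sphere surface by icosahedron subdivision.

    Returns ``(pts, tris)`` with outward-oriented triangles.
    """
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(refinements):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = vlist[a] + vlist[b]
                m = m / np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces)
    pts = verts * radius + np.asarray(center, dtype=float)
    return pts, faces


# ----------------------------------------------------------------------
# tube along a curve
# ----------------------------------------------------------------------

def _disk_template(radius, n_rad):
    """2D points and triangles of a disk (center + concentric rings)."""
    from scipy.spatial import Delaunay

    pts2 = [np.zeros((1, 2))]
    for j in range(1, n_rad + 1):
        r = radius * j / n_rad
        n_j = 6 * j
        th = 2 * np.pi * np.arange(n_j) / n_j + (0.5 * np.pi * j / n_rad)
        pts2.append(np.stack([r * np.cos(th), r * np.sin(th)], axis=1))
    pts2 = np.concatenate(pts2)
    tris = Delaunay(pts2).simplices
    outer_start = len(pts2) - 6 * n_rad
    outer_ids = np.arange(outer_start, len(pts2))
    return pts2, tris, outer_ids


def _split_prism(prism):
    """Dompierre-style conforming split of a triangular prism into 3 tets.

    ``prism`` = (b0,b1,b2,t0,t1,t2) global vertex ids with vertical edges
    bi-ti.  Diagonal choices depend only on global ids, so shared quad
    faces of neighbouring prisms agree.
    """
    rot = [
        (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
        (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
    ]
    imin = int(np.argmin(prism))
    perm = next(r for r in rot if r[0] == imin)
    v = [prism[i] for i in perm]
    if min(v[1], v[5]) < min(v[2], v[4]):
        tets = [(v[0], v[1], v[2], v[5]), (v[0], v[1], v[5], v[4]), (v[0], v[4], v[5], v[3])]
    else:
        tets = [(v[0], v[1], v[2], v[4]), (v[0], v[4], v[2], v[5]), (v[0], v[4], v[5], v[3])]
    return tets


def tube_mesh(curve_points, radius, n_rad=3, cap_rings=None):
    """Structured tet mesh of a tube swept along a polyline centerline.

    Cross-sections are identical disks placed with parallel-transported
    frames.  Returns ``(pts, tets, disks)`` where ``disks`` is a list of
    per-section vertex-id arrays (``disks[k][0]`` is the section center).
    """
    curve = np.asarray(curve_points, dtype=float)
    if len(curve) < 2:
        raise GeometryError("tube centerline needs at least 2 points")
    pts2, tris2, outer_ids = _disk_template(radius, n_rad)
    n_disk = len(pts2)

    # parallel-transported frames
    tangents = np.gradient(curve, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = np.cross(t0, ref)
    n0 /= np.linalg.norm(n0)
    frames = [(n0, np.cross(t0, n0))]
    for k in range(1, len(curve)):
        n_prev = frames[-1][0]
        t = tangents[k]
        n = n_prev - np.dot(n_prev, t) * t
        n /= np.linalg.norm(n)
        frames.append((n, np.cross(t, n)))

    pts = []
    disks = []
    for k, (c, (e1, e2)) in enumerate(zip(curve, frames)):
        sec = c + pts2[:, 0:1] * e1 + pts2[:, 1:2] * e2
        disks.append(np.arange(len(sec)) + k * n_disk)
        pts.append(sec)
    pts = np.concatenate(pts)

    tets = []
    for k in range(len(curve) - 1):
        off0, off1 = k * n_disk, (k + 1) * n_disk
        for a, b, c in tris2:
            tets.extend(_split_prism((a + off0, b + off0, c + off0, a + off1, b + off1, c + off1)))
    tets = orient_tets(pts, np.array(tets, dtype=int))
    from ._fem import tet_volumes

    if np.any(tet_volumes(pts, tets) <= 0):
        raise GeometryError("tube mesh contains degenerate elements")
    return pts, tets, disks


def _tube_chamber(curve, radius, n_rad, ostium_index):
    """Build a ChamberGeometry from a swept tube.

    The first cross-section cap is tagged MV, everything else WALL; the
    region beyond section ``ostium_index`` is tagged as the appendage and
    the outer ring of that section is the ostium ring.
    """
    from .cohort import ChamberGeometry, TAG_MV, TAG_WALL

    pts, tets, disks = tube_mesh(curve, radius, n_rad=n_rad)
    tris = boundary_faces(tets)
    n_disk = len(disks[0])
    # cap facets: all three vertices on the first section
    on_cap0 = np.isin(tris, disks[0]).all(axis=1)
    tags = np.full(len(tris), TAG_WALL, dtype=int)
    tags[on_cap0] = TAG_MV

    first_beyond = disks[ostium_index][0]
    # appendage cells: every vertex lies in a section at or beyond the ostium
    laa_cells = np.nonzero((tets >= first_beyond).all(axis=1))[0]
    wall_vids = np.unique(tris[tags == TAG_WALL].reshape(-1))
    laa_wall = wall_vids[wall_vids >= first_beyond + n_disk]  # strictly beyond the ring section
    # ostium ring: the outer ring of the ostium section, ordered by construction
    outer_count = 6 * _n_rad_of(n_disk)
    ring = disks[ostium_index][n_disk - outer_count :]
    return ChamberGeometry(
        vertices=pts,
        tetrahedra=tets,
        boundary_facets=tris,
        facet_tags=tags,
        laa_wall_vertices=laa_wall,
        laa_cells=laa_cells,
        ostium_ring=ring,
    )


def _n_rad_of(n_disk):
    # n_disk = 1 + sum_{j=1..n} 6j = 1 + 3n(n+1)
    n = 1
    while 1 + 3 * n * (n + 1) < n_disk:
        n += 1
    return n


def straight_tube_chamber(length=0.03, radius=0.006, n_axial=12, n_rad=3, stub=2):
    """Straight-appendage fixture: short stub chamber + straight LAA tube."""
    z = np.linspace(0, length, n_axial + 1)
    curve = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
    return _tube_chamber(curve, radius, n_rad, ostium_index=stub)


def laa_tube_chamber(arc_radius=0.02, radius=0.005, arc_fraction=0.25, n_axial=16, n_rad=3, stub=2):
    """Bent-appendage fixture: LAA tube following a circular arc.

    ``arc_fraction=0.25`` gives a quarter circle beyond the stub, whose
    centerline tortuosity is analytically ``pi/(2*sqrt(2)) - 1``.
    """
    stub_len = 0.2 * arc_radius
    z_stub = np.linspace(-stub_len, 0.0, stub + 1)[:-1]
    stub_pts = np.stack([np.zeros_like(z_stub), np.zeros_like(z_stub), z_stub], axis=1)
    ang = np.linspace(0, 2 * np.pi * arc_fraction, n_axial + 1)
    arc = np.stack(
        [arc_radius * (1 - np.cos(ang)), np.zeros_like(ang), arc_radius * np.sin(ang)], axis=1
    )
    curve = np.concatenate([stub_pts, arc])
    return _tube_chamber(curve, radius, n_rad, ostium_index=stub)
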