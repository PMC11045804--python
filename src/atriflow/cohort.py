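"""Synthetic moving-chamber cohort generator.

Produces phenotype-parameterized "patients": a tagged tetrahedral chamber
mesh (wall, four inlet disks, one outlet disk, appendage pouch) plus
frame-wise boundary displacement fields following a prescribed periodic
volume waveform.  Control cases draw larger volumes / lower heart rates,
stroke cases smaller volumes / higher rates, with ejection-fraction ranges
that overlap between the groups by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Delaunay

from . import _fem
from .errors import GeometryError, InfeasibleMotionError, TopologyError
from .fixtures import orient_tets

__all__ = [
    "TAG_WALL", "TAG_PV1", "TAG_PV2", "TAG_PV3", "TAG_PV4", "TAG_MV",
    "TAG_LEGEND", "PV_TAGS",
    "GeometryParams", "PhenotypeParams", "ChamberGeometry", "FrameSet",
    "sample_cohort", "build_reference_mesh", "scale_to_volume",
    "volume_waveform", "frames_from_waveform", "centerline_fixture",
]

TAG_WALL, TAG_PV1, TAG_PV2, TAG_PV3, TAG_PV4, TAG_MV = 0, 1, 2, 3, 4, 5
PV_TAGS = (TAG_PV1, TAG_PV2, TAG_PV3, TAG_PV4)
TAG_LEGEND = {
    TAG_WALL: "WALL", TAG_PV1: "PV1", TAG_PV2: "PV2",
    TAG_PV3: "PV3", TAG_PV4: "PV4", TAG_MV: "MV",
}

ML = 1e-6  # m^3 per mL


# ----------------------------------------------------------------------
# parameter records
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryParams:
    """Constructive parameters of the synthetic chamber (SI units)."""

    chamber_semi_axes: tuple[float, float, float] = (0.030, 0.026, 0.024)
    pv_radius: float = 0.0065
    pv_length: float = 0.010
    mv_radius: float = 0.012
    laa_length: float = 0.020
    laa_radius: float = 0.009
    laa_bend_angle: float = 0.7
    target_edge_length: float = 0.004

    def __post_init__(self):
        ax = self.chamber_semi_axes
        if len(ax) != 3 or any(a <= 0 for a in ax):
            raise ValueError("chamber_semi_axes must be 3 positive lengths")
        for name in ("pv_radius", "pv_length", "mv_radius", "target_edge_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.laa_length < 0 or self.laa_radius < 0:
            raise ValueError("appendage dimensions must be >= 0")
        if self.laa_length > 0 and not (self.laa_radius < self.laa_length):
            raise ValueError("laa_radius must be smaller than laa_length")
        if not self.mv_radius < min(ax):
            raise ValueError("mv_radius must be smaller than the smallest semi-axis")

    @property
    def has_laa(self) -> bool:
        return self.laa_length > 0


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-case functional phenotype."""

    group: str
    v_max: float  # mL
    v_min: float  # mL
    bpm: float
    n_frames: int
    e_fraction: float
    seed: int

    def __post_init__(self):
        if self.group not in ("control", "stroke"):
            raise ValueError("group must be 'control' or 'stroke'")
        if not (0 < self.v_min <= self.v_max):
            raise ValueError("need 0 < v_min <= v_max")
        if self.bpm <= 0:
            raise ValueError("bpm must be > 0")
        if self.n_frames not in (25, 30, 40):
            raise ValueError("n_frames must be one of 25, 30, 40")
        if not (0 < self.e_fraction < 1):
            raise ValueError("e_fraction must lie in (0, 1)")

    @property
    def period(self) -> float:
        return 60.0 / self.bpm

    @property
    def stroke_volume(self) -> float:
        return self.v_max - self.v_min

    @property
    def ejection_fraction(self) -> float:
        return self.stroke_volume / self.v_max


@dataclass
class ChamberGeometry:
    """Tagged tetrahedral chamber mesh (reference configuration, meters)."""

    vertices: np.ndarray        # (N, 3)
    tetrahedra: np.ndarray      # (M, 4), positively oriented
    boundary_facets: np.ndarray  # (F, 3), outward oriented
    facet_tags: np.ndarray      # (F,)
    laa_wall_vertices: np.ndarray
    laa_cells: np.ndarray
    ostium_ring: np.ndarray     # ordered closed loop of vertex ids

    def facets_of(self, tag: int) -> np.ndarray:
        return self.boundary_facets[self.facet_tags == tag]

    @property
    def wall_vertex_ids(self) -> np.ndarray:
        return np.unique(self.facets_of(TAG_WALL).reshape(-1))

    def enclosed_volume_m3(self, displacement=None) -> float:
        pts = self.vertices if displacement is None else self.vertices + displacement
        return _fem.signed_surface_volume(pts, self.boundary_facets)


@dataclass
class FrameSet:
    """Frame-wise wall displacements over one period (meters)."""

    frame_times: np.ndarray          # (n_frames,)
    wall_vertex_ids: np.ndarray      # (W,)
    boundary_displacements: np.ndarray  # (n_frames, W, 3)
    period: float

    def full_displacement(self, frame: int, n_vertices: int) -> np.ndarray:
        d = np.zeros((n_vertices, 3))
        d[self.wall_vertex_ids] = self.boundary_displacements[frame]
        return d


# ----------------------------------------------------------------------
# cohort sampling
# ----------------------------------------------------------------------

_CONTROL = dict(v_max=(102.0, 140.0), ef=(0.28, 0.45), bpm=(50.3, 57.7))
_STROKE = dict(v_max=(50.0, 60.0), ef=(0.28, 0.45), bpm=(60.0, 76.0))
# EF is drawn from the SAME range for both groups (it does not separate
# them); the v_max gap alone guarantees stroke SV < control SV:
# 102 * 0.28 = 28.6 > 60 * 0.45 = 27.0


def _sample_case(group: str, index: int, cohort_seed: int) -> PhenotypeParams:
    rng = np.random.default_rng([int(cohort_seed), 0 if group == "control" else 1, index])
    rng_ranges = _CONTROL if group == "control" else _STROKE
    v_max = rng.uniform(*rng_ranges["v_max"])
    ef = rng.uniform(*rng_ranges["ef"])
    bpm = rng.uniform(*rng_ranges["bpm"])
    e_fraction = rng.uniform(0.50, 0.65)
    n_frames = 40 if bpm < 55 else (30 if bpm < 65 else 25)
    case_seed = int(rng.integers(0, 2**31 - 1))
    return PhenotypeParams(
        group=group, v_max=v_max, v_min=v_max * (1 - ef), bpm=bpm,
        n_frames=n_frames, e_fraction=e_fraction, seed=case_seed,
    )


def sample_cohort(n_control: int, n_stroke: int, seed: int) -> list[PhenotypeParams]:
    """Draw a reproducible synthetic cohort.

    Each case has its own random stream derived from ``(seed, group,
    index)``, so individual cases are reproducible independently of the
    cohort size.  The groups' EF intervals are guaranteed to intersect
    (a generator contract): in the rare draw where they do not, the
    closest case of one group is re-pinned into the other group's range.
    """
    if n_control < 0 or n_stroke < 0:
        raise ValueError("cohort counts must be >= 0")
    cases = [_sample_case("control", i, seed) for i in range(n_control)]
    cases += [_sample_case("stroke", i, seed) for i in range(n_stroke)]
    if n_control and n_stroke:
        cases = _enforce_ef_overlap(cases)
    return cases


def _enforce_ef_overlap(cases):
    efs = {g: [p.ejection_fraction for p in cases if p.group == g]
           for g in ("control", "stroke")}
    lo = max(min(efs["control"]), min(efs["stroke"]))
    hi = min(max(efs["control"]), max(efs["stroke"]))
    if lo <= hi:
        return cases
    # disjoint intervals: move the extreme case of the lower group up to
    # the midpoint of the higher group's interval (deterministic repair)
    low_g = "control" if max(efs["control"]) < min(efs["stroke"]) else "stroke"
    hi_g = "stroke" if low_g == "control" else "control"
    target = float(np.median(efs[hi_g]))
    idx = max(
        (i for i, p in enumerate(cases) if p.group == low_g),
        key=lambda i: cases[i].ejection_fraction,
    )
    p = cases[idx]
    cases[idx] = replace(p, v_min=p.v_max * (1 - target))
    return cases


# ----------------------------------------------------------------------
# reference mesh
# ----------------------------------------------------------------------

# port axes: four inlets high on the chamber, outlet at the bottom
_PV_AXES = np.array(
    [
        [np.sin(0.8) * np.cos(a), np.sin(0.8) * np.sin(a), np.cos(0.8)]
        for a in np.deg2rad([45.0, 135.0, 225.0, 315.0])
    ]
)
_MV_AXIS = np.array([0.0, 0.0, -1.0])
_LAA_AXIS_RAW = np.array([np.sin(1.40), 0.0, np.cos(1.40)])  # near-equatorial


def _ellipsoid_radius(dirs: np.ndarray, axes) -> np.ndarray:
    a, b, c = axes
    return 1.0 / np.sqrt(
        dirs[:, 0] ** 2 / a**2 + dirs[:, 1] ** 2 / b**2 + dirs[:, 2] ** 2 / c**2
    )


def _support_radius(dirs: np.ndarray, g: GeometryParams):
    """Support of the constructive solid, split into chamber and bump.

    Returns ``(r_cut, bump, theta_laa)``: the ellipsoid radius cut by one
    plane per port (flat inlet/outlet disks), and the C1 appendage bump
    height (zero outside the appendage cone).  The surface radius is
    ``r_cut + bump``.
    """
    r_cut = _ellipsoid_radius(dirs, g.chamber_semi_axes)
    theta_laa = 0.0
    bump = np.zeros(len(dirs))
    if g.has_laa:
        r_at_axis = _ellipsoid_radius(_LAA_AXIS_RAW[None], g.chamber_semi_axes)[0]
        theta_laa = 1.6 * g.laa_radius / r_at_axis
        cosang = np.clip(dirs @ _LAA_AXIS_RAW, -1, 1)
        ang = np.arccos(cosang)
        bump = (
            g.laa_length
            * np.clip((np.cos(ang) - np.cos(theta_laa)) / (1 - np.cos(theta_laa)), 0, None) ** 2
        )
    # plane cuts for the ports
    for axis, rad in list(zip(_PV_AXES, [g.pv_radius] * 4)) + [(_MV_AXIS, g.mv_radius)]:
        r_ax = _ellipsoid_radius(axis[None], g.chamber_semi_axes)[0]
        if rad >= r_ax:
            raise GeometryError("port radius exceeds the local chamber radius")
        h = np.sqrt(r_ax**2 - rad**2)
        proj = dirs @ axis
        with np.errstate(divide="ignore"):
            r_plane = np.where(proj > 1e-12, h / np.maximum(proj, 1e-12), np.inf)
        r_cut = np.minimum(r_cut, r_plane)
    return r_cut, bump, theta_laa


def _fibonacci_sphere(n: int, offset: float = 0.0) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    phi = np.pi * (1 + np.sqrt(5)) * i + offset
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def build_reference_mesh(g: GeometryParams) -> ChamberGeometry:
    """Build the tagged reference chamber mesh.

    A unit ball is tetrahedralized (Delaunay of concentric point shells)
    and mapped radially onto the constructive solid; the protruding
    appendage is then bent by ``laa_bend_angle`` about the ostium center.
    """
    axes = np.asarray(g.chamber_semi_axes)
    r_char = float(axes.mean())
    rel = g.target_edge_length / r_char
    n_shells = max(2, int(round(1.0 / rel)))
    pts = [np.zeros((1, 3))]
    for k in range(1, n_shells + 1):
        r = k / n_shells
        n_k = max(6, int(round(4 * np.pi * (r / rel) ** 2)))
        pts.append(r * _fibonacci_sphere(n_k, offset=0.7 * k))
    ball = np.concatenate(pts)
    outer_start = len(ball) - len(pts[-1])

    tri = Delaunay(ball)
    tets = orient_tets(ball, tri.simplices.astype(int))
    hull = tri.convex_hull.astype(int)
    # orient hull facets outward (star-shaped about the origin)
    a, b, c = ball[hull[:, 0]], ball[hull[:, 1]], ball[hull[:, 2]]
    outward = np.einsum("ij,ij->i", np.cross(b - a, c - a), (a + b + c)) > 0
    hull[~outward] = hull[~outward][:, [0, 2, 1]]

    # map: direction-dependent support radius + appendage bend
    rad = np.linalg.norm(ball, axis=1)
    dirs = np.where(rad[:, None] > 1e-12, ball / np.maximum(rad, 1e-12)[:, None], 0.0)
    dirs[rad <= 1e-12] = np.array([1.0, 0.0, 0.0])
    r_cut, bump, theta_laa = _support_radius(dirs, g)
    # bump applied with an s^3 radial profile: surface unchanged, interior
    # angular shear strongly reduced (avoids inverted elements)
    mapped = dirs * (rad * r_cut + rad**3 * bump)[:, None]
    boundary_ids = np.unique(hull.reshape(-1))
    mapped = _untangle_interior(mapped, tets, boundary_ids)

    laa_wall_vertices = np.array([], dtype=int)
    laa_cells = np.array([], dtype=int)
    ostium_ring = np.array([], dtype=int)
    in_cone = np.zeros(len(ball), dtype=bool)
    if g.has_laa:
        excess = rad**3 * bump  # protrusion beyond the un-bumped chamber
        cosang = np.clip(dirs @ _LAA_AXIS_RAW, -1, 1)
        in_cone = np.arccos(cosang) < theta_laa
        if g.laa_bend_angle != 0.0:
            bend_axis = np.array([0.0, 1.0, 0.0])  # perpendicular to the pouch axis
            pivot = _LAA_AXIS_RAW * _ellipsoid_radius(_LAA_AXIS_RAW[None], g.chamber_semi_axes)[0]
            q = excess / g.laa_length
            phi = g.laa_bend_angle * _smoothstep(q)  # gentle at base and tip
            sel = phi > 0
            p = mapped[sel] - pivot
            cph, sph = np.cos(phi[sel])[:, None], np.sin(phi[sel])[:, None]
            k = bend_axis
            kxp = np.cross(np.broadcast_to(k, p.shape), p)
            kdp = (p @ k)[:, None]
            mapped[sel] = pivot + p * cph + kxp * sph + k * kdp * (1 - cph)

    tags = _tag_facets(mapped, hull, g)
    mapped = _untangle_interior(mapped, tets, boundary_ids)
    # quality pass with tiny guarded moves of wall vertices (ports and
    # their rims stay pinned so tags and flat disks survive); protects
    # the worst slivers before any wall motion is applied downstream
    port_vids = np.unique(hull[tags != TAG_WALL].reshape(-1))
    movable = np.setdiff1d(boundary_ids, port_vids)
    mapped = _untangle_interior(
        mapped, tets, boundary_ids, sweeps=16, q_accept=0.08,
        movable_boundary=movable,
    )
    bad = _fem.tet_volumes(mapped, tets) <= 0
    if bad.any():
        raise GeometryError(
            f"{int(bad.sum())} inverted elements after mapping; reduce laa_bend_angle "
            "or laa_length relative to the chamber size"
        )

    if g.has_laa:
        laa_facets_mask = (tags == TAG_WALL) & in_cone[hull].all(axis=1)
        laa_facets_mask = _largest_facet_component(hull, laa_facets_mask)
        laa_facets_mask, ostium_ring = _ring_with_pinch_repair(hull, laa_facets_mask)
        laa_wall_vertices = np.unique(hull[laa_facets_mask].reshape(-1))
        cell_in = (in_cone[tets].all(axis=1)) & (excess[tets] > 0).any(axis=1)
        laa_cells = _largest_cell_component(tets, np.nonzero(cell_in)[0])

    geom = ChamberGeometry(
        vertices=mapped, tetrahedra=tets, boundary_facets=hull, facet_tags=tags,
        laa_wall_vertices=laa_wall_vertices, laa_cells=laa_cells, ostium_ring=ostium_ring,
    )
    _validate_geometry(geom, g)
    return geom


def _untangle_interior(pts, tets, boundary_ids, sweeps=8, q_accept=0.05,
                       movable_boundary=None):
    """Local Laplacian untangling of vertices near bad elements.

    Moves interior vertices freely; vertices listed in
    ``movable_boundary`` (wall vertices away from ports) may move with a
    strong damping, capped at a fraction of the local edge length.  Every
    move must improve the worst local element quality.
    """
    pts = pts.copy()
    n = len(pts)
    is_boundary = np.zeros(n, dtype=bool)
    is_boundary[boundary_ids] = True
    may_move_b = np.zeros(n, dtype=bool)
    if movable_boundary is not None:
        may_move_b[movable_boundary] = True
    # vertex -> incident tets
    incident: list[list[int]] = [[] for _ in range(n)]
    for e, tet in enumerate(tets):
        for v in tet:
            incident[v].append(e)
    # vertex -> neighbour vertices
    nbrs: list[set] = [set() for _ in range(n)]
    for tet in tets:
        for a in tet:
            nbrs[a].update(tet)
    for _ in range(sweeps):
        q = _fem.scaled_jacobians(pts, tets)
        bad_tets = np.nonzero(q < q_accept)[0]
        if len(bad_tets) == 0:
            break
        cand = np.unique(tets[bad_tets].reshape(-1))
        cand = cand[~is_boundary[cand] | may_move_b[cand]]
        moved = False
        for v in cand:
            old = pts[v].copy()
            others = [w for w in nbrs[v] if w != v]
            target = pts[others].mean(axis=0)
            loc = incident[v]
            q_best = _fem.scaled_jacobians(pts, tets[loc]).min()
            best = old
            alphas = (0.2, 0.1, 0.05) if is_boundary[v] else (1.0, 0.5, 0.25)
            if is_boundary[v]:
                # cap surface moves at a fraction of the local edge length
                lmin = min(np.linalg.norm(pts[w] - old) for w in others)
                step = target - old
                ns = np.linalg.norm(step)
                if ns > 0.5 * lmin:
                    target = old + step * (0.5 * lmin / ns)
            proposals = [old + alpha * (target - old) for alpha in alphas]
            # for inverted incident tets, also try the volume-gradient
            # direction (normal of the face opposite to v)
            lmin = min(np.linalg.norm(pts[w] - old) for w in others)
            for e in loc:
                if _fem.tet_volumes(pts, tets[e : e + 1])[0] <= 0:
                    opp = [w for w in tets[e] if w != v]
                    if len(opp) == 3:
                        nrm = np.cross(pts[opp[1]] - pts[opp[0]], pts[opp[2]] - pts[opp[0]])
                        nn = np.linalg.norm(nrm)
                        if nn > 0:
                            nrm /= nn
                            for beta in (0.3, 0.15):
                                proposals.append(old + beta * lmin * nrm)
                                proposals.append(old - beta * lmin * nrm)
            for prop in proposals:
                pts[v] = prop
                q_new = _fem.scaled_jacobians(pts, tets[loc]).min()
                if q_new > q_best:
                    q_best, best = q_new, pts[v].copy()
            pts[v] = best
            moved = moved or not np.array_equal(best, old)
        if not moved:
            break
    return pts


def _tag_facets(pts, hull, g: GeometryParams) -> np.ndarray:
    centroids = pts[hull].mean(axis=1)
    tags = np.full(len(hull), TAG_WALL, dtype=int)
    ports = [(ax, g.pv_radius, t) for ax, t in zip(_PV_AXES, PV_TAGS)]
    ports.append((_MV_AXIS, g.mv_radius, TAG_MV))
    for axis, rad, tag in ports:
        r_ax = _ellipsoid_radius(axis[None], g.chamber_semi_axes)[0]
        h = np.sqrt(r_ax**2 - rad**2)
        on_plane = centroids @ axis >= h * (1 - 1e-6)
        tags[on_plane] = tag
    return tags


def _region_boundary_loop(facets, mask) -> np.ndarray:
    """Ordered vertex loop separating a facet subset from its complement."""
    def edge_set(fs):
        e = np.concatenate([fs[:, [0, 1]], fs[:, [1, 2]], fs[:, [2, 0]]])
        return {tuple(sorted(p)) for p in e.tolist()}

    inside = edge_set(facets[mask])
    outside = edge_set(facets[~mask])
    border = inside & outside
    if not border:
        raise TopologyError("region boundary is empty; appendage tagging failed")
    adj: dict[int, list[int]] = {}
    for u, v in border:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    if any(len(nb) != 2 for nb in adj.values()):
        raise TopologyError("region boundary is not a single simple loop")
    start = next(iter(adj))
    loop = [start]
    prev, cur = None, start
    while True:
        nxt = [w for w in adj[cur] if w != prev]
        nxt = nxt[0] if nxt else prev
        if nxt == start:
            break
        loop.append(nxt)
        prev, cur = cur, nxt
        if len(loop) > len(adj) + 1:
            raise TopologyError("region boundary does not close into a loop")
    if len(loop) != len(adj):
        raise TopologyError("region boundary has more than one loop")
    return np.array(loop, dtype=int)


def _largest_facet_component(facets, mask):
    """Restrict a facet mask to its largest edge-connected component."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    ids = np.nonzero(mask)[0]
    if len(ids) == 0:
        raise TopologyError("appendage facet set is empty")
    sub = facets[ids]
    edges = {}
    for li, f in enumerate(sub):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = tuple(sorted((f[a], f[b])))
            edges.setdefault(key, []).append(li)
    rows, cols = [], []
    for fl in edges.values():
        for i in range(len(fl)):
            for j in range(i + 1, len(fl)):
                rows.append(fl[i])
                cols.append(fl[j])
    G = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids)))
    n_comp, labels = connected_components(G, directed=False)
    if n_comp > 1:
        keep = labels == np.bincount(labels).argmax()
        new_mask = np.zeros_like(mask)
        new_mask[ids[keep]] = True
        return new_mask
    return mask


def _ring_with_pinch_repair(facets, mask, max_repairs=20):
    """Boundary loop of a facet subset, shaving pinch facets if needed."""
    mask = mask.copy()
    for _ in range(max_repairs):
        try:
            return mask, _region_boundary_loop(facets, mask)
        except TopologyError:
            # find a pinch vertex (border-edge degree != 2) and remove one
            # of the subset facets incident to it
            sub = facets[mask]
            comp = facets[~mask]

            def edge_set(fs):
                e = np.concatenate([fs[:, [0, 1]], fs[:, [1, 2]], fs[:, [2, 0]]])
                return {tuple(sorted(p)) for p in e.tolist()}

            border = edge_set(sub) & edge_set(comp)
            deg: dict[int, int] = {}
            for u, v in border:
                deg[u] = deg.get(u, 0) + 1
                deg[v] = deg.get(v, 0) + 1
            pinch = [v for v, d in deg.items() if d != 2]
            if not pinch:
                raise
            target = pinch[0]
            cand = np.nonzero(mask & (facets == target).any(axis=1))[0]
            if len(cand) == 0:
                raise
            mask[cand[0]] = False
    raise TopologyError("could not repair the appendage boundary into a single loop")


def _largest_cell_component(tets, cell_ids):
    """Largest face-connected component of a tetrahedron subset."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    if len(cell_ids) == 0:
        raise TopologyError("appendage cell set is empty")
    sub = tets[cell_ids]
    faces = {}
    local_faces = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for li, tet in enumerate(sub):
        for fa in local_faces:
            key = tuple(sorted(int(tet[i]) for i in fa))
            faces.setdefault(key, []).append(li)
    rows, cols = [], []
    for fl in faces.values():
        if len(fl) == 2:
            rows.append(fl[0])
            cols.append(fl[1])
    G = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(sub), len(sub)))
    _, labels = connected_components(G, directed=False)
    keep = labels == np.bincount(labels).argmax()
    return cell_ids[keep]


def _validate_geometry(geom: ChamberGeometry, g: GeometryParams):
    vol = geom.enclosed_volume_m3()
    if vol <= 0:
        raise GeometryError("boundary surface is inward-oriented")
    # closed surface: every boundary edge shared by exactly 2 facets
    f = geom.boundary_facets
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise GeometryError("boundary surface is not closed")


def scale_to_volume(geom: ChamberGeometry, target_mL: float) -> ChamberGeometry:
    """Isotropically rescale a chamber so its enclosed volume is ``target_mL``."""
    if target_mL <= 0:
        raise ValueError("target volume must be positive")
    s = (target_mL * ML / geom.enclosed_volume_m3()) ** (1.0 / 3.0)
    return replace(geom, vertices=geom.vertices * s)


# ----------------------------------------------------------------------
# volume waveform
# ----------------------------------------------------------------------

def _wrapped_gaussian(t, center, width, period):
    acc = np.zeros_like(t)
    for k in (-1, 0, 1):
        acc += np.exp(-0.5 * ((t + k * period - center) / width) ** 2)
    return acc


@dataclass
class _WaveformShape:
    e_center: float = 0.14
    e_width: float = 0.055
    a_center: float = 0.40
    a_width: float = 0.05
    fill_center: float = 0.74
    fill_width: float = 0.11


def volume_waveform(p: PhenotypeParams, n_samples: int = 400):
    """Smooth periodic volume trace V(t) on one heartbeat.

    t = 0 is the volume maximum (outlet opening); emptying is biphasic
    (early fast decay, diastasis, late active contraction) with the early
    share of emptied volume equal to ``e_fraction``; filling restores the
    volume in the second half of the period.
    """
    from .functional import VolumeTrace

    if p.v_min > p.v_max:
        raise ValueError("v_min must not exceed v_max")
    T = p.period
    times = np.linspace(0.0, T, n_samples, endpoint=False)
    if p.v_max == p.v_min:
        return VolumeTrace(times=times, volumes=np.full(n_samples, p.v_max))

    sv = p.stroke_volume
    sh = _WaveformShape()
    fine = np.linspace(0.0, T, 4096, endpoint=False)
    dt = T / len(fine)

    def unit_bump(center, width):
        gb = _wrapped_gaussian(fine, center * T, width * T, T)
        return gb / (gb.sum() * dt)

    rate = (
        -p.e_fraction * sv * unit_bump(sh.e_center, sh.e_width)
        - (1 - p.e_fraction) * sv * unit_bump(sh.a_center, sh.a_width)
        + sv * unit_bump(sh.fill_center, sh.fill_width)
    )
    v = np.cumsum(rate) * dt
    v -= v.mean()
    # affine rescale so the extremes match the phenotype exactly
    v = p.v_min + (v - v.min()) * sv / (v.max() - v.min())
    vals = np.interp(times, fine, v, period=T)
    # snap the sampled extremes too (interp can miss the fine-grid peak)
    vals = p.v_min + (vals - vals.min()) * sv / (vals.max() - vals.min())
    return VolumeTrace(times=times, volumes=vals)


# ----------------------------------------------------------------------
# frames from waveform
# ----------------------------------------------------------------------

def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def _wall_motion_weights(geom: ChamberGeometry, taper: float = 0.35):
    """Per-wall-vertex radial-motion weight, tapering to 0 at port rims."""
    c = geom.vertices[geom.tetrahedra].mean(axis=(0, 1))
    wall_ids = geom.wall_vertex_ids
    x = geom.vertices[wall_ids] - c
    dirs = x / np.linalg.norm(x, axis=1)[:, None]
    w = np.ones(len(wall_ids))
    for tag in (*PV_TAGS, TAG_MV):
        pf = geom.facets_of(tag)
        if len(pf) == 0:
            continue
        port_vids = np.unique(pf.reshape(-1))
        pc = geom.vertices[port_vids] - c
        pdir = pc.mean(axis=0)
        pdir /= np.linalg.norm(pdir)
        ang_port = np.arccos(np.clip((pc / np.linalg.norm(pc, axis=1)[:, None]) @ pdir, -1, 1)).max()
        ang = np.arccos(np.clip(dirs @ pdir, -1, 1))
        w *= _smoothstep((ang - ang_port) / taper)
        w[np.isin(wall_ids, port_vids)] = 0.0
    return wall_ids, w, c


def frames_from_waveform(
    geom: ChamberGeometry, trace, p: PhenotypeParams, rtol: float = 1e-6
) -> FrameSet:
    """Radial-mode wall displacements matching the volume trace frame-wise.

    The wall moves radially about the chamber centroid with a smooth
    weight that vanishes on the inlet/outlet disks; the per-frame radial
    amplitude is solved so the enclosed volume matches the (relative)
    trace.  Frame 0 is the reference: zero displacement.
    """
    T = p.period
    n = p.n_frames
    frame_times = np.arange(n) * T / n
    targets_mL = np.interp(frame_times, trace.times, trace.volumes, period=T)
    v_ref = geom.enclosed_volume_m3()
    scale = v_ref / (targets_mL[0] * ML)
    if abs(scale - 1.0) > 0.01:
        raise InfeasibleMotionError(
            "reference mesh volume differs from trace(0) by more than 1%; "
            "use scale_to_volume first"
        )
    targets = targets_mL * ML * scale  # follow the relative waveform exactly

    wall_ids, w, c = _wall_motion_weights(geom, taper=0.35)
    radial = (geom.vertices[wall_ids] - c) * w[:, None]

    disps = np.zeros((n, len(wall_ids), 3))
    pts = geom.vertices

    def vol_at(lam):
        moved = pts.copy()
        moved[wall_ids] = pts[wall_ids] + lam * radial
        return _fem.signed_surface_volume(moved, geom.boundary_facets)

    lo, hi = -0.9, 1.5
    v_lo, v_hi = vol_at(lo), vol_at(hi)
    for i, tgt in enumerate(targets):
        if i == 0:
            continue  # reference frame, identically zero
        if not (min(v_lo, v_hi) <= tgt <= max(v_lo, v_hi)):
            raise InfeasibleMotionError(
                f"frame {i}: target volume {tgt / ML:.1f} mL outside the achievable "
                f"range [{min(v_lo, v_hi) / ML:.1f}, {max(v_lo, v_hi) / ML:.1f}] mL"
            )
        lam = brentq(lambda L: vol_at(L) - tgt, lo, hi, xtol=1e-12, rtol=rtol)
        disps[i] = lam * radial
    return FrameSet(
        frame_times=frame_times, wall_vertex_ids=wall_ids,
        boundary_displacements=disps, period=T,
    )


# ----------------------------------------------------------------------
# centerline fixtures
# ----------------------------------------------------------------------

def centerline_fixture(kind: str, scale: float, n_points: int):
    """Analytic polyline fixtures for the tortuosity operator."""
    from .functional import Centerline

    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    s = np.linspace(0.0, 1.0, n_points)
    if kind == "straight":
        pts = np.stack([scale * s, np.zeros_like(s), np.zeros_like(s)], axis=1)
    elif kind == "semicircle":
        ang = np.pi * s
        pts = np.stack([scale * np.cos(ang), scale * np.sin(ang), np.zeros_like(s)], axis=1)
    elif kind == "helix":
        ang = 2 * np.pi * s
        pts = np.stack([scale * np.cos(ang), scale * np.sin(ang), scale * s], axis=1)
    else:
        raise ValueError(f"unknown centerline kind: {kind!r}")
    return Centerline(points=pts)
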