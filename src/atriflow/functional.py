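"""Functional / morphological biomarkers of the moving chamber.

Volume extrema (stroke volume, ejection fraction), transmitral E/A-wave
analysis, appendage centerline + tortuosity, and ostium area, merged into
a per-case :class:`FunctionalSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks
from scipy.sparse.csgraph import dijkstra

from . import _fem
from .errors import TaggingError, TopologyError, WaveDetectionError

__all__ = [
    "VolumeTrace", "Centerline", "FunctionalSummary",
    "enclosed_volume", "volume_extrema", "ea_analysis",
    "tortuosity", "laa_centerline", "ostium_area", "functional_summary",
]

ML = 1e-6


@dataclass
class VolumeTrace:
    """Chamber volume versus time (volumes in mL)."""

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must have the same length")
        if len(self.times) and np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")


@dataclass
class Centerline:
    """Ordered polyline (meters)."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("consecutive centerline points must be distinct")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class FunctionalSummary:
    v_max: float            # mL
    v_min: float            # mL
    sv: float               # mL
    ef: float
    bpm: float
    period: float           # s
    ostium_area: float | None = None   # mm^2
    tortuosity: float | None = None
    e_peak: float | None = None        # mL/s
    a_peak: float | None = None        # mL/s
    ea_ratio: float | None = None


def enclosed_volume(pts: np.ndarray, tris: np.ndarray) -> float:
    """Divergence-theorem volume of a closed outward-oriented surface, in mL.

    Raises :class:`TopologyError` if the surface is open or oriented
    inward.
    """
    edges = np.sort(np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise TopologyError("surface is not closed (boundary edges present)")
    v = _fem.signed_surface_volume(pts, tris)
    if v <= 0:
        raise TopologyError("surface is inward-oriented (negative enclosed volume)")
    return v / ML


def volume_extrema(trace: VolumeTrace):
    """(v_max, v_min, sv, ef) over the final period of a volume trace."""
    if len(trace.times) == 0:
        raise ValueError("empty volume trace")
    v_max = float(trace.volumes.max())
    v_min = float(trace.volumes.min())
    sv = v_max - v_min
    ef = sv / v_max if v_max > 0 else 0.0
    return v_max, v_min, sv, ef


def ea_analysis(times, q_mv, open_interval, prominence_frac=0.05):
    """E/A-wave peaks of the transmitral flowrate over one period.

    ``open_interval = (t_open, t_close)``; peaks are prominence-filtered
    local maxima of the outflow within it: the first is the E-wave, the
    last the A-wave.
    """
    times = np.asarray(times, dtype=float)
    q = np.asarray(q_mv, dtype=float)
    t0, t1 = open_interval
    mask = (times >= t0) & (times <= t1)
    if mask.sum() < 5:
        raise WaveDetectionError("too few samples inside the open interval")
    qo = q[mask]
    qmax = qo.max()
    if qmax <= 0:
        raise WaveDetectionError("no outflow detected in the open interval")
    idx, _ = find_peaks(qo, prominence=prominence_frac * qmax)
    # a peak at the very start of the interval has no left neighbour
    if len(idx) < 2:
        raise WaveDetectionError(
            f"found {len(idx)} prominent outflow peaks; need at least 2 (E and A)"
        )
    e_peak = float(qo[idx[0]])
    a_peak = float(qo[idx[-1]])
    return e_peak, a_peak, e_peak / a_peak


def ea_peak_times(times, q_mv, open_interval, prominence_frac=0.05):
    """Times of the E- and A-wave peaks (same detection as ea_analysis)."""
    times = np.asarray(times, dtype=float)
    q = np.asarray(q_mv, dtype=float)
    t0, t1 = open_interval
    mask = (times >= t0) & (times <= t1)
    qo = q[mask]
    to = times[mask]
    if len(qo) < 5 or qo.max() <= 0:
        raise WaveDetectionError("no usable outflow in the open interval")
    idx, _ = find_peaks(qo, prominence=prominence_frac * qo.max())
    if len(idx) < 2:
        raise WaveDetectionError("fewer than 2 prominent outflow peaks")
    return float(to[idx[0]]), float(to[idx[-1]])


def tortuosity(cl: Centerline) -> float:
    """Polyline length over endpoint chord, minus one."""
    d = cl.chord
    if d == 0:
        raise ValueError("centerline endpoints coincide")
    return cl.length / d - 1.0


def ostium_area(geom, displacement=None) -> float:
    """Area (mm^2) of the ostium-ring polygon projected on its best-fit plane."""
    ring = np.asarray(geom.ostium_ring)
    if len(ring) < 3:
        raise TopologyError("ostium ring must have at least 3 vertices")
    pts = geom.vertices if displacement is None else geom.vertices + displacement
    x = pts[ring]
    c = x.mean(axis=0)
    x0 = x - c
    # least-squares plane normal = smallest principal direction
    _, _, vt = np.linalg.svd(x0, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    u, v = x0 @ e1, x0 @ e2
    area = 0.5 * abs(np.sum(u * np.roll(v, -1) - v * np.roll(u, -1)))
    return float(area * 1e6)  # m^2 -> mm^2


def laa_centerline(geom, displacement=None, n_points: int = 50) -> Centerline:
    """Interior path from the ostium centroid to the appendage tip.

    Shortest path on the intra-appendage vertex graph with edge weights
    ``length / (wall distance + eps)``, so the path hugs the medial axis;
    the tip is the appendage wall vertex farthest (by graph distance)
    from the ostium.  Resampled to ``n_points``.
    """
    if len(geom.laa_cells) == 0 or len(geom.ostium_ring) == 0:
        raise TaggingError("geometry has no tagged appendage")
    pts = geom.vertices if displacement is None else geom.vertices + displacement

    cells = geom.tetrahedra[geom.laa_cells]
    vids = np.unique(cells.reshape(-1))
    local = -np.ones(len(pts), dtype=int)
    local[vids] = np.arange(len(vids))
    # wall distance within the appendage (to its wall facets)
    from .cohort import TAG_WALL

    wall_f = geom.boundary_facets[geom.facet_tags == TAG_WALL]
    in_laa = np.isin(wall_f, vids).all(axis=1)
    wf = wall_f[in_laa] if in_laa.any() else wall_f
    dist = _fem.point_triangle_distance(pts[vids], pts[wf[:, 0]], pts[wf[:, 1]], pts[wf[:, 2]])
    eps = 0.25 * (dist.max() if dist.max() > 0 else 1.0)

    edges = np.concatenate(
        [cells[:, [0, 1]], cells[:, [0, 2]], cells[:, [0, 3]],
         cells[:, [1, 2]], cells[:, [1, 3]], cells[:, [2, 3]]]
    )
    edges = np.unique(np.sort(local[edges], axis=1), axis=0)
    ln = np.linalg.norm(pts[vids[edges[:, 0]]] - pts[vids[edges[:, 1]]], axis=1)
    wmid = 0.5 * (dist[edges[:, 0]] + dist[edges[:, 1]])
    wgt = ln / (wmid + eps)
    n_loc = len(vids)
    G = sp.coo_matrix(
        (np.concatenate([wgt, wgt]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n_loc, n_loc),
    ).tocsr()

    ost_c = pts[geom.ostium_ring].mean(axis=0)
    start = int(np.argmin(np.linalg.norm(pts[vids] - ost_c, axis=1)))
    dmat, pred = dijkstra(G, indices=start, return_predecessors=True)
    wall_local = local[np.intersect1d(vids, np.unique(wf.reshape(-1)))]
    wall_local = wall_local[wall_local >= 0]
    finite = np.isfinite(dmat[wall_local])
    if not finite.any():
        raise TaggingError("appendage graph is disconnected from the ostium")
    # tip region: wall vertices near the maximal graph distance.  Their
    # centroid sits on the medial axis at the far end; the wall vertex
    # nearest that centroid (over ALL wall vertices) is the tip, which
    # avoids picking rim/corner outliers.
    dw = dmat[wall_local][finite]
    cand = wall_local[finite][dw >= 0.95 * dw.max()]
    tip_centroid = pts[vids[cand]].mean(axis=0)
    wl = wall_local[finite]
    tip = int(wl[np.argmin(np.linalg.norm(pts[vids[wl]] - tip_centroid, axis=1))])

    path = [tip]
    while path[-1] != start and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    path = path[::-1]
    poly = np.vstack([ost_c, pts[vids[path]]])
    # drop duplicate consecutive points
    keep = np.ones(len(poly), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-14
    poly = poly[keep]
    res = _resample_smooth(poly, n_points)
    return Centerline(points=res)


def _resample_smooth(poly: np.ndarray, n_points: int) -> np.ndarray:
    """Smoothing-spline resampling of a polyline.

    The smoothing scale is tied to the mesh segment length, so the
    vertex-to-vertex zigzag is removed while genuine large-scale
    curvature (bends much longer than an edge) is preserved.
    """
    from scipy.interpolate import UnivariateSpline

    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if len(poly) < 5:
        si = np.linspace(0.0, s[-1], n_points)
        return np.stack([np.interp(si, s, poly[:, k]) for k in range(3)], axis=1)
    h = seg.mean()
    smooth = len(poly) * (0.35 * h) ** 2
    si = np.linspace(0.0, s[-1], n_points)
    out = np.empty((n_points, 3))
    for k in range(3):
        spl = UnivariateSpline(s, poly[:, k], k=3, s=smooth)
        out[:, k] = spl(si)
    # keep the exact endpoints (ostium centroid and wall tip)
    out[0] = poly[0]
    out[-1] = poly[-1]
    return out


def functional_summary(
    p, trace: VolumeTrace, geom=None, q_mv=None, q_times=None,
    open_interval=None, min_volume_displacement=None,
) -> FunctionalSummary:
    """Assemble the per-case functional summary.

    Ostium area and tortuosity are evaluated at the minimum-volume
    configuration (pass its displacement field); E/A fields are left
    unset when no flowrate trace is given or no two prominent peaks
    exist (degenerate phenotypes).
    """
    v_max, v_min, sv, ef = volume_extrema(trace)
    out = FunctionalSummary(
        v_max=v_max, v_min=v_min, sv=sv, ef=ef, bpm=p.bpm, period=p.period,
    )
    if geom is not None and len(geom.ostium_ring):
        out.ostium_area = ostium_area(geom, displacement=min_volume_displacement)
        out.tortuosity = tortuosity(
            laa_centerline(geom, displacement=min_volume_displacement)
        )
    if q_mv is not None and open_interval is not None and sv > 0:
        try:
            out.e_peak, out.a_peak, out.ea_ratio = ea_analysis(
                q_times, q_mv, open_interval
            )
        except WaveDetectionError:
            pass  # flagged absent
    return out


def smooth_trace_spline(trace: VolumeTrace, period: float) -> CubicSpline:
    """Periodic cubic spline through a volume trace (mL)."""
    t = np.concatenate([trace.times, [trace.times[0] + period]])
    v = np.concatenate([trace.volumes, [trace.volumes[0]]])
    return CubicSpline(t, v, bc_type="periodic")
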