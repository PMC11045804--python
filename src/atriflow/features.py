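"""Hemodynamic biomarkers from flow histories.

Phase-averaged velocity over the retained beats; flow stasis (fraction of
the period below a speed threshold); wall-shear-stress vector history and
its time aggregates TAWSS, OSI, RRT, ECAP; kinetic energy and enstrophy
traces; phase-gated vorticity medians; region-wise medians (whole chamber
vs appendage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fem
from .cohort import TAG_WALL, ChamberGeometry
from .errors import TaggingError
from .flow import FlowHistory

__all__ = [
    "PhaseAveragedFlow", "WallFeatureField", "VolumeFeatureField",
    "GlobalTraces", "FeatureMedians",
    "phase_average", "flow_stasis", "wss_history", "wall_features",
    "global_traces", "vorticity_magnitude", "vorticity_phase_medians",
    "region_medians",
]

FS_THRESHOLD = 0.1  # m/s


@dataclass
class PhaseAveragedFlow:
    """One period of phase-averaged velocity on the vertex correspondence."""

    times: np.ndarray       # (K,) phase times in [0, period)
    u: np.ndarray           # (K, N, 3)
    d: np.ndarray           # (K, N, 3) mesh displacement at each phase
    period: float
    n_discarded: int
    n_averaged: int


@dataclass
class WallFeatureField:
    wall_vertex_ids: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray     # inf where OSI = 0.5 (flagged divergent)
    ecap: np.ndarray


@dataclass
class VolumeFeatureField:
    fs: np.ndarray  # per vertex, fraction of the period


@dataclass
class GlobalTraces:
    times: np.ndarray
    kinetic_energy: np.ndarray  # m^5/s^2 (density omitted, as defined)
    enstrophy: np.ndarray       # m^3/s^2


@dataclass
class FeatureMedians:
    region: str
    fs: float
    tawss: float
    osi: float
    rrt: float
    ecap: float
    vort_e: float | None = None
    vort_a: float | None = None
    vort_sys: float | None = None
    n_excluded: int = 0


# ----------------------------------------------------------------------

def phase_average(history: FlowHistory, n_discard: int = 2, n_average: int | None = None
                  ) -> PhaseAveragedFlow:
    """Vertex-wise mean across beats at matching phase.

    Discards the first ``n_discard`` beats (initial transient) and
    averages the next ``n_average`` (default: all remaining).
    """
    spb = history.snaps_per_beat
    n_beats = history.n_beats
    if n_average is None:
        n_average = n_beats - n_discard
    if n_discard < 0 or n_average < 1:
        raise ValueError("need n_discard >= 0 and n_average >= 1")
    if n_discard + n_average > n_beats:
        raise ValueError(
            f"history has {n_beats} beats; cannot discard {n_discard} and average {n_average}"
        )
    sel = [
        history.u[b * spb : (b + 1) * spb]
        for b in range(n_discard, n_discard + n_average)
    ]
    u_avg = np.mean(sel, axis=0)
    first = n_discard * spb
    phase_times = history.times[first : first + spb] % history.period
    d = history.d[first : first + spb]
    return PhaseAveragedFlow(
        times=phase_times, u=u_avg, d=d, period=history.period,
        n_discarded=n_discard, n_averaged=n_average,
    )


def flow_stasis(pa: PhaseAveragedFlow, threshold: float = FS_THRESHOLD) -> VolumeFeatureField:
    """Fraction of the period with phase-averaged speed <= threshold."""
    if threshold <= 0:
        raise ValueError("stasis threshold must be > 0")
    speed = np.linalg.norm(pa.u, axis=2)  # (K, N)
    return VolumeFeatureField(fs=(speed <= threshold).mean(axis=0))


def _vertex_velocity_gradient(pts, tets, u):
    """(N, 3, 3) recovered gradient, G[n, i, j] = d u_i / d x_j."""
    return _fem.recover_vertex_gradient(pts, tets, u)


def wss_history(pa: PhaseAveragedFlow, geom: ChamberGeometry, mu: float = 3.5e-3):
    """Tangential viscous traction on the wall at each phase.

    The velocity gradient is evaluated on the configuration of each
    phase and results are attached to the reference wall vertices.
    Returns ``(wall_vertex_ids, wss)`` with ``wss`` of shape (K, W, 3).
    """
    wall = geom.facets_of(TAG_WALL)
    if len(wall) == 0:
        raise TaggingError("geometry has no WALL facets")
    wall_ids = geom.wall_vertex_ids
    K = len(pa.times)
    out = np.empty((K, len(wall_ids), 3))
    for k in range(K):
        pts = geom.vertices + pa.d[k]
        G = _vertex_velocity_gradient(pts, geom.tetrahedra, pa.u[k])
        n = _fem.vertex_normals(pts, wall, n_pts=len(pts))[wall_ids]
        Gw = G[wall_ids]
        tau = mu * (Gw + np.transpose(Gw, (0, 2, 1)))
        tn = np.einsum("wij,wj->wi", tau, n)
        out[k] = tn - np.einsum("wi,wi->w", tn, n)[:, None] * n
    return wall_ids, out


def wall_features(wss: np.ndarray, wall_vertex_ids=None) -> WallFeatureField:
    """TAWSS/OSI/RRT/ECAP from a uniform-phase WSS history (K, W, 3).

    Time integrals use the uniform-stride mean (periodic trapezoid).
    RRT is infinite where OSI reaches 1/2; OSI is set to 0 where the
    shear vanishes identically (RRT/ECAP undefined there).
    """
    wss = np.asarray(wss, dtype=float)
    mag_int = np.linalg.norm(wss, axis=2).mean(axis=0)          # (W,) TAWSS
    vec_int = np.linalg.norm(wss.mean(axis=0), axis=1)          # (W,) |mean WSS|
    tawss = mag_int
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = 0.5 * (1.0 - vec_int / mag_int)
        osi = np.where(mag_int > 0, osi, 0.0)
        osi = np.clip(osi, 0.0, 0.5)
        rrt = 1.0 / ((1.0 - 2.0 * osi) * tawss)
        ecap = np.where(tawss > 0, osi / tawss, np.nan)
    rrt = np.where(tawss > 0, rrt, np.nan)
    if wall_vertex_ids is None:
        wall_vertex_ids = np.arange(wss.shape[1])
    return WallFeatureField(
        wall_vertex_ids=np.asarray(wall_vertex_ids), tawss=tawss,
        osi=osi, rrt=rrt, ecap=ecap,
    )


def vorticity_magnitude(pa: PhaseAveragedFlow, geom: ChamberGeometry, k: int) -> np.ndarray:
    """|curl u| per vertex at phase index k."""
    pts = geom.vertices + pa.d[k]
    G = _vertex_velocity_gradient(pts, geom.tetrahedra, pa.u[k])
    w = np.stack(
        [
            G[:, 2, 1] - G[:, 1, 2],
            G[:, 0, 2] - G[:, 2, 0],
            G[:, 1, 0] - G[:, 0, 1],
        ],
        axis=1,
    )
    return np.linalg.norm(w, axis=1)


def global_traces(pa: PhaseAveragedFlow, geom: ChamberGeometry) -> GlobalTraces:
    """Kinetic energy and enstrophy of the phase-averaged flow.

    Volume integrals are taken on the reference configuration (vertex
    quadrature with lumped volume weights); vorticity comes from the
    recovered gradient at each phase.
    """
    w = _fem.lumped_mass(geom.vertices, geom.tetrahedra)
    K = len(pa.times)
    ek = np.empty(K)
    s = np.empty(K)
    for k in range(K):
        ek[k] = 0.5 * float(w @ (pa.u[k] ** 2).sum(axis=1))
        om = vorticity_magnitude(pa, geom, k)
        s[k] = 0.5 * float(w @ om**2)
    return GlobalTraces(times=pa.times, kinetic_energy=ek, enstrophy=s)


def _phase_index(pa: PhaseAveragedFlow, t: float) -> int:
    return int(np.argmin(np.abs((pa.times - t + pa.period / 2) % pa.period - pa.period / 2)))


def vorticity_phase_medians(
    pa: PhaseAveragedFlow, geom: ChamberGeometry,
    e_time: float, a_time: float, systolic_time: float,
) -> dict:
    """Region-wise medians of |vorticity| at the E, A and systolic phases."""
    regions = _region_vertex_sets(geom)
    out = {}
    for name, t in (("e", e_time), ("a", a_time), ("sys", systolic_time)):
        om = vorticity_magnitude(pa, geom, _phase_index(pa, t))
        for region, vids in regions.items():
            out[(region, name)] = float(np.median(om[vids]))
    return out


def _region_vertex_sets(geom: ChamberGeometry) -> dict:
    sets = {"LA": np.arange(len(geom.vertices))}
    if len(geom.laa_cells):
        sets["LAA"] = np.unique(geom.tetrahedra[geom.laa_cells].reshape(-1))
    return sets


def region_medians(
    geom: ChamberGeometry, fs_field: VolumeFeatureField, wall_field: WallFeatureField,
    vort_medians: dict | None = None,
) -> list[FeatureMedians]:
    """Unweighted vertex medians per region (whole chamber and appendage).

    Wall features are pooled over wall vertices, stasis over volume
    vertices.  Non-finite wall values (divergent RRT) are excluded and
    counted.
    """
    vol_regions = _region_vertex_sets(geom)
    wall_ids = wall_field.wall_vertex_ids
    out = []
    for region, vol_vids in vol_regions.items():
        if len(vol_vids) == 0:
            raise TaggingError(f"region {region} has no vertices")
        if region == "LA":
            wall_mask = np.ones(len(wall_ids), dtype=bool)
        else:
            wall_mask = np.isin(wall_ids, geom.laa_wall_vertices)
        if not wall_mask.any():
            raise TaggingError(f"region {region} has no wall vertices")

        def med(values, mask=wall_mask):
            v = values[mask]
            finite = np.isfinite(v)
            return float(np.median(v[finite])), int((~finite).sum())

        tawss, nx1 = med(wall_field.tawss)
        osi, nx2 = med(wall_field.osi)
        rrt, nx3 = med(wall_field.rrt)
        ecap, nx4 = med(wall_field.ecap)
        fs = float(np.median(fs_field.fs[vol_vids]))
        fm = FeatureMedians(
            region=region, fs=fs, tawss=tawss, osi=osi, rrt=rrt, ecap=ecap,
            n_excluded=nx1 + nx2 + nx3 + nx4,
        )
        if vort_medians:
            fm.vort_e = vort_medians.get((region, "e"))
            fm.vort_a = vort_medians.get((region, "a"))
            fm.vort_sys = vort_medians.get((region, "sys"))
        out.append(fm)
    return out
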