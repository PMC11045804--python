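"""Frame displacements -> smooth volumetric mesh motion.

Periodic smoothing splines model the wall displacement in time; a
stiffened harmonic lifting (P1 FEM, natural conditions on the inlet and
outlet disks) extends it to interior vertices.  The stiffening factor is
``psi(x) = max(dist_to_wall(x), alpha)^(-beta)``, which makes near-wall
elements move almost rigidly and protects element quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from ._splines import PeriodicSmoothingSpline, choose_smoothing_gcv
from .cohort import TAG_WALL, ChamberGeometry, FrameSet
from .errors import InsufficientDataError, MeshMotionError, TaggingError

__all__ = [
    "LiftingConfig", "DisplacementModel", "VolumetricMotion",
    "fit_displacement_model", "ale_boundary_velocity",
    "wall_distance_field", "harmonic_lifting", "volumetric_motion",
]


@dataclass(frozen=True)
class LiftingConfig:
    alpha: float = 1.5e-3        # distance floor, m
    beta: float = 2.0            # stiffening exponent
    linear_tolerance: float = 1e-9

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class DisplacementModel:
    """Periodic temporal spline of the wall displacement, per vertex."""

    period: float
    wall_vertex_ids: np.ndarray
    spline: PeriodicSmoothingSpline
    smoothing_weight: float
    frame_times: np.ndarray | None = None

    def __call__(self, t) -> np.ndarray:
        """Wall displacement at time t (wrapped into the period), (W, 3)."""
        return self.spline(t).reshape(-1, 3)

    def velocity(self, t) -> np.ndarray:
        return self.spline(t, nu=1).reshape(-1, 3)


def fit_displacement_model(
    frames: FrameSet, smoothing_weight: float | str = 0.0
) -> DisplacementModel:
    """Fit a periodic cubic smoothing spline to frame displacements.

    ``smoothing_weight = 0`` gives the interpolating periodic spline;
    ``"gcv"`` selects the weight by generalized cross-validation.
    """
    t = np.asarray(frames.frame_times, dtype=float)
    if len(t) < 4:
        raise InsufficientDataError("need at least 4 frames to fit the temporal spline")
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate frame times")
    n, w, _ = frames.boundary_displacements.shape
    Y = frames.boundary_displacements.reshape(n, w * 3)
    lam = smoothing_weight
    if lam == "gcv":
        lam = choose_smoothing_gcv(t, Y, frames.period)
    spline = PeriodicSmoothingSpline(t, Y, frames.period, lam=float(lam))
    return DisplacementModel(
        period=frames.period, wall_vertex_ids=frames.wall_vertex_ids,
        spline=spline, smoothing_weight=float(lam), frame_times=t,
    )


def ale_boundary_velocity(model: DisplacementModel, t: float) -> np.ndarray:
    """Analytic time derivative of the wall displacement model, (W, 3)."""
    return model.velocity(t)


def wall_distance_field(geom: ChamberGeometry) -> np.ndarray:
    """Exact distance from every mesh vertex to the WALL facet set."""
    wall = geom.facets_of(TAG_WALL)
    if len(wall) == 0:
        raise TaggingError("geometry has no WALL-tagged facets")
    pts = geom.vertices
    d = _fem.point_triangle_distance(pts, pts[wall[:, 0]], pts[wall[:, 1]], pts[wall[:, 2]])
    d[geom.wall_vertex_ids] = 0.0
    return d


class _LiftingOperator:
    """Factorized stiffened-Laplace operator with wall Dirichlet rows."""

    def __init__(self, geom: ChamberGeometry, cfg: LiftingConfig, wall_distance=None):
        self.geom = geom
        self.cfg = cfg
        if wall_distance is None:
            wall_distance = wall_distance_field(geom)
        d_e = wall_distance[geom.tetrahedra].mean(axis=1)
        psi = np.maximum(d_e, cfg.alpha) ** (-cfg.beta)
        K = _fem.stiffness_matrix(geom.vertices, geom.tetrahedra, coeff=psi)
        self.wall = geom.wall_vertex_ids
        free = np.ones(len(geom.vertices), dtype=bool)
        free[self.wall] = False
        self.free = np.nonzero(free)[0]
        self.K_ff = K[self.free][:, self.free].tocsr()
        self.K_fw = K[self.free][:, self.wall].tocsr()
        self._lu = None

    def solve(self, wall_values: np.ndarray, use_direct: bool | None = None) -> np.ndarray:
        """Extend wall data (W, m) into the volume; returns (N, m)."""
        wv = np.atleast_2d(wall_values.T).T
        m = wv.shape[1]
        out = np.zeros((len(self.geom.vertices), m))
        out[self.wall] = wv
        rhs = -self.K_fw @ wv
        if use_direct is None:
            use_direct = m > 3 or self._lu is not None
        if use_direct:
            if self._lu is None:
                self._lu = spla.splu(self.K_ff.tocsc())
            sol = self._lu.solve(rhs)
            res = np.linalg.norm(self.K_ff @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
            if res > max(self.cfg.linear_tolerance, 1e-10) * 1e3:
                raise _fem.SolverError(f"direct lifting solve residual {res:.2e}")
        else:
            sol = np.column_stack(
                [
                    _fem.cg_solve(self.K_ff, rhs[:, j], tol=self.cfg.linear_tolerance)
                    for j in range(m)
                ]
            )
        out[self.free] = sol
        return out if wall_values.ndim > 1 else out[:, 0]


def harmonic_lifting(
    geom: ChamberGeometry, boundary_disp: np.ndarray,
    cfg: LiftingConfig | None = None, wall_distance=None,
) -> np.ndarray:
    """Extend a wall displacement field to all mesh vertices.

    ``boundary_disp`` has one row per entry of ``geom.wall_vertex_ids``.
    Wall rows are imposed strongly; inlet/outlet vertices carry the
    natural (zero normal gradient) condition.  The three components
    decouple and are solved as independent SPD systems.
    """
    cfg = cfg or LiftingConfig()
    op = _LiftingOperator(geom, cfg, wall_distance=wall_distance)
    return op.solve(np.asarray(boundary_disp, dtype=float))


@dataclass
class VolumetricMotion:
    """Time-periodic volumetric mesh motion with analytic ALE velocity."""

    geom: ChamberGeometry
    spline: PeriodicSmoothingSpline  # over flattened (N*3) lifted fields
    period: float

    def displacement(self, t) -> np.ndarray:
        return self.spline(t).reshape(-1, 3)

    def velocity(self, t) -> np.ndarray:
        return self.spline(t, nu=1).reshape(-1, 3)

    def moved_points(self, t) -> np.ndarray:
        return self.geom.vertices + self.displacement(t)

    def volume_m3(self, t) -> float:
        return _fem.signed_surface_volume(self.moved_points(t), self.geom.boundary_facets)


def volumetric_motion(
    geom: ChamberGeometry, model: DisplacementModel,
    cfg: LiftingConfig | None = None, time_grid=None, wall_distance=None,
) -> VolumetricMotion:
    """Solve the lifting at collocation times and interpolate in time.

    Collocation defaults to the model's fitted frame times (one lifting
    solve per frame); between frames the lifted fields are interpolated
    with the same periodic-spline machinery, and the ALE velocity is its
    analytic derivative.
    """
    cfg = cfg or LiftingConfig()
    if time_grid is None:
        if model.frame_times is None:
            raise ValueError("model has no frame times; pass time_grid explicitly")
        time_grid = model.frame_times
    time_grid = np.asarray(time_grid, dtype=float)
    boundary_ids = np.unique(geom.boundary_facets.reshape(-1))
    from .cohort import _untangle_interior

    def build():
        op = _LiftingOperator(geom, cfg, wall_distance=wall_distance)
        lifted = np.empty((len(time_grid), len(geom.vertices) * 3))
        for i, t in enumerate(time_grid):
            lifted[i] = op.solve(model(t)).reshape(-1)
        return PeriodicSmoothingSpline(time_grid, lifted, model.period, lam=0.0)

    def worst_time(spline):
        gaps = np.diff(np.append(time_grid, time_grid[0] + model.period))
        check = np.concatenate(
            [time_grid] + [time_grid + f * gaps for f in (0.25, 0.5, 0.75)]
        ) % model.period
        qmin, tmin = np.inf, None
        for t in np.sort(check):
            q = _fem.scaled_jacobians(
                geom.vertices + spline(t).reshape(-1, 3), geom.tetrahedra
            ).min()
            if q < qmin:
                qmin, tmin = q, t
        return qmin, tmin

    # Elements can pinch near peak contraction on sliver-prone desk meshes.
    # Rather than adjusting individual time frames (which makes the temporal
    # spline ring), shift the offending INTERIOR vertices of the REFERENCE
    # mesh - a time-independent change that keeps the motion smooth - and
    # rebuild the lifting, iterating until the whole period stays valid.
    spline = build()
    for _ in range(5):
        qmin, tmin = worst_time(spline)
        if qmin > 0.005:
            break
        moved = geom.vertices + spline(tmin).reshape(-1, 3)
        fixed = _untangle_interior(
            moved, geom.tetrahedra, boundary_ids, sweeps=10, q_accept=0.05
        )
        delta = fixed - moved
        if not np.any(delta):
            raise MeshMotionError(
                f"mesh motion at t={tmin:.4f}s produced unfixable inverted elements"
            )
        geom.vertices = geom.vertices + delta  # interior-only reference shift
        if wall_distance is not None:
            wall_distance = None  # stale after moving interior vertices
        spline = build()
    else:
        qmin, tmin = worst_time(spline)
        if qmin <= 0.0:
            raise MeshMotionError(
                f"mesh motion at t={tmin:.4f}s produced inverted elements"
            )
    return VolumetricMotion(geom=geom, spline=spline, period=model.period)
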