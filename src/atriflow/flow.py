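"""Incompressible Navier-Stokes in ALE form on the moving chamber.

Equal-order P1-P1 elements with residual-based SUPG/PSPG and grad-div
stabilization, implicit Euler in time, semi-implicit convection (the
convecting velocity is the previous step's velocity relative to the
mesh).  Inlet disks carry a traction boundary condition with backflow
stabilization; the outlet switches between traction (open) and a no-slip
condition following the mesh (closed) according to the volume schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from . import _fem
from .cohort import ML, PV_TAGS, TAG_MV, TAG_WALL, ChamberGeometry
from .errors import MeshMotionError, ScheduleError
from .functional import VolumeTrace

__all__ = [
    "MMHG", "FluidProperties", "BoundarySpec", "SolverConfig",
    "FlowState", "FlowHistory", "StaticMotion",
    "mv_schedule", "advance", "run", "section_flowrate",
]

MMHG = 133.322  # Pa


@dataclass(frozen=True)
class FluidProperties:
    density: float = 1.06e3           # kg/m^3
    dynamic_viscosity: float = 3.5e-3  # kg/(m s)

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass
class BoundarySpec:
    """Pressure levels and outlet open/close schedule.

    ``mv_schedule`` is a list of ``(time, state)`` transitions within one
    period; states alternate between "open" and "closed".
    """

    p_in: float = 10 * MMHG
    p_out: float = 5 * MMHG
    mv_schedule: list = field(default_factory=list)
    period: float | None = None
    backflow_coefficient: float = 1.0
    # optional strong velocity data per inlet tag (tag -> (N,3) array);
    # such tags become Dirichlet instead of traction boundaries
    velocity_bc: dict = field(default_factory=dict)

    def mv_open(self, t: float) -> bool:
        if not self.mv_schedule:
            return True
        if self.period:
            t = t % self.period
        state = self.mv_schedule[-1][1]  # wraps around
        for tt, s in self.mv_schedule:
            if tt <= t + 1e-12:
                state = s
        return state == "open"


@dataclass
class SolverConfig:
    dt: float = 2e-3
    n_beats: int = 3
    output_stride: int = 1
    linear_tolerance: float = 1e-8
    max_linear_iterations: int = 500
    refactor_every: int = 8  # steps between LU refactorizations (run loop)
    # stabilization constants: tau = ((c_t/dt)^2 + (c_a |w|/h)^2 + (c_d nu/h^2)^2)^-1/2
    c_time: float = 2.0
    c_adv: float = 2.0
    c_diff: float = 4.0
    c_graddiv: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


@dataclass
class FlowState:
    time: float
    u: np.ndarray  # (N, 3)
    p: np.ndarray  # (N,)
    d: np.ndarray  # (N, 3) current mesh displacement


@dataclass
class FlowHistory:
    """Snapshots at a uniform output stride plus per-snapshot diagnostics."""

    times: np.ndarray
    u: np.ndarray          # (K, N, 3)
    p: np.ndarray          # (K, N)
    d: np.ndarray          # (K, N, 3)
    period: float
    dt: float
    stride: int
    n_beats: int
    volume_mL: np.ndarray
    q_mv_mL_s: np.ndarray      # positive = out of the chamber
    q_pv_mL_s: np.ndarray      # positive = into the chamber
    kinetic_energy: np.ndarray
    beat_l2_differences: list = field(default_factory=list)

    @property
    def snaps_per_beat(self) -> int:
        return int(round(self.period / (self.dt * self.stride)))


class StaticMotion:
    """Zero mesh motion (static domain)."""

    def __init__(self, geom: ChamberGeometry):
        self.geom = geom
        self._z = np.zeros_like(geom.vertices)

    def displacement(self, t):
        return self._z

    def velocity(self, t):
        return self._z

    def moved_points(self, t):
        return self.geom.vertices


# ----------------------------------------------------------------------
# valve schedule
# ----------------------------------------------------------------------

def mv_schedule(trace: VolumeTrace, period: float | None = None) -> list:
    """Open/close transitions from the extrema of the smoothed volume trace.

    The outlet opens at the volume maximum (start of emptying) and closes
    at the minimum.  Raises :class:`ScheduleError` for traces without a
    max/min pair.
    """
    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(trace.volumes, dtype=float)
    if period is None:
        period = t[-1] + (t[1] - t[0]) if len(t) > 1 else 0.0
    if len(t) < 4 or v.max() - v.min() <= 1e-9 * max(v.max(), 1.0):
        raise ScheduleError("volume trace has no distinct extrema")
    tt = np.concatenate([t, [t[0] + period]])
    vv = np.concatenate([v, [v[0]]])
    spl = CubicSpline(tt, vv, bc_type="periodic")
    dense = np.linspace(0.0, period, 4096, endpoint=False)
    dv = spl(dense, 1)
    sign = np.sign(dv)
    roots = []
    for i in range(len(dense)):
        j = (i + 1) % len(dense)
        if sign[i] == 0:
            roots.append(dense[i])
        elif sign[i] * sign[j] < 0:
            a, b = dense[i], dense[i] + (period / 4096)
            roots.append(brentq(lambda x: spl(x % period, 1), a, b, xtol=1e-12))
    if len(roots) < 2:
        raise ScheduleError("could not locate a max/min pair on the smoothed trace")
    vals = spl(np.mod(roots, period))
    t_max = roots[int(np.argmax(vals))] % period
    t_min = roots[int(np.argmin(vals))] % period
    sched = sorted([(float(t_max), "open"), (float(t_min), "closed")])
    return sched


# ----------------------------------------------------------------------
# flux
# ----------------------------------------------------------------------

def _outward_flux(pts, facets, u, u_ale) -> float:
    """Integral of (u - u_ale).n over a facet set, m^3/s (outward normal)."""
    areas, normals = _fem.facet_areas_normals(pts, facets)
    rel = (u - u_ale)[facets].mean(axis=1)  # (F, 3), exact for P1
    return float((areas * np.einsum("ij,ij->i", rel, normals)).sum())


def section_flowrate(geom: ChamberGeometry, tag: int, u, u_ale=None, d=None) -> float:
    """Relative flowrate through a tagged open boundary section, mL/s.

    Positive means out of the chamber through the outlet (MV) and into
    the chamber through the inlets (PVs).
    """
    from .cohort import TAG_LEGEND

    if tag not in TAG_LEGEND:
        raise ValueError(f"unknown region tag {tag}")
    facets = geom.facets_of(tag)
    if len(facets) == 0:
        raise ValueError(f"no facets tagged {TAG_LEGEND[tag]}")
    if u_ale is None:
        u_ale = np.zeros_like(u)
    pts = geom.vertices if d is None else geom.vertices + d
    flux = _outward_flux(pts, facets, u, u_ale)
    if tag in PV_TAGS:
        flux = -flux
    return flux / ML


# ----------------------------------------------------------------------
# one implicit step
# ----------------------------------------------------------------------

def _assemble_step(geom, pts, u_old, u_ale, fluid, bc, cfg, mv_is_open,
                   workspace=None):
    """Assemble the monolithic stabilized system at the new configuration.

    The sparsity pattern is constant for a given valve state; when a
    ``workspace`` is supplied the COO->CSR sort is computed once and the
    values are accumulated with a bincount on subsequent steps.
    """
    N = len(pts)
    tets = geom.tetrahedra
    rho, mu = fluid.density, fluid.dynamic_viscosity
    nu = mu / rho
    dt = cfg.dt

    vol, grads = _fem.tet_grads(pts, tets)
    if np.any(vol <= 0):
        raise MeshMotionError("inverted elements in the current configuration")
    w_nodal = u_old - u_ale
    w_e = w_nodal[tets].mean(axis=1)                      # (M,3)
    wn = np.linalg.norm(w_e, axis=1)
    h = np.cbrt(6.0 * np.sqrt(2.0) * vol)
    tau = 1.0 / np.sqrt(
        (cfg.c_time / dt) ** 2 + (cfg.c_adv * wn / h) ** 2 + (cfg.c_diff * nu / h**2) ** 2
    )
    gamma = cfg.c_graddiv * (mu + 0.5 * rho * wn * h)

    wg = np.einsum("ek,eak->ea", w_e, grads)              # (M,4): w.grad(phi_a)
    gg = np.einsum("eak,ebk->eab", grads, grads)          # (M,4,4)
    ub_e = u_old[tets].mean(axis=1)                       # (M,3)

    rows4 = np.repeat(tets, 4, axis=1).reshape(-1)
    cols4 = np.tile(tets, (1, 4)).reshape(-1)

    tri_r, tri_c, tri_v = [], [], []

    def add_block(vals, bi, bj):  # vals (M,4,4) into block (bi, bj)
        tri_r.append(rows4 + bi * N)
        tri_c.append(cols4 + bj * N)
        tri_v.append(vals.reshape(-1))

    # scalar velocity-diagonal piece: mass/dt + convection + SUPG + Laplacian
    mass_e = vol[:, None, None] / 20.0 * (np.ones((4, 4)) + np.eye(4))
    conv_e = vol[:, None, None] / 4.0 * wg[:, None, :]        # phi_a * (w.grad phi_b)
    supg_uu = (tau * vol)[:, None, None] * (
        wg[:, :, None] / (4.0 * dt) + wg[:, :, None] * wg[:, None, :]
    )
    diag_scal = rho * (mass_e / dt + conv_e + supg_uu) + mu * vol[:, None, None] * gg

    # viscous symmetric-gradient coupling and grad-div: blocks (i,j)
    for i in range(3):
        for j in range(3):
            cross = vol[:, None, None] * np.einsum("ea,eb->eab", grads[:, :, j], grads[:, :, i])
            gd = (gamma * vol)[:, None, None] * np.einsum(
                "ea,eb->eab", grads[:, :, i], grads[:, :, j]
            )
            blk = mu * cross + gd
            if i == j:
                blk = blk + diag_scal
            add_block(blk, i, j)

    # pressure gradient (Galerkin + SUPG) and continuity (Galerkin + PSPG)
    for i in range(3):
        galerkin_up = -vol[:, None, None] / 4.0 * np.einsum(
            "ea,b->eab", grads[:, :, i], np.ones(4)
        )
        supg_up = (tau * vol)[:, None, None] * np.einsum("ea,eb->eab", wg, grads[:, :, i])
        add_block(galerkin_up + supg_up, i, 3)
        galerkin_pu = vol[:, None, None] / 4.0 * np.einsum(
            "a,eb->eab", np.ones(4), grads[:, :, i]
        )
        pspg_pu = (tau * vol)[:, None, None] * np.einsum(
            "ea,eb->eab", grads[:, :, i], 1.0 / (4.0 * dt) + wg
        )
        add_block(galerkin_pu + pspg_pu, 3, i)
    add_block((tau / rho * vol)[:, None, None] * gg, 3, 3)

    # right-hand side
    rhs_u = np.zeros((3, N))
    m_uold = rho / dt * (
        vol[:, None, None] / 20.0
        * (u_old[tets].sum(axis=1)[:, None, :] + u_old[tets]).transpose(0, 2, 1)
    )  # (M,3,4): consistent mass times u_old, times rho/dt
    supg_rhs = (tau * rho / dt * vol)[:, None] * wg  # (M,4) scalar factor, per comp mult by ub
    for i in range(3):
        np.add.at(rhs_u[i], tets.reshape(-1), m_uold[:, i, :].reshape(-1))
        np.add.at(rhs_u[i], tets.reshape(-1), (supg_rhs * ub_e[:, i : i + 1]).reshape(-1))
    rhs_p = np.zeros(N)
    pspg_rhs = (tau / dt * vol)[:, None, None] * np.einsum("eak,ek->ea", grads, ub_e)[:, :, None]
    np.add.at(rhs_p, tets.reshape(-1), pspg_rhs[:, :, 0].reshape(-1))

    # Neumann faces: traction -p_bc n plus backflow stabilization
    neumann = [(tag, bc.p_in) for tag in PV_TAGS if tag not in bc.velocity_bc]
    if mv_is_open and TAG_MV not in bc.velocity_bc:
        neumann.append((TAG_MV, bc.p_out))
    any_neumann = False
    for tag, p_bc in neumann:
        facets = geom.boundary_facets[geom.facet_tags == tag]
        if len(facets) == 0:
            continue
        any_neumann = True
        areas, normals = _fem.facet_areas_normals(pts, facets)
        for i in range(3):
            np.add.at(
                rhs_u[i], facets.reshape(-1),
                np.repeat(-p_bc * areas * normals[:, i] / 3.0, 3),
            )
        # backflow penalty: rho*c/2 * (w.n)_- |u|^2 -> face mass term
        # (assembled unconditionally to keep the sparsity pattern fixed)
        w_f = w_nodal[facets].mean(axis=1)
        wn_f = np.einsum("ij,ij->i", w_f, normals)
        pen = 0.5 * rho * bc.backflow_coefficient * np.maximum(0.0, -wn_f)
        fm = (pen * areas)[:, None, None] / 12.0 * (np.ones((3, 3)) + np.eye(3))
        r3 = np.repeat(facets, 3, axis=1).reshape(-1)
        c3 = np.tile(facets, (1, 3)).reshape(-1)
        for i in range(3):
            tri_r.append(r3 + i * N)
            tri_c.append(c3 + i * N)
            tri_v.append(fm.reshape(-1))

    vals = np.concatenate(tri_v)
    cache_key = f"asm_{mv_is_open}"
    cache = workspace.get(cache_key) if workspace is not None else None
    if cache is None:
        rows = np.concatenate(tri_r)
        cols = np.concatenate(tri_c)
        order = np.lexsort((cols, rows))
        rs, cs = rows[order], cols[order]
        new_grp = np.ones(len(rs), dtype=bool)
        new_grp[1:] = (rs[1:] != rs[:-1]) | (cs[1:] != cs[:-1])
        slot = np.cumsum(new_grp) - 1
        nnz = int(slot[-1]) + 1
        indices = cs[new_grp]
        indptr = np.zeros(4 * N + 1, dtype=np.int64)
        np.add.at(indptr, rs[new_grp] + 1, 1)
        indptr = np.cumsum(indptr)
        cache = (order, slot, indices, indptr, nnz)
        if workspace is not None:
            workspace[cache_key] = cache
    order, slot, indices, indptr, nnz = cache
    data = np.bincount(slot, weights=vals[order], minlength=nnz)
    A = sp.csr_matrix((data, indices, indptr), shape=(4 * N, 4 * N))
    rhs = np.concatenate([rhs_u[0], rhs_u[1], rhs_u[2], rhs_p])
    return A, rhs, any_neumann


def _dirichlet_ids(geom: ChamberGeometry, mv_is_open: bool) -> np.ndarray:
    ids = [geom.wall_vertex_ids]
    if not mv_is_open:
        mv = geom.facets_of(TAG_MV)
        if len(mv):
            ids.append(np.unique(mv.reshape(-1)))
    return np.unique(np.concatenate(ids))


def advance(state: FlowState, motion, fluid: FluidProperties, bc: BoundarySpec,
            cfg: SolverConfig, workspace: dict | None = None) -> FlowState:
    """One implicit-Euler step of the stabilized ALE system.

    ``workspace`` (optional, used by :func:`run`) caches the last LU
    factorization; intermediate steps then use it as a preconditioner for
    GMRES on the current matrix, solved to the same tolerance.
    """
    geom = motion.geom
    t_new = state.time + cfg.dt
    d_new = motion.displacement(t_new)
    u_ale = motion.velocity(t_new)
    pts = geom.vertices + d_new
    mv_open = bc.mv_open(t_new)

    A, rhs, any_neumann = _assemble_step(
        geom, pts, state.u, u_ale, fluid, bc, cfg, mv_open, workspace=workspace
    )
    N = len(pts)
    dir_ids = _dirichlet_ids(geom, mv_open)
    dir_field = u_ale.copy()
    if bc.velocity_bc:
        extra = []
        for tag, arr in bc.velocity_bc.items():
            vids = np.unique(geom.facets_of(tag).reshape(-1))
            dir_field[vids] = np.asarray(arr)[vids]
            extra.append(vids)
        dir_field[geom.wall_vertex_ids] = u_ale[geom.wall_vertex_ids]
        dir_ids = np.unique(np.concatenate([dir_ids, *extra]))
    dir_rows = np.concatenate([dir_ids + i * N for i in range(3)])
    dir_vals = np.concatenate([dir_field[dir_ids, i] for i in range(3)])
    # pressure is anchored only if some Neumann facet has a free vertex
    if any_neumann:
        open_tags = [t for t in PV_TAGS if t not in bc.velocity_bc] + (
            [TAG_MV] if mv_open and TAG_MV not in bc.velocity_bc else [])
        fsets = [geom.facets_of(t).reshape(-1) for t in open_tags if len(geom.facets_of(t))]
        any_neumann = bool(fsets) and bool(
            np.setdiff1d(np.concatenate(fsets), dir_ids).size
        )
    pin_pressure = not any_neumann
    if pin_pressure:
        dir_rows = np.concatenate([dir_rows, [3 * N]])
        dir_vals = np.concatenate([dir_vals, [0.0]])

    ndof = A.shape[0]
    mask = np.ones(ndof)
    mask[dir_rows] = 0.0
    diag_dir = np.zeros(ndof)
    diag_dir[dir_rows] = 1.0
    A = (sp.diags(mask) @ A + sp.diags(diag_dir)).tocsc()
    rhs[dir_rows] = dir_vals

    x = _solve_monolithic(A, rhs, cfg, workspace, mv_open)

    u_new = x[: 3 * N].reshape(3, N).T.copy()
    p_new = x[3 * N :]
    if pin_pressure:
        p_new = p_new - p_new.mean()
    return FlowState(time=t_new, u=u_new, p=p_new, d=d_new)


def _solve_monolithic(A, rhs, cfg: SolverConfig, workspace, mv_open):
    """Direct solve, or LU-preconditioned GMRES against a cached LU."""

    def direct():
        try:
            lu = spla.splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular matrix
            raise _fem.SolverError(f"sparse direct solve failed: {exc}") from None
        if workspace is not None:
            workspace.update(lu=lu, age=0, mv_open=mv_open, shape=A.shape)
        return lu.solve(rhs)

    x = None
    if (
        workspace is not None
        and workspace.get("lu") is not None
        and workspace.get("mv_open") == mv_open
        and workspace.get("shape") == A.shape
        and workspace.get("age", 0) < cfg.refactor_every
    ):
        M = spla.LinearOperator(A.shape, workspace["lu"].solve)
        tol = max(cfg.linear_tolerance, 1e-10)
        # a stale-LU preconditioner either converges in a few iterations
        # or is not worth keeping: cap the budget and refactor instead
        xg, info = spla.gmres(A, rhs, rtol=tol, atol=0.0, restart=20, maxiter=3, M=M)
        if info == 0 and np.isfinite(xg).all():
            workspace["age"] = workspace.get("age", 0) + 1
            x = xg
    if x is None:
        x = direct()
    res = np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if not np.isfinite(x).all() or res > max(cfg.linear_tolerance * 100, 1e-6):
        raise _fem.SolverError(f"linear solve residual {res:.3e} exceeds tolerance")
    return x


def run(geom: ChamberGeometry, motion, fluid: FluidProperties, bc: BoundarySpec,
        cfg: SolverConfig, progress=None) -> FlowHistory:
    """Time-march ``n_beats`` heartbeats from a null initial condition.

    ``dt`` is adjusted to divide the period exactly, and the output
    stride divides the steps per beat, so snapshots align in phase
    across beats.  Per-beat cycle-to-cycle L2 velocity differences are
    recorded for periodicity monitoring.
    """
    period = bc.period or getattr(motion, "period", None)
    if period is None:
        raise ValueError("a heartbeat period is needed (set bc.period or use a periodic motion)")
    steps_per_beat = max(1, int(round(period / cfg.dt)))
    stride = max(1, int(cfg.output_stride))
    while steps_per_beat % stride:
        stride -= 1
    dt = period / steps_per_beat
    cfg_run = SolverConfig(
        dt=dt, n_beats=cfg.n_beats, output_stride=stride,
        linear_tolerance=cfg.linear_tolerance,
        max_linear_iterations=cfg.max_linear_iterations,
        c_time=cfg.c_time, c_adv=cfg.c_adv, c_diff=cfg.c_diff,
        c_graddiv=cfg.c_graddiv, refactor_every=cfg.refactor_every,
    )

    N = len(geom.vertices)
    state = FlowState(
        time=0.0, u=np.zeros((N, 3)), p=np.zeros(N), d=motion.displacement(0.0)
    )
    snaps = []
    workspace: dict = {}
    total = steps_per_beat * cfg.n_beats
    for k in range(1, total + 1):
        state = advance(state, motion, fluid, bc, cfg_run, workspace=workspace)
        if k % stride == 0:
            snaps.append(state)
        if progress is not None and k % steps_per_beat == 0:
            progress(k // steps_per_beat, cfg.n_beats)

    times = np.array([s.time for s in snaps])
    U = np.stack([s.u for s in snaps])
    P = np.stack([s.p for s in snaps])
    D = np.stack([s.d for s in snaps])

    vols = np.empty(len(snaps))
    qmv = np.empty(len(snaps))
    qpv = np.empty(len(snaps))
    ek = np.empty(len(snaps))
    vol_w = _fem.lumped_mass(geom.vertices, geom.tetrahedra)
    for i, s in enumerate(snaps):
        pts = geom.vertices + s.d
        vols[i] = _fem.signed_surface_volume(pts, geom.boundary_facets) / ML
        u_ale = motion.velocity(s.time)
        if bc.mv_open(s.time):
            qmv[i] = _outward_flux(pts, geom.facets_of(TAG_MV), s.u, u_ale) / ML
        else:
            qmv[i] = 0.0
        qpv[i] = -sum(
            _outward_flux(pts, geom.facets_of(tag), s.u, u_ale)
            for tag in PV_TAGS if len(geom.facets_of(tag))
        ) / ML
        ek[i] = 0.5 * float(vol_w @ (s.u**2).sum(axis=1))

    spb_out = steps_per_beat // stride
    beat_diffs = []
    for b in range(1, cfg.n_beats):
        a = U[(b - 1) * spb_out : b * spb_out]
        bb = U[b * spb_out : (b + 1) * spb_out]
        num = np.sqrt(((bb - a) ** 2).sum())
        den = max(np.sqrt((bb**2).sum()), 1e-300)
        beat_diffs.append(float(num / den))

    return FlowHistory(
        times=times, u=U, p=P, d=D, period=period, dt=dt, stride=stride,
        n_beats=cfg.n_beats, volume_mL=vols, q_mv_mL_s=qmv, q_pv_mL_s=qpv,
        kinetic_energy=ek, beat_l2_differences=beat_diffs,
    )
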