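"""Analytic solver benchmarks: hydrostatic equilibrium and pressure-driven
pipe flow against the closed-form laminar solution.

Used by the verification suite and the acceptance report; not part of the
cohort pipeline.
"""

from __future__ import annotations

import numpy as np

from . import _fem
from .cohort import TAG_MV, TAG_PV1, TAG_WALL, ChamberGeometry
from .features import PhaseAveragedFlow, wss_history
from .fixtures import boundary_faces, tube_mesh
from .flow import (
    BoundarySpec, FlowState, FluidProperties, SolverConfig, StaticMotion, advance,
)

__all__ = ["pipe_chamber", "poiseuille_benchmark", "hydrostatic_benchmark"]


def pipe_chamber(radius=0.005, length=0.02, n_rad=4, n_ax=8) -> ChamberGeometry:
    """Straight tube tagged inlet (PV1) / outlet (MV) / lateral wall."""
    z = np.linspace(0.0, length, n_ax + 1)
    curve = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
    pts, tets, _ = tube_mesh(curve, radius, n_rad=n_rad)
    tris = boundary_faces(tets)
    zc = pts[tris].mean(axis=1)[:, 2]
    tags = np.full(len(tris), TAG_WALL)
    tags[zc < 1e-9] = TAG_PV1
    tags[zc > length - 1e-9] = TAG_MV
    return ChamberGeometry(pts, tets, tris, tags, np.array([], int),
                           np.array([], int), np.array([], int))


def poiseuille_benchmark(n_rad=8, n_ax=16, radius=0.005, length=0.02,
                         u_max=0.002, dt=2.0, n_steps=25,
                         fluid: FluidProperties | None = None) -> dict:
    """Steady pressure-driven pipe flow vs the parabolic closed form.

    Returns the ratios of the computed mid-length centerline velocity and
    wall shear magnitude to their exact values ``u_max`` and
    ``2*mu*u_max/R``.  Ratios approach 1 under refinement.
    """
    fluid = fluid or FluidProperties()
    mu = fluid.dynamic_viscosity
    geom = pipe_chamber(radius, length, n_rad, n_ax)
    dp = 4 * mu * length * u_max / radius**2
    bc = BoundarySpec(p_in=dp, p_out=0.0, mv_schedule=[(0.0, "open")], period=1.0)
    motion = StaticMotion(geom)
    cfg = SolverConfig(dt=dt, n_beats=1)
    n = len(geom.vertices)
    state = FlowState(0.0, np.zeros((n, 3)), np.zeros(n), np.zeros((n, 3)))
    workspace: dict = {}
    for _ in range(n_steps):
        state = advance(state, motion, fluid, bc, cfg, workspace=workspace)

    pts = geom.vertices
    r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
    on_axis = (r2 < 1e-12) & (np.abs(pts[:, 2] - length / 2) < length / 4)
    u_center = float(state.u[on_axis, 2].mean())

    pa = PhaseAveragedFlow(times=np.array([0.0]), u=state.u[None],
                           d=np.zeros((1, n, 3)), period=1.0,
                           n_discarded=0, n_averaged=1)
    wall_ids, wss = wss_history(pa, geom, mu=mu)
    mag = np.linalg.norm(wss[0], axis=1)
    lateral = np.abs(np.sqrt(r2[wall_ids]) - radius) < 1e-9
    mid = lateral & (np.abs(pts[wall_ids, 2] - length / 2) < length / 4)
    wss_mid = float(mag[mid].mean())
    return {
        "u_ratio": u_center / u_max,
        "wss_ratio": wss_mid / (2 * mu * u_max / radius),
    }


def hydrostatic_benchmark(geom: ChamberGeometry, p_level=1333.22, n_steps=3,
                          dt=2e-3) -> dict:
    """Equal-pressure, zero-motion equilibrium: u must stay numerically zero."""
    motion = StaticMotion(geom)
    bc = BoundarySpec(p_in=p_level, p_out=p_level,
                      mv_schedule=[(0.0, "open")], period=1.0)
    cfg = SolverConfig(dt=dt, n_beats=1)
    n = len(geom.vertices)
    state = FlowState(0.0, np.zeros((n, 3)), np.zeros(n), np.zeros((n, 3)))
    for _ in range(n_steps):
        state = advance(state, motion, FluidProperties(), bc, cfg)
    return {
        "u_max": float(np.abs(state.u).max()),
        "p_deviation": float(np.abs(state.p - p_level).max()),
    }
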