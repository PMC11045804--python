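"""Shared fixtures.

Expensive artifacts (meshes, CFD runs, the 4+4 cohort) are session-scoped
and generated programmatically; nothing is read from checked-in binaries.
"""

from __future__ import annotations

import numpy as np
import pytest

from atriflow.cohort import (
    GeometryParams, PhenotypeParams, build_reference_mesh, sample_cohort,
    scale_to_volume, volume_waveform, frames_from_waveform,
)
from atriflow.fixtures import box_mesh, boundary_faces, straight_tube_chamber, laa_tube_chamber


@pytest.fixture(scope="session")
def coarse_geom():
    """Default chamber at desk-coarse resolution (~1.5k tets)."""
    return build_reference_mesh(GeometryParams(target_edge_length=0.007))


@pytest.fixture(scope="session")
def default_geom():
    """Default chamber at the 4 mm default edge length."""
    return build_reference_mesh(GeometryParams())


@pytest.fixture(scope="session")
def box():
    pts, tets = box_mesh((1.0, 1.0, 1.0), (5, 5, 5))
    return pts, tets, boundary_faces(tets)


@pytest.fixture(scope="session")
def straight_laa():
    return straight_tube_chamber(length=0.03, radius=0.006, n_axial=12, n_rad=3, stub=2)


@pytest.fixture(scope="session")
def bent_laa():
    return laa_tube_chamber()


@pytest.fixture(scope="session")
def control_case():
    return sample_cohort(1, 0, seed=1)[0]


@pytest.fixture(scope="session")
def moving_chamber(control_case):
    """Geometry + frames + fitted motion for one control case (coarse)."""
    from atriflow.motion import fit_displacement_model, volumetric_motion
    from atriflow.pipeline import RunConfig, build_case_geometry

    p = control_case
    geom = build_case_geometry(p, RunConfig(edge_length=0.006))
    trace = volume_waveform(p)
    frames = frames_from_waveform(geom, trace, p)
    model = fit_displacement_model(frames, 0.0)
    motion = volumetric_motion(geom, model)
    return p, geom, trace, frames, model, motion


@pytest.fixture(scope="session")
def three_beat_run(moving_chamber):
    """A 3-beat moving-chamber CFD run at coarse settings (criterion fixture)."""
    from atriflow.flow import BoundarySpec, FluidProperties, SolverConfig, mv_schedule, run

    p, geom, trace, frames, model, motion = moving_chamber
    bc = BoundarySpec(mv_schedule=mv_schedule(trace, period=p.period), period=p.period)
    cfg = SolverConfig(dt=5e-3, n_beats=3, output_stride=2)
    hist = run(geom, motion, FluidProperties(), bc, cfg)
    return p, geom, trace, motion, bc, hist


@pytest.fixture(scope="session")
def cohort_table():
    """Full 4+4 cohort pipeline at scaled-down settings (criterion 9)."""
    from atriflow.pipeline import RunConfig, run_pipeline

    cfg = RunConfig(
        n_control=4, n_stroke=4, seed=1, edge_length=0.005,
        dt=8e-3, n_beats=2, output_stride=2, n_discard=1, n_average=1,
        refactor_every=6,
    )
    manifests, table, matrices, errors = run_pipeline(cfg)
    assert not errors, f"cohort pipeline reported case failures: {errors}"
    return table, matrices
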