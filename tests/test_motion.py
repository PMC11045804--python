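import numpy as np
import pytest

from atriflow import _fem
from atriflow._splines import PeriodicSmoothingSpline, choose_smoothing_gcv
from atriflow.cohort import TAG_MV, TAG_PV1, TAG_WALL, ChamberGeometry, FrameSet
from atriflow.errors import InsufficientDataError, TaggingError
from atriflow.fixtures import box_mesh, boundary_faces
from atriflow.motion import (
    LiftingConfig, ale_boundary_velocity, fit_displacement_model,
    harmonic_lifting, volumetric_motion, wall_distance_field,
)

T = 1.0


def _sine_frames(n_frames=25, amp=1e-3, noise=0.0, rng=None, n_wall=5):
    t = np.arange(n_frames) * T / n_frames
    base = amp * np.sin(2 * np.pi * t / T)
    disps = np.zeros((n_frames, n_wall, 3))
    disps[:, :, 0] = base[:, None]
    if noise:
        disps += rng.normal(0.0, noise, disps.shape)
    return FrameSet(frame_times=t, wall_vertex_ids=np.arange(n_wall),
                    boundary_displacements=disps, period=T)


# ----------------------------------------------------------------------
# temporal spline model
# ----------------------------------------------------------------------

def test_interpolating_limit():
    fr = _sine_frames(n_frames=25, amp=2.0)
    m = fit_displacement_model(fr, smoothing_weight=0.0)
    for i, t in enumerate(fr.frame_times):
        assert np.abs(m(t) - fr.boundary_displacements[i]).max() < 1e-6 * 2.0


def test_smoothing_reduces_noise():
    rng = np.random.default_rng(0)
    amp, sigma = 1.0, 0.05
    t = np.arange(25) * T / 25
    clean = amp * np.sin(2 * np.pi * t / T)
    wins = 0
    for _ in range(100):
        noisy = clean + rng.normal(0, sigma, len(t))
        lam = choose_smoothing_gcv(t, noisy, T)
        s = PeriodicSmoothingSpline(t, noisy, T, lam=lam)
        rms_model = np.sqrt(np.mean((s(t) - clean) ** 2))
        rms_noisy = np.sqrt(np.mean((noisy - clean) ** 2))
        wins += rms_model < rms_noisy
    assert wins > 80  # smoothing beats raw noise in the vast majority of draws


def test_model_periodicity():
    fr = _sine_frames()
    m = fit_displacement_model(fr, 0.0)
    rng = np.random.default_rng(1)
    for t in rng.uniform(0, T, 20):
        assert np.abs(m(t + T) - m(t)).max() < 1e-10


def test_too_few_frames():
    fr = _sine_frames(n_frames=25)
    short = FrameSet(frame_times=fr.frame_times[:3],
                     wall_vertex_ids=fr.wall_vertex_ids,
                     boundary_displacements=fr.boundary_displacements[:3],
                     period=T)
    with pytest.raises(InsufficientDataError):
        fit_displacement_model(short)


def test_duplicate_frame_times():
    fr = _sine_frames()
    tt = fr.frame_times.copy()
    tt[3] = tt[2]
    dup = FrameSet(frame_times=tt, wall_vertex_ids=fr.wall_vertex_ids,
                   boundary_displacements=fr.boundary_displacements, period=T)
    with pytest.raises(ValueError):
        fit_displacement_model(dup)


# ----------------------------------------------------------------------
# ALE boundary velocity
# ----------------------------------------------------------------------

def test_constant_displacement_zero_velocity():
    fr = _sine_frames(amp=0.0)
    fr.boundary_displacements[:] = 3.3e-3
    m = fit_displacement_model(fr, 0.0)
    assert np.abs(ale_boundary_velocity(m, 0.37)).max() < 1e-12


def test_sine_velocity_amplitude():
    amp = 1e-3
    fr = _sine_frames(n_frames=40, amp=amp)
    m = fit_displacement_model(fr, 0.0)
    v0 = ale_boundary_velocity(m, 0.0)[0, 0]
    assert abs(v0 - 2 * np.pi * amp / T) / (2 * np.pi * amp / T) < 0.01


def test_velocity_period_average_zero():
    rng = np.random.default_rng(2)
    fr = _sine_frames(n_frames=30, amp=1e-3, noise=2e-4, rng=rng)
    m = fit_displacement_model(fr, 0.0)
    tt = np.linspace(0, T, 4001)
    vals = np.stack([ale_boundary_velocity(m, t) for t in tt])
    avg = np.trapezoid(vals, tt, axis=0) / T
    scale = np.abs(vals).max()
    assert np.abs(avg).max() < 1e-6 * scale  # exact up to quadrature error


def test_velocity_matches_finite_difference():
    fr = _sine_frames(n_frames=30, amp=1e-3)
    m = fit_displacement_model(fr, 0.0)
    h = 1e-6
    for t in (0.11, 0.42, 0.9):
        fd = (m(t + h) - m(t - h)) / (2 * h)
        assert np.abs(ale_boundary_velocity(m, t) - fd).max() < 1e-6


# ----------------------------------------------------------------------
# wall distance
# ----------------------------------------------------------------------

def test_wall_distance_basics(coarse_geom):
    d = wall_distance_field(coarse_geom)
    assert np.all(d >= 0)
    assert np.abs(d[coarse_geom.wall_vertex_ids]).max() == 0.0


def test_wall_distance_sphere_oracle():
    from atriflow.cohort import GeometryParams, build_reference_mesh

    r = 0.025
    g = build_reference_mesh(GeometryParams(
        chamber_semi_axes=(r, r, r), laa_length=0.0, laa_radius=0.0,
        target_edge_length=r / 6))
    d = wall_distance_field(g)
    c = g.vertices[g.tetrahedra].mean(axis=(0, 1))
    rho = np.linalg.norm(g.vertices - c, axis=1)
    interior = rho < 0.7 * r  # away from the port disks
    expected = r - rho[interior]
    assert np.abs(d[interior] - expected).max() < r / 6


def test_wall_distance_requires_wall_tag(coarse_geom):
    g = ChamberGeometry(
        vertices=coarse_geom.vertices, tetrahedra=coarse_geom.tetrahedra,
        boundary_facets=coarse_geom.boundary_facets,
        facet_tags=np.full(len(coarse_geom.boundary_facets), TAG_MV),
        laa_wall_vertices=np.array([], int), laa_cells=np.array([], int),
        ostium_ring=np.array([], int))
    with pytest.raises(TaggingError):
        wall_distance_field(g)


# ----------------------------------------------------------------------
# harmonic lifting
# ----------------------------------------------------------------------

def _box_chamber(n=5):
    """Unit box as a chamber: x=0 and x=1 faces tagged WALL, rest PV/MV."""
    pts, tets = box_mesh((1.0, 1.0, 1.0), (n, n, n))
    tris = boundary_faces(tets)
    c = pts[tris].mean(axis=1)
    tags = np.full(len(tris), TAG_PV1)
    wall = (c[:, 0] < 1e-9) | (c[:, 0] > 1 - 1e-9)
    tags[wall] = TAG_WALL
    tags[c[:, 2] < 1e-9] = TAG_MV
    return ChamberGeometry(pts, tets, tris, tags, np.array([], int),
                           np.array([], int), np.array([], int))


def test_lifting_uniform_translation(coarse_geom):
    c = np.array([1e-3, -2e-3, 0.5e-3])
    wall = coarse_geom.wall_vertex_ids
    bd = np.tile(c, (len(wall), 1))
    d = harmonic_lifting(coarse_geom, bd)
    assert np.abs(d - c).max() < 1e-8 * np.linalg.norm(c)


def test_lifting_linear_profile_on_box():
    g = _box_chamber(5)
    wall = g.wall_vertex_ids
    bd = np.zeros((len(wall), 3))
    bd[:, 0] = g.vertices[wall, 0]  # d_x = 0 at x=0, 1 at x=1
    d = harmonic_lifting(g, bd, LiftingConfig(beta=0.0))
    assert np.abs(d[:, 0] - g.vertices[:, 0]).max() < 1e-6


def test_lifting_dirichlet_exact(coarse_geom):
    rng = np.random.default_rng(3)
    wall = coarse_geom.wall_vertex_ids
    bd = rng.normal(0, 1e-3, (len(wall), 3))
    d = harmonic_lifting(coarse_geom, bd)
    assert np.abs(d[wall] - bd).max() == 0.0  # strong imposition


def test_lifting_max_principle_box():
    g = _box_chamber(5)
    wall = g.wall_vertex_ids
    rng = np.random.default_rng(4)
    bd = np.zeros((len(wall), 3))
    bd[:, 1] = rng.uniform(-1.0, 2.0, len(wall))
    d = harmonic_lifting(g, bd, LiftingConfig(beta=0.0))
    lo, hi = bd[:, 1].min(), bd[:, 1].max()
    eps = 1e-8 * (hi - lo)
    assert d[:, 1].min() >= lo - eps
    assert d[:, 1].max() <= hi + eps


def test_stiffening_protects_quality(coarse_geom):
    # strong uniform contraction toward the centroid
    g = coarse_geom
    c = g.vertices[g.tetrahedra].mean(axis=(0, 1))
    wall = g.wall_vertex_ids
    bd = -0.18 * (g.vertices[wall] - c)
    dist = wall_distance_field(g)
    qmin = {}
    for beta in (0.0, 1.0, 2.0):
        d = harmonic_lifting(g, bd, LiftingConfig(beta=beta), wall_distance=dist)
        qmin[beta] = _fem.scaled_jacobians(g.vertices + d, g.tetrahedra).min()
    assert qmin[2.0] >= qmin[0.0] - 1e-12
    assert qmin[1.0] >= qmin[0.0] - 1e-12


# ----------------------------------------------------------------------
# volumetric motion
# ----------------------------------------------------------------------

def test_zero_motion(coarse_geom):
    fr = FrameSet(
        frame_times=np.arange(25) / 25.0,
        wall_vertex_ids=coarse_geom.wall_vertex_ids,
        boundary_displacements=np.zeros((25, len(coarse_geom.wall_vertex_ids), 3)),
        period=1.0)
    m = fit_displacement_model(fr, 0.0)
    mo = volumetric_motion(coarse_geom, m)
    assert np.abs(mo.displacement(0.4)).max() == 0.0
    assert np.abs(mo.velocity(0.4)).max() == 0.0


def test_motion_tracks_volume(moving_chamber):
    p, geom, trace, frames, model, motion = moving_chamber
    ts = np.linspace(0, p.period, 40, endpoint=False)
    for t in ts:
        v = motion.volume_m3(t) / 1e-6
        target = np.interp(t, trace.times, trace.volumes, period=p.period)
        assert abs(v - target) / target < 0.015


def test_motion_positive_jacobians(moving_chamber):
    p, geom, trace, frames, model, motion = moving_chamber
    for t in np.linspace(0, p.period, 37, endpoint=False):
        q = _fem.scaled_jacobians(motion.moved_points(t), geom.tetrahedra)
        assert q.min() > 0


def test_motion_velocity_consistent(moving_chamber):
    p, geom, trace, frames, model, motion = moving_chamber
    h = 1e-5
    for t in (0.2 * p.period, 0.7 * p.period):
        fd = (motion.displacement(t + h) - motion.displacement(t - h)) / (2 * h)
        v = motion.velocity(t)
        assert np.abs(v - fd).max() < 1e-7 + 1e-4 * np.abs(v).max()
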