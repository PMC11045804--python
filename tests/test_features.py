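import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriflow import _fem
from atriflow.cohort import TAG_MV, TAG_PV1, TAG_WALL, ChamberGeometry
from atriflow.features import (
    PhaseAveragedFlow, flow_stasis, global_traces, phase_average,
    region_medians, vorticity_magnitude, vorticity_phase_medians,
    wall_features, wss_history,
)
from atriflow.fixtures import box_mesh, boundary_faces
from atriflow.flow import FlowHistory

MU = 3.5e-3


def _history(u_snaps, period=1.0, n_beats=1):
    K, N, _ = u_snaps.shape
    dt = period * n_beats / K
    return FlowHistory(
        times=dt * (np.arange(K) + 1), u=u_snaps, p=np.zeros((K, N)),
        d=np.zeros((K, N, 3)), period=period, dt=dt, stride=1,
        n_beats=n_beats, volume_mL=np.zeros(K), q_mv_mL_s=np.zeros(K),
        q_pv_mL_s=np.zeros(K), kinetic_energy=np.zeros(K))


def _pa(u_snaps, d=None, period=1.0):
    K, N, _ = u_snaps.shape
    return PhaseAveragedFlow(
        times=period * np.arange(K) / K, u=u_snaps,
        d=np.zeros((K, N, 3)) if d is None else d, period=period,
        n_discarded=0, n_averaged=1)


# ----------------------------------------------------------------------
# phase averaging
# ----------------------------------------------------------------------

def test_phase_average_of_periodic_history():
    rng = np.random.default_rng(0)
    beat = rng.normal(size=(10, 30, 3))
    hist = _history(np.tile(beat, (3, 1, 1)), n_beats=3)
    pa = phase_average(hist, n_discard=1, n_average=2)
    assert np.abs(pa.u - beat).max() < 1e-12


def test_phase_average_single_beat_identity():
    rng = np.random.default_rng(1)
    u = rng.normal(size=(8, 20, 3))
    hist = _history(u, n_beats=2)
    pa = phase_average(hist, n_discard=1, n_average=1)
    assert np.array_equal(pa.u, u[4:])


def test_phase_average_noise_reduction():
    rng = np.random.default_rng(2)
    sigma, reps = 0.3, 50
    beat = np.zeros((6, 10, 3))
    ratios = []
    for _ in range(reps):
        noisy = np.tile(beat, (8, 1, 1)) + rng.normal(0, sigma, (48, 10, 3))
        pa = phase_average(_history(noisy, n_beats=8), 0, 8)
        ratios.append(np.sqrt(np.mean(pa.u**2)) / (sigma / np.sqrt(8)))
    assert abs(np.mean(ratios) - 1.0) < 0.2


def test_phase_average_insufficient_beats():
    hist = _history(np.zeros((9, 5, 3)), n_beats=3)
    with pytest.raises(ValueError):
        phase_average(hist, n_discard=2, n_average=2)


def test_features_invariant_under_beat_duplication():
    rng = np.random.default_rng(3)
    beat = rng.normal(0, 0.2, size=(6, 25, 3))
    h1 = _history(np.tile(beat, (2, 1, 1)), n_beats=2)
    h2 = _history(np.tile(beat, (4, 1, 1)), n_beats=4)
    fs1 = flow_stasis(phase_average(h1, 1, 1)).fs
    fs2 = flow_stasis(phase_average(h2, 1, 3)).fs
    assert np.abs(fs1 - fs2).max() < 1e-12


# ----------------------------------------------------------------------
# flow stasis
# ----------------------------------------------------------------------

def test_fs_zero_flow():
    pa = _pa(np.zeros((10, 7, 3)))
    assert np.all(flow_stasis(pa).fs == 1.0)


def test_fs_fast_flow():
    u = np.zeros((10, 7, 3))
    u[:, :, 0] = 0.2
    assert np.all(flow_stasis(_pa(u), threshold=0.1).fs == 0.0)


def test_fs_two_level_fixture():
    K = 100
    u = np.zeros((K, 4, 3))
    u[: int(0.3 * K), :, 0] = 0.05
    u[int(0.3 * K):, :, 0] = 0.2
    fs = flow_stasis(_pa(u), threshold=0.1).fs
    assert np.abs(fs - 0.30).max() <= 1.0 / K + 1e-12


def test_fs_monotone_in_threshold():
    rng = np.random.default_rng(4)
    u = rng.normal(0, 0.1, (20, 50, 3))
    pa = _pa(u)
    prev = None
    for thr in (0.02, 0.05, 0.1, 0.2, 0.5):
        fs = flow_stasis(pa, thr).fs
        if prev is not None:
            assert np.all(fs >= prev - 1e-15)
        prev = fs


def test_fs_invalid_threshold():
    with pytest.raises(ValueError):
        flow_stasis(_pa(np.zeros((5, 3, 3))), threshold=0.0)


# ----------------------------------------------------------------------
# WSS
# ----------------------------------------------------------------------

def _box_chamber(n=4, lengths=(1.0, 1.0, 1.0)):
    pts, tets = box_mesh(lengths, (n, n, n))
    tris = boundary_faces(tets)
    c = pts[tris].mean(axis=1)
    tags = np.full(len(tris), TAG_PV1)
    tags[c[:, 1] < 1e-9] = TAG_WALL  # wall at y = 0
    tags[c[:, 2] < 1e-9] = TAG_MV
    return ChamberGeometry(pts, tets, tris, tags, np.array([], int),
                           np.array([], int), np.array([], int))


def test_wss_couette():
    g = _box_chamber(4)
    gamma = 2.5
    u = np.zeros((1, len(g.vertices), 3))
    u[0, :, 0] = gamma * g.vertices[:, 1]  # u = gamma*y*e1, wall at y=0
    ids, wss = wss_history(_pa(u), g, mu=MU)
    exact = MU * gamma
    mag = np.linalg.norm(wss[0], axis=1)
    assert np.abs(mag - exact).max() / exact < 0.02
    # direction along +-e1
    assert np.abs(np.abs(wss[0, :, 0]) - mag).max() < 1e-12 * exact


def test_wss_normal_velocity_projected_out():
    g = _box_chamber(4)
    u = np.zeros((1, len(g.vertices), 3))
    u[0, :, 1] = 3.0 * g.vertices[:, 1]  # purely wall-normal, varies along normal
    ids, wss = wss_history(_pa(u), g, mu=MU)
    assert np.linalg.norm(wss[0], axis=1).max() < 1e-8 * MU * 3.0


# ----------------------------------------------------------------------
# TAWSS / OSI / RRT / ECAP
# ----------------------------------------------------------------------

def _uni_wss(K, W, w, pattern):
    """WSS history +-w*e1 following a boolean pattern of length K."""
    wss = np.zeros((K, W, 3))
    for k in range(K):
        wss[k, :, 0] = w if pattern[k] else -w
    return wss


def test_wall_features_constant_unidirectional():
    w = 0.8
    wss = _uni_wss(8, 5, w, [True] * 8)
    f = wall_features(wss)
    assert np.allclose(f.tawss, w)
    assert np.allclose(f.osi, 0.0)
    assert np.allclose(f.rrt, 1.0 / w)
    assert np.allclose(f.ecap, 0.0)


def test_wall_features_half_period_reversal():
    w = 0.6
    wss = _uni_wss(8, 5, w, [True] * 4 + [False] * 4)
    f = wall_features(wss)
    assert np.allclose(f.osi, 0.5)
    assert np.all(~np.isfinite(f.rrt))  # flagged divergent


def test_wall_features_three_to_one_duty():
    w = 1.2
    wss = _uni_wss(8, 5, w, [True] * 6 + [False] * 2)
    f = wall_features(wss)
    # mean vec = w/2, mean |.| = w -> osi = 1/4, rrt = 2/w
    assert np.abs(f.osi - 0.25).max() < 1e-12
    assert np.abs(f.tawss - w).max() < 1e-12
    assert np.abs(f.rrt - 2.0 / w).max() / (2 / w) < 0.01


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_wall_feature_identities_random(seed):
    rng = np.random.default_rng(seed)
    wss = rng.normal(0, 1.0, (12, 8, 3))
    f = wall_features(wss)
    assert np.all(f.osi >= 0.0) and np.all(f.osi <= 0.5)
    defined = np.isfinite(f.rrt)
    prod = f.rrt[defined] * (1 - 2 * f.osi[defined]) * f.tawss[defined]
    assert np.abs(prod - 1.0).max() < 1e-10
    assert np.abs(f.ecap * f.tawss - f.osi).max() < 1e-12


def test_wall_features_zero_shear_vertex():
    wss = np.zeros((6, 3, 3))
    f = wall_features(wss)
    assert np.all(f.osi == 0.0)
    assert np.all(~np.isfinite(f.rrt))


# ----------------------------------------------------------------------
# kinetic energy / enstrophy / vorticity
# ----------------------------------------------------------------------

def test_global_traces_zero_flow(coarse_geom):
    pa = _pa(np.zeros((3, len(coarse_geom.vertices), 3)))
    gt = global_traces(pa, coarse_geom)
    assert np.all(gt.kinetic_energy == 0.0)
    assert np.all(gt.enstrophy == 0.0)


def test_global_traces_uniform_velocity(coarse_geom):
    g = coarse_geom
    U = np.array([0.3, -0.1, 0.2])
    u = np.tile(U, (1, len(g.vertices), 1))
    gt = global_traces(_pa(u), g)
    V = np.abs(_fem.tet_volumes(g.vertices, g.tetrahedra)).sum()
    ek_exact = 0.5 * np.dot(U, U) * V
    assert abs(gt.kinetic_energy[0] - ek_exact) / ek_exact < 1e-6
    L = 0.06  # chamber size scale
    assert gt.enstrophy[0] < 1e-6 * np.dot(U, U) * V / L**2


def _ball_geom():
    from atriflow.cohort import GeometryParams, build_reference_mesh

    r = 0.025
    return build_reference_mesh(GeometryParams(
        chamber_semi_axes=(r, r, r), laa_length=0.0, laa_radius=0.0,
        target_edge_length=r / 7))


def test_enstrophy_rigid_rotation():
    g = _ball_geom()
    Om = np.array([0.0, 0.0, 12.0])
    c = g.vertices.mean(axis=0)
    u = np.cross(Om, g.vertices - c)[None]
    gt = global_traces(_pa(u), g)
    V = np.abs(_fem.tet_volumes(g.vertices, g.tetrahedra)).sum()
    exact = 2.0 * np.dot(Om, Om) * V
    assert abs(gt.enstrophy[0] - exact) / exact < 0.05


def test_vorticity_rigid_rotation_median():
    g = _ball_geom()
    Om = np.array([0.0, 3.0, 4.0])
    u = np.cross(Om, g.vertices - g.vertices.mean(axis=0))[None]
    om = vorticity_magnitude(_pa(u), g, 0)
    assert abs(np.median(om) - 2 * np.linalg.norm(Om)) / (2 * np.linalg.norm(Om)) < 0.05


def test_vorticity_phase_medians_zero(default_geom):
    g = default_geom
    pa = _pa(np.zeros((6, len(g.vertices), 3)))
    med = vorticity_phase_medians(pa, g, 0.1, 0.4, 0.8)
    assert all(v == 0.0 for v in med.values())


# ----------------------------------------------------------------------
# region medians
# ----------------------------------------------------------------------

def _fields(geom, fs_value=0.5, wall_values=None):
    from atriflow.features import VolumeFeatureField, WallFeatureField

    n = len(geom.vertices)
    wall_ids = geom.wall_vertex_ids
    w = np.full(len(wall_ids), 1.0) if wall_values is None else wall_values
    return (VolumeFeatureField(fs=np.full(n, fs_value)),
            WallFeatureField(wall_vertex_ids=wall_ids, tawss=w, osi=w / 10,
                             rrt=1 / w, ecap=w / 5))


def test_region_medians_constant_field(default_geom):
    fsf, wf = _fields(default_geom, fs_value=0.37)
    med = region_medians(default_geom, fsf, wf)
    by_region = {m.region: m for m in med}
    assert by_region["LA"].fs == 0.37
    assert by_region["LAA"].fs == 0.37
    assert by_region["LA"].tawss == 1.0


def test_region_medians_brute_force(default_geom):
    g = default_geom
    rng = np.random.default_rng(7)
    wall_ids = g.wall_vertex_ids
    w = rng.uniform(0.1, 2.0, len(wall_ids))
    fsf, wf = _fields(g, wall_values=w)
    med = {m.region: m for m in region_medians(g, fsf, wf)}
    assert med["LA"].tawss == float(np.median(np.sort(w)))
    mask = np.isin(wall_ids, g.laa_wall_vertices)
    assert med["LAA"].tawss == float(np.median(np.sort(w[mask])))


def test_region_medians_permutation_invariance(default_geom):
    g = default_geom
    rng = np.random.default_rng(8)
    w = rng.uniform(0.1, 2.0, len(g.wall_vertex_ids))
    fsf, wf = _fields(g, wall_values=w)
    m1 = {m.region: m.tawss for m in region_medians(g, fsf, wf)}
    perm = rng.permutation(len(w))
    from atriflow.features import WallFeatureField

    wf2 = WallFeatureField(wall_vertex_ids=wf.wall_vertex_ids[perm],
                           tawss=w[perm], osi=wf.osi[perm],
                           rrt=wf.rrt[perm], ecap=wf.ecap[perm])
    m2 = {m.region: m.tawss for m in region_medians(g, fsf, wf2)}
    assert m1 == m2


def test_region_masking(default_geom):
    g = default_geom
    wall_ids = g.wall_vertex_ids
    indicator = np.isin(wall_ids, g.laa_wall_vertices).astype(float)
    fsf, wf = _fields(g, wall_values=np.where(indicator > 0, 1.0, 1e-12))
    med = {m.region: m for m in region_medians(g, fsf, wf)}
    assert med["LAA"].tawss == 1.0
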