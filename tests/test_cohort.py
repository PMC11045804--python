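import numpy as np
import pytest

from atriflow import _fem
from atriflow.cohort import (
    TAG_MV, TAG_WALL, PV_TAGS,
    GeometryParams, PhenotypeParams, build_reference_mesh, centerline_fixture,
    frames_from_waveform, sample_cohort, scale_to_volume, volume_waveform,
)
from atriflow.errors import InfeasibleMotionError
from atriflow.functional import VolumeTrace, tortuosity


# ----------------------------------------------------------------------
# sample_cohort
# ----------------------------------------------------------------------

def test_empty_cohort():
    assert sample_cohort(0, 0, seed=3) == []


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        sample_cohort(-1, 2, seed=0)


def test_bpm_ranges_follow_reported_cohort():
    # control heart rates within [50.3, 57.7], stroke within [51.5, 76.0]
    cases = sample_cohort(4, 4, seed=11)
    for p in cases:
        if p.group == "control":
            assert 50.3 <= p.bpm <= 57.7
        else:
            assert 51.5 <= p.bpm <= 76.0


def test_seeded_determinism():
    a = sample_cohort(3, 3, seed=5)
    b = sample_cohort(3, 3, seed=5)
    assert a == b
    c = sample_cohort(3, 3, seed=6)
    assert any(x != y for x, y in zip(a, c))


@pytest.mark.parametrize("seed", [0, 1, 2, 17, 123])
def test_group_contracts_any_seed(seed):
    cases = sample_cohort(4, 4, seed=seed)
    ctrl = [p for p in cases if p.group == "control"]
    strk = [p for p in cases if p.group == "stroke"]
    sv = lambda ps: np.median([p.stroke_volume for p in ps])
    bpm = lambda ps: np.median([p.bpm for p in ps])
    assert sv(strk) < sv(ctrl)
    assert bpm(strk) > bpm(ctrl)
    # EF intervals intersect
    ef_c = [p.ejection_fraction for p in ctrl]
    ef_s = [p.ejection_fraction for p in strk]
    assert min(ef_c) <= max(ef_s) and min(ef_s) <= max(ef_c)
    assert all(p.n_frames in (25, 30, 40) for p in cases)


def test_stroke_has_smaller_volumes():
    cases = sample_cohort(4, 4, seed=2)
    vmax_c = [p.v_max for p in cases if p.group == "control"]
    vmax_s = [p.v_max for p in cases if p.group == "stroke"]
    assert max(vmax_s) < min(vmax_c)


def test_phenotype_validation():
    with pytest.raises(ValueError):
        PhenotypeParams("control", v_max=50, v_min=60, bpm=60, n_frames=25,
                        e_fraction=0.5, seed=0)
    with pytest.raises(ValueError):
        PhenotypeParams("control", v_max=50, v_min=40, bpm=60, n_frames=26,
                        e_fraction=0.5, seed=0)


# ----------------------------------------------------------------------
# build_reference_mesh
# ----------------------------------------------------------------------

def test_sphere_degenerate_volume():
    r = 0.025
    gp = GeometryParams(
        chamber_semi_axes=(r, r, r), laa_length=0.0, laa_radius=0.0,
        target_edge_length=r / 8,
    )
    g = build_reference_mesh(gp)
    v = g.enclosed_volume_m3()
    assert abs(v - 4 / 3 * np.pi * r**3) / (4 / 3 * np.pi * r**3) < 0.05


def test_default_mesh_tags_and_topology(default_geom):
    g = default_geom
    # every boundary facet carries exactly one tag (tags array covers all)
    assert len(g.facet_tags) == len(g.boundary_facets)
    assert set(np.unique(g.facet_tags)) == {TAG_WALL, *PV_TAGS, TAG_MV}
    # Euler characteristic of the closed boundary surface = 2
    f = g.boundary_facets
    V = len(np.unique(f.reshape(-1)))
    E = len(np.unique(np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1), axis=0))
    assert V - E + len(f) == 2
    # positively oriented tets, outward volume
    assert _fem.tet_volumes(g.vertices, g.tetrahedra).min() > 0
    assert g.enclosed_volume_m3() > 0


def test_constructive_volume_matches_support_quadrature(default_geom):
    # independent oracle: (1/3) * integral of R(u)^3 over the sphere of
    # directions, by dense Fibonacci quadrature on the support function
    from atriflow.cohort import _fibonacci_sphere, _support_radius

    gp = GeometryParams()
    dirs = _fibonacci_sphere(200_000)
    r_cut, bump, _ = _support_radius(dirs, gp)
    R = r_cut + bump
    v_solid = (R**3).mean() * 4 * np.pi / 3  # = (1/3) * mean(R^3) * 4*pi
    assert abs(default_geom.enclosed_volume_m3() - v_solid) / v_solid < 0.10


def test_refinement_scaling():
    gp1 = GeometryParams(laa_length=0.0, laa_radius=0.0, target_edge_length=0.004)
    gp2 = GeometryParams(laa_length=0.0, laa_radius=0.0, target_edge_length=0.002)
    n1 = len(build_reference_mesh(gp1).boundary_facets)
    n2 = len(build_reference_mesh(gp2).boundary_facets)
    assert 3.0 <= n2 / n1 <= 5.0


def test_geometry_error_on_extreme_parameters():
    from atriflow.errors import GeometryError

    with pytest.raises((GeometryError, ValueError)):
        # port radius exceeding the chamber radius must fail loudly
        build_reference_mesh(GeometryParams(pv_radius=0.05))


def test_laa_region_contracts(default_geom):
    g = default_geom
    assert len(g.laa_cells) > 0
    assert len(g.laa_wall_vertices) > 0
    # ostium ring is a single closed loop of distinct vertices
    assert len(g.ostium_ring) >= 3
    assert len(np.unique(g.ostium_ring)) == len(g.ostium_ring)


def test_scale_to_volume(default_geom):
    g2 = scale_to_volume(default_geom, 100.0)
    assert abs(g2.enclosed_volume_m3() / 1e-6 - 100.0) < 1e-6


# ----------------------------------------------------------------------
# volume_waveform
# ----------------------------------------------------------------------

def _pheno(v_max=120.0, v_min=75.0, bpm=60.0, e_fraction=0.55):
    return PhenotypeParams("control", v_max=v_max, v_min=v_min, bpm=bpm,
                           n_frames=30, e_fraction=e_fraction, seed=0)


def test_degenerate_constant_waveform():
    p = _pheno(v_max=100.0, v_min=100.0)
    tr = volume_waveform(p)
    assert np.allclose(tr.volumes, 100.0)


def test_waveform_extrema_match_phenotype():
    p = _pheno()
    tr = volume_waveform(p)
    assert abs(tr.volumes.max() - p.v_max) / p.v_max < 1e-3
    assert abs(tr.volumes.min() - p.v_min) / p.v_min < 1e-3


def test_waveform_biphasic_emptying():
    from scipy.signal import find_peaks

    p = _pheno(e_fraction=0.55)
    tr = volume_waveform(p, n_samples=800)
    rate = -np.gradient(tr.volumes, tr.times)
    emptying = rate > 0.02 * rate.max()
    peaks, _ = find_peaks(np.where(emptying, rate, 0.0),
                          prominence=0.05 * rate.max())
    assert len(peaks) == 2


def test_waveform_fundamental_theorem():
    p = _pheno()
    tr = volume_waveform(p, n_samples=2000)
    rate = -np.gradient(tr.volumes, tr.times)
    mask = rate > 0
    emptied = np.trapezoid(np.where(mask, rate, 0.0), tr.times)
    assert abs(emptied - p.stroke_volume) / p.stroke_volume < 5e-3


# ----------------------------------------------------------------------
# frames_from_waveform
# ----------------------------------------------------------------------

def test_identity_motion_for_constant_trace(coarse_geom):
    p = _pheno(v_max=100.0, v_min=100.0)
    g = scale_to_volume(coarse_geom, 100.0)
    tr = volume_waveform(p)
    fr = frames_from_waveform(g, tr, p)
    assert np.allclose(fr.boundary_displacements, 0.0)


def test_frames_match_trace_volumes(coarse_geom):
    p = _pheno()
    g = scale_to_volume(coarse_geom, p.v_max)
    tr = volume_waveform(p)
    fr = frames_from_waveform(g, tr, p)
    assert len(fr.frame_times) == p.n_frames
    assert np.allclose(fr.boundary_displacements[0], 0.0)
    for i, t in enumerate(fr.frame_times):
        d = fr.full_displacement(i, len(g.vertices))
        v = g.enclosed_volume_m3(d) / 1e-6
        target = np.interp(t, tr.times, tr.volumes, period=p.period)
        assert abs(v - target) / target < 0.01


def test_frames_infeasible_volume(coarse_geom):
    p = _pheno()
    g = scale_to_volume(coarse_geom, p.v_max)
    bad = VolumeTrace(
        times=np.linspace(0, p.period, 50, endpoint=False),
        volumes=np.full(50, p.v_max),
    )
    bad.volumes[10:] = 0.5  # absurdly small target volume
    with pytest.raises(InfeasibleMotionError):
        frames_from_waveform(g, bad, p)


def test_displaced_surfaces_stay_valid(coarse_geom):
    p = _pheno()
    g = scale_to_volume(coarse_geom, p.v_max)
    tr = volume_waveform(p)
    fr = frames_from_waveform(g, tr, p)
    for i in range(0, p.n_frames, 5):
        d = fr.full_displacement(i, len(g.vertices))
        # outward orientation preserved => positive enclosed volume
        assert g.enclosed_volume_m3(d) > 0


# ----------------------------------------------------------------------
# centerline fixtures
# ----------------------------------------------------------------------

def test_centerline_fixture_straight():
    assert tortuosity(centerline_fixture("straight", 1.0, 10)) == 0.0


def test_centerline_fixture_semicircle():
    tau = tortuosity(centerline_fixture("semicircle", 1.0, 200))
    assert abs(tau - (np.pi / 2 - 1)) < 1e-3


def test_centerline_fixture_helix():
    cl = centerline_fixture("helix", 1.0, 500)
    exact = np.sqrt((2 * np.pi) ** 2 + 1.0)
    assert abs(cl.length - exact) / exact < 5e-3


def test_centerline_fixture_unknown_kind():
    with pytest.raises(ValueError):
        centerline_fixture("zigzag", 1.0, 10)


def test_centerline_fixture_too_few_points():
    with pytest.raises(ValueError):
        centerline_fixture("straight", 1.0, 1)
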