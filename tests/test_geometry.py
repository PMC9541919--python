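"""Volumes, anatomical frame, regions, valve flows, phases, Dice."""

import numpy as np
import pytest

import lvflow as lv
from lvflow.geometry import (
    DataError,
    GeometryError,
    PhaseDetectionError,
    build_frame,
    detect_phases,
    dice,
    lv_volume_series,
    subdivide_regions,
    transvalvular_flow,
)
from lvflow.synthetic import sphere_mask


# -- volumes ---------------------------------------------------------------


def test_single_voxel_volume():
    mask = np.zeros((1, 4, 4, 4), dtype=bool)
    mask[0, 1, 2, 3] = True
    assert lv_volume_series(mask, [2.0, 2.0, 2.0])[0] == pytest.approx(0.008)


def test_rasterized_sphere_volume():
    m = sphere_mask((48, 48, 48), (1.0, 1.0, 1.0), radius_mm=20.0)
    vol = lv_volume_series(m[None], [1.0, 1.0, 1.0])[0]
    assert vol == pytest.approx(4.0 / 3.0 * np.pi * 20.0**3 / 1000.0, rel=0.02)


def test_sphere_volume_error_halves_with_spacing():
    """Mean rasterization error over generic sphere placements at least halves."""
    exact = 4.0 / 3.0 * np.pi * 20.0**3 / 1000.0
    rng = np.random.default_rng(0)
    errs = []
    for sp, n in ((2.0, 26), (1.0, 48)):
        e = []
        for _ in range(6):
            c = 0.5 * (n - 1) * sp + rng.uniform(-0.5, 0.5, 3) * sp
            m = sphere_mask((n, n, n), (sp,) * 3, radius_mm=20.0, center=c)
            e.append(abs(lv_volume_series(m[None], [sp] * 3)[0] - exact))
        errs.append(np.mean(e))
    assert errs[1] <= 0.55 * errs[0]


def test_phantom_volume_matches_truth(default_phantom):
    ds, truth = default_phantom
    vols = lv_volume_series(ds.mask, ds.spacing)
    assert np.all(np.abs(vols - truth.volume_curve) / truth.volume_curve < 0.03)


def test_empty_frame_raises():
    with pytest.raises(DataError):
        lv_volume_series(np.zeros((2, 3, 3, 3), dtype=bool), [1, 1, 1])


# -- anatomical frame ------------------------------------------------------


def _axis_aligned_landmarks():
    phi = 2 * np.pi * np.arange(6) / 6
    ring = np.stack([10 * np.cos(phi), 10 * np.sin(phi), np.zeros(6)], axis=1)
    return lv.LandmarkSet(
        apex=[0, 0, -80.0],
        mitral_points=ring,
        aortic_points=ring * 0.5 + np.array([20.0, 0.0, 5.0]),
        pm_tips=[[0, -10, -30], [0, 10, -30]],
        pm_bases=[[0, -10, -50], [0, 10, -50]],
    )


def test_frame_axis_aligned_construction():
    fr = build_frame(_axis_aligned_landmarks())
    assert np.allclose(fr.basal_apical, [0, 0, -1])
    assert np.allclose(fr.septal_lateral, [1, 0, 0])
    assert np.allclose(fr.inferior_anterior, np.cross(fr.basal_apical, fr.septal_lateral))


def test_frame_orthonormal_and_right_handed(default_phantom):
    ds, _ = default_phantom
    for lm in ds.landmarks[::7]:
        fr = build_frame(lm)
        M = fr.matrix
        assert np.allclose(M @ M.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-9)


def test_frame_rotation_equivariance():
    from scipy.spatial.transform import Rotation

    lm = _axis_aligned_landmarks()
    R = Rotation.from_rotvec([0.7, -0.2, 1.3]).as_matrix()
    fr = build_frame(lm)
    frR = build_frame(lm.transformed(R))
    for a, b in ((fr.basal_apical, frR.basal_apical),
                 (fr.septal_lateral, frR.septal_lateral),
                 (fr.inferior_anterior, frR.inferior_anterior)):
        assert np.allclose(R @ a, b, atol=1e-9)


def test_collinear_aortic_centroid_rejected():
    lm = _axis_aligned_landmarks()
    phi = 2 * np.pi * np.arange(6) / 6
    lm_bad = lv.LandmarkSet(
        apex=lm.apex,
        mitral_points=lm.mitral_points,
        aortic_points=np.stack([5 * np.cos(phi), 5 * np.sin(phi), np.full(6, -20.0)], axis=1),
        pm_tips=lm.pm_tips,
        pm_bases=lm.pm_bases,
    )
    with pytest.raises(GeometryError, match="collinear"):
        build_frame(lm_bad)


# -- regions ---------------------------------------------------------------


def test_regions_partition_and_slab_fractions(default_phantom):
    ds, _ = default_phantom
    labels = subdivide_regions(ds.mask, ds.landmarks, ds.spacing, ds.origin, ds.axes)
    # exact partition, every frame
    assert np.array_equal(labels > 0, ds.mask)
    total, regional = lv_volume_series(ds.mask, ds.spacing, labels)
    assert np.allclose(regional["basal"] + regional["mid"] + regional["apical"], total)
    # closed-form truncated-ellipsoid slab volumes: the phantom places the
    # papillary tip/base planes at 40% / 65% of the base-apex distance
    kappa, ar = 0.5, 1.8  # phantom base cut and aspect ratio defaults
    a = 1.0

    def G(z):
        return (z + a) - (z**3 + a**3) / (3 * a**2)

    zb = kappa * a
    z40 = zb - 0.40 * (zb + a)
    z65 = zb - 0.65 * (zb + a)
    f_basal = (G(zb) - G(z40)) / G(zb)
    f_mid = (G(z40) - G(z65)) / G(zb)
    f_apical = G(z65) / G(zb)
    k = 0  # end-diastole
    for name, f in (("basal", f_basal), ("mid", f_mid), ("apical", f_apical)):
        assert regional[name][k] / total[k] == pytest.approx(f, abs=0.03)


def test_pm_planes_same_height_rejected(default_phantom):
    ds, _ = default_phantom
    lm = ds.landmarks[0]
    bad = lv.LandmarkSet(
        apex=lm.apex, mitral_points=lm.mitral_points, aortic_points=lm.aortic_points,
        pm_tips=lm.pm_tips, pm_bases=lm.pm_tips,
    )
    with pytest.raises(GeometryError):
        subdivide_regions(ds.mask[:1], [bad], ds.spacing, ds.origin, ds.axes)


# -- transvalvular flow ----------------------------------------------------


def test_uniform_flow_through_disc():
    """0.5 m/s axial plug through a 10 mm disc: 157.1 mL/s."""
    ds, _ = lv.make_analytic_field(
        lv.AnalyticFieldSpec(kind="uniform", speed=0.5, direction=(0, 0, 1),
                             shape=(30, 30, 30), spacing=(2.0, 2.0, 2.0))
    )
    phi = 2 * np.pi * np.arange(8) / 8
    c = 0.5 * (np.array(ds.grid_shape) - 1) * ds.spacing
    ring = np.stack([c[0] + 10 * np.cos(phi), c[1] + 10 * np.sin(phi), np.full(8, c[2])], axis=1)
    lm = lv.LandmarkSet(
        apex=c - [0, 0, 20], mitral_points=ring, aortic_points=ring * 1.0,
        pm_tips=[[c[0], c[1] - 5, c[2] - 6], [c[0], c[1] + 5, c[2] - 6]],
        pm_bases=[[c[0], c[1] - 5, c[2] - 12], [c[0], c[1] + 5, c[2] - 12]],
    )
    import dataclasses
    ds = dataclasses.replace(ds, landmarks=[lm] * ds.n_frames)
    q = transvalvular_flow(ds, "mitral")
    # mitral normal points toward the apex (-z); axial +z flow is an outflow
    assert abs(q[0]) == pytest.approx(0.5 * np.pi * 100.0, rel=0.02)
    # a velocity tangent to the disc contributes nothing
    ds_t = dataclasses.replace(ds, velocity=np.roll(ds.velocity, 1, axis=-1))
    assert transvalvular_flow(ds_t, "mitral")[0] == pytest.approx(0.0, abs=1e-6)


def test_phantom_aortic_flow_matches_truth(default_phantom):
    ds, truth = default_phantom
    qa = transvalvular_flow(ds, "aortic")
    assert np.max(np.abs(qa - truth.aortic_flow)) <= 0.05 * truth.aortic_flow.max()


# -- phases ----------------------------------------------------------------


def test_phase_detection_on_phantom(default_phantom, default_phases):
    ds, truth = default_phantom
    phases, qa, qm, vols = default_phases
    half_frame = 0.5 * ds.rr_interval / ds.n_frames
    assert abs(phases.aortic_valve_closure - truth.extras["t_avc"]) <= half_frame + 1e-9
    assert not phases.merged_ea
    assert phases.e_peak < phases.a_peak
    assert abs(phases.e_peak - truth.extras["e_peak_time"]) <= half_frame + 1e-9
    assert abs(phases.a_peak - truth.extras["a_peak_time"]) <= half_frame + 1e-9
    s0, s1 = phases.systole
    d0, d1 = phases.diastole
    assert s0 == 0.0 and s1 == d0 and d1 == pytest.approx(ds.rr_interval)


def test_merged_inflow_flagged():
    ds, truth = lv.make_ellipsoid_lv(
        lv.EllipsoidLVSpec(single_diastolic_wave=True, shape=(24, 24, 36),
                           spacing=3.0, n_frames=20)
    )
    vols = lv_volume_series(ds.mask, ds.spacing)
    qa = transvalvular_flow(ds, "aortic")
    qm = transvalvular_flow(ds, "mitral")
    phases = detect_phases(qa, qm, ds.frame_times, ds.rr_interval, vols)
    assert phases.merged_ea
    assert phases.a_peak is None


def test_no_aortic_peak_raises():
    t = np.linspace(0, 0.9, 10)
    with pytest.raises(PhaseDetectionError):
        detect_phases(np.zeros(10), np.ones(10), t, 1.0)


# -- dice ------------------------------------------------------------------


def test_dice_identities():
    a = np.zeros((4, 4, 4), dtype=bool)
    a[1:3, 1:3, 1:3] = True
    assert dice(a, a) == 1.0
    b = np.zeros_like(a)
    b[0, 0, 0] = True
    assert dice(a, b) == 0.0


def test_dice_shifted_cube():
    a = np.zeros((5, 5, 5), dtype=bool)
    a[0:2, 0:2, 0:2] = True
    b = np.roll(a, 1, axis=0)
    assert dice(a, b) == pytest.approx(0.5)


def test_dice_empty_masks_error():
    z = np.zeros((3, 3, 3), dtype=bool)
    with pytest.raises(DataError):
        dice(z, z)
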