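"""The synthetic generators and the independent verification of their truths.

The analytic-field closed forms are cross-checked numerically (brute-force
finite differences / dense quadrature on fine grids) before the rest of the
suite relies on them as oracles.
"""

import numpy as np
import pytest

import lvflow as lv
from lvflow.synthetic import SpecError, _VolumeCurve, perturb_mask_boundary


# -- oracle verification (independent of the package's operators) -----------


def test_poiseuille_pressure_gradient_truth_by_brute_force():
    """dp/dz = mu * laplacian(v_z) from dense central differences on a fine grid."""
    mu, vmax, R = 3.5e-3, 1.0, 0.01  # SI: Pa s, m/s, m
    h = 2e-4  # 0.2 mm
    n = 61
    x = (np.arange(n) - n // 2) * h
    X, Y = np.meshgrid(x, x, indexing="ij")
    v = vmax * (1 - (X**2 + Y**2) / R**2)  # evaluate beyond the wall too: smooth
    lap = (np.roll(v, 1, 0) + np.roll(v, -1, 0) + np.roll(v, 1, 1) + np.roll(v, -1, 1) - 4 * v) / h**2
    grad = mu * lap[5:-5, 5:-5]
    assert np.allclose(grad, -4 * mu * vmax / R**2, rtol=1e-9)
    assert -4 * mu * vmax / R**2 == pytest.approx(-140.0)


def test_poiseuille_dissipation_truth_by_dense_quadrature():
    """Integral of Phi = mu * (dv/dr)^2 over the tube section, dense polar grid."""
    mu, vmax, R = 3.5e-3, 1.0, 0.01
    r = np.linspace(0, R, 20001)
    dvdr = -2 * vmax * r / R**2
    phi = mu * dvdr**2
    per_length = np.trapezoid(phi * 2 * np.pi * r, r)
    assert per_length == pytest.approx(2 * np.pi * mu * vmax**2, rel=1e-6)


def test_uniform_acceleration_truth():
    ds, truth = lv.make_analytic_field(
        lv.AnalyticFieldSpec(kind="uniform_acceleration", acceleration=1.0,
                             direction=(1, 0, 0), shape=(25, 25, 20),
                             spacing=(2, 2, 2))
    )
    vol_m3 = ds.mask[0].sum() * ds.voxel_volume_m3
    assert vol_m3 == pytest.approx(1e-4)  # 100 mL
    assert np.allclose(np.linalg.norm(truth.hdf_truth, axis=1), 1025.0 * 1.0 * vol_m3)


def test_rigid_rotation_and_uniform_truths_are_zero():
    _, t_rot = lv.make_analytic_field(lv.AnalyticFieldSpec(kind="rigid_rotation"))
    assert np.all(t_rot.dissipation_truth == 0)
    _, t_uni = lv.make_analytic_field(lv.AnalyticFieldSpec(kind="uniform"))
    assert np.all(t_uni.hdf_truth == 0)
    assert np.all(t_uni.dissipation_truth == 0)


def test_unknown_kind_rejected():
    with pytest.raises(SpecError):
        lv.AnalyticFieldSpec(kind="vortex")
    with pytest.raises(SpecError):
        lv.AnalyticFieldSpec(kind="poiseuille", tube_radius=100.0)


# -- prescribed volume curve -------------------------------------------------


def test_volume_curve_conserves_stroke_volume():
    c = _VolumeCurve(edv=150.0, sv=90.0, rr=0.857, systole_fraction=0.35, e_to_a_ratio=2.0)
    t = np.linspace(0, 0.857, 4001)
    v = c.volume(t)
    assert v[0] == pytest.approx(150.0)
    assert v[-1] == pytest.approx(150.0, abs=1e-9)
    assert v.min() == pytest.approx(60.0, rel=1e-6)
    # E/A peak-flow ratio is exactly the prescribed one
    qm = c.q_mitral(t)
    assert c.filling[0].peak / c.filling[1].peak == pytest.approx(2.0)
    assert qm.max() == pytest.approx(c.filling[0].peak, rel=1e-4)


# -- ellipsoid phantom -------------------------------------------------------


def test_phantom_truth_definitional_invariants(default_phantom):
    ds, truth = default_phantom
    assert truth.sv == pytest.approx(truth.volume_curve.max() - truth.volume_curve.min(), rel=1e-6)
    assert truth.ef == pytest.approx(truth.sv / truth.volume_curve.max(), rel=1e-6)
    assert truth.sv == pytest.approx(90.0)
    assert truth.volume_curve.min() == pytest.approx(60.0, rel=1e-6)


def test_phantom_deterministic_under_seed():
    spec = lv.EllipsoidLVSpec(noise_sd=0.02, seed=11, edv=120.0, shape=(16, 16, 24),
                              spacing=4.0, n_frames=8)
    d1, _ = lv.make_ellipsoid_lv(spec)
    d2, _ = lv.make_ellipsoid_lv(spec)
    assert np.array_equal(d1.velocity, d2.velocity)
    d3, _ = lv.make_ellipsoid_lv(lv.EllipsoidLVSpec(noise_sd=0.02, seed=12, edv=120.0,
                                                    shape=(16, 16, 24), spacing=4.0, n_frames=8))
    assert not np.array_equal(d1.velocity, d3.velocity)


def test_prescribed_ea_ratio_read_back(default_phantom):
    ds, truth = default_phantom
    qm = truth.mitral_flow
    t = ds.frame_times
    dia = t > truth.extras["t_avc"]
    # the two diastolic maxima of the truth curve
    seg = qm[dia]
    from scipy.signal import find_peaks

    pk, _ = find_peaks(seg)
    assert len(pk) == 2
    assert seg[pk[0]] / seg[pk[1]] == pytest.approx(2.0, rel=0.01)


def test_orifice_flux_matches_volume_rate(default_phantom):
    """|flux - dV/dt| <= 3% of the peak flow at the phantom's own resolution."""
    ds, truth = default_phantom
    qa = lv.transvalvular_flow(ds, "aortic")
    qm = lv.transvalvular_flow(ds, "mitral")
    err = max(
        np.max(np.abs(qa - truth.aortic_flow)),
        np.max(np.abs(qm - truth.mitral_flow)),
    ) / truth.aortic_flow.max()
    assert err <= 0.03


def test_orifice_flux_error_halves_under_refinement():
    errs = {}
    for sp, shape in ((3.0, (24, 24, 36)), (1.5, (48, 48, 72))):
        spec = lv.EllipsoidLVSpec(edv=120.0, shape=shape, spacing=sp, n_frames=16)
        ds, truth = lv.make_ellipsoid_lv(spec)
        qa = lv.transvalvular_flow(ds, "aortic")
        qm = lv.transvalvular_flow(ds, "mitral")
        errs[sp] = max(
            np.max(np.abs(qa - truth.aortic_flow)),
            np.max(np.abs(qm - truth.mitral_flow)),
        ) / truth.aortic_flow.max()
    assert errs[3.0] < 0.06
    assert errs[1.5] <= 0.6 * errs[3.0]


def test_invalid_phantom_specs_rejected():
    with pytest.raises(SpecError):
        lv.EllipsoidLVSpec(ef=1.2)
    with pytest.raises(SpecError):
        lv.EllipsoidLVSpec(systole_fraction=1.5)
    with pytest.raises(SpecError):
        lv.EllipsoidLVSpec(edv=-10)


def test_mask_perturbation_stays_near_original(default_phantom):
    ds, _ = default_phantom
    rng = np.random.default_rng(3)
    pm = perturb_mask_boundary(ds.mask, rng, flip_probability=0.3)
    d = [lv.dice(ds.mask[k], pm[k]) for k in range(ds.n_frames)]
    assert min(d) >= 0.87
    assert max(d) < 1.0
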