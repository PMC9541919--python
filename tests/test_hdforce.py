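"""Pressure-gradient field, hemodynamic force, RMS summaries and the impulse."""

import dataclasses

import numpy as np
import pytest

import lvflow as lv
from lvflow.geometry import DataError, PhaseMap
from lvflow.hdforce import (
    compute_hdf_series,
    filling_impulse,
    hemodynamic_force,
    pressure_gradient_field,
    summarize_hdf,
)

FRAME = lv.AnatomicalFrame([0, 0, -1], [1, 0, 0], [0, -1, 0], [0, 0, 0])


def _mu(ds, value=3.5e-3):
    return np.full(ds.grid_shape, value)


def test_steady_uniform_flow_zero_everywhere():
    ds, _ = lv.make_analytic_field(lv.AnalyticFieldSpec(kind="uniform", speed=0.5))
    b = pressure_gradient_field(ds, 2, _mu(ds), 1025.0)
    assert np.allclose(b, 0.0, atol=1e-9)
    vec, comps, hdfv = hemodynamic_force(b, ds.mask[2], ds.spacing, FRAME, 100.0)
    assert np.allclose(vec, 0.0, atol=1e-12)


def test_uniform_acceleration_interior_and_force():
    """a = 1 m/s^2 along x: b = (-1025, 0, 0) Pa/m; |HDF| = rho a V."""
    spec = lv.AnalyticFieldSpec(kind="uniform_acceleration", acceleration=1.0,
                                direction=(1, 0, 0), shape=(25, 25, 20),
                                spacing=(2, 2, 2), n_frames=5)
    ds, truth = lv.make_analytic_field(spec)
    b = pressure_gradient_field(ds, 2, _mu(ds), 1025.0)
    interior = b[ds.mask[2]]
    assert np.allclose(interior[:, 0], -1025.0, rtol=0.01)
    assert np.allclose(interior[:, 1:], 0.0, atol=1e-9)
    vol_ml = ds.mask[2].sum() * ds.voxel_volume_mm3 / 1000.0
    vec, comps, hdfv = hemodynamic_force(b, ds.mask[2], ds.spacing, FRAME, vol_ml)
    assert np.linalg.norm(vec) == pytest.approx(0.1025, rel=0.01)
    assert np.linalg.norm(hdfv) == pytest.approx(1.025, rel=0.01)
    assert np.linalg.norm(vec - truth.hdf_truth[2]) <= 0.01 * np.linalg.norm(vec)


def test_poiseuille_axial_pressure_gradient(poiseuille_1mm):
    ds, truth = poiseuille_1mm
    b = pressure_gradient_field(ds, 1, _mu(ds), 1025.0)
    coords = ds.voxel_centers()
    c = coords.reshape(-1, 3).mean(axis=0)
    r2 = (coords[..., 0] - c[0] - 0.37) ** 2 + (coords[..., 1] - c[1] - 0.21) ** 2
    interior = ds.mask[1] & (r2 <= 8.0**2)
    bz = b[..., 2][interior]
    assert np.mean(bz) == pytest.approx(truth.extras["pressure_gradient_pa_per_m"], rel=0.05)
    assert np.allclose(b[..., :2][interior], 0.0, atol=1e-6)


def test_components_pythagorean_consistency(default_bundle):
    comps = default_bundle.hdf.components
    vecs = default_bundle.hdf.vectors
    assert np.allclose(
        np.sum(comps**2, axis=1), np.sum(vecs**2, axis=1), rtol=1e-9, atol=1e-30
    )


def test_fewer_than_three_frames_rejected(small_phantom):
    ds, _ = small_phantom
    short = dataclasses.replace(
        ds,
        velocity=ds.velocity[:2], mask=ds.mask[:2],
        frame_times=ds.frame_times[:2], landmarks=list(ds.landmarks[:2]),
    )
    with pytest.raises(DataError):
        pressure_gradient_field(short, 0, _mu(ds), 1025.0)


def test_constant_mu_field_equals_newtonian_path(small_phantom):
    """With spatially constant viscosity the variable-mu operator is identical."""
    ds, _ = small_phantom
    from lvflow.rheology import RheologyParams, shear_rate, velocity_gradient, viscosity

    L = velocity_gradient(ds.velocity[4], ds.mask[4], ds.spacing)
    mu_newton = viscosity(shear_rate(L), ds.hematocrit, RheologyParams(model="newtonian"))
    b1 = pressure_gradient_field(ds, 4, mu_newton, 1025.0)
    b2 = pressure_gradient_field(ds, 4, _mu(ds, 3.5e-3), 1025.0)
    assert np.array_equal(b1, b2)


def _phases(rr=1.0, avc=0.4):
    return PhaseMap(systole=(0.0, avc), diastole=(avc, rr), aortic_valve_closure=avc,
                    e_peak=None, a_peak=None, e_wave_window=(avc, rr),
                    a_wave_window=None, merged_ea=True, rr_interval=rr)


def test_r_rms_plugin_values():
    T, rr = 20, 1.0
    times = rr * np.arange(T) / T
    # force exactly along basal-apical
    hdf_v = np.zeros((T, 3))
    hdf_v[:, 0] = np.sin(2 * np.pi * times / rr) + 0.5
    rms, r_rms, _ = summarize_hdf(times, hdf_v, _phases())
    assert r_rms["systole"] == pytest.approx(0.0, abs=1e-12)
    assert r_rms["diastole"] == pytest.approx(0.0, abs=1e-12)
    # equal-RMS transversal components, each equal to the longitudinal one
    hdf_v[:, 1] = hdf_v[:, 0]
    hdf_v[:, 2] = -hdf_v[:, 0]
    rms, r_rms, _ = summarize_hdf(times, hdf_v, _phases())
    assert r_rms["systole"] == pytest.approx(np.sqrt(2.0), rel=1e-9)
    assert r_rms["diastole"] == pytest.approx(np.sqrt(2.0), rel=1e-9)


def test_r_rms_undefined_without_longitudinal_force():
    T = 10
    times = np.arange(T) / T
    hdf_v = np.zeros((T, 3))
    hdf_v[:, 1] = 1.0
    with pytest.raises(DataError):
        summarize_hdf(times, hdf_v, _phases())


def test_axisymmetric_phantom_force_stays_aligned():
    """Long-axis-aligned flow gives R_RMS well below 0.2 in both phases."""
    ds, _ = lv.make_ellipsoid_lv(lv.EllipsoidLVSpec(axisymmetric=True, shape=(24, 24, 36),
                                                    spacing=3.0, n_frames=20))
    vols = lv.lv_volume_series(ds.mask, ds.spacing)
    qa = lv.transvalvular_flow(ds, "aortic")
    qm = lv.transvalvular_flow(ds, "mitral")
    phases = lv.detect_phases(qa, qm, ds.frame_times, ds.rr_interval, vols)
    from lvflow.rheology import shear_rate, velocity_gradient, viscosity

    grads = [velocity_gradient(ds.velocity[k], ds.mask[k], ds.spacing) for k in range(ds.n_frames)]
    mus = [viscosity(shear_rate(L), ds.hematocrit) for L in grads]
    series = compute_hdf_series(ds, FRAME, vols, mus, 1025.0, phases, gradients=grads)
    assert series.r_rms["systole"] <= 0.2
    assert series.r_rms["diastole"] <= 0.2


def test_filling_impulse_rectangle():
    """Constant -0.5 N/L for 0.1 s after closure, then a sharp crossing: 0.05 Ns/L."""
    rr = 1.0
    times = np.array([0.0, 0.2, 0.4, 0.5, 0.5001, 0.7, 0.9]) * rr
    y = np.array([0.0, 0.0, -0.5, -0.5, 0.2, 0.2, 0.0])
    phases = _phases(rr=rr, avc=0.4)
    imp, defined = filling_impulse(times, y, phases)
    assert defined
    assert abs(imp) == pytest.approx(0.05, rel=0.01)


def test_filling_impulse_undefined_when_flat():
    times = np.linspace(0, 0.9, 10)
    y = np.zeros(10)
    y[:4] = -1.0  # systolic activity only; zero after closure
    imp, defined = filling_impulse(times, y, _phases(rr=1.0, avc=0.4))
    assert not defined and imp is None


def test_phantom_impulse_negative_then_recovery(default_bundle):
    """Early diastolic deceleration force points base-ward: negative impulse."""
    assert default_bundle.hdf.impulse_defined
    assert default_bundle.hdf.impulse_ba < 0
    assert 0.005 < abs(default_bundle.hdf.impulse_ba) < 0.5
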