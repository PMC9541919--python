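"""Kinetic energy, viscous dissipation, normalization and peaks."""


import numpy as np
import pytest

import lvflow as lv
from lvflow.energetics import (
    integrate_window,
    kinetic_energy,
    normalize_and_summarize,
    viscous_loss_rate,
    window_mean,
)
from lvflow.geometry import PhaseMap
from lvflow.synthetic import cylinder_mask


def test_single_voxel_kinetic_energy():
    """One 2 mm voxel of blood at 1 m/s carries 4.1e-6 J."""
    v = np.zeros((4, 4, 4, 3))
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1, 1, 1] = True
    v[1, 1, 1, 0] = 1.0
    ke = kinetic_energy(v, mask, 1025.0, [2.0, 2.0, 2.0])
    assert ke == pytest.approx(0.5 * 1025.0 * 8e-9, rel=1e-12)
    assert kinetic_energy(np.zeros_like(v), mask, 1025.0, [2, 2, 2]) == 0.0


def test_rigid_rotation_cylinder_ke_closed_form():
    """KE of rigid rotation in a cylinder: 1/4 rho pi h omega^2 R^4."""
    omega, R, h = 10.0, 20.0, 40.0  # rad/s, mm, mm
    spec = lv.AnalyticFieldSpec(kind="rigid_rotation", angular_rate=omega,
                                shape=(48, 48, 20), spacing=(1.0, 1.0, 2.0))
    ds, _ = lv.make_analytic_field(spec)
    mask = cylinder_mask(ds.grid_shape, ds.spacing, R)
    ke = kinetic_energy(ds.velocity[0], mask, 1025.0, ds.spacing)
    closed = 0.25 * 1025.0 * np.pi * (h * 1e-3) * omega**2 * (R * 1e-3) ** 4
    assert ke == pytest.approx(closed, rel=0.02)


def test_rigid_rotation_dissipation_negligible():
    ds, _ = lv.make_analytic_field(lv.AnalyticFieldSpec(kind="rigid_rotation", angular_rate=10.0))
    mask = ds.mask[0]
    mu = np.full(mask.shape, 3.5e-3)
    el = viscous_loss_rate(ds.velocity[0], mask, mu, ds.spacing)
    ke = kinetic_energy(ds.velocity[0], mask, 1025.0, ds.spacing)
    assert abs(el) < 1e-10 * ke
    # uniform flow likewise
    du, _ = lv.make_analytic_field(lv.AnalyticFieldSpec(kind="uniform"))
    mu = np.full(du.grid_shape, 3.5e-3)
    assert viscous_loss_rate(du.velocity[0], du.mask[0], mu, du.spacing) == pytest.approx(0.0, abs=1e-20)


def test_poiseuille_dissipation_closed_form(poiseuille_1mm):
    ds, truth = poiseuille_1mm
    mu = np.full(ds.grid_shape, 3.5e-3)
    el = viscous_loss_rate(ds.velocity[0], ds.mask[0], mu, ds.spacing)
    assert el == pytest.approx(truth.dissipation_truth[0], rel=0.05)


def test_regional_additivity_exact(default_phantom):
    ds, _ = default_phantom
    labels = lv.subdivide_regions(ds.mask, ds.landmarks, ds.spacing, ds.origin, ds.axes)
    mu = np.full(ds.grid_shape, 3.5e-3)
    for k in (0, 10, 20):
        ke, reg = kinetic_energy(ds.velocity[k], ds.mask[k], 1025.0, ds.spacing, labels[k])
        assert sum(reg.values()) == pytest.approx(ke, rel=1e-12)
        el, reg = viscous_loss_rate(ds.velocity[k], ds.mask[k], mu, ds.spacing, labels[k])
        assert sum(reg.values()) == pytest.approx(el, rel=1e-12)
        assert ke >= 0 and el >= 0


def test_quadratic_scaling_under_velocity_doubling(small_phantom):
    ds, _ = small_phantom
    mu = np.full(ds.grid_shape, 3.5e-3)
    k = 5
    ke1 = kinetic_energy(ds.velocity[k], ds.mask[k], 1025.0, ds.spacing)
    el1 = viscous_loss_rate(ds.velocity[k], ds.mask[k], mu, ds.spacing)
    ke2 = kinetic_energy(2 * ds.velocity[k], ds.mask[k], 1025.0, ds.spacing)
    el2 = viscous_loss_rate(2 * ds.velocity[k], ds.mask[k], mu, ds.spacing)
    assert ke2 == pytest.approx(4 * ke1, rel=1e-12)
    assert el2 == pytest.approx(4 * el1, rel=1e-12)


def _flat_phases(rr):
    return PhaseMap(systole=(0.0, 0.4 * rr), diastole=(0.4 * rr, rr),
                    aortic_valve_closure=0.4 * rr, e_peak=None, a_peak=None,
                    e_wave_window=None, a_wave_window=None, merged_ea=True,
                    rr_interval=rr)


def test_constant_series_normalization():
    """ke = 5 mJ at constant 100 mL volume -> KE_V = 0.05 J/L at every frame."""
    T, rr = 10, 1.0
    times = rr * np.arange(T) / T
    ke = np.full(T, 5e-3)
    zeros = np.zeros(T)
    reg = {n: zeros for n in ("basal", "mid", "apical")}
    vols = np.full(T, 100.0)
    regv = {n: np.full(T, 100.0 / 3) for n in ("basal", "mid", "apical")}
    es = normalize_and_summarize(times, rr, ke, reg, zeros, reg, vols, regv, _flat_phases(rr))
    assert np.allclose(es.ke_v, 0.05)
    assert es.phase_means["systole"]["global"] == pytest.approx(0.05)
    assert es.el_v["diastole"]["global"] == pytest.approx(0.0)


def test_el_v_phase_normalization_rectangle():
    """Constant 1 mW over a 0.6 s phase at constant 100 mL -> 0.006 J/L."""
    T, rr = 12, 1.0
    times = rr * np.arange(T) / T
    zeros = np.zeros(T)
    reg = {n: zeros for n in ("basal", "mid", "apical")}
    vols = np.full(T, 100.0)
    regv = {n: np.full(T, 100.0 / 3) for n in ("basal", "mid", "apical")}
    es = normalize_and_summarize(times, rr, zeros, reg, np.full(T, 1e-3), reg,
                                 vols, regv, _flat_phases(rr))
    assert es.el_v["diastole"]["global"] == pytest.approx(1e-3 * 0.6 / 0.1)


def test_e_wave_peak_time_matches_truth(default_bundle, default_phantom):
    """Raw KE peaks with the inflow; KE_V peaks slightly earlier because the
    normalizing volume grows during filling (d(KE/V)/dt < 0 at the KE peak)."""
    ds, truth = default_phantom
    frame = ds.rr_interval / ds.n_frames
    en = default_bundle.energetics
    win = default_bundle.phases.e_wave_window
    idx = np.where((en.times >= win[0]) & (en.times <= win[1]))[0]
    t_ke = en.times[idx[np.argmax(en.ke[idx])]]
    assert abs(t_ke - truth.extras["e_peak_time"]) <= 0.5 * frame + 1e-9
    peak_kev = en.peaks["e_wave"]["global"]
    assert peak_kev is not None
    assert abs(peak_kev[1] - truth.extras["e_peak_time"]) <= 1.5 * frame + 1e-9
    assert peak_kev[1] <= t_ke + 1e-9


def test_integrate_window_cyclic_wrap():
    times = np.array([0.0, 0.25, 0.5, 0.75])
    y = np.array([1.0, 1.0, 1.0, 1.0])
    assert integrate_window(times, y, 0.0, 1.0, 1.0) == pytest.approx(1.0)
    assert integrate_window(times, y, 0.9, 1.1, 1.0) == pytest.approx(0.2)
    assert window_mean(times, y, 0.3, 0.7, 1.0) == pytest.approx(1.0)
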