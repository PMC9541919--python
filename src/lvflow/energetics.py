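"""Intraventricular kinetic energy and viscous energy loss.

Kinetic energy per frame is the voxel sum of ``1/2 m |v|^2`` with
``m = rho * V_voxel`` and rho = 1025 kg/m^3.  The viscous loss rate is the
bulk Newtonian/generalized-Newtonian dissipation

    Phi = 2 mu (S : S)        [W/m^3],   S = strain-rate tensor,

summed over in-mask voxels; boundary-layer dissipation at the endocardium is
deliberately not represented (the bulk term is what a voxel-scale velocity
field can resolve).  Energy loss over a phase is the time integral of the
rate (trapezoidal on the, possibly non-uniform, frame times, with cyclic
closure).

Volume normalization: ``KE_V(t) = KE(t) / V(t)`` in J/L with the current
(global or regional) cavity volume; phase-level ``EL_V`` divides the phase
time-integral of the loss rate by the phase-mean volume (a per-frame
normalize-then-integrate variant is available via ``el_v_mode``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    REGION_APICAL,
    REGION_BASAL,
    REGION_MID,
    REGION_NAMES,
    DataError,
    PhaseMap,
)
from .rheology import strain_rate_tensor, velocity_gradient

_REGION_CODES = dict(zip(REGION_NAMES, (REGION_BASAL, REGION_MID, REGION_APICAL)))


# --------------------------------------------------------------------------
# time-series utilities (piecewise-linear in time, cyclic period rr)


def _extended(times, values, rr):
    """Append the wrap-around sample at t = rr (value = first sample)."""
    t = np.concatenate([np.asarray(times, dtype=float), [rr]])
    v = np.concatenate([np.asarray(values, dtype=float), [values[0]]])
    return t, v


def sample_series(times, values, t, rr):
    """Piecewise-linear, cyclic evaluation of a frame series at time ``t``."""
    te, ve = _extended(times, values, rr)
    return float(np.interp(float(t) % rr, te, ve))


def integrate_window(times, values, t0, t1, rr):
    """Integral of the piecewise-linear series over [t0, t1] (cyclic).

    ``t1`` may exceed the last frame time up to ``rr``; windows crossing the
    cycle boundary are supported via t1 > rr as well.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    te, ve = _extended(times, values, rr)

    def _one_cycle(a, b):
        if b <= a:
            return 0.0
        pts = [a] + [float(x) for x in te if a < x < b] + [b]
        ys = np.interp(pts, te, ve)
        return float(np.trapezoid(ys, pts))

    total = 0.0
    a = float(t0)
    remaining = float(t1 - t0)
    while remaining > 1e-15:
        a_mod = a % rr
        span = min(remaining, rr - a_mod)
        total += _one_cycle(a_mod, a_mod + span)
        a += span
        remaining -= span
    return total


def window_mean(times, values, t0, t1, rr):
    if t1 - t0 <= 0:
        raise ValueError("empty window")
    return integrate_window(times, values, t0, t1, rr) / (t1 - t0)


# --------------------------------------------------------------------------
# per-frame energies


def kinetic_energy(velocity, mask, density, spacing, labels=None):
    """Global (and regional) kinetic energy of one frame, in J.

    ``velocity`` (X, Y, Z, 3) m/s, ``spacing`` mm.  With ``labels`` the
    regional sums over the basal/mid/apical slabs are returned as a dict;
    they add up exactly to the global value (same voxel partition).
    """
    mask = np.asarray(mask).astype(bool)
    v2 = np.einsum("...i,...i->...", velocity, velocity)
    vox_m3 = float(np.prod(np.asarray(spacing, dtype=float))) * 1e-9
    e = 0.5 * density * vox_m3 * v2
    total = float(e[mask].sum())
    if labels is None:
        return total
    regional = {
        name: float(e[labels == code].sum()) for name, code in _REGION_CODES.items()
    }
    return total, regional


def viscous_loss_rate(velocity, mask, mu_field, spacing, labels=None, axes=None,
                      gradient=None):
    """Global (and regional) bulk viscous dissipation rate of one frame, W.

    ``mu_field`` is the per-voxel viscosity (Pa s).  A precomputed velocity
    ``gradient`` tensor can be passed to avoid recomputation.
    """
    mask = np.asarray(mask).astype(bool)
    L = gradient if gradient is not None else velocity_gradient(velocity, mask, spacing, axes)
    S = strain_rate_tensor(L)
    ss = np.einsum("...ij,...ij->...", S, S)
    vox_m3 = float(np.prod(np.asarray(spacing, dtype=float))) * 1e-9
    phi = 2.0 * np.asarray(mu_field, dtype=float) * ss * vox_m3
    total = float(phi[mask].sum())
    if labels is None:
        return total
    regional = {
        name: float(phi[labels == code].sum()) for name, code in _REGION_CODES.items()
    }
    return total, regional


# --------------------------------------------------------------------------
# series container and summary


@dataclass
class EnergeticsSeries:
    """Per-frame energetics with phase aggregates and peak table.

    ``ke`` / ``el_rate`` are raw (J / W); ``ke_v`` is J/L against the current
    volume.  ``el_v[phase][region]`` is the phase-integrated loss normalized
    to the phase-mean volume, J/L (region "global" included).  ``peaks`` maps
    window name (systole / e_wave / a_wave) to region -> (value, time);
    the a_wave entry is None when the E and A waves are merged.
    """

    times: np.ndarray
    ke: np.ndarray
    ke_regional: dict
    el_rate: np.ndarray
    el_rate_regional: dict
    ke_v: np.ndarray
    ke_v_regional: dict
    el_v: dict
    phase_means: dict
    peaks: dict


def _window_peak(times, values, window):
    t0, t1 = window
    idx = np.where((times >= t0 - 1e-12) & (times <= t1 + 1e-12))[0]
    if idx.size == 0:
        return None
    j = idx[int(np.argmax(values[idx]))]
    return float(values[j]), float(times[j])


def normalize_and_summarize(
    times: np.ndarray,
    rr: float,
    ke: np.ndarray,
    ke_regional: dict,
    el_rate: np.ndarray,
    el_rate_regional: dict,
    volumes: np.ndarray,
    regional_volumes: dict,
    phases: PhaseMap,
    el_v_mode: str = "phase_mean",
) -> EnergeticsSeries:
    """Assemble the volume-normalized series, phase means, EL_V and peaks."""
    times = np.asarray(times, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes <= 0):
        raise DataError("zero cavity volume encountered")
    vol_l = volumes / 1000.0
    ke_v = np.asarray(ke) / vol_l
    ke_v_regional = {}
    for name in REGION_NAMES:
        rv = np.asarray(regional_volumes[name], dtype=float) / 1000.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ke_v_regional[name] = np.where(rv > 0, np.asarray(ke_regional[name]) / np.maximum(rv, 1e-30), 0.0)

    windows = {"systole": phases.systole, "diastole": phases.diastole}

    def _el_v(rate, vols_ml, window):
        t0, t1 = window
        if el_v_mode == "per_frame":
            dens = np.asarray(rate) / (np.asarray(vols_ml) / 1000.0)
            return integrate_window(times, dens, t0, t1, rr)
        e = integrate_window(times, rate, t0, t1, rr)
        vbar = window_mean(times, vols_ml, t0, t1, rr) / 1000.0
        return e / vbar

    el_v = {}
    for phase, win in windows.items():
        entry = {"global": _el_v(el_rate, volumes, win)}
        for name in REGION_NAMES:
            entry[name] = _el_v(el_rate_regional[name], regional_volumes[name], win)
        el_v[phase] = entry

    phase_means = {}
    for phase, (t0, t1) in windows.items():
        entry = {"global": window_mean(times, ke_v, t0, t1, rr)}
        for name in REGION_NAMES:
            entry[name] = window_mean(times, ke_v_regional[name], t0, t1, rr)
        phase_means[phase] = entry

    peak_windows = {"systole": phases.systole}
    if phases.e_wave_window is not None:
        peak_windows["e_wave"] = phases.e_wave_window
    peaks = {}
    for wname, win in peak_windows.items():
        entry = {"global": _window_peak(times, ke_v, win)}
        for name in REGION_NAMES:
            entry[name] = _window_peak(times, ke_v_regional[name], win)
        peaks[wname] = entry
    if phases.a_wave_window is not None and not phases.merged_ea:
        win = phases.a_wave_window
        entry = {"global": _window_peak(times, ke_v, win)}
        for name in REGION_NAMES:
            entry[name] = _window_peak(times, ke_v_regional[name], win)
        peaks["a_wave"] = entry
    else:
        peaks["a_wave"] = None

    return EnergeticsSeries(
        times=times,
        ke=np.asarray(ke, dtype=float),
        ke_regional={k: np.asarray(v, dtype=float) for k, v in ke_regional.items()},
        el_rate=np.asarray(el_rate, dtype=float),
        el_rate_regional={k: np.asarray(v, dtype=float) for k, v in el_rate_regional.items()},
        ke_v=ke_v,
        ke_v_regional=ke_v_regional,
        el_v=el_v,
        phase_means=phase_means,
        peaks=peaks,
    )
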