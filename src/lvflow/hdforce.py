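"""Hemodynamic force from the Navier--Stokes pressure gradient.

The per-voxel pressure-gradient vector (Pa/m) follows from the momentum
balance of an incompressible generalized-Newtonian fluid,

    b = grad p = -rho (dv/dt + (v . grad) v) + div(2 mu S),

evaluated inside the LV mask with a cyclic central temporal derivative on
the frame times and the masked finite-difference spatial operators of the
rheology module.  The viscous term is implemented as div(2 mu S), correct
for a spatially varying viscosity (it reduces to mu laplacian(v) for
uniform mu); at 4D-flow resolution it contributes little and can be dropped
with ``include_viscous=False`` to mimic common hemodynamic-force
implementations.

The hemodynamic force (N) is the volume integral of b over the cavity,
projected per frame onto the anatomical triad; positive basal--apical points
base -> apex, positive septal--lateral toward the lateral wall, positive
inferior--anterior toward the anterior wall.  This is the "pressure
gradient" sign convention; the action--reaction reading (net momentum
transferred from wall to blood) is the global sign flip available via
``sign_flip=True``.

Summaries: per-component RMS over the full cycle and per phase
(time-weighted), the transversal-to-longitudinal ratio

    R_RMS = sqrt(RMS_sl^2 + RMS_ia^2) / RMS_ba

per phase, a peak table, and the early-diastolic filling impulse: the time
integral of the volume-normalized basal--apical component from aortic valve
closure to its next zero crossing (both endpoints sub-frame by linear
interpolation), in Ns/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset import FlowDataset
from .energetics import integrate_window, sample_series
from .geometry import AnatomicalFrame, DataError, PhaseMap
from .rheology import masked_derivative, strain_rate_tensor, velocity_gradient

COMPONENT_NAMES = ("basal_apical", "septal_lateral", "inferior_anterior")


class TemporalDerivativeError(DataError):
    """Not enough frames for the cyclic temporal derivative."""


def pressure_gradient_field(
    ds: FlowDataset,
    frame_index: int,
    mu_field: np.ndarray,
    density: float,
    include_viscous: bool = True,
    gradient: np.ndarray = None,
) -> np.ndarray:
    """Navier--Stokes pressure gradient b (X, Y, Z, 3) in Pa/m for one frame.

    Zero outside the mask.  A precomputed velocity-gradient tensor for the
    frame may be passed to avoid recomputation.
    """
    T = ds.n_frames
    if T < 3:
        raise TemporalDerivativeError("cyclic temporal derivative needs >= 3 frames")
    k = int(frame_index) % T
    mask = ds.mask[k]
    v = ds.velocity[k]
    A = ds.axes
    spacing = ds.spacing

    # cyclic central difference in time
    km, kp = (k - 1) % T, (k + 1) % T
    t_m = ds.frame_times[km] - (ds.rr_interval if k == 0 else 0.0)
    t_p = ds.frame_times[kp] + (ds.rr_interval if k == T - 1 else 0.0)
    dvdt = (ds.velocity[kp] - ds.velocity[km]) / (t_p - t_m)

    L = gradient if gradient is not None else velocity_gradient(v, mask, spacing, A)
    conv = np.einsum("...j,...ij->...i", v, L)

    b = -density * (dvdt + conv)

    if include_viscous:
        S = strain_rate_tensor(L)
        Tv = 2.0 * np.asarray(mu_field, dtype=float)[..., None, None] * S
        # (div T)_i = sum_j dT_ij/dx_j = sum_{j,m} A[j, m] / s_m * dT_ij/du_m
        dT = np.empty(v.shape[:3] + (3, 3, 3))
        for i in range(3):
            for j in range(3):
                for m in range(3):
                    dT[..., i, j, m], _ = masked_derivative(Tv[..., i, j], mask, axis=m)
        inv_s = 1.0 / (spacing * 1e-3)
        div = np.einsum("jm,m,...ijm->...i", A, inv_s, dT)
        b = b + div

    b[~mask] = 0.0
    return b


def hemodynamic_force(
    b: np.ndarray,
    mask: np.ndarray,
    spacing: np.ndarray,
    frame: AnatomicalFrame,
    volume_ml: float,
    sign_flip: bool = False,
):
    """Volume integral of b and its anatomical projection for one frame.

    Returns ``(vector, components, hdf_v)``: the world-frame force (N), its
    coordinates in the (basal_apical, septal_lateral, inferior_anterior)
    triad (N), and the volume-normalized components (N/L).
    """
    vox_m3 = float(np.prod(np.asarray(spacing, dtype=float))) * 1e-9
    vec = b[np.asarray(mask).astype(bool)].sum(axis=0) * vox_m3
    if sign_flip:
        vec = -vec
    comps = frame.matrix @ vec
    hdf_v = comps / (float(volume_ml) / 1000.0)
    return vec, comps, hdf_v


@dataclass
class HDFSeries:
    """Per-frame hemodynamic force with cycle/phase summaries.

    ``components`` / ``hdf_v`` columns follow :data:`COMPONENT_NAMES`.
    ``rms`` maps window name (cycle / systole / diastole) to a 3-vector of
    component RMS values of ``hdf_v`` (N/L); ``r_rms`` maps systole/diastole
    to the transversal-to-longitudinal RMS ratio.  ``impulse_ba`` is the
    early-diastolic filling impulse (Ns/L, signed) or None when undefined.
    ``peaks[window][component]`` = (value, time) of the largest-magnitude
    sample in the window.
    """

    times: np.ndarray
    vectors: np.ndarray
    components: np.ndarray
    hdf_v: np.ndarray
    rms: dict
    r_rms: dict
    impulse_ba: Optional[float]
    impulse_defined: bool
    peaks: dict


def _window_rms(times, values, t0, t1, rr):
    return np.sqrt(integrate_window(times, values**2, t0, t1, rr) / (t1 - t0))


def summarize_hdf(times: np.ndarray, hdf_v: np.ndarray, phases: PhaseMap):
    """RMS per component (cycle and per phase), R_RMS, and the peak table."""
    times = np.asarray(times, dtype=float)
    hdf_v = np.asarray(hdf_v, dtype=float)
    rr = phases.rr_interval
    windows = {"cycle": (0.0, rr), "systole": phases.systole, "diastole": phases.diastole}
    rms = {
        name: np.array([_window_rms(times, hdf_v[:, c], t0, t1, rr) for c in range(3)])
        for name, (t0, t1) in windows.items()
    }
    r_rms = {}
    for phase in ("systole", "diastole"):
        ba, sl, ia = rms[phase]
        if ba <= 0:
            raise DataError(f"basal-apical RMS is zero in {phase}; R_RMS undefined")
        r_rms[phase] = float(np.hypot(sl, ia) / ba)

    peak_windows = {"systole": phases.systole}
    if phases.e_wave_window is not None:
        peak_windows["e_wave"] = phases.e_wave_window
    if phases.a_wave_window is not None and not phases.merged_ea:
        peak_windows["a_wave"] = phases.a_wave_window
    peaks = {}
    for wname, (t0, t1) in peak_windows.items():
        idx = np.where((times >= t0 - 1e-12) & (times <= t1 + 1e-12))[0]
        entry = {}
        for c, cname in enumerate(COMPONENT_NAMES):
            if idx.size == 0:
                entry[cname] = None
                continue
            j = idx[int(np.argmax(np.abs(hdf_v[idx, c])))]
            entry[cname] = (float(hdf_v[j, c]), float(times[j]))
        peaks[wname] = entry
    return rms, r_rms, peaks


def filling_impulse(times: np.ndarray, hdf_v_ba: np.ndarray, phases: PhaseMap):
    """Early-diastolic filling impulse I_BA in Ns/L (signed).

    Integrates the volume-normalized basal--apical component from aortic
    valve closure to its next zero crossing, both endpoints located by
    linear interpolation.  Returns ``(impulse, defined)``; undefined when
    the component never crosses zero within diastole or is negligibly small
    after closure.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(hdf_v_ba, dtype=float)
    rr = phases.rr_interval
    t_avc = phases.aortic_valve_closure

    scale = float(np.max(np.abs(y))) if y.size else 0.0
    # dense sampling of the piecewise-linear series after closure
    grid = [t_avc] + [float(t) for t in times if t > t_avc] + [rr]
    vals = np.array([sample_series(times, y, t, rr) for t in grid])
    if scale <= 0 or np.max(np.abs(vals)) < 1e-12 * max(scale, 1.0) or np.max(np.abs(vals)) == 0:
        return None, False

    # establish the sign after closure from the first clearly nonzero value
    s0 = 0.0
    for v in vals:
        if abs(v) > 1e-9 * scale:
            s0 = np.sign(v)
            break
    if s0 == 0.0:
        return None, False
    t_cross = None
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if s0 * v1 < 0:
            t_cross = grid[i] + (grid[i + 1] - grid[i]) * v0 / (v0 - v1)
            break
    if t_cross is None:
        return None, False
    return integrate_window(times, y, t_avc, float(t_cross), rr), True


def compute_hdf_series(
    ds: FlowDataset,
    frames: list,
    volumes_ml: np.ndarray,
    mu_fields: list,
    density: float,
    phases: PhaseMap = None,
    include_viscous: bool = True,
    sign_flip: bool = False,
    gradients: list = None,
) -> HDFSeries:
    """Full-cycle hemodynamic-force series with summaries.

    ``frames`` is one :class:`AnatomicalFrame` per time frame (or a single
    frame reused), ``mu_fields`` one viscosity volume per frame.
    """
    T = ds.n_frames
    vectors = np.zeros((T, 3))
    comps = np.zeros((T, 3))
    hdf_v = np.zeros((T, 3))
    for k in range(T):
        fr = frames[k] if isinstance(frames, (list, tuple)) else frames
        g = gradients[k] if gradients is not None else None
        b = pressure_gradient_field(
            ds, k, mu_fields[k], density, include_viscous=include_viscous, gradient=g
        )
        vectors[k], comps[k], hdf_v[k] = hemodynamic_force(
            b, ds.mask[k], ds.spacing, fr, volumes_ml[k], sign_flip=sign_flip
        )
    if phases is None:
        return HDFSeries(ds.frame_times, vectors, comps, hdf_v, {}, {}, None, False, {})
    rms, r_rms, peaks = summarize_hdf(ds.frame_times, hdf_v, phases)
    impulse, defined = filling_impulse(ds.frame_times, hdf_v[:, 0], phases)
    return HDFSeries(
        times=ds.frame_times,
        vectors=vectors,
        components=comps,
        hdf_v=hdf_v,
        rms=rms,
        r_rms=r_rms,
        impulse_ba=impulse,
        impulse_defined=defined,
        peaks=peaks,
    )
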