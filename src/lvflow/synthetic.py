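"""Synthetic velocity-field generators with known ground truth.

Two families of inputs are produced, emulating what a 4D flow acquisition
plus cine segmentation would deliver (velocity volumes, LV mask, landmarks,
timing, hematocrit):

**Analytic fields** (uniform, rigid rotation, Poiseuille, uniform
acceleration) have closed-form energetics and pressure gradients and serve
as oracles for the differential operators:

* rigid rotation has zero strain rate, hence zero viscous dissipation;
* steady uniform flow has zero pressure gradient and zero hemodynamic force;
* Newtonian Poiseuille flow (peak velocity ``v_max``, radius ``R``) has a
  uniform axial pressure gradient ``-4 mu v_max / R^2`` and bulk dissipation
  ``2 pi mu v_max^2`` per unit length;
* a spatially uniform velocity ramp with acceleration ``a`` has pressure
  gradient ``-rho a`` everywhere, so the hemodynamic force is ``-rho a V``.

**The contracting-ellipsoid LV phantom** is a truncated prolate spheroid
(long axis fixed, short axes breathing with the prescribed volume curve)
whose interior velocity is built from a Stokes stream function: the flux
through every cross-section perpendicular to the long axis equals exactly
the rate of volume change below that section, which makes the field
continuity-consistent with the moving wall, and a smooth "funnel" steers
the flow through the active valve orifice (aortic in systole, mitral in
diastole) so that the transvalvular flux matches -dV/dt / +dV/dt.  The
volume curve has a half-cosine systolic ejection followed by biphasic
(E/A) raised-cosine filling with prescribed peak-flow ratio.  This is a
prescribed smooth flow model, not a CFD solve: its contract is flux
consistency and smoothness, which is all the downstream operators assume.

An optional ``transverse_mixing`` term superposes a smooth, wall-bounded
transverse sloshing velocity (direction rotating once per cycle) to emulate
the loss of basal--apical flow organization seen in remodelled ventricles;
it leaves the valve flow curves untouched because it is tangent to the
valve-plane normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import FlowDataset, LandmarkSet, ValidationError
from .rheology import BLOOD_DENSITY


class SpecError(ValidationError):
    """Invalid synthetic-field specification."""


# --------------------------------------------------------------------------
# ground-truth carrier


@dataclass
class PhantomTruth:
    """Closed-form ground truth carried alongside a generated dataset.

    ``dissipation_truth`` (W per frame) and ``hdf_truth`` (N per frame,
    world vector) are filled only where a closed form exists.  ``extras``
    holds phantom-specific scalars (event times, peak flows, ...).
    """

    volume_curve: np.ndarray
    aortic_flow: np.ndarray
    mitral_flow: np.ndarray
    sv: float
    ef: float
    dissipation_truth: Optional[np.ndarray] = None
    hdf_truth: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# small helpers


def _generic_landmarks(center: np.ndarray, half: np.ndarray) -> LandmarkSet:
    """A geometrically valid landmark set for analytic (non-LV) fields."""
    cx, cy, cz = center
    hx, hy, hz = half
    phi = 2.0 * np.pi * np.arange(8) / 8.0
    base_z = cz + 0.8 * hz

    def ring(c, r):
        return np.stack(
            [c[0] + r * np.cos(phi), c[1] + r * np.sin(phi), np.full(8, base_z)], axis=1
        )

    return LandmarkSet(
        apex=np.array([cx, cy, cz - 0.8 * hz]),
        mitral_points=ring((cx - 0.2 * hx, cy), 0.3 * hx),
        aortic_points=ring((cx + 0.4 * hx, cy), 0.2 * hx),
        pm_tips=np.array([[cx, cy - 0.3 * hy, cz + 0.4 * hz], [cx, cy + 0.3 * hy, cz + 0.4 * hz]]),
        pm_bases=np.array([[cx, cy - 0.3 * hy, cz], [cx, cy + 0.3 * hy, cz]]),
    )


def _voxel_centers(shape, spacing):
    nx, ny, nz = shape
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).astype(float)
    return idx * np.asarray(spacing, dtype=float)


def cylinder_mask(shape, spacing, radius_mm, axis=2, center=None):
    """Voxel mask of a cylinder along a grid axis (world-aligned grids)."""
    coords = _voxel_centers(shape, spacing)
    if center is None:
        center = 0.5 * (np.array(shape) - 1) * np.asarray(spacing, dtype=float)
    trans = [i for i in range(3) if i != axis]
    r2 = sum((coords[..., i] - center[i]) ** 2 for i in trans)
    return r2 <= radius_mm**2


def sphere_mask(shape, spacing, radius_mm, center=None):
    coords = _voxel_centers(shape, spacing)
    if center is None:
        center = 0.5 * (np.array(shape) - 1) * np.asarray(spacing, dtype=float)
    return np.sum((coords - np.asarray(center)) ** 2, axis=-1) <= radius_mm**2


# --------------------------------------------------------------------------
# analytic fields


@dataclass
class AnalyticFieldSpec:
    """Specification of an analytic oracle field.

    ``kind`` in {uniform, rigid_rotation, poiseuille, uniform_acceleration}.
    Dimensional parameters: ``speed`` m/s, ``angular_rate`` rad/s,
    ``tube_radius`` mm, ``peak_velocity`` m/s, ``acceleration`` m/s^2.
    ``mu`` (Pa s) and ``density`` (kg/m^3) only parameterize the closed-form
    truths.  The tube axis is the grid z axis.
    """

    kind: str
    speed: float = 0.5
    direction: tuple = (0.0, 0.0, 1.0)
    angular_rate: float = 10.0
    tube_radius: float = 10.0
    peak_velocity: float = 1.0
    acceleration: float = 1.0
    tube_center_offset: tuple = (0.0, 0.0)
    mu: float = 3.5e-3
    density: float = BLOOD_DENSITY
    shape: tuple = (24, 24, 24)
    spacing: tuple = (2.0, 2.0, 2.0)
    n_frames: int = 5
    rr_interval: float = 1.0

    def __post_init__(self) -> None:
        kinds = ("uniform", "rigid_rotation", "poiseuille", "uniform_acceleration")
        if self.kind not in kinds:
            raise SpecError(f"unknown analytic field kind {self.kind!r}")
        for name in ("tube_radius", "mu", "density", "rr_interval"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if self.n_frames < 3:
            raise SpecError("need at least 3 frames (cyclic temporal derivative)")
        if self.kind == "poiseuille":
            half = 0.5 * min(
                (self.shape[0] - 1) * self.spacing[0], (self.shape[1] - 1) * self.spacing[1]
            )
            if self.tube_radius >= half:
                raise SpecError("tube does not fit inside the grid")


def make_analytic_field(spec: AnalyticFieldSpec):
    """Sample an analytic field at voxel centers; return (dataset, truth)."""
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    T = spec.n_frames
    times = spec.rr_interval * np.arange(T) / T
    coords = _voxel_centers(shape, spacing)
    center = 0.5 * (np.array(shape) - 1) * spacing
    half = 0.5 * np.array(shape) * spacing

    vel = np.zeros((T,) + shape + (3,))
    mask = np.ones((T,) + shape, dtype=bool)
    nvox = int(np.prod(shape))
    vol_m3 = nvox * float(np.prod(spacing)) * 1e-9

    diss = np.zeros(T)
    hdf = np.zeros((T, 3))
    extras = {}

    if spec.kind == "uniform":
        d = np.asarray(spec.direction, dtype=float)
        d = d / np.linalg.norm(d)
        vel[:] = spec.speed * d
    elif spec.kind == "rigid_rotation":
        rel = coords - center  # mm
        # omega about z through the grid centre; v = omega x r
        vx = -spec.angular_rate * rel[..., 1] * 1e-3
        vy = spec.angular_rate * rel[..., 0] * 1e-3
        vel[:, ..., 0] = vx
        vel[:, ..., 1] = vy
    elif spec.kind == "uniform_acceleration":
        d = np.asarray(spec.direction, dtype=float)
        d = d / np.linalg.norm(d)
        for k in range(T):
            vel[k] = spec.acceleration * times[k] * d
        hdf = -spec.density * spec.acceleration * vol_m3 * d[None, :] * np.ones((T, 1))
        extras["pressure_gradient_pa_per_m"] = -spec.density * spec.acceleration
    else:  # poiseuille
        R = spec.tube_radius
        rel = coords - center
        rel = rel - np.array([spec.tube_center_offset[0], spec.tube_center_offset[1], 0.0])
        r2 = rel[..., 0] ** 2 + rel[..., 1] ** 2
        inside = r2 <= R**2
        prof = np.where(inside, spec.peak_velocity * (1.0 - r2 / R**2), 0.0)
        vel[:, ..., 2] = prof
        mask[:] = inside
        L_m = shape[2] * spacing[2] * 1e-3
        diss[:] = 2.0 * np.pi * spec.mu * spec.peak_velocity**2 * L_m
        grad = -4.0 * spec.mu * spec.peak_velocity / (R * 1e-3) ** 2
        extras["pressure_gradient_pa_per_m"] = grad
        vol_m3 = int(inside.sum()) * float(np.prod(spacing)) * 1e-9
        hdf[:, 2] = grad * vol_m3
        extras["wall_shear_rate_per_s"] = 2.0 * spec.peak_velocity / (R * 1e-3)

    lm = _generic_landmarks(center, half)
    ds = FlowDataset(
        velocity=vel,
        mask=mask,
        spacing=spacing,
        frame_times=times,
        rr_interval=spec.rr_interval,
        hematocrit=0.42,
        landmarks=[lm] * T,
    )
    vols = mask.sum(axis=(1, 2, 3)) * float(np.prod(spacing)) / 1000.0
    truth = PhantomTruth(
        volume_curve=vols,
        aortic_flow=np.zeros(T),
        mitral_flow=np.zeros(T),
        sv=0.0,
        ef=0.0,
        dissipation_truth=diss,
        hdf_truth=hdf,
        extras=extras,
    )
    return ds, truth


# --------------------------------------------------------------------------
# volume curve of the LV phantom


class _Bump:
    """Raised-cosine flow bump: q(t) = peak/2 (1 - cos 2pi (t-t0)/w) on [t0, t0+w]."""

    def __init__(self, t0: float, width: float, area: float):
        self.t0 = float(t0)
        self.w = float(width)
        self.peak = 2.0 * area / self.w

    def q(self, t):
        t = np.asarray(t, dtype=float)
        u = (t - self.t0) / self.w
        inside = (u >= 0.0) & (u <= 1.0)
        return np.where(inside, 0.5 * self.peak * (1.0 - np.cos(2.0 * np.pi * u)), 0.0)

    def cum(self, t):
        """Integral of q from t0 to t (clamped)."""
        t = np.asarray(t, dtype=float)
        u = np.clip((t - self.t0) / self.w, 0.0, 1.0)
        return 0.5 * self.peak * self.w * (u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi))


class _VolumeCurve:
    """Prescribed V(t): systolic ejection then biphasic (or merged) filling."""

    def __init__(self, edv, sv, rr, systole_fraction, e_to_a_ratio,
                 e_onset=0.08, e_duration=0.50, a_duration=0.30, merged=False):
        self.edv, self.sv, self.rr = edv, sv, rr
        ts = systole_fraction * rr
        td = rr - ts
        self.t_systole_end = ts
        self.ejection = _Bump(0.0, ts, sv)
        if merged:
            self.filling = [_Bump(ts + e_onset * td, (1.0 - e_onset) * td, sv)]
            self.e_peak_time = self.filling[0].t0 + 0.5 * self.filling[0].w
            self.a_peak_time = None
        else:
            w_e = e_duration * td
            w_a = a_duration * td
            if e_onset * td + w_e > td - w_a + 1e-9:
                raise SpecError("E and A waves overlap; reduce their durations")
            q_a_area = sv / (e_to_a_ratio * w_e / w_a + 1.0)
            q_e_area = sv - q_a_area
            e = _Bump(ts + e_onset * td, w_e, q_e_area)
            a = _Bump(rr - w_a, w_a, q_a_area)
            self.filling = [e, a]
            self.e_peak_time = e.t0 + 0.5 * e.w
            self.a_peak_time = a.t0 + 0.5 * a.w

    def q_aortic(self, t):
        return self.ejection.q(t)

    def q_mitral(self, t):
        return sum(b.q(t) for b in self.filling)

    def volume(self, t):
        return self.edv - self.ejection.cum(t) + sum(b.cum(t) for b in self.filling)

    def vdot(self, t):
        return -self.q_aortic(t) + self.q_mitral(t)


# --------------------------------------------------------------------------
# contracting-ellipsoid LV phantom


@dataclass
class EllipsoidLVSpec:
    """Knobs of the contracting-ellipsoid LV phantom.

    Defaults describe a healthy adult left ventricle at rest: EDV 150 mL,
    EF 0.60, 70 bpm, systole 35% of the cycle, E/A peak-flow ratio 2.0,
    imaged at 2.5 mm isotropic on a 32x32x48 grid with 30 reconstructed
    phases.  ``noise_sd`` adds seeded isotropic Gaussian noise to every
    velocity component (m/s).  ``e_wave_duration`` is the E-wave width as a
    fraction of diastole (shorter = sharper early-filling deceleration, the
    restrictive-filling pattern).  ``transverse_mixing`` scales a smooth
    transverse sloshing component (0 = perfectly base--apex organized flow).
    ``axisymmetric`` centres a single shared orifice on the long axis
    (useful for force-alignment oracles; the valve landmark rings then
    coincide, so the anatomical frame must be supplied externally).
    """

    edv: float = 150.0
    ef: float = 0.60
    heart_rate: float = 70.0
    systole_fraction: float = 0.35
    e_to_a_ratio: float = 2.0
    long_axis_direction: tuple = (0.0, 0.0, -1.0)
    noise_sd: float = 0.0
    seed: int = 0
    shape: tuple = (32, 32, 48)
    spacing: float = 2.5
    n_frames: int = 30
    hematocrit: float = 0.42
    aspect_ratio: float = 1.8
    base_cut: float = 0.5
    funnel_fraction: float = 0.35
    e_onset: float = 0.08
    e_wave_duration: float = 0.50
    a_wave_duration: float = 0.30
    single_diastolic_wave: bool = False
    transverse_mixing: float = 0.0
    axisymmetric: bool = False
    # orifice placement, fractions of the basal disc radius
    mitral_offset_frac: float = -0.46
    mitral_radius_frac: float = 0.50
    aortic_offset_frac: float = 0.46
    aortic_radius_frac: float = 0.38

    def __post_init__(self) -> None:
        if not 0.0 < self.ef < 1.0:
            raise SpecError("ef must be in (0, 1)")
        if not 0.0 < self.systole_fraction < 1.0:
            raise SpecError("systole_fraction must be in (0, 1)")
        if self.edv <= 0 or self.heart_rate <= 0:
            raise SpecError("edv and heart_rate must be positive")
        if self.e_to_a_ratio <= 0:
            raise SpecError("e_to_a_ratio must be positive")
        if not 0.0 < self.base_cut < 1.0:
            raise SpecError("base_cut must be in (0, 1)")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u), 6.0 * u * (1.0 - u)


def make_ellipsoid_lv(spec: EllipsoidLVSpec):
    """Generate the contracting-ellipsoid phantom; return (dataset, truth)."""
    rr = 60.0 / spec.heart_rate
    sv = spec.edv * spec.ef
    curve = _VolumeCurve(
        spec.edv, sv, rr, spec.systole_fraction,
        spec.e_to_a_ratio, spec.e_onset, spec.e_wave_duration,
        spec.a_wave_duration, spec.single_diastolic_wave,
    )

    kappa = spec.base_cut
    # truncated prolate spheroid: V = pi b^2 G(kappa a), G in units of a
    g_kappa = (kappa + 1.0) - (kappa**3 + 1.0) / 3.0
    a_long = (spec.edv * 1000.0 * spec.aspect_ratio**2 / (np.pi * g_kappa)) ** (1.0 / 3.0)
    z_base = kappa * a_long

    def b_of_V(vol_ml):
        return np.sqrt(vol_ml * 1000.0 / (np.pi * g_kappa * a_long))

    b_ed = b_of_V(spec.edv)
    r_base_ed = b_ed * np.sqrt(1.0 - kappa**2)

    shape = tuple(spec.shape)
    spacing = np.full(3, float(spec.spacing))
    extent = np.array(shape) * spacing
    jet_ext = 3.0 * spec.spacing
    cavity_len = a_long + z_base + jet_ext
    if cavity_len > extent[2] - 2 * spec.spacing or 2.2 * b_ed > min(extent[0], extent[1]):
        raise SpecError("phantom does not fit inside the grid")
    # ellipsoid centre in world coordinates (apex margin at the -z side)
    margin = 0.5 * (extent[2] - cavity_len)
    center = np.array([0.5 * extent[0], 0.5 * extent[1], margin + a_long])
    center -= 0.5 * spacing  # voxel-centre grid starts at 0

    T = spec.n_frames
    times = rr * np.arange(T) / T
    coords = _voxel_centers(shape, spacing)
    local = coords - center
    zc = local[..., 2]
    xh, yh = local[..., 0], local[..., 1]

    w2 = np.clip(1.0 - (zc / a_long) ** 2, 0.0, None)
    w = np.sqrt(w2)
    G = (zc + a_long) - (zc**3 + a_long**3) / (3.0 * a_long**2)
    G_base = (z_base + a_long) - (z_base**3 + a_long**3) / (3.0 * a_long**2)

    z_funnel = z_base - spec.funnel_fraction * (z_base + a_long)
    s_blend, s_prime = _smoothstep((zc - z_funnel) / (z_base - z_funnel))
    s_prime = s_prime / (z_base - z_funnel)
    in_slab = (zc >= -a_long) & (zc <= z_base)
    above = (zc > z_base) & (zc <= z_base + jet_ext)

    if spec.axisymmetric:
        o_m_frac = o_a_frac = 0.0
        r_m_frac = r_a_frac = 0.45
    else:
        o_m_frac, r_m_frac = spec.mitral_offset_frac, spec.mitral_radius_frac
        o_a_frac, r_a_frac = spec.aortic_offset_frac, spec.aortic_radius_frac

    peak_ao = curve.ejection.peak  # mL/s
    v_ref = peak_ao / (np.pi * (r_a_frac * r_base_ed) ** 2)  # m/s (mL/s per mm^2)

    rng = np.random.default_rng(spec.seed)
    vel = np.zeros((T,) + shape + (3,))
    mask = np.zeros((T,) + shape, dtype=bool)
    landmarks = []
    vols = np.zeros(T)

    for k, t in enumerate(times):
        V = float(curve.volume(t))
        Vd = float(curve.vdot(t))  # mL/s
        b = float(b_of_V(V))
        r_base = b * np.sqrt(1.0 - kappa**2)
        rho_w = b * w
        cavity = in_slab & (xh**2 + yh**2 <= rho_w**2) & (rho_w > 0)
        mask[k] = cavity
        vols[k] = cavity.sum() * float(np.prod(spacing)) / 1000.0
        # evaluate the velocity slightly beyond the wall as well: the smooth
        # wall-following continuation keeps near-wall interpolation (and
        # pathlines hugging the contracting wall) physically consistent
        vel_region = in_slab & (xh**2 + yh**2 <= (rho_w + 2.0 * spec.spacing) ** 2) & (rho_w > 0)

        # active orifice: aortic while ejecting, mitral while filling
        if Vd <= 0:
            off, r_o = o_a_frac * r_base, r_a_frac * r_base
        else:
            off, r_o = o_m_frac * r_base, r_m_frac * r_base

        # flux (mm^3/s) through the cross-section at z and its z-derivative
        F = -Vd * 1000.0 * G / G_base
        Fp = -Vd * 1000.0 * w2 / G_base

        cx = s_blend * off
        cpx = s_prime * off
        rho2 = (xh - cx) ** 2 + yh**2
        rho = np.sqrt(rho2)
        R_eff = (1.0 - s_blend) * rho_w + s_blend * r_o
        Rp = -s_prime * rho_w + (1.0 - s_blend) * b * np.where(
            w > 1e-9, -zc / (a_long**2 * np.maximum(w, 1e-9)), 0.0
        ) + s_prime * r_o
        R_eff = np.maximum(R_eff, 1e-9)
        u = rho / R_eff
        inside_tube = u < 1.0

        vz = np.where(
            vel_region & inside_tube,
            (2.0 * F / (np.pi * R_eff**2)) * (1.0 - np.minimum(u, 1.0) ** 2),
            0.0,
        )
        # radial (shifted-axis) component from d(psi)/dz
        g_u = np.minimum(u, 1.0) ** 2 * (2.0 - np.minimum(u, 1.0) ** 2)
        gp_u = 4.0 * np.minimum(u, 1.0) * (1.0 - np.minimum(u, 1.0) ** 2)
        safe_rho = np.maximum(rho, 1e-9)
        v_rho = np.where(
            vel_region,
            np.where(
                inside_tube,
                -(Fp / (2.0 * np.pi)) * (rho * (2.0 - u**2) / R_eff**2)
                + (F / (2.0 * np.pi)) * gp_u * Rp / R_eff**2,
                -(Fp / (2.0 * np.pi)) / safe_rho,
            ),
            0.0,
        )
        rx = np.where(rho > 1e-9, (xh - cx) / safe_rho, 0.0)
        ry = np.where(rho > 1e-9, yh / safe_rho, 0.0)

        vx = v_rho * rx + vz * cpx
        vy = v_rho * ry

        # straight jet continuation above the base plane (keeps the valve
        # crossing well defined for flux sampling and pathline tracing)
        rho_o2 = (xh - off) ** 2 + yh**2
        F_b = -Vd * 1000.0
        jet = above & (rho_o2 < r_o**2)
        vz = np.where(jet, (2.0 * F_b / (np.pi * r_o**2)) * (1.0 - rho_o2 / r_o**2), vz)

        frame_v = np.stack([vx, vy, vz], axis=-1) * 1e-3  # mm/s -> m/s

        if spec.transverse_mixing > 0:
            zeta = np.clip((zc + a_long) / (z_base + a_long), 0.0, 1.0)
            env = np.where(
                cavity, (1.0 - np.clip((xh**2 + yh**2) / np.maximum(rho_w, 1e-9) ** 2, 0, 1))
                * 4.0 * zeta * (1.0 - zeta), 0.0,
            )
            theta = 2.0 * np.pi * t / rr
            amp = spec.transverse_mixing * v_ref
            frame_v[..., 0] += amp * env * np.cos(theta)
            frame_v[..., 1] += amp * env * np.sin(theta)

        vel[k] = frame_v

        # landmarks
        scale = b / b_ed
        phi = 2.0 * np.pi * np.arange(8) / 8.0

        def ring(offset, radius):
            return np.stack(
                [center[0] + offset + radius * np.cos(phi),
                 center[1] + radius * np.sin(phi),
                 np.full(8, center[2] + z_base)], axis=1)

        z_tip = z_base - 0.40 * (z_base + a_long)
        z_pmb = z_base - 0.65 * (z_base + a_long)
        w_tip = b * np.sqrt(max(1.0 - (z_tip / a_long) ** 2, 0.0))
        w_pmb = b * np.sqrt(max(1.0 - (z_pmb / a_long) ** 2, 0.0))
        landmarks.append(
            LandmarkSet(
                apex=center + np.array([0.0, 0.0, -a_long]),
                mitral_points=ring(o_m_frac * r_base, r_m_frac * r_base),
                aortic_points=ring(
                    (o_a_frac if not spec.axisymmetric else 0.3) * r_base, r_a_frac * r_base
                ),
                pm_tips=np.array(
                    [[center[0], center[1] - 0.55 * w_tip, center[2] + z_tip],
                     [center[0], center[1] + 0.55 * w_tip, center[2] + z_tip]]
                ),
                pm_bases=np.array(
                    [[center[0], center[1] - 0.55 * w_pmb, center[2] + z_pmb],
                     [center[0], center[1] + 0.55 * w_pmb, center[2] + z_pmb]]
                ),
            )
        )

    if spec.noise_sd > 0:
        vel += rng.normal(0.0, spec.noise_sd, size=vel.shape)

    ds = FlowDataset(
        velocity=vel,
        mask=mask,
        spacing=spacing,
        frame_times=times,
        rr_interval=rr,
        hematocrit=spec.hematocrit,
        landmarks=landmarks,
    )

    direction = np.asarray(spec.long_axis_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    if not np.allclose(direction, [0.0, 0.0, -1.0]):
        from .dataset import rotate_dataset
        from scipy.spatial.transform import Rotation

        src = np.array([0.0, 0.0, -1.0])
        axis = np.cross(src, direction)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            R = -np.eye(3) if direction @ src < 0 else np.eye(3)
            if np.linalg.det(R) < 0:
                R = Rotation.from_rotvec(np.pi * np.array([1.0, 0.0, 0.0])).as_matrix()
        else:
            angle = np.arctan2(n, float(src @ direction))
            R = Rotation.from_rotvec(angle * axis / n).as_matrix()
        ds = rotate_dataset(ds, R)

    truth = PhantomTruth(
        volume_curve=np.asarray(curve.volume(times)),
        aortic_flow=np.asarray(curve.q_aortic(times)),
        mitral_flow=np.asarray(curve.q_mitral(times)),
        sv=sv,
        ef=spec.ef,
        extras={
            "edv": spec.edv,
            "esv": spec.edv - sv,
            "t_avc": curve.t_systole_end,
            "e_peak_time": curve.e_peak_time,
            "a_peak_time": curve.a_peak_time,
            "e_peak_flow": curve.filling[0].peak,
            "a_peak_flow": curve.filling[1].peak if len(curve.filling) > 1 else None,
            "rr_interval": rr,
            "rasterized_volume_curve": vols,
        },
    )
    return ds, truth


# --------------------------------------------------------------------------
# transit-tube phantom (flow-component limiting cases)


def perturb_mask_boundary(mask: np.ndarray, rng, flip_probability: float = 0.5) -> np.ndarray:
    """Randomly flip mask voxels within one voxel of the boundary.

    Emulates interoperator segmentation variability: inner-shell voxels may
    be dropped and outer-shell voxels added, each independently with
    ``flip_probability``.  Works frame-wise on (T, X, Y, Z) masks and never
    empties a frame.
    """
    from scipy import ndimage

    mask = np.asarray(mask).astype(bool)
    out = mask.copy()
    frames = mask if mask.ndim == 4 else mask[None]
    res = out if mask.ndim == 4 else out[None]
    for k in range(frames.shape[0]):
        m = frames[k]
        inner = m & ~ndimage.binary_erosion(m)
        outer = ndimage.binary_dilation(m) & ~m
        drop = inner & (rng.random(m.shape) < flip_probability)
        add = outer & (rng.random(m.shape) < flip_probability)
        new = (m & ~drop) | add
        if new.any():
            res[k] = new
    return out if mask.ndim == 4 else res[0]


def make_transit_tube(
    radius_mm: float = 10.0,
    length_mm: float = 60.0,
    shape: tuple = (20, 20, 44),
    spacing: float = 2.5,
    n_frames: int = 24,
    rr_interval: float = 1.0,
    systole_fraction: float = 0.5,
    travel_factor: float = 1.3,
    speed_scale: float = 1.0,
):
    """Straight-tube phantom in which the whole pool transits each cycle.

    Plug flow along +z: during diastole the pool enters through the inlet
    (mitral) disc at the tube's lower end, during systole it leaves through
    the outlet (aortic) disc at the upper end, each phase displacing the
    fluid by ``travel_factor x length``.  With ``speed_scale=0`` the fluid
    never moves (the residual-volume limiting case).  The mask is the static
    tube interior; velocity extends beyond the tube ends so that valve
    crossings are well defined.
    """
    shape = tuple(shape)
    spacing_v = np.full(3, float(spacing))
    coords = _voxel_centers(shape, spacing_v)
    extent = np.array(shape) * spacing
    cx, cy = 0.5 * extent[0] - 0.5 * spacing, 0.5 * extent[1] - 0.5 * spacing
    z0 = 0.5 * (extent[2] - length_mm)
    z1 = z0 + length_mm
    r2 = (coords[..., 0] - cx) ** 2 + (coords[..., 1] - cy) ** 2
    tube = r2 <= radius_mm**2
    mask3 = tube & (coords[..., 2] >= z0) & (coords[..., 2] <= z1)

    T = n_frames
    times = rr_interval * np.arange(T) / T
    ts = systole_fraction * rr_interval
    travel = travel_factor * length_mm  # mm per phase
    sys_bump = _Bump(0.0, ts, travel)
    dia_bump = _Bump(ts, rr_interval - ts, travel)

    vel = np.zeros((T,) + shape + (3,))
    speed_mm_s = speed_scale * (sys_bump.q(times) + dia_bump.q(times))
    vel_tube = tube & (r2 <= (radius_mm + spacing) ** 2)
    for k in range(T):
        vel[k, ..., 2] = np.where(vel_tube, speed_mm_s[k] * 1e-3, 0.0)

    phi = 2.0 * np.pi * np.arange(8) / 8.0

    def ring(z):
        return np.stack(
            [cx + radius_mm * np.cos(phi), cy + radius_mm * np.sin(phi), np.full(8, z)],
            axis=1,
        )

    lm = LandmarkSet(
        apex=np.array([cx + 2.0, cy, 0.5 * (z0 + z1)]),
        mitral_points=ring(z0),
        aortic_points=ring(z1),
        pm_tips=np.array([[cx, cy - 3.0, z0 + 0.3 * length_mm],
                          [cx, cy + 3.0, z0 + 0.3 * length_mm]]),
        pm_bases=np.array([[cx, cy - 3.0, z0 + 0.6 * length_mm],
                           [cx, cy + 3.0, z0 + 0.6 * length_mm]]),
    )
    ds = FlowDataset(
        velocity=vel,
        mask=np.broadcast_to(mask3, (T,) + shape).copy(),
        spacing=spacing_v,
        frame_times=times,
        rr_interval=rr_interval,
        hematocrit=0.42,
        landmarks=[lm] * T,
    )
    area = np.pi * radius_mm**2  # mm^2
    q = speed_mm_s * area / 1000.0  # mL/s
    vol = mask3.sum() * float(np.prod(spacing_v)) / 1000.0
    truth = PhantomTruth(
        volume_curve=np.full(T, vol),
        aortic_flow=np.where(times < ts, q, 0.0),
        mitral_flow=np.where(times >= ts, q, 0.0),
        sv=0.0,
        ef=0.0,
        extras={"t_avc": ts},
    )
    return ds, truth
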