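"""LV geometry: cavity volumes, the anatomical reference frame, regional
subdivision, transvalvular flow curves, cardiac-phase detection and the Dice
mask-overlap utility.

Anatomical axes
---------------
The hemodynamic-force components are reported in an orthonormal triad built
from the landmarks of each frame:

* **basal--apical**: unit vector from the mitral-annulus centroid to the
  apex (positive values point apex-ward),
* **septal--lateral**: the direction from the mitral centroid towards the
  aortic-annulus centroid (the LVOT plane), orthogonalized against the
  basal--apical axis,
* **inferior--anterior**: completes the right-handed triad
  (basal_apical x septal_lateral).

The construction works directly in 3D world coordinates; it is the 3D
equivalent of deriving the axes from HLA/LVOT long-axis views.

Regional subdivision
--------------------
Two cutting planes perpendicular to the basal--apical axis, through the mean
papillary-muscle tip and mean papillary-muscle base positions, split the
cavity into basal (mitral valve to PM tips), mid (PM tips to PM bases) and
apical (below PM bases) slabs.  By default the planes follow the landmarks
frame by frame; ``fixed_at_ed=True`` freezes them at the first frame.

Cardiac phases
--------------
The cycle starts at end-diastole.  Systole ends at aortic valve closure,
located as the downward zero crossing of the aortic flow curve after its
systolic peak (sub-frame, by linear interpolation); the E- and A-wave peaks
are the local maxima of the transmitral flow curve in diastole, with the
A wave flagged as merged when no separate late peak exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .dataset import FlowDataset, LandmarkSet, ValidationError, trilinear_sample


class GeometryError(ValidationError):
    """Degenerate or inconsistent anatomical geometry."""


class PhaseDetectionError(ValidationError):
    """Cardiac phases could not be identified from the flow curves."""


class DataError(ValidationError):
    """Input data violate an operation's preconditions."""


REGION_NAMES = ("basal", "mid", "apical")
REGION_BASAL, REGION_MID, REGION_APICAL = 1, 2, 3


# --------------------------------------------------------------------------
# volumes


def lv_volume_series(mask: np.ndarray, spacing: np.ndarray, labels: np.ndarray = None):
    """Cavity volume per frame in mL (voxel count x voxel volume).

    ``mask`` is (T, X, Y, Z).  With a region ``labels`` volume (same shape,
    values 0 outside / 1 basal / 2 mid / 3 apical) a dict of per-region
    volume series is returned as well.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 4:
        raise DataError("mask must be (T, X, Y, Z)")
    counts = mask.sum(axis=(1, 2, 3))
    if np.any(counts == 0):
        raise DataError(f"mask empty at frame {int(np.argmin(counts > 0))}")
    vox_ml = float(np.prod(np.asarray(spacing, dtype=float))) / 1000.0
    total = counts * vox_ml
    if labels is None:
        return total
    regional = {
        name: (labels == code).sum(axis=(1, 2, 3)) * vox_ml
        for code, name in zip((REGION_BASAL, REGION_MID, REGION_APICAL), REGION_NAMES)
    }
    return total, regional


# --------------------------------------------------------------------------
# anatomical frame


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal anatomical triad with its origin (mm)."""

    basal_apical: np.ndarray
    septal_lateral: np.ndarray
    inferior_anterior: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        for name in ("basal_apical", "septal_lateral", "inferior_anterior", "origin"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        M = self.matrix
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise GeometryError("anatomical triad is not orthonormal")
        if np.linalg.det(M) < 0:
            raise GeometryError("anatomical triad is not right-handed")

    @property
    def matrix(self) -> np.ndarray:
        """Rows = (basal_apical, septal_lateral, inferior_anterior)."""
        return np.stack([self.basal_apical, self.septal_lateral, self.inferior_anterior])


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Anatomical triad from the apex, mitral and aortic annulus landmarks.

    Raises :class:`GeometryError` when the aortic centroid is collinear with
    the long axis (the LVOT plane is then undefined).
    """
    mc = landmarks.mitral_centroid
    ba = landmarks.apex - mc
    nba = np.linalg.norm(ba)
    if nba < 1e-9:
        raise GeometryError("apex coincides with mitral centroid")
    ba = ba / nba
    d = landmarks.aortic_centroid - mc
    sl = d - (d @ ba) * ba
    nsl = np.linalg.norm(sl)
    if nsl < 1e-9 * max(np.linalg.norm(d), 1.0) or nsl < 1e-12:
        raise GeometryError("aortic centroid collinear with the long axis")
    sl = sl / nsl
    ia = np.cross(ba, sl)
    return AnatomicalFrame(ba, sl, ia, origin=mc)


# --------------------------------------------------------------------------
# regional subdivision


def subdivide_regions(
    mask: np.ndarray,
    landmarks: Sequence[LandmarkSet],
    spacing: np.ndarray,
    origin: np.ndarray = None,
    axes: np.ndarray = None,
    fixed_at_ed: bool = False,
) -> np.ndarray:
    """Label every in-mask voxel basal / mid / apical.

    Cutting planes are perpendicular to the basal--apical axis through the
    mean papillary-muscle tip and base positions.  Returns (T, X, Y, Z)
    uint8 labels (0 outside the mask).
    """
    mask = np.asarray(mask).astype(bool)
    T = mask.shape[0]
    if len(landmarks) != T:
        raise GeometryError("need one LandmarkSet per frame")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    A = np.eye(3) if axes is None else np.asarray(axes, dtype=float)

    nx, ny, nz = mask.shape[1:]
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).astype(float)
    coords = (idx * spacing) @ A.T + origin

    labels = np.zeros(mask.shape, dtype=np.uint8)
    for k in range(T):
        lm = landmarks[0] if fixed_at_ed else landmarks[k]
        frame = build_frame(lm)
        ba, mc = frame.basal_apical, frame.origin
        s_tip = float(np.mean((lm.pm_tips - mc) @ ba))
        s_base = float(np.mean((lm.pm_bases - mc) @ ba))
        if s_tip >= s_base - 1e-9:
            raise GeometryError(
                "papillary tip plane is not basal to the papillary base plane"
            )
        s = (coords - mc) @ ba
        lab = np.where(s < s_tip, REGION_BASAL, np.where(s < s_base, REGION_MID, REGION_APICAL))
        labels[k] = np.where(mask[k], lab, 0).astype(np.uint8)
    return labels


# --------------------------------------------------------------------------
# valve discs and transvalvular flow


@dataclass
class ValveDisc:
    """A valve plane discretized as a disc: centre (mm), unit normal, radius (mm).

    ``ventricle_side`` is the sign of ``(x - center) . normal`` for points on
    the ventricular side of the plane (0 when unknown); pathline tracing uses
    it to resolve crossings that start exactly on the plane.
    """

    center: np.ndarray
    normal: np.ndarray
    radius: float
    ventricle_side: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.radius = float(self.radius)


def fit_valve_disc(points: np.ndarray, apex: np.ndarray, inward: bool) -> ValveDisc:
    """Best-fit disc through annulus points.

    Normal from the plane fit (smallest principal direction), oriented
    towards the apex for ``inward=True`` (mitral: inflow positive) and away
    for ``inward=False`` (aortic: outflow positive).  Radius = mean distance
    of the points from their centroid.
    """
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    centered = pts - c
    _, sv, vt = np.linalg.svd(centered, full_matrices=True)
    if pts.shape[0] < 3 or sv[1] < 1e-9:
        raise GeometryError("annulus points do not define a plane")
    n = vt[2]
    radius = float(np.mean(np.linalg.norm(centered, axis=1)))
    if radius < 1e-9:
        raise GeometryError("annulus points are degenerate (zero radius)")
    sign = np.sign(n @ (np.asarray(apex, dtype=float) - c))
    if sign == 0:
        sign = 1.0
    if not inward:
        sign = -sign
    # mitral normal points into the ventricle, aortic out of it
    return ValveDisc(center=c, normal=sign * n, radius=radius,
                     ventricle_side=1.0 if inward else -1.0)


def disc_quadrature(disc: ValveDisc, step: float):
    """Polar quadrature points (world mm) and area weights (mm^2) on a disc."""
    n = disc.normal
    # in-plane orthonormal basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = a - (a @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    n_r = max(3, int(np.ceil(disc.radius / step)))
    dr = disc.radius / n_r
    pts, wts = [], []
    for j in range(n_r):
        r = (j + 0.5) * dr
        m = max(8, int(np.ceil(2.0 * np.pi * r / dr)))
        phi = 2.0 * np.pi * (np.arange(m) + 0.5) / m
        ring = disc.center + r * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
        area = np.pi * ((j + 1) ** 2 - j**2) * dr**2 / m
        pts.append(ring)
        wts.append(np.full(m, area))
    return np.concatenate(pts), np.concatenate(wts)


def valve_disc_series(ds: FlowDataset, which: str) -> list:
    """Per-frame fitted :class:`ValveDisc` for ``which`` in {mitral, aortic}."""
    if which not in ("mitral", "aortic"):
        raise ValueError("which must be 'mitral' or 'aortic'")
    discs = []
    for lm in ds.landmarks:
        pts = lm.mitral_points if which == "mitral" else lm.aortic_points
        discs.append(fit_valve_disc(pts, lm.apex, inward=(which == "mitral")))
    return discs


def transvalvular_flow(
    ds: FlowDataset, which: str, quad_step: float = None, order: int = 3
) -> np.ndarray:
    """Flow rate through the mitral or aortic valve disc, mL/s per frame.

    Velocity is sampled at disc quadrature points by spline interpolation
    (cubic by default: transvalvular jets are strongly curved across the
    orifice and linear interpolation systematically underestimates their
    flux; pass ``order=1`` for trilinear).  Signs follow the convention that
    mitral inflow and aortic outflow are positive in their own curves.
    """
    from scipy import ndimage

    step = quad_step if quad_step is not None else float(np.min(ds.spacing)) / 2.0
    discs = valve_disc_series(ds, which)
    flow = np.zeros(ds.n_frames)
    for k, disc in enumerate(discs):
        pts, wts = disc_quadrature(disc, step)
        idx = ds.index_from_world(pts)
        if order == 1:
            v = trilinear_sample(ds.velocity[k], idx)  # m/s
        else:
            v = np.stack(
                [ndimage.map_coordinates(ds.velocity[k, ..., c], idx.T, order=order,
                                         mode="nearest") for c in range(3)],
                axis=1,
            )
        # 1 m/s x 1 mm^2 = 1 mL/s
        flow[k] = float(np.sum((v @ disc.normal) * wts))
    return flow


# --------------------------------------------------------------------------
# phase detection


@dataclass
class PhaseMap:
    """Systole/diastole intervals and diastolic filling-wave structure.

    Times in seconds from cycle start (end-diastole).  ``a_peak`` is None
    when the E and A waves are merged into a single diastolic peak.
    """

    systole: tuple
    diastole: tuple
    aortic_valve_closure: float
    e_peak: Optional[float]
    a_peak: Optional[float]
    e_wave_window: Optional[tuple]
    a_wave_window: Optional[tuple]
    merged_ea: bool
    rr_interval: float


def _refine_peak_time(times: np.ndarray, values: np.ndarray, i: int) -> float:
    """3-point parabolic refinement of a sampled peak location."""
    if i <= 0 or i >= len(values) - 1:
        return float(times[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-30:
        return float(times[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    # assumes locally uniform sampling around the peak
    dt = 0.5 * (times[min(i + 1, len(times) - 1)] - times[max(i - 1, 0)])
    return float(times[i] + delta * dt)


def detect_phases(
    aortic_flow: np.ndarray,
    mitral_flow: np.ndarray,
    frame_times: np.ndarray,
    rr_interval: float,
    volume_series: np.ndarray = None,
) -> PhaseMap:
    """Locate aortic valve closure and the diastolic E/A structure.

    The curves must cover one full cycle starting at end-diastole.  Aortic
    valve closure is the downward zero crossing of the aortic flow after its
    systolic peak; if the aortic curve never crosses zero, the minimum of
    ``volume_series`` is used as a fallback (when provided).
    """
    qa = np.asarray(aortic_flow, dtype=float)
    qm = np.asarray(mitral_flow, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    rr = float(rr_interval)

    ipk = int(np.argmax(qa))
    if qa[ipk] <= 0:
        raise PhaseDetectionError("aortic flow curve has no positive systolic peak")

    t_avc = None
    for k in range(ipk, len(qa) - 1):
        if qa[k] > 0 >= qa[k + 1]:
            t_avc = t[k] + (t[k + 1] - t[k]) * qa[k] / (qa[k] - qa[k + 1])
            break
    if t_avc is None:
        if volume_series is not None:
            t_avc = float(t[int(np.argmin(volume_series))])
        else:
            raise PhaseDetectionError("no downward zero crossing of aortic flow found")
    t_avc = float(t_avc)

    # diastolic transmitral peaks
    dia = np.where(t > t_avc)[0]
    e_peak = a_peak = None
    e_win = a_win = None
    merged = True
    if dia.size >= 3:
        seg = qm[dia]
        prom = 0.05 * max(float(seg.max()), 1e-12)
        pk, _ = find_peaks(seg, prominence=prom)
        if pk.size == 0 and seg.max() > 0:
            pk = np.array([int(np.argmax(seg))])
        if pk.size >= 1:
            ie = dia[pk[0]]
            e_peak = _refine_peak_time(t, qm, ie)
        if pk.size >= 2:
            ia_ = dia[pk[-1]]
            valley = float(np.min(qm[dia[pk[0]] : dia[pk[-1]] + 1]))
            if valley < min(qm[ie], qm[ia_]):
                a_peak = _refine_peak_time(t, qm, ia_)
                merged = False
                i_valley = dia[pk[0]] + int(np.argmin(qm[dia[pk[0]] : dia[pk[-1]] + 1]))
                t_valley = float(t[i_valley])
                e_win = (t_avc, t_valley)
                a_win = (t_valley, rr)
        if merged and e_peak is not None:
            e_win = (t_avc, rr)

    return PhaseMap(
        systole=(0.0, t_avc),
        diastole=(t_avc, rr),
        aortic_valve_closure=t_avc,
        e_peak=e_peak,
        a_peak=a_peak,
        e_wave_window=e_win,
        a_wave_window=a_win,
        merged_ea=merged,
        rr_interval=rr,
    )


# --------------------------------------------------------------------------
# mask comparison


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice score coefficient 2|A n B| / (|A| + |B|) between binary masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise DataError("masks must share the same grid")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise DataError("Dice score undefined for two empty masks")
    return 2.0 * float(np.logical_and(a, b).sum()) / (sa + sb)
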