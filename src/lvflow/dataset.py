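"""Core data model for time-resolved three-directional velocity (4D flow) studies.

Internal unit conventions, used everywhere downstream:

* geometry in **mm** (voxel spacing, landmark coordinates, world positions),
* time in **s**,
* velocity in **m/s** (world-frame Cartesian components),
* derived quantities in SI (J, W, N, Pa).

The voxel grid uses voxel-center coordinates with 0-based indices.  A dataset
carries an ``origin`` (mm) and an orthonormal ``axes`` matrix (direction
cosines, columns = world directions of the grid axes), so that

    world = origin + axes @ (index * spacing)

Velocity vectors are stored as world-frame components.  This NIfTI-style
orientation convention lets a rigid rotation of a study be represented
exactly (rotate ``axes``, ``origin``, the velocity vectors and the landmarks)
without resampling, which is what makes the frame-equivariance guarantees of
the pipeline exact rather than approximate.

Time is cyclic with period ``rr_interval``: frame times live in
``[0, rr_interval)`` and the last frame wraps around to the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


@dataclass
class LandmarkSet:
    """Anatomical landmarks for one time frame, in world coordinates (mm).

    ``mitral_points`` / ``aortic_points`` are annulus points (>= 2 each);
    ``pm_tips`` / ``pm_bases`` hold the tip and base of each papillary
    muscle (2 points each).
    """

    apex: np.ndarray
    mitral_points: np.ndarray
    aortic_points: np.ndarray
    pm_tips: np.ndarray
    pm_bases: np.ndarray

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float).reshape(3)
        for name in ("mitral_points", "aortic_points", "pm_tips", "pm_bases"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"{name} must be an (n, 3) array")
            setattr(self, name, arr)
        if self.mitral_points.shape[0] < 2 or self.aortic_points.shape[0] < 2:
            raise ValidationError("annulus landmark sets need at least 2 points")
        if self.pm_tips.shape[0] != 2 or self.pm_bases.shape[0] != 2:
            raise ValidationError("expected exactly 2 papillary-muscle tips and bases")
        for name in ("apex", "mitral_points", "aortic_points", "pm_tips", "pm_bases"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"{name} contains non-finite coordinates")
        if np.linalg.norm(self.apex - self.mitral_points.mean(axis=0)) < 1e-9:
            raise ValidationError("apex coincides with the mitral-annulus centroid")

    @property
    def mitral_centroid(self) -> np.ndarray:
        return self.mitral_points.mean(axis=0)

    @property
    def aortic_centroid(self) -> np.ndarray:
        return self.aortic_points.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray = None) -> "LandmarkSet":
        """Return a rigidly transformed copy (rotation 3x3, translation mm)."""
        R = np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)

        def f(p):
            return p @ R.T + t

        return LandmarkSet(
            apex=f(self.apex),
            mitral_points=f(self.mitral_points),
            aortic_points=f(self.aortic_points),
            pm_tips=f(self.pm_tips),
            pm_bases=f(self.pm_bases),
        )


@dataclass
class FlowDataset:
    """One cardiac cycle of 4D flow data on a regular voxel grid.

    Attributes
    ----------
    velocity : (T, X, Y, Z, 3) float array, m/s, world-frame components.
    mask : (T, X, Y, Z) boolean LV blood-pool mask on the same grid.
    spacing : (3,) voxel edge lengths, mm.
    frame_times : (T,) seconds from cycle start, strictly increasing,
        first value 0, all below ``rr_interval``.
    rr_interval : cycle length, s.
    hematocrit : volume fraction in [0, 1].
    landmarks : one :class:`LandmarkSet` per frame.
    origin : world position of voxel (0,0,0), mm.
    axes : 3x3 orthonormal direction-cosine matrix (columns = grid axes).
    """

    velocity: np.ndarray
    mask: np.ndarray
    spacing: np.ndarray
    frame_times: np.ndarray
    rr_interval: float
    hematocrit: float
    landmarks: Sequence[LandmarkSet]
    origin: np.ndarray = None
    axes: np.ndarray = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.rr_interval = float(self.rr_interval)
        self.hematocrit = float(self.hematocrit)
        self.origin = np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.eye(3) if self.axes is None else np.asarray(self.axes, dtype=float).reshape(3, 3)
        self._validate()

    def _validate(self) -> None:
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValidationError("velocity must have shape (T, X, Y, Z, 3)")
        if self.mask.shape != self.velocity.shape[:4]:
            raise ValidationError(
                f"mask shape {self.mask.shape} disagrees with velocity grid "
                f"{self.velocity.shape[:4]}"
            )
        if np.any(self.spacing <= 0):
            raise ValidationError("spacing must be positive")
        T = self.velocity.shape[0]
        if self.frame_times.shape != (T,):
            raise ValidationError("frame_times length must equal the frame count")
        if T and abs(self.frame_times[0]) > 1e-12:
            raise ValidationError("first frame time must be 0")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if self.rr_interval <= 0 or np.any(self.frame_times >= self.rr_interval):
            raise ValidationError("frame_times must all be below rr_interval")
        if not 0.0 <= self.hematocrit <= 1.0:
            raise ValidationError("hematocrit must be a fraction in [0, 1]")
        empty = np.where(~self.mask.any(axis=(1, 2, 3)))[0]
        if empty.size:
            raise ValidationError(f"mask is empty at frame {empty[0]}")
        if len(self.landmarks) != T:
            raise ValidationError("need one LandmarkSet per frame")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValidationError("axes matrix must be orthonormal")

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.velocity.shape[1:4]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_volume_mm3 * 1e-9

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape (X, Y, Z, 3)."""
        nx, ny, nz = self.grid_shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).astype(float)
        return self.world_from_index(idx)

    def world_from_index(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return (index * self.spacing) @ self.axes.T + self.origin

    def index_from_world(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return ((world - self.origin) @ self.axes) / self.spacing

    def frame_weights(self, t: float) -> tuple:
        """Bracketing frames and interpolation weight for cyclic time ``t``.

        Returns ``(i0, i1, w)`` with the value at ``t`` given by
        ``(1 - w) * frame[i0] + w * frame[i1]``.
        """
        t = float(t) % self.rr_interval
        times = self.frame_times
        i0 = int(np.searchsorted(times, t, side="right") - 1)
        i1 = (i0 + 1) % self.n_frames
        t1 = times[i1] if i1 > i0 else self.rr_interval
        dt = t1 - times[i0]
        w = 0.0 if dt <= 0 else (t - times[i0]) / dt
        return i0, i1, w


def rotate_dataset(ds: FlowDataset, rotation: np.ndarray) -> FlowDataset:
    """Rigidly rotate a dataset about the world origin.

    The voxel data are untouched; the grid orientation, the origin, the
    velocity vector components and the landmarks are rotated, so the
    transformed dataset represents exactly the same physical flow expressed
    in a rotated world frame.
    """
    R = np.asarray(rotation, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
        raise ValidationError("rotation must be orthonormal")
    return replace(
        ds,
        velocity=ds.velocity @ R.T,
        origin=R @ ds.origin,
        axes=R @ ds.axes,
        landmarks=[lm.transformed(R) for lm in ds.landmarks],
    )


# -- interpolation --------------------------------------------------------


def trilinear_sample(field: np.ndarray, index_points: np.ndarray) -> np.ndarray:
    """Trilinearly sample ``field`` (X, Y, Z[, C]) at fractional indices.

    Points are clamped to the grid, so sampling just outside returns the
    nearest face value.  Returns shape (N[, C]).
    """
    pts = np.asarray(index_points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    shape = field.shape[:3]
    out_extra = field.shape[3:]

    clipped = np.clip(pts, 0.0, np.array(shape, dtype=float) - 1.0)
    i0 = np.floor(clipped).astype(np.intp)
    i0 = np.minimum(i0, np.array(shape, dtype=np.intp) - 2).clip(min=0)
    f = clipped - i0

    vals = np.zeros((pts.shape[0],) + out_extra, dtype=float)
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                w = wx * wy * wz
                corner = field[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                vals += (w.reshape((-1,) + (1,) * len(out_extra))) * corner
    return vals[0] if squeeze else vals
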