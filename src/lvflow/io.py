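"""Readers and writers for the formats the pipeline touches.

The reference interchange format is a single-file **HDF5 bundle** holding
velocity, mask, grid geometry, timing, hematocrit and per-frame landmarks.
For interoperability with imaging tools, a **NIfTI-1 series** (one volume
per frame per velocity component plus per-frame masks and a JSON sidecar)
and a **legacy-ASCII VTK structured-points series** are supported.  On-disk
units are declared in the metadata and converted at the I/O boundary to the
internal conventions (mm / s / m/s), whatever the files declare.

Naming convention of the NIfTI/VTK series (0-based frame index ``ttt``):

* ``vel_t{ttt}_{x|y|z}.nii`` - velocity component volumes,
* ``mask_t{ttt}.nii`` - binary mask,
* ``meta.json`` - frame times, RR interval, hematocrit, units, landmarks.

``write_results`` emits the per-frame time series as CSV, scalar summaries
as JSON, classified pathlines as VTK polydata, and a manifest with SHA-256
checksums of every file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .dataset import FlowDataset, LandmarkSet, ValidationError

_LENGTH_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "micron": 1e-3}
_VEL_TO_M_S = {"m/s": 1.0, "cm/s": 0.01, "mm/s": 0.001}
_LM_FIELDS = ("apex", "mitral_points", "aortic_points", "pm_tips", "pm_bases")


class FormatError(ValidationError):
    """File set does not match the documented on-disk convention."""


def _length_factor(unit: str) -> float:
    try:
        return _LENGTH_TO_MM[unit]
    except KeyError:
        raise FormatError(f"unknown length unit {unit!r}") from None


def _velocity_factor(unit: str) -> float:
    try:
        return _VEL_TO_M_S[unit]
    except KeyError:
        raise FormatError(f"unknown velocity unit {unit!r}") from None


def _landmarks_to_jsonable(lm: LandmarkSet) -> dict:
    return {f: np.asarray(getattr(lm, f)).tolist() for f in _LM_FIELDS}


def _landmarks_from_jsonable(d: dict, length_factor: float = 1.0) -> LandmarkSet:
    return LandmarkSet(**{f: np.asarray(d[f], dtype=float) * length_factor for f in _LM_FIELDS})


# --------------------------------------------------------------------------
# HDF5 bundle


def write_hdf5_bundle(ds: FlowDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=ds.velocity, compression="gzip", compression_opts=1)
        f.create_dataset("mask", data=ds.mask.astype(np.uint8), compression="gzip", compression_opts=1)
        f.attrs["spacing"] = ds.spacing
        f.attrs["frame_times"] = ds.frame_times
        f.attrs["rr_interval"] = ds.rr_interval
        f.attrs["hematocrit"] = ds.hematocrit
        f.attrs["origin"] = ds.origin
        f.attrs["axes"] = ds.axes
        f.attrs["length_units"] = "mm"
        f.attrs["velocity_units"] = "m/s"
        g = f.create_group("landmarks")
        for k, lm in enumerate(ds.landmarks):
            gk = g.create_group(f"frame_{k:04d}")
            for name in _LM_FIELDS:
                gk.create_dataset(name, data=np.asarray(getattr(lm, name)))


def read_hdf5_bundle(path) -> FlowDataset:
    with h5py.File(path, "r") as f:
        lf = _length_factor(str(f.attrs.get("length_units", "mm")))
        vf = _velocity_factor(str(f.attrs.get("velocity_units", "m/s")))
        velocity = np.asarray(f["velocity"]) * vf
        mask = np.asarray(f["mask"]).astype(bool)
        T = velocity.shape[0]
        lms = []
        for k in range(T):
            key = f"landmarks/frame_{k:04d}"
            if key not in f:
                raise FormatError(f"missing landmarks for frame {k}")
            gk = f[key]
            lms.append(
                LandmarkSet(**{n: np.asarray(gk[n]) * lf for n in _LM_FIELDS})
            )
        return FlowDataset(
            velocity=velocity,
            mask=mask,
            spacing=np.asarray(f.attrs["spacing"]) * lf,
            frame_times=np.asarray(f.attrs["frame_times"]),
            rr_interval=float(f.attrs["rr_interval"]),
            hematocrit=float(f.attrs["hematocrit"]),
            landmarks=lms,
            origin=np.asarray(f.attrs["origin"]) * lf,
            axes=np.asarray(f.attrs["axes"]),
        )


# --------------------------------------------------------------------------
# NIfTI series (nibabel)


def write_nifti_series(ds: FlowDataset, out_dir) -> None:
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    affine[:3, :3] = ds.axes @ np.diag(ds.spacing)
    affine[:3, 3] = ds.origin
    for k in range(ds.n_frames):
        for c, cname in enumerate("xyz"):
            img = nib.Nifti1Image(ds.velocity[k, ..., c].astype(np.float32), affine)
            img.header.set_xyzt_units(xyz="mm")
            nib.save(img, out / f"vel_t{k:03d}_{cname}.nii")
        img = nib.Nifti1Image(ds.mask[k].astype(np.uint8), affine)
        img.header.set_xyzt_units(xyz="mm")
        nib.save(img, out / f"mask_t{k:03d}.nii")
    meta = {
        "frame_times": ds.frame_times.tolist(),
        "rr_interval": ds.rr_interval,
        "hematocrit": ds.hematocrit,
        "velocity_units": "m/s",
        "landmark_length_units": "mm",
        "landmarks": [_landmarks_to_jsonable(lm) for lm in ds.landmarks],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def read_nifti_series(in_dir) -> FlowDataset:
    import nibabel as nib

    src = Path(in_dir)
    meta_path = src / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    T = len(meta["frame_times"])
    vf = _velocity_factor(meta.get("velocity_units", "m/s"))
    lmf = _length_factor(meta.get("landmark_length_units", "mm"))

    velocity = None
    mask = None
    spacing = origin = axes = None
    for k in range(T):
        vols = []
        for cname in "xyz":
            p = src / f"vel_t{k:03d}_{cname}.nii"
            if not p.exists():
                raise FormatError(f"missing velocity volume for frame {k} ({p.name})")
            img = nib.load(str(p))
            xyz_unit = img.header.get_xyzt_units()[0]
            lf = _length_factor(xyz_unit if xyz_unit != "unknown" else "mm")
            M = img.affine[:3, :3] * lf
            sp = np.linalg.norm(M, axis=0)
            ax = M / sp
            if spacing is None:
                spacing, axes, origin = sp, ax, img.affine[:3, 3] * lf
            elif not (np.allclose(sp, spacing) and np.allclose(ax, axes)):
                raise FormatError(f"inconsistent grid geometry at frame {k}")
            vols.append(np.asarray(img.dataobj, dtype=float))
        pm = src / f"mask_t{k:03d}.nii"
        if not pm.exists():
            raise FormatError(f"missing mask volume for frame {k} ({pm.name})")
        mvol = np.asarray(nib.load(str(pm)).dataobj) > 0.5
        if velocity is None:
            velocity = np.zeros((T,) + vols[0].shape + (3,))
            mask = np.zeros((T,) + vols[0].shape, dtype=bool)
        if vols[0].shape != velocity.shape[1:4] or mvol.shape != velocity.shape[1:4]:
            raise FormatError(f"grid shape changed at frame {k}")
        velocity[k] = np.stack(vols, axis=-1) * vf
        mask[k] = mvol

    lms = [_landmarks_from_jsonable(d, lmf) for d in meta["landmarks"]]
    return FlowDataset(
        velocity=velocity,
        mask=mask,
        spacing=spacing,
        frame_times=np.asarray(meta["frame_times"], dtype=float),
        rr_interval=float(meta["rr_interval"]),
        hematocrit=float(meta["hematocrit"]),
        landmarks=lms,
        origin=origin,
        axes=axes,
    )


# --------------------------------------------------------------------------
# legacy-ASCII VTK series (axis-aligned grids)


def _write_vtk_structured_points(path, spacing, origin, velocity, mask):
    nx, ny, nz = mask.shape
    n = nx * ny * nz
    # VTK structured points iterate x fastest
    v = np.transpose(velocity, (2, 1, 0, 3)).reshape(n, 3)
    m = np.transpose(mask.astype(np.uint8), (2, 1, 0)).reshape(n)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nlvflow velocity frame\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        f.write(f"SPACING {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}\n")
        f.write(f"POINT_DATA {n}\n")
        f.write("VECTORS velocity float\n")
        np.savetxt(f, v, fmt="%.7g")
        f.write("SCALARS mask unsigned_char\nLOOKUP_TABLE default\n")
        np.savetxt(f, m, fmt="%d")


def _read_vtk_structured_points(path):
    with open(path) as f:
        lines = f.read().split("\n")
    dims = spacing = origin = None
    i = 0
    data = {}
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(x) for x in tok[1:4])
        elif key == "SPACING":
            spacing = np.array([float(x) for x in tok[1:4]])
        elif key == "ORIGIN":
            origin = np.array([float(x) for x in tok[1:4]])
        elif key == "VECTORS":
            n = dims[0] * dims[1] * dims[2]
            flat = []
            i += 1
            while len(flat) < 3 * n:
                flat.extend(float(x) for x in lines[i].split())
                i += 1
            arr = np.array(flat).reshape(n, 3)
            data["velocity"] = np.transpose(
                arr.reshape(dims[2], dims[1], dims[0], 3), (2, 1, 0, 3)
            )
            continue
        elif key == "SCALARS":
            name = tok[1]
            n = dims[0] * dims[1] * dims[2]
            flat = []
            i += 2  # skip LOOKUP_TABLE
            while len(flat) < n:
                flat.extend(float(x) for x in lines[i].split())
                i += 1
            data[name] = np.transpose(np.array(flat).reshape(dims[2], dims[1], dims[0]), (2, 1, 0))
            continue
        i += 1
    if dims is None or "velocity" not in data:
        raise FormatError(f"{path}: not a structured-points velocity frame")
    return dims, spacing, origin, data


def write_vtk_series(ds: FlowDataset, out_dir) -> None:
    if not np.allclose(ds.axes, np.eye(3)):
        raise FormatError("VTK structured-points series supports axis-aligned grids only")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k in range(ds.n_frames):
        _write_vtk_structured_points(
            out / f"frame_t{k:03d}.vtk", ds.spacing, ds.origin, ds.velocity[k], ds.mask[k]
        )
    meta = {
        "frame_times": ds.frame_times.tolist(),
        "rr_interval": ds.rr_interval,
        "hematocrit": ds.hematocrit,
        "velocity_units": "m/s",
        "length_units": "mm",
        "landmarks": [_landmarks_to_jsonable(lm) for lm in ds.landmarks],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def read_vtk_series(in_dir) -> FlowDataset:
    src = Path(in_dir)
    meta_path = src / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    T = len(meta["frame_times"])
    lf = _length_factor(meta.get("length_units", "mm"))
    vf = _velocity_factor(meta.get("velocity_units", "m/s"))
    velocity = mask = None
    spacing = origin = None
    for k in range(T):
        p = src / f"frame_t{k:03d}.vtk"
        if not p.exists():
            raise FormatError(f"missing VTK frame {k} ({p.name})")
        dims, sp, org, data = _read_vtk_structured_points(p)
        if velocity is None:
            velocity = np.zeros((T,) + dims + (3,))
            mask = np.zeros((T,) + dims, dtype=bool)
            spacing, origin = sp * lf, org * lf
        elif dims != velocity.shape[1:4] or not np.allclose(sp * lf, spacing):
            raise FormatError(f"inconsistent grid at frame {k}")
        velocity[k] = data["velocity"] * vf
        mask[k] = data.get("mask", np.ones(dims)) > 0.5
    lms = [_landmarks_from_jsonable(d, lf) for d in meta["landmarks"]]
    return FlowDataset(
        velocity=velocity, mask=mask, spacing=spacing,
        frame_times=np.asarray(meta["frame_times"], dtype=float),
        rr_interval=float(meta["rr_interval"]),
        hematocrit=float(meta["hematocrit"]),
        landmarks=lms, origin=origin,
    )


# --------------------------------------------------------------------------
# dispatch


_READERS = {
    "hdf5_bundle": read_hdf5_bundle,
    "nifti_series": read_nifti_series,
    "vtk_series": read_vtk_series,
}
_WRITERS = {
    "hdf5_bundle": write_hdf5_bundle,
    "nifti_series": write_nifti_series,
    "vtk_series": write_vtk_series,
}


def read_flow_dataset(path, format: str) -> FlowDataset:
    """Read a validated :class:`FlowDataset`, converting units to mm / m/s."""
    if format not in _READERS:
        raise FormatError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    return _READERS[format](path)


def write_flow_dataset(ds: FlowDataset, path, format: str) -> None:
    if format not in _WRITERS:
        raise FormatError(f"unknown format {format!r}; choose from {sorted(_WRITERS)}")
    _WRITERS[format](ds, path)


# --------------------------------------------------------------------------
# result bundle export


def _write_vtk_polylines(path, polylines, labels=None):
    """Pathlines as legacy-ASCII VTK polydata; one scalar per line = class."""
    pts = []
    lines = []
    offset = 0
    for pl in polylines:
        pl = np.asarray(pl)
        pts.append(pl)
        lines.append(list(range(offset, offset + len(pl))))
        offset += len(pl)
    allpts = np.concatenate(pts) if pts else np.zeros((0, 3))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nlvflow pathlines\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(allpts)} float\n")
        np.savetxt(f, allpts, fmt="%.6g")
        total = sum(len(l) + 1 for l in lines)
        f.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            f.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        if labels is not None:
            f.write(f"CELL_DATA {len(lines)}\n")
            f.write("SCALARS flow_component int\nLOOKUP_TABLE default\n")
            for lab in labels:
                f.write(f"{lab}\n")


_CLASS_CODES = {"df": 1, "ri": 2, "de": 3, "rv": 4, "unclassified": 0}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(bundle, out_dir) -> dict:
    """Write CSV time series, JSON summary and pathline geometry; return manifest.

    The manifest maps each written file name to its SHA-256 checksum, so a
    re-run with the same seed and config can be verified byte-for-byte.
    """
    import pandas as pd

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out} not writable: {e}") from e

    en = bundle.energetics
    cols = {
        "time_s": en.times,
        "volume_ml": bundle.volumes_ml,
        "aortic_flow_ml_s": bundle.aortic_flow,
        "mitral_flow_ml_s": bundle.mitral_flow,
        "ke_v_global_j_per_l": en.ke_v,
        "el_rate_global_w": en.el_rate,
    }
    for name in ("basal", "mid", "apical"):
        cols[f"ke_v_{name}_j_per_l"] = en.ke_v_regional[name]
        cols[f"el_rate_{name}_w"] = en.el_rate_regional[name]
    for c, cname in enumerate(("basal_apical", "septal_lateral", "inferior_anterior")):
        cols[f"hdf_v_{cname}_n_per_l"] = bundle.hdf.hdf_v[:, c]
    df = pd.DataFrame(cols)
    ts_path = out / "timeseries.csv"
    df.to_csv(ts_path, index=False, float_format="%.10g")

    summary = {
        "metrics": bundle.flat_metrics(),
        "phases": {
            "systole": bundle.phases.systole,
            "diastole": bundle.phases.diastole,
            "aortic_valve_closure_s": bundle.phases.aortic_valve_closure,
            "e_peak_s": bundle.phases.e_peak,
            "a_peak_s": bundle.phases.a_peak,
            "merged_ea": bundle.phases.merged_ea,
        },
        "hdf_rms_n_per_l": bundle.hdf.rms,
        "r_rms": bundle.hdf.r_rms,
        "filling_impulse_ns_per_l": bundle.hdf.impulse_ba,
        "el_v_j_per_l": en.el_v,
        "ke_v_peaks": en.peaks,
        "provenance": bundle.provenance,
    }
    if bundle.components is not None:
        summary["flow_components_pct_edv"] = {
            "df": bundle.components.df,
            "ri": bundle.components.ri,
            "de": bundle.components.de,
            "rv": bundle.components.rv,
            "unclassified": bundle.components.unclassified,
            "quality_flag": bundle.components.quality_flag,
        }
    sm_path = out / "summary.json"
    sm_path.write_text(json.dumps(_jsonable(summary), indent=1, sort_keys=True))

    written = [ts_path, sm_path]

    details = getattr(bundle, "pathline_details", None)
    if details is not None and details.get("forward") is not None:
        fwd = details["forward"]
        if fwd.positions:
            snaps = np.stack(fwd.positions)  # (n_snap, n_seeds, 3)
            n_seeds = snaps.shape[1]
            keep = np.linspace(0, n_seeds - 1, min(500, n_seeds)).astype(int)
            polylines = [snaps[:, j, :] for j in keep]
            labels = [_CLASS_CODES[details["labels"][j]] for j in keep]
            pl_path = out / "pathlines.vtk"
            _write_vtk_polylines(pl_path, polylines, labels)
            written.append(pl_path)

    manifest = {}
    for p in written:
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
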