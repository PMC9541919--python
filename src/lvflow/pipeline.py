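"""End-to-end analysis pipeline and cohort-style descriptive comparison.

``run_analysis`` executes geometry -> rheology -> energetics -> hemodynamic
force -> flow components on one dataset and returns a :class:`ResultBundle`
with full provenance (config snapshot, package version, dataset checksum).
``compare_groups`` reduces bundles to per-metric group means/SDs and percent
differences against a reference group; inferential statistics are left to
dedicated tools on the exported tables.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .components import ComponentFractions, classify_components
from .dataset import FlowDataset, ValidationError
from .energetics import (
    EnergeticsSeries,
    kinetic_energy,
    normalize_and_summarize,
    viscous_loss_rate,
)
from .geometry import (
    REGION_NAMES,
    PhaseMap,
    build_frame,
    detect_phases,
    lv_volume_series,
    subdivide_regions,
    transvalvular_flow,
)
from .hdforce import HDFSeries, compute_hdf_series
from .rheology import RheologyParams, shear_rate, velocity_gradient, viscosity

logger = logging.getLogger("lvflow")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the dataset itself."""

    rheology: RheologyParams = field(default_factory=RheologyParams)
    fixed_regions_at_ed: bool = False
    include_viscous_term: bool = True
    hdf_sign_flip: bool = False
    el_v_mode: str = "phase_mean"
    trace_step_voxels: float = 0.5
    trace_dilation: int = 2
    trace_components: bool = True
    record_pathlines: bool = False
    quad_step: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.el_v_mode not in ("phase_mean", "per_frame"):
            raise ValidationError("el_v_mode must be 'phase_mean' or 'per_frame'")
        if not 0 < self.trace_step_voxels <= 1.0:
            raise ValidationError("trace_step_voxels must be in (0, 1]")
        if self.trace_dilation < 0:
            raise ValidationError("trace_dilation must be >= 0")


@dataclass
class ResultBundle:
    """Complete analysis output for one dataset."""

    energetics: EnergeticsSeries
    hdf: HDFSeries
    components: Optional[ComponentFractions]
    phases: PhaseMap
    volumes_ml: np.ndarray
    regional_volumes_ml: dict
    aortic_flow: np.ndarray
    mitral_flow: np.ndarray
    provenance: dict
    pathline_details: Optional[dict] = None

    def flat_metrics(self) -> dict:
        """Scalar summary metrics for reporting and group comparison."""
        m = {}
        vols = np.asarray(self.volumes_ml, dtype=float)
        m["edv_ml"] = float(vols.max())
        m["esv_ml"] = float(vols.min())
        m["sv_ml"] = m["edv_ml"] - m["esv_ml"]
        m["ef_pct"] = 100.0 * m["sv_ml"] / m["edv_ml"]
        pk = self.energetics.peaks
        if pk.get("systole") and pk["systole"]["global"]:
            m["ke_v_peak_systole_j_per_l"] = pk["systole"]["global"][0]
        if pk.get("e_wave") and pk["e_wave"]["global"]:
            m["ke_v_peak_e_wave_j_per_l"] = pk["e_wave"]["global"][0]
        if pk.get("a_wave") and pk["a_wave"]["global"]:
            m["ke_v_peak_a_wave_j_per_l"] = pk["a_wave"]["global"][0]
        for phase in ("systole", "diastole"):
            m[f"ke_v_mean_{phase}_j_per_l"] = self.energetics.phase_means[phase]["global"]
            m[f"el_v_{phase}_j_per_l"] = self.energetics.el_v[phase]["global"]
            m[f"r_rms_{phase}"] = self.hdf.r_rms[phase]
        if self.hdf.impulse_defined:
            m["filling_impulse_ns_per_l"] = self.hdf.impulse_ba
            m["filling_impulse_magnitude_ns_per_l"] = abs(self.hdf.impulse_ba)
        if self.components is not None:
            m["df_pct"] = self.components.df
            m["ri_pct"] = self.components.ri
            m["de_pct"] = self.components.de
            m["rv_pct"] = self.components.rv
        return m


def _dataset_checksum(ds: FlowDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(ds.velocity).tobytes())
    h.update(np.ascontiguousarray(ds.mask).tobytes())
    h.update(np.ascontiguousarray(ds.frame_times).tobytes())
    return h.hexdigest()


def run_analysis(ds: FlowDataset, config: PipelineConfig = None) -> ResultBundle:
    """Run the full fluid-dynamics analysis on one dataset."""
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t_wall = time.perf_counter()

    def stage(name):
        logger.info("stage %-16s %6.2f s", name, time.perf_counter() - t_wall)

    # geometry
    labels = subdivide_regions(
        ds.mask, ds.landmarks, ds.spacing, ds.origin, ds.axes,
        fixed_at_ed=config.fixed_regions_at_ed,
    )
    volumes, regional_volumes = lv_volume_series(ds.mask, ds.spacing, labels)
    aortic = transvalvular_flow(ds, "aortic", quad_step=config.quad_step)
    mitral = transvalvular_flow(ds, "mitral", quad_step=config.quad_step)
    phases = detect_phases(aortic, mitral, ds.frame_times, ds.rr_interval, volumes)
    frames = [build_frame(lm) for lm in ds.landmarks]
    stage("geometry")

    # rheology + per-frame energies (gradients computed once, reused by HDF)
    T = ds.n_frames
    rho = config.rheology.density
    ke = np.zeros(T)
    el = np.zeros(T)
    ke_reg = {name: np.zeros(T) for name in REGION_NAMES}
    el_reg = {name: np.zeros(T) for name in REGION_NAMES}
    gradients = []
    mu_fields = []
    for k in range(T):
        L = velocity_gradient(ds.velocity[k], ds.mask[k], ds.spacing, ds.axes)
        gradients.append(L)
        mu = viscosity(shear_rate(L), ds.hematocrit, config.rheology)
        mu_fields.append(mu)
        ke[k], reg = kinetic_energy(ds.velocity[k], ds.mask[k], rho, ds.spacing, labels[k])
        for name in REGION_NAMES:
            ke_reg[name][k] = reg[name]
        el[k], reg = viscous_loss_rate(
            ds.velocity[k], ds.mask[k], mu, ds.spacing, labels[k], ds.axes, gradient=L
        )
        for name in REGION_NAMES:
            el_reg[name][k] = reg[name]
    stage("rheology+energy")

    energetics = normalize_and_summarize(
        ds.frame_times, ds.rr_interval, ke, ke_reg, el, el_reg,
        volumes, regional_volumes, phases, el_v_mode=config.el_v_mode,
    )

    hdf = compute_hdf_series(
        ds, frames, volumes, mu_fields, rho, phases,
        include_viscous=config.include_viscous_term,
        sign_flip=config.hdf_sign_flip,
        gradients=gradients,
    )
    stage("hdf")

    components = None
    details = None
    if config.trace_components:
        components, details = classify_components(
            ds, phases,
            step_voxels=config.trace_step_voxels,
            dilation=config.trace_dilation,
            record_every=8 if config.record_pathlines else 0,
        )
        if components.quality_flag:
            logger.warning("flow components: %s", components.quality_flag)
        stage("components")

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "dataset_checksum": _dataset_checksum(ds),
    }
    return ResultBundle(
        energetics=energetics,
        hdf=hdf,
        components=components,
        phases=phases,
        volumes_ml=volumes,
        regional_volumes_ml=regional_volumes,
        aortic_flow=aortic,
        mitral_flow=mitral,
        provenance=provenance,
        pathline_details=details,
    )


def compare_groups(groups: dict, reference: str = None) -> pd.DataFrame:
    """Descriptive per-metric comparison of result bundles by group.

    ``groups`` maps a label to a list of :class:`ResultBundle` (or already
    flattened metric dicts).  Returns a tidy table with one row per
    (metric, group): mean, SD (NaN for single-bundle groups) and percent
    difference of the mean vs. the reference group (first key by default).
    """
    if not groups:
        raise ValidationError("no groups given")
    flat = {}
    for label, bundles in groups.items():
        if not bundles:
            raise ValidationError(f"group {label!r} is empty")
        flat[label] = [
            b.flat_metrics() if isinstance(b, ResultBundle) else dict(b) for b in bundles
        ]
    reference = reference or next(iter(flat))
    if reference not in flat:
        raise ValidationError(f"reference group {reference!r} not found")

    metrics = sorted({k for lst in flat.values() for d in lst for k in d})
    ref_means = {
        met: np.mean([d[met] for d in flat[reference] if met in d])
        if any(met in d for d in flat[reference]) else np.nan
        for met in metrics
    }
    rows = []
    for met in metrics:
        for label, dicts in flat.items():
            vals = np.array([d[met] for d in dicts if met in d], dtype=float)
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            ref = ref_means[met]
            pct = 100.0 * (mean - ref) / abs(ref) if np.isfinite(ref) and ref != 0 else np.nan
            rows.append(
                {"metric": met, "group": label, "n": vals.size, "mean": mean,
                 "sd": sd, "pct_diff_vs_ref": pct}
            )
    return pd.DataFrame(rows)
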