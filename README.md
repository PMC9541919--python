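# lvflow

Left-ventricular fluid-dynamics analysis for 4D flow MRI: pathline-based
flow-component subdivision, volume-normalized intraventricular energetics,
and Navier–Stokes-derived hemodynamic forces, with a synthetic phantom
suite that makes every stage testable against known ground truth.

## Who this is for

Time-resolved three-directional velocity-encoded (4D flow) MRI measures the
blood velocity field inside the left ventricle (LV) across the cardiac
cycle. Post-processing that field yields quantitative markers of how well
the chamber moves blood — markers that are sensitive to systolic and
diastolic dysfunction before conventional indices change. `lvflow` is a
research implementation of that post-processing chain for people who have
(or simulate) velocity volumes, a dynamic LV segmentation, and anatomical
landmarks, and want reproducible numbers rather than a vendor black box.

## What it computes

Given velocity `v(x, t)`, a binary LV mask, voxel spacing, frame times and
per-frame landmarks (apex, mitral/aortic annulus points, papillary-muscle
tips and bases):

- **Flow components** — every end-diastolic blood voxel seeds a pathline
  (RK4, trilinear/linear space–time interpolation) traced backward through
  diastole and forward through systole. Transit through the mitral and
  aortic valve discs classifies the pool into **direct flow** (enters and
  leaves in the same beat), **retained inflow**, **delayed ejection** and
  **residual volume**, each as % of end-diastolic volume.
- **Kinetic energy** — `KE = Σ ½ ρ V_voxel |v|²` over the mask
  (ρ = 1025 kg/m³), globally and per basal/mid/apical region (slabs cut at
  the papillary tip and base planes), normalized to the current cavity or
  regional volume: `KE_V` in J/L.
- **Viscous energy loss** — the bulk dissipation `Φ = 2 μ (S : S)` of a
  generalized-Newtonian fluid, with `S` the strain-rate tensor from masked
  finite differences and `μ(γ̇, hct)` a Carreau–Yasuda law scaled by the
  subject's hematocrit; phase-integrated and volume-normalized: `EL_V` in
  J/L.
- **Hemodynamic force (HDF)** — the pressure gradient from the momentum
  balance `b = −ρ(∂v/∂t + (v·∇)v) + ∇·(2μS)`, integrated over the cavity
  and projected on the anatomical basal–apical / septal–lateral /
  inferior–anterior triad (N and N/L). Summaries: per-phase RMS of each
  component, the alignment ratio
  `R_RMS = √(RMS_sl² + RMS_ia²) / RMS_ba`, and the **early-diastolic
  filling impulse**: the time integral of the volume-normalized
  basal–apical component from aortic valve closure to its next zero
  crossing (Ns/L).
- **Cardiac phases** — aortic valve closure from the downward zero crossing
  of the aortic flow curve; E- and A-wave peaks (or their merging) from the
  transmitral curve; both curves from disc-quadrature flux through the
  landmark-fitted valve planes.

The synthetic module generates analytic fields with closed-form answers
(uniform, rigid rotation, Poiseuille, uniform acceleration) and a
contracting-ellipsoid LV phantom whose wall-consistent interior flow,
biphasic filling, landmark tracks and volume curve are prescribed — so
ejection fraction, stroke volume, E/A ratio, valve timing, dissipation and
forces can all be checked against truth.

## Worked example

Simulate the default phantom (EDV 150 mL, EF 0.60, 70 bpm, E/A 2.0,
32×32×48 voxels at 2.5 mm, 30 frames) and analyze it:

```bash
lvflow simulate --out phantom.h5
lvflow analyze --input phantom.h5 --out results
lvflow report --results results
```

```
lvflow analysis summary
========================
EDV [mL]                              149.5
ESV [mL]                              59.88
SV [mL]                               89.62
EF [%]                                59.95
KE_V systolic peak [J/L]             0.1475
KE_V E-wave peak [J/L]              0.08275
KE_V A-wave peak [J/L]             0.009443
EL_V systole [J/L]                 0.007184
EL_V diastole [J/L]                0.002846
R_RMS systole [-]                   0.09011
R_RMS diastole [-]                   0.1575
filling impulse [Ns/L]             -0.05148
direct flow [% EDV]                    52.3
retained inflow [% EDV]                5.56
delayed ejection [% EDV]              5.539
residual volume [% EDV]               32.07
aortic valve closure [s]             0.3143
```

Reading the numbers: the rasterized cavity recovers the prescribed EF
(59.95 vs 60%) and the prescribed valve-closure time (0.314 s measured vs
0.300 s truth, within half a frame at 28.6 ms temporal resolution). The
force stays strongly aligned with the long axis (R_RMS ≪ 1), as expected
for an organized base–apex flow; the negative filling impulse is the
base-ward deceleration load of early filling. Direct flow plus delayed
ejection (57.8%) tracks the ejection fraction, the volume bookkeeping the
pathline classification must satisfy.

The same pipeline is available as a library:

```python
import lvflow as lv

ds, truth = lv.make_ellipsoid_lv(lv.EllipsoidLVSpec(ef=0.30))  # impaired LV
bundle = lv.run_analysis(ds, lv.PipelineConfig())
print(bundle.flat_metrics()["df_pct"], bundle.hdf.r_rms["systole"])
```

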