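# Methods

This note documents the models implemented in `lvflow`, the choices made
where the problem is genuinely underdetermined, the design of the synthetic
ground-truth phantoms, and what the test suite does and does not establish
about real 4D flow data.

## Data model and conventions

A study is one cardiac cycle of three-component velocity volumes
`(T, X, Y, Z, 3)` with a binary LV mask on the same grid, voxel spacing,
frame times, the RR interval, the subject's hematocrit and per-frame
anatomical landmarks. Internal units are fixed: mm for geometry, s for
time, m/s for velocity, SI for everything derived; all unit conversion
happens at the I/O boundary, whatever the files declare (mm/cm/m, m/s /
cm/s).

The grid uses voxel-center coordinates, 0-based indices, and an explicit
orientation: `world = origin + axes @ (index · spacing)` with `axes` an
orthonormal direction-cosine matrix (NIfTI-style). Velocity vectors are
stored as world components. Because orientation is explicit, a rigid
rotation of a study is represented exactly — no resampling — which is why
the pipeline's rotation invariance holds to machine precision and is tested
at 1e-6 rather than at some interpolation-limited tolerance.

Time is cyclic with period RR (retrospectively gated data are periodic by
construction): temporal derivatives and time integrals wrap the last frame
to the first.

## Anatomical frame, regions, valve planes, phases

- **Triad**: basal–apical = unit vector from the mitral-annulus centroid to
  the apex; septal–lateral = the direction toward the aortic-annulus
  centroid orthogonalized against it (a 3D reformulation of the
  HLA/LVOT-view construction — the aortic centroid pins the LVOT plane);
  inferior–anterior completes the right-handed triad. The septal–lateral
  sign points from the mitral centroid toward the aortic side; flipping it
  changes only the sign of that component, never RMS values or `R_RMS`.
- **Regions**: two planes perpendicular to the basal–apical axis through
  the mean papillary tip and mean papillary base positions cut the cavity
  into basal / mid / apical slabs; every in-mask voxel gets exactly one
  label, so regional energies sum to the global value identically. The
  planes follow the landmarks frame by frame by default
  (`fixed_regions_at_ed=True` freezes them at end-diastole; the underlying
  acquisition protocol does not dictate either choice).
- **Valve discs**: centroid + SVD plane fit of the annulus points, radius =
  mean point distance from the centroid. Flux is a polar-quadrature
  integral of `v · n` over the disc with **cubic B-spline** velocity
  sampling: transvalvular jets are strongly curved across the orifice and
  linear interpolation biases their flux low (≈4% vs ≈2% peak-flow error at
  2.5 mm on the phantom); `order=1` restores trilinear sampling.
- **Phases**: systole runs from cycle start (end-diastole) to aortic valve
  closure, the downward zero crossing of the aortic flow after its peak,
  located sub-frame by linear interpolation (at 20–30 phases per cycle a
  frame is 25–45 ms, too coarse for the impulse integral otherwise). When
  the aortic curve never crosses zero the minimum of the volume curve is
  the fallback. E- and A-wave peaks are prominence-filtered local maxima of
  the transmitral curve in diastole; a single-peak inflow is flagged
  *merged* and the A-wave quantities are reported as absent.

## Rheology

Blood: incompressible, ρ = 1025 kg/m³, shear-thinning. The velocity
gradient uses central differences inside the mask and one-sided
(second-order 3-point where two inward neighbours exist, first-order
otherwise) differences at the wall; voxels with no in-mask neighbour along
an axis are flagged low-confidence and get a zero derivative rather than an
error. Shear rate is `γ̇ = √(2 S:S)` — the normalization that returns
`|k|` for simple shear `v_x = k·y` and under which a Newtonian fluid
dissipates `μ γ̇²`; conventions differing by √2 exist, hence the explicit
statement.

Viscosity is a Carreau–Yasuda law
`μ = μ∞ + (μ0 − μ∞)[1 + (λγ̇)^a]^((n−1)/a)` with the standard whole-blood
constants μ0 = 56 mPa·s, μ∞ = 3.45 mPa·s, λ = 3.313 s, n = 0.3568, a = 2,
and both asymptotes scaled by `exp(k·(hct − 0.45))`, k = 2.5 — the
leading-order exponential dependence of whole-blood viscosity on red-cell
volume fraction. **These constants are a modeling choice**: the μ(hct, γ̇)
dependence is part of the contract, its exact published parameterization is
not, so everything is config-overridable and a Newtonian model
(μ = 3.5 mPa·s) backs all analytic oracles.

## Energetics

`KE = Σ ½ ρ V_voxel |v|²`; dissipation rate `Σ 2 μ (S:S) V_voxel`. This is
*bulk* dissipation only: the boundary layer at the endocardium is far below
voxel resolution and deliberately not modelled, so EL values are a lower
bound on true viscous loss. `KE_V(t) = KE(t)/V(t)` with the instantaneous
(regional) volume. Phase-level `EL_V` divides the phase time-integral of
the rate by the **phase-mean volume**; a normalize-every-frame-then-
integrate variant is available (`el_v_mode="per_frame"`) — the two differ
only when the volume changes a lot within a phase. All time integrals are
trapezoidal on the (possibly non-uniform) frame times with cyclic closure.
Peak detection takes the largest sample inside the phase window, no
smoothing.

One deliberate deviation from naive expectation, confirmed by the phantom:
the **KE_V** E-wave peak leads the transmitral flow peak by about one frame
because the normalizing volume grows during filling (at the KE maximum
`d(KE/V)/dt = −KE·V̇/V² < 0`); the unnormalized KE peak coincides with the
flow peak to within half a frame.

## Hemodynamic force

`b = −ρ(∂v/∂t + (v·∇)v) + ∇·(2μS)` per in-mask voxel (Pa/m), cyclic
central temporal differences, the masked spatial operators above. The
viscous term is implemented for spatially varying μ (it reduces to `μ∇²v`
for uniform μ) and contributes negligibly at 4D-flow resolution; a toggle
drops it to mimic the common inviscid HDF estimators. Near-wall voxels keep
their one-sided derivatives rather than being eroded away.

HDF = `Σ b V_voxel`, projected on the triad; volume-normalized components
in N/L. Sign convention: the **pressure-gradient integral** is reported
(positive basal–apical = toward the apex); the action–reaction reading (net
momentum transferred from wall to blood) is the global sign flip exposed as
`hdf_sign_flip`.

RMS values are time-weighted over the cycle and over each phase;
`R_RMS = √(RMS_sl² + RMS_ia²)/RMS_ba` is computed per phase (whole-cycle
RMS is also reported). The root-of-summed-squares combination of the two
transversal components is the adopted reconstruction of the
transversal-vs-longitudinal ratio; it is stated here because published
usage does not fix the formula. The early-diastolic filling impulse
integrates the volume-normalized basal–apical component from aortic valve
closure to its next zero crossing, both endpoints sub-frame; it is flagged
undefined when the component never crosses zero in diastole.

## Flow components

Seeds are all in-mask voxel centres at end-diastole (equal volumes), traced
**backward over diastole** (mitral entry?) and **forward over systole**
(aortic exit?) with RK4, trilinear spatial and linear cyclic temporal
interpolation, and adaptive sub-steps bounded by half a voxel of
displacement. Entry ∧ exit → direct flow; entry only → retained inflow;
exit only → delayed ejection; neither → residual volume. This single-cycle
bidirectional scheme realizes the "resides at least two cycles" reading of
residual volume under periodicity. Crossings are segment–disc
intersections against the time-interpolated valve discs (radius tolerance
1.05); a seed starting exactly on a disc plane counts as crossing only when
it moves away from the ventricular side. Velocity is zero outside the mask
dilated by 2 voxels — the margin lets pathlines actually pass through discs
that sit on the mask boundary, the zero field beyond makes the wall a
stalling boundary. Seeds whose trace leaves the mask away from a disc are
reported *unclassified* (never silently assigned); above 10% a quality flag
is raised. On the default phantom ≈4–5% of seeds are unclassified, almost
all near-wall voxels stranded by interpolation against the contracting
wall.

## Synthetic ground truth

**Analytic fields.** Uniform flow, rigid rotation, Poiseuille flow and a
spatially uniform velocity ramp carry closed-form truths (zero dissipation,
zero force, `−4μv_max/R²`, `−ρa`, `2πμv_max²` per unit length…). Each
closed form is re-verified inside the test suite by an independent
brute-force evaluation (dense finite differences / dense quadrature) before
the rest of the suite uses it as an oracle. Convergence under grid
refinement is measured with the tube axis at a generic off-lattice position:
a perfectly lattice-aligned circle is a degenerate configuration whose
rasterization error repeats instead of shrinking between some resolution
pairs.

**Contracting-ellipsoid LV phantom.** A prolate spheroid truncated at half
its long semi-axis (fixed long axis, short axes breathing with volume).
The volume curve is a half-cosine ejection over `systole_fraction` of the
cycle followed by two raised-cosine filling waves with prescribed E/A
peak-flow ratio and total volume = stroke volume (single merged wave
optional). The interior velocity comes from a Stokes stream function whose
value at each cross-section equals the instantaneous flux demanded by the
volume change below it — wall-kinematics-consistent by construction — with
a smoothstep "funnel" that steers the flow into the active orifice (aortic
disc while ejecting, mitral while filling) so transvalvular flux equals
∓dV/dt exactly in the continuum. The field is evaluated slightly beyond
the wall (2 voxels) so near-wall interpolation and wall-hugging pathlines
stay consistent with the contraction, and the orifice jets continue a few
voxels past the base plane so disc fluxes and crossings are well defined.
Landmarks (apex, annulus rings, papillary tips at 40% and bases at 65% of
the base–apex distance) track the deformation.

Defaults are the study conditions: EDV 150 mL, EF 0.60, 70 bpm, systole
35% of the cycle, E/A = 2.0, hematocrit 0.42, 32×32×48 voxels at 2.5 mm
isotropic, 30 frames — a typical healthy adult imaged with a typical 4D
flow reconstruction. Velocity noise is off by default (the phantom's role
is verification against truth); seeded isotropic Gaussian noise is
available. Two disease-like knob settings are used in the qualitative
tests: reduced EF at constant EDV (systolic impairment), and a shorter,
sharper E-wave (restrictive filling). The tilt of the funnel toward the
offset orifices makes the phantom non-axisymmetric; an `axisymmetric`
option centres a single orifice for force-alignment oracles.

**Transit tube.** A static cylinder with plug flow that flushes the whole
pool in through one end-disc each diastole and out the other each systole —
the pure-direct-flow limiting case (and, with zero velocity, the pure
residual-volume case).

What the phantoms do **not** emulate: MR signal formation, velocity noise
correlations and background phase errors, partial-volume effects at the
wall, valve leaflets, intracavitary vortex rings, trabeculation, or
through-plane motion of the base. Passing tests therefore establish the
correctness and convergence of the numerics on smooth, flux-consistent
fields — not the clinical accuracy of the markers on real acquisitions.

## Numerical choices and degenerate inputs

- Derivatives: central / 3-point one-sided / 2-point one-sided, in that
  order of availability; thin-mask voxels flagged, not fatal.
- Sub-frame event times (valve closure, impulse endpoints) by linear
  interpolation of the sampled curves.
- Peak times optionally refined by a 3-point parabola (used for event
  reporting, not for peak values).
- Pathline sub-step: `Δt = 0.5·min(spacing)/v_max`, capped at one frame
  interval; deterministic (no randomness anywhere in seeding or tracing).
- Degenerate geometry raises typed errors: collinear landmarks, papillary
  planes out of order, annulus points without a plane, two empty masks in a
  Dice comparison, zero basal–apical RMS in `R_RMS`.
- Problem sizes in the shipped tests: the full-resolution phantom
  (32×32×48×30) for parameter recovery, bookkeeping and robustness
  batches; a 24×24×36×20 phantom at 3 mm for equivariance and refinement
  stability — sizes chosen to exercise the same code paths at desk scale.

## Known limitations

- EL omits boundary-layer dissipation (inherent to voxel-scale velocimetry).
- The Carreau–Yasuda constants and the hematocrit scaling are literature
  defaults, not a fitted published parameterization.
- The temporal derivative assumes a periodic cycle; non-gated or
  arrhythmic data violate that silently.
- Pathline classification near the wall depends on the mask's moving
  boundary; the unclassified fraction is the honest reporting of that
  uncertainty rather than a reclassification heuristic.
- The VTK reader/writer covers the legacy-ASCII structured-points and
  polydata subsets only, and axis-aligned grids only.
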