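# Methods

This package analyzes the mechanics of the left ventricle (LV) over one
cardiac cycle from two complementary angles: tissue deformation, via the
eigen-structure of the surface Lagrangian strain tensor, and intraventricular
flow, via boundary-data hemodynamic forces, mean vorticity and vortex
formation time. Because clinical exercise-echocardiography geometries are not
publicly available, a synthetic ventricle generator supplies mesh sequences
with analytic ground truth at the published study conditions, and every
numerical kernel is validated against closed-form oracles.

## Input model

A cycle is a closed triangulated surface with fixed connectivity and
per-frame vertex positions; each vertex is a material point. Frames span
`[0, T)` with `T` the heartbeat period. Coordinates are in mm, volumes in mL,
times in s; conversions happen only at I/O boundaries. A quality-control flag
is raised below 10 frames per cycle, the floor at which wall-motion analysis
remains reliable in exercise echo (acquired frame counts drop from ~32 at
rest to ~11 at peak exercise because speckle tracking fails at high wall
speeds).

Volumes are signed divergence-theorem integrals of the closed surface.
Registration places each sequence in an anatomical frame at end diastole
(ED = maximum volume): area-weighted surface centroid at the origin, long
axis (mitral-annulus center to apex) along −z so the apex points down, roll
fixed so the aortic-orifice center lies on the +x half-plane. Cohort
averaging is vertex-wise after periodic cubic-spline resampling to a common
number of phase points; the common clock is the phase fraction t/T since
heart rate differs across exercise phases.

## Synthetic ventricle generator

Geometry: a half prolate spheroid (long-axis/radius ratio 2.0), closed by a
triangle fan across the mitral annulus; the aortic orifice is the set of cap
triangles inside a circle of radius 0.35 R offset to (0.45 R, 0) on the base
plane. The default mesh (24 rings × 48 sectors, 2304 triangles) reproduces
the analytic enclosed volume to ≈0.4%, converging quadratically under
refinement; ratios such as the ejection fraction cancel the discretization
bias almost entirely.

Volume waveform `V(t)`: half-cosine systolic ejection from EDV to ESV over
`systolic_fraction · T`, then diastolic filling whose dV/dt is a sum of two
Hann bumps — the E wave starting at end systole and the A wave ending at T —
with peak ratio equal to the prescribed E/A. The flat diastasis between them
occupies the remaining 25% of diastole, so it shrinks in absolute terms as
heart rate rises and the waves visually merge, as seen clinically.

Deformation is an axisymmetric material map applied to the ED vertices:
radial/circumferential scaling `λ_C = g^{(1−s)/2}`, longitudinal scaling
`λ_L = g^{s}` with `g = V(t)/EDV` and `s = long_circ_split` (default 0.27,
giving resting GLS ≈ −20% and GCS ≈ −27%), plus a torsion linear in the
apex–base material coordinate (default 12° apical twist, scaled by the
contraction phase). Because scaling is linear and torsion is
volume-preserving, the mesh volume tracks `V(t)` exactly. A transient
`activation_lead` term (default 1.5) raises the longitudinal weighting at
contraction onset so the cross (secondary) direction is briefly stretched —
producing the early positive peak of the secondary-strain time course
observed in vivo — and decays to zero by end systole, leaving end-systolic
values untouched.

Cohort sampling: per-phase truncated normals (±3 SD, physiologic floors) at
the published exercise-protocol conditions — heart rate, EDV, EF and frame
counts per phase for Rest/Mid/Peak/Recovery-5/Recovery-10 and the control
group. ESV is derived from correlated (EDV, EF) draws: EDV and ESV covary
strongly within subjects, and drawing them independently would misstate the
EF spread (a ratio of independent normals is biased low and over-dispersed);
an explicit `esv` override switches to independent draws. E/A spreads are
not published, so the per-phase point values (1.6, 6.3, 1.5, 1.1, 1.2) carry
an illustrative 15% relative SD. Per-phase systolic fractions (0.375 at
rest/control rising to 0.50 at peak) reflect the preferential shortening of
diastole with heart rate. All draws are reproducible from a single integer
seed; identical specs produce bit-identical meshes.

Analytic fixtures: solid-body rotation (vorticity modulus exactly 2Ω),
Hill's spherical vortex (interior vorticity `(15U/2a²)σ`, volume mean
`(45π/32)·U/a`), and rigid translation of a closed mesh by spectral double
integration of a periodic acceleration profile (net force exactly ρVa).

## Strain analysis

Each reference (ED) triangle carries an orthonormal tangent frame: t1 is the
unit projection of the global longitudinal axis onto the triangle plane
(longest edge as fallback where the plane is nearly horizontal), t2 = n × t1
is the circumferential sense. The in-plane deformation gradient F maps
reference edge vectors to current edge vectors in these frames; the right
stretch U = sqrt(FᵀF) removes the rotation, and the Lagrangian strain is
S = U − I. Eigenvalues are computed by a closed-form symmetric 2×2
eigendecomposition of C = FᵀF (λ = sqrt(eig C) − 1); the principal (most
negative) eigenvector is lifted back to 3D in the reference tangent plane as
the local strain-line direction. For near-equal eigenvalues the
longitudinal-most eigenvector is reported as principal, keeping strain-lines
well defined on isotropically deforming patches (e.g. near the apex under
pure circumferential shortening).

Global values (GPS, GSS, and the directional GLS/GCS probed along t1/t2) are
reference-area-weighted means of per-triangle scalars, not eigenvalues of a
mean tensor — the average of a basis-dependent tensor would not commute with
the eigen-analysis. Reference-configuration weighting was chosen (current-
area weighting changes values by < 1 strain-percent on these geometries but
would make the weights time-dependent). Degenerate triangles are masked and
must cover < 1% of the reference area. All four series are zero at ED by
construction and GPS ≤ GSS pointwise.

## Hemodynamic forces

The net force the blood exerts on the chamber boundary is evaluated from
boundary velocities alone:

    F(t) = ρ [ d/dt ∮_S x (v·n) dS + ∮_S v (v·n) dS ]

The printed source formulation is typographically ambiguous about grouping;
this reading is fixed uniquely by the rigid-body oracle — translating a
closed surface with acceleration a must give F = ρVa (the first moment
identity ∮ x (a·n) dS = aV holds exactly per flat triangle), and the
convective term must vanish for rigid motion. The time derivative of the
first moment is taken by spectral (FFT) differencing across the uniform
frame grid, which is exact for band-limited motion and robust at 11–32
frames per cycle; an optional Fourier truncation (`harmonics`, off by
default) is available for noisy inputs.

Wall fluid velocity is the material vertex velocity (no-slip), also by
spectral differencing. Valves are binary: during ejection (dV/dt < 0) the
aortic orifice patch carries a uniform outward plug velocity |dV/dt|/A_AV on
top of the wall motion; during filling the mitral patch carries the inward
equivalent; the closed valve carries none. This closes the mass balance
(total boundary flux of fluid is zero) frame by frame.

F is reported dimensionless as f = F/(ρ g V(t)) in percent, with
ρ = 1060 kg/m³ and g = 9.81 m/s² by default. The longitudinal axis is the
registered +z (apex → base), so systolic propulsion toward the aorta is
positive. Six scalars summarize f_z(t): RMS amplitudes over the cycle,
systole [ED, ES) and diastole (LVLF, LVsysLF, LVdiaLF), and lobe means —
LVsysIm over the contiguous positive lobe containing the systolic maximum,
LVs (reported as a magnitude) over the negative interval starting at the
first zero-crossing after it, LVdiaIm over the next positive lobe. Lobe
boundaries are linearly interpolated zero crossings, with the cycle closed
periodically so a lobe ending at t = T is integrated completely; the LVs
window ends at the force zero-crossing (rather than the E-wave peak, which
the sources leave unspecified). Absent lobes are flagged `None`, never
reported as 0.

## Flow metrics

Mean vorticity: `ω̄(t) = (T/V) ∫_V |∇×v| dV` on a uniform Cartesian grid
restricted to a chamber mask, with mask-aware second-order derivatives
(centered in the interior, 3-point one-sided at the mask boundary) and
midpoint quadrature; integral and mask volume use the same discrete measure,
so ω̄ is T times the in-mask average. It is exact for solid-body rotation,
invariant under addition of a uniform velocity, linear in amplitude and in
T, and second-order convergent on smooth fields (Hill's vortex, whose
vorticity is only C⁰ at the sphere, still converges at the closed form
(45π/32)·UT/a to < 0.5% at 48³ nodes). The diastolic peak is the maximum
over frames after end systole.

Vortex formation time: VFT = ∫ over the E-wave period of v_MV(t)/d dt with
v_MV = Q_MV/A_eff and d = sqrt(4 A_eff/π), integrated with the trapezoidal
rule. (The printed diameter expression "4πA_eff" is dimensionally
inconsistent; the circle-of-area-A_eff diameter is the only reading that
makes VFT dimensionless.) Q_MV comes from dV/dt during filling by mass
conservation; the E-wave window runs from the dV/dt zero-crossing before the
E peak to the E–A local minimum. Bands: < 3 suboptimal, [3, 4] optimal,
(4, 5] acceptable, > 5 vortex-ring breakdown; boundaries inclusive as
stated.

## Statistics

Mean ± SD per metric and phase, with stroke volume derived per subject as
EDV − ESV before summarizing. The Control-vs-Rest contrast uses Welch's
(unequal-variance) two-sided t-test — the sources say only "unpaired", and
Welch is the robust default. Normality screening reports sample skewness and
excess kurtosis with package-default flags |skew| ≤ 2 and |kurtosis| ≤ 4
(the screening is named in the sources without cut-offs). Regressions are
ordinary least squares with R² = 1 − SS_res/SS_tot; a constant response is
reported as R² = 0. No multiple-testing correction is applied (one planned
contrast per metric). The statistical layer delegates to scipy.stats and is
cross-checked against statsmodels in the test suite to 1e-10.

## Pipeline and problem sizes

`simulate → analyze → report` runs a full synthetic study: 19 subjects ×
5 phases plus 25 controls by default, one directory per sequence (ASCII PLY
per frame with double-precision vertices — stock exporters down-cast to
float32 and break lossless round-trips — plus a JSON sidecar and the
ground-truth volume curve). Analysis registers each sequence, resamples to
32 uniform frames, and produces the volume/filling indices, strain series,
force parameters and VFT; per-entry failures are quarantined and the run
continues. The default study (120 sequences, 2304 triangles each) completes
in a few minutes on one CPU; the mesh resolution and cohort size are
configurable and were chosen so the whole study remains an interactive-scale
computation. Determinism is by a single config seed; the manifest hash is
recorded in every output.

## What passing tests do and do not show

The generator emulates volumes, filling-wave structure, shortening patterns
and torsion with known ground truth, but not real endocardial shape
irregularity, speckle-tracking noise, inter-subject anatomical
correspondence problems, or valve geometry. Consequences worth keeping in
mind:

- Synthetic hemodynamic-force magnitudes exceed the published clinical
  ranges (LVLF ~5% in vivo): the axisymmetric generator concentrates all
  orifice momentum flux in idealized plug profiles and its wall
  accelerations are not tuned to clinical force levels. The force kernel is
  validated by exact oracles instead; cohort force values should be read as
  internally consistent, not clinically calibrated.
- E/A detection is reliable on densely sampled waveforms (recovering the
  constructed ratio to < 2%), but at 11–12 frames per cycle the per-subject
  estimate can be off by tens of percent — matching the clinical reality
  that Mid/Peak filling indices come from model-interpolated curves.
- ESV from spline extrema carries a few percent of positive bias at low
  frame counts because the sharp end-systolic minimum is rounded.
- No flow solver is included: gridded velocity fields come from analytic
  fixtures or external exports, so cohort-level vorticity is only computed
  when such fields are supplied.
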