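# Methods

This note documents the physical model, the defaults and the numerical
choices in `boldsim`, in enough detail to judge what a simulation result
does and does not show.

## Units and conventions

Lengths mm, times s, fields T, angles rad.  Susceptibility differences are
dimensionless SI volume susceptibilities; ppm (cgs) values convert as
χ_SI = 4π·χ_cgs (`ppm_cgs_to_si`).  The gyromagnetic ratio defaults to
2.6752218744e8 rad/s/T.  The voxel spans `[0, W)` per axis; gridded voxels
place element centers at `(i + 1/2)·W/N` so the discretization is
consistent with the periodic wrap of diffusing spins.  Compartment label 0
is extra-perturber ("extravascular") space; label k > 0 is the k-th
perturber.

## Geometry and random generation

Cylinders are infinite: containment and field use only the perpendicular
distance to the axis.  2D voxels hold cylinders perpendicular to the
plane; to emulate an isotropic 3D network each 2D cylinder carries its own
effective field orientation, with cos θ drawn uniformly on [−1, 1] (the
distribution of the angle between a fixed B0 and an isotropic axis) and
the in-plane azimuth φ0 uniform.

Random generation at a target volume fraction (CBV) adds perturbers one at
a time — isotropic axis, axis point uniform in the enclosing ball of
radius W·√3/2 (3D cylinders), centers uniform in the square (2D), centers
uniform in the cube expanded by one radius (spheres, so coverage stays
uniform at the faces) — until the covered fraction of a fixed set of
probe points first reaches the target.  The estimate is Monte Carlo with
union semantics; overlap is allowed by default, with an optional
hard-perturber mode that redraws on pairwise overlap.  Because each
perturber adds a finite area/volume quantum, small voxels cannot hit the
target exactly; the generation tolerance (default 10% relative) is
configurable and the small test voxels relax it explicitly.  Generation is
a pure function of the seed.

Sampling rule: on a grid, every perturber should span at least 6 elements
across its diameter; `check_sampling` warns when it does not, and the
deliberately under-resolved tests silence that warning.

## Field computation

The analytic route superposes the closed forms (inside term for the
containing perturber, outside terms for all others); it is exact and
evaluated either at arbitrary continuous positions or at element centers.
For performance the hot paths are vectorized over perturbers with
trigonometry-free expansions (cos 2φ via dot products).

The Fourier route convolves the discretized χ map with the spatial-domain
z-dipole kernel, zeroed at r = 0, using FFTs.  Choices that matter:

- Kernel support is M = N elements per axis, restricted to a *symmetric*
  (odd-count) window: an asymmetric even window breaks the cubic-symmetry
  cancellation of Σ(3z² − r²)/r⁵ and leaks a spurious uniform offset of a
  few percent into the voxel.
- The zero-frequency value is whatever the spatial sum yields (≈0 by the
  symmetry above); no analytic Lorentz-term override is applied.  With
  this convention a discretized sphere reproduces the closed-form sphere
  field, which is the package's operational definition of the k=0 gauge.
- Padding is per axis.  `None` (default) applies the full N+M−1 zero
  padding (isolated perturber, no wrap-around; beyond that length extra
  padding changes nothing and fast FFT lengths are used).  `0` keeps the
  axis periodic — the voxel is surrounded by copies of itself.  On
  periodic axes the kernel is *folded over periodic images* (default ±3):
  the one-period truncation of the dipole kernel converges only as 1/L²
  for extended sources, and folding is what makes a z-periodic voxel an
  actually infinite cylinder.  An infinite cylinder is therefore best
  computed with pad 0 along its axis and full padding transversally; a
  fully zero-padded cylinder is physically a finite stick, and near the
  cut ends the two disagree strongly — that is a property of the geometry,
  not an implementation error.
- Expected accuracy: with ≥ 8 elements across the diameter, interior
  relative RMS error (away from the surface shell and the faces) is ~2–4%
  at N = 64 and decreases with N when evaluated on a fixed physical
  region.  Error is largest in the ±2-element shell around the surface
  where the binary discretization staircases the boundary.

## Diffusion

**Monte Carlo.**  Spin positions are continuous even on gridded voxels.
Per step, per axis: displacement ~ N(0, 2DΔt); positions wrap modulo W.  A
step whose endpoint lies in a different compartment than its start is a
wall crossing (sub-step chords that re-exit within one step are not
detected — acceptable when the step length is small against the perturber
radius); it succeeds with the wall's permeation probability, one Bernoulli
draw per attempted crossing, where leaving one perturber and entering
another gates on both walls.  A blocked spin redraws its step until one
stays in its compartment, up to 100 retries, after which it rests for that
step (counted and reported in the run metadata).  Blocked redraws
condition the step distribution on non-crossing; the ensemble acquires no
net drift.

**Deterministic diffusion (2D gridded).**  One step multiplies the
magnetization grid by the per-element precession/relaxation factor and
convolves it with a separable 1D kernel per axis under periodic (self-
padded) boundary conditions, implemented with cached FFTs.  Kernels:
samples of the Gaussian with σ = √(2DΔt) (the printed continuous form
needs the negative exponent, exp(−x²/2σ²), which is what is implemented),
or the discrete kernel exp(−t)·Iₙ(t), t = (σ/Δx)², which solves the
lattice diffusion equation exactly and whose untruncated sum is exactly 1.
Both are renormalized to unit sum after truncation — conservation takes
precedence over matching the continuous tail — and warn when the truncated
tail mass exceeds 1e-3.  The default half-width covers 4σ and at least 11
elements.  At σ/Δx ≥ 1 the two kernels give spin-echo rates within 2% of
each other.

Impermeable walls (the only non-permeable option in this backend): kernel
weight that would cross the intravascular/extravascular boundary is
retained at its source element —
`new(p) = conv(M·1_c)(p) + M(p)·conv(1_{¬c})(p)` for p in class c — which
conserves each class's total exactly (machine precision).  The correction
uses the binary IV/EV union, not per-perturber identity, and intermediate
or mixed permeabilities are rejected (use Monte Carlo for those).

**Under-resolution hazard.**  The kernel is sampled at grid spacing Δx;
if the voxel grows at fixed N, σ/Δx shrinks and the kernel degenerates
toward a delta, silently killing the diffusion effect (the spin-echo rate
collapses toward its D = 0 value of zero).  `effective_elements` gauges
this; the cure is increasing N, and the acceptance suite demonstrates both
the collapse and the recovery.

## Sequences and signal

Step s covers (s·Δt, (s+1)·Δt]; a pulse with `step_index = s` acts at time
s·Δt before that step's evolution, so an SE refocusing pulse at step
TE/(2Δt) splits the echo time exactly and a D = 0 spin echo refocuses to
machine precision.  Pulses are right-handed rotations about an axis given
in polar coordinates (x-pulse = (π/2, 0), y-pulse = (π/2, π/2)).  Built-in
sequences: GE (90°x), SE (90°x + 180°y at TE/2), ASE (refocusing displaced
by τ); arbitrary pulse lists are accepted for anything else.

Phase accrual uses the trapezoidal rule in Monte Carlo — the mean of the
field at the step's start and end positions, second-order accurate in Δt
at the cost of one cached evaluation — where the pure endpoint rule was
measurably first-order biased at practical Δt.  The deterministic backend
follows the relax-then-diffuse operator ordering; the two orderings agree
to O(Δt) and exactly in every static case.  Longitudinal magnetization
relaxes toward equilibrium +1 as mz′ = 1 + (mz − 1)·e^(−Δt/T1).  Absent
relaxation times mean no decay.  Signals are recorded per step as complex
total/IV/EV sums partitioned by current compartment label (total = IV + EV
exactly), unnormalized (site-count units).

## Rates

ΔR2(\*) = −(1/TE)·ln(|S(TE)|/|S_ref(TE)|) with the reference the identical
run (same seed, same geometry, same walk) with every Δχ = 0, which cancels
T2 decay and common sampling noise exactly; rates come from the single TE
point, not a multi-TE fit.  `radius_sweep` redraws fresh voxels per
(radius, repeat) cell at fixed CBV, sizing the voxel so the expected
perturber count stays constant (default 50) so all radii are simulated
under comparable statistics.

## Synthetic fixtures: what they emulate

- `gm_cylinders_2d`: cortical grey matter as randomly oriented 1 µm-radius
  vessels at CBV 2%, Δχ = 0.3 ppm cgs (deoxygenated blood), D = 1e-3
  mm²/s, SE TE = 70 ms at 3 T.  Defaults chosen where unstated: W = 0.1 mm
  (≈64 vessels — large enough for ~5% geometry scatter between seeds,
  small enough for desk-scale runs), Δt = 0.1 ms so the step length
  √(2DΔt) ≈ R/2 resolves the smallest vessel, walls impermeable (healthy
  vasculature; water exchange is slow on a 70 ms scale).
- `wm_axons_2d`: a white-matter bundle as a jittered hexagonal packing of
  hard (non-overlapping) axon cross-sections, diameters uniform in
  0.4–3.5 µm, Δχ = −0.15 ppm cgs (myelin), B0 perpendicular to the fibers,
  threaded by 1% CBV randomly oriented vessels.  The axon volume fraction
  targets 0.5 (override `axon_fraction`); hard packing with random
  diameters cannot always fill a site, so the realized fraction falls
  short of the target by up to ~10 percentage points, and the realized
  vessel CBV is quantized in ~0.8% steps in so small a voxel.
- `single_cylinder_3d` / `single_sphere_3d`: one centered analytic
  perturber — the oracle geometries for field-computation checks.
- `toy_mask_3d`: a small labelled grid built by discretizing two analytic
  shapes; a synthetic stand-in for a measured vascular network that
  exercises the custom-mask (FFT-only) path end to end.

What the fixtures do **not** emulate: curved/branching vessels, real
microvascular topology, axon g-ratio substructure, flow, exchange-driven
T2 changes.  Tests passing on these fixtures validate the numerics and the
qualitative physics (rate-vs-radius shapes, refocusing, conservation), not
the quantitative fidelity of any particular tissue.

## Method combinations

Five choices name a method (`3D-CTN-CYL-ANA-MC`, ...).  Compatibility
rules enforced: FFT requires a gridded voxel; custom masks (VAN) require
FFT and 3D; deterministic diffusion requires 2D gridded; spheres are 3D
only; FFT requires 3D, because the dipole kernel is three-dimensional and
2D cylinders carry per-cylinder effective field directions that a single
convolution cannot represent.

## Problem sizes and scaled-down checks

The validation suite runs desk-scale versions of the scientific checks:
cross-method rate agreement uses ten W = 0.1 mm grey-matter voxels at 10⁴
spins and Δt = 0.2 ms with fully permeable walls (the regime where both
diffusion representations are exact and differences isolate the field
representation); radius sweeps use 40 perturbers and 4000 spins per cell;
the under-resolution demonstration uses W = 0.02 mm, N = 90 baselines.
The two backends agree on mean rates to within a few percent, inside the
seed-to-seed geometry scatter; residual differences at finite Δt and Δx
are the expected discretization effects (gridded field sampling near the
surface shell, endpoint wall detection in Monte Carlo with impermeable
walls) and shrink with finer steps/grids.

## Known limitations

2D-only deterministic diffusion; no intermediate permeability in that
backend; no flow/advection; no time-varying gradients (imaging or
diffusion encoding); field sampled per step, not integrated within steps;
single voxel, no neurovascular coupling or multi-voxel composition; binary
(non-antialiased) discretization of perturber boundaries.
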