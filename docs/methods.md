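# Methods

`lungifea` implements an inverse finite-element analysis (IFEA) workflow for
a reduced-order *surface* model of an inflating lung lobe.  The visible lobe
surface is discretised with three-node membrane elements (in-plane stress
only, fixed reference thickness 1 mm).  The model is driven by two measured
inputs: an airway pressure trace applied as a follower load on the deforming
surface, and displacement boundary conditions at the nodes on the open
perimeter of the surface, standing in for the mechanical action of the
adjacent, unobserved tissue.  Material parameters are found by minimising
the mismatch between simulated displacements and a full-field probe
displacement dataset of the kind a stereo digital-image-correlation (DIC)
system produces.

Units are mm / kPa / mN throughout (1 kPa = 1 mN/mm²); pressures given in
cmH2O convert with 1 cmH2O = 0.0980665 kPa.

## Forward model

**Kinematics.** Each triangle carries a constant in-plane deformation
gradient `F` (3×2, local reference plane → deformed 3-D), computed from its
nodal positions; `C = FᵀF` is the in-plane right Cauchy–Green tensor.  The
through-thickness stretch λ₃ is *condensed* per constitutive law (below),
never a degree of freedom.

**Constitutive laws.** Three cases:

* *Homogeneous isotropic hyperelastic* — compressible Mooney–Rivlin,
  `W = C10 (Ī₁−3) + C01 (Ī₂−3) + (1/D1)(J−1)²`.  λ₃ is found per element by
  a safeguarded vectorised Newton iteration on the plane-stress condition
  ∂W/∂λ₃² = 0 (bracketed, driven to ~1e−13 relative so that the condensation
  is transparent to finite differencing at any sensible step).  The in-plane
  second Piola–Kirchhoff stress is the exact analytic derivative
  `S = 2 ∂W/∂C` of the condensed energy (envelope theorem).
* *Homogeneous anisotropic hyperelastic* — Holzapfel–Gasser–Ogden with one
  dispersed fiber family, fibers along the element-local x direction
  (medial–lateral).  The membrane formulation treats the response as
  isochoric: λ₃ = 1/J₂d, so the volumetric coefficient `D` is inert and is
  deliberately excluded from calibration sensitivity.  The exponential fiber
  term is active only under fiber tension; its k₂ → 0 limit is evaluated by
  the series limit `k1 E_f²/2` (no reparameterisation).
* *Heterogeneous isotropic linear elastic* — per-element (E, ν) under plane
  stress, geometrically linear, the case the adjoint machinery addresses.

Small-strain moduli implied by the hyperelastic laws: μ₀ = 2(C10+C01) and
K₀ = 2/D1 for Mooney–Rivlin; μ₀ = 2 C10 for HGO (no meaningful bulk modulus
in the isochoric membrane).

**Element frames.** Per element, z is the outward winding normal, y the
in-plane projection of a user-supplied anterior–posterior axis (a bare STL
encodes no anatomy, so the axis travels with the mesh), and x = y × z closes
the right-handed triad.  Frames are rejected as degenerate when the normal
is within ~1e−6 rad of the AP axis.

**Nonlinear solve.** Quasi-static Newton continuation: per inflation stage
the pressure and perimeter displacements are interpolated linearly in a
continuation parameter, with adaptive halving of the step on divergence and
a backtracking line search on the residual norm.  The element internal force
is the exact gradient of the membrane energy; the consistent tangent
(material + geometric + follower-pressure terms) is assembled by central
differencing each element's 9-DOF force vector — 18 vectorised force
evaluations per assembly, accurate to ~1e−5 relative, which preserves
Newton's fast local convergence at a fraction of the cost and fragility of a
hand-derived follower tangent.  Convergence: residual below 1e−8 of the
external load norm (absolute floor 1e−10 mN).  A stabilisation term (1e−6 of
the mean stiffness diagonal, free DOFs only) enters the *iteration matrix*
only, regularising wrinkling-prone states without touching converged
equilibria; it is switchable.

A quasi-static path replaces transient dynamics deliberately: at breathing
rates the inertial terms are a numerical vehicle toward the static state,
and no mass/damping data would constrain them.

**Linear heterogeneous solve.** `K(p) u = f` assembled from standard CST
plane-stress membrane stiffness in the local frames, with two
parameter-independent additions: an optional isotropic pre-tension
(geometric stiffness, the classical "drum" operator that carries transverse
load on flat regions — also the basis of the patch test), and an optional
frozen diagonal stabilisation (default off).  Pressure enters as a dead load
along reference normals, so ∂f/∂p = 0 exactly.  Per solve, the reduced
(free-DOF) matrix is factorised once and all five stage right-hand sides are
back-substituted.

**Outputs.** Per stage: nodal displacements, element Cauchy stress, major
and minor in-plane principal technical strains (principal stretch minus one)
with global direction vectors, strain energy, and the pressure–volume sample
(the exact signed volume swept by the surface, computed by a closed-form
flux integral that is additive over patches and identically zero at zero
displacement).

## Probe-field interpolation

Probe displacements and FE nodes do not coincide; a k-nearest-neighbor
interpolator (k = 5, unweighted mean, reference coordinates, per component)
maps between them.  Its accuracy is reported as the mean 10-fold
cross-validated coefficient of determination (shuffled, seeded folds;
zero-variance fold targets are excluded with a warning).  The same neighbor
map is materialised as a sparse operator `W` (rows = queries, 1/k entries at
neighbor columns), which is what the objective and its adjoint load use.
Distance ties resolve by index order of the fitted tree, making the operator
deterministic for a fixed probe ordering.

## Calibration

**Objective.**  `Π(p) = ½ Σₙ ‖W u_sim,n(p) − u_exp,n‖² / ν  + ρ(p)` over the
five stages at 20 % increments of the inflation.  For the homogeneous cases
ν normalises by (probes × stages × max squared measured displacement),
making Π dimensionless; no regularisation is applied there (ρ = 0), so the
normalisation is a pure rescaling of the objective.  For the regularised
heterogeneous gradient path the raw (mm²) misfit is used together with
Tikhonov regularisation ρ = (α/2)‖p̃‖² on bound-normalised parameters and
α = 1e−6.  The raw scale is what keeps α "very small": against the
dimensionless misfit the same α is comparable to the data term near the
optimum and measurably biases the recovered field (we observed ~45 % field
RMSE versus ~2 % without regularisation on a 40-element benchmark); against
the mm² misfit its bias is negligible while it still fixes the null-space
conditioning.  Reported separately from Π: the mean Euclidean displacement
error in mm, and per-component errors as a percentage of the maximum
measured displacement.

**Gradients.**
* Finite differences: central, per-parameter steps of 1e−6 of the bound
  range, 2N forward runs per gradient — the cost that motivates the adjoint.
* Adjoint (heterogeneous linear case): one forward solve and one adjoint
  solve per gradient regardless of N.  The adjoint system `K λₙ = Wᵀ(W uₙ −
  u_exp,n)/ν` shares the stiffness matrix (K is symmetric), and
  `dΠ/dpᵢ = −Σₙ λₙᵀ (∂K/∂pᵢ) uₙ + ∂ρ/∂pᵢ` with ∂K/∂pᵢ assembled
  analytically per element (∂K/∂E = K_e/E; ∂K/∂ν through the plane-stress
  matrix derivative).  Since the five stages share one factorisation, the
  two "solves" per gradient are two factorisations with five right-hand
  sides each.  Verified against central differences to better than 1e−5
  relative on randomised heterogeneous cases.

**Optimizers.**
* Homogeneous cases: bounded nonlinear least squares (trust-region
  reflective) from seven random starts drawn uniformly in the search ranges
  (C10, C01, k1 ∈ [1, 200] kPa; D1, D ∈ [1e−4, 1e−2] kPa⁻¹; k2 ∈ [0, 1];
  κ ∈ [0, 0.33]).  Parameters are bound-range scaled; finite-difference
  Jacobian steps of 1e−5 relative sit safely above forward-solver noise.
  Forward runs are warm-started from the previous evaluation's converged
  stage states (with a cold-continuation fallback), which cuts calibration
  cost several-fold.
* Heterogeneous case: L-BFGS-B in bound-normalised variables
  (E ∈ [50, 2000] kPa, ν ∈ [0.25, 0.49] per element) with the adjoint
  gradient; the limited-memory Hessian is refreshed by periodic restarts
  (up to 4 × 1500 iterations), which measurably accelerates progress on
  this ill-conditioned problem.
* Particle swarm: custom implementation with c1 = c2 = 2.0, inertia starting
  at 1.0 and damped by 0.99 per iteration, velocity clamping to
  [vMin, vMax], and the position rule: a particle that would leave the box
  has the offending velocity component zeroed and its position set to the
  violated bound.  Populations default to 24 / 48 / 1000 for the three
  cases; failed forward evaluations are penalised at 1e6 × the current
  global best (1e12 before one exists).  Stops when the global best improves
  by less than 1e−6 of its initial value for 10 consecutive iterations.  The
  forward evaluations of a swarm iteration are independent and can run in
  parallel worker processes (`n_jobs`, serial by default).

The multi-start winner is the lowest final objective, ties broken by the
lower mean displacement error.  A failed start is recorded and skipped.

## Synthetic scenarios

No public lung-surface DIC dataset exists, so verification uses parameter
recovery on synthetic data with known answers:

* **Geometry** — an open ellipsoidal cap (default semi-axes 60 × 45 × 35 mm,
  lobe-like scale) triangulated as a centre fan plus ring strips, with ring
  populations adjusted so the element count is met *exactly* (457 for the
  standard coarse model; any n ≥ 4 is reachable).  Winding is outward; the
  AP axis is global y.
* **Loading** — a concave-down pressure ramp `p(t) = p̂ sin(πt/2T)` over a
  2 s inflation (15 breaths per minute), peak 2 kPa (~20 cmH2O), stages at
  the five 20 % time increments.
* **Ground truth** — homogeneous scenarios use the canonical calibrated
  parameter sets (Mooney–Rivlin 136.5 / 1.0 / 13.43e−4; HGO 116.4 / 43.6e−4
  / 1.0 / 0.12 / 0.33); the heterogeneous scenario a linear (optionally
  sigmoidal) E gradient along the AP axis between 300 and 900 kPa with
  ν = 0.43 — i.e. shear moduli ~105–315 kPa, a posterior-to-anterior
  softening pattern.
* **Probes** — seeded blue-noise (dart-throwing) sampling on the surface;
  probe displacements are the forward solution mapped through the *same*
  k = 5 kNN operator the objective uses, plus optional i.i.d. Gaussian noise
  per component (a realistic DIC accuracy scale is ~0.11 mm).  Using the
  model's own probe operator makes the generating parameters an exact zero
  of the noise-free misfit, which is what a recovery benchmark requires.
* **Strain regime** — the anisotropy-detection study inflates to a 6 kPa
  peak (~20–25 % strain, the deformation scale lung-surface measurements
  exhibit).  This matters scientifically: at small strains (~7 %, the 2 kPa
  default) the HGO fiber term contributes below the Mooney–Rivlin-versus-HGO
  misfit floor, the objective is flat in (k1, k2, κ) jointly, and the
  dispersion parameter is *unidentifiable* — individual starts then leave κ
  anywhere in its range at identical objective values.  In the finite-strain
  regime the isotropised fiber correction genuinely improves the fit and
  every start pins κ at the 1/3 bound.
* **Boundary data** — extracted from the truth run's perimeter
  displacements.  For the heterogeneous scenario the generator prescribes a
  radial perimeter motion growing *linearly* in time against the concave
  pressure ramp: with proportional stage loads all five stages are scalar
  multiples of one solution and two unknowns per element cannot be
  identified from ~1.5 free DOFs per element; the non-proportional mix makes
  the stages informative.

What the generator does **not** emulate: correlated DIC noise, probe
dropout near steep flanks, geometric reconstruction error, pre-conditioning
hysteresis, and genuinely nonlinear heterogeneous tissue.  Passing recovery
tests therefore demonstrates the correctness and identifiability machinery
of the inverse pipeline, not field performance on real DIC data.

## Numerical choices and degenerate inputs

* STL reads merge duplicate vertices within 1e−6 mm and reject zero-area
  facets by index; meshes must be open 2-manifolds.
* Plane-stress root find: bracketed Newton-with-bisection on λ₃² ∈
  [1e−8, 1e6], tolerance ~1e−13 relative; failure raises with diagnostics.
* Element inversion (non-positive in-plane Jacobian) raises, naming the
  element, and failed forward runs surface as objective penalties.
* Principal-strain directions for (near-)equibiaxial states are arbitrary
  but orthonormal; ties in kNN distance resolve by index.
* The five-stage boundary series interpolates linearly in time and ramps
  from zero at t = 0.

## Problem sizes used in the shipped verification runs

Recovery and gradient benchmarks run at deliberately desk-scale sizes: the
457-element cap with 500–7,000 probes for the homogeneous recovery and
interpolation studies, a 120-element cap for the anisotropy-detection study,
and a 40-element cap (80 unknowns) for heterogeneous field recovery and
adjoint/finite-difference cross-checks, with the 2N-versus-2 solve-count
comparison demonstrated at the full N = 914 on the 457-element mesh.  These
sizes exercise every code path while keeping the whole battery re-runnable
in minutes on one core.

## Known limitations

* The heterogeneous path is geometrically linear by construction; a
  nonlinear heterogeneous model would need the adjoint of the Newton solve.
* The follower-pressure tangent is finite-differenced per element rather
  than derived; exotic load states (deep wrinkling, snap-through) are
  outside the validated envelope.
* kNN interpolation is a zeroth-order estimator: it biases toward the local
  mean and its CV score degrades gracefully, but deliberately, with noise.
* PSO at the published heterogeneous population (1000 particles) is
  supported but expensive; the shipped benchmarks use the gradient/adjoint
  path for that case.
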