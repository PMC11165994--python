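# Methods

## The estimation problem

Susceptibility-induced off-resonance displaces EPI signal only along the
phase-encoding (PE) axis. With two acquisitions of opposite PE polarity,
the displacement field *b* (mm) enters both observations with opposite
sign, and the mass-preserving operator

T[I, b, v](x) = I(x + b(x) v) · (1 + ∂_v b)(x)

maps each distorted image back toward the undistorted anatomy: the first
factor undoes the geometric shift, the second rescales intensity by the 1D
Jacobian so integrated signal per column is conserved. The field map is
the minimizer of

J(b) = D(b) + α·S(b) + β·P(b),

with D the half squared L2 distance between the two corrected images, S
the half squared gradient norm of *b*, and P the barrier
½∫φ(∂_v b), φ(z) = z⁴/(1−z²) on (−1,1) and +∞ outside. The barrier keeps
1 + ∂_v b > 0, i.e. the distortion invertible; any β > 0 suffices in
principle, small β keeps the bias negligible.

Assumptions: distortion is purely along one axis (no through-plane
component), the two acquisitions are geometrically aligned (no inter-scan
motion), and signal outside the object is zero.

## Discretization

All computation permutes the PE axis last. Images live at cell centers
(k + ½)h₃; the field map on a PE-staggered grid: nodes k·h₃ along PE,
cell centers elsewhere. Averaging (node→center) and forward differencing
(node→center, divided by h₃) make the transform's two factors exact on
this grid; integrals use midpoint quadrature with weight h₁h₂h₃. Images
are modeled by 1D piecewise-linear interpolation along PE, returning 0
outside the sampled extent (air); at exact knots the derivative takes the
left segment's slope, making the gradient deterministic.

The smoothness operator H is assembled as Σ_d D_dᵀD_d with first
differences per axis and homogeneous Neumann boundaries, so
S(b) = (h₁h₂h₃/2)·bᵀHb equals the summed squared difference quotients
exactly, constants are cost-free, and H is symmetric positive
semi-definite with exactly the constants in its null space.

Units: the field map is stored in mm of displacement. The quadrature
factor ½ is applied uniformly to D, S and P.

## Derivatives

The residual r(b) = T[I₊ᵥ,b,v] − T[I₋ᵥ,b,−v] has the Jacobian
J_r = diag(I₊′·m₊ + I₋′·m₋)·A + diag(I₊ + I₋)·D, where A and D are the
staggered averaging/differencing operators, primes are interpolation
slopes at the warped sample points and m± = 1 ± ∂_v b. The gradient of J
is assembled from J_rᵀr plus the (exact, convex) regularizer gradients;
the Hessian uses the Gauss-Newton approximation
J_rᵀJ_r + α·hV·H + (β·hV/2)·Dᵀdiag(φ″)D, exposed as a matrix-free matvec.
Its diagonal is extracted analytically (each PE node touches exactly two
cell centers of its column) for Jacobi preconditioning. Correctness is
established against central finite differences (relative error < 1e−6 in
double precision) and dense unit-vector assembly (symmetry, positive
definiteness, diagonal agreement to 1e−10).

An infeasible field (any |∂_v b| ≥ 1) evaluates to J = +∞ rather than
raising, so line searches reject such trial points naturally.

## 1D optimal-transport initialization

Because distortion preserves per-column mass, each pair of opposite
columns defines two 1D measures (after a small positivity shift of
1e−5 × the global image maximum, and per-column normalization — both
constants cancel in the map composition). 1D optimal transport is closed
form: with C± the columns' CDFs, the pseudoinverse of the Wasserstein
midpoint is (C₊⁻¹ + C₋⁻¹)/2, and the transport maps to the midpoint are
T± = C_half⁻¹ ∘ C±. Since C⁻¹(C(x)) = x for the strictly increasing
(shifted) CDFs, the displacement reduces to

d(x) = (T₋(x) − T₊(x))/2 = ¼·[C₊⁻¹(C₋(x)) − C₋⁻¹(C₊(x))],

evaluated per index and converted to mm. A numerical point that matters:
the pseudoinverses are evaluated *at the exact levels needed* (the other
column's CDF values) by linear interpolation of the (cdf, position) graph.
Pre-sampling C_half⁻¹ on a uniform level grid is not an option — in
near-empty (air) regions the pseudoinverse ramps from 0 to the object edge
within a level interval of width ~1e−4, and any fixed level grid misses
that ramp, corrupting the maps at object boundaries by several voxels.

The column-wise field is resampled to PE nodes by adjacent averaging with
boundary replication. It is accurate but non-smooth across columns, so a
normalized 3×3×3 sampled Gaussian (σ = 1 voxel, circular/FFT convolution)
is applied by default before optimization; the un-blurred variant is kept
for diagnostics and is itself the subject of the initialization-quality
check.

## Optimizers

All three share an Armijo backtracking line search (c₁ = 1e−4, shrink ½,
≤ 12 backtracks; infinite trial values are backtracked past) and stopping
rules: gradient norm below 1e−2 of its initial value, relative loss change
below 1e−4, relative step below 1e−4, or the iteration cap.

* **Gauss-Newton + PCG** (default, cap 50): each outer step solves
  H_J q = −∇J with ≤ 10 Jacobi-preconditioned CG iterations, stopping
  early at relative residual 0.1.
* **ADMM** (cap 200): splits J into F(b) = D + α·S_pe + β·P (separable per
  PE column) and G(z) = α·(S₁+S₂), coupled by b = z with scaled multiplier
  u. The b-update takes one GN step whose normal equations decouple per
  column and are solved by a vectorized per-column PCG (each column has
  its own step sizes and stopping test); the z-update solves
  (α·hV·L₁₂ + ρh₃)z = ρh₃(b+u) slice-wise by 2D FFT, using periodic
  boundaries so the blocks are circulant (BCCB) and invert exactly; ρ
  adapts by factor 2 whenever primal and dual residuals differ by more
  than 10× (u is rescaled accordingly). Stops when b, z and u all change
  by less than the field tolerance.
* **LBFGS** (cap 500, memory 10): two-loop recursion on the explicit
  gradient. The first iteration uses unit-norm steepest descent — the raw
  gradient has the magnitude of J itself, far beyond any backtracking
  budget. Curvature pairs with non-positive sᵀy are skipped.

The optimizers are deterministic; all randomness in the package lives in
the synthetic-data generator.

Under these production stopping rules the three optimizers halt at
different points of a rather flat valley and their final losses can differ
by tens of percent. For convergence comparisons the test suite uses a
shared tight protocol (gradient tolerance 1e−4, loss/step tolerances 1e−9,
caps 200/600/2000, LBFGS memory 20), under which the three final losses
agree to ~2%.

## Output correction

Jacobian-modulation correction applies T to each input, giving two
corrected images whose residual distance is the quality surrogate.
Least-squares correction instead assembles the sparse push-forward
operators P± (each source voxel's unit mass split linearly between the two
cells bracketing its displaced position; mass leaving the domain is
dropped) and solves min_I ‖P₊I − I₊‖² + ‖P₋I − I₋‖² by CG on the normal
equations (relative tolerance 1e−6, cap 200). If voxels are unobserved
under both polarities the normal equations are singular; a minimal
Laplacian regularization (1e−6 × mean diagonal) is then enabled
automatically with a warning.

## Synthetic data and what it does (not) show

The generator emulates a distortion-only RGP study: a deterministic,
seeded phantom; a smooth random true field; and a distorted pair produced
*exactly* by the push-forward model, so estimator and simulator share the
physics and the true field and image are known.

Design choices, fixed once:

* **Phantom**: a rounded super-ellipsoid body filling most of the field of
  view (as in a tightly cropped acquisition) with ~5 internal ellipsoids
  of varying contrast, softened by a 2-voxel Gaussian, zero in a 3-voxel
  margin. Intensities are on the MRI magnitude scale (~10³ a.u.); this is
  load-bearing, because α = 300 and β = 1e−4 balance the data term against
  the regularizers at that intensity scale.
* **True field**: white noise blurred with σ = 1/8 of each axis (leaving
  only low spatial frequencies), windowed by the cubed smooth support mask
  of the phantom, centered, and rescaled so max |∂_v b| equals the
  requested bound exactly (default 0.5, comfortably inside the barrier's
  open interval). The windowing concentrates displacement where there is
  signal: displacement of air is unobservable in the data, and hiding
  random field structure there would make the global field-error metric
  measure nothing but the unrecoverable component.
* Problem sizes in the tests — 32³ for optimizer comparisons, 48³ for
  recovery studies, 64³ for initialization quality — are the package's
  desk-scale study conditions; all complete on one CPU core in minutes.

What passing these tests does *not* show about real data: there is no
noise, no inter-scan motion, no eddy currents, no partial-volume or spin
history effects, and the simulator and estimator share the same forward
model — real-data accuracy is bounded by how well that model holds. An
additive-noise hook exists in the generator (off by default) for
robustness experiments.

One numerical property of the simulator worth knowing: scattering mass
through the push-forward operator onto a regular grid produces a
voxel-scale intensity ripple proportional to the local field slope (the
hat-kernel quadrature over a non-uniformly mapped grid does not telescope
exactly). Correcting simulated data with the *true* field therefore
converges to the truth only down to an h-independent floor of a few
percent at slope ≈ 0.4; grid-refinement behavior is checked on the coarse
doubling where discretization error still dominates. The least-squares
correction, which inverts the push-forward operators themselves, is immune
and recovers the truth to < 0.01%.

## Known limitations

* Axis-aligned PE directions only; no resampling between mismatched
  geometries.
* No multilevel (coarse-to-fine) optimization; the OT initialization is
  the sole globalization device.
* Field maps are reported in mm of displacement, not Hz; conversion
  requires the readout timing, which the tool does not parse.
* 4D series must be split into 3D volumes upstream.
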