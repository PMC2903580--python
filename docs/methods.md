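# Methods

This note documents the models, estimators and numerical choices in
`lvstrain`: what is assumed, what is approximated, and what the phantom
validation does and does not demonstrate.

## The single-slice problem and what is identifiable

The deformation gradient `F = ∂x/∂X` is fitted locally by least squares
over a neighborhood of displacement pairs, minimizing
`Σ ‖dx − F·dX‖²`. On a single image slice the reference distance
vectors `dX` are coplanar, so the normal matrix `Σ dX dXᵀ` is rank-2:
the column of F along the surface normal is unobservable. Working in a
local frame whose third axis is the surface normal (the least-scatter
direction of the reference neighborhood, sign-aligned with the slice
normal) confines this singularity to the third column; the third *row*
is as well-posed as the rest because the out-of-plane *displacement
component* is measured with in-plane precision.

How much of the missing column can constraints restore? Write the
unknowns as the images of the two surface normals: `a = F·e₃` and
`q = G·n_d` (`G` the inverse-map tensor, `n_d` the deformed-surface
normal). The data determine `F` on the slice plane and `G` on the
deformed surface, and these two restrictions are mutual inverses —
they carry the same information. The available constraints are
`G F = I` on the missing column (3 equations) and `det F = 1`
(`det G = 1` is then implied), i.e. 4 equations for 6 unknowns:
**a 2-parameter family of deformations is fundamentally
indistinguishable from single-slice data**, even noise-free. Those two
degrees of freedom are exactly the out-of-plane shear couplings
F₁₃, F₂₃. This is why the estimator needs a *physiological* input — the
semi-symmetric-torsion pre-estimate — and why the package's exactness
guarantees are stated for the observable class (motions whose
out-of-plane shear couplings vanish in the slice frame, or are supplied
exactly by the torsion model). Arbitrary affine motions, and rigid
rotations that tilt the slice, are recovered exactly only by the
two-slice estimator.

## The estimation pipeline

Per masked point and time frame:

1. **Neighborhood**: the N nearest in-mask grid points,
   `N = round(area/spacing²)` (25 points for 25 mm² at 1 mm — the
   point count represents the smoothing area exactly; an axis-aligned
   square cannot represent 15 mm² at 1 mm spacing with the required
   minimum of 10 points). Points with fewer than 10 reachable
   neighbors are skipped. Ties in distance are broken
   lexicographically, so runs are deterministic.
2. **Local frame** from the PCA of the reference neighborhood; the
   in-plane first axis follows the projected radial direction of the
   long-axis model so that frame-local elements read approximately
   (radial, longitudinal, circumferential).
3. **Torsion pre-estimate** (long-axis slices): the per-neighbor ratio
   u_out/d (out-of-plane displacement over perpendicular distance to
   the long axis, same-side neighbors only) averages to sin β of the
   local rotation — exact for any finite rigid rotation about the
   axis, and equal to −F₁₃ in the phantom's composition where rotation
   acts on the contracted configuration. Couplings:
   (F₁₃, F₂₃) = −sin β · (radial direction projected on e₁, e₂).
   Points within 2 px of the axis are flagged and get zero
   pre-estimates. On short-axis slices the in-plane rotation is fully
   observable and the pre-estimate is disabled.
4. **Least squares with spectral fallback**: each row of F solves the
   damped normal equations; eigendirections of the normal matrix below
   10⁻² of its trace — *and always the smallest one* — are treated as
   informationless, and the solution component along them is taken
   from a prior (identity with the torsion couplings in the third
   column). The unconditional smallest-direction fallback matters for
   two reasons: the deformed cloud's singular direction is the
   *deformed*-surface normal, tilted away from the frame axis (damping
   a fixed matrix entry leaves it unregularized and surface bowing
   then produces O(1) systematic errors in G); and displacement noise
   inflates the through-surface spread past any fixed threshold, after
   which the structurally singular direction would be fitted from pure
   noise (observed: det G < 0 at half the points at σ = 0.02). The
   Tikhonov floor inside the informative subspace is 10⁻¹² of the
   trace.
5. **G with fixed-point refinement**: the inverse fit's prior is the
   inverse of the current F; alternating the G fit, det(G) = 1
   enforcement (third-column rescale), the adjugate recovery
   `F₃₃ = G₁₁G₂₂ − G₁₂G₂₁`, the orthogonality solve for (F₁₃, F₂₃),
   the smaller-|E₁₃|+|E₂₃| candidate selection (ties keep the
   F-based candidate) and det(F) = 1 enforcement converges in a few
   iterations (max 20, tolerance 10⁻¹³) and is required for
   machine-precision self-consistency on the observable affine class.
   Points where a determinant is non-positive are voided.
6. **Strain**: `E = (FᵀF − I)/2` in the local frame; E₃₃ is replaced
   by the area-ratio estimate
   `E₃₃ = ½[(λ₃F² − 1)/2 + (λ₃G² − 1)/2]`, with
   `λ₃F = 1/(λ₁F λ₂F)` and `λ₃G = λ₁G λ₂G` from the in-plane principal
   stretches of F and G (their product is |det| of the in-plane 2×2
   block). For a rotation by θ this approximation leaves a second-order
   bias `sin⁴θ/(4cos²θ)` (≈ 4·10⁻⁴ at θ = 0.2 rad) — the documented
   price of its noise robustness. E is then rotated to Cartesian and
   re-expressed in the RCL triad computed from the *reference*
   positions (so all time frames share material directions). Points
   within 10 % of the apex-to-base length of the apex are flagged as
   having an ill-defined frame rather than silently reported.

Pre-processing (region-growing unwrapping with the |Δφ| > π wrap
criterion and a maximum-temporal-coherence seed; u = φ/(2πk_e);
five-pixel plus median; least-squares projection on a 5th-order
temporal Fourier basis of the heart period, default = covered span plus
one frame interval) and strain post-filtering (|E| > 1 elimination,
then per-component slice-wide 2-SD voiding, plus-median, mask-aware
1 cm² moving average that also fills voids) are separate stages; the
noise-free validation experiments run with both disabled to isolate the
singularity's effect on the tensor estimation.

## The analytical phantom

The phantom is an axisymmetric LV wall between the apical cap (Z = 0,
open) and the base (Z = L): epicardial radius `R₂(Z) = (R₀/2)(1+Z/L)`,
constant thickness R₀/4. Defaults: R₀ = 30 mm, L = 60 mm — chosen so
the long-axis myocardial cross-section is ≈ 900 mm², making a 25 mm²
neighborhood ≈ 2.8 % of it (equivalently 1/36, and 15 mm² ≈ 1/60).

The motion composes an in-plane (radial/longitudinal) deformation and
an axial rotation, `F = F_rot · F_inplane` (rotation applied to the
contracted configuration; the order is recorded in the slice
metadata). The in-plane map is a composition of three exactly
area-preserving maps of the (R², Z) half-plane — volume preservation in
an axisymmetric motion is area preservation in (R², Z) — so
`det F = 1` holds to machine precision by construction, for every
parameter value:

- longitudinal shear `Z → Z + g(R)`,
  `g(R) = 2f(t)[γ(R − L/5) + (δ/k)sin k(R − L/5)]`: the linear part
  mimics the descent of the base, the oscillation imprints fast
  transmural variation on ∂u_z/∂R (γ = 0.31, δ = 0.56,
  k = 0.55 rad/mm);
- conical rescale `(R², Z) → (R²/h, hZ)`, `h = 1 − 0.2·f/f_max`
  (20 % longitudinal shortening at peak);
- radial squeeze `R² → R² − 35 mm²·f/f_max` (transmurally graded
  circumferential contraction, strongest at the endocardium; the
  parameter must stay below the squared apical endocardial radius,
  56 mm²).

Waveforms: `f(t) = f_max sin²(πt/T)` with f_max = 0.4 and T = 780 ms
(peak contraction at 390 ms); rotation
`β(Z,t) = θ(1 − Z/L)·sin²(π(t+t₀)/T)` with θ = 15° base-to-apex twist
and torsion lead t₀ = 100 ms (torsion precedes shortening; peak torsion
at 290 ms). Because β is independent of R, the analytic
radial-circumferential shear E_RC is identically zero — a structural
test for spurious couplings. Note that with a nonzero torsion lead
there is no time at which both contraction and twist vanish; the
reference configuration is the undeformed geometry itself.

**Calibration.** γ, δ, h and the squeeze were set analytically from the
printed variation magnitudes of the reference validation (F₂₁ 0.320,
F₂₂−1 0.192, F₁₃ 0.113, F₁₂ 0.006); the wavelength 2π/k is constrained
only through the smoothing error it induces, and k = 0.55 rad/mm makes
the 25/15 mm² neighborhoods reproduce the reported F₂₁ error structure
(0.11/0.086 vs 0.107/0.080). A structural limitation is worth stating:
with a Z-independent radial map (required for the near-zero F₁₂) and a
constant longitudinal stretch, exact incompressibility forces the
circumferential stretch to *increase* with R²; uniform circumferential
shortening is impossible in this family, so the analytic E_CC and E_RR
magnitudes (0.069, 0.297) undershoot a field with uniform ~15 %
circumferential shortening (0.133, 0.523). Error *magnitudes* that
scale with these components inherit part of that gap; the spurious
E_RC in particular comes out ≈ 0.002 rather than ≈ 0.017, because the
exactly axisymmetric torsion makes the pre-estimate nearly exact.

**Noise model**: i.i.d. zero-mean Gaussian noise per displacement
component, point and time, SD = σ_rel × (maximum displacement magnitude
over the masked motion, ≈ 13 mm at the defaults); one master seed
spawns per-frame substreams, so runs are reproducible and frames
independent.

**What the phantom does not emulate**: no MRI signal or phase noise
physics (noise is additive Gaussian on displacement), no right
ventricle, papillary muscles or apex, no breathing or inter-breathhold
misregistration, no through-plane motion of material into or out of
the slice (meta-DENSE's Lagrangian labeling is assumed perfect).
Passing the phantom tests therefore demonstrates the *numerics* of the
reconstruction under the stated geometry and noise, not robustness to
acquisition artifacts.

## Reference two-slice method

Unconstrained least squares over neighborhoods spanning two parallel
slices (same in-plane square area on each). No incompressibility is
imposed; on the phantom the recovered det F stays within 0.05 RMS of
unity, which is itself a consistency check. Known bias: strains are
evaluated along chords across the wall curvature and are slightly
underestimated; this is a property of the reference method and is not
corrected. The through-plane (third-column) error decreases as the
slice separation shrinks from 8 to 2 mm; at 1 mm separation the
through-plane conditioning degrades and the error rises again, so the
convergence statement is for separations above the in-plane spacing.

## Validation experiments and problem sizes

All experiments run on the 1 mm long-axis slice (924 myocardial pixels)
at peak contraction. The noise-free error tables and the two-slice
comparison take seconds; the noise sweep uses 5 seeds × 5 noise levels
× 2 smoothing areas with precomputed neighborhoods (~10 s). Relative
RMS errors under noise are heavy-tailed (the area-ratio E₃₃ involves
1/det² of a noisy 2×2 block), so seed means at σ = 0.05 with the small
smoothing area can be very large; the criterion-level statements are
trends (monotone growth, faster out-of-plane growth, larger area wins
at σ ≥ 0.02), which hold with seed-wise tolerance.

## Numerical details and edge cases

- Degenerate neighborhoods (collinear reference points) raise; masks
  smaller than the minimum point count skip the point with a flag.
- det ≤ 0 after estimation voids the point (non-physical deformation).
- A singular in-plane block of G keeps the prior third-column
  estimates (flagged).
- Relative errors are reported as NA when the analytic component is
  identically zero (E_RC).
- Regional summaries average each component over six regions
  (apical/equatorial/basal bands at 30/55/80 % of the apex-to-base
  distance, ±10 %, × septal/lateral labels); the peak is the extremum
  of the regional mean in the 330–450 ms window, by absolute value so
  that sign-varying shears are handled consistently.
- TSV output uses 17 significant digits and round-trips losslessly;
  NIfTI voxel data are float32.
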