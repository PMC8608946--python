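# Methods

## Indentation models

A rigid sphere of radius *R* (mm) resting under its own weight
*F* = (*m* + *m*ₒᵥ)·g₀ (g₀ = 9.81 m/s²; buoyancy and capillary forces
neglected) indents a cylindrical gel (height *h*, diameter *D*) to an
equilibrium depth *δ*. Four nested estimators are implemented, all
assuming an incompressible gel (ν = 0.5) and frictionless (slip,
non-adhesive) contact:

* **H** — Hertz half-space: *E*ᴴ = 9*F*/(16√*R* δ³ᐟ²).
* **H-fh** — linear material, finite height: *E*ᴴ divided by the
  free-slip incompressible finite-thickness series
  1 + 1.133χ + 1.283χ² + 0.769χ³ + 0.0975χ⁴ with χ = √(*Rδ*)/*h*.
* **NH-fh** — neo-Hookean material, finite height: *E*ᴴ·*f*(*R/h*, ω),
  ω = (*Rδ*/*h*²)³ᐟ², with
  *f* = (1 + 2.3ω)/(1 + 1.15ω¹ᐟ³ + αω + βω²),
  α = 10.05 − 0.63√(*R/h*)(3.1 + *h*²/*R*²), β = 4.8 − 4.23 *h*²/*R*².
* **NH-fdh** — additionally finite diameter: *E*ᴺᴴ⁻ᶠʰ/*g* where *g* is a
  polynomial in (*δ/h*, *Rh*/*D*²) regressed from finite element
  simulations of a rigid sphere on an incompressible neo-Hookean
  cylinder.

The algebraic identities *E*ᴺᴴ⁻ᶠʰ = *E*ᴴ·*f* and
*E*ᴺᴴ⁻ᶠᵈʰ·*g* = *E*ᴺᴴ⁻ᶠʰ hold exactly by construction and are asserted
property-style over random geometry.

The *f* denominator can change sign at parameter combinations that are
not physically reachable (large ω together with small *R/h*; ω is bounded
by ((*R/h*)(*δ/h*))³ᐟ² since *δ* < *h*). Positivity and finiteness are
therefore guaranteed — and tested — over the admissible region
ω ≤ (0.9 *R/h*)³ᐟ² only. The *g* polynomial was fitted for
*δ/h* ≤ 0.4 and *Rh*/*D*² ≤ 0.15; evaluation outside that box attaches a
`g_extrapolation` warning instead of failing. In the lab operating regime
*Rh*/*D*² = 0.05 the diameter correction stays below 1 % (bounded by the
7 % figure quoted for the full experimental envelope).

**Forward model and indenter choice.** `predict_indentation` inverts the
NH-fdh relation for *δ* by bracketed root finding on
(*δ*ₘᵢₙ, 0.9 *h*) with *δ*ₘᵢₙ = 0.02 *h* (the smallest depth worth
reading off a photograph); the model modulus is strictly decreasing in
*δ* there, so the root is unique. Spheres whose equilibrium falls outside
the bracket are "unsuitable". `select_indenter` targets a readable strain
window *δ/h* ∈ [0.05, 0.45] centred on 0.225 (chosen from the observed
range of practical sessions, ~0.07–0.36, with margin) and breaks ties
toward the lighter sphere. Validity flags (`strain_out_of_range` outside
[0.05, 0.40], `slope_violation` when √(*Rδ*)/*D* > 0.25, `thin_gel` when
χ > 1) are warnings; nothing is silently rejected.

Units: mg/mm/kPa at every interface (lab-facing); the Hertz kernel itself
is SI (N, m, Pa).

## Micropipette aspiration

For a capillary of internal radius *a* (default 0.375 mm, external
radius *A* = 0.5 mm) and aspiration ratio *x* = *l/a*:
*E* = |*p*|/(1.07*x*) for *x* < 0.3 (linear regime) and
*E* = |*p*|/(0.872*x* + 0.748*x*²) for *x* ≥ 0.3. The boundary is
assigned to the non-linear branch — the branch used for all reliable
readings, since resolving *l* optically requires *x* > 0.3 (smaller
readings carry a `low_aspiration` warning). Pressures are stored signed
(suction negative) and used in magnitude, so either sign convention gives
the same estimate. Readings with *x* > 2 are rejected as implausible.

The two branch formulas disagree by ≈2.5 % at *x* = 0.3, so the estimator
*E*(*x*) is discontinuous there and skips a narrow band of moduli
(pressure ratios |*p*|/*E* ∈ [0.321, 0.329)). The closed-form inverse
`predict_aspiration_length` maps ratios in that band to the boundary
reading *x* = 0.3; composed as reading → modulus → reading the round trip
is exact to machine precision.

Aggregation over a pressure sweep reports the arithmetic mean and the
*n*−1 sample SD, plus a `pressure_trend` warning when a linear fit of *E*
against |*p*| moves the estimate by more than 10 % of its mean across the
sweep — estimates should be constant with applied pressure if the model
holds.

## Constitutive fitting

Compression tests are treated in nominal (engineering) strain and stress,
compression positive; whether lab curves are nominal or true is an
assumption the fits inherit. Two one-parameter laws: σ = *E*ε and the
incompressible uniaxial neo-Hookean form σ = (*E*/3)|λ − λ⁻²| with
λ = 1 − ε (so *E* = 3µ₀ = 6C₁₀; the compressibility parameter is
reported as not-applicable for incompressible fits). Both laws are linear
in *E*, so the unweighted least-squares optimum is computed by exact
projection rather than iterative search — noise-free generated data is
recovered to machine precision, which the tests use as the
identifiability oracle. Model preference is by SSE; no toe-region
trimming or weighting is applied.

## Image metrology

Detectors are built for backlit silhouettes (bright background, dark
objects), binarised with Otsu's threshold; all edges are refined to
sub-pixel precision by linearly interpolating the intensity crossing.
Coordinates are raster (row, col), origin top-left; scale is assumed
isotropic.

* **Indentation.** The sphere's visible arc is extracted from the
  per-column top-edge profile and circle-fitted (algebraic least squares
  with one inlier-reselection pass at 2 px); the fitted radius against
  the known sphere radius calibrates mm/px. The undeformed free surface
  is a robust line fit to the gel's top edge, excluding columns under the
  sphere silhouette and a contact zone of half-width 1.5√(*Rδ*) around
  the axis (one refinement iteration); *δ* is the depth of the sphere's
  lowest point below that line, *h* and *D* come from the silhouette's
  base and lateral edges. Failure modes (no silhouette, no arc, surface
  inlier fraction < 0.5, sphere above the surface) raise distinct
  diagnostic errors. The analysis is fully automatic on clean
  silhouettes; interactive refinement of messy frames is out of scope.
* **Aspiration.** The two dark wall bands in the top of the frame give
  four sub-pixel edges: the outer pair spans the known external diameter
  2*A* (scale), the inner pair gives *a*. The mouth plane is the median
  gel-surface row outside the pipette; *l* is the height of the meniscus
  apex (first dark row on the axis) above it.
* **YAP/TAZ.** Given binary nuclear and cell masks and a stain channel,
  nc_ratio = mean(nucleus)/mean(cytoplasm); the call is `in` above
  1 + *t*, `out` below 1 − *t*, `even` between, with *t* = 0.2 a
  documented convention (user-configurable), not a measured constant.
  Percentages use largest-remainder rounding to sum to exactly 100.

## Synthetic fixtures

Scenes are composed from analytic coverage functions (half-planes, discs,
a spherical-cap meniscus — only the apex height is metrologically
meaningful) anti-aliased at the pixel edge, then degraded by the noise
model: Gaussian blur σ = 1 px plus additive Gaussian noise at 2 % of the
dynamic range ("realistic" preset; a "clean" preset renders noise-free).
Defaults place the lab geometries at 0.01 mm/px on a 1000×800 canvas
(indentation) and 0.002 mm/px on 600×600 (aspiration). Ground truth
always satisfies the corresponding forward model exactly before
rasterisation. Every generator takes a single seed and is bit-identical
under (parameters, seed); no global random state is touched.

Simulated sessions apply multiplicative Gaussian noise to the observable
only (*δ* or *l*), never to the ground truth; the defaults (10 repeats,
3 % depth noise / 5 % length noise, ~14-point compression curves to
22.5 % strain) mirror a realistic bench protocol. What the fixtures do
*not* emulate: optical refraction through the water bath, uneven
illumination beyond a linear ramp, surface pile-up around the contact,
meniscus profile physics, dye chemistry, or segmentation of touching
cells. Passing round-trip tests therefore demonstrates the correctness of
the measurement chain on well-formed frames, not robustness to every
artefact of real imagery.

## Validation problem sizes

The shipped validation suite uses 25 indentation and 25 aspiration scenes
spanning 0.2–50 kPa, 200 simulated 10-repeat sessions, and 100-seed
constitutive studies — sizes at which the stochastic checks are stable
from seed to seed while the whole suite stays interactive (seconds).
Session recovery is judged against twice the session-level standard
error (SD/√10 of a single 10-repeat session): the per-measurement
estimator *E* ∝ δ⁻³ᐟ² carries an O(σ²) Jensen bias (~0.2 % at 3 % noise)
that is physically negligible but would dominate an SE shrunk by
unlimited replication; the meaningful claim is bias ≪ measurement-scale
uncertainty.

## Known limitations

* Adhesion (JKR/DMT), poroelastic creep and viscoelastic rate effects are
  outside all models; measurements are assumed quasi-static.
* The finite-diameter polynomial is an empirical fit; outside its fitted
  box it only warns.
* The aspiration model assumes a frictionless, flat, semi-infinite
  surface under the pipette; cell-scale aspiration and creep analysis are
  out of scope.
* The bundled reference tables are inputs for arithmetic-consistency
  checks only; nothing is calibrated against them.
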