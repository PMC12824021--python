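# Methods

## Constitutive model

The wall is modelled as a homogeneous, incompressible, hyperelastic solid.
The strain-energy density combines a Mooney–Rivlin/exponential isotropic
matrix with an exponential two-fiber-family term:

    W = c1 (I1 − 3) + D1 (exp(D2 (I1 − 3)) − 1)
      + K1/(2 K2) [exp(K2 (J4 − 1)²) + exp(K2 (J6 − 1)²) − 2]

The fiber families lie in the circumferential–axial plane at ±θ from the
circumferential direction, so for the shear-free states used throughout
(diagonal right Cauchy–Green tensor in the circumferential/axial/radial
frame) I4 = I6.  Incompressibility is imposed kinematically
(λ_r = 1/(λ_c λ_a)), which makes I3 = 1 and J4 = I4 exactly; the J-forms
are retained so that the energy stays well defined for any intermediate
non-isochoric state a caller might construct.  I2 is computed and exposed
but does not enter the energy.

Parameters: c1, D1, K1 are stress-like (kPa) and the response is
homogeneous of degree one in this triple — the load-bearing fact behind
the inverse algorithm.  D2, K2 are dimensionless exponents; θ is in
degrees, constrained to (0°, 45°) by fitting and allowed up to <90° in
storage for sensitivity runs.  K2 = 0 is replaced by a floor of 1e−6; the
energy then uses the analytic quadratic limit (K1/2)[(J4−1)² + (J6−1)²]
(the stress expression K1 (J4−1) exp(K2 (J4−1)²) is continuous through the
limit and needs no special case).  Exponential arguments above 500 raise
an explicit range error instead of returning infinity.

Plane-stress biaxial stresses are analytic: with λ_r eliminated,
σ_i = λ_i ∂W/∂λ_i, and the Lagrange pressure follows from σ_r = 0.
Uniaxial curves drive the transverse in-plane Cauchy stress to zero by a
nested Brent solve; strip-biaxial holds the transverse stretch at 1.

## Biaxial testing layer

Force-controlled protocols at circumferential:axial force ratios 1:1,
1:0.75, 0.75:1, 1:0.5, 0.5:1 with a 2.0 N maximal force emulate the
standard battery for ~2 cm × 2 cm aortic samples.  Forces convert to
engineering (first Piola–Kirchhoff) stress via the undeformed cross
section P = F/(edge × thickness) — the biaxial-rig convention, since
forces and undeformed dimensions are what the rig records.  Each load step
solves a 2-D root find for the in-plane stretches, warm-started along the
load path.

Fitting minimizes the pooled sum of squared engineering-stress residuals
(both directions, all protocols, equal weight) with scipy's
trust-region-reflective bounded least squares; bounds are c1, D1, D2,
K1 ≥ 0, K2 ≥ 1e−6, θ ∈ (0°, 45°).  The landscape is nonconvex and the
six parameters trade off (D1·D2 near-degeneracy at small strain), so eight
seeded multi-start restarts over log-uniform coefficient ranges are run
and the best residual wins, ties broken by lower K1.  The identification
contract is response recovery, not coefficient recovery: noiseless
generate-then-fit reproduces stresses pointwise to <1% of maximum stress
even when individual coefficients differ.  R² is computed about the pooled
mean of both stress components.

## Tube forward model

The imaging-based estimation needs only a map from (zero-pressure
geometry, pressure, axial stretch) to lumen perimeter.  This is provided
by the classical inflation–extension of an incompressible thick-walled
tube: r(R)² = r_i² + (R² − R_i²)/λ_z, λ_θ = r/R, with the pressure
integral P = ∫(σ_θ − σ_r)/r dr evaluated by fixed-order Gauss–Legendre
quadrature (order 16, configurable) over the reference wall.  The inverse
map (pressure → radius) is a safeguarded bracketing Brent solve with
radius tolerance 1e−10 mm; pressures beyond the material's inflation limit
raise an explicit error.  Transmural Cauchy stress profiles are
reconstructed from the traction conditions σ_r(lumen) = −P,
σ_r(outer) = 0.  Axial stretch defaults to 1.25 (20% axial shrinkage),
the literature average for the ascending aorta.  The model is quasi-static
and axisymmetric: no inertia, no bending, no residual-stress opening
angle, circular cross-sections only.

Validation oracles: the quadrature agrees with dense trapezoid
integration of the closed-form neo-Hookean integrand to 1e−6 relative;
at thickness/radius = 0.01 the mean hoop stress matches the Laplace
estimate P·r/t within 5%; wall volume is conserved to 1e−10 relative.

## Inverse estimation

Given a subject's diastolic/systolic cuff pressures and TEE lumen
perimeters, the zero-pressure inner radius is S × reference-perimeter/2π
with S ∈ (0, 1]; the zero-pressure thickness preserves wall cross-section
area under the axial shrink (area_0 = area_invivo × λ_z), consistent with
wall incompressibility.  The reference perimeter defaults to the systolic
(maximum) perimeter and is overridable per subject — only the product
S × reference enters the physics, so the convention rescales S, not the
recovered material.

Inner loop.  Because the stress response is homogeneous of degree one in
(c1, D1, K1), matching both perimeters reduces exactly to one scalar
equation: at matched perimeters the deformed radii are known
(r = perimeter/2π), so the pressures P^_dia(S), P^_sys(S) holding the
shrunk tube at those radii under the unscaled initial guess give
k(S) = P_dia/P^_dia(S) in closed form, and S must solve
P^_sys(S)/P^_dia(S) = P_sys/P_dia.  The log-ratio residual is scanned over
S ∈ (0.05, 1] at 97 points, each sign-change interval is resolved by
Brent's method, and the solution is verified against both perimeters
through the full forward model at relative tolerance 1e−5.

Non-uniqueness and selection.  The pressure-ratio curve can dip through
the target twice, so the two-observation inverse problem can admit two
exact (S, k) solutions — a genuine identifiability limit, not a numerical
artifact (surveyed on seeded virtual cohorts: roughly two-thirds of
subjects have two solutions).  The full solution set is reported; the
selected solution minimizes |log k|, i.e. the least stiffness adjustment
of the initial guess.  This encodes the clinical premise that the initial
guess (an ex vivo fit) is approximately scaled correctly.  Two
consequences follow and are tested: (i) the solution set, matched by S, is
exactly invariant to the stress scale of the initial guess (k scales
inversely, the products c1·k, D1·k, K1·k are unchanged); (ii) the
*selected* solution can change if the guess's scale is shifted far enough
to flip which root is nearer — with two observations no algorithm can do
better, and resolving the ambiguity needs either a third observation or a
prior on S.

A note on monotonicity: the systolic residual at fixed diastolic match is
not globally monotone in k.  As k → 0 the soft wall must be strongly
pre-stretched to carry diastolic pressure and sits on the steep branch of
the exponential, leaving little incremental compliance; as k → ∞ there is
no distension at all.  Both limits undershoot the systolic target, and the
residual rises through the solution in between.  The ratio formulation
sidesteps this entirely.

Middle and outer loops.  If no admissible (S, k) exists — typically when
the guess's anisotropy deviates strongly from the tissue's — K2 is stepped
by ±0.01 in an expanding alternating schedule (floored at the positive
floor), and when that budget is exhausted θ is stepped by ±1° within
(0°, 45°], restarting the K2 schedule at each θ.  The first feasible
solution terminates the search.  Defaults: 40 K2 corrections per θ, 45 θ
corrections.  Exhausting the budget raises an error carrying the full
residual trace.

Initial-guess settings: M01 uses each subject's own ex vivo coefficients;
M02 a common guess (the packaged median-stiffness subject's ex vivo fit);
M03 that guess with a 5% per-coefficient variation (the packaged printed
set, or a seeded signed ±5% pattern for custom bases).

## Stiffness metrics and statistics

Effective Young's moduli are slopes of proportional fits σ = E (λ − 1)
anchored through (1, 0), over 31 uniform stretches on [1.0, 1.3] under the
equibiaxial protocol by default (configurable to uniaxial or
strip-biaxial).  The estimator is a grid-weighted fit of a nonlinear
curve, so its value depends mildly (~1%) on grid density; the default grid
is part of the metric's definition.  The packaged published moduli are not
reproducible from the packaged coefficients under any of the three
protocols (the upstream loading protocol is not recoverable), so the
published values are used as inputs to the statistics layer, never
regenerated.

The anisotropy index AI = (YMc − YMa)/(½(YMc + YMa)) is bounded in
(−2, 2).  Descriptives are medians with interquartile ranges by linear
interpolation at positions 1 + (n−1)q — the convention pinned by
reproducing the published quartiles exactly.  The paired comparison is the
exact one-sided Wilcoxon signed-rank test: zero differences dropped,
average ranks for tied magnitudes, and the null distribution enumerated
over all 2ⁿ sign assignments (computed by integer polynomial convolution
on doubled ranks; n ≤ 25).  The effect size is r = Φ⁻¹(1 − p)/√n, the
standard-normal upper quantile of the exact one-sided p normalized by the
pair count — the one formula consistent with all four published (W, p, r)
triples.  Table output rounds half away from zero to 2 decimals.

## Synthetic data

Virtual subjects sample constitutive coefficients log-uniformly for the
stress-like triple (they span three orders of magnitude in the observed
cohort) and uniformly for D2 ∈ [0.5, 2.3], K2 ∈ [0.01, 15], θ ∈ [5°, 41°];
geometry and pressures sample the observed clinical spans (reference
perimeter 8–15 cm, thickness 1.2–2.8 mm, systolic 79–140 / diastolic
45–91 mmHg), true shrinkage S* ∈ [0.55, 0.90], axial stretch 1.25.  The
zero-pressure tube is built from S* and the reference perimeter, and the
forward model produces the perimeters a TEE examination would observe; the
sampled reference plays the role of the CT-derived anchor and need not
coincide with the systolic perimeter.  Perimeter noise is multiplicative
(echo tracing error scales with size), default CV 0 so that records
satisfy the forward model exactly; 1% is suggested for robustness studies.
Draws whose inflation fails are resampled with bounded retries, and
generation is deterministic in (seed, index).

What the generator does not emulate: non-circular cross-sections, regional
wall heterogeneity, imaging segmentation error structure, waveform shape
between diastole and systole, axial-stretch variability.  Passing round
trips therefore demonstrate correctness of the estimation machinery under
the stated model, not robustness to the full error budget of clinical
imaging.

## Known limitations

- The clinical cohort's subject AD5 is infeasible for the tube model under
  every initial-guess setting: its 22.5% cyclic distension at a 1.88×
  pressure ratio lies outside the achievable range for its near-isotropic
  coefficients (K1 = 0.01 kPa renders the K2/θ corrections ineffective).
  It is reported as a flagged infeasible row.
- The published stiffness table contains one internally inconsistent row
  (N3: printed RE −20.76% vs −17.67% recomputed from its own printed
  moduli); the package's worked-number checks document and skip that row,
  while still consuming the printed RE column verbatim for the descriptive
  and test statistics it feeds.
- With two observations per subject the inverse problem is at the edge of
  identifiability (see above); reported k and S inherit the min-|log k|
  selection and should be read jointly with the solution set when the
  initial guess's scale is uncertain.
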