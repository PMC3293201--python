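# Methods

`linefpt` models how narrow linear clearings ("seismic lines") alter the
movement of a coursing predator and, through movement, the rate at which it
encounters stationary prey and ultimately its functional response. This note
records the model, the numerical choices, and the limits of what the
simulation studies can show.

## The movement model

A predator relocated at a fix interval τ (default 5 min) is described by a
discrete random walk with, at each step,

* an exponential step length with class-specific mean α — classes are
  assigned from the distance of the step's start point to the nearest line
  centreline: **on** (≤ 27 m = 2.5 m half-width + 24.5 m GPS error buffer),
  **near** (27–50 m, 50 m being the assumed perception distance), **off**
  (> 50 m);
* a relative move direction ξ, the angle between the step heading and the
  bearing to the nearest line: uniform off lines; axial (period-π) von Mises
  with modes at ±90° (along the line, either way) with concentration κ_on
  when on a line; univariate von Mises with mode 0° (toward the line) with
  concentration κ_near when near a line and bias is enabled.

Steps shorter than 55 m are retained for step-length estimation but excluded
from direction fits, because GPS positioning error dominates headings at
that scale. All boundary ties classify toward the more line-associated class
(inclusive ≤, with a 1 nm floating-point guard).

Default ("wolf-like") parameters: α_on = 0.1466 km and α_off = α_near =
0.0922 km — the values implied by per-5-min mean-squared displacements of
0.043 and 0.017 km² via E[L²] = 2α² — with κ_on = 2, κ_near = 1, and mean
turning-angle cosines ψ_on = 0.43, ψ_off = 0.18. The axial/toward von Mises
forms are the natural reading of "continues along the line in either
direction" and "moves toward the line"; their exact normalisations matter
nowhere because all estimators condition on the known mode.

### Estimation

* α̂ is the sample mean (the exponential MLE); 90% CIs by non-parametric
  percentile bootstrap (1000 resamples, seeded).
* κ̂ solves I₁(κ)/I₀(κ) = R̄, with R̄ the mean resultant length toward the
  known mode (after angle doubling for the axial law); this is the exact
  likelihood maximiser. Uniformity (κ = 0) is tested by parametric
  bootstrap: B = 999 uniform samples of the same size. Because the
  likelihood-ratio statistic is a monotone function of max(R̄, 0) with a
  point mass at zero, the null ordering uses R̄ itself; this breaks the
  boundary ties exactly and makes the p-values uniform under the null while
  rejecting for the same samples.
* Persistence diagnostics: Fisher–Lee circular correlation of successive
  headings (computed via the O(n) expansion of the pairwise double sum), and
  the Patlak correction 1/(1 − ψ) quantifying how much directional
  persistence would inflate a diffusion coefficient (+22% off, +75% on lines
  at the default ψ values). The PDE coefficients are *not* rescaled by this
  factor; it is reported as a sensitivity.

## From parameters to PDE coefficients

The walk's diffusion limit gives, per class,

* isotropic D = α²/(2τ) off and near lines;
* on lines, an anisotropic tensor with principal values
  D_par = D_on(1 + R̄₂), D_perp = D_on(1 − R̄₂), R̄₂ = I₁(κ_on)/I₀(κ_on),
  rotated into grid axes by the local line orientation. This is the exact
  second-moment limit of the axial walk (trace 2 D_on preserved; isotropy at
  κ_on → 0, one-dimensional transport at κ_on → ∞). A config switch
  (`cross_diffusion="off_perp"`) instead pins the across-line diffusivity to
  the off-line value, since the two readings cannot be distinguished from
  the available description;
* in the biased model, an advection of magnitude
  |c| = (α_near/τ)·I₁(κ_near)/I₀(κ_near) in near cells, pointing at the
  nearest line (the mean per-step displacement of the toward-biased walk).

Cells are classed by their centre (simple and convergent under refinement);
cells within perception range of several lines take the nearest line's
orientation, exact ties to the lowest segment index.

## The first-passage problem

The mean first-passage time T(x) to any prey solves

    −∇·(D ∇T) + c·∇T = 1,   T = 0 on prey discs (radius r = 100 m),
                            zero normal flux on the home-range boundary,

on a square domain (25 × 25 km at full scale). The spatial average T̄ (with
uniform weight over the whole domain, absorbing discs included at value 0)
gives the encounter rate E = 1/T̄.

**Advection sign.** For a microscopic walk whose near-line steps drift
toward the line, the textbook backward-equation form would carry the
opposite advection sign (−c·∇T on this side). The equation above is the
form used in this analysis tradition, and it is the form under which the
biased model produces *lower* encounter rates than the purely anisotropic
model — a searcher leashed to the line corridor re-searches the same band
and misses prey placed away from lines. A direct walker-ensemble simulation
of the toward-line step rule instead mildly *raises* encounter rates under
these parameter values, so the two readings of "bias toward lines" are not
equivalent; the package implements the equation as written above and uses
the walker ensemble as an oracle only for the no-response and anisotropic
models. Both behaviours are reproducible with `first_passage_ensemble`.

**Discretisation.** Cell-centred finite volumes: face-averaged coefficients
for the divergence terms; the cross term ∂x(d_xy ∂y T) + ∂y(d_xy ∂x T) as a
composition of central differences with reflected ghost cells (a compact
9-point stencil); first-order upwinding for advection; prey discs rasterised
by cell-centre inclusion (a disc capturing no cell is inflated to its
nearest cell and a warning issued); an optional boolean mask carves
non-rectangular domains with reflecting walls, used for the disc-domain
benchmark. Direct sparse LU factorisation, with an ILU-preconditioned
BiCGStab fallback; the normwise backward error must not exceed 1e−10.

Accuracy, measured not assumed: on the annulus benchmark (R = 1 km
reflecting disc, central absorbing disc r = 0.1 km, D = 0.05 km²/h) the
solution at ρ = 0.5 km is within ~1.3% of the closed form
(R²/2D)·ln(ρ/r) − (ρ² − r²)/(4D) at h = 5 m; and on an anisotropic
multi-line fixture the surface agrees with 10⁴-walker Monte-Carlo
first-passage estimates within Monte-Carlo error. That fixture is designed
inside the diffusion limit's validity regime — step length below ~1/15 of
the perception radius and below the 27 m on-band half-width, axis-aligned
lines (no cross-diffusion), probes away from absorbing discs and edges —
because the PDE only claims to approximate the walk in that regime; the
residual discrete-walk capture deficit scales with step length over disc
radius.

## Simulation campaigns

* Campaign 1 (model comparison): prey density fixed at 0.16 km⁻², all three
  movement models across line densities {0, 2.23, 4.46, 8.91} km/km²
  (half/one/two times the 4.46 baseline, spanning the ≈2–9 study range).
* Campaign 2 (regression factorial): prey densities {0.5, 1, 1.5, 2, 2.5,
  3} km⁻² × the four line densities × 10 replicates under the anisotropic
  model = 240 solutions.

Seeding is hierarchical from a base seed; within a replicate the landscape
realisation is shared across movement models and prey densities, and the
prey placement is shared across line densities, so model and density
contrasts are paired. Landscapes are Poisson line processes (uniform random
orientation — the orientation law of real line networks is not specified,
so uniformity is the default and a config choice) whose realised density is
made exact by trimming the final chord.

The package runs these campaigns at any scale; the test suite and the
acceptance script use 10 × 10 km domains with 50 m cells and 2–3 replicates,
which keeps the full pipeline under a few minutes while preserving every
qualitative contrast (the flat no-response line, the increasing anisotropic
line, the bias deficit, and the positive prey × line interaction). The fitted
regression coefficients at this scale are not numerically the same as at
25 × 25 km — encounter rates scale with domain and prey configuration — but
model identities and signs are stable.

## Encounter-rate models and selection

Eleven candidate laws E(N, S) (linear, quadratic and exponential in S;
directed N, random N², mixtures and powers of N; and multivariate
power-plus-interaction forms) are fit by nonlinear least squares with a
deterministic multi-start (exponents b ∈ {0.5, 1, 1.5, 2} plus a log-log
regression seed; A, b kept positive via log-parameterisation) and ranked by
the least-squares AIC n·ln(RSS/n) + 2k (AICc by flag). RSS is floored at
n·(1e−8·rms E)² so that on effectively noiseless data nested exact fits are
ordered purely by parameter count. Replicates enter as rows (n = 240 at full
scale), not averaged.

Selection calibration is verified by simulation: data generated from each
candidate (1% multiplicative Gaussian noise) must be recovered as AIC-best,
or beaten only by a model that nests the truth, in ≥ 90% of replicates. The
non-C3 truth coefficients used in that study are chosen so the families are
distinguishable at the 1% noise level (e.g. the exponential-in-S truth uses
b = 0.15, since a gentler curvature is quadratic-indistinguishable on the
design support); the C3 truth uses the reference coefficients A = 7.43e−2,
b = 1.15, β₁ = 2.74e−3.

## Functional response

The disc equation f = E/(1 + E·T_h) converts encounter rates to kill rates,
with handling times 10.6 h (small-bodied) and 20.4 h (large-bodied prey).
With the interaction law E = A N^b (1 + (β₁/A) S) and β₁ > 0, the kill-rate
ratio f(N; S)/f(N; 0) is ≥ 1, decreases with prey density (at high N the
predator is handling-limited, so mobility matters less), increases with S,
and is larger for the shorter handling time — all asserted as properties of
the fitted composition rather than as numbers, since no reference kill-rate
values exist to compare against.

## What the synthetic data do and do not show

The generators reproduce exactly the statistical structure the estimators
assume: exponential lengths, the three-class direction laws, Poisson line
placement, uniform prey. Passing tests therefore demonstrate internal
consistency of the pipeline (estimators recover generating values; the PDE
agrees with the microscopic walk; selection recovers generating laws) — not
that real telemetry satisfies those assumptions. Known departures in real
data that are out of scope here: directional persistence between steps
(ψ > 0, handled only diagnostically via the Patlak factor), GPS dropouts,
curved or branching line networks, grid-aligned line orientations, moving
prey, and kill success below 1.

## Numerical conventions

Internal units are kilometres and hours; τ is quoted in minutes, angles in
degrees at interfaces (radians internally, wrapped to (−180°, 180°]).
Compass convention (North = 0°, clockwise) at the track interface. All
stochastic components take explicit integer seeds; campaign runs derive
child seeds from (base seed, factor indices) via `numpy` seed sequences, so
any run is reproducible in isolation.
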