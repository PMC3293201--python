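# linefpt

Mechanistic first-passage-time analysis of how linear landscape features —
seismic lines, the narrow forest clearings cut for energy exploration —
alter the movement of a coursing predator (wolves are the motivating case),
its encounter rate with prey, and ultimately its functional response.

Telemetry studies show wolves travel faster along seismic lines and tend to
stay on them. `linefpt` turns that observation into a quantitative chain:

1. **Movement statistics** (`movestats`). From 5-min GPS fixes, classify
   locations as on (≤ 27 m of a centreline), near (27–50 m) or off a line;
   fit exponential step lengths (mean α, MLE = sample mean) per class with
   bootstrap CIs; fit von Mises concentrations to relative move directions
   ξ — an axial law ∝ exp(κ_on cos 2(ξ − 90°)) for along-line movement, a
   univariate law ∝ exp(κ_near cos ξ) for attraction toward lines — with
   parametric-bootstrap likelihood-ratio tests of κ = 0.
2. **Diffusion coefficients** (`coeffs`). The walk's diffusion limit:
   isotropic D = α²/(2τ) off lines; on lines an anisotropic tensor with
   principal values D_on(1 ± R̄₂), R̄₂ = I₁(κ_on)/I₀(κ_on); optionally an
   advection |c| = (α_near/τ)·I₁(κ_near)/I₀(κ_near) toward the nearest line.
3. **Mean first passage time** (`solver`). T(x), the expected search time to
   first come within r = 100 m of any prey, solves
   −∇·(D∇T) + c·∇T = 1 with T = 0 on prey discs and a reflecting home-range
   boundary; the encounter rate is E = 1/T̄ with T̄ the domain average of T.
4. **Encounter-rate laws and selection** (`experiment`, `encmodels`).
   Factorial campaigns over prey density N and line density S; eleven
   candidate laws E(N, S) fit by nonlinear least squares and ranked by AIC.
5. **Functional response** (`funcresp`). The Holling disc equation
   f = E/(1 + E·T_h) and the kill-rate ratio between landscapes with and
   without lines.

Synthetic generators (`synthetic`) produce landscapes (Poisson line process
at an exact line density), prey (complete spatial randomness) and GPS tracks
with precisely the statistical structure the estimators assume, plus a
walker-ensemble Monte-Carlo first-passage oracle used to validate the
solver.

## Worked example

Solving the first-passage problem on a 10 × 10 km landscape (50 m grid,
wolf-like movement parameters, 16 prey at 0.16 km⁻²), with and without
seismic lines at the 4.46 km km⁻² baseline density:

```text
$ python examples/03_mfpt_surface.py
no lines : T̄ =   67.75 h, E = 0.01476 h⁻¹, max T = 147.2 h
S = 4.46 : T̄ =   54.31 h, E = 0.01841 h⁻¹, max T = 116.6 h
```

The average search time drops by ~20% when lines are present: enhanced
along-line diffusion lets the searcher reach unsearched ground instead of
re-visiting old ground. Running the reduced prey × line-density factorial
and ranking the multivariate encounter-rate candidates:

```text
$ python examples/04_encounter_campaign.py
model  k     rss        aic  delta_aic
   C3  3 0.02503 -356.83422    0.00000
   C2  3 0.02586 -355.26839    1.56582
   C4  4 0.02501 -354.86975    1.96447
   C1  2 0.16425 -268.52263   88.31159
best model: C3 with interaction beta1 = 0.00642
```

The winner is the interaction law E = A·N^b + β₁·N^b·S with β₁ > 0 and
b > 1: encounter rates rise faster than linearly with prey density (the
type-III signature) and seismic lines amplify the effect. Feeding this law
through the disc equation (`examples/05_functional_response.py`) shows kill
-rate ratios above 1 that are largest at low prey density and for
short-handling prey — scarce, small-bodied prey bear the brunt of the
line effect.

The other examples (`01`, `02`) generate a landscape-plus-track and recover
the generating movement parameters from the simulated fixes.

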