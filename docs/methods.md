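# Methods

## Scope and model

`lipocharge` models the pH-dependent surface charge of zwitterionic
phosphatidylcholine (PC) membranes in 1:1 sodium electrolytes and estimates
the four ion–lipid association constants from σ(pH) titration data.

The PC head group exposes two ionogenic sites: the phosphate A⁻ (–PO⁻) and
the trimethylammonium B⁺ (–N⁺(CH₃)₃). Four mass-action equilibria are
assumed:

    A⁻ + H⁺  ⇌ AH      K_AH  = a_AH /(a_A⁻ · a_H)
    A⁻ + Na⁺ ⇌ ANa     K_ANa = a_ANa/(a_A⁻ · a_Na)
    B⁺ + OH⁻ ⇌ BOH     K_BOH = a_BOH/(a_B⁺ · a_OH)
    B⁺ + X⁻  ⇌ BX      K_BX  = a_BX /(a_B⁺ · a_X)

Site concentrations are areal (mol m⁻²), ion concentrations volumetric
(mol m⁻³); the constants therefore carry units m³ mol⁻¹. With both sites
conserved at C_PC = 1/(A·N_A), the free-site fractions follow in closed
form and the net surface charge density is

    δ(pH)/F = C_PC/(1 + K_BOH·a_OH + K_BX·a_X)
            − C_PC/(1 + K_AH·a_H + K_ANa·a_Na),

with a_H = 10^(3−pH) and a_OH = K_W/a_H. δ is strictly decreasing in pH
when all constants are positive, so the isoelectric point (IEP) is unique;
|δ| is bounded by C_PC·F ≈ 0.229 C m⁻² at 70 Å² per lipid.

Assumptions: unit activity coefficients (reasonable at 155 mol m⁻³);
Na⁺ is the only competing cation and X⁻ the only competing anion (titrant
counter-ions are ignored); no Stern-layer or multi-site structure; binding
does not change the area per lipid.

## Electrokinetic chain

Mobility → zeta uses Henry's relation ζ = 3µη/(2εε₀·f(κa)). For ~0.2 µm
liposomes in ≥ millimolar salt, κa ≫ 1 and f(κa) = 1.5, reducing to the
Smoluchowski form ζ = µη/(εε₀). The Henry factor is exposed as a scalar
parameter; the full f(κa) interpolation is deliberately not implemented
because every supported scenario sits in the thin-double-layer limit.

Mobility → charge density treats the particle plus diffuse layer as a
parallel-plate condenser of spacing d: δ = ηµ/d, equivalently δ = εε₀ζ/d.
All relations are used in SI form. The spacing d defaults to the Debye
length κ⁻¹ = sqrt(εε₀ k_B T/(2 N_A e² I)) with ionic strength I equal to
the salt concentration; H⁺/OH⁻ contributions to I (≤ 10 vs 155 mol m⁻³
over the measured pH range) are neglected, a ≤ 3% effect on d that is
uniform across a titration and therefore immaterial to constant estimation.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 298.15 | K | measurement temperature (25 °C) |
| viscosity η | 8.903e-4 | Pa s | water at 25 °C |
| relative permittivity ε | 78.36 | – | water at 25 °C |
| K_W | 1e-8 | (mol m⁻³)² | 1e-14 mol² L⁻² at 25 °C |
| area per lipid A | 70 | Å² | PC in a fluid bilayer → C_PC ≈ 2.372e-6 mol m⁻² |
| salt concentration | 155 | mol m⁻³ | physiological ionic strength, the study design |
| Henry factor | 1.5 | – | Smoluchowski limit |
| F | 96485.332 | C mol⁻¹ | fixed physical constant |

All are overridable through `Medium`/`Electrolyte`/`Membrane`, `RunConfig`,
or estimator parameters.

## Linearized estimation route

At high a_H the closed form linearizes (first order in K_BOH·K_W/a_H and in
1/(K_AH·a_H)) to the acid branch

    y_a = δ·a_H/F ≈ [C_PC/(1+K_BX a_X)]·a_H
                   − [C_PC K_BOH K_W/(1+K_BX a_X)² + C_PC/K_AH],

and at low a_H (first order in K_AH·a_H and in a_H(1+K_BX a_X)/(K_BOH K_W))
to the base branch

    y_b = δ/(F·a_H) ≈ −[C_PC/(1+K_ANa a_Na)]·(1/a_H)
                     + [C_PC K_AH/(1+K_ANa a_Na)² + C_PC/(K_BOH K_W)].

OLS slopes give K_BX and K_ANa directly; the two intercepts are then solved
simultaneously for (K_AH, K_BOH), which reduces to a quadratic in K_AH.

**Root ambiguity.** The intercept system generically has *two* positive
solutions that reproduce exactly the same asymptote lines: the pair
(u, v) = (K_AH, K_BOH·K_W) and a spurious pair u′ = P(Q+uv)/(v(P+uv)) with
P = (1+K_BX a_X)², Q = (1+K_ANa a_Na)² (derived symbolically; the two
candidates always straddle the threshold u·v = √(PQ)). Slopes and
intercepts alone cannot distinguish them. The default resolution is the
*strong protolytic-association branch* (larger K_AH root): chemically, H⁺
binds phosphate and OH⁻ binds trimethylammonium orders of magnitude more
strongly than Na⁺/X⁻ do, i.e. K_AH·K_BOH·K_W ≫ (1+K_BX a_X)(1+K_ANa a_Na),
which holds by one to two orders of magnitude for all reported PC
parameter sets. A data-driven alternative (`root_selection="curve_rmse"`,
choosing the candidate whose full model better fits the source curve) is
available; it is exact when the fits are consistent, but with
truncation-biased coefficients it can prefer the unphysical branch, so it
is not the default.

**Inconsistent intercepts.** Window-OLS coefficient bias can push the two
intercept equations into mutual inconsistency (negative discriminant or no
positive pair) — this occurs for the weak-acid-binding salts (NaNO₃, NaI)
on the study grid. The orchestrated pipeline then falls back to a
least-squares compromise over log₁₀(K_AH), log₁₀(K_BOH·K_W), minimizing the
two relative equation residuals, and flags `intercept_fallback` in the
diagnostics. The low-level `constants_from_linear_fits` keeps the strict
behaviour (raises `NonPhysicalRootError`) unless the fallback is enabled.

**Fit windows.** The acid-branch expansion parameter
K_BOH·K_W/(a_H(1+K_BX a_X)) grows by 10^0.3 per pH step, so the asymptote
is only approached at the lowest measured pH. Calibrating on noiseless
model curves generated from the four reported parameter sets (grid pH 2–8,
step 0.3), the truncation bias of slope-derived K_BX grows from 4–21%
using the two lowest grid points (acid window [2.0, 2.3]) to 23–95% over
[2.0, 3.5], where the intercept system also loses positive roots for two
of the four salts. The defaults are therefore acid [2.0, 2.3] and base
[5.5, 8.0]; both are configuration options, are reported in every result,
and should be widened only with a denser or lower-reaching pH grid. For
NaI (K_AH = 13 m³ mol⁻¹) the acid asymptote would require pH ≪ 1.9, below
the measured range, so its K_BX carries an irreducible ≈ +21% truncation
bias through this route — a property of the asymptotic approximation
itself, quantified in the test suite, not a defect of the implementation.

Points above pH 8 are excluded from all fits by default (`exclude_above`):
the model is not intended to describe that region and experimental scatter
grows there. OLS is unweighted by default; 1/sd² weighting is available
when per-point SDs are present.

## Nonlinear refit

The closed-form model is refit directly by Levenberg–Marquardt over
t = log₁₀(K) (enforcing positivity), initialized from the linearized
estimate (or a generic magnitude-correct point if that route fails, or a
user-supplied start). Inside the residual function the exponents are
clipped to ±30 so that optimizer exploration cannot overflow. Convergence
tolerances are xtol = ftol = gtol = 1e-15; the fit is deterministic given
data and initialization. On noiseless model data the generating constants
are recovered to machine precision (tested to ≤ 0.1%, observed ~1e-15
relative). From strongly perturbed starts the optimizer can occasionally
settle in a shallow basin where K_BOH is driven small (its influence on the
pH ≤ 8 window is weak); on noiseless data such solutions are detectable by
a non-zero residual, and the acceptance script restarts from fresh
perturbations until the residual is numerically zero.

## Isoelectric point

Bisection on pH ∈ [0, 14] (monotonicity guarantees bracketing and
uniqueness), to xtol = 1e-13 pH, giving |δ| < 1e-12 C m⁻² at the root.
When δ does not change sign on [0, 14] — including the degenerate all-zero
constants case — `NoIsoelectricPointError` is raised.

## Synthetic data generator

The generator emulates the study design: pH grid 2.0–9.5 in 0.3 steps
(26 points), three replicates per point, reported as replicate mean ±
sample SD. Noise is i.i.d. Gaussian and homoscedastic, applied either in σ
(default SD 5e-4 C m⁻², ~4% of the low-pH NaCl signal, the magnitude class
of typical reported error bars) or in mobility for instrument-level
generation (µ = δ·d/η with d the Debye length). Gaussian homoscedastic
noise is the minimal assumption consistent with mean ± SD reporting.

What the generator does *not* emulate: pH-dependent heteroscedasticity
(real scatter grows above pH 8), pH-measurement error (noise is applied to
the observable only), liposome polydispersity and size drift, electrode or
instrument drift, and activity-coefficient effects. Parameter-recovery
results on these synthetic data therefore demonstrate the identifiability
and correctness of the estimation machinery under the stated noise model,
not the accuracy of the published constants for real membranes.

## Numerical choices

* OLS via `numpy.linalg.lstsq` on the design matrix; r² clipped to [0, 1];
  exact for collinear input.
* Quadratic discriminants within 1e-12·a₁² of zero are treated as a double
  root (numerically marginal case).
* Slope-derived constants within rounding of zero are clamped to 0 (a
  non-adsorbing ion); genuinely negative values raise
  `NonPhysicalRootError`.
* Ranking ties (equal K_BX) keep input order and set a warning flag.
* Duplicate pH rows in input files are averaged with a warning; rows are
  sorted by pH.
* Seeds feed `numpy.random.default_rng`; identical seeds give
  byte-identical CSV output.

## Known limitations

* The linearized route's truncation bias is irreducible on the standard
  grid for weakly H⁺-binding systems (see above); use the nonlinear route
  (the default) for quantitative constants.
* The model ignores surface-potential feedback on interfacial ion
  concentrations (no Boltzmann accumulation factor); constants are
  therefore *apparent* constants at the working ionic strength and are not
  transferable across concentrations.
* Conversion of mobility to σ depends linearly on the assumed condenser
  spacing d; the default (Debye length at the ambient salt concentration)
  is a convention, and any constant multiplicative error in d rescales σ
  and the fitted C_PC-relative quantities accordingly.
* Only 1:1 sodium salts are supported; divalent competition and mixed
  electrolytes are out of scope.
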