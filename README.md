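# lipocharge

Membrane electrokinetics and ion-binding equilibria of phosphatidylcholine
(PC) liposomes.

Microelectrophoresis is the workhorse method for probing how electrolyte
ions adsorb to lipid membranes: liposome electrophoretic mobility µ is
measured as a function of pH, converted to a surface charge density σ, and
the σ(pH) titration curve is interpreted with a mass-action binding model.
`lipocharge` implements that whole chain for zwitterionic PC membranes in
1:1 sodium salts (NaCl, NaBr, NaNO₃, NaI — the Hofmeister anion series):

* **Electrokinetics** — Smoluchowski-regime conversions between mobility,
  zeta potential and surface charge density, with Debye-length computation:
  ζ = 3µη/(2εε₀ f(κa)) with f(κa) = 1.5, and the parallel-plate condenser
  relation δ = ηµ/d = εε₀ζ/d.
* **Four-equilibrium binding model** — the PC head group exposes a
  phosphate (A⁻) and a trimethylammonium (B⁺) site; H⁺/Na⁺ bind the former,
  OH⁻/X⁻ the latter. With association constants K (m³ mol⁻¹), volumetric ion
  concentrations a (mol m⁻³) and the PC surface concentration
  C_PC = 1/(A·N_A) (70 Å² per lipid), the net charge density is

      δ(pH)/F = C_PC/(1 + K_BOH·a_OH + K_BX·a_X)
              − C_PC/(1 + K_AH·a_H + K_ANa·a_Na),

  strictly decreasing in pH, with a unique isoelectric point.
* **Constant estimation** — the historical linearized route (asymptotic
  acid/base branch regressions plus intercept algebra) and a nonlinear
  least-squares refit of the closed form, wrapped in a scikit-learn style
  estimator (`IonBindingModel.fit(pH, sigma)` → `constants_`, `predict`).
* **Synthetic data** — a generator emulating the study design (155 mol m⁻³
  salts, pH 2–9.5 every 0.3 units, three replicates, Gaussian noise), so the
  entire pipeline is testable without any experimental download.
* **CLI** — `lipocharge convert | fit | simulate | iep | rank` for shell use
  on titration CSVs.

## Worked example

Simulate a noisy NaBr titration with the published constants, refit it, and
inspect the result:

```python
from lipocharge import IonBindingModel, SyntheticSpec, generate_titration

spec = SyntheticSpec.for_salt("NaBr", noise_sd=5e-4, seed=0)
curve = generate_titration(spec)
model = IonBindingModel(salt="NaBr").fit(curve.pH, curve.sigma)
k = model.constants_
print(f"K_AH  = {k.K_AH:8.1f} m^3/mol")
print(f"K_ANa = {k.K_ANa:8.3f} m^3/mol")
print(f"K_BOH = {k.K_BOH:8.2e} m^3/mol")
print(f"K_BX  = {k.K_BX:8.3f} m^3/mol")
print(f"IEP   = {model.isoelectric_point():.2f}")
print(f"RMSE  = {model.rmse_:.2e} C m^-2")
```

prints

```
K_AH  =    252.4 m^3/mol
K_ANa =    0.199 m^3/mol
K_BOH = 3.47e+09 m^3/mol
K_BX  =    0.136 m^3/mol
IEP   = 3.45
RMSE  = 1.96e-04 C m^-2
```

The generating constants were K_AH = 264, K_ANa = 0.197, K_BOH = 3.54e9,
K_BX = 0.133 m³ mol⁻¹: with ~4% measurement noise every constant is
recovered within a few percent, the membrane's isoelectric point sits at
pH ≈ 3.5, and the residual RMSE (≈2e-4 C m⁻², i.e. noise_sd/√3 of the
replicate means) shows the fit reaches the noise floor.

Anion adsorption strength ranks by K_BX: `lipocharge rank --reference`
reports the order I⁻ > NO₃⁻ > Br⁻ > Cl⁻, the Hofmeister series, with a
Spearman radius–affinity correlation of 0.8 across the four anions.

From a shell the same round trip is:

```sh
lipocharge simulate --salt NaBr --noise-sd 0 nabr.csv
lipocharge fit --salt NaBr nabr.csv        # constants JSON on stdout
lipocharge iep --salt NaCl                 # -> 3.698649
```

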