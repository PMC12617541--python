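# cugel

Modelling copper-ion release through pH-responsive hydrogel coatings on
intrauterine devices (IUDs).

## The problem

Copper IUDs work by releasing Cu²⁺ as a spermicide, but they release it
continuously, which drives chronic inflammation and side effects. The
vaginal environment is acidic at rest (pH ≈ 4) and rises to pH ≈ 7 during
intercourse — exactly when the copper dose is needed. Coating the copper
element with a pH-responsive hydrogel can gate the release:

* a **polyacid gel** (polyacrylamide, PAAm) ionizes and **swells** at pH 7,
  opening its mesh so Cu²⁺ diffuses through;
* a **polybasic gel** (chitosan) is swollen at pH 4 and **shrinks** at
  pH 7, partially uncovering the copper surface.

At pH 4 both coatings act as steric barriers that keep the ions confined at
the copper surface. `cugel` asks the design question quantitatively: for
which coating thickness does the fluid stay below the spermicidal threshold
C* = 10⁻⁶ M at pH 4 yet reach it within 8 h at pH 7?

## The model

The coated element is a cylindrical copper sleeve (lateral area
A = 200 mm²) with an annular gel coating, inside a closed, well-mixed fluid
compartment of volume V = 7.5 mL. Corrosion injects Cu²⁺ at constant molar
flux

> J = ṁ / (M_Cu · A) = 4.55 × 10⁻⁸ mol m⁻² s⁻¹  for ṁ = 50 µg/day,

a zeroth-order "surface reaction" at the inner boundary. In the gel annulus
the concentration C(r, t) obeys Fick's second law in radial coordinates,

> R ∂C/∂t = (1/r) ∂/∂r ( r D ∂C/∂r ),

with retardation R = 1 + K_p when linear reversible sorption (partition
constant K_p) is active — chitosan is a good Cu²⁺ sorbent at pH 4. At the
outer face the concentration is continuous with the fluid (partition
coefficient 1) and the exchanged flux feeds the compartment balance
V dC_f/dt; nothing leaves the compartment (no-flux wall). Raising the pH
deforms the coating anisotropically using measured axial/radial variations
(PAAm +27.6 %/+14.1 %, chitosan −28.6 %/−18.1 %); the axially shrunken
chitosan leaves a fraction 0.286 of the copper injecting J directly into
the fluid.

The discretization is a conservative finite-volume scheme (geometric radial
grid refined toward the copper, backward Euler or Crank–Nicolson), so the
mole ledger *injected = gel + fluid + adsorbed* closes to machine precision
at every step.

Around the solver the package provides swelling-curve analysis (ratio,
first-order kinetics m(t) = m∞ + (m₀ − m∞)e^(−kt), plateau time, 25-day
degradation, cyclic reversibility), a seeded synthetic-data generator that
emulates the wet-lab campaign (triplicate masses, caliper dimensions,
colorimetric assay), and a dose pipeline sweeping coating thickness.

## Worked example

```python
from cugel import ScenarioSpec, default_config, run_scenario

cfg = default_config()
for material in ("paam", "chitosan"):
    for ph in ("4", "7"):
        row = run_scenario(ScenarioSpec(cfg, material, ph, thickness_mm=2.0))
        print(material, ph, f"{row.fluid_conc_8h_M:.3e} M")
```

prints

```
paam 4 6.790e-21 M
paam 7 2.705e-05 M
chitosan 4 6.708e-21 M
chitosan 7 3.298e-05 M
```

At pH 4 the 2-mm coatings confine the ions at the copper surface (the
penetration depth √(4Dt) ≈ 0.34 mm is well inside the coating, so the fluid
concentration is effectively zero). At pH 7 both materials deliver a few
tens of micromolar after 8 h — 27–33× the 10⁻⁶ M spermicidal threshold.
The `examples/` directory holds one short script per capability (flux
conversion, swelling fit, release simulation, thickness sweep, synthetic
campaign); each prints what it computes and what the numbers mean. A thin
CLI mirrors the pipeline: `cugel simulate`, `cugel sweep`,
`cugel swell-fit`, `cugel synth`.

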