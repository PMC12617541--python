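# Methods

## Model reduction

The physical device is a T-shaped IUD whose copper element sits in a
uterine cavity of irregular 3-D shape. `cugel` reduces this to a
one-dimensional radial problem: a cylindrical copper sleeve (radius 1.5 mm,
length 21.22 mm, chosen so the lateral area is the nominal 200 mm² copper
area; the individual radius/length split is a modelling convenience), an
annular gel coating, and a single closed, well-mixed fluid compartment.
The reduction is justified by what the model is asked to produce: a
*volume-averaged* fluid concentration after 8 h. A well-mixed compartment
reproduces that observable exactly in the fast-mixing limit, and the
no-flux cavity wall translates into a closed mole balance. No claim is made
about spatial concentration fields in the cavity.

## Governing equations

Free Cu²⁺ concentration C(r, t) in the gel annulus a ≤ r ≤ b:

    (1 + K_p) ∂C/∂t = (1/r) ∂/∂r ( r D ∂C/∂r )

* **Inner boundary** (r = a): constant inward molar flux J over the
  gel-covered area. J is derived from the daily release figure:
  J = (50 µg/day) / (63.546 g/mol) / 86400 s / (2×10⁻⁴ m²)
  = 4.55×10⁻⁸ mol m⁻² s⁻¹. The flux is zeroth-order (independent of the
  local concentration): corrosion does not slow down as ions accumulate.
* **Outer boundary** (r = b): concentration continuity with the fluid
  (gel/fluid partition coefficient fixed at 1); the exchanged flux enters
  the compartment balance V dC_f/dt = Φ_out + J·A_exposed.
* **Exposed pathway**: when an axially shrunken coating covers only a
  fraction of the sleeve, the uncovered fraction of the copper area injects
  J directly into the fluid.
* **Closed compartment**: no sink anywhere; total moles grow linearly as
  J·A·t.

Adsorption (chitosan at pH 4) is an instantaneous linear isotherm: sorbed
concentration K_p·C, giving the retardation factor above. The capacity
parameter (100 mol/m³ default) marks the range where a linear isotherm is
sensible; it does not enter the linear dynamics. A kinetic
(exchange-rate) model was rejected because no data in scope could identify
the extra rate constant, and a Langmuir isotherm because the source
material supports only the qualitative statement that protonated chitosan
sorbs copper.

Electromigration is deliberately absent: the model is dilute-species
diffusion only, and Cu²⁺ carries no charge-transport physics.

## Deformation

Deformation is an instantaneous equilibrium state per pH, applied from the
pH-4 reference: thickness scales with the radial percent variation, length
with the axial one (PAAm +27.6 %/+14.1 %; chitosan −28.6 %/−18.1 %, both
axially dominant, consistent with anisotropic deformation of cylindrical
gels). The exposed copper fraction is max(0, 1 − L_gel/L_sleeve) — 0.286
for chitosan at pH 7. Static deformation matches the two fixed geometries
the release predictions refer to; the swelling kinetics module shows the
transition completes in ~4 h, so an 8-h horizon spends most of its time
near equilibrium. Gel mass loss by degradation is likewise negligible over
8 h (chitosan rate 0.3 day⁻¹ → <1% in 8 h) and is off by default in the
transport geometry.

## Discretization

Conservative finite volumes on a geometric radial grid (default 100 cells,
width ratio 1.03 refining toward the copper surface, where the pH-4
boundary layer lives). Face fluxes use two-point differences between cell
centers; the fluid compartment is the (n+1)-th unknown, coupled through the
outer-face conductance. Because every face flux appears with opposite signs
in exactly two balance equations, the total-mole ledger

    injected = Σ_i V_i (1 + K_p) C_i···(free + sorbed) + V C_f

telescopes exactly; the reported residual (|injected − held|/injected,
default tolerance 10⁻⁶) is observed at 10⁻¹³–10⁻¹⁰, i.e. linear-solver
roundoff, independent of grid resolution.

Time stepping is backward Euler by default (unconditionally stable,
first-order, adequate for smooth monotone solutions); Crank–Nicolson is
available and agrees within 1% at defaults. The constant system matrix is
LU-factorized once per run, so the default 2880-step, 101-unknown run takes
tens of milliseconds. Halving dt and doubling the cell count moves the 8-h
fluid concentration by <0.5%. Coatings thinner than 1 µm are treated as
fully exposed copper (pure well-mixed release) — a radial grid across them
would be meaningless.

Useful analytic anchors, used as test oracles:

* **Well-mixed bound**: C_f(t) ≤ J·A·t/V always. The exact D → ∞ limit is
  J·A·t/(V + V_gel) because the gel, in equilibrium with the fluid at
  partition 1, retains its volumetric share (~8% for a 2-mm coating). The
  bound J·A·t/V itself is approached only when V_gel ≪ V.
* **Penetration depth**: √(4Dt) ≈ 0.34 mm for D = 10⁻¹² m²/s over 8 h —
  the confinement regime at pH 4.
* **Dense reference**: a 20-cell backward-Euler run matches an
  independently assembled dense linear-algebra implementation to 10⁻¹⁰.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| daily release ṁ | 50 | µg/day | steady-state release of a commercial Cu-IUD |
| copper area A | 200 | mm² | nominal Cu-IUD copper area; reproduces the reference flux from ṁ |
| fluid volume V | 7.5 | mL | anatomically plausible cavity volume; makes complete transmission of the 8-h injection (2.62×10⁻⁷ mol) equal 3.5×10⁻⁵ M |
| threshold C* | 10⁻⁶ | M | efficacious spermicidal concentration; verdicts use ≥ |
| D, PAAm pH 7 | 4.5×10⁻¹⁰ | m²/s | **calibrated** so the 2-mm scenario yields 2.7×10⁻⁵ M |
| D, chitosan pH 7 | 2.2×10⁻⁹ | m²/s | **calibrated** effective transmissivity of the thin collapsed remnant (likely microcracked/partially debonded after −28.6%/−18.1% shrinkage); not a molecular diffusivity |
| D, both pH 4 | 10⁻¹² (PAAm), 10⁻¹¹ with K_p = 9 (chitosan) | m²/s | steric-hindrance regime: effective D/(1+K_p) = 10⁻¹², penetration 0.34 mm |
| sweep | 1–2 mm, 0.25 mm pitch | mm | stability/handling range for a cast coating |
| horizon | 28 800 | s | 8 h, the window of elevated vaginal pH after intercourse |

No literature table of Cu²⁺ diffusivities in these exact gel formulations
is bundled, so all D values are declared calibrated placeholders,
config-overridable, calibrated **once** against the pH-7 release pair
(27/35 µM for 2-mm coatings) and frozen in `src/cugel/data/defaults.yaml`.
Note the closed compartment caps the chitosan prediction at ≈3.33×10⁻⁵ M
(the D → ∞ equilibrium limit above); the frozen default delivers
3.30×10⁻⁵ M, about 6% under the 3.5×10⁻⁵ M reference value, which assumes
zero gel holdup.

## Swelling analysis

The swelling ratio is percent *change*: 100·(m₇ − m₄)/m₄ — the only
reading consistent with reported values of +34% and −61%. Kinetics use the
minimal single-rate exponential approach m(t) = m∞ + (m₀ − m∞)e^(−kt);
replicates are pooled into one least-squares fit (scipy `curve_fit`),
mirroring triplicate mean ± SD reporting. "Plateau" is defined as 95%
completion, t₉₅ = −ln(0.05)/k, which reproduces the ~4 h observation at
k = 0.75 h⁻¹. Degradation series reuse the same model over days with a 2%
total-change floor below which a gel is classified stable (rate and
plateau 0). Cyclic reversibility is the maximum relative spread of masses
recorded at revisits of the same pH.

## Synthetic data

The generator emulates the reported study conditions: triplicates sampled
at 0/1/2/4/24 h, equilibrium swelling targets +34% (PAAm) and −61%
(chitosan) at pH 7 with replicate SDs of 26 and 8 percentage points
applied to the 24-h *relative change* (not absolute mass, because SDs are
reported on ratios), rate k = 0.75 h⁻¹, baseline mass 531 mg from the
13 mm × 4 mm cylindrical mold at density ≈1 g/mL (cosmetic; cancels in
every ratio). pH-4 targets are 0% (PAAm) and −8% (chitosan, matching the
observed gradual 24-h loss; the exact figure is not reported and the value
is property-tested only). Chitosan degradation decays at 0.3 day⁻¹ toward
−30% (95% completion near day 10; the plateau loss is likewise not
reported numerically). The colorimetric assay is an affine calibration
(default 1.5×10⁴ AU/M, intercept 0.05 AU, noise 0.005 AU) with its exact
inverse.

A single global seed fans out to named substreams (CRC32 of the stream
name into a `SeedSequence`), so adding a generator never perturbs existing
streams, and identical configurations are byte-reproducible.

What the generator does **not** emulate: instrument drift, evaporation and
handling losses, non-Gaussian replicate scatter, coupling between swelling
and degradation, or real assay nonlinearity at high concentration. Tests
passing on synthetic data therefore demonstrate internal consistency of
the generator/analyzer/solver chain under the assumed statistical model,
not fidelity to any particular bench campaign.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script run
in seconds: 100 radial cells × 2880 implicit steps per scenario, 20
scenarios per sweep, 1000-replicate batches for noise-fidelity checks.
Refinement tests double/halve these and bound the change.

## Known limitations

* The compartment model cannot resolve spatial gradients in the cavity
  fluid; its concentrations are volume averages by construction.
* The pH-7 predictions rest on calibrated effective diffusivities, not
  independently measured ones; only the pH-contrast *structure* (barrier
  at pH 4, delivery at pH 7, monotone thickness dependence, conservation)
  is parameter-free.
* Deformation is static per pH; the time-resolved swelling transition and
  within-horizon degradation are not fed back into the transport geometry.
* The chitosan pH-7 run keeps the full corrosion flux under the remnant
  gel as well as at exposed copper (a constant surface reaction over the
  whole copper area); whether a real shrunken coating passivates the
  covered surface is untested.
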