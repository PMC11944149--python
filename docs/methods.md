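# Methods

## Model

### Elementary modes and the steady-state cone

A metabolic network is a list of reactions with signed rational
stoichiometry over internal and external (boundary-crossing) metabolites.
An elementary flux mode (EM) is a flux vector `v` with `S_int·v = 0`,
nonnegative flux on irreversible reactions, and support-minimality: no
other admissible vector's support is strictly contained in it. Coefficients
are kept as exact `fractions.Fraction` throughout network handling and
enumeration; floats appear only at the thermodynamics boundary. This makes
the elementarity test exact (a support is elementary iff the kernel of
`S_int` restricted to it is one-dimensional) and outputs reproducible.

Enumeration uses the classical tableau (double-description) scheme:
reversible reactions are split into forward/backward nonnegative columns,
internal metabolites are eliminated one at a time by combining
positive/negative candidate pairs, non-minimal candidates are pruned by the
support-subset test at each step (plus a final global minimality pass), the
trivial forward+backward two-cycles are discarded and split pairs
recombined to signed net fluxes. Modes are ordered lexicographically by
reaction support and scaled to coprime integers; a configurable candidate
cap (`max_candidates`, default 2·10⁶) guards against combinatorial blow-up
with an explicit failure. The implementation targets desk-scale networks
(up to ~10⁴ modes); it is not a parallel genome-scale enumerator.

Every mode is then rescaled so its external glucose coefficient is exactly
−1 (the statistics are written per mole glucose). Modes with zero glucose
exchange — futile cycles or glucose-independent paths — are segregated into
a `non_glucose` subset and never enter the partition function, since usage
probabilities are defined as fractions of glucose uptake.

### Mode thermodynamics

Per-mode reaction properties follow from linearity over the external
reaction equation: `Δg_j = Σ ν_ij·g_i`, `Δh_j = Σ ν_ij·h_i`, and
`Δs_j = Σ ν_ij·s_i` with per-species `s_i = (h_i − g_i)/T`, so
`Δg = Δh − T·Δs` holds to machine precision by construction.

Species properties are condition-adjusted in Alberty's transformed
convention. For a species with charge `z` and hydrogen count `nH`:

```
μ = ΔfG° − RT·α(T)·(z² − nH)·√I/(1 + 1.6·√I) + nH·RT·ln10·pH + RT·ln(c/c°)
h = ΔfH° + RT²·α′(T)·(z² − nH)·√I/(1 + 1.6·√I)
```

with `α(T) = 1.10708 − 1.54508·10⁻³·T + 5.95584·10⁻⁶·T²` (so
`RT·α ≈ 2.915 kJ/mol` at 298 K). The enthalpy term is the
Gibbs–Helmholtz-consistent derivative of the Debye–Hückel contribution
(coefficient ≈ 1.48 kJ/mol at 298 K). Gas species use partial pressure in
bar in place of `c/c°`. A metabolite's ionic forms are combined as a
pseudoisomer group with weights `p_i = exp((μ_iso − μ_i)/RT)`,
`μ_iso = −RT·ln Σ exp(−μ_i/RT)` (log-sum-exp stabilized); the effective
enthalpy, mean charge and mean hydrogen count are `p_i`-weighted means.
The enthalpy average uses simple `p_i` weighting (not the van 't
Hoff-consistent form); this choice is deliberate and flagged here.

Mixed-phase metabolites (water) take a molar average of liquid and gas
effective properties at a supplied gas mole fraction. O₂ and CO₂ are
treated as pure gas-phase reactants in the fully aerated culture. Protons
are the thermodynamic reference at pH 7 (zero formation enthalpy and free
energy); a mode's proton coefficient for charge neutrality is
`−Σ ν_i·z̄_i` over the mean charges and contributes bookkeeping only.
Mg²⁺ binding is not modeled.

The shipped species table (`data/species_thermo.tsv`) is a small curated
set of standard-state formation properties in the style of the standard
physical-chemistry tabulations, sufficient for the external metabolites of
aerobic glucose growth (glucose, O₂, CO₂/bicarbonate, water, ammonia,
acetate, phosphate, sulfate, a Cmol biomass pseudo-species
CH₁.₆N₀.₂₆O₀.₃₈P₀.₀₂₃S₀.₀₀₆). Phosphate's pK structure is encoded from the
known pK₁/pK₂/pK₃ = 2.15/7.20/12.35. Users with their own tables load them
via `ThermoTable.from_tsv`.

### CSTR balances

The serial-transfer culture is approximated as a steady-state CSTR with
dilution rate equal to μ (defaults: V = 15 mL, 2 g/L glucose feed, 37 °C).
Outlet concentrations are `c_i = c_i,in + τ·ξ̇·ν_i`; system entropy and
Gibbs content are `S_sys = Σ s_i·c_i,in + τ·ξ̇·ΔS_R` and
`G_sys = Σ g_i·c_i,in + τ·ξ̇·ΔG_R = Σ g_i·c_i,in − τ·T·σ̇_rxn` with the
volumetric (type 1) entropy production rate `σ̇_rxn = ξ̇·A/T`. The
biomass-specific type 1 rate `ξ̂·Σ p_j·(−Δg_j)/T` includes the enthalpic
heat exported to the surroundings; the type 2 rate `ξ̂·Σ p_j·Δs_j` is the
reaction-entropy part that remains in the system. They coincide exactly
when every `Δh_j = 0`. The heat-transfer term is not modeled explicitly; at
isothermal steady state it is implied by the enthalpy balance and not
needed downstream.

Water's gas–liquid split equates the vapor carried by the saturated
aeration stream (Antoine vapor pressure) with the liquid throughput
(55.34 mol/L). The default aeration rate (12.8 L/h) is chosen once so the
split is ~4 mol% at the default culture scale — a stated property of the
modeled system, not a fitted quantity — and is configurable.

### Boltzmann distribution and calibration

`p_j = exp(−ξ̂·x_j/(b·Q·R))/Z` with `x_j = Δs_j` (entropy variant, type 2)
or `A_j/T` (affinity variant, type 1). All exponentials go through
log-sum-exp; `c = −ln Z`. Unit bookkeeping converts uptake rates to
mol/(h·gCDW) before the exponent (`Q = 1 [1/(h·gCDW)]`).

`b` is calibrated so the model expectation matches the measured overall
growth reaction, `Σ p_j(b)·x_j = X_R`. Because the expectation is a
strictly increasing function of `b` — from `min x_j` (b→0) to the uniform
mean (b→∞) — the root is unique; it is found by bracketed Brent iteration
on `ln b` over [10⁻⁴, 10⁴] with tolerance 10⁻¹⁰. Targets at or outside the
open interval `(min x_j, mean x_j)` raise an infeasibility error naming the
violated bound; hitting the upper bracket reports the uniform-limit
condition. The full (n+2)-unknown Levenberg–Marquardt formulation
(unknowns ln p_j, b, c; residuals the n linearized Boltzmann relations plus
normalization and the expectation constraint) is retained as a cross-check
(`fit_b_least_squares`) and agrees with the scalar solve to ≤10⁻⁶ relative
in tests. A single-mode network leaves `b` unidentifiable (min = mean);
this surfaces as an infeasibility, by design.

Derived maxima: `μ_max = μ/b`, `q_s,max = q_s/b`, `τ_min = ln2/μ_max`.
Uptake rates are stored as positive magnitudes; signed (negative) uptake
values are reported alongside, since flux-sign conventions differ between
tables and text in the field.

### Flux prediction and comparison

`ν_i = Σ_j p_j·ν_{j,i}` (glucose exactly −1), `r_i = ξ̂·ν_i`,
`r_k = ξ̂·Σ_j p_j·v_{k,j}`; the internal rate vector lies in the nullspace
of `S_int` by linearity. Rates default to percent-of-glucose scale
(glucose uptake = 100 %). Measured-vs-predicted comparison is ordinary
least squares (R², slope, intercept, residuals); outlier exclusion is
explicit, caller-supplied and echoed in the output — never automatic,
because outliers in this analysis (e.g. ATP-maintenance reactions missing
from a model) need a mechanistic justification.

## Synthetic worlds

The generator's defaults state the modeled conditions once:

* `synthetic_thermo`: `Δs_j ~ U(200, 1500) J/(K·mol glucose)` — at
  ξ̂ ≈ 0.012 mol/(h·gCDW) and b ≈ 0.4 this places the Boltzmann exponents
  (and hence c) in the experimentally relevant range; `Δh_j =
  −2·T·Δs_j·(1+ε)`, ε ~ N(0, 0.05) (strongly correlated, exothermic), or
  zero under `dh_model="zero"`; `Δg_j` from the Gibbs relation, negative by
  construction.
* `synthetic_strain`: exact probabilities at `b_true`, observed overall
  reaction entropy `Σ p*_j·Δs_j` with optional multiplicative Gaussian
  noise on the per-mode contributions; μ = Y·ξ̂ with Y in g biomass per mol
  glucose (defaults ξ̂ = 0.012, Y = 0.42 g/g — the measured range of
  glucose-evolved *E. coli*).
* One seeded `numpy` generator threads through all draws; identical seeds
  give byte-identical fixture bundles.

What a green synthetic test establishes: the machinery (enumeration,
normalization, stability, calibration, prediction) is correct against
independent oracles and ground truth. What it does not establish: agreement
with any particular organism's measured fluxes — the toy networks have 1–4
modes and the synthetic thermodynamics only mimic the qualitative structure
(Δs > 0, Δg < 0, Δg–Δh correlation) of real mode sets, not their values.

## Numerical choices

* Exact rational arithmetic in parsing/enumeration; float64 elsewhere.
* Log-sum-exp for every Boltzmann sum (probabilities stable over ≥6 decades
  of ξ̂/b; extreme exponent spreads may underflow individual p_j to 0).
* Steady-state validation of imported modes at 1e−9 relative; Gibbs
  relation maintained to machine precision by construction.
* Deterministic orderings everywhere (input order for matrices,
  support-lexicographic for modes), so reruns are byte-identical.

## Known limitations

* EM enumeration is exact but single-threaded and desk-scale; genome-scale
  networks need an external enumerator, whose mode matrix can be imported
  and validated via `import_modes`.
* The curated thermodynamic table is minimal; quantitative work on real
  networks should supply a full table.
* No group-contribution estimation, no temperature-dependent heat
  capacities, no Mg²⁺ corrections, no dynamic CSTR simulation, no oxygen
  mass-transfer modeling.
* The affinity variant shares the entropy variant's calibration path; when
  only an overall reaction entropy is observed (no enthalpy), the pipeline
  treats the overall reaction as heat-free for the affinity target.
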