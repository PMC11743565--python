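# Methods

## Electron bookkeeping

All pools are expressed in electron-equivalents (e⁻ mmol). A compound at
`Sm` mmol/L contributes `Sm·N` e⁻ mmol/L, where `N` is the electron count of
its complete-oxidation half-reaction (formate 2, acetate 8, lactate 12,
propionate 14, butyrate/isobutyrate 20, glucose 24, starch 24 per
anhydroglucose unit). The half-reactions are written out in
`stoichiometry.py`. COD and electrons interconvert at 8 mg COD per e⁻ mmol.
Starch is counted per anhydroglucose monomer (162 g/mol) because polymer
length is unknown and COD scales with monomers; "mmol/L of starch" therefore
means monomer-equivalents throughout.

Dead-end classification (acids electrogens cannot oxidize directly) defaults
to propionate, butyrate and isobutyrate. Formate and lactate default to
consumable but can be reclassified per analysis
(`SpeciesTable.with_dead_end_override`), since their fate depends on the
community present.

## Charge integration

Current is `V/R` sample-by-sample; cumulative charge is a trapezoidal
integral on the native (possibly non-uniform) grid, with the window edges
linearly interpolated so charge is exactly additive over adjacent windows.
At one-minute logging the trapezoid discretization error is far below every
tolerance used here (the test suite verifies second-order convergence on an
analytically integrable trace). Negative voltage samples — sensor noise —
are integrated as-is; `VoltageTrace.negative_fraction()` reports how much of
the record they are, but nothing is clipped.

## First-order fits

Every degradation step is modeled as `rate = −k[R]`, fitted as an
unweighted OLS line of `ln R` on `t`. Points at or below the detection limit
(0.2 mg/L for the VFA assay) are **excluded** rather than substituted with
half the limit: substitution biases `k` on series this short. A constant
series yields `k = 0` with `r²` reported as 0 (the statistic is undefined at
zero log-variance). Windowed consumption/accumulation rates are plain linear
slopes over the window, reported as magnitude plus a direction flag.

### Inferred residual substrate

Residual starch cannot be assayed in small reactors, so it is inferred as
`feed − Σ COD(VFA measured at t)` (the subtraction can also be run in raw
mg/L; COD units are the default because they make feed and products
commensurable). This plain subtraction undercounts VFA *production* whenever
acids are consumed downstream while still being produced: in a simulated
non-stirred starch cycle (k_hf = 0.0045 h⁻¹, k_ac = 0.023 h⁻¹, noiseless)
the hydrolysis–fermentation constant fitted on the plain-subtraction series
is biased low by ~30% over the first 24 h and worse over longer windows.
The assumption that production is proportional to accumulation supplies the
fix: acetate obeys `dAc/dt = production − k_ac·Ac`, so cumulative production
is `Ac(t) + k_ac·∫₀ᵗ Ac dτ`, computable from the measured series once
`k_ac` is known from acetate-fed cycles. With this consumption correction
(`infer_substrate_remaining(..., consumption_correction_k=k_ac)`) the same
simulated cycle refits k_hf within ~2%; the residual error is cascade
curvature — the glucose transient and the sparse trapezoid on the sampling
grid. The plain subtraction remains the default; the corrected mode is what
the rate-recovery validation uses.

## Balance snapshots

At each sampling time the feed-electron fractions are: cumulative charge
(from t = 0, the feed time, not inoculation), instantaneous acetate,
instantaneous dead-end acids, optionally the inferred residual substrate,
and an unknown remainder defined as `100 − (sum of measured fractions)`.
The unknown may be negative: charge stored in the biofilm during earlier
cycles and discharged later makes the measured closure exceed 100%, which is
an observation, not an accounting error. Sampling withdrawals (≤10% of the
anolyte) are not volume-corrected by default, matching how such balances are
usually reported; a proportional correction switch exists for sensitivity
analysis.

## Performance metrics

The batch coulombic efficiency replaces the continuous-flow `I/q` with
`∫I dt / V`; the flow form is retained as a separate entry point and the two
agree identically for steady current (tested). Oxygen accounting assumes
1 mg O₂ consumes 1 mg COD and uses a default cycle duration of 160 h — the
round value consistent with the four reported oxygen percentages given the
measured influx rates and feeds; it is a config default, not a constant.
Printed-percentage comparisons round to the nearest integer above 5% and to
one decimal at or below 5%.

## The simulator

`simulate_batch` integrates

```
dS/dt  = −k_hf·S
dG/dt  = +k_hf·S − k_ferm·G
dAc/dt = +f_acetate·k_ferm·G − k_ac·Ac
```

with the remaining fermented COD split across
propionate/butyrate/isobutyrate at weights 0.5/0.3/0.2 (no measured
proportions exist; configurable). Acetate-fed mode starts the whole feed in
the acetate pool. Consumed-acetate flux is routed: intruding oxygen takes up
to `do_rate` (facultative aerobes compete for the same pool and are served
first), a fraction `phi_electro` of the remainder becomes current, the rest
is an unmeasured biomass/methane sink. Electrogenic routing has a hard onset
at `lag_time_h` (observed lags carry no growth parameters, so a growth model
would be unidentifiable). The integrator is fixed-step RK4 on the one-minute
logging grid; at these rates (≤0.05 h⁻¹) the step is ~10⁴ times shorter
than the fastest time constant, and the noiseless acetate solution matches
the closed form to <0.1%. Ground-truth electron routing is conserved to
machine precision at every step and is checked in the tests.

**Storage.** The >100% closures seen in practice can only come from
electrons banked before the analysed cycle, so storage is parameterized as a
pre-charged pool (`storage_eeq`, e⁻ mmol) discharging first-order at
`storage_discharge_per_h` into the circuit, rather than as a
capacity-with-charge-rate during the cycle — the latter adds parameters the
data cannot identify. Its magnitude is a free scenario knob defaulting to 0.

**Measurement model.** Voltage (every minute) and VFAs (a sparse schedule,
dense inside the first 24 h) carry multiplicative Gaussian noise (default
relative sd 0.05, a typical IC/logger precision); VFA values below 0.2 mg/L
are censored to NaN. COD endpoints get the same noise. Everything is
deterministic given the seed.

**Condition presets.** `scenario()` encodes the four study conditions:
feeds 150/250 mgCOD/L, oxygen influx 0.14 (stirred) vs 0.017 (non-stirred)
mg O₂/L/h, the condition-fitted rate constants (acetate consumption
0.0411/0.023 h⁻¹; hydrolysis–fermentation 0.0034/0.0045 h⁻¹), and
`phi_electro` = 0.43/0.67/0.27/0.20 set by a closed-form electron budget so
the simulated coulombic efficiencies land near the reported condition values
(38/66/19/19%); the noiseless presets give 38.4/65.8/18.8/19.3%.

**What the simulator does not emulate.** Electrode kinetics and internal
resistance (current is the routed electron flux, so simulated current
densities exceed a real anode-limited peak), biofilm growth dynamics (the
lag is a hard switch), pH/speciation, methanogenesis as an explicit pathway
(it is folded into the unknown sink), and cycle-to-cycle memory beyond the
pre-charged storage pool. Passing tests on simulated cycles therefore
validate the estimators' arithmetic and statistical behaviour under the
stated noise/censoring model — not the biology of any particular reactor.

## Community metrics

Rarefaction draws once per sample, without replacement (multivariate
hypergeometric), to the minimum sample depth by default; no averaging over
repeated draws. Shannon uses the natural log (base configurable). Bray–Curtis
feeds average-linkage (UPGMA) clustering — the linkage a practitioner would
default to for abundance dendrograms. The exported Newick is ultrametric
with node heights at half the merge distance, so leaf-to-leaf path lengths
equal cophenetic dissimilarities. Upstream read processing (ASV calling,
taxonomy) is out of scope; the input is a taxa × samples count table.

## Problem sizes used in validation

The test suite and acceptance script run on simulated cycles of 160 h at
one-minute logging (~9 600 integrator steps), 14-point VFA schedules,
20-point decay series for the noisy-recovery studies (200 replicates), and
small hand-checkable community tables. These sizes exercise every code path
at the sampling densities the instruments produce.
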