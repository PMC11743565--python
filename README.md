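# mfcbalance

Electron-equivalent balance accounting, first-order degradation kinetics,
coulombic efficiency and community-diversity metrics for **batch air-cathode
microbial fuel cell (MFC) experiments**.

An MFC oxidizes organic substrate at a microbial anode and delivers the
released electrons through an external resistor. Evaluating one means asking,
at every sampling time, *where the feed electrons went*: into current, into
acids still in solution, into "dead-end" acids the electrogens cannot oxidize
(propionate, butyrate, isobutyrate), into aerobic metabolism fed by oxygen
leaking through the air cathode, or into unmeasured sinks (biomass, methane,
biofilm charge storage). This package implements that accounting for batch
cycles, together with the kinetics and performance metrics that go with it,
and a ground-truth simulator so every estimator can be validated without
access to raw reactor logs. It is written for bioelectrochemists and
environmental engineers analysing voltage logs and anolyte chemistry from
bench-scale cells.

## The calculations at its core

With voltage `V(t)` across a known external resistance `R`, Ohm's law gives
`I = V/R` and the projected anode area `A` gives the current density
`J = I/A`. Cumulative charge is the trapezoidal integral `Q = ∫ I dt`, and
Faraday's constant `F = 96 485 C/mol e⁻` converts it to electron-equivalents.

* **Electron equivalents.** A compound at `Sm` mmol/L releasing `N` electrons
  on complete mineralization carries `Se = Sm·N` e⁻ mmol/L; 8 mg COD
  corresponds to 1 e⁻ mmol (one mole O₂, 32 g, accepts four moles of
  electrons).
* **COD removal.** `(S₀ − S_end)/S₀ × 100 %`.
* **Batch coulombic efficiency.**
  `CE = Ms·Q / (F·b·V·ΔCOD) × 100 %` with `Ms = 32 g/mol`, `b = 4 e⁻/O₂`,
  anolyte volume `V` and removed COD `ΔCOD` (g/L) — the batch form of the
  continuous-flow expression, with `∫ I dt` replacing `I/q`.
* **First-order kinetics.** Degradation steps follow `rate = −k[R]`, so
  `ln R = −k t + ln R₀` and `k` is the negative slope of an ordinary
  least-squares line of `ln R` on `t`. Points at or below the 0.2 mg/L
  detection limit are excluded, not substituted.
* **Oxygen intrusion.** An influx of `r` mg O₂/L/h over a cycle of duration
  `T` can consume `r·T/S₀ × 100 %` of the feed COD (1:1 O₂:COD mass basis).
* **Community metrics.** Rarefaction to even depth, Shannon index
  `H = −Σ p ln p`, Bray–Curtis dissimilarity
  `1 − 2Σmin(a,b)/(Σa+Σb)`, and UPGMA clustering with Newick export.

The `synthetic_data` module integrates the degradation cascade
`starch →(k_hf) glucose →(k_ferm) acids →(k_ac) electrons` with fixed-step
RK4 on the one-minute logging grid, routes consumed-acetate electrons between
current, aerobic loss and an unknown sink, supports a pre-charged biofilm
storage pool, and emits noisy, detection-censored measurements plus the full
ground truth. Presets for the four study conditions
(acetate/starch × stirred/non-stirred) are built in.

## Worked example

Simulate the non-stirred acetate condition and push it through the full
analysis:

```python
from mfcbalance import scenario, simulate_batch
from mfcbalance.electrochem import integrate_charge
from mfcbalance.performance import coulombic_efficiency_batch, cod_removal
from mfcbalance.kinetics import fit_first_order
from mfcbalance.ledger import build_ledger
from mfcbalance.stoichiometry import default_species_table

params, config = scenario("nonstirred_acetate", seed=1)
ds = simulate_batch(params, config)

q = integrate_charge(ds.voltage)
ce = coulombic_efficiency_batch(
    q, (ds.cod_start_mg_per_l - ds.cod_end_mg_per_l) / 1000,
    config.anolyte_volume_l)
fit = fit_first_order(next(s for s in ds.vfa if s.species == "acetate"))
ledger = build_ledger(ds.voltage, ds.vfa, config, default_species_table())
```

This prints (seed 1):

```
charge passed:            382.4 C
COD removal:              97.4 %
coulombic efficiency:     65.7 %
fitted k (acetate):       0.0234 1/h  (truth 0.023)
terminal electron pools:  current 64.0 %, acetate 2.5 %, unknown 33.5 %
```

Read: the cycle removed nearly all the 150 mgCOD/L acetate feed; 65.7% of the
removed electrons were recovered as charge (the generating preset routes 0.67
of consumed-acetate electrons to current, minus a small aerobic draw); the
ln-linear fit on the sparse, noisy acetate series recovers the generating
consumption constant within 2%; at the last sampling time 64% of the feed
electrons have passed through the circuit, 2.5% remain as acetate, and the
rest sit in unmeasured sinks.

The same pipeline is scriptable from the shell:

```sh
mfcbalance simulate --scenario nonstirred_acetate --seed 1 --out cycle/
mfcbalance ledger --voltage cycle/voltage.csv --vfa cycle/vfa.csv --out ledger.csv
mfcbalance community --counts counts.tsv --depth 5000 --seed 1 --out diversity/
```

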