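"""Electron-balance accounting across a batch cycle.

At each sampling time the electrons of the initial feed are assigned to
pools: cumulative charge through the circuit, acetate still in solution,
dead-end acids (propionate, butyrate, isobutyrate), optionally residual
inferred substrate, and an "unknown" remainder that closes the balance.
The unknown pool absorbs biomass growth, methanogenesis, unmeasured
intermediates and (when negative) electrons released from biofilm storage
charged in earlier cycles — closures above 100% are real observations, not
errors, so the unknown fraction may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .electrochem import ReactorConfig, VoltageTrace, charge_to_electron_mmol, integrate_charge
from .kinetics import ConcentrationSeries
from .stoichiometry import COD_MG_PER_ELECTRON_MMOL, SpeciesTable


@dataclass(frozen=True)
class BalanceSnapshot:
    """Feed-electron fractions (%) at one sampling time.

    ``frac_unknown`` closes the balance and may be negative;
    ``closure = 100 - frac_unknown`` is the measured total.
    """

    time_h: float
    frac_current: float
    frac_acetate: float
    frac_dead_end: float
    frac_other_measured: float
    frac_unknown: float

    @property
    def closure(self) -> float:
        return 100.0 - self.frac_unknown

    def fractions_sum(self) -> float:
        return (self.frac_current + self.frac_acetate + self.frac_dead_end
                + self.frac_other_measured + self.frac_unknown)


@dataclass
class ElectronLedger:
    snapshots: list[BalanceSnapshot]
    feed_eeq_mmol: float

    def __post_init__(self) -> None:
        times = [s.time_h for s in self.snapshots]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("snapshots must be strictly time-ordered")
        currents = [s.frac_current for s in self.snapshots]
        if any(b < a - 1e-9 for a, b in zip(currents, currents[1:])):
            raise ValueError("cumulative-charge fraction cannot decrease")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time_h, pool, fraction_percent) table for stacked plots."""
        rows = []
        for s in self.snapshots:
            for pool, frac in (("current", s.frac_current),
                               ("acetate", s.frac_acetate),
                               ("dead_end_vfa", s.frac_dead_end),
                               ("other_measured", s.frac_other_measured),
                               ("unknown", s.frac_unknown)):
                rows.append({"time_h": s.time_h, "pool": pool,
                             "fraction_percent": frac})
        return pd.DataFrame(rows)


def feed_electron_pool(config: ReactorConfig, table: SpeciesTable) -> float:
    """Total e-mmol in the reactor at feeding.

    Feed is specified in mgCOD/L; 8 mg COD carries 1 e-mmol, independent of
    the substrate's identity, but the substrate must still be registered so
    typos fail loudly.
    """
    if config.substrate not in table:
        raise KeyError(f"unknown substrate {config.substrate!r}")
    return config.feed_cod_mg_per_l / COD_MG_PER_ELECTRON_MMOL * config.anolyte_volume_l


def _pool_fraction(conc_mg_per_l: float, species_name: str, config: ReactorConfig,
                   table: SpeciesTable, feed_eeq: float) -> float:
    sp = table[species_name]
    mmol_l = sp.mg_per_l_to_mmol_per_l(conc_mg_per_l)
    eeq = mmol_l * sp.n_electrons * config.anolyte_volume_l
    return eeq / feed_eeq * 100.0


def balance_at(
    t_h: float,
    trace: VoltageTrace,
    vfa_at_t: dict[str, float],
    config: ReactorConfig,
    table: SpeciesTable,
    other_measured_cod: float | None = None,
    volume_fraction: float = 1.0,
) -> BalanceSnapshot:
    """One balance snapshot at time ``t_h``.

    ``vfa_at_t`` maps acid name to its concentration in mg/L at t (below
    detection entries may be passed as 0).  ``other_measured_cod`` moves an
    inferred-substrate pool (mgCOD/L) out of the unknown remainder.

    ``volume_fraction`` scales the solution pools for anolyte withdrawn by
    sampling (<=10% of the reactor in practice).  The default of 1.0 is the
    constant-volume assumption balances are normally reported under; set it
    below 1 for sensitivity analysis.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume_fraction must be in (0, 1]")
    lo, hi = trace.span_h
    if t_h < lo or t_h > hi:
        raise ValueError(f"t={t_h} h outside trace span [{lo}, {hi}]")
    feed_eeq = feed_electron_pool(config, table)

    if t_h == lo:
        frac_current = 0.0
    else:
        q = integrate_charge(trace, lo, t_h)
        frac_current = charge_to_electron_mmol(max(q, 0.0)) / feed_eeq * 100.0

    frac_acetate = 0.0
    frac_dead_end = 0.0
    other_cod = float(other_measured_cod or 0.0)
    for name, conc in vfa_at_t.items():
        if not np.isfinite(conc):
            continue
        if table[name].is_dead_end:
            frac_dead_end += _pool_fraction(conc, name, config, table, feed_eeq)
        elif name.strip().lower() == "acetate":
            frac_acetate += _pool_fraction(conc, name, config, table, feed_eeq)
        else:
            # consumable non-acetate acids (formate, lactate) count as "other"
            other_cod += conc * table[name].cod_per_mg

    frac_acetate *= volume_fraction
    frac_dead_end *= volume_fraction
    frac_other = (other_cod / COD_MG_PER_ELECTRON_MMOL * config.anolyte_volume_l
                  * volume_fraction / feed_eeq * 100.0)

    frac_unknown = 100.0 - (frac_current + frac_acetate + frac_dead_end + frac_other)
    return BalanceSnapshot(time_h=float(t_h), frac_current=frac_current,
                           frac_acetate=frac_acetate, frac_dead_end=frac_dead_end,
                           frac_other_measured=frac_other, frac_unknown=frac_unknown)


def build_ledger(
    trace: VoltageTrace,
    vfa_series: list[ConcentrationSeries],
    config: ReactorConfig,
    table: SpeciesTable,
    other_measured: ConcentrationSeries | None = None,
) -> ElectronLedger:
    """Ledger at every VFA sampling time inside the voltage span."""
    times = vfa_series[0].times_h
    for s in vfa_series[1:]:
        if not np.array_equal(s.times_h, times):
            raise ValueError("VFA series must share sampling times; align first")
    lo, hi = trace.span_h
    snapshots = []
    for i, t in enumerate(times):
        if t < lo or t > hi:
            continue
        vfa_at_t = {s.species: (s.values[i] if np.isfinite(s.values[i]) else 0.0)
                    for s in vfa_series}
        other = None
        if other_measured is not None:
            j = np.searchsorted(other_measured.times_h, t)
            if j < other_measured.times_h.size and other_measured.times_h[j] == t:
                other = float(other_measured.values[j])
        snapshots.append(balance_at(float(t), trace, vfa_at_t, config, table,
                                    other_measured_cod=other))
    return ElectronLedger(snapshots=snapshots,
                          feed_eeq_mmol=feed_electron_pool(config, table))


def sink_trajectory(ledger: ElectronLedger) -> tuple[pd.DataFrame, float, float]:
    """Unknown-sink fraction over time, plus its peak (time, value)."""
    if len(ledger.snapshots) < 2:
        raise ValueError("need at least two snapshots")
    df = pd.DataFrame({"time_h": [s.time_h for s in ledger.snapshots],
                       "frac_unknown": [s.frac_unknown for s in ledger.snapshots]})
    i = int(df["frac_unknown"].idxmax())
    return df, float(df.loc[i, "time_h"]), float(df.loc[i, "frac_unknown"])
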