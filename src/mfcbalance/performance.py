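"""Whole-cycle performance metrics.

COD removal, coulombic efficiency, oxygen-intrusion COD accounting and net
energy for a batch microbial fuel cell cycle.

Coulombic efficiency compares the charge recovered at the circuit with the
charge available in the COD removed.  The continuous-flow form
CE = Ms*I / (F*b*q*dCOD) is rewritten for a batch cycle by replacing the
instantaneous current and flow with the cumulative charge Q = int I dt and
the anolyte volume V:

    CE = Ms * Q / (F * b * V * dCOD) * 100   [%]

with Ms = 32 g/mol O2, b = 4 e- per O2, F = 96485 C/mol e-, V in litres
and dCOD in g/L.

Oxygen drawn through the air cathode oxidizes substrate aerobically; on a
COD basis 1 mg of O2 consumes exactly 1 mg of COD, so the fraction of the
feed lost to oxygen over a cycle is (rate * duration) / feed * 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .stoichiometry import (
    ELECTRONS_PER_MOL_O2,
    FARADAY_C_PER_MOL,
    OXYGEN_MW_G_PER_MOL,
)

#: Default batch-cycle duration, hours. Cycles ran to substrate depletion
#: within a week; 160 h is the value consistent with the oxygen accounting.
DEFAULT_CYCLE_DURATION_H = 160.0


@dataclass(frozen=True)
class PerformanceSummary:
    cod_removal_percent: float
    coulombic_efficiency_percent: float
    peak_current_density_a_m2: float
    oxygen_cod_fraction_percent: float
    cycle_duration_h: float


def cod_removal(s0_mg_per_l: float, s_end_mg_per_l: float) -> float:
    """COD removal efficiency (%), (S0 - Send)/S0 * 100.

    A measured effluent above the influent is clipped to 0% removal with a
    warning (analytical scatter, never negative removal).
    """
    if s0_mg_per_l <= 0:
        raise ValueError("influent COD must be positive")
    if s_end_mg_per_l < 0:
        raise ValueError("effluent COD must be non-negative")
    if s_end_mg_per_l > s0_mg_per_l:
        warnings.warn("effluent COD exceeds influent; clipping removal to 0%",
                      stacklevel=2)
        return 0.0
    return (s0_mg_per_l - s_end_mg_per_l) / s0_mg_per_l * 100.0


def coulombic_efficiency_batch(charge_c: float, delta_cod_g_per_l: float,
                               volume_l: float) -> float:
    """Batch coulombic efficiency (%) from cumulative charge."""
    if charge_c < 0:
        raise ValueError("charge must be non-negative")
    if delta_cod_g_per_l <= 0:
        raise ValueError("coulombic efficiency is undefined for zero COD removal")
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return (OXYGEN_MW_G_PER_MOL * charge_c
            / (FARADAY_C_PER_MOL * ELECTRONS_PER_MOL_O2 * volume_l
               * delta_cod_g_per_l) * 100.0)


def coulombic_efficiency_flow(current_a: float, delta_cod_g_per_l: float,
                              flow_l_per_s: float) -> float:
    """Continuous-flow CE (%) from steady current and volumetric flow."""
    if flow_l_per_s <= 0:
        raise ValueError("flow must be positive")
    if delta_cod_g_per_l <= 0:
        raise ValueError("coulombic efficiency is undefined for zero COD removal")
    return (OXYGEN_MW_G_PER_MOL * current_a
            / (FARADAY_C_PER_MOL * ELECTRONS_PER_MOL_O2 * flow_l_per_s
               * delta_cod_g_per_l) * 100.0)


def oxygen_cod_consumption_fraction(do_rate_mg_per_l_h: float, duration_h: float,
                                    feed_cod_mg_per_l: float) -> float:
    """% of the feed COD the intruding oxygen can consume over a cycle."""
    if do_rate_mg_per_l_h < 0 or duration_h < 0:
        raise ValueError("rate and duration must be non-negative")
    if feed_cod_mg_per_l <= 0:
        raise ValueError("feed COD must be positive")
    return do_rate_mg_per_l_h * duration_h / feed_cod_mg_per_l * 100.0


def net_energy(produced_kwh_m3: float, consumed_kwh_m3: float) -> float:
    """Net volumetric energy balance, kWh/m^3 (may be negative)."""
    return produced_kwh_m3 - consumed_kwh_m3


def round_like_reported(percent: float) -> float:
    """Round a percentage the way condition tables print them:
    nearest integer above 5%, one decimal at or below 5%."""
    return round(percent) if percent > 5 else round(percent, 1)
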