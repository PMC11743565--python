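"""Voltage-to-charge conversions for a cell on a fixed external resistor.

The logged quantity is cell voltage across a known external resistance
(200 Ω in the reference setup), sampled at one-minute intervals.  Ohm's law
gives current, the projected anode area gives current density, and a
trapezoidal integral of I(t) gives cumulative charge, which Faraday's
constant converts to electron-equivalents.  Time is in hours everywhere at
the API boundary; seconds appear only inside the charge integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stoichiometry import FARADAY_C_PER_MOL

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class ReactorConfig:
    """Physical configuration of one batch reactor.

    Reference values: anode 27.2 cm^2 projected, 0.33 L anolyte, 200 Ω
    external resistance; feeds 150 mgCOD/L (acetate) or 250 mgCOD/L
    (starch).
    """

    anode_area_m2: float = 27.2e-4
    anolyte_volume_l: float = 0.33
    external_resistance_ohm: float = 200.0
    substrate: str = "acetate"
    feed_cod_mg_per_l: float = 150.0
    stirred: bool = False
    do_influx_mg_per_l_h: float = 0.0

    def __post_init__(self) -> None:
        for name in ("anode_area_m2", "anolyte_volume_l", "external_resistance_ohm",
                     "feed_cod_mg_per_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.do_influx_mg_per_l_h < 0:
            raise ValueError("do_influx_mg_per_l_h must be non-negative")


class VoltageTrace:
    """Timestamped voltage record across a known external resistor."""

    def __init__(self, times_h, voltages_v, external_resistance_ohm: float):
        times = np.asarray(times_h, dtype=float)
        volts = np.asarray(voltages_v, dtype=float)
        if times.ndim != 1 or times.shape != volts.shape:
            raise ValueError("times and voltages must be 1-D and the same length")
        if times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(volts)):
            raise ValueError("voltages must be finite")
        if external_resistance_ohm <= 0:
            raise ValueError("external resistance must be positive")
        self.times_h = times
        self.voltages_v = volts
        self.external_resistance_ohm = float(external_resistance_ohm)

    @property
    def currents_a(self) -> np.ndarray:
        return self.voltages_v / self.external_resistance_ohm

    @property
    def span_h(self) -> tuple[float, float]:
        return float(self.times_h[0]), float(self.times_h[-1])

    def negative_fraction(self) -> float:
        """QC: fraction of samples with negative voltage (sensor noise).

        Negative samples are integrated as-is, never clipped; this flags
        how much of the record they are.
        """
        return float(np.mean(self.voltages_v < 0))

    @classmethod
    def from_csv(cls, path: str | Path, external_resistance_ohm: float) -> "VoltageTrace":
        df = pd.read_csv(path)
        if not {"time_h", "voltage_V"}.issubset(df.columns):
            raise ValueError(
                f"{path}: expected columns time_h, voltage_V; got {list(df.columns)}"
            )
        return cls(df["time_h"].to_numpy(), df["voltage_V"].to_numpy(),
                   external_resistance_ohm)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_h": self.times_h, "voltage_V": self.voltages_v}).to_csv(
            path, index=False
        )


def current_from_voltage(voltage_v: float, resistance_ohm: float) -> float:
    """Ohm's law, I = V/R. Sign of the voltage is preserved."""
    if resistance_ohm <= 0:
        raise ValueError("resistance must be positive")
    return voltage_v / resistance_ohm


def current_density(current_a: float, anode_area_m2: float) -> float:
    """J = I/A over the projected anode area, A/m^2."""
    if anode_area_m2 <= 0:
        raise ValueError("anode area must be positive")
    return current_a / anode_area_m2


def integrate_charge(trace: VoltageTrace, t_start_h: float | None = None,
                     t_end_h: float | None = None) -> float:
    """Cumulative charge in coulombs over [t_start, t_end].

    Trapezoid on the native (possibly non-uniform) grid; current at the
    window edges is obtained by linear interpolation so the integral is
    exactly additive over adjacent windows.
    """
    lo, hi = trace.span_h
    t_start = lo if t_start_h is None else float(t_start_h)
    t_end = hi if t_end_h is None else float(t_end_h)
    if t_start < lo or t_end > hi:
        raise ValueError(f"window [{t_start}, {t_end}] outside trace span [{lo}, {hi}]")
    if t_end <= t_start:
        raise ValueError("empty integration window")

    times = trace.times_h
    currents = trace.currents_a
    inside = (times > t_start) & (times < t_end)
    grid = np.concatenate(([t_start], times[inside], [t_end]))
    vals = np.concatenate((
        [np.interp(t_start, times, currents)],
        currents[inside],
        [np.interp(t_end, times, currents)],
    ))
    if grid.size < 2:
        raise ValueError("integration window contains no samples")
    return float(np.trapezoid(vals, grid * SECONDS_PER_HOUR))


def charge_to_electron_mmol(charge_c: float) -> float:
    """Coulombs to mmol of electrons via Faraday's constant."""
    if charge_c < 0:
        raise ValueError("charge must be non-negative")
    return charge_c / FARADAY_C_PER_MOL * 1000.0


def peak_current_density(trace: VoltageTrace, anode_area_m2: float) -> float:
    """Maximum of J(t) over the trace, A/m^2."""
    return current_density(float(np.max(trace.currents_a)), anode_area_m2)


def window_charge_summary(trace: VoltageTrace, edges_h) -> pd.DataFrame:
    """Per-window charge table for a sequence of window edges (hours)."""
    edges = np.asarray(edges_h, dtype=float)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        q = integrate_charge(trace, a, b)
        rows.append({"t_start_h": a, "t_end_h": b, "charge_C": q,
                     "electron_mmol": charge_to_electron_mmol(max(q, 0.0))})
    return pd.DataFrame(rows)
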