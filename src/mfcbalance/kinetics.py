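"""First-order degradation kinetics from sparse concentration series.

Substrate turnover in the anolyte is modeled as first order, R -> P with
rate = -k[R], so ln R = -k t + ln R0 and k comes from an ordinary
least-squares line of ln(concentration) on time.  Points at or below the
analytical detection limit (0.2 mg/L for the ion-chromatography VFA assay)
are excluded from log fits rather than substituted, since substitution
biases k on short series.

Residual complex substrate (starch) cannot be assayed directly; it is
inferred by subtracting the COD-equivalent of accumulated VFAs from the
feed concentration, under the assumption that VFA production is
proportional to VFA accumulation (valid before significant downstream
consumption of the acids).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stoichiometry import SpeciesTable, cod_from_mg_per_l

DEFAULT_DETECTION_LIMIT_MG_L = 0.2


@dataclass
class ConcentrationSeries:
    """Sparse timestamped concentrations of one compound."""

    times_h: np.ndarray
    values: np.ndarray
    species: str
    unit: str = "mg/L"  # or "mgCOD/L"
    detection_limit: float = DEFAULT_DETECTION_LIMIT_MG_L

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.shape != self.values.shape or self.times_h.ndim != 1:
            raise ValueError("times and values must be 1-D and the same length")
        if np.any(np.diff(self.times_h) < 0):
            raise ValueError("times must be non-decreasing")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ValueError("concentrations must be non-negative")

    def above_detection(self) -> "ConcentrationSeries":
        keep = np.isfinite(self.values) & (self.values > self.detection_limit)
        return ConcentrationSeries(self.times_h[keep], self.values[keep],
                                   self.species, self.unit, self.detection_limit)

    def window(self, t_start_h: float, t_end_h: float) -> "ConcentrationSeries":
        keep = (self.times_h >= t_start_h) & (self.times_h <= t_end_h)
        return ConcentrationSeries(self.times_h[keep], self.values[keep],
                                   self.species, self.unit, self.detection_limit)


@dataclass(frozen=True)
class KineticFit:
    """Result of a ln-linear first-order fit: ln R = -k t + ln R0."""

    k_per_h: float
    ln_r0: float
    r_squared: float
    stderr_k: float
    n_points: int


def fit_first_order(series: ConcentrationSeries) -> KineticFit:
    """OLS of ln(value) on time; k is the negative slope in 1/h.

    Requires at least three points strictly above the detection limit.
    A perfectly constant series has zero slope; its r^2 is reported as 0
    (the log-scale variance is zero, so the statistic is undefined).
    """
    usable = series.above_detection()
    if usable.values.size < 3:
        raise ValueError(
            f"need >=3 points above the detection limit "
            f"({series.detection_limit} {series.unit}); got {usable.values.size}"
        )
    res = stats.linregress(usable.times_h, np.log(usable.values))
    r2 = res.rvalue ** 2
    if not np.isfinite(r2):
        r2 = 0.0
    return KineticFit(
        k_per_h=-float(res.slope),
        ln_r0=float(res.intercept),
        r_squared=float(r2),
        stderr_k=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        n_points=int(usable.values.size),
    )


def windowed_rate(series: ConcentrationSeries, t_start_h: float,
                  t_end_h: float) -> tuple[float, str]:
    """Linear consumption/accumulation rate over a window, mg/L/h.

    Returns ``(rate, direction)`` where rate is the absolute value of the
    least-squares slope of value vs time and direction is "consumption"
    (falling) or "accumulation" (rising).  Flat series report
    ``(0.0, "consumption")``.
    """
    win = series.window(t_start_h, t_end_h)
    if win.values.size < 2:
        raise ValueError(f"need >=2 points in [{t_start_h}, {t_end_h}] h; "
                         f"got {win.values.size}")
    slope = float(stats.linregress(win.times_h, win.values).slope)
    if slope <= 0:
        return -slope, "consumption"
    return slope, "accumulation"


def align_series(series_list: list[ConcentrationSeries]) -> list[ConcentrationSeries]:
    """Restrict every series to the sampling times common to all of them."""
    common = series_list[0].times_h
    for s in series_list[1:]:
        common = np.intersect1d(common, s.times_h)
    out = []
    for s in series_list:
        keep = np.isin(s.times_h, common)
        out.append(ConcentrationSeries(s.times_h[keep], s.values[keep],
                                       s.species, s.unit, s.detection_limit))
    return out


def infer_substrate_remaining(
    feed_cod_mg_per_l: float,
    vfa_series: list[ConcentrationSeries],
    table: SpeciesTable,
    cod_units: bool = True,
    consumption_correction_k: float | None = None,
) -> ConcentrationSeries:
    """Residual complex substrate from VFA accumulation, mgCOD/L.

    remaining(t) = feed - sum over acids of the COD-equivalent (default) or
    raw mg/L of the acid pool at t.  Negative remainders are floored at 0;
    a floor signals unmeasured intermediates and is flagged on the returned
    series as ``.floored``.

    The plain subtraction undercounts VFA production whenever the acids are
    consumed downstream while still being produced, which biases any rate
    fitted on the result low.  ``consumption_correction_k`` (1/h), the
    first-order acetate-consumption constant fitted independently on
    acetate-fed cycles, reconstructs the produced pool from the acetate
    mass balance: produced = Ac(t) + k * int_0^t Ac dt (trapezoid on the
    sampling grid), which the accumulation-proportional-to-production
    assumption makes exact up to sampling curvature.
    """
    if feed_cod_mg_per_l <= 0:
        raise ValueError("feed COD must be positive")
    if not vfa_series:
        raise ValueError("at least one VFA series is required")
    for s in vfa_series:
        if s.species not in table:
            raise KeyError(f"species {s.species!r} not in table")
    aligned = align_series(vfa_series)
    times = aligned[0].times_h
    total = np.zeros_like(times)
    acetate_cod = np.zeros_like(times)
    for s in aligned:
        vals = np.where(np.isfinite(s.values), s.values, 0.0)
        if cod_units and s.unit == "mg/L":
            sp = table[s.species]
            vals = np.array([cod_from_mg_per_l(v, sp) for v in vals])
        total += vals
        if s.species.strip().lower() == "acetate":
            acetate_cod = acetate_cod + vals
    if consumption_correction_k is not None:
        if consumption_correction_k < 0:
            raise ValueError("consumption_correction_k must be non-negative")
        seg = 0.5 * (acetate_cod[1:] + acetate_cod[:-1]) * np.diff(times)
        consumed = np.concatenate(([0.0], np.cumsum(seg))) * consumption_correction_k
        total = total + consumed
    remaining = feed_cod_mg_per_l - total
    floored = bool(np.any(remaining < 0))
    remaining = np.maximum(remaining, 0.0)
    out = ConcentrationSeries(times, remaining, "inferred_substrate",
                              unit="mgCOD/L", detection_limit=0.0)
    out.floored = floored
    return out


def fits_table(fits: dict[str, KineticFit]) -> pd.DataFrame:
    """Tidy table of fits keyed by '<condition>/<pathway>' labels."""
    rows = []
    for label, fit in fits.items():
        cond, _, pathway = label.partition("/")
        rows.append({"condition": cond, "pathway": pathway or cond,
                     "k_per_h": fit.k_per_h, "stderr_k": fit.stderr_k,
                     "r_squared": fit.r_squared, "n_points": fit.n_points})
    return pd.DataFrame(rows)


def read_vfa_csv(path, detection_limit: float = DEFAULT_DETECTION_LIMIT_MG_L
                 ) -> list[ConcentrationSeries]:
    """Read a wide VFA table (time_h, one column per acid, mg/L)."""
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: missing time_h column")
    out = []
    for col in df.columns:
        if col == "time_h":
            continue
        out.append(ConcentrationSeries(df["time_h"].to_numpy(),
                                       df[col].to_numpy(dtype=float),
                                       species=col,
                                       detection_limit=detection_limit))
    if not out:
        raise ValueError(f"{path}: no concentration columns")
    return out
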