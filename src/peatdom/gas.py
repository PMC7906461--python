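"""Closed-vial incubation gas accounting, production rates and isotopes.

Headspace mixing ratios (ppm) are converted to molar amounts with the ideal
gas law for the vial geometry (default: 125 mL serum vial holding 40 g wet
peat and 40 mL water, ≈ 0.085 L headspace, incubated at 18 °C). Production
rates come from ordinary least squares of cumulative amount per gram dry
weight against elapsed day — peat incubations of this kind show nearly
constant production, so a straight line is the natural model. CO2:CH4 ratios
are averaged over fixed day windows, and the apparent carbon isotope
fractionation

    αC = (δ13C-CO2 + 1000) / (δ13C-CH4 + 1000)

separates methanogenic pathways: larger α indicates hydrogenotrophic
(CO2-reducing) methanogenesis, smaller α acetoclastic. Dissolved-phase
partitioning (Henry's law, carbonate speciation) is not modeled: the
accounting is headspace-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "R_L_ATM",
    "DEFAULT_VIAL",
    "VialGeometry",
    "IncubationSeries",
    "RateEstimate",
    "IsotopeRecord",
    "RatioWindow",
    "RATIO_WINDOWS",
    "headspace_to_amount",
    "amount_series",
    "production_rate",
    "co2_ch4_ratio",
    "alpha_c",
    "classify_pathway",
    "compare_groups",
]

#: Gas constant, L·atm·mol^-1·K^-1.
R_L_ATM = 0.0820574

#: Day windows over which CO2:CH4 ratios are averaged.
RATIO_WINDOWS: tuple[tuple[float, float], ...] = ((0, 5), (20, 30), (45, 55), (70, 80), (90, 100))


@dataclass(frozen=True)
class VialGeometry:
    headspace_volume_l: float = 0.085
    temperature_k: float = 291.15  # 18 °C incubation
    pressure_atm: float = 1.0
    peat_mass_gdw: float = 1.0

    def __post_init__(self) -> None:
        if min(self.headspace_volume_l, self.temperature_k, self.pressure_atm, self.peat_mass_gdw) <= 0:
            raise ValueError("vial geometry values must all be positive")


DEFAULT_VIAL = VialGeometry()


@dataclass(frozen=True)
class IncubationSeries:
    """Headspace time series for one vial.

    ``data`` columns: day, co2_ppm, ch4_ppm and optionally d13_co2, d13_ch4
    (‰ vs VPDB).
    """

    sample_id: str
    data: pd.DataFrame
    vial: VialGeometry = field(default_factory=VialGeometry)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        needed = {"day", "co2_ppm", "ch4_ppm"}
        if not needed <= set(df.columns):
            raise ValueError(f"series needs columns {sorted(needed)}")
        if np.any(np.diff(df["day"].to_numpy(float)) < 0):
            raise ValueError("days must be non-decreasing")
        if (df[["co2_ppm", "ch4_ppm"]].to_numpy(float) < 0).any():
            raise ValueError("mixing ratios must be non-negative")
        object.__setattr__(self, "data", df)


@dataclass(frozen=True)
class RateEstimate:
    gas: str
    slope: float  # µmol gdw^-1 d^-1
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n_points: int

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2.0, self.n_points - 2)
        return self.slope - t * self.stderr, self.slope + t * self.stderr


@dataclass(frozen=True)
class IsotopeRecord:
    alpha_c: float
    pathway_label: str


@dataclass(frozen=True)
class RatioWindow:
    window: tuple[float, float]
    co2_ch4: float
    n_points: int
    mode: str


def headspace_to_amount(
    ppm: float, volume_l: float, temp_k: float, pressure_atm: float = 1.0
) -> float:
    """Ideal-gas conversion of a headspace mixing ratio to µmol.

    n = (ppm·1e-6 · P · V)/(R·T), returned in µmol (so numerically
    ppm·P·V/(R·T)).
    """
    if volume_l <= 0 or temp_k <= 0 or pressure_atm <= 0:
        raise ValueError("volume, temperature and pressure must be positive")
    if np.any(np.asarray(ppm) < 0):
        raise ValueError("ppm must be non-negative")
    return ppm * pressure_atm * volume_l / (R_L_ATM * temp_k)


def amount_series(series: IncubationSeries, gas: str, per_gdw: bool = True) -> np.ndarray:
    """Cumulative headspace amount of one gas (µmol, optionally per gdw)."""
    col = {"CO2": "co2_ppm", "CH4": "ch4_ppm"}.get(gas.upper())
    if col is None:
        raise ValueError(f"unknown gas {gas!r}")
    v = series.vial
    n = headspace_to_amount(
        series.data[col].to_numpy(float), v.headspace_volume_l, v.temperature_k, v.pressure_atm
    )
    return n / v.peat_mass_gdw if per_gdw else n


def production_rate(series: IncubationSeries, gas: str, per_gdw: bool = True) -> RateEstimate:
    """OLS production rate of CO2 or CH4 over the incubation.

    Requires >= 3 time points with day variance; returns the slope
    (µmol gdw^-1 d^-1 by default, per vial with ``per_gdw=False``) with r²
    and the two-sided p-value for slope ≠ 0.
    """
    days = series.data["day"].to_numpy(float)
    if len(days) < 3:
        raise ValueError("production rate needs at least 3 time points")
    if np.ptp(days) == 0:
        raise ValueError("days have zero variance")
    y = amount_series(series, gas, per_gdw=per_gdw)
    res = stats.linregress(days, y)
    return RateEstimate(
        gas=gas.upper(),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n_points=len(days),
    )


def co2_ch4_ratio(
    series: IncubationSeries,
    window: tuple[float, float],
    mode: str = "cumulative",
) -> RatioWindow:
    """CO2:CH4 ratio averaged over a day window.

    ``cumulative`` averages pointwise amount ratios inside the window;
    ``increment`` uses the production increments Δ(CO2)/Δ(CH4) across it.
    A zero-CH4 denominator flags the ratio as undefined (NaN).
    """
    lo, hi = window
    days = series.data["day"].to_numpy(float)
    mask = (days >= lo) & (days <= hi)
    if not mask.any():
        raise ValueError(f"window {window} does not overlap the series")
    co2 = amount_series(series, "CO2")[mask]
    ch4 = amount_series(series, "CH4")[mask]
    if mode == "cumulative":
        if np.any(ch4 <= 0):
            warnings.warn(f"CH4 amount zero inside window {window}; ratio undefined", stacklevel=2)
            value = float("nan")
        else:
            value = float(np.mean(co2 / ch4))
    elif mode == "increment":
        d_ch4 = ch4[-1] - ch4[0]
        if len(co2) < 2 or d_ch4 <= 0:
            warnings.warn(f"no CH4 production inside window {window}; ratio undefined", stacklevel=2)
            value = float("nan")
        else:
            value = float((co2[-1] - co2[0]) / d_ch4)
    else:
        raise ValueError(f"unknown ratio mode {mode!r}")
    return RatioWindow(window=(lo, hi), co2_ch4=value, n_points=int(mask.sum()), mode=mode)


def alpha_c(d13_co2: float, d13_ch4: float) -> float:
    """Apparent carbon isotope fractionation (δ13CO2+1000)/(δ13CH4+1000)."""
    if d13_co2 <= -1000 or d13_ch4 <= -1000:
        raise ValueError("delta values must exceed -1000 permil")
    return (d13_co2 + 1000.0) / (d13_ch4 + 1000.0)


def classify_pathway(
    alpha: float, thresholds: tuple[float, float] = (1.055, 1.065)
) -> str:
    """Label the dominant methanogenic pathway from αC.

    Below the lower threshold → acetoclastic-dominant, above the upper →
    hydrogenotrophic-dominant, the closed interval between → mixed. α < 1 is
    unusual for methanogenic systems and is flagged with a warning but still
    classified.
    """
    lo, hi = thresholds
    if lo > hi:
        raise ValueError("thresholds must be ordered")
    if alpha < 1.0:
        warnings.warn(f"alpha {alpha} < 1 is atypical for methanogenesis", stacklevel=2)
    if alpha < lo:
        return "acetoclastic-dominant"
    if alpha > hi:
        return "hydrogenotrophic-dominant"
    return "mixed"


def isotope_record(d13_co2: float, d13_ch4: float) -> IsotopeRecord:
    a = alpha_c(d13_co2, d13_ch4)
    return IsotopeRecord(alpha_c=a, pathway_label=classify_pathway(a))


def compare_groups(values_a, values_b, method: str = "t-test") -> tuple[float, float]:
    """Two-sided field-vs-incubation group comparison.

    ``t-test`` is the Welch two-sample t test; ``anova`` a one-way ANOVA of
    the two groups. Each group needs n >= 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if method == "t-test":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif method == "anova":
        res = stats.f_oneway(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
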