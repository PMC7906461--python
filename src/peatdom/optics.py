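"""UV-Vis and fluorescence (EEM) optical characterization of DOM.

Absorbance side: SUVA254 (decadic absorption coefficient at 254 nm per mg C)
and the spectral slope ratio S275–295 / S350–400, each slope estimated as the
negated least-squares slope of ln a(λ) over its window (a regression reading
of the "first derivative of the log spectrum"; a pointwise finite-difference
mode is available for comparison).

Fluorescence side: Rayleigh/Raman scatter excision with interpolation,
water-Raman area normalization, quinine-sulfate-equivalent scaling, and
trapezoidal integration of the canonical Coble peak windows (A, B, T, M, C)
with the four diagnostic ratios C/M, C/T, C/A, A/T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbsorbanceSpectrum",
    "EEM",
    "OpticalSummary",
    "suva254",
    "spectral_slope",
    "spectral_slope_ratio",
    "remove_scatter",
    "raman_normalize",
    "qse_convert",
    "COBLE_WINDOWS",
    "integrate_coble_peaks",
    "peak_ratios",
    "default_ex_grid",
    "default_em_grid",
    "read_absorbance",
    "write_absorbance",
    "read_eem",
    "write_eem",
]

#: Coble peak integration windows: label -> ((ex_lo, ex_hi), (em_lo, em_hi)), nm.
COBLE_WINDOWS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "A": ((250.0, 260.0), (380.0, 460.0)),
    "B": ((270.0, 280.0), (300.0, 320.0)),
    "T": ((270.0, 280.0), (330.0, 350.0)),
    "M": ((290.0, 310.0), (370.0, 410.0)),
    "C": ((320.0, 360.0), (420.0, 460.0)),
}

#: Water Raman shift band used for ridge excision, cm^-1.
RAMAN_SHIFT_BAND = (3400.0, 3600.0)

#: Emission band (nm) integrated on the blank at 350 nm excitation for
#: Raman-area normalization.
RAMAN_INTEGRATION_EM = (371.0, 428.0)


def default_ex_grid() -> np.ndarray:
    """Excitation grid 240–500 nm in 5 nm steps."""
    return np.arange(240.0, 500.0 + 1e-9, 5.0)


def default_em_grid() -> np.ndarray:
    """Emission grid 290–600 nm in 2 nm steps."""
    return np.arange(290.0, 600.0 + 1e-9, 2.0)


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Blank-corrected UV-Vis absorbance (AU) on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    pathlength_m: float = 0.01
    doc_mg_l: float | None = None
    dilution_factor: float = 1.0
    blank_corrected: bool = True

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise ValueError("wavelengths and absorbance must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.pathlength_m <= 0:
            raise ValueError("pathlength must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    def at(self, wavelength: float) -> float:
        """Linearly interpolated absorbance (AU) at a wavelength."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength <= wl[-1]):
            raise ValueError(f"{wavelength} nm outside grid [{wl[0]}, {wl[-1]}]")
        return float(np.interp(wavelength, wl, self.absorbance))

    def absorption_coefficient(self, wavelength: float) -> float:
        """Decadic absorption coefficient a(λ) = A(λ)/l in m^-1."""
        return self.at(wavelength) / self.pathlength_m


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix; ``intensity[i, j]`` at em[i], ex[j]."""

    ex: np.ndarray
    em: np.ndarray
    intensity: np.ndarray
    units: str = "raw"  # raw | Raman-normalized | QSE

    def __post_init__(self) -> None:
        ex = np.asarray(self.ex, dtype=float)
        em = np.asarray(self.em, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        if z.shape != (em.size, ex.size):
            raise ValueError(f"intensity shape {z.shape} != (len(em), len(ex)) = {(em.size, ex.size)}")
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise ValueError("ex and em grids must be strictly increasing")
        object.__setattr__(self, "ex", ex)
        object.__setattr__(self, "em", em)
        object.__setattr__(self, "intensity", z)

    def scaled(self, factor: float, units: str | None = None) -> "EEM":
        return EEM(self.ex, self.em, self.intensity * factor, units or self.units)


@dataclass(frozen=True)
class OpticalSummary:
    sample_id: str
    suva254: float
    slope_ratio: float
    peak_areas: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)


# -- absorbance metrics -----------------------------------------------------

def suva254(spec: AbsorbanceSpectrum) -> float:
    """Specific UV absorbance at 254 nm, L mgC^-1 m^-1.

    Decadic absorption coefficient a(254) = A(254)/pathlength divided by the
    DOC concentration in mg L^-1.
    """
    if spec.doc_mg_l is None:
        raise ValueError("SUVA254 requires a DOC concentration")
    if spec.doc_mg_l <= 0:
        raise ValueError("DOC concentration must be positive")
    return spec.absorption_coefficient(254.0) / spec.doc_mg_l


def spectral_slope(
    spec: AbsorbanceSpectrum,
    window: tuple[float, float],
    method: str = "regression",
) -> float:
    """CDOM spectral slope S (nm^-1) over a wavelength window.

    ``regression`` fits ln a(λ) vs λ by least squares and negates the slope;
    ``finite-difference`` averages the pointwise first derivative of the log
    spectrum. For a clean single exponential both give S exactly.
    """
    lo, hi = window
    wl = spec.wavelengths
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window {window} needs >= 2 grid points")
    a = spec.absorbance[mask]
    if np.any(a <= 0):
        raise ValueError(f"non-positive absorbance inside window {window}: log undefined")
    x, y = wl[mask], np.log(a)
    if method == "regression":
        slope = stats.linregress(x, y).slope
    elif method == "finite-difference":
        slope = float(np.mean(np.diff(y) / np.diff(x)))
    else:
        raise ValueError(f"unknown slope method {method!r}")
    return -float(slope)


def spectral_slope_ratio(spec: AbsorbanceSpectrum, method: str = "regression") -> float:
    """Slope ratio S275–295 / S350–400; NaN (with warning) for flat spectra."""
    s_short = spectral_slope(spec, (275.0, 295.0), method=method)
    s_long = spectral_slope(spec, (350.0, 400.0), method=method)
    if abs(s_long) < 1e-12:
        warnings.warn("long-wavelength slope is zero; slope ratio undefined", stacklevel=2)
        return float("nan")
    return s_short / s_long


# -- EEM corrections --------------------------------------------------------

def _raman_emission(ex_nm: float, shift_cm: float) -> float:
    """Emission wavelength (nm) of the water Raman band for one excitation."""
    return 1.0 / (1.0 / ex_nm - shift_cm * 1e-7)


def remove_scatter(eem: EEM, rayleigh_width: float = 14.0, raman_pad: float = 16.0) -> EEM:
    """Excise Rayleigh (1st/2nd order) and water-Raman ridges, interpolate.

    For each excitation column, emission cells within ``rayleigh_width`` nm
    of em = ex or em = 2·ex, or inside the water-Raman band (3400–3600 cm^-1
    shift, padded by ``raman_pad`` nm), are replaced by linear interpolation
    along the emission axis (zero beyond the grid edge).
    """
    z = eem.intensity.copy()
    em = eem.em
    for j, ex in enumerate(eem.ex):
        r_lo = _raman_emission(ex, RAMAN_SHIFT_BAND[0]) - raman_pad
        r_hi = _raman_emission(ex, RAMAN_SHIFT_BAND[1]) + raman_pad
        bad = (
            (np.abs(em - ex) <= rayleigh_width)
            | (np.abs(em - 2.0 * ex) <= rayleigh_width)
            | ((em >= r_lo) & (em <= r_hi))
        )
        if not bad.any():
            continue
        good = ~bad
        if good.sum() < 2:
            z[:, j] = 0.0
            continue
        z[bad, j] = np.interp(em[bad], em[good], z[good, j], left=0.0, right=0.0)
    return EEM(eem.ex, eem.em, np.clip(z, 0.0, None), eem.units)


def raman_peak_area(blank: EEM) -> float:
    """Water-Raman peak area of a blank: em 371–428 nm at ex nearest 350 nm."""
    j = int(np.argmin(np.abs(blank.ex - 350.0)))
    lo, hi = RAMAN_INTEGRATION_EM
    mask = (blank.em >= lo) & (blank.em <= hi)
    if mask.sum() < 2:
        raise ValueError("blank emission grid does not cover the Raman integration band")
    return float(np.trapezoid(blank.intensity[mask, j], blank.em[mask]))


def raman_normalize(eem: EEM, blank: EEM) -> EEM:
    """Divide the EEM by the blank's water-Raman peak area (gain cancels)."""
    area = raman_peak_area(blank)
    if area <= 0:
        raise ValueError("blank Raman area must be positive")
    return eem.scaled(1.0 / area, units="Raman-normalized")


def qse_convert(eem: EEM, quinine_slope: float) -> EEM:
    """Scale to quinine sulfate equivalents (ppb) by the calibration slope."""
    if quinine_slope <= 0:
        raise ValueError("calibration slope must be positive")
    return eem.scaled(1.0 / quinine_slope, units="QSE")


def integrate_coble_peaks(
    eem: EEM,
    windows: dict[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
) -> dict[str, float]:
    """Trapezoidal 2-D integral of each Coble window, in (units)·nm²."""
    windows = windows or COBLE_WINDOWS
    areas = {}
    for label, ((ex_lo, ex_hi), (em_lo, em_hi)) in windows.items():
        jx = (eem.ex >= ex_lo) & (eem.ex <= ex_hi)
        iy = (eem.em >= em_lo) & (eem.em <= em_hi)
        if jx.sum() < 2 or iy.sum() < 2:
            raise ValueError(f"Coble window {label} lies outside the EEM grid")
        sub = eem.intensity[np.ix_(iy, jx)]
        along_em = np.trapezoid(sub, eem.em[iy], axis=0)
        areas[label] = float(np.trapezoid(along_em, eem.ex[jx]))
    return areas


def peak_ratios(peak_areas: dict[str, float], eps: float = 1e-12) -> dict[str, float]:
    """The four diagnostic Coble ratios; NaN where the denominator vanishes.

    C/M: diagenetic alteration; C/T: humic vs fresh; C/A: humic vs fulvic;
    A/T: fulvic vs fresh.
    """
    out = {}
    for name, num, den in (
        ("C/M", "C", "M"),
        ("C/T", "C", "T"),
        ("C/A", "C", "A"),
        ("A/T", "A", "T"),
    ):
        d = peak_areas.get(den, 0.0)
        out[name] = peak_areas.get(num, 0.0) / d if d > eps else float("nan")
    return out


# -- I/O --------------------------------------------------------------------

def read_absorbance(
    path: str | Path,
    pathlength_m: float = 0.01,
    doc_mg_l: float | None = None,
) -> AbsorbanceSpectrum:
    df = pd.read_csv(path)
    if not {"wavelength_nm", "absorbance"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns wavelength_nm,absorbance")
    return AbsorbanceSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
        pathlength_m=pathlength_m,
        doc_mg_l=doc_mg_l,
    )


def write_absorbance(spec: AbsorbanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "absorbance": spec.absorbance}
    ).to_csv(path, index=False, float_format="%.8g")


def read_eem(path: str | Path, units: str = "raw") -> EEM:
    """Wide CSV: first column emission nm, header row excitation nm."""
    df = pd.read_csv(path, index_col=0)
    em = df.index.to_numpy(float)
    ex = np.asarray([float(c) for c in df.columns])
    return EEM(ex=ex, em=em, intensity=df.to_numpy(float), units=units)


def write_eem(eem: EEM, path: str | Path) -> None:
    pd.DataFrame(eem.intensity, index=eem.em, columns=eem.ex).to_csv(
        path, index_label="em_nm", float_format="%.8g"
    )
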