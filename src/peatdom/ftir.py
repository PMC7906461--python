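"""FTIR band-area fractions for solid-phase peat chemistry.

Six diagnostic absorbance bands are quantified: carbohydrates (1030 cm⁻¹),
lignin-like aromatics (1510), aromatics/deprotonated carboxylic acids (1630),
organic acids (1720), and lipids (2850, 2920). Each band is locally
baseline-corrected by subtracting the straight line joining local minima near
the band-window endpoints, and its trapezoidal area is expressed as a
fraction of the whole baseline-corrected spectrum area — making the result
invariant to overall signal scaling.

ATR correction and the instrument-level global baseline are assumed to have
been applied upstream (vendor software); input spectra are absorbance vs
wavenumber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FTIRSpectrum",
    "FTIRBandResult",
    "DEFAULT_BANDS",
    "local_baseline_correct",
    "normalized_band_areas",
    "read_ftir",
    "write_ftir",
]

#: Band windows, cm^-1: center -> (lo, hi). ±40 cm^-1 around each center,
#: narrowed to ±25 for the two lipid C-H stretches so they do not overlap.
DEFAULT_BANDS: dict[int, tuple[float, float]] = {
    1030: (990.0, 1070.0),
    1510: (1470.0, 1550.0),
    1630: (1590.0, 1670.0),
    1720: (1680.0, 1760.0),
    2850: (2825.0, 2875.0),
    2920: (2895.0, 2945.0),
}

ENDPOINT_PAD = 15.0  # cm^-1 searched around each window endpoint for a local minimum


@dataclass(frozen=True)
class FTIRSpectrum:
    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or wn.shape != ab.shape:
            raise ValueError("wavenumbers and absorbance must be matching 1-D arrays")
        d = np.diff(wn)
        if np.any(d <= 0) and np.any(d >= 0):
            raise ValueError("wavenumber grid must be strictly monotonic")
        if wn[0] > wn[-1]:  # store ascending
            wn, ab = wn[::-1], ab[::-1]
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class FTIRBandResult:
    band_center: int
    area: float
    area_fraction: float


def _anchor_index(spec: FTIRSpectrum, target: float, pad: float) -> int:
    """Index of the local absorbance minimum within ``target ± pad``."""
    wn = spec.wavenumbers
    mask = (wn >= target - pad) & (wn <= target + pad)
    if not mask.any():
        raise ValueError(f"no grid points near {target} cm^-1")
    idx = np.flatnonzero(mask)
    return int(idx[np.argmin(spec.absorbance[idx])])


def local_baseline_correct(
    spec: FTIRSpectrum,
    band_window: tuple[float, float],
    endpoint_pad: float = ENDPOINT_PAD,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected segment of one band.

    Anchors are the local minima within ``endpoint_pad`` of each window
    endpoint; the straight line through the anchors is subtracted and
    negative residuals are clipped to zero. Returns (wavenumbers, corrected).
    """
    lo, hi = sorted(band_window)
    i0 = _anchor_index(spec, lo, endpoint_pad)
    i1 = _anchor_index(spec, hi, endpoint_pad)
    if i1 <= i0:
        raise ValueError(f"degenerate band window {band_window}")
    wn = spec.wavenumbers[i0 : i1 + 1]
    ab = spec.absorbance[i0 : i1 + 1]
    baseline = np.interp(wn, [wn[0], wn[-1]], [ab[0], ab[-1]])
    return wn, np.clip(ab - baseline, 0.0, None)


def _full_spectrum_area(spec: FTIRSpectrum, endpoint_pad: float) -> float:
    """Area of the whole spectrum above its end-to-end straight baseline."""
    wn, corrected = local_baseline_correct(
        spec, (spec.wavenumbers[0], spec.wavenumbers[-1]), endpoint_pad
    )
    return float(np.trapezoid(corrected, wn))


def normalized_band_areas(
    spec: FTIRSpectrum,
    bands: dict[int, tuple[float, float]] | None = None,
    endpoint_pad: float = ENDPOINT_PAD,
) -> list[FTIRBandResult]:
    """Baseline-corrected band areas as fractions of total spectral area.

    A spectrum with (near-)zero total area yields zero fractions and a
    warning rather than an error.
    """
    bands = bands or DEFAULT_BANDS
    total = _full_spectrum_area(spec, endpoint_pad)
    results = []
    flagged = total <= 1e-15
    if flagged:
        warnings.warn("total spectral area is zero; band fractions set to 0", stacklevel=2)
    for center in sorted(bands):
        wn, corrected = local_baseline_correct(spec, bands[center], endpoint_pad)
        area = float(np.trapezoid(corrected, wn))
        frac = 0.0 if flagged else area / total
        results.append(FTIRBandResult(band_center=center, area=area, area_fraction=frac))
    return results


def read_ftir(path: str | Path) -> FTIRSpectrum:
    df = pd.read_csv(path)
    if not {"wavenumber", "absorbance"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns wavenumber,absorbance")
    return FTIRSpectrum(df["wavenumber"].to_numpy(float), df["absorbance"].to_numpy(float))


def write_ftir(spec: FTIRSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber": spec.wavenumbers, "absorbance": spec.absorbance}
    ).to_csv(path, index=False, float_format="%.8g")
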