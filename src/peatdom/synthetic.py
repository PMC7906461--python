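"""Synthetic study generator with known ground truth.

Emulates the seven measurement streams of a field-vs-incubation peat study —
FTICR-MS peak lists, moiety reference table, UV-Vis spectra, EEMs with a
matched blank, FTIR spectra, incubation headspace time series, and sample
metadata — so every downstream estimator has a parameter-recovery test with
no external data.

The emulations are deliberately simple and invertible:

* compound libraries are CHNOSP formulas whose O/C and H/C are drawn around
  habitat targets (rule-valid by construction);
* peak lists place one peak per formula with Gaussian ppm mass error and
  log-normal intensity, plus non-assignable uniform noise peaks kept a 3σ
  exclusion zone away from every true mass;
* CDOM absorbance is a single exponential a0·exp(−S·(λ−240));
* EEMs are sums of 2-D Gaussians at canonical Coble coordinates plus
  synthetic Rayleigh/Raman ridges (the blank carries ridges only);
* FTIR spectra are Gaussian bands on a smooth polynomial baseline;
* gas series are linear accumulations with Gaussian amount noise and δ13C
  values constructed to hold αC exactly at every time point.

Habitat presets are illustrative contrasts (labile fen > bog > palsa
gradient in H/C and lability), not claims about any particular mire.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assignment import neutralize_mass
from .chem import Formula
from .ftir import FTIRSpectrum
from .gas import DEFAULT_VIAL, IncubationSeries, R_L_ATM, VialGeometry
from .optics import EEM, AbsorbanceSpectrum, default_em_grid, default_ex_grid, _raman_emission

__all__ = [
    "HabitatProfile",
    "GroundTruth",
    "HABITAT_PRESETS",
    "COBLE_CENTERS",
    "FTIR_BAND_CENTERS",
    "library_assignment_config",
    "generate_compound_library",
    "generate_peak_list",
    "generate_gas_timeseries",
    "generate_uvvis",
    "generate_eem",
    "generate_ftir",
    "gaussian_window_mass",
    "write_study",
]


@dataclass(frozen=True)
class HabitatProfile:
    """Target DOM composition for one habitat."""

    habitat: str
    mean_oc: float
    mean_hc: float
    n_compounds: int
    lability_index: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_oc <= 1.2):
            raise ValueError("mean_oc must be in (0, 1.2]")
        if not (0.3 <= self.mean_hc <= 2.25):
            raise ValueError("mean_hc must be in [0.3, 2.25]")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not (0.0 <= self.lability_index <= 1.0):
            raise ValueError("lability_index must be in [0, 1]")


#: Illustrative habitat contrasts along a permafrost-thaw gradient:
#: the fen end is more aliphatic/labile (higher H/C), the palsa end more
#: oxidized/aromatic. Numbers are package constants for simulation, not
#: measurements of any field site.
HABITAT_PRESETS: dict[str, HabitatProfile] = {
    "palsa": HabitatProfile("palsa", mean_oc=0.48, mean_hc=1.05, n_compounds=800, lability_index=0.3),
    "bog": HabitatProfile("bog", mean_oc=0.52, mean_hc=1.20, n_compounds=900, lability_index=0.5),
    "fen": HabitatProfile("fen", mean_oc=0.55, mean_hc=1.35, n_compounds=1000, lability_index=0.7),
}


@dataclass(frozen=True)
class GroundTruth:
    """Container for the true parameters behind one synthetic sample set."""

    formulas: frozenset
    rate_co2: float  # µmol gdw^-1 d^-1
    rate_ch4: float
    alpha_true: float
    slope_s: float  # nm^-1
    coble_weights: tuple[tuple[str, float], ...]
    ftir_weights: tuple[tuple[int, float], ...]
    seed: int

    def __post_init__(self) -> None:
        if self.rate_co2 < 0 or self.rate_ch4 < 0:
            raise ValueError("rates must be non-negative")
        if not (1.0 <= self.alpha_true <= 1.12):
            raise ValueError("alpha_true must be in [1.0, 1.12]")
        if self.slope_s <= 0:
            raise ValueError("slope_s must be positive")


# -- compound library -------------------------------------------------------

def generate_compound_library(profile: HabitatProfile, seed: int) -> set[Formula]:
    """Draw ``n_compounds`` distinct rule-valid CHNOSP formulas.

    Per-compound O/C and H/C targets are drawn around the profile means and
    recentred so the drawn means hit the targets exactly; integer rounding
    then keeps the realized sample means within 0.1 of the profile (carbon
    counts are >= 8, so a rounding step moves a ratio by at most ~0.06).
    Every emitted formula passes the default assignment screening rules
    (ratio bounds, valence parity, DBE−O, phosphate-P; S and P never
    co-occur, matching their chemistry in natural DOM). Deterministic for a
    given (profile, seed).
    """
    from .assignment import AssignmentConfig, apply_rules

    rule_cfg = AssignmentConfig()
    rng = np.random.default_rng(seed)
    formulas: set[Formula] = set()
    target_n = profile.n_compounds
    # heteroatom probabilities scale weakly with lability (N-richer labile DOM)
    p_n = 0.10 + 0.10 * profile.lability_index
    attempts = 0
    while len(formulas) < target_n:
        attempts += 1
        if attempts > 200:
            raise RuntimeError("compound library generation failed to converge")
        batch = max(64, target_n - len(formulas))
        oc = rng.normal(profile.mean_oc, 0.08, batch)
        hc = rng.normal(profile.mean_hc, 0.12, batch)
        oc += profile.mean_oc - oc.mean()
        hc += profile.mean_hc - hc.mean()
        oc = np.clip(oc, 0.05, 1.2)
        hc = np.clip(hc, 0.35, 2.2)
        c = rng.integers(8, 31, batch)
        n_het = rng.choice([0, 1, 2], batch, p=[1 - p_n, 0.8 * p_n, 0.2 * p_n])
        s_het = (rng.random(batch) < 0.05).astype(int)
        p_het = (rng.random(batch) < 0.03).astype(int) * (1 - s_het)  # S and P exclusive
        for i in range(batch):
            ci = int(c[i])
            oi = int(np.clip(np.rint(ci * oc[i]), 0, int(1.2 * ci)))
            # H parity must equal (N+P) parity for an integer DBE
            parity = int((n_het[i] + p_het[i]) % 2)
            hi_target = ci * hc[i]
            hi = int(np.rint((hi_target - parity) / 2.0) * 2 + parity)
            hi = int(np.clip(hi, 0, int(2.25 * ci)))
            if hi < 0.3 * ci:
                hi += 2
            f = Formula(c=ci, h=hi, n=int(n_het[i]), o=oi, s=int(s_het[i]), p=int(p_het[i]))
            if 100.0 <= f.mass <= 1000.0 and apply_rules([f], rule_cfg):
                formulas.add(f)
            if len(formulas) == target_n:
                break
    return formulas


def library_assignment_config(tolerance_ppm: float = 1.0):
    """AssignmentConfig with element limits matched to the generator space.

    The generator emits C 8–30, N ≤ 2, S ≤ 1, P ≤ 1 and O ≤ 1.2·C; matching
    the search limits to the known compound space of a sample — exactly what
    a practitioner does when configuring assignment for a given sample type
    — keeps the search sharp without excluding any true composition.
    """
    from .assignment import AssignmentConfig

    return AssignmentConfig(tolerance_ppm=tolerance_ppm).with_limits(
        C=40, H=80, N=2, O=36, S=1, P=1
    )


# -- peak list --------------------------------------------------------------

def _ionized_mass(neutral: float, mode: str) -> float:
    # inverse of neutralize_mass: observed m/z for a singly charged ion
    if mode == "negative":
        return neutralize_mass(neutral, "positive")  # neutral - proton
    if mode == "positive":
        return neutralize_mass(neutral, "negative")
    if mode == "neutral":
        return neutral
    raise ValueError(f"unknown ionization mode {mode!r}")


def generate_peak_list(
    formulas,
    ppm_sigma: float = 0.5,
    n_noise: int = 0,
    mode: str = "negative",
    seed: int = 0,
    sample_id: str = "synthetic",
) -> pd.DataFrame:
    """One peak per formula with Gaussian ppm error, plus unassignable noise.

    Noise peaks are uniform over 100–1000 Da but rejected inside a
    3·ppm_sigma exclusion zone around every true ionized mass, so a
    downstream false-positive count is well-defined. Intensities are
    log-normal. Returns a ``sample_id,mz,intensity`` table sorted by m/z.
    """
    if ppm_sigma < 0:
        raise ValueError("ppm_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    true_mz = np.array(sorted(_ionized_mass(f.mass, mode) for f in formulas))
    rows_mz: list[float] = []
    if true_mz.size:
        err = rng.normal(0.0, ppm_sigma, true_mz.size) * 1e-6
        rows_mz.extend(true_mz * (1.0 + err))
    n_placed = 0
    while n_placed < n_noise:
        cand = rng.uniform(100.0, 1000.0)
        if true_mz.size:
            rel = np.min(np.abs(true_mz - cand)) / cand * 1e6
            if rel <= 3.0 * ppm_sigma:
                continue
        rows_mz.append(cand)
        n_placed += 1
    intensity = rng.lognormal(mean=13.0, sigma=1.0, size=len(rows_mz))
    df = pd.DataFrame({"sample_id": sample_id, "mz": rows_mz, "intensity": intensity})
    return df.sort_values("mz", kind="mergesort").reset_index(drop=True)


# -- gas time series --------------------------------------------------------

def generate_gas_timeseries(
    truth: GroundTruth,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    d13_ch4_base: float = -60.0,
    vial: VialGeometry = DEFAULT_VIAL,
    sample_id: str = "synthetic",
) -> IncubationSeries:
    """Linear gas accumulation with exact isotopic fractionation.

    Cumulative amounts are rate·t·peat_mass plus Gaussian noise (truncated at
    zero), converted back to headspace ppm via the ideal gas law. δ13CH4 is
    held at ``d13_ch4_base`` and δ13CO2 constructed so that
    (δ13CO2+1000)/(δ13CH4+1000) = alpha_true at every time point.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("at least 2 time points required")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    m = vial.peat_mass_gdw
    co2 = truth.rate_co2 * times * m
    ch4 = truth.rate_ch4 * times * m
    if noise_sd > 0:
        co2 = co2 + rng.normal(0.0, noise_sd, times.size)
        ch4 = ch4 + rng.normal(0.0, noise_sd, times.size)
    co2 = np.clip(co2, 0.0, None)
    ch4 = np.clip(ch4, 0.0, None)
    to_ppm = R_L_ATM * vial.temperature_k / (vial.pressure_atm * vial.headspace_volume_l)
    d13_ch4 = np.full(times.size, d13_ch4_base)
    d13_co2 = truth.alpha_true * (d13_ch4 + 1000.0) - 1000.0
    df = pd.DataFrame(
        {
            "day": times,
            "co2_ppm": co2 * to_ppm,
            "ch4_ppm": ch4 * to_ppm,
            "d13_co2": d13_co2,
            "d13_ch4": d13_ch4,
        }
    )
    return IncubationSeries(sample_id=sample_id, data=df, vial=vial)


# -- UV-Vis -----------------------------------------------------------------

def generate_uvvis(
    slope_s: float,
    a0: float,
    doc: float,
    wavelengths=None,
    pathlength_m: float = 0.01,
) -> AbsorbanceSpectrum:
    """Single-exponential CDOM spectrum a(λ) = a0·exp(−S·(λ−240)) in m^-1.

    Absorbance (AU) is the absorption coefficient times the pathlength; DOC
    is carried in metadata for SUVA254. Both slope windows see the same S,
    so the spectral slope ratio of the output is exactly 1.
    """
    wl = np.asarray(wavelengths, dtype=float) if wavelengths is not None else np.arange(240.0, 801.0)
    a = a0 * np.exp(-slope_s * (wl - 240.0))  # m^-1
    return AbsorbanceSpectrum(
        wavelengths=wl,
        absorbance=a * pathlength_m,
        pathlength_m=pathlength_m,
        doc_mg_l=doc,
    )


# -- EEM --------------------------------------------------------------------

#: Gaussian fluorophore centers (ex, em) nm at canonical Coble coordinates.
COBLE_CENTERS: dict[str, tuple[float, float]] = {
    "A": (255.0, 420.0),
    "B": (275.0, 310.0),
    "T": (275.0, 340.0),
    "M": (300.0, 390.0),
    "C": (340.0, 440.0),
}

EEM_SIGMA_EX = 8.0
EEM_SIGMA_EM = 18.0


def _gaussian_2d(ex, em, cx, cm, sx, sm):
    gx = np.exp(-0.5 * ((ex - cx) / sx) ** 2)
    gm = np.exp(-0.5 * ((em - cm) / sm) ** 2)
    return np.outer(gm, gx)


def generate_eem(
    coble_weights: dict[str, float],
    scatter_amplitude: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[EEM, EEM]:
    """Sum of Coble-centered 2-D Gaussians plus scatter ridges, with blank.

    Rayleigh ridges sit at em = ex and em = 2·ex, the water-Raman ridge at
    the 3500 cm^-1 shift from each excitation; the matched blank contains
    the ridges (and noise) only. Returns ``(sample_eem, blank_eem)`` in raw
    units.
    """
    ex, em = default_ex_grid(), default_em_grid()
    z = np.zeros((em.size, ex.size))
    for label, w in coble_weights.items():
        if label not in COBLE_CENTERS:
            raise ValueError(f"unknown Coble peak {label!r}")
        cx, cm = COBLE_CENTERS[label]
        z += w * _gaussian_2d(ex, em, cx, cm, EEM_SIGMA_EX, EEM_SIGMA_EM)
    ridges = np.zeros_like(z)
    if scatter_amplitude > 0:
        emg, exg = np.meshgrid(em, ex, indexing="ij")
        raman_em = np.array([_raman_emission(x, 3500.0) for x in ex])
        ridges = scatter_amplitude * (
            np.exp(-0.5 * ((emg - exg) / 4.0) ** 2)
            + 0.5 * np.exp(-0.5 * ((emg - 2.0 * exg) / 4.0) ** 2)
            + 0.3 * np.exp(-0.5 * ((emg - raman_em[None, :]) / 5.0) ** 2)
        )
    rng = np.random.default_rng(seed)
    noise_s = rng.normal(0.0, noise_sd, z.shape) if noise_sd > 0 else 0.0
    noise_b = rng.normal(0.0, noise_sd, z.shape) if noise_sd > 0 else 0.0
    sample = EEM(ex, em, np.clip(z + ridges + noise_s, 0.0, None), units="raw")
    blank = EEM(ex, em, np.clip(ridges + noise_b, 0.0, None), units="raw")
    return sample, blank


def gaussian_window_mass(
    center: tuple[float, float],
    window: tuple[tuple[float, float], tuple[float, float]],
    sigma_ex: float = EEM_SIGMA_EX,
    sigma_em: float = EEM_SIGMA_EM,
) -> float:
    """Closed-form mass of a unit-height 2-D Gaussian inside a window.

    Analytic oracle for the Coble integration tests: the separable integral
    is a product of 1-D Gaussian masses, each
    σ√(2π)·[Φ((hi−c)/σ) − Φ((lo−c)/σ)].
    """
    from scipy.stats import norm

    (ex_lo, ex_hi), (em_lo, em_hi) = window
    cx, cm = center
    mx = sigma_ex * np.sqrt(2 * np.pi) * (
        norm.cdf((ex_hi - cx) / sigma_ex) - norm.cdf((ex_lo - cx) / sigma_ex)
    )
    mm = sigma_em * np.sqrt(2 * np.pi) * (
        norm.cdf((em_hi - cm) / sigma_em) - norm.cdf((em_lo - cm) / sigma_em)
    )
    return float(mx * mm)


# -- FTIR -------------------------------------------------------------------

FTIR_BAND_CENTERS = (1030, 1510, 1630, 1720, 2850, 2920)
FTIR_SIGMA = 12.0


def generate_ftir(
    band_weights: dict[int, float],
    baseline_poly=(0.0,),
    seed: int = 0,
    noise_sd: float = 0.0,
    wavenumbers=None,
) -> FTIRSpectrum:
    """Gaussian bands (area = weight) at the six diagnostic wavenumbers.

    The baseline is the polynomial with the given coefficients (lowest order
    first) in the scaled variable (wn − 650)/3350, so coefficients are O(1).
    """
    wn = np.asarray(wavenumbers, dtype=float) if wavenumbers is not None else np.arange(650.0, 4001.0, 2.0)
    x = (wn - 650.0) / 3350.0
    ab = np.polynomial.polynomial.polyval(x, np.asarray(baseline_poly, dtype=float))
    ab = np.broadcast_to(ab, wn.shape).copy()
    for center, w in band_weights.items():
        if center not in FTIR_BAND_CENTERS:
            raise ValueError(f"unknown FTIR band {center}")
        amp = w / (FTIR_SIGMA * np.sqrt(2 * np.pi))
        ab += amp * np.exp(-0.5 * ((wn - center) / FTIR_SIGMA) ** 2)
    if noise_sd > 0:
        ab = ab + np.random.default_rng(seed).normal(0.0, noise_sd, wn.size)
    return FTIRSpectrum(wavenumbers=wn, absorbance=ab)


# -- full study directory ---------------------------------------------------

def default_ground_truth(profile: HabitatProfile, seed: int) -> GroundTruth:
    """Habitat-flavored ground truth for a full synthetic study.

    Rates and alpha follow the qualitative gradient: the labile (fen-like)
    end produces faster and more acetoclastically (low alpha), the palsa end
    slower and hydrogenotrophically (high alpha).
    """
    lab = profile.lability_index
    return GroundTruth(
        formulas=frozenset(generate_compound_library(profile, seed)),
        rate_co2=4.0 + 8.0 * lab,
        rate_ch4=1.0 + 6.0 * lab,
        alpha_true=round(1.075 - 0.035 * lab, 4),
        slope_s=0.012 + 0.008 * lab,
        coble_weights=(("A", 2.0), ("B", 0.3), ("T", 0.4 + lab), ("M", 1.0), ("C", 1.5 + lab)),
        ftir_weights=((1030, 3.0), (1510, 1.0), (1630, 1.5), (1720, 1.0), (2850, 0.5), (2920, 0.7)),
        seed=seed,
    )


def write_study(
    out_dir: str | Path,
    seed: int = 0,
    habitats=("palsa", "bog", "fen"),
    n_compounds: int | None = None,
    ppm_sigma: float = 0.2,
    n_noise: int = 20,
    gas_noise_sd: float = 1.0,
) -> dict:
    """Emit a full synthetic study directory plus ``ground_truth.json``.

    One sample per habitat; every stream is written in the CSV dialect the
    analysis modules read. ``n_compounds`` overrides the preset library
    sizes (useful for fast smoke runs). Returns the ground-truth dict.
    """
    from .ftir import write_ftir
    from .optics import write_absorbance, write_eem
    from .transforms import builtin_moieties, write_moiety_db

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_moiety_db(builtin_moieties(), out / "moieties.csv")

    truth_all: dict[str, dict] = {}
    peaks_frames, gas_frames, meta_rows = [], [], []
    times = np.arange(0.0, 51.0, 5.0)
    for k, habitat in enumerate(habitats):
        prof = HABITAT_PRESETS[habitat]
        if n_compounds is not None:
            prof = HabitatProfile(prof.habitat, prof.mean_oc, prof.mean_hc, n_compounds, prof.lability_index)
        sub_seed = seed + 1000 * (k + 1)
        truth = default_ground_truth(prof, sub_seed)
        sid = f"{habitat}_shallow"
        peaks_frames.append(
            generate_peak_list(
                truth.formulas, ppm_sigma=ppm_sigma, n_noise=n_noise, mode="negative",
                seed=sub_seed + 1, sample_id=sid,
            )
        )
        series = generate_gas_timeseries(truth, times, noise_sd=gas_noise_sd, seed=sub_seed + 2, sample_id=sid)
        gdf = series.data.copy()
        gdf.insert(0, "sample_id", sid)
        gas_frames.append(gdf)
        a0 = 25.0 * np.exp(truth.slope_s * 14.0)  # pins a(254) = 25 m^-1
        write_absorbance(generate_uvvis(truth.slope_s, a0=a0, doc=12.5), out / f"uvvis_{sid}.csv")
        eem, blank = generate_eem(dict(truth.coble_weights), scatter_amplitude=0.5, seed=sub_seed + 3)
        write_eem(eem, out / f"eem_{sid}.csv")
        write_eem(blank, out / f"eem_blank_{sid}.csv")
        write_ftir(
            generate_ftir(dict(truth.ftir_weights), baseline_poly=(0.02, 0.01), seed=sub_seed + 4),
            out / f"ftir_{sid}.csv",
        )
        meta_rows.append(
            {"sample_id": sid, "habitat": habitat, "depth": "shallow", "timepoint": "day0", "replicate": 1}
        )
        truth_all[sid] = {
            "habitat": habitat,
            "n_compounds": len(truth.formulas),
            "rate_co2": truth.rate_co2,
            "rate_ch4": truth.rate_ch4,
            "alpha_true": truth.alpha_true,
            "slope_s": truth.slope_s,
            "coble_weights": dict(truth.coble_weights),
            "ftir_weights": {str(kk): vv for kk, vv in truth.ftir_weights},
            "seed": sub_seed,
        }
    pd.concat(peaks_frames, ignore_index=True).to_csv(out / "peaks.csv", index=False, float_format="%.10g")
    pd.concat(gas_frames, ignore_index=True).to_csv(out / "gas.csv", index=False, float_format="%.8g")
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth_all, indent=2, sort_keys=True))
    return truth_all
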