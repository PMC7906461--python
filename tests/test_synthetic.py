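"""Ground-truth generator: determinism, target recovery, noise contracts."""

import numpy as np
import pandas as pd
import pytest

from peatdom.assignment import apply_rules
from peatdom.chem import PROTON_MASS, Formula
from peatdom.optics import integrate_coble_peaks, spectral_slope_ratio, suva254
from peatdom.synthetic import (
    HABITAT_PRESETS,
    HabitatProfile,
    GroundTruth,
    generate_compound_library,
    generate_eem,
    generate_ftir,
    generate_gas_timeseries,
    generate_peak_list,
    generate_uvvis,
    write_study,
)


def test_presets_are_valid_profiles():
    assert set(HABITAT_PRESETS) == {"palsa", "bog", "fen"}
    for p in HABITAT_PRESETS.values():
        assert 0 < p.mean_oc <= 1.2 and 0.3 <= p.mean_hc <= 2.25


@pytest.mark.parametrize(
    "kw",
    [
        dict(mean_oc=1.5),
        dict(mean_hc=0.1),
        dict(n_compounds=0),
        dict(lability_index=2.0),
    ],
)
def test_invalid_profiles_rejected(kw):
    base = dict(habitat="x", mean_oc=0.5, mean_hc=1.2, n_compounds=10, lability_index=0.5)
    base.update(kw)
    with pytest.raises(ValueError):
        HabitatProfile(**base)


def test_ground_truth_invariants():
    with pytest.raises(ValueError):
        GroundTruth(frozenset(), -1.0, 1.0, 1.05, 0.018, (), (), 0)
    with pytest.raises(ValueError):
        GroundTruth(frozenset(), 1.0, 1.0, 1.5, 0.018, (), (), 0)


# -- compound library -------------------------------------------------------

def test_library_deterministic_and_distinct(fen_profile):
    a = generate_compound_library(fen_profile, seed=42)
    b = generate_compound_library(fen_profile, seed=42)
    assert a == b
    assert len(a) == fen_profile.n_compounds
    assert generate_compound_library(fen_profile, seed=43) != a


def test_library_hits_ratio_targets():
    prof = HabitatProfile("fen", 0.55, 1.35, 500, 0.7)
    lib = generate_compound_library(prof, seed=3)
    oc = np.mean([f.oc for f in lib])
    hc = np.mean([f.hc for f in lib])
    assert abs(oc - prof.mean_oc) < 0.1
    assert abs(hc - prof.mean_hc) < 0.1


def test_single_compound_pins_ratios_exactly():
    prof = HabitatProfile("sugar", 1.0, 2.0, 1, 0.5)
    (f,) = generate_compound_library(prof, seed=0)
    assert f.oc == 1.0 and f.hc == 2.0


def test_library_formulas_pass_screening_rules(small_library):
    assert apply_rules(list(small_library)) == list(small_library)
    assert not any(f.s and f.p for f in small_library)


# -- peak lists -------------------------------------------------------------

def test_noise_free_neutral_peak_is_exact():
    peaks = generate_peak_list({Formula(c=6, h=12, o=6)}, ppm_sigma=0.0, mode="neutral", seed=0)
    assert len(peaks) == 1
    assert peaks["mz"].iloc[0] == pytest.approx(180.06339, abs=1e-5)
    neg = generate_peak_list({Formula(c=6, h=12, o=6)}, ppm_sigma=0.0, mode="negative", seed=0)
    assert neg["mz"].iloc[0] == pytest.approx(180.06339 - PROTON_MASS, abs=1e-5)


def test_empty_formula_set_gives_empty_list():
    assert len(generate_peak_list(set(), ppm_sigma=0.5, n_noise=0, seed=0)) == 0


def test_peak_list_determinism_and_noise_exclusion(small_library):
    a = generate_peak_list(small_library, ppm_sigma=0.5, n_noise=50, seed=9)
    b = generate_peak_list(small_library, ppm_sigma=0.5, n_noise=50, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == len(small_library) + 50
    # every noise peak sits >= 3 sigma (ppm) from every true ionized mass
    true_mz = np.sort([f.mass - PROTON_MASS for f in small_library])
    observed = a["mz"].to_numpy()
    dist_ppm = np.min(np.abs(observed[:, None] - true_mz[None, :]), axis=1) / observed * 1e6
    n_near = int((dist_ppm <= 3 * 0.5).sum())
    assert n_near == len(small_library)  # only the true peaks themselves


def test_true_peaks_within_gaussian_tail_bound(small_library):
    peaks = generate_peak_list(small_library, ppm_sigma=0.5, n_noise=0, seed=5)
    true_mz = np.sort([f.mass - PROTON_MASS for f in small_library])
    err_ppm = np.abs(np.sort(peaks["mz"].to_numpy()) - true_mz) / true_mz * 1e6
    assert (err_ppm < 2.0).mean() > 0.95  # 4-sigma bound


# -- gas series -------------------------------------------------------------

def test_gas_linear_no_noise_amounts():
    truth = GroundTruth(frozenset(), 10.0, 5.0, 1.0, 0.018, (), (), 0)
    series = generate_gas_timeseries(truth, [0.0, 5.0, 10.0], noise_sd=0.0, seed=0)
    from peatdom.gas import amount_series

    assert amount_series(series, "CO2") == pytest.approx([0.0, 50.0, 100.0], abs=1e-9)


def test_gas_alpha_identity_and_exact_construction():
    t_eq = GroundTruth(frozenset(), 1.0, 1.0, 1.0, 0.018, (), (), 0)
    s = generate_gas_timeseries(t_eq, [0.0, 5.0], seed=0)
    assert np.allclose(s.data["d13_co2"], s.data["d13_ch4"])

    alpha = 1000.0 / 940.0  # makes d13_co2 exactly 0 at d13_ch4 = -60
    t = GroundTruth(frozenset(), 1.0, 1.0, alpha, 0.018, (), (), 0)
    s2 = generate_gas_timeseries(t, [0.0, 5.0], seed=0, d13_ch4_base=-60.0)
    assert s2.data["d13_co2"].to_numpy() == pytest.approx(0.0, abs=1e-9)


def test_gas_requires_two_increasing_points():
    truth = GroundTruth(frozenset(), 1.0, 1.0, 1.05, 0.018, (), (), 0)
    with pytest.raises(ValueError):
        generate_gas_timeseries(truth, [0.0], seed=0)
    with pytest.raises(ValueError):
        generate_gas_timeseries(truth, [0.0, 0.0], seed=0)


# -- optics streams ---------------------------------------------------------

def test_uvvis_closed_forms():
    a254 = 25.0
    spec = generate_uvvis(0.018, a0=a254 * np.exp(0.018 * 14.0), doc=12.5)
    assert suva254(spec) == pytest.approx(2.0, abs=1e-9)
    assert spectral_slope_ratio(spec) == pytest.approx(1.0, abs=1e-9)
    doubled = generate_uvvis(0.018, a0=2 * a254 * np.exp(0.018 * 14.0), doc=12.5)
    assert suva254(doubled) == pytest.approx(4.0, abs=1e-9)
    assert spectral_slope_ratio(doubled) == pytest.approx(1.0, abs=1e-9)


def test_eem_weights_control_peak_areas():
    only_c, blank = generate_eem({"C": 1.0}, scatter_amplitude=0.0, seed=0)
    areas = integrate_coble_peaks(only_c)
    assert areas["C"] > 0
    assert areas["T"] == pytest.approx(0.0, abs=1e-6 * areas["C"])
    zero, zero_blank = generate_eem({}, scatter_amplitude=0.0, seed=0)
    assert all(v == 0.0 for v in integrate_coble_peaks(zero).values())
    assert float(zero_blank.intensity.sum()) == 0.0


def test_eem_blank_contains_only_ridges():
    eem, blank = generate_eem({"C": 2.0}, scatter_amplitude=1.0, seed=1)
    # the C fluorophore appears in the sample but not in the blank
    assert integrate_coble_peaks(eem)["C"] > 10 * integrate_coble_peaks(blank)["C"]


def test_eem_determinism():
    a, ab = generate_eem({"C": 1.0, "M": 0.5}, scatter_amplitude=0.5, seed=7, noise_sd=0.01)
    b, bb = generate_eem({"C": 1.0, "M": 0.5}, scatter_amplitude=0.5, seed=7, noise_sd=0.01)
    assert np.array_equal(a.intensity, b.intensity)
    assert np.array_equal(ab.intensity, bb.intensity)


def test_ftir_generator_contracts():
    zero = generate_ftir({}, baseline_poly=(0.0,))
    assert np.allclose(zero.absorbance, 0.0)
    with pytest.raises(ValueError):
        generate_ftir({999: 1.0})


# -- study directory --------------------------------------------------------

def test_write_study_emits_all_streams(tmp_path):
    out = tmp_path / "study"
    truth = write_study(out, seed=5, n_compounds=30, n_noise=5)
    assert set(truth) == {"palsa_shallow", "bog_shallow", "fen_shallow"}
    for name in ["peaks.csv", "gas.csv", "metadata.csv", "moieties.csv", "ground_truth.json"]:
        assert (out / name).exists()
    for sid in truth:
        for prefix in ["uvvis", "eem", "eem_blank", "ftir"]:
            assert (out / f"{prefix}_{sid}.csv").exists()
    # deterministic rerun is byte-identical
    out2 = tmp_path / "study2"
    write_study(out2, seed=5, n_compounds=30, n_noise=5)
    assert (out / "peaks.csv").read_bytes() == (out2 / "peaks.csv").read_bytes()
    assert (out / "gas.csv").read_bytes() == (out2 / "gas.csv").read_bytes()
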