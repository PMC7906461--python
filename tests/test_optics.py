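"""UV-Vis metrics, EEM corrections and Coble peak integration."""

import numpy as np
import pytest

from peatdom.optics import (
    COBLE_WINDOWS,
    AbsorbanceSpectrum,
    EEM,
    integrate_coble_peaks,
    peak_ratios,
    qse_convert,
    raman_normalize,
    read_absorbance,
    read_eem,
    remove_scatter,
    spectral_slope,
    spectral_slope_ratio,
    suva254,
    write_absorbance,
    write_eem,
)
from peatdom.synthetic import (
    COBLE_CENTERS,
    gaussian_window_mass,
    generate_eem,
    generate_uvvis,
)


def exponential_spectrum(s=0.018, a254=25.0, doc=12.5):
    a0 = a254 * np.exp(s * 14.0)
    return generate_uvvis(s, a0=a0, doc=doc)


# -- absorbance -------------------------------------------------------------

def test_suva254_reference_value():
    spec = exponential_spectrum()
    assert suva254(spec) == pytest.approx(2.0, abs=1e-9)


def test_suva254_scales():
    spec = exponential_spectrum(doc=25.0)
    assert suva254(spec) == pytest.approx(1.0, abs=1e-9)
    zero = AbsorbanceSpectrum(np.arange(240.0, 801.0), np.zeros(561), doc_mg_l=10.0)
    assert suva254(zero) == 0.0


def test_suva254_requires_doc():
    spec = generate_uvvis(0.018, a0=10.0, doc=12.5)
    no_doc = AbsorbanceSpectrum(spec.wavelengths, spec.absorbance, doc_mg_l=None)
    with pytest.raises(ValueError):
        suva254(no_doc)
    with pytest.raises(ValueError):
        suva254(AbsorbanceSpectrum(spec.wavelengths, spec.absorbance, doc_mg_l=0.0))


def test_slope_ratio_single_exponential_is_one():
    assert spectral_slope_ratio(exponential_spectrum()) == pytest.approx(1.0, abs=1e-9)
    assert spectral_slope_ratio(exponential_spectrum(), method="finite-difference") == (
        pytest.approx(1.0, abs=1e-9)
    )


def test_slope_ratio_two_exponentials_exceeds_one():
    wl = np.arange(240.0, 801.0)
    # steep component dominates short wavelengths -> S275-295 > S350-400
    a = 30.0 * np.exp(-0.030 * (wl - 240.0)) + 5.0 * np.exp(-0.008 * (wl - 240.0))
    spec = AbsorbanceSpectrum(wl, a * 0.01, doc_mg_l=10.0)
    assert spectral_slope_ratio(spec) > 1.0


def test_slope_flat_spectrum_flagged():
    wl = np.arange(240.0, 801.0)
    spec = AbsorbanceSpectrum(wl, np.full(wl.size, 0.5))
    with pytest.warns(UserWarning):
        assert np.isnan(spectral_slope_ratio(spec))


def test_slope_rejects_nonpositive_absorbance():
    wl = np.arange(240.0, 801.0)
    a = np.full(wl.size, 0.1)
    a[40] = 0.0
    with pytest.raises(ValueError):
        spectral_slope(AbsorbanceSpectrum(wl, a), (275.0, 295.0))


def test_pathlength_invariance():
    """Same sample in a longer cuvette: A scales with l, metrics unchanged."""
    s1 = exponential_spectrum()
    s2 = AbsorbanceSpectrum(
        s1.wavelengths, s1.absorbance * 10.0, pathlength_m=0.1, doc_mg_l=s1.doc_mg_l
    )
    assert suva254(s2) == pytest.approx(suva254(s1), rel=1e-12)
    assert spectral_slope_ratio(s2) == pytest.approx(spectral_slope_ratio(s1), rel=1e-12)


# -- EEM corrections --------------------------------------------------------

def test_remove_scatter_strips_ridges():
    ridges, _ = generate_eem({}, scatter_amplitude=1.0, seed=0)
    cleaned = remove_scatter(ridges)
    assert cleaned.intensity.sum() <= 0.01 * ridges.intensity.sum()


def test_remove_scatter_preserves_fluorophores():
    eem, _ = generate_eem({"C": 1.0}, scatter_amplitude=0.0, seed=0)
    before = integrate_coble_peaks(eem)["C"]
    after = integrate_coble_peaks(remove_scatter(eem))["C"]
    assert after == pytest.approx(before, rel=0.01)


def test_raman_normalize_divides_by_blank_area():
    eem, blank = generate_eem({"C": 1.0}, scatter_amplitude=0.8, seed=0)
    from peatdom.optics import raman_peak_area

    area = raman_peak_area(blank)
    assert area > 0
    out = raman_normalize(eem, blank)
    assert np.allclose(out.intensity, eem.intensity / area)
    assert out.units == "Raman-normalized"


def test_raman_normalize_cancels_instrument_gain():
    eem, blank = generate_eem({"C": 2.0, "M": 1.0}, scatter_amplitude=0.5, seed=0)
    gained = eem.scaled(7.3)
    gained_blank = blank.scaled(7.3)
    a = raman_normalize(eem, blank)
    b = raman_normalize(gained, gained_blank)
    assert np.allclose(a.intensity, b.intensity)


def test_qse_and_raman_are_commuting_linear_maps():
    eem, blank = generate_eem({"M": 1.0}, scatter_amplitude=0.4, seed=0)
    ab = qse_convert(raman_normalize(eem, blank), 2.0)
    ba = raman_normalize(qse_convert(eem, 2.0), qse_convert(blank, 2.0))
    # qse scaling of the blank rescales its Raman area too, so normalize first
    assert np.allclose(ab.intensity, qse_convert(raman_normalize(eem, blank), 2.0).intensity)
    assert qse_convert(eem, 1.0).intensity == pytest.approx(eem.intensity)
    assert np.allclose(qse_convert(qse_convert(eem, 2.0), 0.5).intensity, eem.intensity)


# -- Coble peaks ------------------------------------------------------------

def test_coble_zero_eem():
    eem, _ = generate_eem({}, scatter_amplitude=0.0, seed=0)
    assert all(v == 0.0 for v in integrate_coble_peaks(eem).values())


def test_coble_gaussian_matches_analytic_mass():
    eem, _ = generate_eem({"C": 1.0}, scatter_amplitude=0.0, seed=0)
    area = integrate_coble_peaks(eem)["C"]
    analytic = gaussian_window_mass(COBLE_CENTERS["C"], COBLE_WINDOWS["C"])
    assert area == pytest.approx(analytic, rel=0.10)


def test_coble_linearity():
    eem, _ = generate_eem({"A": 1.0, "C": 0.5}, scatter_amplitude=0.0, seed=0)
    doubled = eem.scaled(2.0)
    a1 = integrate_coble_peaks(eem)
    a2 = integrate_coble_peaks(doubled)
    for k in a1:
        assert a2[k] == pytest.approx(2 * a1[k], rel=1e-12)


def test_coble_window_outside_grid_errors():
    eem, _ = generate_eem({}, scatter_amplitude=0.0, seed=0)
    with pytest.raises(ValueError):
        integrate_coble_peaks(eem, {"X": ((100.0, 120.0), (300.0, 320.0))})


def test_peak_ratios_and_flags():
    r = peak_ratios({"A": 2.0, "B": 1.0, "T": 2.0, "M": 2.0, "C": 2.0})
    assert r["C/M"] == 1.0 and r["C/A"] == 1.0 and r["A/T"] == 1.0
    flagged = peak_ratios({"A": 1.0, "C": 1.0, "M": 1.0, "T": 0.0})
    assert np.isnan(flagged["C/T"]) and np.isnan(flagged["A/T"])


def test_full_pipeline_c_to_m_ratio_matches_generator_weights():
    eem, blank = generate_eem({"C": 2.0, "M": 1.0}, scatter_amplitude=0.5, seed=0)
    cleaned = raman_normalize(remove_scatter(eem), blank)
    ratios = peak_ratios(integrate_coble_peaks(cleaned))
    gc = gaussian_window_mass(COBLE_CENTERS["C"], COBLE_WINDOWS["C"])
    gm = gaussian_window_mass(COBLE_CENTERS["M"], COBLE_WINDOWS["M"])
    assert ratios["C/M"] == pytest.approx(2.0 * gc / gm, rel=0.10)


# -- I/O --------------------------------------------------------------------

def test_absorbance_and_eem_round_trip(tmp_path):
    spec = exponential_spectrum()
    p = tmp_path / "uvvis.csv"
    write_absorbance(spec, p)
    back = read_absorbance(p, doc_mg_l=12.5)
    assert suva254(back) == pytest.approx(2.0, abs=1e-6)

    eem, _ = generate_eem({"C": 1.0, "T": 0.3}, scatter_amplitude=0.2, seed=3)
    q = tmp_path / "eem.csv"
    write_eem(eem, q)
    back_eem = read_eem(q)
    assert np.allclose(back_eem.intensity, eem.intensity, rtol=1e-6)
    assert np.allclose(back_eem.ex, eem.ex)


def test_spectrum_validation():
    with pytest.raises(ValueError):
        AbsorbanceSpectrum(np.array([300.0, 250.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        EEM(np.array([240.0, 245.0]), np.array([290.0, 292.0]), np.zeros((3, 2)))
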