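"""Formula assignment: neutralization, enumeration, screening, selection."""

import numpy as np
import pandas as pd
import pytest

from peatdom.assignment import (
    AssignmentConfig,
    apply_rules,
    assign_peak,
    assign_peaklist,
    assignment_rate,
    enumerate_candidates,
    neutralize_mass,
    read_peaklist,
    select_assignment,
    write_assignments,
)
from peatdom.chem import MONOISOTOPIC_MASS, PROTON_MASS, Formula, exact_mass
from peatdom.synthetic import generate_peak_list, library_assignment_config

GLUCOSE = Formula(c=6, h=12, o=6)


# -- neutralization ---------------------------------------------------------

def test_neutralize_modes():
    assert neutralize_mass(180.06339, "neutral") == 180.06339
    assert neutralize_mass(179.05611, "negative") == pytest.approx(180.06339, abs=1e-5)
    x = 412.34
    assert neutralize_mass(neutralize_mass(x, "positive"), "negative") == pytest.approx(x, abs=1e-12)


def test_neutralize_errors():
    with pytest.raises(ValueError):
        neutralize_mass(100.0, "electrospray")
    with pytest.raises(ValueError):
        neutralize_mass(-1.0, "neutral")


# -- candidate enumeration --------------------------------------------------

def brute_force_candidates(neutral_mass, limits, tol_ppm):
    """Independent oracle: full nested loop over every CHNOSP tuple."""
    tol = neutral_mass * tol_ppm * 1e-6
    out = set()
    for c in range(1, limits["C"] + 1):
        for h in range(limits["H"] + 1):
            base_ch = c * 12.0 + h * MONOISOTOPIC_MASS["H"]
            if base_ch > neutral_mass + tol:
                break
            for n in range(limits["N"] + 1):
                for o in range(limits["O"] + 1):
                    for s in range(limits["S"] + 1):
                        for p in range(limits["P"] + 1):
                            m = (
                                base_ch
                                + n * MONOISOTOPIC_MASS["N"]
                                + o * MONOISOTOPIC_MASS["O"]
                                + s * MONOISOTOPIC_MASS["S"]
                                + p * MONOISOTOPIC_MASS["P"]
                            )
                            if abs(m - neutral_mass) <= tol:
                                out.add(Formula(c=c, h=h, n=n, o=o, s=s, p=p))
    return out


def test_enumeration_contains_glucose():
    cfg = AssignmentConfig(tolerance_ppm=1.0).with_limits(C=40, H=80, N=2, O=20, S=1, P=1)
    assert GLUCOSE in enumerate_candidates(180.06339, cfg)


def test_enumeration_empty_for_impossible_mass():
    cfg = AssignmentConfig(tolerance_ppm=1.0).with_limits(C=10, H=20, N=0, O=5, S=0, P=0)
    assert enumerate_candidates(50.0, cfg) == []


def test_enumeration_zero_tolerance_degenerate():
    cfg = AssignmentConfig(tolerance_ppm=1e-9)
    cands = enumerate_candidates(GLUCOSE.mass, cfg)
    assert cands == [GLUCOSE]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_enumeration_matches_brute_force(seed):
    """Oracle equivalence on random masses with small element limits."""
    limits = {"C": 15, "H": 30, "N": 2, "O": 8, "S": 1, "P": 1}
    cfg = AssignmentConfig(tolerance_ppm=5.0).with_limits(**limits)
    rng = np.random.default_rng(seed)
    for mass in rng.uniform(100, 350, 5):
        got = set(enumerate_candidates(mass, cfg))
        want = brute_force_candidates(mass, limits, 5.0)
        assert got == want


def test_enumeration_monotone_in_tolerance():
    mass = 301.1
    prev: set = set()
    for tol in (0.5, 2.0, 10.0, 50.0):
        cur = set(enumerate_candidates(mass, AssignmentConfig(tolerance_ppm=tol)))
        assert prev <= cur
        prev = cur


# -- screening rules --------------------------------------------------------

def test_rules_retain_glucose():
    assert apply_rules([GLUCOSE]) == [GLUCOSE]


@pytest.mark.parametrize(
    "formula,reason",
    [
        (Formula(c=1, h=5, o=1), "H/C=5 outside bounds"),
        (Formula(c=6, h=13, o=6), "odd parity, non-integer DBE"),
        (Formula(c=6, h=2, o=9), "O/C=1.5 outside bounds"),
        (Formula(c=20, h=10, o=0), "DBE-O=16 exceeds plausibility cap"),
        (Formula(c=6, h=15, o=2, p=1), "P without phosphate oxygen"),
        (Formula(c=10, h=17, n=1, o=8, s=1, p=1), "S and P together"),
    ],
)
def test_rules_reject(formula, reason):
    assert apply_rules([formula]) == [], reason


def test_rules_configurable():
    aromatic = Formula(c=20, h=10, o=0)
    cfg = AssignmentConfig(max_dbe_minus_o=None)
    assert apply_rules([aromatic], cfg) == [aromatic]


# -- selection --------------------------------------------------------------

def test_select_single_and_empty():
    a = select_assignment([GLUCOSE], GLUCOSE.mass)
    assert a.formula == GLUCOSE and a.error_ppm == pytest.approx(0.0, abs=1e-9)
    assert select_assignment([], 300.0).formula is None


def test_select_tie_prefers_fewer_heteroatoms():
    # construct two candidates equidistant from the target mass
    cho = Formula(c=10, h=16, o=5)
    chnos = Formula(c=9, h=14, n=2, o=4, s=0)
    target = (cho.mass + chnos.mass) / 2.0
    chosen = select_assignment([chnos, cho], target)
    assert chosen.formula == cho


def test_select_exact_match_never_displaced_by_handicap():
    """A zero-error heteroatom formula beats any near-isobar neighbor."""
    true = Formula(c=15, h=22, n=2, o=8, s=1)
    rival = Formula(c=23, h=18, o=6)  # 0.651 mDa away (2N+S <-> 8C-4H-2O swap)
    assert abs((true.mass - rival.mass)) < 1e-3
    chosen = select_assignment([rival, true], true.mass)
    assert chosen.formula == true


# -- peak list level --------------------------------------------------------

def test_assign_peaklist_round_trip(small_library):
    peaks = generate_peak_list(small_library, ppm_sigma=0.0, n_noise=0, mode="negative", seed=7)
    table = assign_peaklist(peaks, library_assignment_config(1.0))
    recovered = set(table.loc[table["formula"] != "", "formula"])
    assert recovered == {str(f) for f in small_library}
    assert table.attrs["assignment_rate"] == 1.0


def test_assign_peaklist_empty_flags_rate():
    empty = pd.DataFrame(columns=["sample_id", "mz", "intensity"])
    with pytest.warns(UserWarning):
        table = assign_peaklist(empty)
    assert len(table) == 0 and np.isnan(table.attrs["assignment_rate"])


def test_unassignable_noise_mass_lowers_rate():
    peaks = pd.DataFrame(
        {
            "sample_id": ["s"] * 3,
            # glucose and sucrose-like [M-H]- plus a mass with no valid formula nearby
            "mz": [GLUCOSE.mass - PROTON_MASS, exact_mass("C12H22O11") - PROTON_MASS, 150.5123],
            "intensity": [1.0, 1.0, 1.0],
        }
    )
    table = assign_peaklist(peaks, AssignmentConfig(tolerance_ppm=1.0))
    assert assignment_rate(table) == pytest.approx(2 / 3)


def test_assign_peaklist_sorted_by_sample_and_mz():
    peaks = pd.DataFrame(
        {
            "sample_id": ["b", "a", "a"],
            "mz": [200.0, 300.0, 150.0],
            "intensity": [1.0, 1.0, 1.0],
        }
    )
    table = assign_peaklist(peaks)
    assert list(table["sample_id"]) == ["a", "a", "b"]
    assert list(table["mz"]) == [150.0, 300.0, 200.0]


def test_mass_range_gate():
    a = assign_peak(50.0, AssignmentConfig(ionization_mode="neutral"))
    assert a.formula is None


def test_assignment_csv_round_trip(tmp_path, small_library):
    peaks = generate_peak_list(small_library[:20], ppm_sigma=0.0, seed=3)
    table = assign_peaklist(peaks, library_assignment_config(1.0))
    path = tmp_path / "assignments.csv"
    write_assignments(table, path)
    back = pd.read_csv(path)
    assert list(back["formula"]) == list(table["formula"])

    peaks_path = tmp_path / "peaks.csv"
    peaks.to_csv(peaks_path, index=False)
    assert len(read_peaklist(peaks_path)) == len(peaks)
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.csv"
        pd.DataFrame({"mz": [1.0]}).to_csv(bad, index=False)
        read_peaklist(bad)
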