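"""Per-formula DOM quality indices and compound-set comparisons.

Implements the standard organic-matter quality metrics computed from assigned
elemental compositions:

* NOSC — nominal oxidation state of carbon,
  ``4 − (4C + H − 3N − 2O + 5P − 2S)/C``, bounded by CH4 (−4) and CO2 (+4);
  a proxy for the oxidative energy remaining in a compound.
* DBE — double-bond equivalents, ``1 + (2C − H + N + P)/2``.
* AI — Koch–Dittmar aromaticity index (original form by default, the
  modified AImod available via a switch), clamped to 0 when the numerator
  or denominator is non-positive.
* van Krevelen compound classes from rectangular H/C–O/C boxes.

plus field-vs-incubation style set overlaps of formula inventories.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem import Formula

__all__ = [
    "nosc",
    "dbe",
    "aromaticity_index",
    "van_krevelen_class",
    "VK_BOXES",
    "FormulaMetrics",
    "formula_metrics",
    "metrics_table",
    "SampleDOMSummary",
    "sample_summary",
    "OverlapResult",
    "compare_sets",
    "unique_compound_table",
]


def nosc(f: Formula) -> float:
    """Nominal oxidation state of carbon.

    NOSC = 4 − (4·C + H − 3·N − 2·O + 5·P − 2·S)/C.  CH4 → −4 (fully
    reduced), CO2 → +4 (fully oxidized), glucose → 0.
    """
    if f.c < 1:
        raise ValueError("NOSC undefined for carbon-free formula")
    return 4.0 - (4 * f.c + f.h - 3 * f.n - 2 * f.o + 5 * f.p - 2 * f.s) / f.c


def dbe(f: Formula) -> float:
    """Double-bond equivalents: rings plus pi bonds, 1 + (2C − H + N + P)/2."""
    return 1.0 + (2 * f.c - f.h + f.n + f.p) / 2.0


def aromaticity_index(f: Formula, modified: bool = False) -> float:
    """Koch–Dittmar aromaticity index.

    Original form: AI = DBE_AI / C_AI with DBE_AI = 1 + C − O − S − H/2 and
    C_AI = C − O − S − N − P. ``modified=True`` uses AImod, which counts only
    half the oxygen as pi-bonded (carboxyl-corrected): DBE_AI = 1 + C − O/2
    − S − H/2, C_AI = C − O/2 − S − N − P. Clamped to 0 when either term is
    non-positive (fully saturated or heteroatom-dominated compositions).
    """
    o_eff = f.o / 2.0 if modified else float(f.o)
    dbe_ai = 1.0 + f.c - o_eff - f.s - f.h / 2.0
    c_ai = f.c - o_eff - f.s - f.n - f.p
    if dbe_ai <= 0 or c_ai <= 0:
        return 0.0
    return dbe_ai / c_ai


#: Ordered van Krevelen boxes: (label, hc_lo, hc_hi, oc_lo, oc_hi), each
#: interval half-open as (lo, hi] so boundary points land deterministically
#: in the lower-O/C (and lower-H/C) class. First match wins; anything that
#: matches no box is "other". Boundaries follow common DOM-literature
#: conventions and are editable by passing a custom box list.
VK_BOXES: tuple[tuple[str, float, float, float, float], ...] = (
    ("condensed aromatic", 0.0, 0.7, -1.0, 0.67),
    ("unsaturated hydrocarbon", 0.7, 1.5, -1.0, 0.1),
    ("lignin-like", 0.7, 1.5, 0.1, 0.67),
    ("tannin-like", 0.5, 1.5, 0.67, 1.2),
    ("lipid-like", 1.5, 2.3, -1.0, 0.3),
    ("protein/aliphatic", 1.5, 2.3, 0.3, 0.56),
    ("carbohydrate-like", 1.5, 2.3, 0.56, 1.2),
)


def van_krevelen_class(
    f: Formula,
    boxes: tuple[tuple[str, float, float, float, float], ...] = VK_BOXES,
) -> str:
    hc, oc = f.hc, f.oc
    for label, hc_lo, hc_hi, oc_lo, oc_hi in boxes:
        if hc_lo < hc <= hc_hi and oc_lo < oc <= oc_hi:
            return label
    return "other"


@dataclass(frozen=True)
class FormulaMetrics:
    formula: Formula
    oc: float
    hc: float
    nosc: float
    dbe: float
    ai: float
    vk_class: str


def formula_metrics(f: Formula, modified_ai: bool = False) -> FormulaMetrics:
    return FormulaMetrics(
        formula=f,
        oc=f.oc,
        hc=f.hc,
        nosc=nosc(f),
        dbe=dbe(f),
        ai=aromaticity_index(f, modified=modified_ai),
        vk_class=van_krevelen_class(f),
    )


def metrics_table(formulas, sample_id: str = "", modified_ai: bool = False) -> pd.DataFrame:
    """Long table of per-formula indices, sorted by exact mass."""
    rows = []
    for f in sorted(formulas, key=lambda x: x.mass):
        m = formula_metrics(f, modified_ai=modified_ai)
        rows.append(
            {
                "sample_id": sample_id,
                "formula": str(f),
                "mass": f.mass,
                "oc": m.oc,
                "hc": m.hc,
                "nosc": m.nosc,
                "dbe": m.dbe,
                "ai": m.ai,
                "vk_class": m.vk_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "formula", "mass", "oc", "hc", "nosc", "dbe", "ai", "vk_class"],
    )


@dataclass(frozen=True)
class SampleDOMSummary:
    sample_id: str
    n_formulas: int
    mean_nosc: float
    mean_dbe: float
    mean_ai: float
    mean_oc: float
    mean_hc: float


def sample_summary(table: pd.DataFrame, sample_id: str) -> SampleDOMSummary:
    """Unweighted per-sample means of the indices over assigned formulas.

    Intensity weighting is deliberately not applied: FTICR-MS identifies
    which compounds are present but does not quantify them.
    """
    sub = table[(table["sample_id"] == sample_id) & (table["formula"] != "")]
    if len(sub) == 0:
        raise ValueError(f"no assigned formulas for sample {sample_id!r}")
    formulas = [Formula.from_string(s) for s in sub["formula"]]
    n = len(formulas)
    return SampleDOMSummary(
        sample_id=sample_id,
        n_formulas=n,
        mean_nosc=sum(nosc(f) for f in formulas) / n,
        mean_dbe=sum(dbe(f) for f in formulas) / n,
        mean_ai=sum(aromaticity_index(f) for f in formulas) / n,
        mean_oc=sum(f.oc for f in formulas) / n,
        mean_hc=sum(f.hc for f in formulas) / n,
    )


@dataclass(frozen=True)
class OverlapResult:
    n_only_a: int
    n_only_b: int
    n_shared: int
    pct_a_in_b: float


def compare_sets(a: set, b: set) -> OverlapResult:
    """Venn-style overlap of two formula inventories (exact identity).

    ``pct_a_in_b`` is the percentage of A's compounds also found in B —
    the "percent of field compounds also found in the incubations" reading.
    """
    a, b = set(a), set(b)
    shared = a & b
    n_a = len(a)
    pct = 100.0 * len(shared) / n_a if n_a else float("nan")
    return OverlapResult(
        n_only_a=len(a - b), n_only_b=len(b - a), n_shared=len(shared), pct_a_in_b=pct
    )


def unique_compound_table(a: set, b: set) -> pd.DataFrame:
    """Label each formula unique-A / unique-B / shared with its H/C, O/C.

    Ready-to-plot van Krevelen scatter data for field-vs-incubation overlays.
    """
    a, b = set(a), set(b)
    rows = []
    for f in sorted(a | b, key=lambda x: x.mass):
        label = "shared" if (f in a and f in b) else ("unique-A" if f in a else "unique-B")
        rows.append({"formula": str(f), "label": label, "hc": f.hc, "oc": f.oc})
    return pd.DataFrame(rows, columns=["formula", "label", "hc", "oc"])
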