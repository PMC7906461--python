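"""Mass-difference transformation analysis.

Within one sample, every unordered pair of assigned compounds yields an exact
mass difference; differences matching the mass of a reference chemical moiety
(CO2 = decarboxylation, H2 = hydrogenation/dehydrogenation, H2O =
(de)hydration, ...) are counted as potential transformations. Counts are
tallied per moiety and ranked; one compound can participate in many pairs, so
totals may exceed the number of compounds.

Matching is done on an absolute Dalton tolerance (default 1 mDa): the
moieties of interest are small, so a ppm tolerance would be ill-conditioned
for light differences like H2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chem import Formula, exact_mass

__all__ = [
    "Moiety",
    "TransformCounts",
    "builtin_moieties",
    "load_moiety_db",
    "write_moiety_db",
    "pairwise_differences",
    "match_transforms",
    "top_transforms",
    "transform_profile_compare",
]

MASS_CONSISTENCY_TOL = 1e-5  # Da; formula-vs-stated-mass agreement required in a DB


@dataclass(frozen=True)
class Moiety:
    """A named gain/loss unit: plain formula or composite (e.g. methanol−H2O)."""

    name: str
    formula: Formula | None
    exact_mass: float

    def __post_init__(self) -> None:
        if self.exact_mass <= 0:
            raise ValueError(f"moiety {self.name!r} must have positive mass")
        if self.formula is not None:
            if abs(self.formula.mass - self.exact_mass) > MASS_CONSISTENCY_TOL:
                raise ValueError(
                    f"moiety {self.name!r}: stated mass {self.exact_mass} disagrees with "
                    f"formula mass {self.formula.mass:.6f}"
                )


@dataclass(frozen=True)
class TransformCounts:
    sample_id: str
    counts: tuple[tuple[str, int], ...]

    @property
    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total(self) -> int:
        return sum(v for _, v in self.counts)


def _m(name: str, formula: str | None, mass: float | None = None) -> Moiety:
    f = Formula.from_string(formula) if formula else None
    return Moiety(name=name, formula=f, exact_mass=mass if mass is not None else f.mass)


def builtin_moieties() -> list[Moiety]:
    """Starter reference set of ~40 literature-standard moieties.

    Covers the common microbial and abiotic decomposition steps
    (decarboxylation, (de)hydration, hydrogenation, oxygenation,
    (de)methylation, amination, sulfonation, phosphorylation, sugar and
    amino-acid condensations). Composite entries such as ``methanol-H2O``
    carry the net mass of the combined gain/loss. Users studying a specific
    system should extend or replace this set via :func:`load_moiety_db`.
    """
    glucose_h2o = exact_mass("C6H12O6") - exact_mass("H2O")
    methanol_h2o = exact_mass("CH4O") - exact_mass("H2O")
    return [
        _m("H2", "H2"),
        _m("O", "O"),
        _m("H2O", "H2O"),
        _m("OH", "HO"),
        _m("NH", "HN"),
        _m("NH2", "H2N"),
        _m("NH3", "H3N"),
        _m("CH2", "CH2"),
        _m("CH4", "CH4"),
        _m("CO", "CO"),
        _m("CO2", "CO2"),
        _m("CH2O", "CH2O"),
        _m("CHO", "CHO"),
        _m("CH3N", "CH3N"),
        _m("CH4O (methanol)", "CH4O"),
        Moiety("methanol-H2O", None, methanol_h2o),
        _m("C2H2", "C2H2"),
        _m("C2H4", "C2H4"),
        _m("C2H2O (ketene)", "C2H2O"),
        _m("C2H4O (acetaldehyde)", "C2H4O"),
        _m("C2H4O2 (acetic acid)", "C2H4O2"),
        _m("C2H2O2 (glyoxal)", "C2H2O2"),
        _m("C3H4O2", "C3H4O2"),
        _m("C3H6O2 (propionic acid)", "C3H6O2"),
        _m("C3H4O3 (pyruvic acid)", "C3H4O3"),
        _m("C3H6O3 (lactic/glyceraldehyde)", "C3H6O3"),
        _m("C4H6O4 (succinic acid)", "C4H6O4"),
        _m("C6H6O3 (phloroglucinol)", "C6H6O3"),
        _m("HPO3", "HO3P"),
        _m("H3PO4", "H3O4P"),
        _m("SO2", "O2S"),
        _m("SO3", "O3S"),
        _m("H2S", "H2S"),
        _m("glycine (C2H3NO)", "C2H3NO"),
        _m("alanine (C3H5NO)", "C3H5NO"),
        _m("serine (C3H5NO2)", "C3H5NO2"),
        _m("cysteine (C3H5NOS)", "C3H5NOS"),
        Moiety("glucose-H2O (glycosylation)", None, glucose_h2o),
        _m("C5H8O4 (pentose-H2O)", "C5H8O4"),
        _m("C6H10O4 (deoxyhexose-H2O)", "C6H10O4"),
        _m("C6H10O5 (hexose-H2O)", "C6H10O5"),
    ]


def load_moiety_db(path: str | Path) -> list[Moiety]:
    """Load a ``name,formula,exact_mass`` CSV of reference moieties.

    Formula entries may be blank for composite moieties; when both a formula
    and a mass are given they must agree within 1e-5 Da. Duplicate names are
    rejected; an empty file yields an empty database with a warning.
    """
    df = pd.read_csv(path, dtype={"name": str, "formula": str})
    missing = {"name", "formula", "exact_mass"} - set(df.columns)
    if missing:
        raise ValueError(f"moiety DB {path} missing columns {sorted(missing)}")
    if len(df) == 0:
        warnings.warn(f"moiety database {path} is empty", stacklevel=2)
        return []
    if df["name"].duplicated().any():
        dups = sorted(df.loc[df["name"].duplicated(), "name"].unique())
        raise ValueError(f"duplicate moiety names: {dups}")
    moieties = []
    for rec in df.itertuples(index=False):
        fstr = rec.formula if isinstance(rec.formula, str) and rec.formula.strip() else None
        f = Formula.from_string(fstr) if fstr else None
        mass = float(rec.exact_mass) if pd.notna(rec.exact_mass) else None
        if mass is None:
            if f is None:
                raise ValueError(f"moiety {rec.name!r}: neither formula nor mass given")
            mass = f.mass
        moieties.append(Moiety(name=str(rec.name), formula=f, exact_mass=mass))
    return moieties


def write_moiety_db(moieties: list[Moiety], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [m.name for m in moieties],
            "formula": [str(m.formula) if m.formula else "" for m in moieties],
            "exact_mass": [m.exact_mass for m in moieties],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def pairwise_differences(masses) -> list[tuple[int, int, float]]:
    """All n·(n−1)/2 unordered pair mass differences ``(i, j, |Δm|)``."""
    masses = [float(m) for m in masses]
    if any(not np.isfinite(m) or m <= 0 for m in masses):
        raise ValueError("masses must be finite and positive")
    return [(i, j, abs(masses[j] - masses[i])) for i, j in combinations(range(len(masses)), 2)]


def match_transforms(
    differences,
    db: list[Moiety],
    tol_da: float = 0.001,
    sample_id: str = "",
) -> TransformCounts:
    """Count pairs whose |Δm| matches each moiety within ``tol_da``.

    One pair may match several moieties (isobaric references), and one
    compound participates in many pairs; each unordered pair contributes at
    most once per moiety.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    dm = np.asarray([d[2] for d in differences], dtype=float)
    counts = []
    for m in db:
        k = int(np.count_nonzero(np.abs(dm - m.exact_mass) <= tol_da)) if dm.size else 0
        counts.append((m.name, k))
    return TransformCounts(sample_id=sample_id, counts=tuple(counts))


def top_transforms(counts: TransformCounts, k: int = 5) -> list[tuple[str, float]]:
    """Top-k moieties as (name, percent of total counts), descending.

    Ties break alphabetically; an all-zero count table yields an empty list
    with a warning.
    """
    total = counts.total
    if total == 0:
        warnings.warn(f"sample {counts.sample_id!r}: no transform matches", stacklevel=2)
        return []
    nonzero = [(name, c) for name, c in counts.counts if c > 0]
    ranked = sorted(nonzero, key=lambda t: (-t[1], t[0]))
    return [(name, 100.0 * c / total) for name, c in ranked[:k]]


def transform_profile_compare(field: TransformCounts, incubation: TransformCounts) -> pd.DataFrame:
    """Aligned percentage table for two samples plus Spearman rank concordance.

    Moieties with a nonzero count in both samples enter the correlation;
    fewer than two shared moieties leaves it undefined (NaN, flagged via
    ``attrs``).
    """
    fa, fb = field.as_dict, incubation.as_dict
    names = sorted(set(fa) | set(fb))
    tot_a, tot_b = field.total, incubation.total
    df = pd.DataFrame(
        {
            "moiety": names,
            "count_field": [fa.get(n, 0) for n in names],
            "count_incubation": [fb.get(n, 0) for n in names],
        }
    )
    df["pct_field"] = 100.0 * df["count_field"] / tot_a if tot_a else float("nan")
    df["pct_incubation"] = 100.0 * df["count_incubation"] / tot_b if tot_b else float("nan")
    shared = df[(df["count_field"] > 0) & (df["count_incubation"] > 0)]
    if len(shared) < 2:
        rho = float("nan")
        df.attrs["rank_correlation_defined"] = False
    else:
        rho = float(stats.spearmanr(shared["count_field"], shared["count_incubation"]).statistic)
        df.attrs["rank_correlation_defined"] = True
    df.attrs["spearman_rho"] = rho
    return df
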