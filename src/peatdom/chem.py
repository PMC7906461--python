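"""Molecular formulas over C, H, N, O, S, P and exact monoisotopic mass.

Every downstream quantity in this package — assignment errors in ppm, NOSC,
double-bond equivalents, aromaticity index, transformation mass differences —
is arithmetic on the six element counts of a :class:`Formula`, so the atomic
mass constants are pinned here once and shared by all modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "Formula",
    "exact_mass",
]

# Monoisotopic atomic masses, Da (12C scale).
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: Mass of a proton, Da.  The electron mass is folded in: all ions handled
#: here are singly charged, so tracking it separately changes masses by
#: less than 1e-6 Da.
PROTON_MASS = 1.00727646

_ELEMENTS = ("C", "H", "N", "O", "S", "P")
_FORMULA_RE = re.compile(r"([CHNOSP])(\d*)")


@dataclass(frozen=True, order=True)
class Formula:
    """Elemental composition restricted to CHNOSP.

    Ordering is lexicographic on ``(c, h, n, o, s, p)``; it exists to make
    tie-breaking and table sorting deterministic, not to express chemistry.
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"element count {f.name}={v!r} must be a non-negative integer")

    # -- derived quantities -------------------------------------------------

    @property
    def mass(self) -> float:
        """Exact monoisotopic mass in Da."""
        return (
            self.c * MONOISOTOPIC_MASS["C"]
            + self.h * MONOISOTOPIC_MASS["H"]
            + self.n * MONOISOTOPIC_MASS["N"]
            + self.o * MONOISOTOPIC_MASS["O"]
            + self.s * MONOISOTOPIC_MASS["S"]
            + self.p * MONOISOTOPIC_MASS["P"]
        )

    @property
    def oc(self) -> float:
        """O/C ratio (van Krevelen x-axis)."""
        if self.c == 0:
            raise ValueError("O/C undefined for carbon-free formula")
        return self.o / self.c

    @property
    def hc(self) -> float:
        """H/C ratio (van Krevelen y-axis)."""
        if self.c == 0:
            raise ValueError("H/C undefined for carbon-free formula")
        return self.h / self.c

    @property
    def heteroatoms(self) -> int:
        return self.n + self.s + self.p

    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s, "P": self.p}

    # -- formatting ---------------------------------------------------------

    def __str__(self) -> str:
        """Hill notation: C, H, then remaining elements alphabetically."""
        parts = []
        order = ["C", "H", "N", "O", "P", "S"]  # N,O,P,S alphabetical
        cnt = self.counts()
        for el in order:
            k = cnt[el]
            if k == 0:
                continue
            parts.append(el if k == 1 else f"{el}{k}")
        return "".join(parts) or "∅"

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a Hill-order CHNOSP formula string such as ``C6H12O6``."""
        text = text.strip()
        pos = 0
        cnt = dict.fromkeys(_ELEMENTS, 0)
        for m in _FORMULA_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            cnt[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or pos == 0:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(c=cnt["C"], h=cnt["H"], n=cnt["N"], o=cnt["O"], s=cnt["S"], p=cnt["P"])


def exact_mass(f: Formula | str) -> float:
    """Exact monoisotopic mass (Da) of a formula or formula string."""
    if isinstance(f, str):
        f = Formula.from_string(f)
    return f.mass
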