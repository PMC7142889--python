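"""Elemental-composition arithmetic, adduct m/z, and theoretical isotope patterns.

A formula is a plain ``dict[str, int]`` mapping element symbol to count.
All masses are monoisotopic and come from the pinned constants table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ELECTRON_MASS,
    ISOTOPE_ABUNDANCE,
    ISOTOPE_MZ_SPACING,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
)

Formula = dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible compositions."""


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string like ``C42H82NO8P`` into counts."""
    pos = 0
    out: Formula = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at {text[pos:]!r}")
        pos = m.end()
        elem, count = m.group(1), int(m.group(2) or 1)
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {elem!r} in {text!r}")
        out[elem] = out.get(elem, 0) + count
    if pos != len(text) or not out:
        raise FormulaError(f"malformed formula {text!r}")
    return out


def formula_to_string(formula: Formula) -> str:
    """Hill order: C, H, then remaining elements alphabetically."""
    parts = []
    for elem in ["C", "H"] + sorted(k for k in formula if k not in ("C", "H")):
        n = formula.get(elem, 0)
        if n > 0:
            parts.append(elem + (str(n) if n != 1 else ""))
    return "".join(parts)


def formula_add(a: Formula, b: Formula, sign: int = 1) -> Formula:
    out = dict(a)
    for elem, n in b.items():
        out[elem] = out.get(elem, 0) + sign * n
    out = {e: n for e, n in out.items() if n != 0}
    if any(n < 0 for n in out.values()):
        raise FormulaError(f"negative atom count in {out}")
    return out


def monoisotopic_mass(formula: Formula) -> float:
    if not formula or all(n == 0 for n in formula.values()):
        raise FormulaError("empty formula has no mass")
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.items())


@dataclass(frozen=True)
class Adduct:
    name: str
    delta_formula: Formula  # atoms gained (+) / lost (-) relative to M
    charge: int  # signed

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @property
    def mass_delta(self) -> float:
        """Mass added to M, electron-corrected for the ion charge."""
        d = sum(MONOISOTOPIC_MASS[e] * n for e, n in self.delta_formula.items())
        return d - self.charge * ELECTRON_MASS


ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in [
        Adduct("[M+H]+", {"H": 1}, +1),
        Adduct("[M+Na]+", {"Na": 1}, +1),
        Adduct("[M+NH4]+", {"N": 1, "H": 4}, +1),
        Adduct("[M-H]-", {"H": -1}, -1),
        Adduct("[M+HCOO]-", {"C": 1, "H": 1, "O": 2}, -1),
        Adduct("[M+CH3COO]-", {"C": 2, "H": 3, "O": 2}, -1),
    ]
}

# Unicode minus variants seen in the wild normalise to ASCII hyphen.
_MINUS = str.maketrans({"−": "-", "–": "-"})


def get_adduct(name: str) -> Adduct:
    key = name.translate(_MINUS)
    if key not in ADDUCTS:
        raise KeyError(f"unsupported adduct {name!r}; known: {sorted(ADDUCTS)}")
    return ADDUCTS[key]


def precursor_mz(formula: Formula, adduct: str) -> float:
    """m/z of the [M+X]z ion of composition ``formula``."""
    add = get_adduct(adduct)
    return (monoisotopic_mass(formula) + add.mass_delta) / abs(add.charge)


def ion_mz(ion_formula: Formula, polarity: str) -> float:
    """m/z of a singly charged fragment ion whose atoms are ``ion_formula``."""
    m = monoisotopic_mass(ion_formula)
    return m - ELECTRON_MASS if polarity == "positive" else m + ELECTRON_MASS


@dataclass
class IsotopePattern:
    """Relative isotopologue abundances aggregated by nominal mass shift.

    ``ratios[k]`` is the A+k abundance relative to the base (A+0) peak;
    ``ratios[0]`` is always 1.0.
    """

    ratios: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    @property
    def entries(self) -> list[tuple[int, float]]:
        return [(k, float(v)) for k, v in enumerate(self.ratios)]

    def __len__(self) -> int:
        return len(self.ratios)


def _convolve_power(dist: np.ndarray, n: int, trunc: int) -> np.ndarray:
    """``dist`` self-convolved ``n`` times, truncated to ``trunc`` bins."""
    result = np.array([1.0])
    base = dist.copy()
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:trunc]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:trunc]
    return result


def theoretical_isotope_pattern(formula: Formula, n_peaks: int = 4) -> IsotopePattern:
    """Isotope envelope of a composition by per-element polynomial expansion.

    Each element's natural isotope distribution is raised to its atom count by
    repeated convolution in unit-mass bins; element results are convolved
    together and base-peak normalised.  Output is silently truncated to
    ``n_peaks`` entries.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    trunc = n_peaks + 1
    pattern = np.array([1.0])
    for elem, count in formula.items():
        if count <= 0:
            continue
        dist = np.asarray(ISOTOPE_ABUNDANCE[elem], dtype=float)
        pattern = np.convolve(pattern, _convolve_power(dist, count, trunc))[:trunc]
    pattern = pattern[:n_peaks]
    # entry 0 (the monoisotopic peak) is the reference; for CHNOPS lipid-range
    # formulas it is also the most abundant isotopologue
    return IsotopePattern(pattern / pattern[0])
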