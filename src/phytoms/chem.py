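"""Elemental formulas, monoisotopic masses, adduct m/z arithmetic and ppm errors.

Every other module builds on the arithmetic defined here.  A formula is a
map from element symbol to a non-negative count; its monoisotopic mass is
the sum of most-abundant-isotope masses.  Charged-species m/z values are
electron-corrected: ``[M+H]+`` adds a *proton* (1.00727646 Da), not a
hydrogen atom, and ``[M-H]-`` removes a proton, so positive ions are one
electron light and negative ions one electron heavy.  This is the
convention used by high-resolution instrument software and it is the one
that reproduces published 4-dp theoretical masses (e.g. 445.0776 for the
deprotonated C21H18O11 ion).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ElementalFormula",
    "Adduct",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "within_tolerance",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ISOTOPE_MASSES",
    "FormulaError",
]

# Most-abundant-isotope masses, CODATA/NIST atomic mass evaluation values.
ISOTOPE_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = ISOTOPE_MASSES["H"] - ELECTRON_MASS  # 1.00727646 Da

#: Hill order: C first, H second, remaining elements alphabetical.
_HILL_HEAD = ("C", "H")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable formula strings or invalid formula arithmetic."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map with element-wise arithmetic.

    Counts are non-negative; subtraction that would drive any count
    negative raises :class:`FormulaError` (a biotransformation cannot
    remove atoms a molecule does not have).
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if el not in ISOTOPE_MASSES:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction leaves negative {el} count "
                    f"({self} - {other})"
                )
        return ElementalFormula(merged)

    def __str__(self) -> str:
        parts = []
        rest = sorted(el for el in self.counts if el not in _HILL_HEAD)
        for el in (*_HILL_HEAD, *rest):
            n = self.counts.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C21H18O11"``.

    Omitted counts mean 1.  No parentheses, isotope labels or charges are
    accepted.  Unknown element symbols raise :class:`FormulaError` naming
    the offending token.
    """
    text = text.strip()
    if not text:
        return ElementalFormula({})
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"cannot parse formula {text!r} at {text[pos:]!r}"
            )
        el, num = match.groups()
        if el not in ISOTOPE_MASSES:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(ISOTOPE_MASSES[el] * n for el, n in formula.counts.items())


@dataclass(frozen=True)
class Adduct:
    name: str
    polarity: str  # "positive" | "negative"
    charge: int  # +1 or -1
    mass_delta: float  # Da, electron-corrected


def _delta(formula: str, charge: int) -> float:
    """Mass delta of an adduct moiety, corrected for the electron count."""
    return monoisotopic_mass(parse_formula(formula)) - charge * ELECTRON_MASS


#: The supported adduct set: protonated, ammoniated and water-loss ions in
#: positive mode; deprotonated and formate ions in negative mode.
ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", "positive", +1, _delta("H", +1)),
    "[M+NH4]+": Adduct("[M+NH4]+", "positive", +1, _delta("NH4", +1)),
    "[M+H-H2O]+": Adduct(
        "[M+H-H2O]+", "positive", +1, _delta("H", +1) - monoisotopic_mass("H2O")
    ),
    "[M-H]-": Adduct("[M-H]-", "negative", -1, -_delta("H", +1)),
    "[M+HCOO]-": Adduct("[M+HCOO]-", "negative", -1, _delta("CHO2", -1)),
}

# Accept the unicode minus and spaced variants that appear in print.
_ADDUCT_ALIASES = {
    "[M–H]-": "[M-H]-",
    "[M−H]-": "[M-H]-",
    "[M-H]−": "[M-H]-",
    "[M–H]−": "[M-H]-",
    "[M + H]+": "[M+H]+",
    "[M + NH4]+": "[M+NH4]+",
    "[M + H-H2O]+": "[M+H-H2O]+",
    "[M + HCOO]-": "[M+HCOO]-",
    "[M–H]^-^": "[M-H]-",
}


def get_adduct(name: str) -> Adduct:
    key = name.strip()
    key = _ADDUCT_ALIASES.get(key, key)
    key = key.replace(" ", "").replace("–", "-").replace("−", "-")
    if key not in ADDUCTS:
        raise FormulaError(
            f"unsupported adduct {name!r}; supported: {sorted(ADDUCTS)}"
        )
    return ADDUCTS[key]


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of the given adduct of a neutral molecule of ``neutral_mass`` Da."""
    if neutral_mass < 0:
        raise FormulaError(f"negative neutral mass {neutral_mass}")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return (neutral_mass + adduct.mass_delta) / abs(adduct.charge)


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative error (measured - theoretical)/theoretical in ppm."""
    if theoretical <= 0:
        raise FormulaError(f"theoretical m/z must be positive, got {theoretical}")
    return (measured - theoretical) / theoretical * 1e6


def within_tolerance(measured: float, theoretical: float, tol_ppm: float) -> bool:
    return abs(ppm_error(measured, theoretical)) <= tol_ppm


def format_mz(mz: float) -> str:
    """m/z formatted the way instrument reports print it (4 dp)."""
    return f"{mz:.4f}"


def format_ppm(ppm: float) -> str:
    return f"{ppm:.2f}"
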