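"""Molecular-formula parsing, monoisotopic masses and ESI adduct arithmetic.

Element masses are IUPAC monoisotopic values embedded as constants so that
mass computation needs no runtime lookup.  Formulas are Hill-style with
optional parentheses ("C6H12O6", "Ca(OH)2"); charges and isotope labels
("[13C]", "+") are rejected — target lists carry neutral formulas.
"""

from __future__ import annotations

from .core import AdductRule, TargetMetabolite, ValidationError

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_SPACING",
    "parse_formula",
    "monoisotopic_mass",
    "formula_mass",
    "apply_adduct",
    "primary_ion_mz",
]

#: Monoisotopic masses (Da) of the most abundant isotope, IUPAC 2021.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "F": 18.99840322,
    "I": 126.904473,
    "Se": 79.9165213,
    "Si": 27.9769265325,
    "B": 11.0093054,
    "Li": 7.01600455,
    "Mg": 23.9850417,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
    "Cu": 62.9295975,
    "Mn": 54.9380451,
    "Co": 58.9331950,
    "Ni": 57.9353429,
    "As": 74.9215965,
}

#: Mass of a proton (H+), i.e. hydrogen minus one electron.
PROTON_MASS = 1.007276
#: Electron rest mass.
ELECTRON_MASS = 0.000549
#: m/z spacing of consecutive 13C isotopologue peaks at charge 1.
C13_SPACING = 1.0034


class FormulaError(ValidationError):
    """A molecular formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a neutral molecular formula into element counts.

    Supports multi-letter element symbols, implicit count 1, and nested
    parentheses with multipliers.  Unknown symbols and any charge or
    isotope notation raise :class:`FormulaError` naming the offending
    position.

    >>> parse_formula("C9H11NO2")
    {'C': 9, 'H': 11, 'N': 1, 'O': 2}
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    s = formula.strip()
    pos = 0
    n = len(s)

    def parse_group(depth: int) -> dict[str, int]:
        nonlocal pos
        counts: dict[str, int] = {}
        while pos < n:
            ch = s[pos]
            if ch == "(":
                pos += 1
                inner = parse_group(depth + 1)
                if pos >= n or s[pos] != ")":
                    raise FormulaError(f"unbalanced '(' in {formula!r}")
                pos += 1
                mult = _read_count()
                for el, c in inner.items():
                    counts[el] = counts.get(el, 0) + c * mult
            elif ch == ")":
                if depth == 0:
                    raise FormulaError(f"unbalanced ')' at position {pos} in {formula!r}")
                return counts
            elif ch.isupper():
                start = pos
                pos += 1
                if pos < n and s[pos].islower():
                    pos += 1
                symbol = s[start:pos]
                if symbol not in ELEMENT_MASSES:
                    # Two-letter guesses may shadow a valid one-letter element
                    # followed by garbage; report the symbol as written.
                    if symbol[:1] in ELEMENT_MASSES and len(symbol) == 2:
                        raise FormulaError(
                            f"unknown element {symbol!r} at position {start} in {formula!r}"
                        )
                    raise FormulaError(
                        f"unknown element {symbol!r} at position {start} in {formula!r}"
                    )
                count = _read_count()
                counts[symbol] = counts.get(symbol, 0) + count
            else:
                raise FormulaError(
                    f"unexpected character {ch!r} at position {pos} in {formula!r}"
                )
        return counts

    def _read_count() -> int:
        nonlocal pos
        start = pos
        while pos < n and s[pos].isdigit():
            pos += 1
        if pos == start:
            return 1
        count = int(s[start:pos])
        if count < 1:
            raise FormulaError(f"zero count at position {start} in {formula!r}")
        return count

    counts = parse_group(0)
    if pos != n:
        raise FormulaError(f"trailing input at position {pos} in {formula!r}")
    if not counts:
        raise FormulaError(f"formula {formula!r} contains no elements")
    return counts


def monoisotopic_mass(composition: dict[str, int]) -> float:
    """Sum of count x element monoisotopic mass over the composition."""
    try:
        return sum(ELEMENT_MASSES[el] * count for el, count in composition.items())
    except KeyError as exc:
        raise FormulaError(f"unknown element {exc.args[0]!r}") from None


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a formula string — convenience wrapper."""
    return monoisotopic_mass(parse_formula(formula))


def apply_adduct(neutral_mass: float, rule: AdductRule) -> float:
    """m/z of the ion a rule produces from a neutral monoisotopic mass.

    Implements (k * M + mass_shift) / |z| where k is the multiplicity and z
    the signed charge.  The mass_shift of bundled rules already accounts for
    charge carriers and electrons.
    """
    if neutral_mass <= 0:
        raise ValidationError(f"neutral mass must be positive, got {neutral_mass}")
    mz = (rule.multiplicity * neutral_mass + rule.mass_shift) / abs(rule.charge)
    if mz <= 0:
        raise ArithmeticError(
            f"rule {rule.name!r} yields non-positive m/z for mass {neutral_mass}"
        )
    return mz


_PROTONATED = AdductRule("[M+H]+", "positive", 1, 1, PROTON_MASS)
_DEPROTONATED = AdductRule("[M-H]-", "negative", 1, -1, -PROTON_MASS)


def primary_ion_mz(target: TargetMetabolite, ion_mode: str) -> float:
    """m/z of the primary ion of a target: [M+H]+ or [M-H]- by ion mode."""
    mass = formula_mass(target.formula)
    if ion_mode == "positive":
        return apply_adduct(mass, _PROTONATED)
    if ion_mode == "negative":
        return apply_adduct(mass, _DEPROTONATED)
    raise ValidationError(f"unknown ion mode {ion_mode!r}")
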