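"""Elemental-formula arithmetic and exact monoisotopic masses.

Combinatorial library enumeration and fragment prediction reduce to sums and
differences of element-count vectors: each building block contributes a fixed
set of atoms (condensation losses pre-applied), a scaffold may add a constant
offset, and a predicted fragment is the sum over a span of positions, possibly
shifted by one hydrogen.  :class:`ElementalFormula` supports exactly that
signed arithmetic; a *molecule* formula must end up non-negative, but
intermediate results (e.g. neutral losses) may not be.

Masses are CODATA/NIST monoisotopic atomic masses; the mass of a formula is
the count-weighted sum, so ``mass(a + b) == mass(a) + mass(b)`` to well below
1e-9 Da.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "FormulaError",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "ELECTRON_MASS",
    "ADDUCTS",
    "adduct_mass",
]


class FormulaError(ValueError):
    """Malformed formula string or unknown element symbol."""


#: NIST monoisotopic atomic masses (Da) of the elements that occur in
#: small-molecule combinatorial libraries.  Extensible: unknown symbols raise
#: :class:`FormulaError` rather than being silently dropped.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Se": 79.9165213,
    "B": 11.0093054,
    "Si": 27.9769265325,
}

PROTON_MASS = 1.00727646688
HYDROGEN_MASS = MONOISOTOPIC_MASS["H"]
ELECTRON_MASS = 0.00054857990946

#: Supported ionisation adducts: name -> (mass shift in Da, charge).
#: Positive-mode singly charged species only; the decoder subtracts the shift
#: and multiplies by the charge to recover a neutral mass.
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+Na]+": (MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, 1),
    "[M+K]+": (MONOISOTOPIC_MASS["K"] - ELECTRON_MASS, 1),
}


def adduct_mass(adduct: str) -> tuple[float, int]:
    """Return ``(mass_shift_da, charge)`` for a named adduct."""
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise FormulaError(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        ) from None


_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class ElementalFormula(Mapping):
    """Immutable element -> signed count map with formula arithmetic.

    Parameters
    ----------
    counts :
        Mapping of element symbol to (possibly negative) count.  Zero counts
        are pruned; unknown element symbols raise :class:`FormulaError`.

    Examples
    --------
    >>> gly = ElementalFormula.parse("C2H3NO")
    >>> ala = ElementalFormula.parse("C3H5NO")
    >>> (gly + ala).hill
    'C5H8N2O2'
    >>> round((gly + ala).mass - gly.mass - ala.mass, 12)
    0.0
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for elem, n in src.items():
                if elem not in MONOISOTOPIC_MASS:
                    raise FormulaError(f"unknown element symbol {elem!r}")
                if int(n) != n:
                    raise FormulaError(f"non-integer count for {elem!r}: {n!r}")
                merged[elem] = merged.get(elem, 0) + int(n)
        self._counts: dict[str, int] = {e: n for e, n in merged.items() if n != 0}

    # -- construction -------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse Hill-style notation, e.g. ``"C8H3N2O"`` or ``""`` (empty).

        Element order is free, counts must be non-negative integers, and a
        repeated element accumulates.  Whitespace is ignored.
        """
        s = re.sub(r"\s+", "", text or "")
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(s):
            m = _TOKEN.match(s, pos)
            if m is None or m.end() == pos:
                raise FormulaError(f"cannot parse formula {text!r} at {s[pos:]!r}")
            elem, digits = m.groups()
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(
                    f"unknown element symbol {elem!r} in formula {text!r}"
                )
            if digits.startswith("-"):
                raise FormulaError(f"negative count in formula string {text!r}")
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    # -- Mapping protocol ----------------------------------------------------

    def __getitem__(self, elem: str) -> int:
        return self._counts[elem]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, elem: str, default: int = 0) -> int:
        return self._counts.get(elem, default)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        out = dict(self._counts)
        for e, n in other._counts.items():
            out[e] = out.get(e, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        out = dict(self._counts)
        for e, n in other._counts.items():
            out[e] = out.get(e, 0) - n
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int):
            return NotImplemented
        return ElementalFormula({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # -- derived quantities --------------------------------------------------

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (signed if counts are signed)."""
        return sum(n * MONOISOTOPIC_MASS[e] for e, n in self._counts.items())

    @property
    def is_nonnegative(self) -> bool:
        """True iff every element count is >= 0 (a realisable molecule)."""
        return all(n >= 0 for n in self._counts.values())

    @property
    def hill(self) -> str:
        """Hill notation: C, then H, then other elements alphabetically."""
        parts: list[str] = []
        order = [e for e in ("C", "H") if e in self._counts]
        order += sorted(e for e in self._counts if e not in ("C", "H"))
        for e in order:
            n = self._counts[e]
            parts.append(e if n == 1 else f"{e}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalFormula({self.hill!r})"

    def __str__(self) -> str:
        return self.hill


#: The empty formula (mass 0); additive identity.
ElementalFormula.EMPTY = ElementalFormula()  # type: ignore[attr-defined]
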