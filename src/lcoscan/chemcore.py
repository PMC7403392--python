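"""Exact elemental-formula arithmetic and monoisotopic mass / m/z computation.

All downstream structure and fragment math is built on three primitives:
integer element-count bookkeeping (:class:`ElementalFormula`), monoisotopic
mass summation, and singly-protonated adduct m/z. Masses are monoisotopic
only — unit-resolution triple-quadrupole work never needs isotope-averaged
masses — and the charge state is fixed at +1 ([M+H]+), the only adduct the
workflow considers.
"""

from __future__ import annotations

import math
import re
from collections.abc import Mapping
from typing import Iterator

__all__ = [
    "ElementalFormula",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER",
    "GLCNAC_RESIDUE",
    "ACETYL",
    "InvalidCompositionError",
    "UnsupportedElementError",
    "formula_add",
    "monoisotopic_mass",
    "mz_protonated",
    "nominal_mz",
]

#: IUPAC monoisotopic atomic masses (Da), hard-coded for reproducibility
#: independent of any external table.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Mass of the proton (Da). Distinct from the hydrogen *atom* mass: the
#: [M+H]+ adduct gains a bare proton, not a hydrogen atom.
PROTON_MASS: float = 1.007276466879

#: Hill order: C first, H second, then the rest alphabetically.
_HILL_ORDER = ("C", "H", "N", "O", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class InvalidCompositionError(ValueError):
    """A molecule formula ended up with a negative element count."""


class UnsupportedElementError(KeyError):
    """An element symbol outside the supported C/H/N/O/S set."""


class ElementalFormula(Mapping[str, int]):
    """Immutable element-count vector over C, H, N, O, S.

    Supports molecules (all counts >= 0) and signed *group deltas* used to
    express substitutions such as "replace N-acetyl with a fatty acyl chain".
    Addition/subtraction are element-wise; the empty formula is the identity.

    Parameters
    ----------
    **counts
        Element symbol -> integer count. Zero counts are dropped.
    """

    __slots__ = ("_counts",)

    def __init__(self, **counts: int) -> None:
        clean: dict[str, int] = {}
        for element, count in counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise UnsupportedElementError(
                    f"unsupported element {element!r}; supported: "
                    f"{sorted(MONOISOTOPIC_MASS)}"
                )
            if not isinstance(count, int):
                raise TypeError(f"count for {element} must be int, got {count!r}")
            if count != 0:
                clean[element] = count
        object.__setattr__(self, "_counts", clean)

    def __setattr__(self, name: str, value: object) -> None:  # pragma: no cover
        raise AttributeError("ElementalFormula is immutable")

    # -- Mapping protocol ---------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        merged = dict(self._counts)
        for element, count in other._counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalFormula(**merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self + (-other)

    def __neg__(self) -> "ElementalFormula":
        return ElementalFormula(**{e: -c for e, c in self._counts.items()})

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int):
            return NotImplemented
        return ElementalFormula(**{e: c * k for e, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # -- predicates ---------------------------------------------------------
    @property
    def is_molecule(self) -> bool:
        """True when every element count is non-negative."""
        return all(c >= 0 for c in self._counts.values())

    def require_molecule(self) -> "ElementalFormula":
        """Return self, raising :class:`InvalidCompositionError` if any count < 0."""
        if not self.is_molecule:
            raise InvalidCompositionError(
                f"negative element counts in molecule formula: {self.hill()}"
            )
        return self

    # -- mass ---------------------------------------------------------------
    def monoisotopic_mass(self) -> float:
        """Monoisotopic mass in Da (sum of count x atomic monoisotopic mass)."""
        return sum(c * MONOISOTOPIC_MASS[e] for e, c in self._counts.items())

    # -- serialization ------------------------------------------------------
    def hill(self) -> str:
        """Hill-order string, e.g. ``C24H41N3O16``. Empty formula -> ``""``."""
        parts = []
        for element in _HILL_ORDER:
            count = self._counts.get(element, 0)
            if count == 0:
                continue
            parts.append(element if count == 1 else f"{element}{count}")
        return "".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-order formula string such as ``"C8H13NO5"``.

        Signed counts are accepted so group deltas round-trip.
        """
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos or not match.group(0):
                break
            element, digits = match.group(1), match.group(2)
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"malformed formula string: {text!r}")
        return cls(**counts)

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill() or 'empty'})"


#: Water, the condensation remainder closing a glycan chain.
WATER = ElementalFormula(H=2, O=1)

#: In-chain (anhydro) N-acetylglucosamine residue, C8H13NO5 (203.0794 Da).
GLCNAC_RESIDUE = ElementalFormula(C=8, H=13, N=1, O=5)

#: Acetyl group (C2H2O), removed from the non-reducing GlcNAc when a fatty
#: acyl chain takes its place on the terminal nitrogen.
ACETYL = ElementalFormula(C=2, H=2, O=1)


def formula_add(a: ElementalFormula, b: ElementalFormula) -> ElementalFormula:
    """Element-wise sum of a formula and a formula or group delta."""
    return a + b


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass (Da) of a molecule formula.

    Raises
    ------
    InvalidCompositionError
        If any element count is negative (a bare delta has no mass meaning
        as a molecule).
    """
    f.require_molecule()
    return f.monoisotopic_mass()


def mz_protonated(neutral_mass: float) -> float:
    """m/z of the singly charged proton adduct [M+H]+ of a neutral molecule."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return neutral_mass + PROTON_MASS


def nominal_mz(mz: float) -> int:
    """Unit-resolution integer m/z: round half away from zero."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return int(math.floor(mz + 0.5))
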