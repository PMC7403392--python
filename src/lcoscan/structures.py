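"""LCO/CO structure grammar and combinatorial enumeration.

A chitooligosaccharide (CO) is a short beta-1,4 chain of N-acetylglucosamine
(GlcNAc) residues. A lipo-chitooligosaccharide (LCO, the "Nod factor") is a
CO whose non-reducing terminal nitrogen carries a fatty acyl chain in place
of the acetyl group, optionally decorated at positions R2-R6 with small
substituents (methyl, acetyl, carbamoyl, sulfate, fucosyl, methylfucosyl,
sulfated fucosyl). R2-R4 sit on the non-reducing terminal residue, R5-R6 on
the reducing terminal residue — the standard Nod-factor generic structure.

A :class:`StructureGrammar` describes a combinatorial family (backbone
length range x acyl library x allowed substituents per position);
:func:`enumerate_structures` expands it into a deduplicated, name-sorted
structure list. Names follow the field's nomenclature: ``CO4``,
``LCO-IV(C16:0,S)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

from .chemcore import (
    ACETYL,
    GLCNAC_RESIDUE,
    WATER,
    ElementalFormula,
)

__all__ = [
    "AcylChain",
    "SUBSTITUENT_DELTAS",
    "SUBSTITUENT_SITES",
    "NON_REDUCING_POSITIONS",
    "REDUCING_POSITIONS",
    "COStructure",
    "LCOStructure",
    "Structure",
    "StructureGrammar",
    "InvalidStructureError",
    "EmptyGrammarError",
    "structure_formula",
    "canonical_name",
    "backbone_length_from_name",
    "enumerate_structures",
]


class InvalidStructureError(ValueError):
    """Structure violates the grammar (bad site, bad counts, bad codes)."""


class EmptyGrammarError(ValueError):
    """Grammar with no acyl chains or no backbone lengths."""


# ---------------------------------------------------------------------------
# Acyl chains
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class AcylChain:
    """Fatty acyl chain at R1, written Cc:d (c carbons, d double bonds).

    The group replaces the N-acetyl of the non-reducing GlcNAc, so its net
    formula contribution is ``+ CcH(2c-2-2d)O(1+h) - C2H2O`` relative to the
    unmodified residue (h = hydroxyl count, default 0).
    """

    carbons: int
    double_bonds: int = 0
    hydroxyls: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise InvalidStructureError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0 or self.double_bonds > self.carbons - 1:
            raise InvalidStructureError(
                f"double bonds must be in [0, carbons-1], got {self.double_bonds}"
            )
        if self.hydroxyls < 0:
            raise InvalidStructureError("hydroxyl count must be >= 0")

    def group_formula(self) -> ElementalFormula:
        """Formula of the acyl group itself (CcH(2c-2-2d)O(1+h))."""
        h = 2 * self.carbons - 2 - 2 * self.double_bonds
        if h < 0:
            raise InvalidStructureError(f"acyl chain {self.label()} has negative H count")
        return ElementalFormula(C=self.carbons, H=h, O=1 + self.hydroxyls)

    def label(self) -> str:
        base = f"C{self.carbons}:{self.double_bonds}"
        if self.hydroxyls:
            base += f"({self.hydroxyls}OH)"
        return base

    @classmethod
    def from_label(cls, label: str) -> "AcylChain":
        """Parse ``"C16:0"`` or ``"C18:1(1OH)"``."""
        hydroxyls = 0
        body = label.strip()
        if body.endswith("OH)"):
            body, _, tail = body.partition("(")
            hydroxyls = int(tail[:-3])
        if not body.startswith("C") or ":" not in body:
            raise ValueError(f"malformed acyl label {label!r}")
        c, _, d = body[1:].partition(":")
        return cls(carbons=int(c), double_bonds=int(d), hydroxyls=hydroxyls)


# ---------------------------------------------------------------------------
# Substituents
# ---------------------------------------------------------------------------

#: Formula deltas for each substituent code, each replacing one hydrogen.
SUBSTITUENT_DELTAS: dict[str, ElementalFormula] = {
    "H": ElementalFormula(),
    "Me": ElementalFormula(C=1, H=2),
    "Ac": ElementalFormula(C=2, H=2, O=1),
    "Cb": ElementalFormula(C=1, H=1, N=1, O=1),
    "S": ElementalFormula(S=1, O=3),
    "Fuc": ElementalFormula(C=6, H=10, O=4),
    "MeFuc": ElementalFormula(C=7, H=12, O=4),
    "FucS": ElementalFormula(C=6, H=10, O=7, S=1),
}

NON_REDUCING_POSITIONS = ("R2", "R3", "R4")
REDUCING_POSITIONS = ("R5", "R6")
ALL_POSITIONS = NON_REDUCING_POSITIONS + REDUCING_POSITIONS

#: Positions where each code is chemically plausible. H fits anywhere; the
#: N-methyl only at R2 (on the acylated nitrogen's residue); glycosyl and
#: sulfate decorations at the reducing-end R6.
SUBSTITUENT_SITES: dict[str, frozenset[str]] = {
    "H": frozenset(ALL_POSITIONS),
    "Me": frozenset({"R2"}),
    "Ac": frozenset({"R3", "R4", "R5", "R6"}),
    "Cb": frozenset({"R3", "R4"}),
    "S": frozenset({"R6"}),
    "Fuc": frozenset({"R6"}),
    "MeFuc": frozenset({"R6"}),
    "FucS": frozenset({"R6"}),
}


def _roman(n: int) -> str:
    numerals = [(10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10}


def _from_roman(text: str) -> int:
    total, prev = 0, 0
    for ch in reversed(text):
        value = _ROMAN_VALUES[ch]
        total = total - value if value < prev else total + value
        prev = max(prev, value)
    return total


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class COStructure:
    """Unmodified chitin oligomer of ``n`` GlcNAc residues (n >= 2)."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidStructureError(f"CO backbone needs >= 2 residues, got {self.n}")

    def formula(self) -> ElementalFormula:
        return (self.n * GLCNAC_RESIDUE + WATER).require_molecule()

    def name(self) -> str:
        return f"CO{self.n}"


@dataclass(frozen=True)
class LCOStructure:
    """Acylated chitin oligomer with positional substituents.

    Parameters
    ----------
    n
        Backbone length (GlcNAc residues), >= 2.
    acyl
        Fatty acyl chain at R1 (non-reducing terminal nitrogen).
    substituents
        Mapping position ("R2".."R6") -> substituent code; omitted positions
        default to "H". Stored as a sorted tuple so the structure hashes.
    """

    n: int
    acyl: AcylChain
    substituents: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidStructureError(f"LCO backbone needs >= 2 residues, got {self.n}")
        subs = dict(self.substituents)
        if len(subs) != len(self.substituents):
            raise InvalidStructureError("duplicate substituent positions")
        for pos, code in subs.items():
            if pos not in ALL_POSITIONS:
                raise InvalidStructureError(f"unknown substituent position {pos!r}")
            if code not in SUBSTITUENT_DELTAS:
                raise InvalidStructureError(f"unknown substituent code {code!r}")
            if pos not in SUBSTITUENT_SITES[code]:
                raise InvalidStructureError(
                    f"substituent {code!r} not allowed at position {pos}"
                )
        object.__setattr__(
            self, "substituents", tuple(sorted((p, c) for p, c in subs.items()))
        )

    @classmethod
    def make(
        cls,
        n: int,
        acyl: AcylChain,
        substituents: Mapping[str, str] | None = None,
    ) -> "LCOStructure":
        subs = {p: c for p, c in (substituents or {}).items() if c != "H"}
        return cls(n=n, acyl=acyl, substituents=tuple(sorted(subs.items())))

    def substituent_at(self, pos: str) -> str:
        return dict(self.substituents).get(pos, "H")

    def non_reducing_deltas(self) -> ElementalFormula:
        """Sum of substituent deltas on the non-reducing terminal residue."""
        total = ElementalFormula()
        for pos, code in self.substituents:
            if pos in NON_REDUCING_POSITIONS:
                total = total + SUBSTITUENT_DELTAS[code]
        return total

    def reducing_deltas(self) -> ElementalFormula:
        total = ElementalFormula()
        for pos, code in self.substituents:
            if pos in REDUCING_POSITIONS:
                total = total + SUBSTITUENT_DELTAS[code]
        return total

    def formula(self) -> ElementalFormula:
        f = (
            self.n * GLCNAC_RESIDUE
            + WATER
            - ACETYL
            + self.acyl.group_formula()
            + self.non_reducing_deltas()
            + self.reducing_deltas()
        )
        return f.require_molecule()

    def name(self) -> str:
        codes = sorted(code for _, code in self.substituents if code != "H")
        inner = ",".join([self.acyl.label()] + codes)
        return f"LCO-{_roman(self.n)}({inner})"


Structure = Union[COStructure, LCOStructure]


def structure_formula(s: Structure) -> ElementalFormula:
    """Neutral molecular formula of a CO or LCO structure."""
    return s.formula()


def canonical_name(s: Structure) -> str:
    """Order-independent unique label: ``CO<n>`` or ``LCO-<Roman>(<acyl>,<codes>)``."""
    return s.name()


def backbone_length_from_name(name: str) -> int:
    """Recover the GlcNAc backbone length from a canonical structure name."""
    if name.startswith("CO"):
        return int(name[2:])
    if name.startswith("LCO-"):
        roman = name[4:].partition("(")[0]
        return _from_roman(roman)
    raise ValueError(f"unrecognized structure name {name!r}")


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------


def _default_acyl_library() -> tuple[AcylChain, ...]:
    # Even carbon counts only: fatty-acid biosynthesis elongates in C2 units,
    # so odd chains are rare in practice; admitting them would also make
    # Cc:d + N-methyl exactly isobaric with C(c+1):d (identical precursor
    # and B ions), an artifactual degeneracy.
    return tuple(
        AcylChain(c, d) for c in range(12, 23, 2) for d in range(0, 4)
    )


def _default_position_options() -> dict[str, tuple[str, ...]]:
    return {
        "R2": ("H", "Me"),
        "R3": ("H", "Cb"),
        "R4": ("H", "Ac"),
        "R5": ("H",),
        "R6": ("H", "S", "Fuc", "MeFuc", "FucS"),
    }


@dataclass(frozen=True)
class StructureGrammar:
    """Combinatorial description of an LCO structure family.

    Defaults cover the commonly described Nod-factor space: backbones of
    3-5 GlcNAc, acyl chains C12-C22 with 0-3 double bonds, N-methyl at R2,
    carbamoyl at R3, acetyl at R4, and sulfate/fucosyl decorations at R6.
    """

    backbone_lengths: tuple[int, ...] = (3, 4, 5)
    acyl_library: tuple[AcylChain, ...] = field(default_factory=_default_acyl_library)
    #: None -> the default Nod-factor option sets; an explicit mapping lists
    #: only the decorated positions (all others default to hydrogen).
    position_options: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "backbone_lengths", tuple(self.backbone_lengths))
        object.__setattr__(self, "acyl_library", tuple(self.acyl_library))
        if self.position_options is None:
            opts = _default_position_options()
        else:
            given = {p: tuple(v) for p, v in dict(self.position_options).items()}
            for pos in given:
                if pos not in ALL_POSITIONS:
                    raise InvalidStructureError(f"unknown grammar position {pos!r}")
            opts = {p: given.get(p, ("H",)) for p in ALL_POSITIONS}
        object.__setattr__(self, "position_options", opts)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, object]) -> "StructureGrammar":
        """Build a grammar from a configuration mapping.

        Schema (all keys optional)::

            backbone_lengths: [3, 4, 5]
            acyl_library: ["C16:0", "C18:1"]   # Cc:d labels
            positions:
              R2: ["H", "Me"]
              R6: ["H", "S"]
        """
        kwargs: dict[str, object] = {}
        if "backbone_lengths" in cfg:
            kwargs["backbone_lengths"] = tuple(int(n) for n in cfg["backbone_lengths"])  # type: ignore[arg-type]
        if "acyl_library" in cfg:
            kwargs["acyl_library"] = tuple(
                AcylChain.from_label(str(a)) for a in cfg["acyl_library"]  # type: ignore[union-attr]
            )
        if "positions" in cfg:
            kwargs["position_options"] = {
                str(p): tuple(str(c) for c in codes)
                for p, codes in dict(cfg["positions"]).items()  # type: ignore[arg-type]
            }
        return cls(**kwargs)  # type: ignore[arg-type]


def enumerate_structures(grammar: StructureGrammar) -> list[LCOStructure]:
    """Expand a grammar into its full structure list.

    Cartesian product of backbone lengths x acyl library x allowed
    substituent codes per position, deduplicated by canonical name, sorted
    by name. Deterministic for a given grammar.
    """
    if not grammar.acyl_library:
        raise EmptyGrammarError("grammar has an empty acyl library")
    if not grammar.backbone_lengths:
        raise EmptyGrammarError("grammar has no backbone lengths")

    positions = list(ALL_POSITIONS)
    option_sets = [grammar.position_options.get(p, ("H",)) for p in positions]

    seen: dict[str, LCOStructure] = {}
    for n, acyl, codes in itertools.product(
        grammar.backbone_lengths, grammar.acyl_library, itertools.product(*option_sets)
    ):
        s = LCOStructure.make(n, acyl, dict(zip(positions, codes)))
        seen.setdefault(s.name(), s)
    return [seen[name] for name in sorted(seen)]


def structures_to_rows(structures: Sequence[Structure]) -> list[dict[str, object]]:
    """Tabular export rows: name, Hill formula, neutral monoisotopic mass."""
    return [
        {
            "name": canonical_name(s),
            "formula": structure_formula(s).hill(),
            "neutral_mass": round(structure_formula(s).monoisotopic_mass(), 4),
        }
        for s in structures
    ]
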