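"""Theoretical MRM transition database: precursor and B-ion m/z per structure.

Each structure yields one [M+H]+ precursor and the series of singly charged
B ions (glycosidic-cleavage oxocarbenium fragments retaining the
non-reducing end). Cleavage after residue ``i`` (1 <= i <= n-1) keeps the
``i`` non-reducing-side residues with their acyl chain and non-reducing
substituents; reducing-end substituents never appear in any B ion. The B1
of an unmodified GlcNAc has nominal m/z 204, the common product ion used to
monitor chitooligosaccharides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chemcore import (
    ACETYL,
    GLCNAC_RESIDUE,
    PROTON_MASS,
    mz_protonated,
    monoisotopic_mass,
)
from .structures import (
    LCOStructure,
    Structure,
    canonical_name,
    structure_formula,
)

__all__ = [
    "TransitionRecord",
    "TransitionDB",
    "TransitionParseError",
    "precursor_mz",
    "b_ion_mz",
    "build_transition_db",
    "db_stats",
    "select_panel",
    "write_transitions",
    "read_transitions",
]

log = logging.getLogger(__name__)

#: m/z values are considered equal for dedup when they round to the same
#: 4th decimal — below instrument resolution, above float noise.
MZ_DEDUP_DECIMALS = 4

CSV_COLUMNS = ("structure", "precursor_mz", "product_mz", "ion_label", "expected_rt")


class TransitionParseError(ValueError):
    """Malformed transition CSV row (message carries the line number)."""


@dataclass(frozen=True)
class TransitionRecord:
    """One MRM transition: (precursor m/z, product m/z) for a named structure."""

    structure: str
    precursor_mz: float
    product_mz: float
    ion_label: str
    expected_rt: float | None = None

    def __post_init__(self) -> None:
        if self.product_mz >= self.precursor_mz:
            raise ValueError(
                f"product m/z {self.product_mz} must be below precursor "
                f"{self.precursor_mz} ({self.structure} {self.ion_label})"
            )

    @property
    def pair(self) -> tuple[float, float]:
        """Dedup key: (precursor, product) rounded to 4 decimals."""
        return (
            round(self.precursor_mz, MZ_DEDUP_DECIMALS),
            round(self.product_mz, MZ_DEDUP_DECIMALS),
        )


@dataclass(frozen=True)
class TransitionDB:
    """Immutable, deterministically ordered list of transition records."""

    records: tuple[TransitionRecord, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.records, key=lambda r: (r.structure, len(r.ion_label), r.ion_label))
        )
        object.__setattr__(self, "records", ordered)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def structure_names(self) -> list[str]:
        return sorted({r.structure for r in self.records})

    def by_structure(self) -> dict[str, list[TransitionRecord]]:
        out: dict[str, list[TransitionRecord]] = {}
        for r in self.records:
            out.setdefault(r.structure, []).append(r)
        return out

    def merge(self, other: "TransitionDB") -> "TransitionDB":
        """Union of two DBs; duplicate records collapse (idempotent)."""
        return TransitionDB(tuple(dict.fromkeys(self.records + other.records)))

    def with_expected_rt(self, rts: Mapping[str, float]) -> "TransitionDB":
        """Copy with expected retention times attached per structure name."""
        new = tuple(
            replace(r, expected_rt=rts.get(r.structure, r.expected_rt))
            for r in self.records
        )
        return TransitionDB(new)


# ---------------------------------------------------------------------------
# m/z computation
# ---------------------------------------------------------------------------


def precursor_mz(s: Structure) -> float:
    """[M+H]+ m/z of the intact structure."""
    return mz_protonated(monoisotopic_mass(structure_formula(s)))


def b_ion_mz(s: Structure, i: int) -> float:
    """m/z of the Bi oxocarbenium fragment (i non-reducing residues + proton).

    For LCOs the fragment carries the acyl chain and the non-reducing-end
    substituents (R2-R4); reducing-end substituents (R5-R6) are excluded
    from every B ion. Strictly increasing in ``i``.
    """
    n = s.n
    if not 1 <= i <= n - 1:
        raise IndexError(f"cleavage index {i} out of range 1..{n - 1}")
    fragment = i * GLCNAC_RESIDUE
    if isinstance(s, LCOStructure):
        fragment = fragment - ACETYL + s.acyl.group_formula() + s.non_reducing_deltas()
    return fragment.require_molecule().monoisotopic_mass() + PROTON_MASS


# ---------------------------------------------------------------------------
# DB construction and stats
# ---------------------------------------------------------------------------


def build_transition_db(
    structures: Sequence[Structure],
    expected_rt: Mapping[str, float] | None = None,
) -> TransitionDB:
    """One record per (structure, B ion); deterministic order; deduplicated."""
    if not structures:
        raise ValueError("cannot build a transition DB from an empty structure list")
    expected_rt = expected_rt or {}
    records: list[TransitionRecord] = []
    for s in structures:
        name = canonical_name(s)
        prec = precursor_mz(s)
        for i in range(1, s.n):
            records.append(
                TransitionRecord(
                    structure=name,
                    precursor_mz=prec,
                    product_mz=b_ion_mz(s, i),
                    ion_label=f"B{i}",
                    expected_rt=expected_rt.get(name),
                )
            )
    return TransitionDB(tuple(dict.fromkeys(records)))


def db_stats(db: TransitionDB) -> dict[str, int]:
    """Database size summary.

    Returns both readings of "precursor count": ``precursor_entries`` (one
    [M+H]+ entry per structure) and ``unique_precursors`` (distinct precursor
    m/z at 4-decimal rounding), alongside ``structures`` and
    ``unique_transitions`` (distinct precursor/product pairs).
    """
    names = {r.structure for r in db.records}
    precs = {round(r.precursor_mz, MZ_DEDUP_DECIMALS) for r in db.records}
    pairs = {r.pair for r in db.records}
    return {
        "structures": len(names),
        "precursor_entries": len(names),
        "unique_precursors": len(precs),
        "unique_transitions": len(pairs),
    }


def select_panel(
    db: TransitionDB,
    names: Iterable[str] | None = None,
    max_size: int | None = None,
) -> TransitionDB:
    """Reduced panel: all transitions of the named structures.

    Instrument sensitivity caps how many transitions one run can monitor, so
    panels are cut down from the full DB. Unknown names are skipped with a
    logged warning; ``max_size`` truncates the record list after the name
    sort.
    """
    if names is None and max_size is None:
        raise ValueError("select_panel needs a name list or a size cap")
    records = list(db.records)
    if names is not None:
        wanted = list(dict.fromkeys(names))
        known = {r.structure for r in db.records}
        for name in wanted:
            if name not in known:
                log.warning("select_panel: unknown structure %r skipped", name)
        keep = set(wanted) & known
        records = [r for r in records if r.structure in keep]
    records.sort(key=lambda r: (r.structure, len(r.ion_label), r.ion_label))
    if max_size is not None:
        if max_size <= 0:
            raise ValueError(f"size cap must be positive, got {max_size}")
        records = records[:max_size]
    return TransitionDB(tuple(records))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_transitions(db: TransitionDB, path: str | Path) -> None:
    """Write the DB as CSV with fixed column order; m/z at 4 decimals."""
    rows = [
        {
            "structure": r.structure,
            "precursor_mz": f"{r.precursor_mz:.4f}",
            "product_mz": f"{r.product_mz:.4f}",
            "ion_label": r.ion_label,
            "expected_rt": "" if r.expected_rt is None else f"{r.expected_rt:.4f}",
        }
        for r in db.records
    ]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def read_transitions(path: str | Path) -> TransitionDB:
    """Read a transition CSV back; ``read(write(db))`` equals ``db`` at 4 decimals."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TransitionParseError(f"cannot parse {path}: {exc}") from exc
    required = {"structure", "precursor_mz", "product_mz", "ion_label"}
    missing = required - set(frame.columns)
    if missing:
        raise TransitionParseError(f"{path}: missing columns {sorted(missing)}")
    has_rt = "expected_rt" in frame.columns
    records = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            prec = float(row["precursor_mz"])
            prod = float(row["product_mz"])
            if prec <= 0 or prod <= 0:
                raise ValueError(f"non-positive m/z ({prec}, {prod})")
            rt_text = row["expected_rt"] if has_rt else ""
            rt = float(rt_text) if rt_text not in ("", "nan") else None
            records.append(
                TransitionRecord(
                    structure=str(row["structure"]),
                    precursor_mz=prec,
                    product_mz=prod,
                    ion_label=str(row["ion_label"]),
                    expected_rt=rt,
                )
            )
        except (ValueError, TypeError) as exc:
            raise TransitionParseError(f"{path} line {line}: {exc}") from exc
    return TransitionDB(tuple(records))
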