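"""Per-sample evidence aggregation into a detection matrix.

Mirrors the species-by-evidence summary used when screening many fungal
exudates: per sample, a high-confidence LCO flag (any structure detected
with >=2 co-eluting transitions or an untargeted hit), a low-confidence
flag (best evidence is a single transition at the expected RT), and a CO
flag (any chitooligosaccharide precursor matched). Bioassay columns
(root-hair branching, reporter-gene induction) are pass-through booleans
supplied externally — they are wet-lab results, never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .matching import DetectionCall

__all__ = ["EvidenceRecord", "aggregate_sample", "evidence_matrix",
           "write_evidence_tsv", "read_evidence_tsv"]

log = logging.getLogger(__name__)

FLAG_COLUMNS = ("ms_high", "ms_low", "co_detected")


@dataclass(frozen=True)
class EvidenceRecord:
    """One sample's evidence flags. ms_high and ms_low are mutually exclusive."""

    sample: str
    ms_high: bool = False
    ms_low: bool = False
    co_detected: bool = False
    bioassays: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ms_high and self.ms_low:
            raise ValueError("ms_high and ms_low are mutually exclusive")
        object.__setattr__(self, "bioassays", dict(self.bioassays))

    def merged_with(self, other: "EvidenceRecord") -> "EvidenceRecord":
        """Logical-OR merge of duplicate sample labels (max-tier wins)."""
        if other.sample != self.sample:
            raise ValueError("cannot merge records of different samples")
        high = self.ms_high or other.ms_high
        low = (self.ms_low or other.ms_low) and not high
        assays = {**self.bioassays, **{
            k: v or self.bioassays.get(k, False) for k, v in other.bioassays.items()
        }}
        return EvidenceRecord(
            sample=self.sample,
            ms_high=high,
            ms_low=low,
            co_detected=self.co_detected or other.co_detected,
            bioassays=assays,
        )


def aggregate_sample(
    sample: str,
    calls: Sequence[DetectionCall],
    co_calls: Sequence[DetectionCall] = (),
    bioassays: Mapping[str, bool] | None = None,
) -> EvidenceRecord:
    """Collapse one sample's detection calls to evidence flags.

    ``calls`` are LCO detections, ``co_calls`` detections on a CO panel
    (a CO counts as detected when at least one of its transitions matched).
    The sample-level MS tier is the max over structures.
    """
    any_high = any(c.tier == "high" for c in calls)
    any_low = any(c.tier == "low" for c in calls)
    return EvidenceRecord(
        sample=sample,
        ms_high=any_high,
        ms_low=any_low and not any_high,
        co_detected=any(c.matched_transitions >= 1 for c in co_calls),
        bioassays=bioassays or {},
    )


def evidence_matrix(records: Sequence[EvidenceRecord]) -> pd.DataFrame:
    """One row per sample, one boolean column per evidence flag.

    Duplicate sample labels merge with logical OR (logged). Row order
    follows first appearance; a False cell means "no detection".
    """
    if not records:
        raise ValueError("evidence_matrix needs at least one record")
    merged: dict[str, EvidenceRecord] = {}
    for record in records:
        if record.sample in merged:
            log.warning("duplicate sample label %r merged with OR", record.sample)
            merged[record.sample] = merged[record.sample].merged_with(record)
        else:
            merged[record.sample] = record

    assay_columns = sorted({k for r in merged.values() for k in r.bioassays})
    rows = []
    for record in merged.values():
        row: dict[str, object] = {"sample": record.sample}
        row.update({c: getattr(record, c) for c in FLAG_COLUMNS})
        row.update({c: bool(record.bioassays.get(c, False)) for c in assay_columns})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def write_evidence_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_evidence_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t").set_index("sample")
    return frame.astype(bool)
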