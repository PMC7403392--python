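"""Peak extraction, MRM panel matching, confidence tiers, untargeted annotation.

Detection confidence follows the two-tier scheme used for targeted LCO/CO
screening on triple quadrupoles: two or more transitions of one structure
co-eluting at a common retention time give a *high*-confidence call; a
single transition peaking at the structure's expected retention time gives
a *low*-confidence call; anything else is *none*. Untargeted (full-scan
precursor + product-ion) spectra are annotated against the theoretical
database, restricted to backbones of 3-6 GlcNAc residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .structures import backbone_length_from_name
from .transitions import TransitionDB, TransitionRecord

__all__ = [
    "ChromatogramTrace",
    "PeakCall",
    "DetectionCall",
    "UntargetedSpectrum",
    "CandidateMatch",
    "extract_peaks",
    "confidence_tier",
    "match_mrm",
    "match_untargeted",
    "read_traces_csv",
    "write_traces_csv",
    "read_traces_mzml",
    "read_spectra_csv",
    "detection_calls_to_frame",
]

log = logging.getLogger(__name__)

DEFAULT_MZ_TOLERANCE = 0.5  # Da; unit-resolution triple quadrupole
DEFAULT_RT_COELUTION_WINDOW = 0.1  # min
DEFAULT_SNR_THRESHOLD = 10.0
DEFAULT_MIN_HEIGHT = 10.0


@dataclass(frozen=True)
class ChromatogramTrace:
    """Intensity-vs-time series for one monitored (precursor, product) pair."""

    precursor_mz: float
    product_mz: float
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def key(self) -> tuple[float, float]:
        return (self.precursor_mz, self.product_mz)


@dataclass(frozen=True)
class PeakCall:
    """Extracted chromatographic apex."""

    rt: float
    intensity: float
    snr: float


@dataclass(frozen=True)
class DetectionCall:
    """Per-structure evidence from one sample's MRM traces."""

    structure: str
    matched_transitions: int
    coelution_rt: float | None
    tier: str  # "high" | "low" | "none"


@dataclass(frozen=True)
class UntargetedSpectrum:
    """One full-scan precursor with its accumulated product ions."""

    spectrum_id: str
    precursor_mz: float
    products: tuple[tuple[float, float], ...]  # (m/z, intensity)

    def __post_init__(self) -> None:
        for mz, _ in self.products:
            if mz >= self.precursor_mz:
                raise ValueError(
                    f"product m/z {mz} not below precursor {self.precursor_mz}"
                )


@dataclass(frozen=True)
class CandidateMatch:
    """Ranked structure candidate for an untargeted spectrum."""

    spectrum_id: str
    structure: str
    matched_products: int
    precursor_error: float
    rank: int


# ---------------------------------------------------------------------------
# Peak extraction
# ---------------------------------------------------------------------------


def extract_peaks(
    trace: ChromatogramTrace,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    min_height: float = DEFAULT_MIN_HEIGHT,
) -> list[PeakCall]:
    """Local maxima rising max(min_height, snr_threshold x MAD) above baseline.

    The baseline level is the trace median and the noise scale its median
    absolute deviation — both robust when peaks occupy part of the trace.
    Retained apexes are separated by at least one full width at half
    maximum; when two apexes fall closer, the taller wins.
    """
    y = trace.intensities
    if y.size == 0:
        return []
    baseline = float(np.median(y))
    noise = float(np.median(np.abs(y - baseline)))
    threshold = baseline + max(min_height, snr_threshold * noise)
    idx, _ = find_peaks(y, height=threshold)
    if idx.size == 0:
        return []
    widths_samples = peak_widths(y, idx, rel_height=0.5)[0]
    step = float(np.median(np.diff(trace.times))) if trace.times.size > 1 else 1.0
    fwhm = widths_samples * step

    order = np.argsort(y[idx])[::-1]  # tallest first
    kept: list[int] = []
    kept_fwhm: list[float] = []
    for j in order:
        rt_j = trace.times[idx[j]]
        too_close = any(
            abs(rt_j - trace.times[idx[k]]) < max(fwhm[j], kf)
            for k, kf in zip(kept, kept_fwhm)
        )
        if not too_close:
            kept.append(j)
            kept_fwhm.append(float(fwhm[j]))
    kept.sort(key=lambda j: trace.times[idx[j]])
    return [
        PeakCall(
            rt=float(trace.times[idx[j]]),
            intensity=float(y[idx[j]]),
            snr=float((y[idx[j]] - baseline) / noise) if noise > 0 else float("inf"),
        )
        for j in kept
    ]


# ---------------------------------------------------------------------------
# Confidence tiers and MRM matching
# ---------------------------------------------------------------------------


def confidence_tier(matched_count: int, at_expected_rt: bool) -> str:
    """Two-tier detection confidence.

    >=2 co-eluting transitions -> "high"; exactly one transition *at the
    structure's expected retention time* -> "low"; one transition without
    RT corroboration or zero transitions -> "none".
    """
    if matched_count < 0:
        raise ValueError("matched_count must be >= 0")
    if matched_count >= 2:
        return "high"
    if matched_count == 1:
        if at_expected_rt:
            return "low"
        log.info("single-transition match without expected-RT support: uncorroborated")
        return "none"
    return "none"


def _assign_traces(
    panel: TransitionDB,
    traces: Sequence[ChromatogramTrace],
    mz_tolerance: float,
) -> dict[TransitionRecord, list[ChromatogramTrace]]:
    """Map each trace to the panel transition within tolerance (nearest wins)."""
    assignment: dict[TransitionRecord, list[ChromatogramTrace]] = {
        r: [] for r in panel.records
    }
    for trace in traces:
        candidates = [
            r
            for r in panel.records
            if abs(r.precursor_mz - trace.precursor_mz) <= mz_tolerance
            and abs(r.product_mz - trace.product_mz) <= mz_tolerance
        ]
        if not candidates:
            continue
        if len(candidates) > 1:
            log.warning(
                "trace (%.4f, %.4f) matches %d panel transitions; assigning nearest",
                trace.precursor_mz,
                trace.product_mz,
                len(candidates),
            )
        best = min(
            candidates,
            key=lambda r: (
                (r.precursor_mz - trace.precursor_mz) ** 2
                + (r.product_mz - trace.product_mz) ** 2
            ),
        )
        assignment[best].append(trace)
    return assignment


def match_mrm(
    panel: TransitionDB,
    traces: Sequence[ChromatogramTrace],
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    rt_coelution_window: float = DEFAULT_RT_COELUTION_WINDOW,
    rt_expected_window: float | None = None,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    min_height: float = DEFAULT_MIN_HEIGHT,
) -> list[DetectionCall]:
    """Match chromatogram traces against a transition panel.

    Per structure, transitions with extracted apexes are grouped by
    co-elution (apex RTs within ``rt_coelution_window`` of a common RT); the
    largest co-eluting group sets the matched-transition count and the
    confidence tier. Output covers every panel structure, sorted by name.

    ``rt_expected_window`` bounds |co-elution RT - expected RT| for the
    low-tier check; defaults to ``rt_coelution_window``.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    if rt_expected_window is None:
        rt_expected_window = rt_coelution_window
    assignment = _assign_traces(panel, traces, mz_tolerance)

    calls = []
    for structure, records in sorted(panel.by_structure().items()):
        # one apex list per transition of this structure
        apexes: list[list[float]] = []
        for record in records:
            rts: list[float] = []
            for trace in assignment[record]:
                rts.extend(
                    p.rt for p in extract_peaks(trace, snr_threshold, min_height)
                )
            if rts:
                apexes.append(rts)

        matched, coelution_rt = _best_coelution(apexes, rt_coelution_window)
        expected = next((r.expected_rt for r in records if r.expected_rt is not None), None)
        at_expected = (
            coelution_rt is not None
            and expected is not None
            and abs(coelution_rt - expected) <= rt_expected_window
        )
        calls.append(
            DetectionCall(
                structure=structure,
                matched_transitions=matched,
                coelution_rt=coelution_rt,
                tier=confidence_tier(matched, at_expected),
            )
        )
    return calls


def _best_coelution(
    apexes: list[list[float]], window: float
) -> tuple[int, float | None]:
    """Largest set of transitions with apexes within ``window`` of a common RT.

    Candidate anchors are the apex RTs themselves; each transition
    contributes at most once. Ties resolve to the earliest anchor RT, so the
    result is deterministic.
    """
    if not apexes:
        return 0, None
    best_count, best_rt = 0, None
    anchors = sorted({rt for rts in apexes for rt in rts})
    for anchor in anchors:
        members = [
            min((rt for rt in rts if abs(rt - anchor) <= window), default=None)
            for rts in apexes
        ]
        hits = [rt for rt in members if rt is not None]
        if len(hits) > best_count:
            best_count = len(hits)
            best_rt = float(np.mean(hits))
    return best_count, best_rt


# ---------------------------------------------------------------------------
# Untargeted annotation
# ---------------------------------------------------------------------------


def match_untargeted(
    spectra: Sequence[UntargetedSpectrum],
    db: TransitionDB,
    mz_tolerance: float = 0.3,
    residue_range: tuple[int, int] = (3, 6),
    min_products: int = 2,
) -> list[CandidateMatch]:
    """Annotate full-scan spectra with DB structures.

    A candidate must (a) have a backbone length inside ``residue_range``,
    (b) match the spectrum precursor within ``mz_tolerance``, and (c) match
    at least ``min_products`` of its theoretical B ions among the spectrum's
    product ions. Candidates rank by matched-product count (descending),
    then absolute precursor error (ascending).
    """
    lo, hi = residue_range
    catalog = []
    for name, records in db.by_structure().items():
        n = backbone_length_from_name(name)
        if not lo <= n <= hi:
            continue
        catalog.append((name, records[0].precursor_mz, [r.product_mz for r in records]))

    annotations: list[CandidateMatch] = []
    for spectrum in spectra:
        product_mzs = np.array([mz for mz, _ in spectrum.products], dtype=float)
        scored = []
        for name, prec, b_ions in catalog:
            err = abs(prec - spectrum.precursor_mz)
            if err > mz_tolerance:
                continue
            hits = sum(
                1
                for b in b_ions
                if product_mzs.size and np.min(np.abs(product_mzs - b)) <= mz_tolerance
            )
            if hits >= min_products:
                scored.append((name, hits, err))
        scored.sort(key=lambda item: (-item[1], item[2], item[0]))
        for rank, (name, hits, err) in enumerate(scored, start=1):
            annotations.append(
                CandidateMatch(
                    spectrum_id=spectrum.spectrum_id,
                    structure=name,
                    matched_products=hits,
                    precursor_error=err,
                    rank=rank,
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_traces_csv(traces: Iterable[ChromatogramTrace], path: str | Path) -> None:
    """Long-format CSV: precursor_mz, product_mz, rt_min, intensity."""
    frames = []
    for trace in traces:
        frames.append(
            pd.DataFrame(
                {
                    "precursor_mz": np.round(trace.precursor_mz, 4),
                    "product_mz": np.round(trace.product_mz, 4),
                    "rt_min": np.round(trace.times, 6),
                    "intensity": np.round(trace.intensities, 6),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[ChromatogramTrace]:
    frame = pd.read_csv(path)
    required = {"precursor_mz", "product_mz", "rt_min", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for (prec, prod), group in frame.groupby(["precursor_mz", "product_mz"], sort=True):
        group = group.sort_values("rt_min")
        traces.append(
            ChromatogramTrace(
                precursor_mz=float(prec),
                product_mz=float(prod),
                times=group["rt_min"].to_numpy(),
                intensities=group["intensity"].to_numpy(),
            )
        )
    return traces


def _decode_binary_array(array_element) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (64/32-bit float, plain or zlib)."""
    import base64
    import zlib

    accessions = {
        cv.get("accession")
        for cv in array_element.iter("{http://psi.hupo.org/ms/mzml}cvParam")
    }
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    binary = array_element.find("{http://psi.hupo.org/ms/mzml}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_traces_mzml(path: str | Path) -> list[ChromatogramTrace]:
    """Read selected-reaction-monitoring chromatograms from an mzML file.

    Walks the chromatogram list (one SRM chromatogram per transition),
    taking the precursor/product isolation-window target m/z values
    (accession MS:1000827) and the time/intensity arrays. TIC and other
    chromatograms without both isolation windows are skipped.
    """
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    traces = []
    for _, chrom in etree.iterparse(str(path), tag=f"{ns}chromatogram"):
        targets = {}
        for side in ("precursor", "product"):
            element = chrom.find(f"{ns}{side}/{ns}isolationWindow")
            if element is not None:
                for cv in element.iter(f"{ns}cvParam"):
                    if cv.get("accession") == "MS:1000827":
                        targets[side] = float(cv.get("value"))
        arrays = {}
        for array_element in chrom.iter(f"{ns}binaryDataArray"):
            accessions = {
                cv.get("accession") for cv in array_element.iter(f"{ns}cvParam")
            }
            if "MS:1000595" in accessions:  # time array
                arrays["time"] = _decode_binary_array(array_element)
            elif "MS:1000515" in accessions:  # intensity array
                arrays["intensity"] = _decode_binary_array(array_element)
        chrom.clear()
        if {"precursor", "product"} <= targets.keys() and {"time", "intensity"} <= arrays.keys():
            traces.append(
                ChromatogramTrace(
                    precursor_mz=targets["precursor"],
                    product_mz=targets["product"],
                    times=arrays["time"],
                    intensities=arrays["intensity"],
                )
            )
    return traces


def read_spectra_csv(path: str | Path) -> list[UntargetedSpectrum]:
    """Two-level CSV: spectrum_id, precursor_mz, product_mz, intensity."""
    frame = pd.read_csv(path)
    required = {"spectrum_id", "precursor_mz", "product_mz", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    spectra = []
    for (sid, prec), group in frame.groupby(["spectrum_id", "precursor_mz"], sort=True):
        products = tuple(
            (float(mz), float(inten))
            for mz, inten in zip(group["product_mz"], group["intensity"])
        )
        spectra.append(
            UntargetedSpectrum(
                spectrum_id=str(sid), precursor_mz=float(prec), products=products
            )
        )
    return spectra


def detection_calls_to_frame(calls: Sequence[DetectionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "structure": [c.structure for c in calls],
            "matched_transitions": [c.matched_transitions for c in calls],
            "coelution_rt": [c.coelution_rt for c in calls],
            "tier": [c.tier for c in calls],
        }
    )
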