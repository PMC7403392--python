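"""Ground-truth-labeled synthetic MRM chromatograms and untargeted spectra.

Stands in for fungal-exudate injections: each transition of a planted
structure receives a Gaussian elution peak at the structure's true
retention time, every monitored trace carries additive Gaussian baseline
noise, and decoy peaks are placed both on non-planted panel transitions
(wrong-analyte signal, exercises co-elution logic) and on off-panel m/z
pairs (exercises m/z tolerance logic). Identical seeds produce identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .matching import ChromatogramTrace
from .transitions import TransitionDB

__all__ = [
    "SimulationConfig",
    "TruthEntry",
    "TruthTable",
    "SimulationConfigError",
    "simulate_chromatograms",
    "simulate_untargeted",
    "write_truth_tsv",
]

#: LC window (min) matching a typical 10-minute reversed-phase gradient
#: plus the initial isocratic hold.
LC_WINDOW = (1.0, 11.0)


class SimulationConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the chromatogram simulator.

    ``planted`` maps structure name -> true retention time (min); use None
    to draw the RT uniformly inside the LC window. Amplitudes are drawn per
    peak from ``amplitude_range``.
    """

    planted: Mapping[str, float | None] = field(default_factory=dict)
    amplitude_range: tuple[float, float] = (200.0, 1000.0)
    peak_sigma: float = 0.05  # min
    time_start: float = LC_WINDOW[0]
    time_end: float = LC_WINDOW[1]
    time_step: float = 0.01  # min
    #: positive detector baseline level; keeps additive noise away from the
    #: zero clip so baseline statistics stay well defined
    baseline: float = 20.0
    noise_sd: float = 5.0
    decoy_count: int = 0
    off_panel_decoy_count: int = 0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise SimulationConfigError("time_step must be > 0")
        if self.peak_sigma <= 0:
            raise SimulationConfigError("peak_sigma must be > 0")
        if not 0.0 <= self.dropout <= 1.0:
            raise SimulationConfigError("dropout must be in [0, 1]")
        if self.noise_sd < 0:
            raise SimulationConfigError("noise_sd must be >= 0")
        if self.baseline < 0:
            raise SimulationConfigError("baseline must be >= 0")
        if self.amplitude_range[0] > self.amplitude_range[1]:
            raise SimulationConfigError("amplitude_range must be (low, high)")
        object.__setattr__(self, "planted", dict(self.planted))


@dataclass(frozen=True)
class TruthEntry:
    """Per-structure ground truth: what was emitted and what was dropped."""

    structure: str
    true_rt: float
    emitted: tuple[str, ...]  # ion labels with a real peak
    dropped: tuple[str, ...]  # ion labels suppressed by dropout


@dataclass(frozen=True)
class TruthTable:
    entries: tuple[TruthEntry, ...]

    def rt_of(self) -> dict[str, float]:
        return {e.structure: e.true_rt for e in self.entries}

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _gaussian(t: np.ndarray, amplitude: float, t0: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((t - t0) ** 2) / (2.0 * sigma**2))


def simulate_chromatograms(
    panel: TransitionDB,
    config: SimulationConfig,
) -> tuple[list[ChromatogramTrace], TruthTable]:
    """Simulate one injection monitored over every panel transition.

    Every panel transition yields a trace (noise only unless planted);
    decoys add peaks at wrong RTs. Deterministic for a given config/seed.
    """
    by_structure = panel.by_structure()
    for name in config.planted:
        if name not in by_structure:
            raise SimulationConfigError(
                f"planted structure {name!r} has no transitions in the panel"
            )

    rng = np.random.default_rng(config.seed)
    t = np.arange(config.time_start, config.time_end + config.time_step / 2, config.time_step)

    # resolve true RTs in deterministic (name-sorted) order
    true_rts: dict[str, float] = {}
    for name in sorted(config.planted):
        rt = config.planted[name]
        true_rts[name] = float(rt) if rt is not None else float(
            rng.uniform(config.time_start + 0.5, config.time_end - 0.5)
        )

    signals: dict[tuple[str, str], np.ndarray] = {}
    entries = []
    for name in sorted(config.planted):
        emitted, dropped = [], []
        for record in by_structure[name]:
            if rng.uniform() < config.dropout:
                dropped.append(record.ion_label)
                continue
            amplitude = float(rng.uniform(*config.amplitude_range))
            signals[(name, record.ion_label)] = _gaussian(
                t, amplitude, true_rts[name], config.peak_sigma
            )
            emitted.append(record.ion_label)
        entries.append(
            TruthEntry(
                structure=name,
                true_rt=true_rts[name],
                emitted=tuple(emitted),
                dropped=tuple(dropped),
            )
        )

    # decoys on non-planted panel transitions, at random (wrong) RTs
    non_planted = [r for r in panel.records if r.structure not in config.planted]
    if config.decoy_count and non_planted:
        picks = rng.choice(
            len(non_planted), size=min(config.decoy_count, len(non_planted)), replace=False
        )
        for i in sorted(int(p) for p in picks):
            record = non_planted[i]
            amplitude = float(rng.uniform(*config.amplitude_range))
            rt = float(rng.uniform(config.time_start + 0.5, config.time_end - 0.5))
            key = (record.structure, record.ion_label)
            signals[key] = signals.get(key, 0.0) + _gaussian(
                t, amplitude, rt, config.peak_sigma
            )

    traces = []
    for record in panel.records:
        y = np.full_like(t, config.baseline)
        y = y + signals.get((record.structure, record.ion_label), 0.0)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=t.size)
        traces.append(
            ChromatogramTrace(
                precursor_mz=record.precursor_mz,
                product_mz=record.product_mz,
                times=t.copy(),
                intensities=np.clip(y, 0.0, None),
            )
        )

    # off-panel decoys: m/z pairs far from every panel transition
    for _ in range(config.off_panel_decoy_count):
        prec = float(rng.uniform(300.0, 1400.0))
        prod = float(rng.uniform(100.0, prec - 50.0))
        amplitude = float(rng.uniform(*config.amplitude_range))
        rt = float(rng.uniform(config.time_start + 0.5, config.time_end - 0.5))
        y = config.baseline + _gaussian(t, amplitude, rt, config.peak_sigma)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=t.size)
        traces.append(
            ChromatogramTrace(
                precursor_mz=prec,
                product_mz=prod,
                times=t.copy(),
                intensities=np.clip(y, 0.0, None),
            )
        )

    return traces, TruthTable(tuple(entries))


def simulate_untargeted(
    db: TransitionDB,
    k_structures: int,
    noise_products: int = 2,
    seed: int = 0,
):
    """Draw ``k_structures`` DB entries and emit one spectrum per structure.

    Each spectrum holds the structure's precursor m/z, all of its
    theoretical B ions, and ``noise_products`` uniform-random extra product
    m/z values. Returns ``(spectra, truth)`` where truth lists the
    generating structure name per spectrum.
    """
    from .matching import UntargetedSpectrum

    by_structure = db.by_structure()
    names = sorted(by_structure)
    if k_structures > len(names):
        raise SimulationConfigError(
            f"k_structures={k_structures} exceeds DB size {len(names)}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(names), size=k_structures, replace=False)

    spectra, truth = [], []
    for count, i in enumerate(int(p) for p in picks):
        name = names[i]
        records = by_structure[name]
        prec = records[0].precursor_mz
        products = [(r.product_mz, float(rng.uniform(100.0, 1000.0))) for r in records]
        for _ in range(noise_products):
            products.append(
                (float(rng.uniform(80.0, prec - 1.0)), float(rng.uniform(1.0, 100.0)))
            )
        products.sort()
        spectra.append(
            UntargetedSpectrum(
                spectrum_id=f"spec{count:04d}",
                precursor_mz=prec,
                products=tuple(products),
            )
        )
        truth.append(name)
    return spectra, truth


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "structure": [e.structure for e in truth],
            "true_rt": [round(e.true_rt, 4) for e in truth],
            "emitted": [",".join(e.emitted) for e in truth],
            "dropped": [",".join(e.dropped) for e in truth],
        }
    ).to_csv(path, sep="\t", index=False)
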