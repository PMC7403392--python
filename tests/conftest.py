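"""Shared fixtures: small structure sets, panels, and an independent mass oracle."""

from __future__ import annotations

import re

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from lcoscan import (
    AcylChain,
    COStructure,
    LCOStructure,
    StructureGrammar,
    build_transition_db,
    enumerate_structures,
)

# Independent per-atom mass summation, deliberately separate from the
# package's code path: literal constants, regex tokenizer, plain loop.
_ORACLE_MASSES = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}


def oracle_mass(hill: str) -> float:
    total = 0.0
    for element, digits in re.findall(r"([A-Z][a-z]?)(\d*)", hill):
        if element:
            total += _ORACLE_MASSES[element] * (int(digits) if digits else 1)
    return total


@pytest.fixture(scope="session")
def co_structures():
    return [COStructure(n) for n in (3, 4, 5, 6)]


@pytest.fixture(scope="session")
def standards():
    """The four synthetic LCO standards used to calibrate retention times."""
    return [
        LCOStructure.make(4, AcylChain(16, 0)),
        LCOStructure.make(4, AcylChain(16, 0), {"R6": "S"}),
        LCOStructure.make(4, AcylChain(18, 1)),
        LCOStructure.make(4, AcylChain(18, 1), {"R6": "S"}),
    ]


@pytest.fixture(scope="session")
def small_grammar():
    return StructureGrammar(
        backbone_lengths=(4,),
        acyl_library=(AcylChain(16, 0), AcylChain(18, 1)),
        position_options={"R6": ("H", "S")},
    )


@pytest.fixture(scope="session")
def small_db(small_grammar):
    return build_transition_db(enumerate_structures(small_grammar))


@pytest.fixture(scope="session")
def default_db():
    """Full default-grammar DB (built once; ~3k structures)."""
    return build_transition_db(enumerate_structures(StructureGrammar()))
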