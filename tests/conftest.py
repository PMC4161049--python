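"""Shared fixtures: tiny corpora/puzzles built in memory, plus the session
battery used by the factorial-scale tests (generated once, reused)."""

import numpy as np
import pytest

from crossmind import (
    BatterySpec,
    ModelConfig,
    Puzzle,
    ingest_corpus,
    generate_battery,
)

TOY_CORPUS = [
    ("feline pet", "CAT"),
    ("canine pet", "DOG"),
    ("corn cob treat", "COB"),
    ("night bird", "OWL"),
    ("feline pet", "CAT"),
    ("large feline", "TIGER"),
]


@pytest.fixture(scope="session")
def toy_stores():
    return ingest_corpus(TOY_CORPUS)


@pytest.fixture()
def toy_puzzle():
    """3x3 open-corner puzzle: CAT across, COB down, crossing at C."""
    # grid:  C A T
    #        O . .
    #        B . .
    blocks = {(1, 1), (1, 2), (2, 1), (2, 2)}
    clues = {"1A": "feline pet", "1D": "corn cob treat"}
    solution = {(0, 0): "C", (0, 1): "A", (0, 2): "T", (1, 0): "O", (2, 0): "B"}
    return Puzzle.build((3, 3), blocks, clues, solution, min_len=3, id="toy")


@pytest.fixture(scope="session")
def small_battery():
    """A reduced battery (6 puzzles) sharing the full battery's conditions."""
    battery = BatterySpec(n_puzzles=6)
    lexicon, records, puzzles = generate_battery(1, battery)
    sem, orth = ingest_corpus(records)
    return battery, lexicon, records, puzzles, sem, orth


@pytest.fixture()
def expert_config():
    return ModelConfig(time_limit=float("inf"), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
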