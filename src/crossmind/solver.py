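"""The solving agent: selection -> retrieval -> updating, with a clock.

Each iteration selects an unsolved clue (uniformly at random, or by a
Luce-choice over discounted-reward weights), walks the cursor there, reads
the clue, probes the semantic route (always) and the orthographic route
(only when the pattern carries at least one letter), arbitrates, and on
success writes the answer into the grid.  Time is charged with
keystroke-level operators:

    T_solving = d*t_moving + t_reading + n*t_retrieval + wl*t_typing

where d is the Manhattan distance walked, n the candidate draws the winning
route consumed, and wl the letters newly typed.  A failed attempt charges
the walk, the reading, and every draw both routes consumed.  The model
never erases: there is no error detection, correction, or backtracking.

Termination: all slots filled, the simulated clock passes ``time_limit``,
or ``stall_cycles`` consecutive full passes over the unsolved clues produce
no solve.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .grid import GridState, Puzzle, Slot
from .knowledge import AssociationStore, semantic_features
from .retrieval import (
    RouteDistribution,
    arbitrate,
    probe_orthographic,
    probe_semantic,
    route_probability,
)

RANDOM = "random"
OPTIMIZING = "optimizing"


class ConfigError(ValueError):
    """A model parameter is out of range; the offending field is named."""


@dataclass(frozen=True)
class ModelConfig:
    """All simulation parameters, named as in the model's parameter table.

    ``recovery`` (semantic fluency) and ``retrieval`` (seconds per memory
    draw) are the expertise knobs; the factorial crosses them with the two
    gridfill strategies.  Times are in seconds.
    """

    strategy: str = OPTIMIZING
    recovery: float = 15.0
    retrieval: float = 0.25
    reading: float = 1.0
    typing: float = 0.28
    moving: float = 0.14
    smoothing_orth: float = 0.001
    smoothing_sem: float = 1e-8
    likelihood: float = 100.0
    search_set: int = 10
    alpha: float = 0.02
    s1: float = 0.001
    s2: float = 1e-5
    time_limit: float = 1500.0
    stall_cycles: int = 3
    #: a clue is retired after this many failed attempts ("avoid revisiting
    #: failed clues"); retirement is what lets competence asymptote
    max_attempts: int = 6
    seed: int = 0
    selection_argmax: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in (RANDOM, OPTIMIZING):
            raise ConfigError(f"strategy must be random|optimizing, got {self.strategy!r}")
        for name in ("recovery", "retrieval", "reading", "typing", "moving", "time_limit"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.alpha < 1.0:
            raise ConfigError("alpha must lie in [0, 1)")
        for name in ("s1", "s2", "smoothing_orth", "smoothing_sem"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.search_set < 1:
            raise ConfigError("search_set must be >= 1")
        if self.stall_cycles < 1:
            raise ConfigError("stall_cycles must be >= 1")
        if self.max_attempts < 1:
            raise ConfigError("max_attempts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


#: The eight factorial parameterizations: strategy x recovery x retrieval.
#: Codes follow the parameter table; models 1-4 optimize, 5-8 move randomly;
#: odd models retrieve fast (0.25 s), even slow (3.0 s); models 1,2,5,6 are
#: fluent (recovery 15), the rest disfluent (recovery 0.5).
FACTORIAL_MODELS: dict[int, tuple[str, str, float, float]] = {
    1: ("OFF", OPTIMIZING, 15.0, 0.25),
    2: ("OFS", OPTIMIZING, 15.0, 3.0),
    3: ("ODF", OPTIMIZING, 0.5, 0.25),
    4: ("ODS", OPTIMIZING, 0.5, 3.0),
    5: ("RFF", RANDOM, 15.0, 0.25),
    6: ("RDF", RANDOM, 15.0, 3.0),
    7: ("RFS", RANDOM, 0.5, 0.25),
    8: ("RDS", RANDOM, 0.5, 3.0),
}


def model_config(model: int, **overrides) -> ModelConfig:
    """The ModelConfig for factorial model 1..8, with optional overrides."""
    code, strategy, recovery, retrieval = FACTORIAL_MODELS[model]
    base = dict(strategy=strategy, recovery=recovery, retrieval=retrieval)
    base.update(overrides)
    return ModelConfig(**base)


def solving_time(d: int, n_draws: int, wl: int, config: ModelConfig) -> float:
    """Seconds to solve a clue: move + read + retrieve + type."""
    if min(d, n_draws, wl) < 0:
        raise ValueError("operator counts must be non-negative")
    return (
        d * config.moving
        + config.reading
        + n_draws * config.retrieval
        + wl * config.typing
    )


def clue_weight(
    slot: Slot, state: GridState, attempts: dict[str, int], config: ModelConfig
) -> float:
    """Discounted-reward weight of an unsolved clue.

    w_i = (1-alpha)^d_i * (wf_i/att_i + s1) + s2: the reward (letters
    already filled) is discounted per cell of walking distance and divided
    by the number of times the clue has already been attempted; the
    smoothers keep every clue selectable.
    """
    d = state.manhattan_distance(slot)
    wf = state.prefilled_count(slot)
    att = attempts[slot.id]
    return (1.0 - config.alpha) ** d * (wf / att + config.s1) + config.s2


def select_clue_random(
    state: GridState, unsolved: list[str], rng: np.random.Generator
) -> str:
    """Uniform choice over unsolved slot ids."""
    return unsolved[int(rng.integers(len(unsolved)))]


def select_clue_optimizing(
    state: GridState,
    unsolved: list[str],
    attempts: dict[str, int],
    config: ModelConfig,
    rng: np.random.Generator,
) -> str:
    """Luce-choice over clue weights (or argmax when configured)."""
    slots = [state.puzzle.slot(sid) for sid in unsolved]
    w = np.array([clue_weight(s, state, attempts, config) for s in slots])
    if config.selection_argmax:
        best = np.flatnonzero(w == w.max())
        return unsolved[int(best[0])]
    p = w / w.sum()
    return unsolved[int(rng.choice(len(unsolved), p=p))]


@dataclass(frozen=True)
class SolveEvent:
    """One timed attempt at a clue."""

    clock_start: float
    clock_end: float
    slot_id: str
    d: int
    n_draws: int
    outcome: str  # "solved" | "failed"
    answer: Optional[str]
    route: str  # semantic | orthographic | both | none
    prefilled: int
    length: int
    cycle: int
    attempt: int

    @property
    def duration(self) -> float:
        return self.clock_end - self.clock_start


@dataclass
class SolveTrace:
    """Timestamped event log of a solve, plus enough context to replay it."""

    puzzle_id: str
    config: ModelConfig
    seed: int
    events: list[SolveEvent] = field(default_factory=list)
    termination: str = ""

    @property
    def clock(self) -> float:
        return self.events[-1].clock_end if self.events else 0.0

    def solved_events(self, until: float | None = None) -> list[SolveEvent]:
        return [
            e
            for e in self.events
            if e.outcome == "solved" and (until is None or e.clock_end <= until)
        ]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            header = {
                "puzzle_id": self.puzzle_id,
                "config": asdict(self.config),
                "seed": self.seed,
                "termination": self.termination,
            }
            fh.write(json.dumps({"header": header}) + "\n")
            for e in self.events:
                fh.write(json.dumps(asdict(e)) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "SolveTrace":
        with open(path, encoding="utf-8") as fh:
            lines = [json.loads(ln) for ln in fh if ln.strip()]
        header = lines[0]["header"]
        trace = cls(
            header["puzzle_id"],
            ModelConfig(**header["config"]),
            header["seed"],
            [SolveEvent(**rec) for rec in lines[1:]],
            header["termination"],
        )
        return trace

    def to_csv(self, path: str | Path) -> None:
        cols = [f.name for f in fields(SolveEvent)]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for e in self.events:
                w.writerow([getattr(e, c) for c in cols])


def replay(trace: SolveTrace, puzzle: Puzzle, until: float | None = None) -> GridState:
    """Rebuild the grid state implied by a trace's solved events."""
    state = GridState(puzzle)
    for e in trace.solved_events(until):
        state.write_answer(puzzle.slot(e.slot_id), e.answer)
    return state


def run_solver(
    puzzle: Puzzle,
    sem_store: AssociationStore,
    orth_store: AssociationStore,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> SolveTrace:
    """Run the selection -> retrieval -> updating loop to termination.

    The trace is a pure function of (puzzle, stores, config, seed): all
    randomness flows through one generator seeded from ``config.seed``
    unless an explicit ``rng`` is injected.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = GridState(puzzle)
    attempts = {s.id: 1 for s in puzzle.slots}
    trace = SolveTrace(puzzle.id, config, config.seed)
    clock = 0.0
    cycle = 0
    touched_since_solve: set[str] = set()
    stalled_cycles = 0
    # semantic distributions depend only on the clue: compute once per slot
    sem_feats = {s.id: semantic_features(s.clue_text) for s in puzzle.slots}
    sem_dists: dict[str, RouteDistribution] = {}

    while True:
        unsolved = state.unsolved_ids()
        if not unsolved:
            trace.termination = "completed"
            break
        selectable = [sid for sid in unsolved if attempts[sid] <= config.max_attempts]
        if not selectable:
            trace.termination = "exhausted"
            break
        if clock >= config.time_limit:
            trace.termination = "time_limit"
            break
        if stalled_cycles >= config.stall_cycles:
            trace.termination = "stalled"
            break

        if config.strategy == RANDOM:
            sid = select_clue_random(state, selectable, rng)
        else:
            sid = select_clue_optimizing(state, selectable, attempts, config, rng)
        slot = puzzle.slot(sid)
        d = state.manhattan_distance(slot)
        pattern = state.pattern_of(slot)
        feats = sem_feats[sid]
        if sid not in sem_dists:
            sem_dists[sid] = route_probability(sem_store, feats, config.smoothing_sem)

        sem = probe_semantic(feats, pattern, sem_store, config, rng, dist=sem_dists[sid])
        # the orthographic route abstains on an all-unknown pattern
        orth = probe_orthographic(
            pattern, feats, sem_store, orth_store, config, rng, sem_dist=sem_dists[sid]
        )
        winner = arbitrate(sem, orth, config.likelihood)

        if winner is not None:
            prefilled = state.prefilled_count(slot)
            wl = slot.length - prefilled
            duration = solving_time(d, winner.n_draws, wl, config)
            state.write_answer(slot, winner.answer)
            trace.events.append(
                SolveEvent(
                    clock, clock + duration, sid, d, winner.n_draws, "solved",
                    winner.answer, winner.route, prefilled, slot.length,
                    cycle, attempts[sid],
                )
            )
            clock += duration
            touched_since_solve.clear()
            stalled_cycles = 0
        else:
            n_consumed = sem.n_draws + orth.n_draws
            duration = d * config.moving + config.reading + n_consumed * config.retrieval
            trace.events.append(
                SolveEvent(
                    clock, clock + duration, sid, d, n_consumed, "failed",
                    None, "none", state.prefilled_count(slot), slot.length,
                    cycle, attempts[sid],
                )
            )
            clock += duration
            attempts[sid] += 1
            state.cursor = slot.start
            touched_since_solve.add(sid)
            still = {
                s for s in state.unsolved_ids()
                if attempts[s] <= config.max_attempts
            }
            if still and touched_since_solve >= still:
                stalled_cycles += 1
                cycle += 1
                touched_since_solve.clear()
    return trace
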