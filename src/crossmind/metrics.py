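"""Evaluation metrics over solve traces and the eight-model factorial.

All metrics are pure functions of traces (plus the puzzle/solution they
refer to), so recomputation on a stored trace is bit-identical.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .grid import Puzzle
from .knowledge import AssociationStore
from .retrieval import BOTH_ROUTE, ORTH_ROUTE, SEM_ROUTE
from .solver import FACTORIAL_MODELS, SolveTrace, model_config, replay, run_solver


def prefilled_proportion(trace: SolveTrace, block: int | None = None) -> list[float]:
    """Per solved clue, the fraction of its letters already present.

    A 6-letter word solved with three letters already supplied by crossings
    scores 0.5.  With ``block`` set, consecutive blocks of that many solves
    are averaged (the progress-curve view).
    """
    series = [e.prefilled / e.length for e in trace.solved_events()]
    if block is None or not series:
        return series
    return [
        float(np.mean(series[i : i + block])) for i in range(0, len(series), block)
    ]


def score_against_solution(
    trace: SolveTrace, puzzle: Puzzle, until: float | None = None
) -> tuple[int, int]:
    """(completed, correct) slot counts at clock ``until`` (None = trace end).

    Completed counts slots filled by any means, including those completed
    by crossings; correct counts completed slots whose letters match the
    solution grid exactly.
    """
    if puzzle.solution is None:
        raise ValueError("puzzle has no solution grid to score against")
    state = replay(trace, puzzle, until)
    completed = correct = 0
    for slot in puzzle.slots:
        if state.solved[slot.id]:
            completed += 1
            filled = "".join(state.letters[c] for c in slot.cells)
            if filled == puzzle.solution_word(slot):
                correct += 1
    return completed, correct


def route_attribution(
    traces: Sequence[SolveTrace], bins: int = 10, axis: str = "solves"
) -> pd.DataFrame:
    """Share of solved clues credited to each route, by progress bin.

    ``axis="solves"`` scales each trace's solve order to [0, 1) (per-trace
    progress); ``axis="attempts"`` pools solved events by their absolute
    attempt index across traces, the view in which late bins are populated
    only by runs still grinding on hard clues.  Within each non-empty bin
    the semantic / orthographic / both shares sum to 1.
    """
    if axis not in ("solves", "attempts"):
        raise ValueError("axis must be 'solves' or 'attempts'")
    rows = []
    if axis == "solves":
        for trace in traces:
            solved = trace.solved_events()
            for k, e in enumerate(solved):
                progress = k / len(solved)
                rows.append({"bin": min(int(progress * bins), bins - 1), "route": e.route})
    else:
        span = max((len(t.events) for t in traces), default=1)
        for trace in traces:
            for idx, e in enumerate(trace.events):
                if e.outcome == "solved":
                    rows.append(
                        {"bin": min(idx * bins // span, bins - 1), "route": e.route}
                    )
    if not rows:
        return pd.DataFrame(columns=[SEM_ROUTE, ORTH_ROUTE, BOTH_ROUTE])
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["bin", "route"]).size().unstack(fill_value=0)
        .reindex(columns=[SEM_ROUTE, ORTH_ROUTE, BOTH_ROUTE], fill_value=0)
    )
    return table.div(table.sum(axis=1), axis=0)


def _cell_seed(master_seed: int, model: int, puzzle_idx: int, rep: int) -> np.random.Generator:
    # documented counter scheme: one spawn key per factorial cell
    return np.random.default_rng(
        np.random.SeedSequence((master_seed, model, puzzle_idx, rep))
    )


def run_factorial_cell(
    model: int,
    puzzle: Puzzle,
    puzzle_idx: int,
    rep: int,
    sem_store: AssociationStore,
    orth_store: AssociationStore,
    master_seed: int,
    time_limit: float = 1500.0,
) -> tuple[SolveTrace, dict]:
    """Run one (model, puzzle, replicate) cell with its derived seed.

    The solver runs with the time limit lifted (termination by completion
    or stall), and both the within-limit and lifted scores are read off the
    same trace.
    """
    config = model_config(model, time_limit=float("inf"), seed=0)
    rng = _cell_seed(master_seed, model, puzzle_idx, rep)
    trace = run_solver(puzzle, sem_store, orth_store, config, rng)
    n_slots = len(puzzle.slots)
    completed, correct = score_against_solution(trace, puzzle, until=time_limit)
    completed_l, correct_l = score_against_solution(trace, puzzle)
    row = {
        "model": model,
        "code": FACTORIAL_MODELS[model][0],
        "puzzle": puzzle.id,
        "replicate": rep,
        "n_slots": n_slots,
        "completed_frac": completed / n_slots,
        "correct_frac": correct / n_slots,
        "completed_frac_lifted": completed_l / n_slots,
        "correct_frac_lifted": correct_l / n_slots,
        "clock": trace.clock,
        "termination": trace.termination,
    }
    return trace, row


def factorial_experiment(
    puzzles: Sequence[Puzzle],
    sem_store: AssociationStore,
    orth_store: AssociationStore,
    replicates: int = 10,
    time_limit: float = 1500.0,
    master_seed: int = 0,
    models: Sequence[int] = tuple(FACTORIAL_MODELS),
    keep_traces: bool = False,
) -> tuple[pd.DataFrame, dict[int, list[SolveTrace]]]:
    """The full strategy x fluency x speed factorial over a puzzle battery.

    Returns the tidy cell table and, when ``keep_traces`` is set, the
    traces grouped by model for downstream route/strategy analyses.
    """
    rows = []
    traces: dict[int, list[SolveTrace]] = {m: [] for m in models}
    for model in models:
        for puzzle_idx, puzzle in enumerate(puzzles):
            for rep in range(replicates):
                trace, row = run_factorial_cell(
                    model, puzzle, puzzle_idx, rep,
                    sem_store, orth_store, master_seed, time_limit,
                )
                rows.append(row)
                if keep_traces:
                    traces[model].append(trace)
    return pd.DataFrame(rows), traces


def factorial_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean fractions per model, the headline bar-chart analog."""
    return (
        table.groupby(["model", "code"])[
            ["completed_frac", "correct_frac", "completed_frac_lifted", "correct_frac_lifted"]
        ]
        .mean()
        .reset_index()
    )


def correct_over_time(
    traces: Sequence[SolveTrace],
    puzzles: dict[str, Puzzle],
    time_points: Sequence[float],
) -> pd.DataFrame:
    """Mean correct fraction at each simulated time point (progress curves)."""
    rows = []
    for t in time_points:
        vals = []
        for trace in traces:
            puzzle = puzzles[trace.puzzle_id]
            _, correct = score_against_solution(trace, puzzle, until=t)
            vals.append(correct / len(puzzle.slots))
        rows.append({"time": t, "correct_frac": float(np.mean(vals))})
    return pd.DataFrame(rows)


def plot_factorial(summary: pd.DataFrame, path: str) -> None:
    """Completed/correct bars per model, within-limit bars inset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(summary))
    ax.bar(x - 0.2, summary["completed_frac_lifted"], 0.38, label="completed (no limit)")
    ax.bar(x + 0.2, summary["correct_frac_lifted"], 0.38, label="correct (no limit)")
    ax.bar(x - 0.2, summary["completed_frac"], 0.18, color="firebrick",
           label="completed (within limit)")
    ax.bar(x + 0.2, summary["correct_frac"], 0.18, color="darkred",
           label="correct (within limit)")
    ax.set_xticks(x, [f"{m} {c}" for m, c in zip(summary["model"], summary["code"])])
    ax.set_ylabel("fraction of slots")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
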