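"""Crossword grid representation, slot extraction, and puzzle file IO.

A puzzle is a rectangular grid of open and blocked cells.  Every maximal
horizontal or vertical run of open cells at least ``min_len`` long is a
*slot* holding one answer, numbered in standard crossword order.  A
:class:`GridState` tracks the letters written so far, which slots are
filled, and the cursor position (the origin of the movement cost when the
solver walks to its next clue).

Supported formats: the ipuz JSON crossword kind, and a plain-text dialect
(grid rows with ``#`` blocks, a blank line, ``LABEL<TAB>clue`` lines, and
an optional solution grid block).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .knowledge import UNKNOWN

ACROSS = "across"
DOWN = "down"


class PuzzleError(ValueError):
    """Malformed grid, clue mismatch, or conflicting write."""


@dataclass(frozen=True)
class Slot:
    """One across or down answer run: label like ``"3D"``, start cell, cells."""

    id: str
    direction: str
    start: tuple[int, int]
    length: int
    clue_text: str
    cells: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.length != len(self.cells):
            raise PuzzleError(f"slot {self.id}: length != |cells|")


def _runs(line_cells: list[tuple[int, int]], blocks: set[tuple[int, int]], min_len: int):
    run: list[tuple[int, int]] = []
    for cell in line_cells:
        if cell in blocks:
            if len(run) >= min_len:
                yield run
            run = []
        else:
            run.append(cell)
    if len(run) >= min_len:
        yield run


def numbered_starts(
    dims: tuple[int, int], blocks: set[tuple[int, int]], min_len: int = 3
) -> dict[tuple[int, int], int]:
    """Standard crossword numbering: a cell gets a number if it starts a run."""
    rows, cols = dims
    starts: dict[tuple[int, int], int] = {}
    n = 0
    for r in range(rows):
        for c in range(cols):
            if (r, c) in blocks:
                continue
            across_start = (c == 0 or (r, c - 1) in blocks) and all(
                (r, cc) not in blocks for cc in range(c, min(c + min_len, cols))
            ) and c + min_len <= cols
            down_start = (r == 0 or (r - 1, c) in blocks) and all(
                (rr, c) not in blocks for rr in range(r, min(r + min_len, rows))
            ) and r + min_len <= rows
            if across_start or down_start:
                n += 1
                starts[(r, c)] = n
    return starts


def slots_from_grid(
    dims: tuple[int, int],
    blocks: set[tuple[int, int]],
    clue_texts: dict[str, str] | None = None,
    min_len: int = 3,
) -> list[Slot]:
    """Extract numbered slots; attach clue texts by label (e.g. ``"1A"``).

    Raises :class:`PuzzleError` naming missing or extra labels when
    ``clue_texts`` does not cover the slots exactly.
    """
    rows, cols = dims
    starts = numbered_starts(dims, blocks, min_len)
    slots: list[Slot] = []
    for r in range(rows):
        for run in _runs([(r, c) for c in range(cols)], blocks, min_len):
            num = starts[run[0]]
            slots.append(Slot(f"{num}A", ACROSS, run[0], len(run), "", tuple(run)))
    for c in range(cols):
        for run in _runs([(r, c) for r in range(rows)], blocks, min_len):
            num = starts[run[0]]
            slots.append(Slot(f"{num}D", DOWN, run[0], len(run), "", tuple(run)))
    slots.sort(key=lambda s: (s.start, s.direction))
    if clue_texts is not None:
        have = {s.id for s in slots}
        want = set(clue_texts)
        if have != want:
            missing = sorted(have - want)
            extra = sorted(want - have)
            raise PuzzleError(f"clue mismatch: missing {missing}, extra {extra}")
        slots = [
            Slot(s.id, s.direction, s.start, s.length, clue_texts[s.id], s.cells)
            for s in slots
        ]
    return slots


@dataclass
class Puzzle:
    """Static puzzle description: geometry, clues, optional solution grid."""

    dims: tuple[int, int]
    blocks: set[tuple[int, int]]
    slots: list[Slot]
    solution: dict[tuple[int, int], str] | None = None
    min_len: int = 3
    id: str = "puzzle"

    @classmethod
    def build(
        cls,
        dims: tuple[int, int],
        blocks: set[tuple[int, int]],
        clue_texts: dict[str, str],
        solution: dict[tuple[int, int], str] | None = None,
        min_len: int = 3,
        id: str = "puzzle",
    ) -> "Puzzle":
        slots = slots_from_grid(dims, blocks, clue_texts, min_len)
        return cls(dims, blocks, slots, solution, min_len, id)

    def slot(self, slot_id: str) -> Slot:
        for s in self.slots:
            if s.id == slot_id:
                return s
        raise KeyError(slot_id)

    def solution_word(self, slot: Slot) -> str:
        if self.solution is None:
            raise PuzzleError("puzzle has no solution grid")
        return "".join(self.solution[c] for c in slot.cells)


@dataclass
class GridState:
    """Mutable fill state of a puzzle in progress.

    ``solved`` maps slot id -> True once all its cells carry letters,
    whether written directly or completed by crossings; ``answer_record``
    remembers the word written into each directly-solved slot.  Letters are
    never erased: the model has no error correction or backtracking.
    """

    puzzle: Puzzle
    letters: dict[tuple[int, int], str] = field(default_factory=dict)
    cursor: tuple[int, int] = (0, 0)
    solved: dict[str, bool] = field(default_factory=dict)
    answer_record: dict[str, str] = field(default_factory=dict)
    crossings: dict[tuple[int, int], list[Slot]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.puzzle.slots:
            self.solved.setdefault(s.id, False)
            for cell in s.cells:
                self.crossings.setdefault(cell, []).append(s)

    def pattern_of(self, slot: Slot) -> str:
        return "".join(self.letters.get(c, UNKNOWN) for c in slot.cells)

    def unsolved_ids(self) -> list[str]:
        return [s.id for s in self.puzzle.slots if not self.solved[s.id]]

    def prefilled_count(self, slot: Slot) -> int:
        return sum(1 for c in slot.cells if c in self.letters)

    def manhattan_distance(self, slot: Slot) -> int:
        return abs(self.cursor[0] - slot.start[0]) + abs(self.cursor[1] - slot.start[1])

    def write_answer(self, slot: Slot, word: str) -> int:
        """Write ``word`` into ``slot``; return the number of newly set cells.

        The word must match the current pattern at every known cell —
        candidates are pattern-checked upstream, so a conflict here is a
        programming error and raises.  Crossing slots that become fully
        lettered are marked filled ("completed by crossings").  The cursor
        comes to rest on the slot's last cell.
        """
        if len(word) != slot.length:
            raise PuzzleError(f"word {word!r} does not fit slot {slot.id}")
        for cell, ch in zip(slot.cells, word):
            have = self.letters.get(cell)
            if have is not None and have != ch:
                raise PuzzleError(
                    f"conflict at {cell}: {have!r} already written, {ch!r} proposed"
                )
        newly = 0
        touched: dict[str, Slot] = {}
        for cell, ch in zip(slot.cells, word):
            if cell not in self.letters:
                self.letters[cell] = ch
                newly += 1
            for other in self.crossings[cell]:
                touched[other.id] = other
        self.solved[slot.id] = True
        self.answer_record[slot.id] = word
        for sid, other in touched.items():
            if all(c in self.letters for c in other.cells):
                self.solved[sid] = True
        self.cursor = slot.cells[-1]
        return newly


# ---------------------------------------------------------------------------
# plain-text dialect


def puzzle_to_text(puzzle: Puzzle, state: GridState | None = None) -> str:
    rows, cols = puzzle.dims
    letters = state.letters if state is not None else {}
    lines = []
    for r in range(rows):
        lines.append(
            "".join(
                "#" if (r, c) in puzzle.blocks else letters.get((r, c), ".")
                for c in range(cols)
            )
        )
    lines.append("")
    for s in puzzle.slots:
        lines.append(f"{s.id}\t{s.clue_text}")
    if puzzle.solution is not None:
        lines.append("")
        for r in range(rows):
            lines.append(
                "".join(
                    "#" if (r, c) in puzzle.blocks else puzzle.solution[(r, c)]
                    for c in range(cols)
                )
            )
    return "\n".join(lines) + "\n"


def puzzle_from_text(text: str, min_len: int = 3, id: str = "puzzle") -> Puzzle:
    blocks_section, *rest = [b for b in text.split("\n\n")]
    grid_rows = [r for r in blocks_section.splitlines() if r.strip()]
    rows, cols = len(grid_rows), len(grid_rows[0])
    if any(len(r) != cols for r in grid_rows):
        raise PuzzleError("ragged grid rows")
    blocks = {
        (r, c) for r in range(rows) for c in range(cols) if grid_rows[r][c] == "#"
    }
    clue_texts: dict[str, str] = {}
    solution = None
    for section in rest:
        lines = [ln for ln in section.splitlines() if ln.strip()]
        if not lines:
            continue
        if "\t" in lines[0]:
            for ln in lines:
                label, clue = ln.split("\t", 1)
                clue_texts[label.strip()] = clue
        else:
            if len(lines) != rows or any(len(ln) != cols for ln in lines):
                raise PuzzleError("solution grid dims mismatch")
            solution = {
                (r, c): lines[r][c]
                for r in range(rows)
                for c in range(cols)
                if (r, c) not in blocks
            }
    return Puzzle.build((rows, cols), blocks, clue_texts, solution, min_len, id)


def save_text(puzzle: Puzzle, path: str | Path, state: GridState | None = None) -> None:
    Path(path).write_text(puzzle_to_text(puzzle, state), encoding="utf-8")


def load_text(path: str | Path, min_len: int = 3) -> Puzzle:
    return puzzle_from_text(
        Path(path).read_text(encoding="utf-8"), min_len, Path(path).stem
    )


def read_clue_list(path: str | Path) -> dict[str, str]:
    """Read a bare ``LABEL<TAB>clue`` list (one record per line, '#' comments).

    This is the clue-section dialect on its own, used for transcribed
    published clue lists that arrive without a grid.
    """
    clues: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" not in line:
            raise PuzzleError(f"line {lineno}: expected LABEL<TAB>clue, got {line!r}")
        label, clue = line.split("\t", 1)
        label = label.strip()
        if not label or label in clues:
            raise PuzzleError(f"line {lineno}: bad or duplicate label {label!r}")
        clues[label] = clue.strip()
    return clues


# ---------------------------------------------------------------------------
# ipuz JSON (crossword kind)


def puzzle_to_ipuz(puzzle: Puzzle, state: GridState | None = None) -> dict:
    rows, cols = puzzle.dims
    starts = numbered_starts(puzzle.dims, puzzle.blocks, puzzle.min_len)
    cells: list[list[object]] = []
    for r in range(rows):
        row: list[object] = []
        for c in range(cols):
            if (r, c) in puzzle.blocks:
                row.append("#")
            else:
                row.append(starts.get((r, c), 0))
        cells.append(row)
    clues = {"Across": [], "Down": []}
    for s in sorted(puzzle.slots, key=lambda s: int(s.id[:-1])):
        num = int(s.id[:-1])
        key = "Across" if s.direction == ACROSS else "Down"
        clues[key].append([num, s.clue_text])
    out = {
        "version": "http://ipuz.org/v2",
        "kind": ["http://ipuz.org/crossword#1"],
        "dimensions": {"width": cols, "height": rows},
        "puzzle": cells,
        "clues": clues,
    }
    if puzzle.solution is not None:
        out["solution"] = [
            [
                "#" if (r, c) in puzzle.blocks else puzzle.solution[(r, c)]
                for c in range(cols)
            ]
            for r in range(rows)
        ]
    if state is not None:
        out["saved"] = [
            [
                "#" if (r, c) in puzzle.blocks else state.letters.get((r, c), 0)
                for c in range(cols)
            ]
            for r in range(rows)
        ]
    return out


def puzzle_from_ipuz(doc: dict, min_len: int = 3, id: str = "puzzle") -> Puzzle:
    if not any("crossword" in k for k in doc.get("kind", [])):
        raise PuzzleError("not an ipuz crossword")
    rows = doc["dimensions"]["height"]
    cols = doc["dimensions"]["width"]
    grid = doc["puzzle"]
    blocks = {
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if grid[r][c] == "#" or grid[r][c] is None
    }
    dims = (rows, cols)
    starts = numbered_starts(dims, blocks, min_len)
    bare = slots_from_grid(dims, blocks, None, min_len)
    clue_texts: dict[str, str] = {s.id: "" for s in bare}
    for key, suffix in (("Across", "A"), ("Down", "D")):
        for entry in doc.get("clues", {}).get(key, []):
            if isinstance(entry, dict):
                num, clue = entry["number"], entry["clue"]
            else:
                num, clue = entry
            clue_texts[f"{num}{suffix}"] = clue
    solution = None
    if "solution" in doc:
        sol = doc["solution"]
        solution = {
            (r, c): sol[r][c]
            for r in range(rows)
            for c in range(cols)
            if (r, c) not in blocks
        }
    _ = starts
    return Puzzle.build(dims, blocks, clue_texts, solution, min_len, id)


def save_ipuz(puzzle: Puzzle, path: str | Path, state: GridState | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(puzzle_to_ipuz(puzzle, state), fh, indent=1)


def load_ipuz(path: str | Path, min_len: int = 3) -> Puzzle:
    with open(path, encoding="utf-8") as fh:
        return puzzle_from_ipuz(json.load(fh), min_len, Path(path).stem)
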