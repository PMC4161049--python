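"""Synthetic lexica, clue-answer corpora, and solvable toy puzzles.

The solver's memory model cares only about co-occurrence structure, not
about English, so clue tokens are synthetic symbols (``w0042x1``-style) and
answers are random words over a small alphabet.  The corpus mimics the
collision structure of real clue-answer databases with three record bands:
unique diagnostic clues; per-answer signature clues that semantic neighbors
occasionally borrow; and global stock clues ("Long time"-style strings)
shared across many answers of different word lengths with skewed usage
counts, so that a stock probe activates its answer only weakly while
same-length competitors stay rare.  ``ambiguity`` scales every sharing
channel: at 0 each clue token is unique to its answer; at the battery
default (0.2) the bands are at full strength.

Puzzles are produced by backtracking fill: lexicon words are placed into
every slot consistently at crossings, so every generated puzzle is solvable
by construction and ships with its solution grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grid import Puzzle, PuzzleError, Slot, slots_from_grid
from .knowledge import ClueAnswerRecord

#: letters common in crossword fill; 12 symbols keep crossings collision-rich
DEFAULT_ALPHABET = "ADEGILNORSTU"

#: symmetric American-style 7x7 mini pattern: slots of length 3 and 7
BATTERY_BLOCKS_7 = frozenset(
    {
        (0, 3), (1, 3),
        (3, 0), (3, 1), (3, 5), (3, 6),
        (5, 3), (6, 3),
    }
)


class SynthError(ValueError):
    """Infeasible generator specification or unfillable grid."""


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for one synthetic world: lexicon, corpus, and grid shape."""

    lexicon_size: int = 2400
    word_len_range: tuple[int, int] = (3, 7)
    alphabet: str = DEFAULT_ALPHABET
    clues_per_answer: int = 12
    ambiguity: float = 0.2
    dims: tuple[int, int] = (7, 7)
    blocks: frozenset[tuple[int, int]] = BATTERY_BLOCKS_7
    min_slot_len: int = 3
    seed: int = 0
    #: answers per semantic neighborhood; confusable answers share clue
    #: tokens and whole clue strings the way stock clues recur against
    #: many answers in real databases.  Neighborhoods mix word lengths:
    #: a misleading shared clue usually points at an answer that does not
    #: even fit the slot, which costs retrieval draws rather than errors.
    cluster_size: int = 6
    #: probability a record is a unique fully-diagnostic clue; the rest
    #: reuse neighborhood signature clues verbatim (stock-clue collisions)
    diagnostic_rate: float = 0.2
    #: among signature reuses, probability of borrowing a neighbor's
    #: signature instead of the answer's own (the misleading-clue tail)
    borrow_rate: float = 0.08
    #: probability a non-shared token of a fresh clue comes from the cluster
    #: pool rather than the answer's private pool
    cluster_share: float = 0.5
    #: number of global stock clue strings ("Long time"-style), each shared
    #: by answers spread across word lengths with varied usage counts
    stock_pool_size: int = 2000
    tokens_per_answer: int = 4
    tokens_per_cluster: int = 6
    shared_pool_size: int = 40

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambiguity <= 1.0:
            raise SynthError("ambiguity must lie in [0, 1]")
        if self.word_len_range[0] < 1 or self.word_len_range[0] > self.word_len_range[1]:
            raise SynthError("invalid word length range")
        if len(set(self.alphabet)) < 2:
            raise SynthError("alphabet too small")


def _length_allocation(spec: SynthSpec) -> dict[int, int]:
    """Split the lexicon across lengths, capped at 80% of distinct strings."""
    lo, hi = spec.word_len_range
    lengths = list(range(lo, hi + 1))
    caps = {L: int(0.8 * len(spec.alphabet) ** L) for L in lengths}
    if sum(caps.values()) < spec.lexicon_size:
        raise SynthError(
            f"alphabet of {len(spec.alphabet)} cannot yield "
            f"{spec.lexicon_size} distinct words in lengths {lo}-{hi}"
        )
    alloc = {L: 0 for L in lengths}
    remaining = spec.lexicon_size
    while remaining > 0:
        # favor short lengths (crossword lexica are short-word heavy)
        open_lengths = [L for L in lengths if alloc[L] < caps[L]]
        share = max(1, remaining // len(open_lengths))
        for L in open_lengths:
            take = min(share, caps[L] - alloc[L], remaining)
            alloc[L] += take
            remaining -= take
            if remaining == 0:
                break
    return alloc


def generate_lexicon(spec: SynthSpec, rng: np.random.Generator) -> list[str]:
    """Distinct random words over the spec's alphabet, spread across lengths."""
    alloc = _length_allocation(spec)
    letters = list(spec.alphabet)
    lexicon: list[str] = []
    seen: set[str] = set()
    for L, want in sorted(alloc.items()):
        guard = 0
        while sum(1 for w in lexicon if len(w) == L) < want:
            word = "".join(rng.choice(letters, size=L))
            if word not in seen:
                seen.add(word)
                lexicon.append(word)
            guard += 1
            if guard > 100_000:  # pragma: no cover - spec caps make this unreachable
                raise SynthError(f"cannot draw {want} distinct words of length {L}")
    return lexicon


def generate_corpus(
    spec: SynthSpec, rng: np.random.Generator | None = None
) -> tuple[list[str], list[ClueAnswerRecord]]:
    """Generate (lexicon, clue-answer records) for one synthetic world.

    Every answer receives ``clues_per_answer`` clues of 1-4 tokens spread
    over the diagnostic / signature / stock bands; all sharing channels
    scale with ``ambiguity`` so that ambiguity=0 degenerates to fully
    diagnostic clues (every token unique to its answer).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    # sharing channels at full strength at the battery default of 0.2
    sharing = min(1.0, spec.ambiguity / 0.2)
    lexicon = generate_lexicon(spec, rng)
    shared = [f"s{j:03d}" for j in range(spec.shared_pool_size)]
    # mixed-length neighborhoods: chunk a shuffle of the whole lexicon
    order = rng.permutation(len(lexicon))
    cluster_of = {int(i): k // spec.cluster_size for k, i in enumerate(order)}
    n_clusters = -(-len(lexicon) // spec.cluster_size)
    cluster_pools = [
        [f"c{k:03d}x{t}" for t in range(spec.tokens_per_cluster)]
        for k in range(n_clusters)
    ]

    def tokens_from(pools: list[list[str]], weights: list[float]) -> str:
        n_tokens = int(rng.integers(2, 5))
        out = []
        for _ in range(n_tokens):
            u = rng.random()
            acc = 0.0
            for pool, wt in zip(pools, weights):
                acc += wt
                if u < acc:
                    out.append(pool[int(rng.integers(len(pool)))])
                    break
        return " ".join(out)

    # each answer owns one "signature" clue string, reused verbatim across
    # its records the way stock clues recur in real databases; neighbors
    # occasionally borrow it, producing genuinely misleading probes
    amb = spec.ambiguity
    members: dict[int, list[int]] = {}
    for i, k in cluster_of.items():
        members.setdefault(k, []).append(i)
    signature = {
        i: tokens_from(
            [shared, cluster_pools[cluster_of[i]], [f"w{i:04d}x{k}" for k in range(spec.tokens_per_answer)]],
            [amb, (1.0 - amb) * sharing, (1.0 - amb) * (1.0 - sharing)],
        )
        for i in range(len(lexicon))
    }
    # cross-length stock clues ("Long time" -> ERA/EPOCH/PERIOD): each stock
    # string is shared by answers spread over word lengths with varied usage
    # counts, so the correct answer holds only a small share of a stock
    # probe's activation while same-length competitors stay rare
    by_length: dict[int, list[int]] = {}
    for i, w in enumerate(lexicon):
        by_length.setdefault(len(w), []).append(i)
    stock_of: dict[int, list[str]] = {i: [] for i in range(len(lexicon))}
    n_stock = round(spec.stock_pool_size * sharing)
    for _ in range(n_stock):
        clue = tokens_from([shared], [1.0])
        for L, idxs in by_length.items():
            n_users = int(rng.random() < 0.95)
            for _ in range(n_users):
                user = idxs[int(rng.integers(len(idxs)))]
                copies = int(rng.choice([1, 8, 16], p=[0.4, 0.3, 0.3]))
                stock_of[user].extend([clue] * copies)

    records: list[ClueAnswerRecord] = []
    for i, answer in enumerate(lexicon):
        own = [f"w{i:04d}x{k}" for k in range(spec.tokens_per_answer)]
        k = cluster_of[i]
        siblings = [j for j in members[k] if j != i]
        pool_i = stock_of[i]
        stock_i = [pool_i[j] for j in rng.permutation(len(pool_i))]
        stock_i = stock_i[: (3 * spec.clues_per_answer) // 4]
        for clue in stock_i:
            records.append(ClueAnswerRecord(clue, answer))
        for c in range(spec.clues_per_answer - len(stock_i)):
            if rng.random() < spec.diagnostic_rate or not siblings:
                clue = tokens_from(
                    [shared, cluster_pools[k], own],
                    [amb, (1 - amb) * spec.cluster_share * sharing,
                     (1 - amb) * (1 - spec.cluster_share * sharing)],
                )
            elif rng.random() < spec.borrow_rate * sharing:
                clue = signature[siblings[int(rng.integers(len(siblings)))]]
            else:
                clue = signature[i]
            records.append(ClueAnswerRecord(clue, answer))
    return lexicon, records


# ---------------------------------------------------------------------------
# backtracking grid fill


def _fill_slots(
    slots: list[Slot],
    lexicon: list[str],
    rng: np.random.Generator,
    node_budget: int,
) -> dict[str, str] | None:
    by_length: dict[int, list[str]] = {}
    for w in lexicon:
        by_length.setdefault(len(w), []).append(w)
    for L in by_length:
        by_length[L] = list(rng.permutation(by_length[L]))
    for s in slots:
        if s.length not in by_length:
            raise SynthError(f"no lexicon words of length {s.length} for slot {s.id}")

    letters: dict[tuple[int, int], str] = {}
    assignment: dict[str, str] = {}
    used: set[str] = set()
    nodes = 0
    first_stuck: list[str] = []

    def candidates(slot: Slot) -> list[str]:
        pat = [letters.get(c) for c in slot.cells]
        return [
            w
            for w in by_length[slot.length]
            if w not in used
            and all(p is None or p == ch for ch, p in zip(w, pat))
        ]

    def solve() -> bool:
        nonlocal nodes
        open_slots = [s for s in slots if s.id not in assignment]
        if not open_slots:
            return True
        cand_lists = [(s, candidates(s)) for s in open_slots]
        slot, cands = min(cand_lists, key=lambda t: len(t[1]))
        if not cands:
            if not first_stuck:
                first_stuck.append(slot.id)
            return False
        for word in cands:
            nodes += 1
            if nodes > node_budget:
                return False
            placed = []
            for cell, ch in zip(slot.cells, word):
                if cell not in letters:
                    letters[cell] = ch
                    placed.append(cell)
            assignment[slot.id] = word
            used.add(word)
            if solve():
                return True
            for cell in placed:
                del letters[cell]
            del assignment[slot.id]
            used.discard(word)
        return False

    if solve():
        return assignment
    if first_stuck:
        raise SynthError(f"no consistent fill: stuck at slot {first_stuck[0]}")
    return None


def generate_puzzle(
    lexicon: list[str],
    dims: tuple[int, int],
    blocks: set[tuple[int, int]] | frozenset[tuple[int, int]],
    rng: np.random.Generator,
    records: list[ClueAnswerRecord] | None = None,
    min_len: int = 2,
    node_budget: int = 200_000,
    id: str = "synthetic",
) -> Puzzle:
    """Backtracking-fill a grid from the lexicon; attach one clue per slot.

    Returns a :class:`Puzzle` carrying both the clue texts and the solution
    grid.  Raises :class:`SynthError` naming the first unfillable slot when
    no consistent fill exists within the node budget.
    """
    bare = slots_from_grid(dims, set(blocks), None, min_len)
    assignment = _fill_slots(bare, lexicon, rng, node_budget)
    if assignment is None:
        raise SynthError(f"fill search exhausted its {node_budget}-node budget")
    # a slot's clue is drawn uniformly over the answer's *distinct* clue
    # strings, the way a constructor picks one known clue for a fill word
    clues_by_answer: dict[str, list[str]] = {}
    for rec in records or []:
        pool = clues_by_answer.setdefault(rec.answer, [])
        if rec.clue_text not in pool:
            pool.append(rec.clue_text)
    clue_texts: dict[str, str] = {}
    for s in bare:
        word = assignment[s.id]
        pool = clues_by_answer.get(word)
        if pool:
            clue_texts[s.id] = pool[int(rng.integers(len(pool)))]
        else:
            clue_texts[s.id] = f"clue for {s.id}"
    solution: dict[tuple[int, int], str] = {}
    for s in bare:
        for cell, ch in zip(s.cells, assignment[s.id]):
            solution[cell] = ch
    # cells covered by no slot (short orphan runs) still need letters
    rows, cols = dims
    for r in range(rows):
        for c in range(cols):
            if (r, c) not in blocks and (r, c) not in solution:
                solution[(r, c)] = spec_letter(lexicon, rng)
    return Puzzle.build(dims, set(blocks), clue_texts, solution, min_len, id)


def spec_letter(lexicon: list[str], rng: np.random.Generator) -> str:
    alphabet = sorted({ch for w in lexicon for ch in w})
    return alphabet[int(rng.integers(len(alphabet)))]


# ---------------------------------------------------------------------------
# the reproducible battery


@dataclass(frozen=True)
class BatterySpec:
    """The fixed synthetic study conditions: 20 American-style 7x7 minis.

    ``time_limit`` is the simulated session limit for within-limit scoring,
    scaled from the original 25-min / 78-slot session to this battery's 22
    slots at the same seconds-per-slot budget (1500/78 * 22 ~= 423 s).
    """

    n_puzzles: int = 20
    replicates: int = 10
    time_limit: float = 423.0
    synth: SynthSpec = field(default_factory=SynthSpec)
    fill_attempts: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BatterySpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        synth = data.pop("synth", {})
        if "blocks" in synth:
            synth["blocks"] = frozenset(tuple(b) for b in synth["blocks"])
        if "dims" in synth:
            synth["dims"] = tuple(synth["dims"])
        if "word_len_range" in synth:
            synth["word_len_range"] = tuple(synth["word_len_range"])
        return cls(synth=SynthSpec(**synth), **data)


def generate_battery(
    master_seed: int, battery: BatterySpec | None = None
) -> tuple[list[str], list[ClueAnswerRecord], list[Puzzle]]:
    """One lexicon + corpus and ``n_puzzles`` filled puzzles, reproducibly.

    Puzzle k is filled with the rng spawned from (master_seed, "puzzle", k,
    attempt); unfillable draws are retried with the next attempt stream, so
    the battery is a pure function of the master seed and the spec.
    """
    if battery is None:
        battery = BatterySpec()
    spec = battery.synth
    corpus_rng = np.random.default_rng(
        np.random.SeedSequence((master_seed, 0xC0, spec.seed))
    )
    lexicon, records = generate_corpus(spec, corpus_rng)
    puzzles: list[Puzzle] = []
    for k in range(battery.n_puzzles):
        puzzle = None
        for attempt in range(battery.fill_attempts):
            rng = np.random.default_rng(
                np.random.SeedSequence((master_seed, 0xF1, k, attempt))
            )
            try:
                puzzle = generate_puzzle(
                    lexicon,
                    spec.dims,
                    spec.blocks,
                    rng,
                    records,
                    spec.min_slot_len,
                    id=f"battery-{k:02d}",
                )
                break
            except SynthError:
                continue
        if puzzle is None:
            raise SynthError(f"battery puzzle {k} unfillable after retries")
        puzzles.append(puzzle)
    return lexicon, records, puzzles
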