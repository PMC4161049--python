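# crossmind

A simulator of how people — experts and novices — solve crossword puzzles
by memory retrieval rather than constraint search. The solver is a
recognition-primed decision agent: cues activate candidate answers in an
associative memory, a single candidate is evaluated against the grid, and
the agent either commits or moves on. There is no backtracking, no erasure,
and no error correction, because skilled human play largely does without
them.

It is a research tool for computational cognitive modeling: it reproduces,
on fully synthetic material, the qualitative expertise phenomena of
tournament crossword play — what retrieval fluency, memory speed, and
gridfill strategy each contribute.

## The model

**Memory.** Two sparse associative stores are learned from a corpus of
clue–answer pairs. The semantic store links clue features (words, adjacent
word bigrams) to answers; the orthographic store links answer-form features
(a length marker, positional letters and bigrams) to answers. A probe with
feature multiset *u* = {*u*₁…*u*ₙ} scores every candidate answer *Aᵢ* by
per-feature conditionals and a smoothed geometric mean,

    Pr(Aᵢ|uⱼ) = count(uⱼ, Aᵢ) / Σᵢ count(uⱼ, Aᵢ)
    B(Aᵢ|u)  = [ Πⱼ (Pr(Aᵢ|uⱼ) + σ) ]^(1/n)
    Pr(Aᵢ|u) = B(Aᵢ|u) / Σᵢ B(Aᵢ|u)

**Retrieval.** Each clue is probed through both routes independently:
semantic (from the clue text) and orthographic (from the partial grid
pattern, when at least one letter is known). Candidates are sampled without
replacement in proportion to their activation, up to a search-set cap of
10 draws per route. A semantically activated concept must also be
*recovered* as a word form, with probability

    Pr(recovery) = 1 − exp(−Pr(Aᵢ|u) · recovery)

where `recovery` is the fluency parameter — the model's main expertise
knob (15 for fluent, 0.5 for disfluent solvers). The two routes'
survivors are arbitrated by semantic activation, with a confidence gate at
1/λ (λ = 100).

**Agent and clock.** The agent loops over selection → retrieval →
updating. Clue selection is either uniform over unsolved clues (the novice
"random" strategy) or a Luce choice over discounted-reward weights
(the expert "optimizing" strategy),

    wᵢ = (1−α)^dᵢ · (wfᵢ/attᵢ + s₁) + s₂

which prefers nearby, partially-filled, not-yet-attempted clues. Each solve
costs simulated time with keystroke-level operators:

    T = d·t_moving + t_reading + n·t_retrieval + wl·t_typing

(0.14 s per cell moved, 1.0 s reading, 0.25 s or 3.0 s per retrieval draw,
0.28 s per letter typed). Crossing strategy, fluency, and retrieval speed
factorially yields eight models spanning expert to struggling-novice play.

## A worked example

```bash
python examples/01_build_memory.py
```

prints

```
semantic activation for 'feline pet':
  CAT    Pr = 1.0000
  DOG    Pr = 0.0000
  TIGER  Pr = 0.0000
orthographic activation for pattern '?A?':
  CAT    Pr = 0.9572
  DOG    Pr = 0.0214
  OWL    Pr = 0.0214
recovery of the top answer: expert 1.000, novice 0.393
```

`CAT` dominates the semantic probe because both clue words (and their
bigram) co-occurred with it, while `TIGER` and `DOG` each share only one
word; the orthographic probe for `?A?` activates every length-3 word but
concentrates on the one with `A` in the middle. The recovery line is the
expertise knob at work: with the same memory and the same activation, the
fluent solver produces the word essentially always, the disfluent one on
about 39% of attempts.

`examples/02_solve_puzzle.py` runs the full agent on a synthetic 7×7 and
prints the timed attempt log; `examples/03_expert_novice_factorial.py`
runs a reduced strategy × fluency × speed factorial; and
`examples/04_route_and_strategy_analysis.py` shows the expert signatures:
early solves with more prefilled letters under the optimizing strategy, and
the semantic route dominating with orthographic solutions appearing as the
grid fills.

There is also a small CLI for shell pipelines:

```bash
crossmind synth --out battery/ --seed 1
crossmind build-kb battery/corpus.tsv --out kb/
crossmind solve battery/battery-00.txt --stores kb/ --seed 1 --out run/
crossmind simulate --out sim/ --seed 1
```

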