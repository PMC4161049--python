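# Methods

## Model

The solver treats crossword play as recognition-primed decision making:
a clue (and, later, the partial letter pattern) probes an associative
memory; candidate answers come to mind in proportion to their cue-outcome
association strength; the first candidate that survives evaluation is
committed to the grid. The agent holds no global constraint network and
never reconsiders a committed answer — no erasure, no backtracking, no
error detection. Expertise enters through three dials: retrieval fluency,
memory access speed, and gridfill strategy.

### Associative memory

Two stores are built from a corpus of clue–answer records. Association
strength is the raw co-occurrence count by default — the simplest map that
is monotone in exposure frequency. An optional saturating mode transforms
each count c to 1−(1−θ)^c, realizing stimulus-sampling learning in which
strength grows with exposure and asymptotes; θ=1 degenerates to
presence/absence. The exact learning equation behind the original
knowledge base is not published, so both modes are offered and the counts
mode is the default (the two agree in rank order, which is all retrieval
uses).

Semantic features are lowercased word tokens plus adjacent word bigrams,
with stopwords retained (they carry signal in clues) and runs of
underscores mapped to a blank placeholder token (fill-in-the-blank clues
are strong cues). Orthographic features are position-coded: a length
marker, one feature per known letter-position, and one per adjacent known
letter pair. Position coding is what makes a pattern probe like `C?T`
discriminative; the length marker enforces the length constraint
throughout.

### Retrieval

A probe combines per-feature conditionals by a smoothed geometric mean and
normalizes over the candidate universe (answers with positive strength on
at least one probe feature; length-filtered for orthographic probes). The
smoothing constant σ is added to **each factor** before multiplying:
per-factor smoothing keeps a single unseen feature from annihilating
multi-feature evidence, which the geometric mean could otherwise never
recover. σ is 10⁻⁸ for the semantic store and 10⁻³ for the orthographic
store.

Candidate generation is stochastic: sampling without replacement in
proportion to normalized activation, capped at a search set of 10 draws
per route per attempt. Sampling (rather than deterministic best-first) is
required for retrieval count n to vary across trials, and it is n that
carries retrieval time into the clock. A semantically drawn candidate must
pass a recovery Bernoulli trial with rate 1−exp(−p·recovery) before it can
be produced; a failed recovery still consumes a draw (it is a retrieval
event in time). The orthographic route faces no recovery gate — word-form
completion from letters is treated as automatic — but its survivor is
scored by its semantic probability under the clue, the common currency of
arbitration. The orthographic route abstains entirely when the pattern
carries no letters (length alone is not an orthographic cue).

Arbitration: same answer from both routes → credited to "both";
different answers → larger semantic score wins, ties to the semantic
route; the winner is rejected when its semantic score falls below 1/λ
(λ=100), a confidence gate carried from prior work whose operational
definition is not restated there — the gate semantics here are a declared
assumption, isolated in one function.

### The agent and its clock

Selection is uniform over unsolved clues (random strategy) or a Luce
choice over weights w = (1−α)^d·(wf/att + s₁) + s₂ with α=0.02, s₁=10⁻³,
s₂=10⁻⁵ (optimizing strategy). Luce sampling rather than argmax is the
default: the attempt counter in the denominator only breaks
repeat-selection loops under sampling. An argmax toggle exists for
sensitivity analysis.

A solved clue costs d·t_moving + t_reading + n·t_retrieval + wl·t_typing
with t_moving=0.14 s/cell, t_reading=1.0 s, t_typing=0.28 s/keystroke, and
t_retrieval 0.25 s (fast) or 3.0 s (slow); n is the winning route's draw
count (for "both", the semantic route's); wl counts only newly typed
letters — crossing-filled cells are not retyped. A failed attempt charges
the walk to the clue, the reading, and every draw both routes consumed;
the cursor comes to rest on the clue's first cell (last cell after a
solve). Failure timing is an extension — the original specifies timing
only for solves — and is the minimal consistent one.

Termination: completion; a simulated-time limit; three consecutive full
passes over the live clues with no solve; or exhaustion, where every
unsolved clue has been retired. A clue retires after max_attempts=6 failed
attempts. Retirement realizes the "avoid revisiting failed clues"
counters: without it, unlimited revisits let every configuration grind to
completion and fluency loses its effect on the asymptote, which
contradicts the phenomenon the model exists to show. Six attempts is about
twice what a fluent model needs on the hardest solvable clues.

The trace is a pure function of (puzzle, stores, config, seed): one
injected generator drives selection, sampling, and recovery trials.

## Synthetic data

The generator replaces an external clue database with a synthetic world
whose *co-occurrence structure* — not its English — carries the load.
Clue tokens are opaque symbols; answers are random words over a 12-letter
alphabet.

What is emulated, and why it matters to the model:

- **Graded diagnosticity.** In a large clue database the correct answer
  typically holds only a modest share of a clue's total activation.
  Because puzzle clues are verbatim corpus records, graded difficulty can
  only come from clue-string collisions, so the corpus has three record
  bands: unique *diagnostic* clues; per-answer *signature* clues that
  semantic neighbors occasionally borrow; and *global stock* clues
  ("Long time"-style strings) shared by answers across word lengths with
  strongly skewed usage counts. A minor user of a stock clue holds a few
  percent of its activation — hard for a disfluent solver, routine for a
  fluent one.
- **Cross-length collisions.** Stock clues take at most one user per word
  length, so a misleading probe usually points at answers that do not even
  fit the slot: it costs retrieval draws, not errors. This mirrors how the
  length constraint absorbs most clue ambiguity in real play and keeps
  fluent models accurate. Same-length confusables (the ERA/EON kind) enter
  only through the small borrowed-signature band, the main error channel.
- **Solvability by construction.** Puzzles are filled by backtracking over
  slots with lexicon words (most-constrained slot first, node budget,
  distinct words per puzzle); each slot's clue is drawn uniformly from its
  answer's distinct corpus clue strings, the way a constructor picks one
  known clue. Every generated puzzle ships with its solution.

All sharing channels scale with the `ambiguity` parameter; at 0 every clue
token is unique to its answer and every probe is perfectly diagnostic.

What is **not** emulated: natural-language semantics (synonymy,
polysemy, world knowledge), theme or wordplay conventions, letter
frequency structure, and the heavy-tailed answer frequency of real fill.
Passing tests therefore show that the *mechanisms* — dual-route retrieval,
recovery-limited production, strategy-driven crossing use — produce the
expertise phenomena under database-like collision statistics; they do not
validate performance on any real clue corpus.

### The battery

The fixed conditions (configs/battery.yaml, regenerated from a master
seed): 20 puzzles on a symmetric 7×7 block pattern (22 slots of lengths 3
and 7, minimum slot length 3), a 2400-word lexicon, 12 clues per answer,
ambiguity 0.2, clusters of 6 with borrow rate 0.08, 2000 stock strings.
The composition was calibrated in pilot runs against published anchors for
this class of model — fluent configurations solving most clues given
time, disfluent ones asymptoting near 75% completion, expert-like accuracy
around 0.94 — then frozen.

Within-limit scoring uses a session limit scaled with workload: the
original 25-minute limit over 78 slots is ≈19.2 s per slot, which maps to
423 s for a 22-slot puzzle. The full-size limit on a mini puzzle would not
bind any fluent model and the fast/slow contrast would vanish;
`ModelConfig.time_limit` keeps the canonical 1500 s default, and the
scaling is a property of the battery experiment alone. Factorial cells run
with the limit lifted (termination by completion, stall, or retirement)
and both the within-limit and lifted scores are read off the same trace;
cell seeds derive from (master seed, model, puzzle index, replicate), so
cells are independent but reproducible.

## Numerical choices

- Route combination runs in log space; strengths are exponentiated without
  rescaling (products of per-factor terms ≥ σ = 10⁻⁸ cannot underflow at
  these probe sizes), and normalization shifts by the maximum first.
- Distribution entries sort by probability descending with lexicographic
  tie-break, so rank order is deterministic.
- Empty feature sets, empty candidate universes, and route abstention are
  failure *values*, never exceptions; misconfiguration raises at
  construction with the offending field named.
- Grid coordinates are 0-based row-major; the cursor convention (rest on
  the last solved cell, movement measured Manhattan) is declared, not
  inferred — the original does not state where the cursor sits between
  solves.
- Conflicting writes are hard errors: candidates are pattern-checked
  before writing, so a conflict is a programming error, not a recoverable
  state.

## Known limitations

- The solver cannot recover from a wrong committed answer; error cascades
  through crossings are therefore part of the modeled behavior, not a bug.
- The retirement cap and the failure-time charge are extensions beyond
  what the original specifies; both are documented above and isolated in
  the config.
- The λ gate and search-set semantics follow declared assumptions where
  the original defers to prior work.
- Human-subject analyses (response-time regressions, tournament
  correlations) are out of scope: no human data ships with the package.
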