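"""Generate a small synthetic puzzle and watch the agent solve it.

Run: python examples/02_solve_puzzle.py
"""

from crossmind import BatterySpec, ModelConfig, generate_battery, ingest_corpus, run_solver
from crossmind.grid import puzzle_to_text
from crossmind.metrics import score_against_solution

battery = BatterySpec(n_puzzles=1)
_, records, (puzzle,) = generate_battery(4, battery)
sem, orth = ingest_corpus(records)
print(puzzle_to_text(puzzle).split("\n\n")[0])   # the empty grid

config = ModelConfig(strategy="optimizing", recovery=15.0, retrieval=0.25,
                     time_limit=float("inf"), seed=11)
trace = run_solver(puzzle, sem, orth, config)

for e in trace.events[:8]:
    print(f"t={e.clock_start:7.2f}s  {e.slot_id:3s} {e.outcome:6s} "
          f"{e.answer or '-':8s} route={e.route:12s} draws={e.n_draws}")
print("...")
completed, correct = score_against_solution(trace, puzzle)
print(f"completed {completed}/{len(puzzle.slots)} slots, {correct} correct, "
      f"clock {trace.clock:.1f}s, termination: {trace.termination}")
# each line is one timed attempt: the agent walks to a clue, reads it,
# samples candidate answers from memory and writes the first that fits;
# the clock charges moving, reading, retrieval draws and typing.
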