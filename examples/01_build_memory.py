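"""Build the dual associative memory from a handful of clue-answer pairs
and probe it through both routes.

Run: python examples/01_build_memory.py
"""

from crossmind import (
    ingest_corpus,
    orthographic_features,
    recovery_probability,
    route_probability,
    semantic_features,
)

corpus = [
    ("feline pet", "CAT"),
    ("canine pet", "DOG"),
    ("feline pet", "CAT"),        # repeats strengthen the association
    ("large striped feline", "TIGER"),
    ("night bird of prey", "OWL"),
]
sem, orth = ingest_corpus(corpus)

# the semantic route: clue words activate candidate answers
dist = route_probability(sem, semantic_features("feline pet"), sigma=1e-8)
print("semantic activation for 'feline pet':")
for answer, prob in zip(dist.answers, dist.probs):
    print(f"  {answer:6s} Pr = {prob:.4f}")

# the orthographic route: a partial grid pattern activates word forms
dist_o = route_probability(orth, orthographic_features("?A?"), sigma=1e-3, length=3)
print("orthographic activation for pattern '?A?':")
for answer, prob in zip(dist_o.answers, dist_o.probs):
    print(f"  {answer:6s} Pr = {prob:.4f}")

# recovery: the probability of actually producing an activated answer,
# the model's expertise knob (fluent experts ~15, novices ~0.5)
p = dist.probs[0]
print(f"recovery of the top answer: expert {recovery_probability(p, 15.0):.3f}, "
      f"novice {recovery_probability(p, 0.5):.3f}")
# 'CAT' dominates the semantic probe because it co-occurred twice with the
# clue words; the pattern probe is restricted to length-3 words with A in
# the middle; the expert recovers the activated answer almost surely while
# the novice does so on fewer than half of the attempts.
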