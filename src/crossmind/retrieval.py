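"""Dual-route memory retrieval and candidate arbitration.

A probe presents a feature multiset u = {u_1..u_n} to one associative
store.  Per-feature conditionals

    Pr(A_i | u_j) = count(u_j, A_i) / feature_total(u_j)

are combined by a smoothed geometric mean,

    B(A_i | u) = [ prod_j (Pr(A_i | u_j) + sigma) ]^(1/n),

and normalized over the candidate universe to give the route's activation
distribution Pr^X(A_i | u).  The smoothing constant is added to each factor
so that a single unseen feature cannot annihilate multi-feature evidence.

The semantic route samples candidates from its distribution and must both
*recover* the lexical form (a Bernoulli trial with rate
1 - exp(-Pr^S * recovery), the model's fluency/expertise knob) and match
the grid pattern.  The orthographic route samples from pattern features and
faces no recovery gate; its survivor is scored by its semantic probability
under the clue, the common currency in which the two routes are arbitrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .knowledge import UNKNOWN, AssociationStore, FeatureSet, orthographic_features

if TYPE_CHECKING:  # pragma: no cover
    from .solver import ModelConfig

SEM_ROUTE = "semantic"
ORTH_ROUTE = "orthographic"
BOTH_ROUTE = "both"


@dataclass(frozen=True)
class RouteDistribution:
    """Activation distribution of one route: answers, strengths B, probs.

    Entries are sorted by probability descending, ties broken
    lexicographically by answer, so the rank order is deterministic.
    """

    route: str
    answers: tuple[str, ...]
    strengths: tuple[float, ...]
    probs: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.answers)

    def prob_of(self, answer: str) -> float:
        try:
            return self.probs[self.answers.index(answer)]
        except ValueError:
            return 0.0


EMPTY_SEM = RouteDistribution(SEM_ROUTE, (), (), ())
EMPTY_ORTH = RouteDistribution(ORTH_ROUTE, (), (), ())


@dataclass(frozen=True)
class Candidate:
    """An arbitrated (or route-level) retrieval product.

    ``semantic_score`` is the answer's normalized semantic probability under
    the clue — the arbitration currency.  ``n_draws`` counts candidates the
    winning route generated before acceptance (the retrieval-time multiplier).
    """

    answer: str
    route: str
    semantic_score: float
    n_draws: int


@dataclass(frozen=True)
class ProbeResult:
    """Outcome of one route probe: a candidate or failure, plus draws consumed."""

    candidate: Optional[Candidate]
    n_draws: int

    @property
    def failed(self) -> bool:
        return self.candidate is None


FAILED_PROBE = ProbeResult(None, 0)


def route_probability(
    store: AssociationStore,
    features: FeatureSet,
    sigma: float,
    length: int | None = None,
) -> RouteDistribution:
    """Probe ``store`` with ``features``; return the normalized distribution.

    The candidate universe is every answer with positive strength on at
    least one probe feature, optionally restricted to words of ``length``
    (the pattern-length constraint for orthographic probes).  An empty
    feature set or empty universe yields an empty distribution: probe
    failure is a value, not an exception.
    """
    if sigma <= 0:
        raise ValueError("smoothing constant must be positive")
    route = store.modality
    if not features:
        return RouteDistribution(route, (), (), ())
    universe = store.candidates(features.features)
    if length is not None:
        universe &= store.by_length.get(length, set())
    if not universe:
        return RouteDistribution(route, (), (), ())
    n = features.n_features
    # log-domain product keeps tiny sigma (1e-8) per-factor products stable
    answers = sorted(universe)
    logB = np.zeros(len(answers))
    for f in features.features:
        row = store.counts.get(f)
        total = store.feature_totals.get(f, 0.0)
        for k, a in enumerate(answers):
            p = row.get(a, 0.0) / total if row is not None and total > 0 else 0.0
            logB[k] += math.log(p + sigma)
    logB /= n
    B = np.exp(logB)
    shifted = np.exp(logB - logB.max())
    probs = shifted / shifted.sum()
    order = sorted(range(len(answers)), key=lambda k: (-probs[k], answers[k]))
    return RouteDistribution(
        route,
        tuple(answers[k] for k in order),
        tuple(float(B[k]) for k in order),
        tuple(float(probs[k]) for k in order),
    )


def recovery_probability(p: float, recovery: float) -> float:
    """Probability of recovering the lexical form of a semantically
    activated concept: 1 - exp(-p * recovery).

    Strictly increasing in both the activation ``p`` and the fluency
    parameter ``recovery``; saturates at 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if recovery < 0:
        raise ValueError("recovery must be non-negative")
    return 1.0 - math.exp(-p * recovery)


def matches_pattern(word: str, pattern: str) -> bool:
    return len(word) == len(pattern) and all(
        q == UNKNOWN or q == ch for ch, q in zip(word, pattern)
    )


def _sample_without_replacement(
    dist: RouteDistribution, cap: int, rng: np.random.Generator
):
    """Yield answers drawn without replacement, proportional to Pr, up to cap."""
    probs = np.asarray(dist.probs, dtype=float)
    alive = np.ones(len(probs), dtype=bool)
    for _ in range(min(cap, len(probs))):
        p = np.where(alive, probs, 0.0)
        s = p.sum()
        if s <= 0:
            return
        idx = int(rng.choice(len(p), p=p / s))
        alive[idx] = False
        yield dist.answers[idx], float(probs[idx])


def probe_semantic(
    clue_features: FeatureSet,
    pattern: str,
    sem_store: AssociationStore,
    config: "ModelConfig",
    rng: np.random.Generator,
    dist: RouteDistribution | None = None,
) -> ProbeResult:
    """Semantic route: sample candidates by activation, gate each through
    recovery, accept the first that fits the pattern.

    A failed recovery still consumes a draw — it is a retrieval event in
    time.  The probe gives up after ``search_set`` draws or when the
    distribution is exhausted.  ``dist`` may carry a precomputed
    distribution for the clue (they depend only on the clue, so the solver
    caches them).
    """
    if dist is None:
        dist = route_probability(sem_store, clue_features, config.smoothing_sem)
    draws = 0
    for answer, p in _sample_without_replacement(dist, config.search_set, rng):
        draws += 1
        if rng.random() >= recovery_probability(p, config.recovery):
            continue
        if matches_pattern(answer, pattern):
            return ProbeResult(Candidate(answer, SEM_ROUTE, p, draws), draws)
    return ProbeResult(None, draws)


def probe_orthographic(
    pattern: str,
    clue_features: FeatureSet,
    sem_store: AssociationStore,
    orth_store: AssociationStore,
    config: "ModelConfig",
    rng: np.random.Generator,
    sem_dist: RouteDistribution | None = None,
    dist: RouteDistribution | None = None,
) -> ProbeResult:
    """Orthographic route: sample word-form candidates cued by the pattern.

    The route abstains when the pattern carries no letters — length alone
    is not an orthographic cue.  Survivors face no recovery gate but are
    scored semantically (their Pr^S under the clue) for arbitration.
    """
    if all(ch == UNKNOWN for ch in pattern):
        return FAILED_PROBE
    if dist is None:
        dist = route_probability(
            orth_store,
            orthographic_features(pattern),
            config.smoothing_orth,
            length=len(pattern),
        )
    if sem_dist is None:
        sem_dist = route_probability(sem_store, clue_features, config.smoothing_sem)
    draws = 0
    for answer, _ in _sample_without_replacement(dist, config.search_set, rng):
        draws += 1
        if matches_pattern(answer, pattern):
            score = sem_dist.prob_of(answer)
            return ProbeResult(Candidate(answer, ORTH_ROUTE, score, draws), draws)
    return ProbeResult(None, draws)


def arbitrate(
    sem: ProbeResult, orth: ProbeResult, likelihood: float
) -> Optional[Candidate]:
    """Pick between the two routes' products by semantic score.

    Same answer from both routes -> route "both"; different answers -> the
    larger semantic score wins (tie goes to the semantic route).  The
    winner must clear the confidence gate semantic_score >= 1/likelihood,
    else the attempt fails.
    """
    s, o = sem.candidate, orth.candidate
    if s is None and o is None:
        return None
    if s is not None and o is not None:
        if s.answer == o.answer:
            winner = Candidate(s.answer, BOTH_ROUTE, s.semantic_score, s.n_draws)
        elif o.semantic_score > s.semantic_score:
            winner = o
        else:
            winner = s
    else:
        winner = s if s is not None else o
    if likelihood > 0 and winner.semantic_score < 1.0 / likelihood:
        return None
    return winner
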