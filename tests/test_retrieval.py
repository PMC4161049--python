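"""Route probabilities, recovery, probes, and arbitration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossmind.knowledge import (
    AssociationStore,
    FeatureSet,
    SEMANTIC,
    orthographic_features,
    semantic_features,
)
from crossmind.retrieval import (
    Candidate,
    FAILED_PROBE,
    ProbeResult,
    arbitrate,
    matches_pattern,
    probe_orthographic,
    probe_semantic,
    recovery_probability,
    route_probability,
)
from crossmind.solver import ModelConfig


def brute_force_distribution(store, features, sigma):
    """Literal nested-loop evaluation of the route equations: per-feature
    conditionals, smoothed geometric mean, normalization over candidates."""
    universe = sorted(store.candidates(features.features))
    n = features.n_features
    B = {}
    for a in universe:
        prod = 1.0
        for f in features.features:
            total = store.feature_totals.get(f, 0.0)
            cond = store.counts.get(f, {}).get(a, 0.0) / total if total > 0 else 0.0
            prod *= cond + sigma
        B[a] = prod ** (1.0 / n)
    Z = sum(B.values())
    return {a: b / Z for a, b in B.items()}


def make_store(pairs):
    store = AssociationStore(SEMANTIC)
    for f, a, c in pairs:
        store.add(f, a, c)
    return store


def test_degenerate_single_answer():
    store = make_store([("f", "X", 2.0)])
    dist = route_probability(store, FeatureSet(SEMANTIC, ("f",)), 1e-8)
    assert dist.answers == ("X",)
    assert dist.probs[0] == pytest.approx(1.0)


def test_single_feature_hand_arithmetic():
    store = make_store([("f", "X", 3.0), ("f", "Y", 1.0)])
    dist = route_probability(store, FeatureSet(SEMANTIC, ("f",)), 1e-12)
    assert dict(zip(dist.answers, dist.probs)) == pytest.approx(
        {"X": 0.75, "Y": 0.25}
    )


def test_empty_probe_is_failure_value():
    store = make_store([("f", "X", 1.0)])
    assert len(route_probability(store, FeatureSet(SEMANTIC, ()), 1e-3)) == 0
    assert len(route_probability(store, FeatureSet(SEMANTIC, ("unseen",)), 1e-3)) == 0


def test_matches_brute_force_oracle(rng):
    """Vectorized route probabilities equal the literal loop to 1e-12."""
    for _ in range(300):
        n_ans = int(rng.integers(2, 9))
        n_feat = int(rng.integers(1, 7))
        answers = [f"A{i}" for i in range(n_ans)]
        feats = [f"f{j}" for j in range(n_feat)]
        store = AssociationStore(SEMANTIC)
        for f in feats:
            for a in answers:
                if rng.random() < 0.6:
                    store.add(f, a, float(rng.integers(1, 6)))
        probe = FeatureSet(SEMANTIC, tuple(feats))
        if not store.candidates(feats):
            continue
        dist = route_probability(store, probe, 0.001)
        oracle = brute_force_distribution(store, probe, 0.001)
        for a, p in zip(dist.answers, dist.probs):
            assert p == pytest.approx(oracle[a], abs=1e-12)


def test_distribution_sorted_and_normalized(rng):
    store = AssociationStore(SEMANTIC)
    for j in range(5):
        for i in range(10):
            if rng.random() < 0.5:
                store.add(f"f{j}", f"A{i}", float(rng.integers(1, 9)))
    dist = route_probability(store, FeatureSet(SEMANTIC, tuple(f"f{j}" for j in range(5))), 1e-3)
    assert sum(dist.probs) == pytest.approx(1.0, abs=1e-9)
    assert list(dist.probs) == sorted(dist.probs, reverse=True)


def test_count_monotonicity():
    """Raising count(f, A) never lowers Pr(A|u) for a probe containing f."""
    base = [("f", "X", 2.0), ("f", "Y", 3.0), ("g", "X", 1.0), ("g", "Y", 1.0)]
    probe = FeatureSet(SEMANTIC, ("f", "g"))
    p_before = dict(zip(*[route_probability(make_store(base), probe, 1e-3).answers,
                          route_probability(make_store(base), probe, 1e-3).probs]))["X"]
    bumped = [("f", "X", 5.0)] + base[1:]
    dist = route_probability(make_store(bumped), probe, 1e-3)
    p_after = dict(zip(dist.answers, dist.probs))["X"]
    assert p_after >= p_before


@pytest.mark.parametrize(
    "p,recovery,expected",
    [(0.0, 15.0, 0.0), (1.0, 0.5, 0.393469), (0.2, 15.0, 0.950213)],
)
def test_recovery_closed_form(p, recovery, expected):
    assert recovery_probability(p, recovery) == pytest.approx(expected, abs=1e-6)


@given(st.floats(0, 1), st.floats(0, 100))
@settings(max_examples=200, deadline=None)
def test_recovery_bounds_and_monotonicity(p, recovery):
    out = recovery_probability(p, recovery)
    assert 0.0 <= out <= 1.0
    assert recovery_probability(min(1.0, p + 0.1), recovery) >= out
    assert recovery_probability(p, recovery + 1.0) >= out


def test_recovery_limit():
    assert recovery_probability(0.01, 1e6) == pytest.approx(1.0)


def _config(**kw):
    return ModelConfig(time_limit=float("inf"), **kw)


def test_probe_semantic_forced_draw(toy_stores, rng):
    sem, _ = toy_stores
    cfg = _config(recovery=1e9)
    res = probe_semantic(semantic_features("feline pet"), "C?T", sem, cfg, rng)
    assert res.candidate.answer == "CAT"
    assert res.candidate.n_draws == 1
    assert res.candidate.route == "semantic"


def test_probe_semantic_pattern_filter_costs_draws(toy_stores, rng):
    """A drawn candidate that fails the pattern consumes a draw."""
    sem, _ = toy_stores
    cfg = _config(recovery=1e9)
    seen_two = False
    for _ in range(50):
        res = probe_semantic(semantic_features("feline pet"), "?????", sem, cfg, rng)
        # pattern of length 5 excludes CAT; TIGER shares the 'feline' cue
        assert res.candidate.answer == "TIGER"
        seen_two = seen_two or res.candidate.n_draws >= 2
    assert seen_two


def test_fluency_raises_success_rate(toy_stores):
    """Fluent recovery strictly outperforms disfluent on matched probes."""
    sem, _ = toy_stores
    feats = semantic_features("feline pet")
    rates = {}
    for recovery in (0.5, 15.0):
        rng = np.random.default_rng(99)
        cfg = _config(recovery=recovery)
        ok = sum(
            probe_semantic(feats, "???", sem, cfg, rng).candidate is not None
            for _ in range(1000)
        )
        rates[recovery] = ok / 1000
    assert rates[15.0] > rates[0.5]


def test_probe_orthographic_abstains_blind(toy_stores, rng):
    sem, orth = toy_stores
    res = probe_orthographic("????", semantic_features("x"), sem, orth, _config(), rng)
    assert res is FAILED_PROBE


def test_probe_orthographic_constrained(toy_stores, rng):
    sem, orth = toy_stores
    res = probe_orthographic(
        "CAT", semantic_features("feline pet"), sem, orth, _config(), rng
    )
    assert res.candidate.answer == "CAT"
    assert res.candidate.route == "orthographic"
    assert res.candidate.semantic_score > 0.5


def test_probe_pattern_soundness(toy_stores):
    """Any returned candidate matches its pattern at every known position."""
    sem, orth = toy_stores
    feats = semantic_features("feline pet tok")
    for seed in range(1, 101):
        rng = np.random.default_rng(seed)
        for pattern in ("C??", "?A?", "??T", "?????", "T????"):
            res = probe_orthographic(pattern, feats, sem, orth, _config(), rng)
            if res.candidate is not None:
                assert matches_pattern(res.candidate.answer, pattern)
            res = probe_semantic(feats, pattern, sem, _config(recovery=1e9), rng)
            if res.candidate is not None:
                assert matches_pattern(res.candidate.answer, pattern)


def _cand(answer, score, route="semantic", n=1):
    return ProbeResult(Candidate(answer, route, score, n), n)


def test_arbitrate_cases():
    fail = ProbeResult(None, 3)
    assert arbitrate(fail, fail, 100.0) is None
    # one route succeeded
    won = arbitrate(_cand("CAT", 0.6), fail, 100.0)
    assert won.answer == "CAT" and won.route == "semantic"
    # agreement -> both
    both = arbitrate(_cand("CAT", 0.6), _cand("CAT", 0.6, "orthographic"), 100.0)
    assert both.route == "both"
    # disagreement -> larger semantic score; tie -> semantic route
    o = arbitrate(_cand("CAT", 0.3), _cand("DOG", 0.5, "orthographic"), 100.0)
    assert o.answer == "DOG" and o.route == "orthographic"
    tie = arbitrate(_cand("CAT", 0.5), _cand("DOG", 0.5, "orthographic"), 100.0)
    assert tie.answer == "CAT" and tie.route == "semantic"


def test_arbitrate_confidence_gate():
    assert arbitrate(_cand("DOG", 0.004), ProbeResult(None, 0), 100.0) is None
    assert arbitrate(_cand("DOG", 0.011), ProbeResult(None, 0), 100.0) is not None
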