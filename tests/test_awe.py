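"""Anonymous-walk core: canonicalization, enumeration, sampling bound,
exact and sampled distributions, each checked against an independent oracle."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainwalk import (
    ConfigError,
    ElectrodeGraph,
    NoWalkError,
    SamplingPlan,
    canonicalize_walk,
    count_walks,
    enumerate_walks,
    exact_embedding,
    required_walk_count,
    sample_embedding,
)

from conftest import graph_from_edges, random_graph


# ---------------------------------------------------------------- oracles

def oracle_patterns(length):
    """All valid patterns by brute filtering of every integer sequence."""
    out = []
    for seq in product(range(1, length + 2), repeat=length + 1):
        if seq[0] != 1:
            continue
        if any(seq[i] == seq[i + 1] for i in range(length)):
            continue
        if any(seq[i] > 1 + max(seq[:i]) for i in range(1, length + 1)):
            continue
        out.append(seq)
    return sorted(out)


def oracle_exact(g, length):
    """Exact distribution by exhaustive node-walk enumeration in rationals."""
    nbrs = {i: np.nonzero(g.adjacency[i])[0].tolist() for i in range(g.n_nodes)}
    active = [i for i in range(g.n_nodes) if nbrs[i]]
    probs = {}
    stack = [([v], Fraction(1, len(active))) for v in active]
    while stack:
        trail, p = stack.pop()
        if len(trail) == length + 1:
            key = canonicalize_walk(trail)
            probs[key] = probs.get(key, Fraction(0)) + p
            continue
        cur = trail[-1]
        for nxt in nbrs[cur]:
            stack.append((trail + [nxt], p / len(nbrs[cur])))
    index = enumerate_walks(length)
    return np.array([float(probs.get(pat, Fraction(0))) for pat in index.patterns])


# ----------------------------------------------------------- canonicalize

@pytest.mark.parametrize(
    "seq,expected",
    [
        (("Fp1", "F3", "Fp1", "C3"), (1, 2, 1, 3)),
        (("Cz", "Pz", "Cz"), (1, 2, 1)),
        (("O1", "T3", "O1"), (1, 2, 1)),
        (("Fz",), (1,)),
        ((7, 3, 7, 3, 5), (1, 2, 1, 2, 3)),
    ],
)
def test_canonicalize_first_appearance_relabeling(seq, expected):
    assert canonicalize_walk(seq) == expected


def test_walks_with_same_revisit_structure_share_an_encoding():
    assert canonicalize_walk(("Cz", "Pz", "Cz")) == canonicalize_walk(("O1", "T3", "O1"))


def test_canonicalize_rejects_consecutive_repeats_and_empty():
    with pytest.raises(ConfigError):
        canonicalize_walk(("Cz", "Cz", "Pz"))
    with pytest.raises(ConfigError):
        canonicalize_walk(())


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(0, 5), min_size=1, max_size=8))
def test_canonicalize_is_relabeling_invariant(seq):
    # remove consecutive duplicates to make the walk valid
    walk = [seq[0]] + [x for a, x in zip(seq, seq[1:]) if x != a]
    shift = [(x + 3) * 7 for x in walk]  # injective relabeling
    assert canonicalize_walk(walk) == canonicalize_walk(shift)


# ------------------------------------------------------------ enumeration

@pytest.mark.parametrize("length", range(1, 7))
def test_enumeration_matches_brute_force_oracle(length):
    index = enumerate_walks(length)
    assert list(index.patterns) == oracle_patterns(length)
    assert index.size == len(index.patterns)


@pytest.mark.parametrize(
    "length,expected", [(1, 1), (2, 2), (3, 5), (4, 15), (5, 52), (6, 203), (7, 877)]
)
def test_vocabulary_sizes(length, expected):
    """Two independent routes (DFS enumeration vs the closed recursion)
    agree on the exponentially growing vocabulary sizes."""
    assert enumerate_walks(length).size == expected
    assert count_walks(length) == expected


def test_length_three_patterns():
    assert enumerate_walks(3).patterns == (
        (1, 2, 1, 2), (1, 2, 1, 3), (1, 2, 3, 1), (1, 2, 3, 2), (1, 2, 3, 4)
    )


def test_vocabulary_grows_strictly_with_length():
    sizes = [enumerate_walks(l).size for l in range(1, 9)]
    assert all(b > a for a, b in zip(sizes, sizes[1:]))


def test_enumeration_rejects_nonpositive_length():
    with pytest.raises(ConfigError):
        enumerate_walks(0)


# --------------------------------------------------------- sampling bound

@pytest.mark.parametrize("n,expected", [(52, 8130), (2, 1060)])
def test_required_walk_count_frozen_values(n, expected):
    # frozen from an independent high-precision evaluation of
    # ceil((2/eps^2) * (ln(2^N - 2) - ln(delta))) at eps=0.1, delta=0.01
    assert required_walk_count(n, 0.1, 0.01) == expected


def test_required_walk_count_matches_exact_integer_formula():
    from decimal import Decimal, getcontext
    import math

    getcontext().prec = 60
    for n in (2, 5, 52, 203, 877):
        exact = (Decimal(2) / Decimal("0.01")) * (
            Decimal(2**n - 2).ln() - Decimal("0.01").ln()
        )
        assert required_walk_count(n, 0.1, 0.01) == math.ceil(exact)


def test_required_walk_count_rejects_degenerate_vocabulary():
    with pytest.raises(ConfigError):
        required_walk_count(1, 0.1, 0.01)


# -------------------------------------------------------- exact embedding

def test_exact_embedding_on_path(path_abc):
    e = exact_embedding(path_abc, 2)
    np.testing.assert_allclose(e.probabilities, [2 / 3, 1 / 3])


def test_exact_embedding_on_triangle(triangle):
    e = exact_embedding(triangle, 2)
    np.testing.assert_allclose(e.probabilities, [1 / 2, 1 / 2])


@pytest.mark.parametrize("length", [1, 2, 3, 4])
def test_exact_embedding_matches_rational_oracle(length, rng):
    for _ in range(5):
        g = random_graph(6, 0.5, rng)
        mine = exact_embedding(g, length).probabilities
        np.testing.assert_allclose(mine, oracle_exact(g, length), atol=1e-12)


def test_exact_embedding_sums_to_one(rng):
    for _ in range(10):
        g = random_graph(8, 0.3, rng)
        assert abs(exact_embedding(g, 3).probabilities.sum() - 1) < 1e-9


def test_exact_embedding_is_relabeling_invariant(rng):
    for _ in range(10):
        g = random_graph(10, 0.3, rng)
        perm = rng.permutation(g.n_nodes)
        pg = ElectrodeGraph(
            g.adjacency[np.ix_(perm, perm)], tuple(g.node_labels[i] for i in perm)
        )
        assert np.array_equal(
            exact_embedding(g, 3).probabilities, exact_embedding(pg, 3).probabilities
        )


def test_edgeless_graph_raises():
    g = ElectrodeGraph(np.zeros((4, 4), dtype=np.int8), ("A", "B", "C", "D"))
    with pytest.raises(NoWalkError):
        exact_embedding(g, 2)
    with pytest.raises(NoWalkError):
        sample_embedding(g, 2, SamplingPlan(m=10), seed=0)


# ------------------------------------------------------ sampled embedding

def test_single_edge_graph_forces_one_pattern():
    g = graph_from_edges(("A", "B", "C"), [("A", "B")])
    for length in (2, 4):
        e = sample_embedding(g, length, SamplingPlan(m=500), seed=3)
        index = enumerate_walks(length)
        alternating = tuple(1 if i % 2 == 0 else 2 for i in range(length + 1))
        expected = np.zeros(index.size)
        expected[index.position(alternating)] = 1.0
        np.testing.assert_array_equal(e.probabilities, expected)


def test_sampled_embedding_is_deterministic_under_seed(path_abc):
    plan = SamplingPlan(m=500)
    a = sample_embedding(path_abc, 3, plan, seed=7)
    b = sample_embedding(path_abc, 3, plan, seed=7)
    assert np.array_equal(a.probabilities, b.probabilities)
    c = sample_embedding(path_abc, 3, plan, seed=8)
    assert not np.array_equal(a.probabilities, c.probabilities)


def test_sampled_frequencies_are_exact_multiples_of_one_over_m(path_abc):
    plan = SamplingPlan(m=137)
    e = sample_embedding(path_abc, 3, plan, seed=0)
    counts = e.probabilities * plan.m
    np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
    assert abs(e.probabilities.sum() - 1) < 1e-12


def test_sampling_bound_holds_on_path_graph(path_abc):
    """With m from the sampling bound at (0.1, 0.01), the L1 error to the
    exact distribution stays below epsilon in >= 90% of seeded runs."""
    plan = SamplingPlan.for_vocabulary(2, 0.1, 0.01)
    assert plan.m == 1060
    exact = exact_embedding(path_abc, 2).probabilities
    failures = sum(
        np.abs(sample_embedding(path_abc, 2, plan, seed=s).probabilities - exact).sum() > 0.1
        for s in range(20)
    )
    assert failures <= 2


def test_sampled_converges_to_exact_on_denser_graph(rng):
    g = random_graph(8, 0.4, rng)
    exact = exact_embedding(g, 3).probabilities
    plan = SamplingPlan.for_vocabulary(5, 0.1, 0.01)
    sampled = sample_embedding(g, 3, plan, seed=11).probabilities
    assert np.abs(sampled - exact).sum() < 0.1
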