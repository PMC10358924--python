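"""Anonymous-walk embeddings: enumeration, exact distribution, sampling.

An anonymous walk records only the revisit structure of a random walk —
nodes are relabeled 1, 2, 3, ... by order of first appearance — so walks
that visit different nodes in the same sequence get the same encoding.
The embedding of a graph at walk length ``l`` (number of edges traversed)
is the probability distribution over all anonymous-walk patterns of that
length, a label-free, isomorphism-invariant graph fingerprint.

Two routes to the distribution are provided:

* :func:`exact_embedding` — brute-force enumeration of every node walk,
  exact probabilities (feasible for small lengths / sparse graphs);
* :func:`sample_embedding` — Monte-Carlo frequencies from ``m`` independent
  uniform random walks, with :func:`required_walk_count` giving the sample
  size that bounds the L1 error by ``epsilon`` with failure probability
  ``delta``:  m = ceil( (2/eps^2) * ( ln(2^N - 2) - ln(delta) ) ),
  N being the pattern-vocabulary size at the chosen length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import ConfigError, NoWalkError
from .signal_graph import ElectrodeGraph

__all__ = [
    "AnonymousWalk",
    "WalkIndex",
    "SamplingPlan",
    "WalkEmbedding",
    "canonicalize_walk",
    "enumerate_walks",
    "count_walks",
    "required_walk_count",
    "exact_embedding",
    "sample_embedding",
]

AnonymousWalk = tuple[int, ...]


@dataclass(frozen=True)
class WalkIndex:
    """All anonymous-walk patterns of one length, lexicographically ordered.

    The ordering is total and deterministic, so it fixes the coordinate
    system of every embedding vector of that length across graphs and runs.
    """

    length: int
    patterns: tuple[AnonymousWalk, ...]

    @property
    def size(self) -> int:
        return len(self.patterns)

    def position(self, walk: AnonymousWalk) -> int:
        return self._lookup()[walk]

    def _lookup(self) -> dict[AnonymousWalk, int]:
        cached = getattr(self, "_lookup_cache", None)
        if cached is None:
            cached = {p: i for i, p in enumerate(self.patterns)}
            object.__setattr__(self, "_lookup_cache", cached)
        return cached


@dataclass(frozen=True)
class SamplingPlan:
    """Monte-Carlo budget: ``m`` walks bound the L1 error by ``epsilon``
    except with probability ``delta``."""

    epsilon: float = 0.1
    delta: float = 0.01
    m: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if not 0 < self.delta < 1:
            raise ConfigError("delta must be in (0, 1)")
        if self.m < 1:
            raise ConfigError("m must be a positive integer")

    @classmethod
    def for_vocabulary(
        cls, n_patterns: int, epsilon: float = 0.1, delta: float = 0.01
    ) -> "SamplingPlan":
        return cls(epsilon, delta, required_walk_count(n_patterns, epsilon, delta))


@dataclass(frozen=True)
class WalkEmbedding:
    """Probability vector over the anonymous-walk vocabulary of one length."""

    probabilities: np.ndarray
    length: int
    seed: int | None = None  # recorded for sampled embeddings

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1:
            raise ConfigError("embedding must be a 1-D probability vector")
        if p.min() < 0:
            raise ConfigError("embedding entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("embedding entries must sum to 1")

    @property
    def size(self) -> int:
        return self.probabilities.shape[0]


def canonicalize_walk(node_sequence: Sequence) -> AnonymousWalk:
    """Relabel a node sequence by order of first appearance, starting at 1.

    ``(Fp1, F3, Fp1, C3) -> (1, 2, 1, 3)``.  Two walks with the same
    revisit structure map to the same pattern regardless of node labels.
    Consecutive repeats are rejected: the graphs have no self-loops.
    """
    if len(node_sequence) == 0:
        raise ConfigError("cannot canonicalize an empty walk")
    labels: dict = {}
    out = []
    prev = object()
    for node in node_sequence:
        if node == prev:
            raise ConfigError(f"invalid walk: node {node!r} repeated consecutively")
        if node not in labels:
            labels[node] = len(labels) + 1
        out.append(labels[node])
        prev = node
    return tuple(out)


@lru_cache(maxsize=None)
def enumerate_walks(length: int) -> WalkIndex:
    """All anonymous-walk patterns of the given length, in lexicographic order.

    A pattern of length ``l`` has ``l + 1`` entries, starts at 1, never
    jumps past ``1 + max`` of its prefix, and never repeats consecutively.
    Generation is depth-first with candidates visited in increasing order,
    which yields lexicographic output directly.
    """
    if length < 1:
        raise ConfigError("walk length must be >= 1")
    patterns: list[AnonymousWalk] = []

    def extend(prefix: list[int], hi: int) -> None:
        if len(prefix) == length + 1:
            patterns.append(tuple(prefix))
            return
        for nxt in range(1, hi + 2):
            if nxt != prefix[-1]:
                prefix.append(nxt)
                extend(prefix, max(hi, nxt))
                prefix.pop()

    extend([1], 1)
    return WalkIndex(length, tuple(patterns))


def count_walks(length: int) -> int:
    """Number of anonymous-walk patterns of a length, without enumeration.

    Uses the recursion ``a(t+1, k) = a(t, k) * (k - 1) + a(t, k - 1)``
    where ``a(t, k)`` counts length-``t`` patterns using exactly ``k``
    distinct labels; the total is the sum over ``k``.  Serves as an
    independent cross-check of :func:`enumerate_walks` and as a fast route
    to the vocabulary size for :func:`required_walk_count`.
    """
    if length < 1:
        raise ConfigError("walk length must be >= 1")
    # a[k] = number of length-t walks on exactly k distinct labels
    a = {1: 1}  # t = 0: the single-node walk (1)
    for _ in range(length):
        nxt: dict[int, int] = {}
        for k, cnt in a.items():
            if k > 1:
                nxt[k] = nxt.get(k, 0) + cnt * (k - 1)
            nxt[k + 1] = nxt.get(k + 1, 0) + cnt
        a = nxt
    return sum(a.values())


def required_walk_count(n_patterns: int, epsilon: float = 0.1, delta: float = 0.01) -> int:
    """Sample size guaranteeing L1 error <= epsilon with probability 1 - delta.

    ``m = ceil( (2 / eps^2) * ( ln(2^N - 2) - ln(delta) ) )``, with the first
    logarithm evaluated stably as ``N ln 2 + log1p(-2^(1-N))`` so vocabularies
    of thousands of patterns do not overflow.  The bound is a minimum, hence
    the ceiling.
    """
    if n_patterns < 2:
        raise ConfigError("sample bound needs at least 2 patterns (2^N - 2 > 0)")
    if epsilon <= 0:
        raise ConfigError("epsilon must be positive")
    if not 0 < delta < 1:
        raise ConfigError("delta must be in (0, 1)")
    log_term = n_patterns * math.log(2.0) + math.log1p(-(2.0 ** (1 - n_patterns)))
    return math.ceil((2.0 / epsilon**2) * (log_term - math.log(delta)))


def _active_nodes(g: ElectrodeGraph) -> np.ndarray:
    deg = g.degrees
    active = np.nonzero(deg >= 1)[0]
    if active.size == 0:
        raise NoWalkError("graph has no edges; no random walk can be started")
    return active


def exact_embedding(g: ElectrodeGraph, length: int) -> WalkEmbedding:
    """Exact anonymous-walk distribution by brute-force walk enumeration.

    The start node is uniform over nodes of degree >= 1 and each step is
    uniform over the current node's neighbors, so a node walk
    ``v0, ..., vl`` has probability ``(1/|V+|) * prod_i 1/deg(v_i)`` over
    its first ``l`` positions.  Contributions are accumulated per pattern
    keyed by the integer product of degrees and summed with ``math.fsum``,
    so the result is invariant under node relabeling down to the last bit.

    Cost grows as the number of length-``l`` walks (roughly ``n * d^l``);
    intended as an oracle for short walks and as ground truth for
    :func:`sample_embedding`.
    """
    if length < 1:
        raise ConfigError("walk length must be >= 1")
    active = _active_nodes(g)
    nbrs = [np.nonzero(g.adjacency[i])[0] for i in range(g.n_nodes)]
    deg = g.degrees
    index = enumerate_walks(length)
    # per pattern: {product of step degrees: walk count}
    buckets: list[dict[int, int]] = [dict() for _ in range(index.size)]

    def walk(node: int, trail: list[int], labels: dict[int, int], pattern: list[int], prod: int) -> None:
        if len(trail) == length + 1:
            b = buckets[index.position(tuple(pattern))]
            b[prod] = b.get(prod, 0) + 1
            return
        d = int(deg[node])
        for nxt in nbrs[node]:
            nxt = int(nxt)
            new = nxt not in labels
            if new:
                labels[nxt] = len(labels) + 1
            trail.append(nxt)
            pattern.append(labels[nxt])
            walk(nxt, trail, labels, pattern, prod * d)
            trail.pop()
            pattern.pop()
            if new:
                del labels[nxt]

    for start in active:
        start = int(start)
        walk(start, [start], {start: 1}, [1], 1)

    n_start = active.size
    probs = np.array(
        [
            math.fsum(cnt / (n_start * prod) for prod, cnt in sorted(b.items()))
            for b in buckets
        ]
    )
    return WalkEmbedding(probs, length)


def sample_embedding(
    g: ElectrodeGraph,
    length: int,
    plan: SamplingPlan | None = None,
    seed: int | None = None,
) -> WalkEmbedding:
    """Monte-Carlo anonymous-walk distribution from ``m`` independent walks.

    Each walk restarts independently: start node uniform over degree->=1
    nodes, each step uniform over the current node's neighbors (immediate
    backtracking allowed).  Returns empirical pattern frequencies on the
    lexicographic vocabulary; reproducible given ``seed``.
    """
    if length < 1:
        raise ConfigError("walk length must be >= 1")
    index = enumerate_walks(length)
    if plan is None:
        plan = SamplingPlan.for_vocabulary(index.size)
    active = _active_nodes(g)
    deg = g.degrees
    maxdeg = int(deg.max())
    pad = np.zeros((g.n_nodes, maxdeg), dtype=np.int64)
    for i in range(g.n_nodes):
        nb = np.nonzero(g.adjacency[i])[0]
        pad[i, : nb.size] = nb

    rng = np.random.default_rng(seed)
    m = plan.m
    nodes = np.empty((m, length + 1), dtype=np.int64)
    nodes[:, 0] = rng.choice(active, size=m)
    for t in range(length):
        cur = nodes[:, t]
        k = (rng.random(m) * deg[cur]).astype(np.int64)
        nodes[:, t + 1] = pad[cur, k]

    codes = _canonicalize_matrix(nodes)
    base = length + 2
    weights = base ** np.arange(length + 1, dtype=np.int64)
    keys = codes @ weights
    pattern_keys = np.array([np.dot(np.array(p), weights) for p in index.patterns])
    order = np.argsort(pattern_keys)
    pos = order[np.searchsorted(pattern_keys[order], keys)]
    counts = np.bincount(pos, minlength=index.size)
    return WalkEmbedding(counts / m, length, seed=seed)


def _canonicalize_matrix(nodes: np.ndarray) -> np.ndarray:
    """Row-wise first-appearance relabeling of an (m, l+1) walk matrix."""
    m, w = nodes.shape
    codes = np.zeros((m, w), dtype=np.int64)
    codes[:, 0] = 1
    maxlab = np.ones(m, dtype=np.int64)
    rows = np.arange(m)
    for j in range(1, w):
        eq = nodes[:, :j] == nodes[:, j : j + 1]
        seen = eq.any(axis=1)
        first = eq.argmax(axis=1)
        lab = np.where(seen, codes[rows, first], maxlab + 1)
        codes[:, j] = lab
        maxlab = np.maximum(maxlab, lab)
    return codes
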