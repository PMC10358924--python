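"""Pairwise feature assembly and the degree-histogram baseline.

Every unordered pair of players is compared within each game: the feature
vector is ``z = |e1 - e2|``, the element-wise absolute difference of the
two players' graph embeddings, and the label is 1 when both players chose
the same option (coordination) and 0 otherwise.  Ten players and twelve
games yield C(10,2) * 12 = 540 observations.

The Bag-of-Node-Degree baseline replaces the anonymous-walk embedding by
the normalized degree histogram of the graph — a much cheaper fingerprint
that discards all structure beyond first-order connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .awe import WalkEmbedding
from .errors import ConfigError, IncompleteDataError
from .signal_graph import ElectrodeGraph

__all__ = [
    "ChoiceTable",
    "PairObservation",
    "PairDataset",
    "difference_vector",
    "label_pair",
    "assemble_dataset",
    "bag_of_node_degree",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChoiceTable:
    """Chosen option per (player, game)."""

    entries: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def players(self) -> tuple[str, ...]:
        return tuple(sorted({p for p, _ in self.entries}))

    @property
    def games(self) -> tuple[str, ...]:
        return tuple(sorted({g for _, g in self.entries}))

    def option(self, player: str, game: str) -> str:
        try:
            return self.entries[(player, game)]
        except KeyError:
            raise IncompleteDataError(
                f"no recorded choice for player {player!r} in game {game!r}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"player_id": p, "game_id": g, "option": o}
            for (p, g), o in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["player_id", "game_id", "option"])


@dataclass(frozen=True)
class PairObservation:
    """One (player pair, game) comparison: features z and coordination label."""

    player_a: str
    player_b: str
    game_id: str
    z: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if not self.player_a < self.player_b:
            raise ConfigError("pair must be ordered player_a < player_b and distinct")
        if self.label not in (0, 1):
            raise ConfigError("label must be 0 or 1")
        z = np.asarray(self.z, dtype=float)
        if z.min() < 0:
            raise ConfigError("difference features must be non-negative")
        object.__setattr__(self, "z", z)


@dataclass
class PairDataset:
    """All pair observations plus class totals; feeds the classifier."""

    observations: list[PairObservation]

    @property
    def n_positive(self) -> int:
        return sum(o.label for o in self.observations)

    @property
    def n_negative(self) -> int:
        return len(self.observations) - self.n_positive

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def feature_matrix(self) -> np.ndarray:
        return np.vstack([o.z for o in self.observations])

    @property
    def labels(self) -> np.ndarray:
        return np.array([o.label for o in self.observations], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        n_feat = self.observations[0].z.shape[0] if self.observations else 0
        cols = ["player_a", "player_b", "game_id", "label"] + [
            f"z{i+1}" for i in range(n_feat)
        ]
        rows = [
            [o.player_a, o.player_b, o.game_id, o.label, *o.z]
            for o in self.observations
        ]
        return pd.DataFrame(rows, columns=cols)


def difference_vector(
    e1: "WalkEmbedding | np.ndarray", e2: "WalkEmbedding | np.ndarray"
) -> np.ndarray:
    """z = |e1 - e2|: element-wise absolute difference, symmetric in arguments.

    Accepts walk embeddings (checked for matching walk length) or plain
    probability vectors such as the Bag-of-Node-Degree histogram.
    """
    if isinstance(e1, WalkEmbedding) and isinstance(e2, WalkEmbedding):
        if e1.length != e2.length or e1.size != e2.size:
            raise ConfigError(
                f"embedding mismatch: lengths {e1.length}/{e2.length}, "
                f"sizes {e1.size}/{e2.size}"
            )
        return np.abs(e1.probabilities - e2.probabilities)
    v1 = e1.probabilities if isinstance(e1, WalkEmbedding) else np.asarray(e1, float)
    v2 = e2.probabilities if isinstance(e2, WalkEmbedding) else np.asarray(e2, float)
    if v1.shape != v2.shape:
        raise ConfigError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    return np.abs(v1 - v2)


def label_pair(choices: ChoiceTable, player_a: str, player_b: str, game: str) -> int:
    """1 if both (distinct) players chose the same option in the game, else 0."""
    if player_a == player_b:
        raise ConfigError("a pair must consist of two distinct players")
    return int(choices.option(player_a, game) == choices.option(player_b, game))


def assemble_dataset(
    embeddings: "Mapping[tuple[str, str], WalkEmbedding | np.ndarray]",
    choices: ChoiceTable,
    strict: bool = True,
) -> PairDataset:
    """Build the labeled pair dataset from per-(player, game) embeddings.

    One observation per unordered pair of distinct players per game (players
    sorted by identifier, so each pair appears once; the absolute value in z
    makes the orientation irrelevant).  With ``strict=False`` a missing
    embedding drops only the affected pairs, with a logged warning.
    """
    players = choices.players
    games = choices.games
    obs: list[PairObservation] = []
    for game in games:
        for a, b in combinations(players, 2):
            missing = [(p, game) for p in (a, b) if (p, game) not in embeddings]
            if missing:
                if strict:
                    p, g = missing[0]
                    raise IncompleteDataError(
                        f"no embedding for player {p!r} in game {g!r}"
                    )
                logger.warning("dropping pair (%s, %s) in game %s: missing embedding", a, b, game)
                continue
            z = difference_vector(embeddings[(a, game)], embeddings[(b, game)])
            obs.append(PairObservation(a, b, game, z, label_pair(choices, a, b, game)))
    return PairDataset(obs)


def bag_of_node_degree(g: ElectrodeGraph) -> np.ndarray:
    """Normalized degree histogram: entry d = fraction of nodes of degree d.

    Length-n vector over the possible degrees 0..n-1; sums to 1.  The
    baseline graph fingerprint against which the anonymous-walk embedding
    is compared.
    """
    n = g.n_nodes
    counts = np.bincount(g.degrees, minlength=n)
    return counts / n
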