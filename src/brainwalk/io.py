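"""Text-format readers and writers for every pipeline artifact.

All artifacts are plain delimited text so synthetic and recorded data are
interchangeable end-to-end:

* channel matrix CSV — header row of electrode labels, one row per sample
  (read back as channels x samples);
* graph — edge-list text (``labelA<TAB>labelB`` per line) or a square 0/1
  adjacency CSV with labeled rows and columns;
* embeddings — long CSV keyed by (player_id, game_id, walk length) with
  one column per anonymous-walk pattern (pattern string like ``1-2-1-3``);
* choice table — CSV with columns player_id, game_id, option;
* pair dataset — one row per observation: player_a, player_b, game_id,
  label, z1..zN.

Writers and readers round-trip: bit-exact for integer and label fields,
within 1e-12 for reals.  EDF input is supported when ``mne`` is installed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .awe import WalkEmbedding, enumerate_walks
from .errors import ConfigError, ParseError
from .features import ChoiceTable, PairDataset, PairObservation
from .signal_graph import ElectrodeGraph, EpochRecording

__all__ = [
    "read_channel_matrix",
    "write_channel_matrix",
    "read_edf",
    "read_graph",
    "write_graph",
    "read_adjacency",
    "write_adjacency",
    "read_embeddings",
    "write_embeddings",
    "read_choices",
    "write_choices",
    "read_dataset",
    "write_dataset",
]


def write_channel_matrix(path: str | Path, epoch: EpochRecording) -> None:
    df = pd.DataFrame(epoch.data.T, columns=list(epoch.channel_labels))
    df.to_csv(path, index=False, float_format="%.17g")


def read_channel_matrix(
    path: str | Path, fs: float, player_id: str = "", game_id: str = ""
) -> EpochRecording:
    """Read a samples x channels CSV (header = electrode labels) as an epoch."""
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: no samples")
    return EpochRecording(df.to_numpy().T, fs, tuple(df.columns), player_id, game_id)


def read_edf(path: str | Path) -> EpochRecording:
    """Read a raw EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigError(
            "EDF input requires the optional 'mne' dependency (pip install brainwalk[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EpochRecording(raw.get_data() * 1e6, raw.info["sfreq"], tuple(raw.ch_names))


def write_graph(path: str | Path, g: ElectrodeGraph) -> None:
    """Edge-list text: one ``labelA<TAB>labelB`` line per edge, after a node header."""
    lines = ["# nodes\t" + "\t".join(g.node_labels)]
    lines += [f"{a}\t{b}" for a, b in g.edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph(path: str | Path, node_labels: tuple[str, ...] | None = None) -> ElectrodeGraph:
    """Read an edge-list file; the node vocabulary comes from the header line
    (or ``node_labels``), so isolated nodes survive the round trip."""
    labels: list[str] | None = list(node_labels) if node_labels else None
    edges: list[tuple[str, str]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("#").strip().split("\t")
            if parts and parts[0] == "nodes":
                labels = parts[1:]
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"expected 'labelA<TAB>labelB', got {line!r}", line=ln)
        if parts[0] == parts[1]:
            raise ParseError(f"self-loop on {parts[0]!r} is not allowed", line=ln)
        edges.append((parts[0], parts[1]))
    if labels is None:
        labels = sorted({n for e in edges for n in e})
    pos = {lab: i for i, lab in enumerate(labels)}
    a = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for ln, (u, v) in enumerate(edges):
        if u not in pos or v not in pos:
            raise ParseError(f"edge ({u}, {v}) references an unknown node")
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = 1
    return ElectrodeGraph(a, tuple(labels))


def write_adjacency(path: str | Path, g: ElectrodeGraph) -> None:
    df = pd.DataFrame(g.adjacency, index=list(g.node_labels), columns=list(g.node_labels))
    df.to_csv(path)


def read_adjacency(path: str | Path) -> ElectrodeGraph:
    """Read a labeled square 0/1 adjacency CSV; rejects asymmetry, self-loops
    and non-binary entries (the graph invariants)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column labels differ")
    a = df.to_numpy()
    if not np.all(np.isin(a, (0, 1))):
        raise ParseError(f"{path}: adjacency entries must be 0 or 1")
    if np.any(np.diag(a) != 0):
        raise ParseError(f"{path}: nonzero diagonal (self-loops are not allowed)")
    if not np.array_equal(a, a.T):
        raise ParseError(f"{path}: adjacency matrix is not symmetric")
    return ElectrodeGraph(a.astype(np.int8), tuple(str(c) for c in df.columns))


def _pattern_str(pattern: tuple[int, ...]) -> str:
    return "-".join(map(str, pattern))


def write_embeddings(
    path: str | Path, embeddings: Mapping[tuple[str, str], WalkEmbedding]
) -> None:
    """Long-form CSV: player_id, game_id, length, then one column per pattern."""
    if not embeddings:
        raise ConfigError("nothing to write: empty embedding map")
    lengths = {e.length for e in embeddings.values()}
    if len(lengths) != 1:
        raise ConfigError("all embeddings in one table must share a walk length")
    (length,) = lengths
    index = enumerate_walks(length)
    cols = [_pattern_str(p) for p in index.patterns]
    rows = []
    for (player, game), emb in sorted(embeddings.items()):
        rows.append([player, game, length, *emb.probabilities])
    df = pd.DataFrame(rows, columns=["player_id", "game_id", "length", *cols])
    df.to_csv(path, index=False, float_format="%.17g")


def read_embeddings(path: str | Path) -> dict[tuple[str, str], WalkEmbedding]:
    df = pd.read_csv(path)
    need = {"player_id", "game_id", "length"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: missing key columns {sorted(need - set(df.columns))}")
    out = {}
    for _, row in df.iterrows():
        length = int(row["length"])
        index = enumerate_walks(length)
        probs = np.array([row[_pattern_str(p)] for p in index.patterns], dtype=float)
        out[(str(row["player_id"]), str(row["game_id"]))] = WalkEmbedding(probs, length)
    return out


def write_choices(path: str | Path, choices: ChoiceTable) -> None:
    choices.to_frame().to_csv(path, index=False)


def read_choices(path: str | Path) -> ChoiceTable:
    df = pd.read_csv(path)
    need = {"player_id", "game_id", "option"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    entries = {}
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        key = (str(row.player_id), str(row.game_id))
        if key in entries:
            raise ParseError(f"duplicate choice for {key}", line=ln)
        entries[key] = str(row.option)
    return ChoiceTable(entries)


def write_dataset(path: str | Path, ds: PairDataset) -> None:
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> PairDataset:
    df = pd.read_csv(path)
    zcols = [c for c in df.columns if c.startswith("z")]
    obs = [
        PairObservation(
            str(r.player_a), str(r.player_b), str(r.game_id),
            np.array([getattr(r, c) for c in zcols], dtype=float), int(r.label),
        )
        for r in df.itertuples(index=False)
    ]
    return PairDataset(obs)
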