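"""EEG epoch conditioning and coherence-graph construction.

A 1-second multichannel epoch is band-pass filtered, decimated to the
analysis rate (512 Hz -> 64 Hz by default), re-referenced to the common
average and baseline-corrected.  Magnitude coherence is then estimated for
every electrode pair with a Welch-style cross-spectral estimate, averaged
over the analysis band, and thresholded (>= 0.5 by default) into an
undirected binary graph on the electrodes.  For a 16-channel montage the
graph has at most 120 edges and node degree at most 15; self-loops are
excluded because the coherence of a signal with itself is always one.

Independent-component artifact rejection is deliberately not part of this
pipeline: component selection is a manual, rater-dependent step.  Callers
working with real recordings should clean epochs before handing them to
:func:`preprocess_epoch`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import networkx as nx
from scipy import signal as sps

from .errors import ConfigError, DataQualityError, TruncationError

__all__ = [
    "EpochRecording",
    "PreprocessConfig",
    "CoherenceMatrix",
    "GraphConfig",
    "ElectrodeGraph",
    "preprocess_epoch",
    "coherence_matrix",
    "build_graph",
]


# standard 16-channel 10-20 montage used as the default label set
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "F4", "F8", "T3", "C3",
    "C4", "T4", "T5", "P3", "P4", "T6", "O1", "O2",
)


@dataclass
class EpochRecording:
    """One task epoch: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    player_id: str = ""
    game_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ConfigError("epoch data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ConfigError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DataQualityError("epoch contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    ``bandpass`` defaults to 1-32 Hz: the upper edge must not exceed the
    post-decimation Nyquist frequency (32 Hz at the 64 Hz target rate).
    ``baseline_mode='epoch_mean'`` subtracts each channel's temporal mean;
    there is no pre-stimulus segment in a task-onset epoch.
    """

    bandpass_low: float = 1.0
    bandpass_high: float = 32.0
    target_fs: float = 64.0
    epoch_length: float = 1.0
    baseline_mode: str = "epoch_mean"
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ConfigError("need 0 < bandpass_low < bandpass_high")
        if self.bandpass_high > self.target_fs / 2:
            raise ConfigError("bandpass_high exceeds the target Nyquist frequency")
        if self.baseline_mode not in ("epoch_mean", "none"):
            raise ConfigError(f"unknown baseline_mode {self.baseline_mode!r}")


@dataclass(frozen=True)
class CoherenceMatrix:
    """Symmetric matrix of pairwise band-averaged coherence values in [0, 1]."""

    values: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        n = len(self.channel_labels)
        if v.shape != (n, n):
            raise ConfigError("coherence matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ConfigError("coherence matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ConfigError("coherence values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ConfigError("coherence of a signal with itself must be 1")


@dataclass(frozen=True)
class GraphConfig:
    """Coherence-estimation and thresholding parameters.

    ``estimator`` selects magnitude of the complex coherency
    (``magnitude_coherency``, the default reading of "absolute coherence")
    or magnitude-squared coherence.  The Welch segmentation defaults
    (Hann window, 32-sample segments, 16-sample overlap) give three
    segments on a 64-sample epoch; the resulting high bias of the
    coherence estimate is a known property of few-segment estimates and
    the parameters are exposed for longer epochs.
    """

    threshold: float = 0.5
    estimator: str = "magnitude_coherency"
    segment_length: int = 32
    segment_overlap: int = 16
    band: tuple[float, float] = (1.0, 32.0)

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ConfigError("threshold must be in (0, 1]")
        if self.estimator not in ("magnitude_coherency", "magnitude_squared"):
            raise ConfigError(f"unknown estimator {self.estimator!r}")
        if not 0 <= self.segment_overlap < self.segment_length:
            raise ConfigError("need 0 <= segment_overlap < segment_length")
        if self.band[0] > self.band[1]:
            raise ConfigError("band must be (low, high) with low <= high")


@dataclass(frozen=True)
class ElectrodeGraph:
    """Undirected simple graph on labeled electrodes (binary adjacency)."""

    adjacency: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.issubdtype(a.dtype, np.integer):
            if not np.all(np.isin(a, (0, 1))):
                raise ConfigError("adjacency must be binary")
            a = a.astype(np.int8)
        else:
            a = a.astype(np.int8)
            if not np.all(np.isin(a, (0, 1))):
                raise ConfigError("adjacency must be binary")
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        n = len(self.node_labels)
        if a.shape != (n, n):
            raise ConfigError("adjacency shape does not match node labels")
        if not np.array_equal(a, a.T):
            raise ConfigError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(a) != 0):
            raise ConfigError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edges(self) -> list[tuple[str, str]]:
        """Edge list as label pairs, each unordered edge once (i < j)."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.node_labels[a], self.node_labels[b]) for a, b in zip(i, j)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "ElectrodeGraph":
        labels = tuple(str(v) for v in g.nodes())
        a = nx.to_numpy_array(g, nodelist=list(g.nodes()), dtype=np.int8)
        np.fill_diagonal(a, 0)
        return cls(a, labels)


def preprocess_epoch(raw: EpochRecording, cfg: PreprocessConfig | None = None) -> EpochRecording:
    """Condition a raw epoch: band-pass, decimate, re-reference, baseline.

    The filter is applied forward-backward (zero phase) so the epoch stays
    aligned to task onset.  Decimation requires an integer factor
    ``raw.fs / cfg.target_fs``.  The output has exactly
    ``target_fs * epoch_length`` samples, a ~zero mean across channels at
    every sample (average reference) and, with ``baseline_mode='epoch_mean'``,
    a ~zero temporal mean per channel.
    """
    cfg = cfg or PreprocessConfig()
    if raw.fs < 2 * cfg.bandpass_high:
        raise ConfigError(
            f"sampling rate {raw.fs} Hz cannot resolve bandpass_high={cfg.bandpass_high} Hz"
        )
    factor = raw.fs / cfg.target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigError(
            f"decimation factor {raw.fs}/{cfg.target_fs} is not an integer"
        )
    factor = int(round(factor))
    n_need_raw = int(round(cfg.epoch_length * raw.fs))
    if raw.n_samples < n_need_raw:
        raise TruncationError(
            f"epoch has {raw.n_samples} samples, need {n_need_raw} for "
            f"{cfg.epoch_length} s at {raw.fs} Hz"
        )

    sos = sps.butter(
        cfg.filter_order,
        (cfg.bandpass_low, cfg.bandpass_high),
        btype="bandpass",
        fs=raw.fs,
        output="sos",
    )
    x = sps.sosfiltfilt(sos, raw.data, axis=1)
    if factor > 1:
        x = sps.decimate(x, factor, axis=1, zero_phase=True)
    n_out = int(round(cfg.target_fs * cfg.epoch_length))
    x = x[:, :n_out]
    # common-average reference, then per-channel baseline; in this order
    # both the per-sample channel mean and the per-channel temporal mean
    # end up exactly zero (baseline shifts sum to zero across channels)
    x = x - x.mean(axis=0, keepdims=True)
    if cfg.baseline_mode == "epoch_mean":
        x = x - x.mean(axis=1, keepdims=True)
    return replace(raw, data=x, fs=cfg.target_fs)


def _welch_cross_spectra(
    x: np.ndarray, fs: float, cfg: GraphConfig
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Welch cross-spectral matrix, shape (n_freqs, n, n)."""
    nper = min(cfg.segment_length, x.shape[1])
    step = nper - cfg.segment_overlap if nper == cfg.segment_length else nper
    window = sps.get_window("hann", nper)
    starts = range(0, x.shape[1] - nper + 1, max(step, 1))
    segs = np.stack([x[:, s : s + nper] for s in starts], axis=0)  # (k, n, nper)
    segs = segs - segs.mean(axis=2, keepdims=True)
    spec = np.fft.rfft(segs * window, axis=2)  # (k, n, nf)
    # average over segments of the cross-periodogram; scaling cancels in coherence
    s = np.einsum("kif,kjf->fij", spec, np.conj(spec)) / segs.shape[0]
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, s


def coherence_matrix(epoch: EpochRecording, cfg: GraphConfig | None = None) -> CoherenceMatrix:
    """Band-averaged pairwise coherence of a conditioned epoch.

    For each electrode pair the coherency spectrum
    ``S_xy / sqrt(S_xx S_yy)`` is estimated with Welch averaging and its
    magnitude (or magnitude squared) is averaged over the frequency bins
    inside ``cfg.band``, yielding one scalar per pair in [0, 1].
    """
    cfg = cfg or GraphConfig()
    if epoch.n_channels < 2:
        raise ConfigError("coherence needs at least two channels")
    power = (epoch.data - epoch.data.mean(axis=1, keepdims=True)).var(axis=1)
    dead = np.nonzero(power == 0)[0]
    if dead.size:
        names = ", ".join(epoch.channel_labels[i] for i in dead)
        raise DataQualityError(f"coherence undefined for constant channel(s): {names}")

    freqs, s = _welch_cross_spectra(epoch.data, epoch.fs, cfg)
    in_band = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    if not in_band.any():
        raise ConfigError("no frequency bins fall inside the requested band")
    auto = np.real(np.einsum("fii->fi", s))  # (nf, n)
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(s) / denom
    coh = np.nan_to_num(coh, nan=0.0)
    if cfg.estimator == "magnitude_squared":
        coh = coh**2
    c = coh[in_band].mean(axis=0)
    c = np.clip((c + c.T) / 2, 0.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CoherenceMatrix(c, epoch.channel_labels)


def build_graph(c: CoherenceMatrix, cfg: GraphConfig | None = None) -> ElectrodeGraph:
    """Threshold a coherence matrix into a binary electrode graph.

    An edge is present iff the pairwise coherence is ``>= cfg.threshold``
    (inclusive); the diagonal is ignored, so the graph is simple and an
    empty graph is a legal output.
    """
    cfg = cfg or GraphConfig()
    a = (c.values >= cfg.threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return ElectrodeGraph(a, c.channel_labels)
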