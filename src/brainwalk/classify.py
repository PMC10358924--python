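"""Pair classification: stratified CV, grid search, and the walk-length sweep.

The difference vectors ``z`` with their coordination labels feed a
gradient-boosted tree classifier (XGBoost).  Hyperparameters — number of
estimators, maximal depth, learning rate — are grid-searched; evaluation
uses stratified 3-fold cross-validation (each fold preserves the class
split, e.g. 51 positive / 129 negative per fold for the 153/387 totals of
a 540-observation dataset).  Because the classes are imbalanced, per-class
precision (PPV = TP/(TP+FP)) and recall (TPR = TP/(TP+FN)) are reported
alongside accuracy.

The walk-length sweep trains one optimized classifier per walk length and
picks the shortest length on the accuracy plateau: the smallest l whose
successor improves mean CV accuracy by less than the plateau threshold
(1 percentage point by default) — longer walks enlarge the vocabulary
exponentially without buying accuracy.

By default the grid is selected on the same folds used for reporting.
``nested=True`` switches to nested cross-validation (grid search run
inside each training split), which is methodologically safer because the
reported score then never sees the data that picked the hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from xgboost import XGBClassifier

from .awe import SamplingPlan, WalkEmbedding, enumerate_walks, sample_embedding
from .errors import ConfigError, StratificationError
from .features import ChoiceTable, PairDataset, assemble_dataset
from .signal_graph import ElectrodeGraph

__all__ = [
    "ClassifierConfig",
    "ClassMetrics",
    "GridSearchResult",
    "SweepRecord",
    "SweepResult",
    "stratified_folds",
    "grid_search_cv",
    "permutation_null",
    "select_plateau_length",
    "walk_length_sweep",
    "embeddings_for_length",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameter grids, fold count and seed for the evaluation harness."""

    n_estimators_grid: tuple[int, ...] = (50, 100, 200)
    max_depth_grid: tuple[int, ...] = (3, 5, 7)
    learning_rate_grid: tuple[float, ...] = (0.01, 0.1, 0.3)
    n_folds: int = 3
    seed: int = 0
    nested: bool = False
    group_by_pair: bool = False  # keep each player pair inside one fold
    model_factory: Callable[..., object] | None = None  # pluggable backend

    def __post_init__(self) -> None:
        if not (self.n_estimators_grid and self.max_depth_grid and self.learning_rate_grid):
            raise ConfigError("hyperparameter grids must be non-empty")
        if self.n_folds < 2:
            raise ConfigError("cross-validation needs at least 2 folds")

    @property
    def grid(self) -> list[dict]:
        return [
            {"n_estimators": n, "max_depth": d, "learning_rate": lr}
            for n, d, lr in product(
                self.n_estimators_grid, self.max_depth_grid, self.learning_rate_grid
            )
        ]

    def make_model(self, params: dict):
        if self.model_factory is not None:
            return self.model_factory(**params, random_state=self.seed)
        return XGBClassifier(
            **params,
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )


@dataclass(frozen=True)
class ClassMetrics:
    """Pooled out-of-fold confusion counts and the derived per-class rates.

    ``tp/fp/fn/tn`` are counted with coordination (label 1) as the positive
    class; per-class precision/recall for class 0 are obtained by swapping
    the roles.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def precision(self, cls: int = 1) -> float:
        num, den = (self.tp, self.tp + self.fp) if cls == 1 else (self.tn, self.tn + self.fn)
        return num / den if den else float("nan")

    def recall(self, cls: int = 1) -> float:
        num, den = (self.tp, self.tp + self.fn) if cls == 1 else (self.tn, self.tn + self.fp)
        return num / den if den else float("nan")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ClassMetrics":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_pos": self.precision(1),
            "recall_pos": self.recall(1),
            "precision_neg": self.precision(0),
            "recall_neg": self.recall(0),
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


@dataclass(frozen=True)
class GridSearchResult:
    best_params: dict
    mean_cv_accuracy: float
    metrics: ClassMetrics
    grid_accuracies: tuple[tuple[frozenset, float], ...] = ()


@dataclass(frozen=True)
class SweepRecord:
    length: int
    mean_cv_accuracy: float
    best_params: dict
    metrics: ClassMetrics


@dataclass(frozen=True)
class SweepResult:
    records: tuple[SweepRecord, ...]
    selected_length: int
    plateau_threshold: float

    def accuracy_curve(self) -> dict[int, float]:
        return {r.length: r.mean_cv_accuracy for r in self.records}


def stratified_folds(
    ds: PairDataset, k: int, seed: int, group_by_pair: bool = False
) -> np.ndarray:
    """Fold assignment (array of fold ids) preserving the class split.

    Per-fold class counts differ by at most 1 from an equal division; the
    shuffle is seeded, so the assignment is reproducible.  With
    ``group_by_pair`` every observation of one player pair (the same pair
    recurs in every game) lands in the same fold, trading exact class
    balance for pair-identity isolation.
    """
    y = ds.labels
    _check_class_sizes(y, k)
    assignment = np.empty(len(y), dtype=int)
    if group_by_pair:
        groups = np.array([f"{o.player_a}|{o.player_b}" for o in ds.observations])
        skf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros((len(y), 1)), y, groups)
    else:
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = kf.split(np.zeros((len(y), 1)), y)
    for fold, (_, test_idx) in enumerate(splits):
        assignment[test_idx] = fold
    return assignment


def _check_class_sizes(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise StratificationError("dataset contains a single class; cannot train")
    small = counts.min()
    if small < k:
        raise StratificationError(
            f"smallest class has {small} members, fewer than {k} folds"
        )


def _grid_mean_accuracies(
    X: np.ndarray, y: np.ndarray, folds: np.ndarray, cfg: ClassifierConfig
) -> list[tuple[dict, float]]:
    out = []
    k = folds.max() + 1
    for params in cfg.grid:
        accs = []
        for f in range(k):
            tr, te = folds != f, folds == f
            model = cfg.make_model(params)
            model.fit(X[tr], y[tr])
            accs.append(float(np.mean(model.predict(X[te]) == y[te])))
        out.append((params, float(np.mean(accs))))
    return out


def _oof_predictions(
    X: np.ndarray, y: np.ndarray, folds: np.ndarray, cfg: ClassifierConfig, params: dict
) -> np.ndarray:
    pred = np.empty_like(y)
    for f in range(folds.max() + 1):
        tr, te = folds != f, folds == f
        model = cfg.make_model(params)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return pred


def grid_search_cv(ds: PairDataset, cfg: ClassifierConfig | None = None) -> GridSearchResult:
    """Grid-search the classifier and report pooled out-of-fold metrics.

    Flat mode (default): every grid point is scored by mean accuracy over
    the k stratified folds; the argmax configuration (first in grid order
    on ties) is refit per fold to pool out-of-fold predictions into one
    confusion matrix.  Nested mode: an inner grid search runs on each
    training split, so each fold may select different hyperparameters and
    the pooled score is selection-free; ``best_params`` is then the most
    frequently selected configuration.
    """
    cfg = cfg or ClassifierConfig()
    X, y = ds.feature_matrix, ds.labels
    folds = stratified_folds(ds, cfg.n_folds, cfg.seed, cfg.group_by_pair)

    if not cfg.nested:
        scored = _grid_mean_accuracies(X, y, folds, cfg)
        best_params, best_acc = max(scored, key=lambda t: t[1])
        pred = _oof_predictions(X, y, folds, cfg, best_params)
        metrics = ClassMetrics.from_predictions(y, pred)
        grid_acc = tuple((frozenset(p.items()), a) for p, a in scored)
        return GridSearchResult(best_params, best_acc, metrics, grid_acc)

    pred = np.empty_like(y)
    chosen: list[dict] = []
    for f in range(cfg.n_folds):
        tr, te = folds != f, folds == f
        inner_ds = PairDataset([ds.observations[i] for i in np.nonzero(tr)[0]])
        inner_folds = stratified_folds(inner_ds, cfg.n_folds, cfg.seed + 1, cfg.group_by_pair)
        scored = _grid_mean_accuracies(X[tr], y[tr], inner_folds, cfg)
        params, _ = max(scored, key=lambda t: t[1])
        chosen.append(params)
        model = cfg.make_model(params)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    metrics = ClassMetrics.from_predictions(y, pred)
    keys = [tuple(sorted(p.items())) for p in chosen]
    best = dict(max(set(keys), key=keys.count))
    return GridSearchResult(best, metrics.accuracy, metrics)


def permutation_null(
    ds: PairDataset,
    params: dict,
    n_repeats: int = 20,
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """CV accuracies with labels randomly permuted; the chance baseline.

    Features are left untouched and labels are shuffled, so any real
    signal is destroyed; the mean of the returned accuracies should sit
    near the majority-class rate.
    """
    cfg = cfg or ClassifierConfig()
    X, y = ds.feature_matrix, ds.labels
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_repeats):
        yp = rng.permutation(y)
        skf = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
        fold_accs = []
        for tr, te in skf.split(X, yp):
            model = cfg.make_model(params)
            model.fit(X[tr], yp[tr])
            fold_accs.append(float(np.mean(model.predict(X[te]) == yp[te])))
        accs.append(float(np.mean(fold_accs)))
    return np.array(accs)


def embeddings_for_length(
    graphs: Mapping[tuple[str, str], ElectrodeGraph],
    length: int,
    epsilon: float = 0.1,
    delta: float = 0.01,
    seed: int = 0,
) -> dict[tuple[str, str], WalkEmbedding]:
    """Sampled embeddings for every (player, game) graph at one walk length.

    The Monte-Carlo budget m comes from the sampling bound at (epsilon,
    delta) for this length's vocabulary; each graph gets a distinct
    deterministic sub-seed derived from ``seed``.
    """
    plan = SamplingPlan.for_vocabulary(enumerate_walks(length).size, epsilon, delta)
    out = {}
    for i, key in enumerate(sorted(graphs)):
        sub = np.random.SeedSequence((seed, length, i)).generate_state(1)[0] % (2**31)
        out[key] = sample_embedding(graphs[key], length, plan, seed=int(sub))
    return out


def select_plateau_length(
    curve: Mapping[int, float] | Sequence[tuple[int, float]], threshold: float = 0.01
) -> int:
    """Shortest walk length on the accuracy plateau.

    Returns the smallest l whose successor improves mean accuracy by less
    than ``threshold``; if every gain clears the threshold, the largest l.
    """
    items = sorted(dict(curve).items())
    if not items:
        raise ConfigError("empty accuracy curve")
    for (l, acc), (_, nxt) in zip(items, items[1:]):
        if nxt - acc < threshold:
            return l
    return items[-1][0]


def walk_length_sweep(
    graphs: Mapping[tuple[str, str], ElectrodeGraph],
    choices: ChoiceTable,
    lengths: Sequence[int],
    cfg: ClassifierConfig | None = None,
    plateau_threshold: float = 0.01,
    epsilon: float = 0.1,
    delta: float = 0.01,
) -> SweepResult:
    """Train one optimized classifier per walk length and pick the plateau.

    ``selected_length`` is the smallest l in the sweep whose successor
    improves mean CV accuracy by less than ``plateau_threshold`` (a flat
    curve selects the smallest l; gains above threshold everywhere select
    the largest).
    """
    lengths = sorted(set(lengths))
    if not lengths:
        raise ConfigError("walk-length sweep needs a non-empty range")
    cfg = cfg or ClassifierConfig()
    records = []
    for l in lengths:
        emb = embeddings_for_length(graphs, l, epsilon, delta, seed=cfg.seed)
        ds = assemble_dataset(emb, choices)
        res = grid_search_cv(ds, cfg)
        records.append(SweepRecord(l, res.mean_cv_accuracy, res.best_params, res.metrics))
    selected = select_plateau_length({r.length: r.mean_cv_accuracy for r in records},
                                     plateau_threshold)
    return SweepResult(tuple(records), selected, plateau_threshold)
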