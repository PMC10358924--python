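"""Stratified folds, grid-searched CV, metrics and the walk-length sweep."""

import numpy as np
import pytest

from brainwalk import (
    ChoiceTable,
    ClassifierConfig,
    PairDataset,
    PairObservation,
    StratificationError,
    WalkEmbedding,
    grid_search_cv,
    permutation_null,
    stratified_folds,
    walk_length_sweep,
)
from brainwalk.classify import ClassMetrics
from brainwalk.features import assemble_dataset

SMALL = ClassifierConfig(
    n_estimators_grid=(25, 50), max_depth_grid=(2, 3), learning_rate_grid=(0.3,), seed=0
)


def toy_dataset(n_pos, n_neg, separation, seed=0, noise=0.05):
    """Positive pairs have near-zero z, negative pairs z shifted by `separation`."""
    rng = np.random.default_rng(seed)
    obs = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        z = np.abs(rng.normal(0 if label else separation, noise, size=6))
        obs.append(PairObservation(f"a{i:03d}", f"b{i:03d}", "g1", z, label))
    return PairDataset(obs)


# ------------------------------------------------------------------ folds

def test_fold_class_counts_for_printed_totals():
    """153 positives / 387 negatives in 3 folds -> 51 + 129 per fold."""
    ds = toy_dataset(153, 387, 1.0)
    folds = stratified_folds(ds, 3, seed=0)
    y = ds.labels
    for f in range(3):
        assert np.sum(y[folds == f] == 1) == 51
        assert np.sum(y[folds == f] == 0) == 129


def test_exact_division_small_dataset():
    ds = toy_dataset(3, 3, 1.0)
    folds = stratified_folds(ds, 3, seed=1)
    y = ds.labels
    for f in range(3):
        assert np.sum(y[folds == f] == 1) == 1 and np.sum(y[folds == f] == 0) == 1


def test_fold_assignment_is_seed_deterministic():
    ds = toy_dataset(30, 60, 1.0)
    a = stratified_folds(ds, 3, seed=5)
    b = stratified_folds(ds, 3, seed=5)
    c = stratified_folds(ds, 3, seed=6)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_class_smaller_than_k_rejected():
    ds = toy_dataset(2, 30, 1.0)
    with pytest.raises(StratificationError):
        stratified_folds(ds, 3, seed=0)


# ---------------------------------------------------------------- metrics

def test_metrics_from_confusion_counts():
    m = ClassMetrics(tp=40, fp=10, fn=10, tn=120)
    assert m.precision(1) == pytest.approx(0.8)
    assert m.recall(1) == pytest.approx(0.8)
    assert m.accuracy == pytest.approx(160 / 180)
    assert m.n == 180


# ------------------------------------------------------------ grid search

def test_separable_dataset_is_classified_perfectly():
    ds = toy_dataset(60, 120, 5.0, noise=0.0)
    res = grid_search_cv(ds, SMALL)
    assert res.mean_cv_accuracy == 1.0
    assert res.metrics.precision(1) == 1.0 and res.metrics.precision(0) == 1.0


def test_out_of_fold_counts_cover_every_observation():
    ds = toy_dataset(30, 90, 0.5, seed=3)
    res = grid_search_cv(ds, SMALL)
    m = res.metrics
    assert m.n == len(ds)
    assert m.tp + m.fn == ds.n_positive
    assert m.tn + m.fp == ds.n_negative
    assert m.accuracy == pytest.approx((m.tp + m.tn) / len(ds))


def test_grid_search_is_reproducible():
    ds = toy_dataset(30, 60, 0.8, seed=2)
    r1 = grid_search_cv(ds, SMALL)
    r2 = grid_search_cv(ds, SMALL)
    assert r1.best_params == r2.best_params
    assert r1.mean_cv_accuracy == r2.mean_cv_accuracy
    assert r1.metrics == r2.metrics


def test_single_class_dataset_rejected():
    ds = toy_dataset(30, 0, 1.0)
    with pytest.raises(StratificationError):
        grid_search_cv(ds, SMALL)


def test_nested_mode_runs_and_reports_full_coverage():
    ds = toy_dataset(30, 60, 2.0, seed=4)
    res = grid_search_cv(ds, ClassifierConfig(
        n_estimators_grid=(25,), max_depth_grid=(2, 3), learning_rate_grid=(0.3,),
        nested=True, seed=0,
    ))
    assert res.metrics.n == len(ds)
    assert res.mean_cv_accuracy > 0.9


def test_permuted_labels_fall_to_majority_rate():
    """Shuffling labels on informative features destroys the signal: mean
    accuracy lands within 5 points of the majority-class rate."""
    ds = toy_dataset(153, 387, 3.0, seed=5)
    null = permutation_null(ds, {"n_estimators": 25, "max_depth": 2, "learning_rate": 0.3},
                            n_repeats=20, cfg=SMALL, seed=0)
    majority = 387 / 540
    assert abs(null.mean() - majority) < 0.05


# ------------------------------------------------------------------ sweep

def sweep_inputs(seed=0):
    """Tiny synthetic scenario for sweep tests."""
    from brainwalk import ScenarioConfig, generate_scenario

    cfg = ScenarioConfig(n_players=6, n_games=4, seed=seed)
    choices, graphs, _ = generate_scenario(cfg)
    return graphs, choices


def test_sweep_produces_one_record_per_length_and_selects_in_range():
    graphs, choices = sweep_inputs()
    res = walk_length_sweep(graphs, choices, [2, 3, 4], SMALL)
    assert [r.length for r in res.records] == [2, 3, 4]
    assert res.selected_length in (2, 3, 4)


def test_plateau_selection_rules():
    from brainwalk.classify import select_plateau_length

    assert select_plateau_length({1: 0.7, 2: 0.7, 3: 0.7}) == 1  # flat from the start
    assert select_plateau_length({1: 0.6, 2: 0.7, 3: 0.8}) == 3  # gains everywhere
    assert select_plateau_length({1: 0.6, 2: 0.75, 3: 0.752}) == 2  # plateau after jump
    assert select_plateau_length({5: 0.8}) == 5  # single point


def test_empty_sweep_range_rejected():
    graphs, choices = sweep_inputs()
    from brainwalk import ConfigError

    with pytest.raises(ConfigError):
        walk_length_sweep(graphs, choices, [], SMALL)


def test_group_by_pair_keeps_each_pair_in_one_fold():
    """With pair grouping, all 12 games of one player pair share a fold, so
    pair identity cannot leak between training and test splits."""
    graphs, choices = sweep_inputs()
    from brainwalk import assemble_dataset, embeddings_for_length

    ds = assemble_dataset(embeddings_for_length(graphs, 2, seed=0), choices)
    folds = stratified_folds(ds, 3, seed=0, group_by_pair=True)
    seen = {}
    for o, f in zip(ds.observations, folds):
        key = (o.player_a, o.player_b)
        assert seen.setdefault(key, f) == f
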