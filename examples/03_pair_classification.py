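"""End-to-end coordination prediction on a synthetic study.

Generates the default scenario (10 players x 12 games, 4 options, strong
focal points, 5% edge-flip noise), embeds every player's coherence graph
with length-5 anonymous walks, forms z = |e1 - e2| for each of the 540
player pairs per game, and trains a grid-searched gradient-boosted tree
classifier under stratified 3-fold cross-validation.
"""

from brainwalk import (
    ClassifierConfig,
    ScenarioConfig,
    assemble_dataset,
    embeddings_for_length,
    generate_scenario,
    grid_search_cv,
    permutation_null,
)

seed = 0
cfg = ScenarioConfig(seed=seed)
choices, graphs, _ = generate_scenario(cfg)
emb = embeddings_for_length(graphs, length=5, seed=seed)
ds = assemble_dataset(emb, choices)
print(f"dataset: {len(ds)} observations "
      f"({ds.n_positive} coordination, {ds.n_negative} no-coordination)")

res = grid_search_cv(ds, ClassifierConfig(seed=seed))
m = res.metrics
majority = max(ds.n_positive, ds.n_negative) / len(ds)
print(f"mean CV accuracy: {100 * res.mean_cv_accuracy:.2f}% "
      f"(majority-class rate {100 * majority:.2f}%)")
print(f"best hyperparameters: {res.best_params}")
print(f"no-coordination class: precision {100 * m.precision(0):.2f}%, "
      f"recall {100 * m.recall(0):.2f}%")
print(f"coordination class:    precision {100 * m.precision(1):.2f}%, "
      f"recall {100 * m.recall(1):.2f}%")

null = permutation_null(ds, res.best_params, n_repeats=5,
                        cfg=ClassifierConfig(seed=seed), seed=seed)
print(f"permuted-label null accuracy: {100 * null.mean():.2f}% "
      f"— the gap above it is the recovered coordination signal")
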