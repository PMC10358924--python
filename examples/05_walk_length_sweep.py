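"""Walk-length selection: accuracy as a function of anonymous-walk length.

One optimized classifier is trained per walk length; the selected length
is the shortest one on the accuracy plateau (successor gain below 1
percentage point).  Longer walks grow the pattern vocabulary exponentially
(2, 5, 15, 52, 203 for l = 2..6), so stopping at the plateau keeps the
embedding compact.  A reduced scenario and grid keep this demo quick.
"""

from brainwalk import ClassifierConfig, ScenarioConfig, generate_scenario, walk_length_sweep

seed = 0
cfg = ScenarioConfig(n_players=8, n_games=8, seed=seed)
choices, graphs, _ = generate_scenario(cfg)

clf = ClassifierConfig(
    n_estimators_grid=(50, 100), max_depth_grid=(3, 5), learning_rate_grid=(0.1, 0.3),
    seed=seed,
)
res = walk_length_sweep(graphs, choices, lengths=range(2, 7), cfg=clf)

print("walk length -> mean CV accuracy")
for rec in res.records:
    mark = "  <- selected" if rec.length == res.selected_length else ""
    print(f"  l={rec.length}: {100 * rec.mean_cv_accuracy:.2f}%{mark}")
print(f"selected walk length: {res.selected_length} "
      f"(plateau threshold {100 * res.plateau_threshold:.0f} percentage point)")
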