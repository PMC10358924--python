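# Methods

## Model and procedure

`brainwalk` operationalizes inter-brain similarity without simultaneous
recording. Each player's 1-second task epoch becomes an undirected binary
graph on the EEG electrodes (nodes = electrodes, edges = pairs whose
band-averaged coherence reaches a threshold), each graph becomes a
probability distribution over anonymous-walk patterns, and a supervised
classifier maps the element-wise absolute difference of two players'
distributions to a binary coordination outcome. The central modeling
assumptions are:

- **Spatial, not spectral, similarity carries the signal.** Only the
  thresholded topology of the coherence graph enters the embedding;
  electrode identities, frequencies and amplitudes are all discarded.
- **Anonymity is the right invariance.** Anonymous walks encode revisit
  structure only, so the fingerprint is invariant under any relabeling of
  electrodes; two players with isomorphic networks have identical
  embeddings by construction.
- **Coordination ≈ network similarity.** Players who converge on the same
  focal option are assumed to exhibit more similar network configurations
  than players who diverge; the classifier has signal exactly insofar as
  this holds.

## Signal conditioning and coherence

Pipeline order: zero-phase Butterworth band-pass (order 4, 1–32 Hz) →
integer decimation to 64 Hz → crop to the epoch length → common-average
reference → per-channel epoch-mean baseline. With the reference applied
before the baseline, both the per-sample channel mean and the per-channel
temporal mean are exactly zero on output. Non-integer decimation factors
and epochs shorter than the window are hard errors. Independent-component
artifact rejection is out of scope (it is a manual, rater-dependent step);
epochs from real recordings should be cleaned upstream.

Coherence is the magnitude of the Welch-estimated complex coherency
(magnitude-squared available as an option), averaged over the frequency
bins inside the analysis band (default 1–32 Hz). Welch defaults — Hann
window, 32-sample segments, 16-sample overlap — give three segments on a
64-sample epoch. Three-segment coherence estimates are strongly biased
upward (independent white noise averages ≈ 0.55), which makes 1-second
epochs produce dense graphs at the 0.5 threshold; this is an inherent
property of short-epoch coherence, not a defect, and all segmentation
parameters are exposed for longer epochs (a 10-s surrogate epoch yields
≈ 0.15 for independent noise and an empty recovered graph). Constant
channels make coherence undefined and raise an error naming the channel.

## Anonymous-walk embeddings

A walk of length `l` traverses `l` edges and visits `l+1` node slots;
patterns are canonicalized by order of first appearance starting at 1.
This edge-counting convention matters: it makes the length-5 vocabulary
contain 52 patterns. The vocabulary is enumerated depth-first in
lexicographic order, which fixes the coordinate system of every embedding;
an independent recursion `a(t+1,k) = a(t,k)(k−1) + a(t,k−1)` (patterns of
length `t` on exactly `k` labels) cross-checks the counts.

Walk dynamics: the start node is uniform over nodes of degree ≥ 1
(isolated nodes can begin no walk), each step is uniform over the current
node's neighbors, immediate backtracking is allowed, and sampled walks
restart independently. An edgeless graph raises an error rather than
returning a zero vector, which would silently violate normalization.

The exact distribution is computed by brute-force walk enumeration with
per-pattern accumulation keyed by the integer product of step degrees and
a correctly rounded (`fsum`) final summation — this makes the result
bit-identical under node permutation, with cost growing as ~n·d^l (an
oracle for short walks and small graphs, and the ground truth for the
sampler). The Monte-Carlo estimator performs
`m = ⌈(2/ε²)(ln(2^N − 2) − ln δ)⌉` walks — natural logarithms, ceiling
because the bound is a minimum, and `ln(2^N − 2)` evaluated stably as
`N·ln 2 + log1p(−2^{1−N})`. Sampling is vectorized (padded neighbor
arrays, column-wise canonicalization), and the per-call seed is recorded
in the returned embedding.

## Pair dataset and baseline

Pairs are unordered (players sorted by identifier); `z = |e₁ − e₂|` is
symmetric so orientation is irrelevant. A missing (player, game) entry is
a hard error by default; a lenient mode drops only the affected pairs
with a logged warning. The Bag-of-Node-Degree baseline is the normalized
degree histogram (length n over degrees 0…n−1); it is served through the
same dataset assembly and classifier so the comparison isolates the
embedding.

## Classification harness

Defaults: XGBoost (`hist`, single-thread, seeded) over the grid
n_estimators ∈ {50, 100, 200}, max_depth ∈ {3, 5, 7}, learning_rate ∈
{0.01, 0.1, 0.3}; stratified 3-fold cross-validation (per-fold class
counts within 1 of equal division; 153/387 totals split 51/129). Grid
selection on the same folds used for reporting matches the apparent
original protocol; a nested mode (inner grid search per training split)
is provided and is the methodologically safer choice since its pooled
out-of-fold score never sees the data that picked the hyperparameters.
Folds stratify by class only by default — player overlap across folds can
leak identity information, a caveat inherited from the protocol being
mirrored; `group_by_pair=True` keeps all twelve games of one player pair
inside a single fold (via stratified group K-fold), trading exact class
balance for pair-identity isolation. The backend is pluggable
behind a fit/predict factory, so other model families can be swapped in
for comparison.

The walk-length sweep trains one optimized classifier per length and
selects the smallest length whose successor improves mean CV accuracy by
less than 1 percentage point (configurable); a flat curve selects the
smallest length in range, and gains above threshold everywhere select the
largest.

## Synthetic-data generator

The generator emulates the study design: 10 players, 12 games, 4 options,
one 1-s epoch per (player, game) at 512 Hz. Defaults and their rationale:

- **Salience (0.40, 0.25, 0.20, 0.15).** A strong focal option first;
  the expected pair-coordination rate Σp² = 0.285 reproduces the ≈ 28%
  positive rate of a 540-observation pair dataset with a 153/387-style
  class imbalance.
- **Templates.** One fixed random template per (game, option). Template
  density is drawn per option from `template_density ± density_spread/2`
  (default 0.3 ± 0.15): distinct solutions are modeled as distinct global
  synchronization levels, so different options' networks differ in
  density as well as wiring. This matters because equal-density
  Erdős–Rényi graphs concentrate: their anonymous-walk distributions are
  nearly identical, leaving almost no between-option signal regardless of
  embedding quality.
- **Player noise (`flip_prob_same` = 0.05).** Each edge indicator of the
  player's option template flips independently; symmetric flips keep
  expected density stable. At 0.5 the player's graph is independent of
  the template and all class signal vanishes.
- **Cross-option coupling (`flip_prob_diff` = 0.5).** Each template edge
  is copied from a per-game base with probability 1 − 2·flip_prob_diff
  and resampled at the option's own density otherwise: 0.5 gives mutually
  independent option templates, 0 identical ones (harder tasks in
  between).
- **Signal synthesis (`snr` = 3).** Each edge carries a narrow-band
  (4–30 Hz) random-phase source injected into its two endpoints in
  antiphase — dipole-like, so the source cancels exactly in the
  common-average reference instead of leaking shared variance into every
  channel — plus unit white noise per channel. Because edge sources are
  independent, the recoverable pairwise coherence falls roughly as
  snr²/degree; the 0.5 threshold cleanly recovers low-degree couplings,
  and 1-s epochs additionally carry the few-segment bias above. The fast
  graph-level path (templates + flips, no signals) is therefore the
  default for embedding/classification experiments, with the signal path
  exercising the conditioning and coherence stages.

Everything is deterministic under the scenario seed via purpose-keyed
seed sequences, so a (game, option) template is identical no matter which
player asks for it or in what order.

**What passing synthetic tests do not show:** the generator has no volume
conduction, no 1/f spectrum, no artifacts, no inter-epoch nonstationarity
and no behavioral structure beyond per-game salience. Recovery on this
data demonstrates that the pipeline's machinery is correct and that the
method detects planted network similarity at realistic noise levels — it
does not certify the headline accuracy obtainable on real recordings.

## Numerical choices and problem sizes

- Exact embeddings are bit-stable under relabeling (degree-product
  bucketing + `fsum`); tests assert exact equality, not tolerance.
- Sampled embeddings sum to exactly k/m; the exact oracle to within 1e−9.
- Embedding/choice/dataset text round-trips are bit-exact for labels and
  integers and within 1e−12 for reals (17-significant-digit output).
- Ties in grid search resolve to the first configuration in deterministic
  grid order.
- Routine checks use walk length 3–5, 6–16-node graphs, and the default
  540-observation scenario; exact-embedding checks use length 3 on
  16-node graphs, where brute-force enumeration is comfortably fast. The
  default-scenario CV accuracy is ≈ 82–85% with seed-to-seed variability
  of roughly ±3 percentage points.

## Known limitations

- Welch coherence on 1-s, 64-sample epochs is heavily biased; graphs
  derived from such epochs are density-inflated. Mitigations: longer
  epochs, different segmentation, or a higher threshold.
- The flat (non-nested) grid-search mode mildly overstates accuracy by
  construction; use `nested=True` for honest generalization estimates.
- The "spirally" degree-measurement variant of the Bag-of-Node-Degree is
  not well defined; the normalized degree histogram is used.
- EDF support is read-only and optional (`mne`); delimited text is the
  first-class interchange format.
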