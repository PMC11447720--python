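# Methods

## Scope and data model

The package targets dense HTE reaction tables: one row per reaction, one
SMILES column per reaction role, one numeric yield column in percent.
Components are heavy-atom graphs (implicit hydrogens, standard ECFP/Mol2Vec
practice); salts stay one graph with disconnected fragments. A component may
be ABSENT (a "none" cell, e.g. a ligand-free reaction); it is represented
without a graph and contributes a single all-zero pseudo-atom row to the
model input, before the role embedding is added, so downstream shapes stay
valid. Registry lookups are always by canonical SMILES, never by the input
string.

## Atom-environment identifiers

Per-atom identifiers at radii 0–3 are computed by iterated neighbourhood
hashing on the parsed graph: radius 0 hashes (element, formal charge,
aromaticity, heavy-atom degree); radius r+1 hashes the radius-r identifier
with the sorted multiset of (bond order, neighbour radius-r identifier).
Hashes are 32-bit truncations of blake2b, so identifiers are stable across
runs and platforms, invariant to input atom order, and equal for
automorphic atoms. Computing them in-package (rather than through a
fingerprint library) matters because contrastive augmentation deletes atoms
and the pruned remnant need not be a valid molecule — identifiers must still
be recomputable on it. The descriptor baselines use standard RDKit Morgan
hashes instead, keeping the two code paths independent.

Identifier vectors: a pretrained atom-environment table is an
optional input; by default the identifier embedding table is learned
end-to-end, with the per-atom input vector the **sum** of the four radius
embeddings. Identifiers unseen at fit time map to a dedicated UNK row —
unavoidable under extrapolation splits — and a MASK row serves the
atom-masking augmentation.

## Architecture

One MPNN shared by all components: input projection of the summed identifier
embeddings to width `d_hidden`, then `L` rounds of message passing. The
message function is a linear map of (neighbour state ⊕ bond-type embedding),
aggregation is a sum over neighbours, and the update is a GRU cell with
weights shared across rounds (`mpnn_update: linear` swaps in a plain linear
update, used by the dense-adjacency oracle tests). `L = 0` reduces to the
input projection.

The per-component atom matrices are concatenated row-wise; each row receives
the additive role embedding of its component, once, before the first encoder
block. The encoder applies `N` blocks of multi-head self-attention with a
residual connection and layer normalisation; no positional encoding and no
feed-forward sublayer, so the encoder is exactly permutation-equivariant
over rows. Readout is a column-wise sum over all (unmasked) rows followed by
a two-layer MLP. Batches pad to the longest reaction; padded rows are
excluded from attention (additive −1e30 logit bias) and from the readout
sum, which the tests verify by comparing batched against per-reaction
forward passes.

Yields are trained on the unit scale (percent / 100) and reported in
percent.

### Initialisation

The output layer of the readout MLP is zero-initialised and its bias set to
the training-mean yield at the start of `train_model`. Because the readout
is a sum over a variable number of rows, a generically initialised output
layer gives the first predictions a seed-dependent scale (observed
first-epoch validation MSE varying by three orders of magnitude across
seeds), and some seeds then converge much more slowly. Starting every seed
from the constant mean predictor removes that variance; gradients reach the
lower layers from the second optimizer step on.

### Defaults

All hyper-parameter defaults are implementation choices exposed in
`ModelConfig`, not reference values: `d_embed = d_hidden = 128`, `L = 3`,
`N = 2`, 4 heads, dropout 0.1, Adam with lr 1e-3, batch 32, early stopping
on a seeded 10 % validation split with patience 10 (best parameters
restored). Tests and the acceptance script use scaled-down widths
(`d = 16–32`, `L = 2`, `N = 1`) to stay inside CPU budgets; the scaling is
in the config, never in the algorithms.

## Contrastive pretraining

Corpus molecules are filtered to 10–30 heavy atoms inclusive; unparsable
entries are dropped and counted. Per batch, each molecule receives two
independent augmentations; embeddings are sum-pooled MPNN states passed
through a two-layer projection head (discarded after pretraining, the usual
contrastive-learning convention), and the loss is NT-Xent over cosine
similarities with temperature 0.1 by default: each anchor's softmax runs
over the other 2B−1 views, positives being the sibling view of the same
molecule. With two orthogonal unit pairs at τ = 1 the per-anchor loss is
−log(e/(e+2)), which the tests assert in closed form.

Augmentations and their conventions (`ratio` defaults to 0.25 for every
method; ceilings are used wherever a fraction of a count is needed):

- **atom masking** — ⌈ratio·n⌉ atoms' identifier tuples replaced by MASK;
- **bond deletion** — ⌈ratio·|E|⌉ bonds removed;
- **subgraph removal** — one connected ⌈ratio·n⌉-atom region grown
  breadth-first from a random seed atom, deleted;
- **mini-subgraph removal** — repeat {pick a random surviving center,
  delete it and its radius-1 neighbours} and stop at the first repetition
  at which the deleted count reaches the target (overshoot within the last
  closed neighbourhood is accepted; centers are drawn uniformly from
  surviving atoms).

Deleted atoms are removed, not masked; the remnant may be disconnected and
is kept as is, with identifiers recomputed on the pruned topology. A
deletion that would consume the whole graph is rejected at the ratio check,
and as a second guard the last neighbourhood stops one atom short of
emptying the graph.

Loading a checkpoint into supervised training initialises the MPNN only
(embedding rows remapped by identifier; identifiers new to the supervised
set keep fresh initialisation); encoder and MLP always start fresh. Whether
the embedding table should be frozen afterwards is left to the caller — both
modes work, since the table is an ordinary parameter.

## Splits

- **Random ratio** — seeded permutation; the train count is
  round-half-up of ratio·n (reference row counts at extreme ratios are not
  mutually consistent under any single rounding rule, so the realised sizes
  are recorded in the manifest). The optional coverage restriction for
  extreme ratios (every training compound must also occur in the test
  partition) is implemented by rejection sampling with a bounded retry
  budget (default 1000) — the restriction is stated as a property, not a
  mechanism, and rejection sampling is the least-structured mechanism that
  satisfies it.
- **Component-out** — test = all reactions containing any held-out
  structure under the role; single-role and multi-role variants (the
  organoboron-out and two-random-ligands-out families are expressed through
  these, with no special-case code).
- **sTest** — per (ligand, halide-triad) pair: test is the full cross of
  the ligand × the 3-halide triad × 5 fixed additives × all bases; training
  excludes any reaction containing *any* held-out component, so rows sharing
  some but not all held-out components belong to neither partition. Triads
  are user-supplied (the scaffold grouping is domain knowledge, not
  auto-detectable).

`leakage_scan` re-derives the held-out set from the split manifest and
brute-force scans training rows; it is the invariant check for every
component-out family.

## Baselines

ECFP6 spaces are built on the training partition only (leakage-safe; a
joint-build mode is not provided because it would silently peek at test
chemistry). Bits are presence bits. Hashes first seen at prediction time are
dropped and counted on the space (`dropped_novel`) — under component-out
splits this is a real, measurable event, not an error. One-hot dimensions
default to the per-role vocabulary size; random vectors are standard normal
draws, seed-reproducible. Forest = 500 trees; boosting =
histogram-gradient-boosted trees with native early stopping, tuned by seeded
3-fold CV over a small documented grid (learning rate {0.05, 0.1} × depth
{3, 6}).

## Evaluation

R² is the coefficient of determination (not squared correlation); it is
undefined for constant observations (error) and may be negative. The
ensemble protocol trains `pool_size` models with seeds 0..pool−1 (shared
across methods), samples `members_per_ensemble` without replacement per
ensemble, averages member predictions, and reports mean (SD) over
ensemble-level R². Defaults follow the 50-model pool / 10-member / 5-ensemble
protocol; the CI-scale defaults in the CLI are pool 6 / members 3 /
ensembles 2. For random-ratio families a single ensemble is conventional.

`component_swap_correlation` pairs reactions identical in every role except
the probed one and returns (n pairs, Pearson r, r²); both statistics are
returned because the two are easily conflated in the literature this
analysis style comes from. Fewer than 3 pairs is an error.
`groupwise_yield_summary` emits tidy five-number summaries per group
structure, split by membership of a marker set — the tabular form of the
box-plot outlier analysis; plotting is deliberately out of scope.

## Synthetic fixtures

The generator enumerates the full cross of per-role vocabularies and draws
yields from clip(base + Σ per-component effects + pairwise interactions +
N(0, σ), 0, 100). Defaults: base 30, noise σ = 5 yield points, effect
spreads per role (halide ±15, additive ±20, ligand ±15, base ±10) — chosen
once as a realistic spread for a cross-coupling screen where additives and
catalysts dominate yield variation. The BHC-shaped spec (15 halides in 5
scaffold triads × 22 isoxazole additives × 4 phosphine ligands × 3 amidine
bases = 3960 rows) mirrors the combinatorial geometry the split
constructions assume. Vocabularies are real small molecules so charges,
aromaticity and salt handling are exercised.

What a green test on these fixtures establishes: the pipeline recovers a
known additive law from graphs, splits have exactly the stated structure,
and invariances hold. What it does not establish: performance on real HTE
chemistry — real yields are not additive, carry heteroscedastic noise and
heavy censoring at 0 %, and real extrapolation difficulty depends on
chemical similarity, none of which the generator models (`clipped_fraction`
in the truth record is the only censoring the fixture has).

## Numerical choices

Everything runs in float64 on a minimal reverse-mode autodiff engine
(`autodiff.py`); gradients of every primitive are tested against finite
differences. Attention masking uses an additive −1e30 bias; softmax and
log-sum-exp are max-shifted. Prediction invariance tolerances in the tests
are 1e-4 on the percent scale, far above float64 associativity noise.
Determinism: every stochastic step (init, batching, dropout, validation
split, augmentation, ensemble member selection) draws from a seeded
generator; identical seeds give bitwise-identical parameter trajectories.

## Known limitations

- No stereochemistry, conformers, or atom-mapping; graphs are 2-D topology.
- The identifier hash is 32-bit; collisions are possible in principle and
  harmless in practice (they merge two embedding rows).
- Training is CPU-bound NumPy; the design point is desk-scale experiments
  (thousands of reactions, widths ≤ 128), not the full-corpus pretraining
  regime, for which the checkpoint interface accepts externally trained
  weights.
- The boosting grid is intentionally small; it is a baseline, not a tuned
  competitor.
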