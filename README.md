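# hteyield

Graph-based yield prediction for high-throughput experimentation (HTE)
reaction datasets.

HTE screens enumerate combinations of reaction components — aryl halides,
additives, ligands, bases, organoboron reagents — under fixed conditions and
record a yield (in percent) for every combination. `hteyield` predicts those
yields directly from the chemical graphs of the components, and provides the
full workflow around the model: rigorous train/test split constructions
(including component hold-outs that test extrapolation to unseen reagents),
contrastive pretraining on unlabelled compound corpora, descriptor baselines,
seed-pool ensembling, and outlier/correlation analyses. A synthetic fixture
generator produces HTE-shaped tables with a known yield law so every stage is
testable without external data.

## The model

Each reaction component is parsed into a heavy-atom molecular graph. Every
atom is keyed by four circular-substructure identifiers (radii 0–3, in the
spirit of Mol2Vec/ECFP atom environments); its input vector is the sum of the
four identifier embeddings. A single message-passing network (MPNN), shared
by all components, updates atom states *L* times:

    m_i^(t)  =  Σ_{j ∈ N(i)}  W [ h_j^(t) ; e_b(i,j) ]
    h_i^(t+1) =  GRU(m_i^(t), h_i^(t))

where `e_b` is a bond-type embedding. The per-component atom matrices are
concatenated row-wise, a learned **role embedding** (one vector per reaction
role) is added to every row of its component, and *N* transformer-encoder
blocks — multi-head self-attention followed by layer normalisation, with no
positional encoding — model interactions between atoms of different
components. The encoder output is vectorised by summation over rows and an
MLP maps it to the yield. Sum pooling and position-free attention make the
prediction invariant to component order and atom order by construction.

The MPNN can be pretrained on an unlabelled corpus (filtered to 10–30 heavy
atoms) with an NT-Xent contrastive objective over pairs of augmented graph
views. Besides the standard atom masking, bond deletion and subgraph
removal, the package implements **mini-subgraph removal**: repeatedly delete
a random atom together with its radius-1 neighbours until at least
⌈0.25·n⌉ atoms are gone — many small local deletions instead of one large
one, so the radius-3 atom environments of the survivors retain information
about what was removed.

Baselines: collision-free per-role ECFP6 reaction descriptors (observed
Morgan hashes renumbered in decreasing order, one dedicated bit per
environment, concatenated across roles) and one-hot / random-vector compound
codebooks, fed to random-forest (500 trees) or gradient-boosted regressors.

Evaluation uses the coefficient of determination R² = 1 − SSres/SStot and a
seed-pool ensemble protocol: train a pool of models differing only in seed,
average members sampled without replacement, and report mean (SD) of the
ensemble-level R².

## Worked example

```python
import dataclasses
import numpy as np
import hteyield as hy
from hteyield.model import ModelConfig, train_model

# a 5 x 5 x 4 x 4 = 400-reaction additive-law screen, zero noise
ds, truth = hy.generate_fixture(hy.small_additive_spec(noise_sd=0.0, seed=1))
split = hy.random_split(ds, (70, 30), seed=1)
train, test = ds.subset(split.train_idx), [ds.reactions[i] for i in split.test_idx]
obs = np.array([r.yield_pct for r in test])

cfg = ModelConfig(d_embed=32, d_hidden=32, L=2, N=1, n_heads=4, d_mlp=32,
                  dropout=0.0, lr=3e-3, batch_size=32, max_epochs=60, patience=15)
members = [train_model(train, dataclasses.replace(cfg, seed=s)) for s in (1, 2)]
pred = hy.ensemble_predict(members, test)
print(f"test R^2 = {hy.r_squared(obs, pred):.3f}")
```

This prints `test R^2 = 0.999`: the fixture's yields are additive in the
component identities, and the network recovers that law almost exactly from
the graphs. The one-hot forest baseline on the same split reaches
`test R^2 = 0.982` — it can also represent an additive law, but knows only
compound identity, so it cannot generalise to compounds outside the training
registry, which is exactly what the component-out splits probe:

```python
bhc, _ = hy.generate_fixture(hy.bhc_like_spec())   # 15 x 22 x 4 x 3 = 3960
splits = hy.stest_splits(bhc, "ligand", "halide", "additive",
                         hy.halide_triads(), bhc.structures("additive")[:5])
len(splits), len(splits[0].test_idx)               # (20, 45)
```

Each of the 20 splits holds out one ligand, one chloro/bromo/iodo scaffold
triad and five additives; every test set is the 1 × 3 × 5 × 3 = 45-reaction
cross of the held-out components, and `hy.leakage_scan` verifies none of
them appears in training.

The same workflow is available from the shell:

```sh
hteyield fixture --shape small --seed 1 --out fix/
hteyield train --csv fix/table.csv --config table.yaml --out model/
hteyield predict --model-dir model/ --csv fix/table.csv --config table.yaml --out pred.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's end-to-end workflow from
scratch: it generates the synthetic screens, builds the 20-way component
hold-out family (checking sizes and leakage), trains a scaled-down
MPNN-Transformer seed ensemble and the one-hot forest baseline on a 70:30
split, prints their test R², and writes the result JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/hteyield/reaction_data.py` — molecular graphs, environment identifiers, reaction tables
- `src/hteyield/splitters.py` — random / component-out / sTest split constructions
- `src/hteyield/model.py` — the MPNN-Transformer, training and persistence
- `src/hteyield/pretrain.py` — graph augmentations, NT-Xent, contrastive pretraining
- `src/hteyield/baselines.py` — ECFP6 / one-hot / random descriptors, forest and boosting adapters
- `src/hteyield/evaluation.py` — R², ensembling, workflow, swap-correlation and group summaries
- `src/hteyield/fixtures.py` — synthetic combinatorial screens with known yield laws
- `src/hteyield/autodiff.py` — minimal reverse-mode autodiff used by the neural parts
- `src/hteyield/cli.py` — the `hteyield` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
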