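"""Corpus filtering, graph augmentations and the contrastive objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hteyield as hy
from hteyield import autodiff as ad
from hteyield.fixtures import synthetic_corpus
from hteyield.model import ModelConfig
from hteyield.pretrain import (
    AugmentationConfig,
    MPNNCheckpoint,
    augment,
    contrastive_loss,
    embed_graphs,
    filter_corpus,
    pretrain_mpnn,
)


class TestFilterCorpus:
    @pytest.mark.parametrize(
        "smiles,kept",
        [
            ("CCCCCCCCC", False),  # 9 heavy atoms: below the lower bound
            ("CCCCCCCCCC", True),  # 10: inclusive boundary
            ("C" * 30, True),  # 30: inclusive boundary
            ("C" * 31, False),  # 31: above the upper bound
        ],
    )
    def test_heavy_atom_boundaries(self, smiles, kept):
        assert (filter_corpus([smiles]) == [smiles]) is kept

    def test_unparsable_entries_dropped_not_raised(self):
        out = filter_corpus(["CCCCCCCCCC", "((bad", "C1CCCCCCCCC1"])
        assert out == ["CCCCCCCCCC", "C1CCCCCCCCC1"]


class TestAugment:
    GRAPH = None  # built lazily: a 12-atom molecule

    @classmethod
    def graph(cls):
        if cls.GRAPH is None:
            cls.GRAPH = hy.graph_from_smiles("Cc1ccc(C(=O)NCC)cc1")  # 12 heavy atoms
        return cls.GRAPH

    def test_mini_subgraph_removal_deletes_at_least_ceiling(self):
        g = self.graph()
        assert g.n_atoms == 12
        out = augment(g, AugmentationConfig("mini_subgraph_removal", 0.25, 3))
        assert g.n_atoms - out.n_atoms >= 3  # ceil(0.25 * 12)

    def test_mini_subgraph_stop_at_first_crossing(self):
        # each deletion removes >= 1 atom, so the deleted count can overshoot
        # the target by at most one center's closed neighbourhood; re-running
        # with many seeds, deletions never continue after the target is met
        g = self.graph()
        max_degree = max(len(n) for n in g.neighbor_lists())
        for seed in range(50):
            out = augment(g, AugmentationConfig("mini_subgraph_removal", 0.25, seed))
            deleted = g.n_atoms - out.n_atoms
            assert 3 <= deleted <= 3 - 1 + max_degree + 1

    def test_mini_subgraph_locality(self):
        """Every deleted atom lies within graph distance 1 of a chosen center.

        Replays the stated procedure (pick a random surviving center, delete
        its closed radius-1 neighbourhood, stop at the first crossing of the
        target) with the same seed and asserts the augmented graph equals the
        graph minus exactly that union of closed neighbourhoods."""
        g = self.graph()
        nbrs = g.neighbor_lists()
        target = int(np.ceil(0.25 * g.n_atoms))
        for seed in range(30):
            rng = np.random.default_rng(seed)
            deleted: set[int] = set()
            while len(deleted) < target:
                survivors = [i for i in range(g.n_atoms) if i not in deleted]
                if len(survivors) <= 1:
                    break
                center = survivors[int(rng.integers(len(survivors)))]
                region = [center] + [j for j, _ in nbrs[center] if j not in deleted]
                for j in region:
                    if g.n_atoms - len(deleted) <= 1:
                        break
                    deleted.add(j)
                # locality: the region is the center's closed neighbourhood
                assert all(
                    j == center or any(k == j for k, _ in nbrs[center])
                    for j in region
                )
            out = augment(g, AugmentationConfig("mini_subgraph_removal", 0.25, seed))
            keep = [i for i in range(g.n_atoms) if i not in deleted]
            assert out.n_atoms == len(keep)
            assert out.atoms == tuple(g.atoms[i] for i in keep)

    def test_atom_masking_replaces_ceiling_many_env_tuples(self):
        g = self.graph()
        out = augment(g, AugmentationConfig("atom_masking", 0.25, 0))
        masked = [ids for ids in out.env_ids if set(ids) == {hy.reaction_data.MASK_ENV_ID}]
        assert len(masked) == 3  # ceil(0.25 * 12)
        assert out.n_atoms == g.n_atoms and out.bonds == g.bonds

    def test_bond_deletion_single_bond_ceiling(self):
        g = hy.graph_from_smiles("CC")  # one bond; ceil(0.25 * 1) = 1
        out = augment(g, AugmentationConfig("bond_deletion", 0.25, 0))
        assert out.n_bonds == 0 and out.n_atoms == 2

    def test_subgraph_removal_deletes_connected_region(self):
        g = self.graph()
        out = augment(g, AugmentationConfig("subgraph_removal", 0.25, 1))
        assert out.n_atoms == g.n_atoms - 3

    @pytest.mark.parametrize("method", hy.pretrain.AUGMENTATION_METHODS)
    def test_seed_determinism(self, method):
        g = self.graph()
        a = augment(g, AugmentationConfig(method, 0.25, 11))
        b = augment(g, AugmentationConfig(method, 0.25, 11))
        assert a == b

    def test_surviving_atoms_have_recomputed_env_ids(self):
        """env_ids of augmented graphs equal a fresh recomputation on the
        pruned topology (determinism of the identifier function)."""
        g = self.graph()
        out = augment(g, AugmentationConfig("mini_subgraph_removal", 0.25, 5))
        recomputed = hy.compute_env_ids(out.atoms, out.bonds, 3)
        assert out.env_ids == recomputed

    def test_whole_graph_deletion_rejected(self):
        g = hy.graph_from_smiles("CC")
        with pytest.raises(ValueError, match="whole graph"):
            augment(g, AugmentationConfig("subgraph_removal", 0.6, 0))

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig("atom_masking", 0.0, 0)
        with pytest.raises(ValueError):
            AugmentationConfig("not_a_method", 0.25, 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10**6))
def test_augmentation_determinism_property(seed):
    corpus = synthetic_corpus(5, seed=7)
    g = hy.graph_from_smiles(corpus[seed % len(corpus)])
    cfg = AugmentationConfig("mini_subgraph_removal", 0.25, seed)
    assert augment(g, cfg) == augment(g, cfg)
    assert g.n_atoms - augment(g, cfg).n_atoms >= int(np.ceil(0.25 * g.n_atoms))


class TestContrastiveLoss:
    def test_orthogonal_pairs_closed_form(self):
        """B=2 with views (u,u) and (v,v), u orthogonal to v, tau=1: each
        anchor sees one positive at similarity 1 and two negatives at 0, so
        the per-anchor loss is -log(e / (e + 2))."""
        u = np.array([1.0, 0.0])
        v = np.array([0.0, 1.0])
        z = ad.Tensor(np.stack([u, v, u, v]))
        loss = contrastive_loss(z, temperature=1.0)
        expected = -np.log(np.e / (np.e + 2.0))
        assert loss.data == pytest.approx(expected, abs=1e-9)

    def test_identical_embeddings_give_uniform_softmax_value(self):
        z = ad.Tensor(np.ones((6, 4)))
        loss = contrastive_loss(z, temperature=0.5)
        assert loss.data == pytest.approx(np.log(5.0), abs=1e-9)  # log(2B-1)

    def test_temperature_sharpening_nonincreasing_loss(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(8, 16))
        # push positives together so sharpening helps
        z[4:] = z[:4] + 0.05 * rng.normal(size=(4, 16))
        losses = [
            float(contrastive_loss(ad.Tensor(z), t).data)
            for t in (1.0, 0.5, 0.2, 0.1)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_pair_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(3, 8)), rng.normal(size=(3, 8))
        base = float(contrastive_loss(ad.Tensor(np.vstack([a, b])), 0.3).data)
        perm = [2, 0, 1]
        swapped = float(
            contrastive_loss(ad.Tensor(np.vstack([a[perm], b[perm]])), 0.3).data
        )
        assert base == pytest.approx(swapped, abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(ad.Tensor(np.ones((2, 4))), 0.5)


class TestPretrainMpnn:
    CFG = ModelConfig(d_embed=16, d_hidden=16, L=1, n_heads=2, lr=3e-3, seed=0)

    def test_loss_decreases_on_small_corpus(self):
        graphs = [hy.graph_from_smiles(s) for s in synthetic_corpus(48, seed=2)]
        ckpt = pretrain_mpnn(
            graphs,
            AugmentationConfig("mini_subgraph_removal", 0.25, 0),
            self.CFG,
            epochs=5,
            batch_size=24,
        )
        assert ckpt.loss_history[-1] < ckpt.loss_history[0]

    def test_checkpoint_round_trip_preserves_forward(self, tmp_path):
        graphs = [hy.graph_from_smiles(s) for s in synthetic_corpus(8, seed=3)]
        ckpt = pretrain_mpnn(
            graphs,
            AugmentationConfig("atom_masking", 0.25, 0),
            self.CFG,
            epochs=1,
            batch_size=8,
        )
        ckpt.save(tmp_path / "ckpt")
        loaded = MPNNCheckpoint.load(tmp_path / "ckpt")
        z1 = embed_graphs(graphs, ckpt.build_mpnn(), ckpt.env_vocab).data
        z2 = embed_graphs(graphs, loaded.build_mpnn(), loaded.env_vocab).data
        assert np.array_equal(z1, z2)

    def test_checkpoint_loads_into_supervised_model(self, tiny_ds, small_cfg):
        import dataclasses

        graphs = [hy.graph_from_smiles(s) for s in synthetic_corpus(8, seed=4)]
        cfg = dataclasses.replace(
            small_cfg, d_embed=16, d_hidden=16, L=2, max_epochs=1, patience=1
        )
        ckpt = pretrain_mpnn(
            graphs,
            AugmentationConfig("bond_deletion", 0.25, 0),
            cfg,
            epochs=1,
            batch_size=8,
        )
        model = hy.train_model(tiny_ds, cfg, pretrained_mpnn=ckpt)
        assert np.isfinite(model.predict(tiny_ds.reactions)).all()

    def test_width_mismatch_rejected(self, tiny_ds, small_cfg):
        import dataclasses

        graphs = [hy.graph_from_smiles(s) for s in synthetic_corpus(8, seed=5)]
        ckpt = pretrain_mpnn(
            graphs,
            AugmentationConfig("atom_masking", 0.25, 0),
            self.CFG,
            epochs=1,
            batch_size=8,
        )
        wide = dataclasses.replace(small_cfg, d_hidden=32, d_embed=32, n_heads=2)
        with pytest.raises(ValueError, match="mismatch"):
            hy.train_model(tiny_ds, wide, pretrained_mpnn=ckpt)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pretrain_mpnn(
                [], AugmentationConfig("atom_masking", 0.25, 0), self.CFG, epochs=1
            )
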