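"""The MPNN-Transformer yield regressor.

Every component of a reaction is processed by one shared message-passing
network: atom input vectors are sums of learned embeddings of the atom's four
circular-substructure identifiers (radii 0-3), projected to the hidden width
and updated L times by a common message-passing operation (messages are a
linear map of neighbour state and bond-type embedding, summed over
neighbours; the update is a gated recurrent cell by default, a plain linear
map if configured).  The per-component atom matrices are concatenated
row-wise, a learned role embedding is added to every row of its component (no
positional encoding), and N blocks of multi-head self-attention + layer
normalisation let atoms of different components interact.  The encoder output
is vectorised by summation over rows and mapped to a scalar yield by an MLP.

Because the readout is a sum and attention carries no positional signal, the
prediction is invariant to the order of components within a reaction and to
atom order within a component.

Yields are trained on the [0, 1] scale (percent / 100) and reported in
percent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .reaction_data import MolecularGraph, Reaction, ReactionDataset

logger = logging.getLogger(__name__)

#: reserved rows in the identifier-embedding table
UNK_INDEX = 0  # identifier never seen at fit time
MASK_INDEX = 1  # masked atom (contrastive pretraining)
N_RESERVED = 2

#: bond-type embedding rows: single, aromatic, double, triple
BOND_TYPES = {1.0: 0, 1.5: 1, 2.0: 2, 3.0: 3}


@dataclass
class ModelConfig:
    """Hyper-parameters. Defaults are implementation choices, configurable."""

    d_embed: int = 128
    d_hidden: int = 128
    L: int = 3
    N: int = 2
    n_heads: int = 4
    d_mlp: int = 128
    dropout: float = 0.1
    mpnn_update: str = "gru"  # "gru" | "linear"
    yield_scale: str = "percent"  # observed yields are percentages
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.L < 0 or self.N < 0:
            raise ValueError("L and N must be >= 0")
        if self.d_hidden % self.n_heads:
            raise ValueError("d_hidden must be divisible by n_heads")
        if self.mpnn_update not in ("gru", "linear"):
            raise ValueError(f"unknown mpnn_update {self.mpnn_update!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


class MPNN(ad.Module):
    """Shared message-passing network over a disjoint union of graphs."""

    def __init__(self, cfg: ModelConfig, n_env: int, rng: np.random.Generator):
        self.cfg = cfg
        self.atom_emb = ad.Embedding(n_env, cfg.d_embed, rng)
        self.in_proj = ad.Linear(cfg.d_embed, cfg.d_hidden, rng)
        self.bond_emb = ad.Embedding(len(BOND_TYPES), cfg.d_hidden, rng)
        self.msg = ad.Linear(2 * cfg.d_hidden, cfg.d_hidden, rng)
        if cfg.mpnn_update == "gru":
            self.update = ad.GRUCell(cfg.d_hidden, rng)
        else:
            self.update_lin = ad.Linear(cfg.d_hidden, cfg.d_hidden, rng)

    def __call__(self, env_idx, src, dst, btype, n_atoms: int) -> ad.Tensor:
        """env_idx: (n_atoms, R+1) embedding indices; src/dst/btype: directed
        edge arrays.  Returns the (n_atoms, d_hidden) atom-state matrix."""
        x = self.atom_emb(env_idx).sum(axis=1)
        h = self.in_proj(x)
        for _ in range(self.cfg.L):
            if len(src):
                inputs = ad.concat([ad.take_rows(h, src), self.bond_emb(btype)], axis=1)
                m = ad.scatter_sum(self.msg(inputs), dst, n_atoms)
            else:  # no bonds: zero aggregated message
                m = ad.scatter_sum(
                    self.msg(ad.concat([h, self.bond_emb(np.zeros(n_atoms, int))], axis=1))
                    * 0.0,
                    np.arange(n_atoms),
                    n_atoms,
                )
            if self.cfg.mpnn_update == "gru":
                h = self.update(m, h)
            else:
                h = self.update_lin(h) + m
        return h


class _Encoder(ad.Module):
    """N blocks of (multi-head self-attention -> residual -> layer norm)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.blocks = []
        for _ in range(cfg.N):
            self.blocks.append(ad.MultiheadSelfAttention(cfg.d_hidden, cfg.n_heads, rng))
            self.blocks.append(ad.LayerNorm(cfg.d_hidden))

    def __call__(self, h: ad.Tensor, mask: np.ndarray, drop=None) -> ad.Tensor:
        for i in range(0, len(self.blocks), 2):
            attn, ln = self.blocks[i], self.blocks[i + 1]
            a = attn(h, mask)
            if drop is not None:
                a = a * ad.Tensor(drop())
            h = ln(h + a)
        return h


class YieldModel(ad.Module):
    """Trainable MPNN-Transformer bound to an identifier and role vocabulary."""

    def __init__(self, cfg: ModelConfig, env_vocab: dict, role_vocab: list):
        self.cfg = cfg
        self.env_vocab = dict(env_vocab)  # identifier -> embedding row
        self.role_vocab = list(role_vocab)
        rng = np.random.default_rng(cfg.seed)
        self.mpnn = MPNN(cfg, N_RESERVED + len(env_vocab), rng)
        self.role_emb = ad.Embedding(len(role_vocab), cfg.d_hidden, rng)
        self.encoder = _Encoder(cfg, rng)
        self.head1 = ad.Linear(cfg.d_hidden, cfg.d_mlp, rng)
        self.head2 = ad.Linear(cfg.d_mlp, 1, rng)
        # zero-init the output layer: the sum-pooled readout has a
        # seed-dependent scale, and starting from a constant prediction
        # (the bias) makes early optimization seed-robust
        self.head2.W.data[:] = 0.0
        self.head2.b.data[:] = 0.5

    # -- featurization ----------------------------------------------------
    def _env_index(self, env_id: int) -> int:
        return self.env_vocab.get(env_id, UNK_INDEX)

    def _featurize(self, reactions) -> dict:
        """Flatten a batch into a disjoint-union graph + padded row layout.

        ABSENT components contribute one all-zero pseudo-atom row (before the
        role embedding is added); padding rows are masked out of attention and
        the readout.
        """
        env_rows, src, dst, btype = [], [], [], []
        row_maps, role_rows = [], []
        offset = 0
        for rxn in reactions:
            rows, roles = [], []
            for comp in rxn.components:
                if comp.role not in self.role_vocab:
                    raise KeyError(f"unknown role {comp.role!r}")
                role_ix = self.role_vocab.index(comp.role)
                if comp.is_absent:
                    rows.append(-1)  # sentinel -> zero row
                    roles.append(role_ix)
                    continue
                g: MolecularGraph = comp.graph
                for a in range(g.n_atoms):
                    env_rows.append([self._env_index(e) for e in g.env_ids[a]])
                    rows.append(offset + a)
                    roles.append(role_ix)
                for i, j, order in g.bonds:
                    t = BOND_TYPES.get(order, 0)
                    src += [offset + i, offset + j]
                    dst += [offset + j, offset + i]
                    btype += [t, t]
                offset += g.n_atoms
            row_maps.append(rows)
            role_rows.append(roles)
        T = max(len(r) for r in row_maps)
        B = len(reactions)
        row_index = np.full((B, T), -1, dtype=int)
        role_index = np.zeros((B, T), dtype=int)
        mask = np.zeros((B, T))
        for b, (rows, roles) in enumerate(zip(row_maps, role_rows)):
            row_index[b, : len(rows)] = rows
            role_index[b, : len(roles)] = roles
            mask[b, : len(rows)] = 1.0
        return {
            "env_idx": np.asarray(env_rows, dtype=int).reshape(offset, -1)
            if offset
            else np.zeros((0, 4), dtype=int),
            "src": np.asarray(src, dtype=int),
            "dst": np.asarray(dst, dtype=int),
            "btype": np.asarray(btype, dtype=int),
            "n_atoms": offset,
            "row_index": row_index,
            "role_index": role_index,
            "mask": mask,
        }

    # -- forward ----------------------------------------------------------
    def forward(self, reactions, training=False, rng=None) -> ad.Tensor:
        """Predicted yields on the unit scale, shape (B,)."""
        f = self._featurize(reactions)
        h = self.mpnn(f["env_idx"], f["src"], f["dst"], f["btype"], f["n_atoms"])
        # append a zero row used by ABSENT pseudo-atoms and padding (index -1)
        h_ext = ad.concat([h, ad.Tensor(np.zeros((1, self.cfg.d_hidden)))], axis=0)
        B, T = f["mask"].shape
        H = ad.take_rows(h_ext, f["row_index"].reshape(-1)).reshape(
            B, T, self.cfg.d_hidden
        )
        roles = self.role_emb(f["role_index"].reshape(-1)).reshape(
            B, T, self.cfg.d_hidden
        )
        mask3 = f["mask"][:, :, None]
        H = H + roles * ad.Tensor(mask3)

        drop = None
        if training and self.cfg.dropout > 0 and rng is not None:
            p = self.cfg.dropout

            def drop():
                return (rng.random((B, T, self.cfg.d_hidden)) >= p) / (1.0 - p)

        H = self.encoder(H, f["mask"], drop)
        pooled = (H * ad.Tensor(mask3)).sum(axis=1)
        hidden = self.head1(pooled).relu()
        if drop is not None:
            hidden = hidden * ad.Tensor(
                (rng.random(hidden.shape) >= self.cfg.dropout) / (1.0 - self.cfg.dropout)
            )
        return self.head2(hidden).reshape(B)

    def predict(self, reactions) -> np.ndarray:
        """Predicted yields in percent."""
        if isinstance(reactions, Reaction):
            reactions = [reactions]
        out = []
        bs = max(1, self.cfg.batch_size)
        for i in range(0, len(reactions), bs):
            out.append(self.forward(reactions[i : i + bs]).data)
        return np.concatenate(out) * 100.0

    def mpnn_atom_states(self, g: MolecularGraph) -> np.ndarray:
        """Atom-state matrix (n_atoms x d_hidden) of the shared MPNN."""
        env_idx = np.asarray(
            [[self._env_index(e) for e in ids] for ids in g.env_ids], dtype=int
        )
        src, dst, btype = [], [], []
        for i, j, order in g.bonds:
            t = BOND_TYPES.get(order, 0)
            src += [i, j]
            dst += [j, i]
            btype += [t, t]
        return self.mpnn(
            env_idx,
            np.asarray(src, int),
            np.asarray(dst, int),
            np.asarray(btype, int),
            g.n_atoms,
        ).data

    # -- persistence ------------------------------------------------------
    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.cfg), fh)
        with open(d / "vocab.json", "w") as fh:
            json.dump(
                {
                    "env_vocab": {str(k): v for k, v in self.env_vocab.items()},
                    "role_vocab": self.role_vocab,
                },
                fh,
            )
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(d / "params.npz", **arrays)

    @classmethod
    def load(cls, model_dir) -> "YieldModel":
        d = Path(model_dir)
        with open(d / "config.yaml") as fh:
            cfg = ModelConfig.from_dict(yaml.safe_load(fh))
        with open(d / "vocab.json") as fh:
            vocab = json.load(fh)
        model = cls(
            cfg,
            {int(k): v for k, v in vocab["env_vocab"].items()},
            vocab["role_vocab"],
        )
        with np.load(d / "params.npz") as z:
            model.load_state_arrays([z[f"p{i}"] for i in range(len(z.files))])
        return model


def build_env_vocab(reactions) -> dict:
    """Map every identifier observed in `reactions` to an embedding row."""
    vocab: dict[int, int] = {}
    for rxn in reactions:
        for comp in rxn.components:
            if comp.is_absent:
                continue
            for ids in comp.graph.env_ids:
                for e in ids:
                    if e not in vocab:
                        vocab[e] = N_RESERVED + len(vocab)
    return vocab


def train_model(
    train: ReactionDataset | list,
    cfg: ModelConfig,
    pretrained_mpnn=None,
    verbose: bool = False,
) -> YieldModel:
    """Fit a :class:`YieldModel` by MSE on yield/100 with early stopping.

    A seeded `val_fraction` of the training reactions is held out for early
    stopping (patience epochs without improvement); the best-validation
    parameters are restored.  If `pretrained_mpnn` (an
    :class:`~hteyield.pretrain.MPNNCheckpoint`) is given, only the MPNN is
    initialised from it; the encoder and MLP always start fresh.
    """
    reactions = train.reactions if isinstance(train, ReactionDataset) else list(train)
    if not reactions:
        raise ValueError("training set is empty")
    if isinstance(train, ReactionDataset):
        role_vocab = list(train.role_vocabulary)
    else:
        role_vocab = list(dict.fromkeys(c.role for r in reactions for c in r.components))
    env_vocab = build_env_vocab(reactions)
    model = YieldModel(cfg, env_vocab, role_vocab)
    if pretrained_mpnn is not None:
        pretrained_mpnn.load_into(model)

    rng = np.random.default_rng(cfg.seed)
    n = len(reactions)
    if cfg.val_fraction <= 0 or n < 2:
        n_val = 0
    else:
        n_val = min(max(int(round(cfg.val_fraction * n)), 1), n - 1)
    perm = rng.permutation(n)
    val = [reactions[i] for i in perm[:n_val]]
    fit = [reactions[i] for i in perm[n_val:]]

    y_fit = np.array([r.yield_pct for r in fit]) / 100.0
    y_val = np.array([r.yield_pct for r in val]) / 100.0
    # fitted normalization constant: start from the training-mean yield
    model.head2.b.data[:] = float(y_fit.mean())

    opt = ad.Adam(model.parameters(), lr=cfg.lr)
    best_val = np.inf
    best_params = [p.copy() for p in model.state_arrays()]
    bad_epochs = 0
    history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(fit))
        for start in range(0, len(fit), cfg.batch_size):
            batch_ix = order[start : start + cfg.batch_size]
            batch = [fit[i] for i in batch_ix]
            pred = model.forward(batch, training=True, rng=rng)
            err = pred - ad.Tensor(y_fit[batch_ix])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        if val:
            pv = model.predict(val) / 100.0
            val_loss = float(np.mean((pv - y_val) ** 2))
        else:
            pv = model.predict(fit) / 100.0
            val_loss = float(np.mean((pv - y_fit) ** 2))
        history.append(val_loss)
        if verbose:
            logger.info("epoch %d val_mse %.5f", epoch, val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = [p.copy() for p in model.state_arrays()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.load_state_arrays(best_params)
    model.validation_history = history
    return model
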