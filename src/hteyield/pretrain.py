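"""Contrastive pretraining of the shared MPNN on an unlabelled corpus.

Two independently augmented views of one molecule form a positive pair; views
of different molecules in the batch are negatives.  Molecule embeddings are
the summed MPNN atom states passed through a two-layer projection head (the
head is discarded after pretraining), and the objective is the
normalised-temperature cross-entropy (NT-Xent) over cosine similarities.

Four augmentations are provided: atom masking, bond deletion, subgraph
removal, and mini-subgraph removal.  Mini-subgraph removal repeatedly picks a
random surviving atom and deletes it together with its radius-1 neighbours,
stopping at the first repetition at which the number of deleted atoms reaches
ceil(ratio * n); because the atom features already encode neighbourhoods up
to radius 3, deleting many small local regions preserves more recoverable
context in the surviving atoms than removing one large subgraph.

The pretraining corpus is filtered to molecules with 10 to 30 heavy atoms
(inclusive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from . import autodiff as ad
from .model import MPNN, ModelConfig, N_RESERVED, MASK_INDEX, YieldModel
from .reaction_data import MolecularGraph, MASK_ENV_ID, compute_env_ids

logger = logging.getLogger(__name__)

AUGMENTATION_METHODS = (
    "atom_masking",
    "bond_deletion",
    "subgraph_removal",
    "mini_subgraph_removal",
)


@dataclass(frozen=True)
class AugmentationConfig:
    method: str = "mini_subgraph_removal"
    ratio: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.method not in AUGMENTATION_METHODS:
            raise ValueError(f"unknown augmentation method {self.method!r}")
        if not (0.0 < self.ratio < 1.0):
            raise ValueError("ratio must be in (0, 1)")


@dataclass(frozen=True)
class AugmentedPair:
    view_a: MolecularGraph
    view_b: MolecularGraph
    source_id: int


def filter_corpus(smiles_list, min_heavy: int = 10, max_heavy: int = 30) -> list:
    """Keep molecules with min_heavy <= heavy atoms <= max_heavy.

    Unparsable entries are dropped with a logged count.
    """
    kept, n_bad = [], 0
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            n_bad += 1
            continue
        if min_heavy <= mol.GetNumHeavyAtoms() <= max_heavy:
            kept.append(smi)
    if n_bad:
        logger.warning("filter_corpus: dropped %d unparsable SMILES", n_bad)
    return kept


# ---------------------------------------------------------------------------
# augmentations


def _delete_atoms(g: MolecularGraph, deleted: set) -> MolecularGraph:
    """Remove atoms (and incident bonds), reindex, recompute env_ids.

    Disconnected remnants are kept.  The result need not be a valid molecule,
    so identifiers are recomputed directly on the pruned graph.
    """
    keep = [i for i in range(g.n_atoms) if i not in deleted]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = tuple(g.atoms[i] for i in keep)
    bonds = tuple(
        (remap[i], remap[j], order)
        for i, j, order in g.bonds
        if i not in deleted and j not in deleted
    )
    radius_max = len(g.env_ids[0]) - 1 if g.env_ids else 3
    return MolecularGraph(
        atoms, bonds, compute_env_ids(atoms, bonds, radius_max), g.canonical_smiles
    )


def _atom_masking(g: MolecularGraph, ratio: float, rng) -> MolecularGraph:
    n_mask = int(np.ceil(ratio * g.n_atoms))
    chosen = set(rng.choice(g.n_atoms, size=n_mask, replace=False).tolist())
    n_radii = len(g.env_ids[0])
    env_ids = tuple(
        (MASK_ENV_ID,) * n_radii if i in chosen else g.env_ids[i]
        for i in range(g.n_atoms)
    )
    return MolecularGraph(g.atoms, g.bonds, env_ids, g.canonical_smiles)


def _bond_deletion(g: MolecularGraph, ratio: float, rng) -> MolecularGraph:
    if g.n_bonds == 0:
        return g
    n_del = int(np.ceil(ratio * g.n_bonds))
    chosen = set(rng.choice(g.n_bonds, size=n_del, replace=False).tolist())
    bonds = tuple(b for k, b in enumerate(g.bonds) if k not in chosen)
    radius_max = len(g.env_ids[0]) - 1
    return MolecularGraph(
        g.atoms, bonds, compute_env_ids(g.atoms, bonds, radius_max), g.canonical_smiles
    )


def _subgraph_removal(g: MolecularGraph, ratio: float, rng) -> MolecularGraph:
    """Delete one connected region of ceil(ratio*n) atoms grown from a seed."""
    target = int(np.ceil(ratio * g.n_atoms))
    nbrs = g.neighbor_lists()
    seed = int(rng.integers(g.n_atoms))
    region = {seed}
    frontier = [seed]
    while len(region) < target and frontier:
        nxt = sorted(
            {j for i in frontier for j, _ in nbrs[i] if j not in region}
        )
        if not nxt:
            break
        rng.shuffle(nxt)
        for j in nxt:
            if len(region) >= target:
                break
            region.add(j)
        frontier = nxt
    return _delete_atoms(g, region)


def _mini_subgraph_removal(g: MolecularGraph, ratio: float, rng) -> MolecularGraph:
    """Repeat {pick random surviving center, delete it + radius-1 neighbours}
    until at least ceil(ratio*n) atoms are deleted (stop at first crossing)."""
    target = int(np.ceil(ratio * g.n_atoms))
    nbrs = g.neighbor_lists()
    deleted: set[int] = set()
    while len(deleted) < target:
        survivors = [i for i in range(g.n_atoms) if i not in deleted]
        if len(survivors) <= 1:
            break
        center = survivors[int(rng.integers(len(survivors)))]
        region = [center] + [j for j, _ in nbrs[center] if j not in deleted]
        for j in region:
            if g.n_atoms - len(deleted) <= 1:
                break  # never delete the entire graph
            deleted.add(j)
    return _delete_atoms(g, deleted)


def augment(g: MolecularGraph, cfg: AugmentationConfig) -> MolecularGraph:
    """Apply the configured augmentation; same seed gives the same result."""
    if g.n_atoms == 0:
        raise ValueError("cannot augment an empty graph")
    rng = np.random.default_rng(cfg.seed)
    if cfg.method != "atom_masking" and cfg.method != "bond_deletion":
        if int(np.ceil(cfg.ratio * g.n_atoms)) >= g.n_atoms:
            raise ValueError("augmentation would delete the whole graph")
    fn = {
        "atom_masking": _atom_masking,
        "bond_deletion": _bond_deletion,
        "subgraph_removal": _subgraph_removal,
        "mini_subgraph_removal": _mini_subgraph_removal,
    }[cfg.method]
    return fn(g, cfg.ratio, rng)


# ---------------------------------------------------------------------------
# contrastive loss


def contrastive_loss(z: ad.Tensor, temperature: float) -> ad.Tensor:
    """NT-Xent over a batch of 2B embeddings arranged as [a_0..a_{B-1},
    b_0..b_{B-1}] with positives (a_i, b_i).

    Rows are L2-normalised; each anchor's cross-entropy runs over the other
    2B-1 rows (self-similarity excluded); the loss is symmetric over the pair
    and averaged over all 2B anchors.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    m = z.shape[0]
    if m % 2 or m < 4:
        raise ValueError("need at least 2 positive pairs (4 embeddings)")
    B = m // 2
    norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    zn = z / norm
    sim = (zn @ zn.transpose(1, 0)) * (1.0 / temperature)
    self_mask = np.where(np.eye(m) > 0, -1e30, 0.0)
    logits = sim + ad.Tensor(self_mask)
    # log-softmax with constant max-shift
    shift = ad.Tensor(logits.data.max(axis=1, keepdims=True))
    lse = ((logits - shift).exp().sum(axis=1, keepdims=True)).log() + shift
    log_probs = logits - lse
    pos = np.concatenate([np.arange(B) + B, np.arange(B)])
    picked = log_probs[np.arange(m), pos]
    return -picked.mean()


# ---------------------------------------------------------------------------
# pretraining


class MPNNCheckpoint:
    """Pretrained MPNN parameters plus the identifier vocabulary they index."""

    def __init__(self, cfg: ModelConfig, env_vocab: dict, arrays: list, loss_history=None):
        self.cfg = cfg
        self.env_vocab = dict(env_vocab)
        self.arrays = [np.asarray(a, dtype=np.float64) for a in arrays]
        self.loss_history = list(loss_history or [])

    @property
    def n_embedding_rows(self) -> int:
        return N_RESERVED + sum(1 for v in self.env_vocab.values() if v >= N_RESERVED)

    def build_mpnn(self) -> MPNN:
        mpnn = MPNN(self.cfg, self.n_embedding_rows, np.random.default_rng(0))
        mpnn.load_state_arrays(self.arrays)
        return mpnn

    def load_into(self, model: YieldModel) -> None:
        """Initialise `model`'s MPNN from this checkpoint.

        Widths must match.  Embedding rows are remapped through the identifier
        vocabularies: identifiers seen during pretraining reuse their
        pretrained vectors, identifiers new to the supervised set keep their
        fresh initialisation.
        """
        for attr in ("d_embed", "d_hidden", "L", "mpnn_update"):
            if getattr(model.cfg, attr) != getattr(self.cfg, attr):
                raise ValueError(
                    f"pretrained MPNN mismatch on {attr}: "
                    f"{getattr(self.cfg, attr)} != {getattr(model.cfg, attr)}"
                )
        src_mpnn = self.build_mpnn()
        src_arrays = src_mpnn.state_arrays()
        dst_params = model.mpnn.parameters()
        src_emb = src_arrays[0]
        dst_emb = dst_params[0].data
        for row in range(N_RESERVED):
            dst_emb[row] = src_emb[row]
        for env_id, src_row in self.env_vocab.items():
            dst_row = model.env_vocab.get(env_id)
            if dst_row is not None:
                dst_emb[dst_row] = src_emb[src_row]
        for p_dst, a_src in zip(dst_params[1:], src_arrays[1:]):
            p_dst.data = a_src.copy()

    def save(self, path) -> None:
        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        import yaml
        from dataclasses import asdict

        with open(d / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.cfg), fh)
        with open(d / "vocab.json", "w") as fh:
            json.dump(
                {
                    "env_vocab": {str(k): v for k, v in self.env_vocab.items()},
                    "loss_history": self.loss_history,
                },
                fh,
            )
        np.savez(d / "params.npz", **{f"p{i}": a for i, a in enumerate(self.arrays)})

    @classmethod
    def load(cls, path) -> "MPNNCheckpoint":
        import yaml

        d = Path(path)
        with open(d / "config.yaml") as fh:
            cfg = ModelConfig.from_dict(yaml.safe_load(fh))
        with open(d / "vocab.json") as fh:
            meta = json.load(fh)
        with np.load(d / "params.npz") as z:
            arrays = [z[f"p{i}"] for i in range(len(z.files))]
        return cls(
            cfg,
            {int(k): v for k, v in meta["env_vocab"].items()},
            arrays,
            meta.get("loss_history"),
        )


def _graph_batch_arrays(graphs, env_vocab):
    """Disjoint-union arrays for a list of graphs (see MPNN.__call__)."""
    env_rows, src, dst, btype, segment = [], [], [], [], []
    offset = 0
    from .model import UNK_INDEX, BOND_TYPES

    for k, g in enumerate(graphs):
        for ids in g.env_ids:
            env_rows.append([env_vocab.get(e, UNK_INDEX) for e in ids])
        for i, j, order in g.bonds:
            t = BOND_TYPES.get(order, 0)
            src += [offset + i, offset + j]
            dst += [offset + j, offset + i]
            btype += [t, t]
        segment += [k] * g.n_atoms
        offset += g.n_atoms
    n_radii = len(graphs[0].env_ids[0]) if graphs and graphs[0].env_ids else 4
    env = (
        np.asarray(env_rows, int)
        if env_rows
        else np.zeros((0, n_radii), dtype=int)
    )
    return (
        env,
        np.asarray(src, int),
        np.asarray(dst, int),
        np.asarray(btype, int),
        np.asarray(segment, int),
        offset,
    )


def embed_graphs(graphs, mpnn: MPNN, env_vocab: dict, head=None) -> ad.Tensor:
    """Sum-pooled MPNN embeddings (optionally through a projection head)."""
    env_idx, src, dst, btype, segment, n = _graph_batch_arrays(graphs, env_vocab)
    h = mpnn(env_idx, src, dst, btype, n)
    pooled = ad.scatter_sum(h, segment, len(graphs))
    if head is not None:
        pooled = head[1](head[0](pooled).relu())
    return pooled


def build_corpus_env_vocab(graphs) -> dict:
    vocab: dict[int, int] = {}
    for g in graphs:
        for ids in g.env_ids:
            for e in ids:
                if e not in vocab:
                    vocab[e] = N_RESERVED + len(vocab)
    return vocab


def pretrain_mpnn(
    corpus,
    aug_cfg: AugmentationConfig,
    model_cfg: ModelConfig,
    epochs: int = 5,
    batch_size: int = 256,
    temperature: float = 0.1,
) -> MPNNCheckpoint:
    """Contrastively pretrain an MPNN on `corpus` (list of MolecularGraph).

    Per batch, two independent augmentations are drawn per molecule; molecule
    embeddings go through a two-layer projection head (discarded afterwards)
    into the NT-Xent loss.  Returns a checkpoint loadable by ``train_model``.
    """
    graphs = list(corpus)
    if not graphs:
        raise ValueError("pretraining corpus is empty")
    env_vocab = build_corpus_env_vocab(graphs)
    # the MASK sentinel must map to the reserved MASK row
    env_vocab = {MASK_ENV_ID: MASK_INDEX, **{k: v for k, v in env_vocab.items()}}
    rng = np.random.default_rng(model_cfg.seed)
    mpnn = MPNN(model_cfg, N_RESERVED + len([k for k in env_vocab if k != MASK_ENV_ID]), rng)
    head = (
        ad.Linear(model_cfg.d_hidden, model_cfg.d_hidden, rng),
        ad.Linear(model_cfg.d_hidden, model_cfg.d_hidden, rng),
    )
    params = mpnn.parameters() + head[0].parameters() + head[1].parameters()
    opt = ad.Adam(params, lr=model_cfg.lr)
    aug_rng = np.random.default_rng(aug_cfg.seed)
    loss_history = []
    for epoch in range(epochs):
        order = rng.permutation(len(graphs))
        epoch_losses = []
        for start in range(0, len(graphs), batch_size):
            ix = order[start : start + batch_size]
            if len(ix) < 2:
                continue
            views = []
            for i in ix:
                for _ in range(2):
                    c = AugmentationConfig(
                        aug_cfg.method, aug_cfg.ratio, int(aug_rng.integers(2**31))
                    )
                    views.append(augment(graphs[i], c))
            # layout [a_0..a_{B-1}, b_0..b_{B-1}]
            view_a = views[0::2]
            view_b = views[1::2]
            z = embed_graphs(view_a + view_b, mpnn, env_vocab, head)
            loss = contrastive_loss(z, temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        loss_history.append(float(np.mean(epoch_losses)))
        logger.info("pretrain epoch %d NT-Xent %.4f", epoch, loss_history[-1])
    return MPNNCheckpoint(model_cfg, env_vocab, mpnn.state_arrays(), loss_history)
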