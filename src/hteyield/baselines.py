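"""Non-neural baselines: collision-free per-role ECFP6 descriptors, one-hot
and random-vector compound codebooks, and adapters to forest/boosting
regressors.

The ECFP6 reaction descriptor avoids bit collisions by construction: for each
reaction role, the unique Morgan (radius-3) hash values observed over that
role's compounds are collected and renumbered in decreasing order, giving one
dedicated position per observed atomic environment.  Per-role vectors are
presence bits and are simply concatenated (in role-vocabulary order) into the
reaction descriptor, so descriptor lengths differ across roles.

One-hot and random-vector codebooks carry compound identity but no structural
information and serve as controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

from .reaction_data import Reaction, ReactionDataset

logger = logging.getLogger(__name__)


def _morgan_hashes(smiles: str, radius: int = 3) -> set:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable structure {smiles!r}")
    fp = AllChem.GetMorganFingerprint(mol, radius)
    return set(fp.GetNonzeroElements())


@dataclass
class RoleDescriptorSpace:
    """Per-role bijection from observed ECFP6 hashes to dense positions."""

    role_vocabulary: list
    hash_positions: dict  # role -> {hash: position}
    radius: int = 3
    dropped_novel: int = field(default=0, compare=False)

    def role_length(self, role: str) -> int:
        return len(self.hash_positions[role])

    @property
    def total_length(self) -> int:
        return sum(len(m) for m in self.hash_positions.values())


def build_ecfp6_space(ds: ReactionDataset, radius: int = 3) -> RoleDescriptorSpace:
    """Collect per-role Morgan hashes over the dataset and renumber them in
    decreasing order, yielding a collision-free position map per role."""
    positions = {}
    for role in ds.role_vocabulary:
        hashes: set[int] = set()
        for smi in ds.structures(role):
            hashes |= _morgan_hashes(smi, radius)
        ordered = sorted(hashes, reverse=True)
        positions[role] = {h: i for i, h in enumerate(ordered)}
    return RoleDescriptorSpace(list(ds.role_vocabulary), positions, radius)


def reaction_descriptor(r: Reaction, space: RoleDescriptorSpace) -> np.ndarray:
    """Concatenated per-role presence-bit vector for one reaction.

    ABSENT components give an all-zero block.  Hashes unseen when the space
    was built (possible on extrapolation splits) are dropped; the drop count
    accumulates on ``space.dropped_novel`` (the position maps themselves are
    frozen after build).
    """
    blocks = []
    by_role = {c.role: c for c in r.components}
    for role in space.role_vocabulary:
        pos = space.hash_positions[role]
        vec = np.zeros(len(pos))
        comp = by_role.get(role)
        if comp is None:
            raise KeyError(f"reaction {r.reaction_id} lacks role {role!r}")
        if not comp.is_absent:
            for h in _morgan_hashes(comp.structure, space.radius):
                if h in pos:
                    vec[pos[h]] = 1.0
                else:
                    space.dropped_novel += 1
                    logger.debug(
                        "novel environment %d under role %s dropped", h, role
                    )
        blocks.append(vec)
    return np.concatenate(blocks)


@dataclass
class CompoundCodebook:
    """Per-role map from canonical structure to a fixed vector."""

    role_vocabulary: list
    vectors: dict  # role -> {structure: ndarray}
    dims: dict  # role -> vector length
    mode: str = "one_hot"

    @property
    def total_length(self) -> int:
        return sum(self.dims.values())


def build_codebook(
    ds: ReactionDataset, mode: str, dim: int | None = None, seed: int = 0
) -> CompoundCodebook:
    """Assign each compound a one-hot or seeded random vector, per role.

    For one-hot, `dim` must be at least the per-role vocabulary size (it is
    auto-set to that size when None).  Random vectors are reproducible from
    `seed`.
    """
    if mode not in ("one_hot", "random"):
        raise ValueError(f"unknown codebook mode {mode!r}")
    rng = np.random.default_rng(seed)
    vectors, dims = {}, {}
    for role in ds.role_vocabulary:
        structures = ds.structures(role)
        d = dim if dim is not None else len(structures)
        if mode == "one_hot" and d < len(structures):
            raise ValueError(
                f"one_hot dim {d} < vocabulary size {len(structures)} for "
                f"role {role!r}"
            )
        table = {}
        for k, smi in enumerate(structures):
            if mode == "one_hot":
                v = np.zeros(d)
                v[k] = 1.0
            else:
                v = rng.normal(size=d)
            table[smi] = v
        vectors[role] = table
        dims[role] = d
    return CompoundCodebook(list(ds.role_vocabulary), vectors, dims, mode)


def codebook_descriptor(r: Reaction, book: CompoundCodebook) -> np.ndarray:
    blocks = []
    by_role = {c.role: c for c in r.components}
    for role in book.role_vocabulary:
        comp = by_role.get(role)
        if comp is None:
            raise KeyError(f"reaction {r.reaction_id} lacks role {role!r}")
        if comp.is_absent or comp.structure not in book.vectors[role]:
            blocks.append(np.zeros(book.dims[role]))
        else:
            blocks.append(book.vectors[role][comp.structure])
    return np.concatenate(blocks)


def descriptor_matrix(reactions, featurizer) -> np.ndarray:
    return np.vstack([featurizer(r) for r in reactions])


#: documented default grid for the boosting regressor
BOOSTING_GRID = {
    "learning_rate": [0.05, 0.1],
    "max_depth": [3, 6],
}


def fit_baseline(
    X: np.ndarray,
    y: np.ndarray,
    model: str = "forest",
    seed: int = 0,
    n_estimators: int = 500,
    cv_folds: int = 3,
    grid: dict | None = None,
):
    """Fit a forest or boosting regressor on a descriptor matrix.

    Forest: 500 trees by default.  Boosting: gradient-boosted trees with
    native early stopping, tuned by seeded cross-validation over a small
    documented grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptor matrix contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("degenerate training target: all yields identical")
    if model == "forest":
        reg = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
        reg.fit(X, y)
        return reg
    if model == "boosting":
        base = HistGradientBoostingRegressor(
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=10,
            random_state=seed,
        )
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(base, grid or BOOSTING_GRID, cv=cv)
        search.fit(X, y)
        return search.best_estimator_
    raise ValueError(f"unknown baseline model {model!r}")


class BaselinePredictor:
    """A fitted baseline bound to its descriptor featurizer.

    Exposes the same ``predict(reactions) -> percent yields`` contract as the
    neural model so evaluation code can treat both uniformly.
    """

    def __init__(self, regressor, featurizer):
        self.regressor = regressor
        self.featurizer = featurizer

    def predict(self, reactions) -> np.ndarray:
        if isinstance(reactions, Reaction):
            reactions = [reactions]
        return self.regressor.predict(descriptor_matrix(reactions, self.featurizer))
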