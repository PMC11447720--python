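"""Data model for molecules, reactions and HTE reaction tables.

Molecules are heavy-atom graphs parsed from SMILES with RDKit.  Each atom
carries four circular-substructure identifiers (radii 0-3), computed from the
parsed graph by iterated Weisfeiler-Lehman style neighbourhood hashing.  The
identifiers are the keys into the model's atom-embedding table, standing in
for pretrained atom-environment vectors: they are deterministic functions of
the graph, invariant to input atom order, and identical for topologically
equivalent atoms.

Reactions are ordered lists of role-labelled components (a fixed role
vocabulary: aryl halide, additive, ligand, base, ...), each either a molecular
graph or ABSENT (e.g. a "none" ligand cell), plus an observed yield in
percent.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: sentinel env identifier for masked atoms (contrastive atom-masking)
MASK_ENV_ID = 0

ABSENT_TOKENS = {"", "none", "nan"}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        msg = f"unparsable SMILES: {smiles!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class TableFormatError(ValueError):
    """Raised for malformed reaction tables (missing columns, bad yields)."""


# ---------------------------------------------------------------------------
# molecular graphs


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom molecular graph with per-atom environment identifiers.

    atoms: (element symbol, formal charge, aromatic flag) per atom.
    bonds: (i, j, order) with i < j, each undirected bond stored once;
        aromatic bonds carry order 1.5.
    env_ids: per-atom tuple of circular-substructure identifiers for
        radii 0..radius_max (unsigned 32-bit).
    """

    atoms: tuple
    bonds: tuple
    env_ids: tuple
    canonical_smiles: str

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbor_lists(self) -> list:
        nbrs: list[list[tuple[int, float]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            nbrs[i].append((j, order))
            nbrs[j].append((i, order))
        return nbrs


def _hash32(payload: str) -> int:
    digest = hashlib.blake2b(payload.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def compute_env_ids(atoms, bonds, radius_max: int = 3) -> tuple:
    """Circular-substructure identifiers per atom for radii 0..radius_max.

    Radius 0 hashes the atom's own attributes (element, formal charge,
    aromaticity, heavy-atom degree); radius r+1 hashes the radius-r identifier
    together with the sorted (bond order, neighbour radius-r id) multiset, as
    in Morgan/ECFP identifier generation.  Sorting makes the result invariant
    to atom input order, and the refinement assigns equal identifiers to
    automorphic atoms.
    """
    n = len(atoms)
    nbrs: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, order in bonds:
        nbrs[i].append((j, float(order)))
        nbrs[j].append((i, float(order)))
    current = [
        _hash32(f"{sym}|{charge}|{int(bool(arom))}|{len(nbrs[i])}")
        for i, (sym, charge, arom) in enumerate(atoms)
    ]
    per_atom = [[c] for c in current]
    for _ in range(radius_max):
        nxt = []
        for i in range(n):
            env = sorted((order, current[j]) for j, order in nbrs[i])
            nxt.append(_hash32(f"{current[i]}|{env}"))
        current = nxt
        for i in range(n):
            per_atom[i].append(current[i])
    return tuple(tuple(ids) for ids in per_atom)


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def graph_from_smiles(smiles: str, id_radius_max: int = 3) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Hydrogens stay implicit.  Multi-fragment inputs (salt pairs such as
    ``...[B-](F)(F)F.[K+]``) are kept as one graph with no bonds between
    fragments.  Raises :class:`SmilesParseError` for unparsable input.
    """
    if id_radius_max < 0:
        raise ValueError("id_radius_max must be >= 0")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        order = _BOND_ORDER.get(b.GetBondType(), 1.0)
        bonds.append((i, j, order))
    bonds = tuple(sorted(bonds))
    env_ids = compute_env_ids(atoms, bonds, id_radius_max)
    return MolecularGraph(atoms, bonds, env_ids, Chem.MolToSmiles(mol))


# ---------------------------------------------------------------------------
# reactions and datasets


@dataclass(frozen=True)
class ReactionComponent:
    """A role-labelled reaction component; ``graph is None`` means ABSENT."""

    role: str
    graph: MolecularGraph | None

    @classmethod
    def absent(cls, role: str) -> "ReactionComponent":
        return cls(role, None)

    @property
    def is_absent(self) -> bool:
        return self.graph is None

    @property
    def structure(self) -> str | None:
        return None if self.graph is None else self.graph.canonical_smiles


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    components: tuple
    yield_pct: float

    def __post_init__(self):
        y = float(self.yield_pct)
        if not (y == y and abs(y) != float("inf")):
            raise ValueError(f"yield must be finite, got {self.yield_pct!r}")

    def component(self, role: str) -> ReactionComponent:
        for c in self.components:
            if c.role == role:
                return c
        raise KeyError(f"no component with role {role!r}")

    def structure(self, role: str) -> str | None:
        return self.component(role).structure


@dataclass
class ReactionDataset:
    """A list of reactions plus the per-role registry of distinct structures.

    Registry lookups are by canonical structure (ABSENT excluded), never by
    the input string.
    """

    reactions: list
    role_vocabulary: list
    component_registry: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.component_registry:
            self.component_registry = self._build_registry()

    def _build_registry(self) -> dict:
        reg: dict[str, dict[str, None]] = {r: {} for r in self.role_vocabulary}
        for rxn in self.reactions:
            for c in rxn.components:
                if not c.is_absent:
                    reg[c.role][c.structure] = None
        return {role: list(seen) for role, seen in reg.items()}

    def __len__(self) -> int:
        return len(self.reactions)

    def structures(self, role: str) -> list:
        return list(self.component_registry[role])

    def subset(self, indices) -> "ReactionDataset":
        return ReactionDataset(
            [self.reactions[i] for i in indices], list(self.role_vocabulary)
        )


def _is_absent_cell(value) -> bool:
    if value is None or (isinstance(value, float) and value != value):
        return True
    return str(value).strip().lower() in ABSENT_TOKENS


def read_reaction_table(
    path,
    role_columns: dict,
    yield_column: str,
    clamp_yields: bool = False,
    id_radius_max: int = 3,
) -> ReactionDataset:
    """Read a reaction CSV into a :class:`ReactionDataset`.

    `role_columns` maps CSV column names to role labels; `yield_column` names
    the numeric yield column (percent).  The cell value "none"
    (case-insensitive) or an empty cell denotes an ABSENT component.  Yields
    outside [0, 100] are rejected unless `clamp_yields` is set.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in list(role_columns) + [yield_column] if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing column(s): {missing}")
    graph_cache: dict[str, MolecularGraph] = {}
    reactions = []
    for row_pos, (_, row) in enumerate(df.iterrows()):
        components = []
        for col, role in role_columns.items():
            cell = row[col]
            if _is_absent_cell(cell):
                components.append(ReactionComponent.absent(role))
                continue
            smi = str(cell).strip()
            if smi not in graph_cache:
                try:
                    graph_cache[smi] = graph_from_smiles(smi, id_radius_max)
                except SmilesParseError as exc:
                    raise SmilesParseError(
                        smi, f"row {row_pos}, column {col!r}"
                    ) from exc
            components.append(ReactionComponent(role, graph_cache[smi]))
        try:
            y = float(row[yield_column])
        except (TypeError, ValueError):
            raise TableFormatError(
                f"non-numeric yield {row[yield_column]!r} in row {row_pos}"
            ) from None
        if not (0.0 <= y <= 100.0):
            if clamp_yields:
                y = min(max(y, 0.0), 100.0)
            else:
                raise TableFormatError(
                    f"yield {y} outside [0, 100] in row {row_pos}"
                )
        reactions.append(Reaction(str(row_pos), tuple(components), y))
    return ReactionDataset(reactions, list(role_columns.values()))


def write_reaction_table(ds: ReactionDataset, path) -> None:
    """Write a dataset back to CSV (role columns named by role, plus yield).

    Structures are written as canonical SMILES; ABSENT components as "none".
    """
    rows = []
    for rxn in ds.reactions:
        row = {}
        for c in rxn.components:
            row[c.role] = "none" if c.is_absent else c.structure
        row["yield"] = rxn.yield_pct
        rows.append(row)
    pd.DataFrame(rows, columns=ds.role_vocabulary + ["yield"]).to_csv(
        path, index=False
    )
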