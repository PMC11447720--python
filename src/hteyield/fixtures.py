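"""Synthetic HTE-style reaction tables with a known yield law.

The generator enumerates the full combinatorial cross of small per-role
compound vocabularies (optionally dropping a random fraction of rows) and
assigns each reaction a yield

    clip(base + sum of per-component effects + pairwise interactions
         + Gaussian noise, 0, 100).

The effect table, interactions and noise level are recorded alongside the
dataset so recovery tests can assert against ground truth.  The default
vocabularies are small real molecules — halogenated (hetero)arenes with
chloro/bromo/iodo variants of shared scaffolds, isoxazole additives,
phosphine ligands and amine/amidine bases — so chemistry-dependent code paths
(aromaticity, charges, salts, scaffold triads) are exercised.  The generator
emulates the shape of a combinatorial cross-coupling screen, not reaction
mechanism: yields are additive by construction.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .reaction_data import (
    Reaction,
    ReactionComponent,
    ReactionDataset,
    SmilesParseError,
    graph_from_smiles,
)

logger = logging.getLogger(__name__)

#: 5 scaffolds x {Cl, Br, I} — triad structure mirrors a halide-variant screen
HALIDES = [
    s.format(X=x)
    for s in (
        "{X}c1ccccn1",
        "{X}c1ccc(C)cc1",
        "{X}c1ccc(OC)cc1",
        "{X}c1ccc(C(F)(F)F)cc1",
        "{X}c1cccc2ccccc12",
    )
    for x in ("Cl", "Br", "I")
]

ADDITIVES = [
    "c1cc(on1)c1ccccc1",
    "Cc1cc(on1)c1ccccc1",
    "Cc1onc(c1)c1ccccc1",
    "c1cc(on1)C",
    "Cc1ccon1",
    "CCc1ccon1",
    "c1cc(on1)CC",
    "c1cc(on1)c1ccc(C)cc1",
    "c1cc(on1)c1ccc(OC)cc1",
    "c1cc(on1)c1ccc(F)cc1",
    "c1cc(on1)c1ccc(Cl)cc1",
    "Cc1onc(C)c1",
    "CC(C)c1ccon1",
    "c1cc(on1)C(C)C",
    "c1cc(on1)c1ccco1",
    "c1cc(on1)c1cccs1",
    "c1cc(on1)C1CC1",
    "c1cc(on1)c1ccncc1",
    "COc1ccon1",
    "c1cc(on1)CO",
    "OCc1ccon1",
    "c1cc(on1)c1ccc(Br)cc1",
]

LIGANDS = [
    "c1ccc(P(c2ccccc2)c2ccccc2)cc1",
    "C1CCC(P(C2CCCCC2)C2CCCCC2)CC1",
    "CC(C)(C)P(C(C)(C)C)C(C)(C)C",
    "CCCCP(CCCC)CCCC",
]

BASES = [
    "CN(C)c1ccncc1",
    "C1CCC2=NCCCN2CC1",
    "CN1CCCN2CCCN=C12",
]

#: realistic per-role effect spreads in yield points
DEFAULT_EFFECT_RANGES = {
    "halide": 15.0,
    "additive": 20.0,
    "ligand": 15.0,
    "base": 10.0,
    "organoboron": 15.0,
}
_FALLBACK_EFFECT_RANGE = 12.0


@dataclass
class FixtureSpec:
    """Stated world of a synthetic screen.

    roles: per-role SMILES vocabularies (order defines the role vocabulary).
    effects: per-role map structure -> yield-point effect; roles left out are
        drawn uniformly from +-effect_ranges[role] at generation time.
    interactions: list of ((role_a, smiles_a), (role_b, smiles_b), delta)
        applied when both structures co-occur.
    noise_sd: Gaussian noise SD in yield points (default 5).
    drop_fraction: fraction of the full cross to drop at random.
    """

    roles: dict
    base_yield: float = 30.0
    effects: dict = field(default_factory=dict)
    interactions: list = field(default_factory=list)
    noise_sd: float = 5.0
    drop_fraction: float = 0.0
    effect_ranges: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_RANGES))
    seed: int = 0


def bhc_like_spec(noise_sd: float = 5.0, seed: int = 0, **kwargs) -> FixtureSpec:
    """A fixture shaped like a combinatorial C-N coupling screen:
    15 aryl halides (5 scaffold triads) x 22 additives x 4 ligands x 3 bases
    = 3960 reactions."""
    return FixtureSpec(
        roles={
            "halide": list(HALIDES),
            "additive": list(ADDITIVES),
            "ligand": list(LIGANDS),
            "base": list(BASES),
        },
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


def small_additive_spec(noise_sd: float = 0.0, seed: int = 0, **kwargs) -> FixtureSpec:
    """A 5 x 5 x 4 x 4 = 400-reaction purely additive screen used for
    signal-recovery checks."""
    return FixtureSpec(
        roles={
            "halide": HALIDES[:5],
            "additive": ADDITIVES[:5],
            "ligand": LIGANDS[:4],
            "base": BASES[:3] + ["CCN(CC)CC"],
        },
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


def halide_triads(halides=None) -> list:
    """Group the default halide vocabulary into its scaffold triads
    (canonical SMILES), for the sTest-style construction."""
    smis = halides if halides is not None else HALIDES
    canon = [graph_from_smiles(s).canonical_smiles for s in smis]
    return [canon[i : i + 3] for i in range(0, len(canon), 3)]


_CORPUS_CORES = (
    "{a}c1ccc({b})cc1",
    "{a}c1ccc({b})cc1{c}",
    "{a}c1cccc2c1cccc2{b}",
    "{a}c1ccc(C(=O)O{b})cc1",
    "{a}c1ccc(N({b})C)cc1",
    "{a}c1ccc(-c2ccc({b})cc2)cc1",
    "{a}C1CCC({b})CC1",
    "{a}c1ccc(OC{b})cc1",
)

_CORPUS_SUBS = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C(F)(F)F", "C#N", "C(=O)C", "C(=O)OC",
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "CO", "CCO", "CCl",
)


def synthetic_corpus(n: int, seed: int = 0, min_heavy: int = 10, max_heavy: int = 30):
    """Deterministically sample `n` distinct valid SMILES with `min_heavy` to
    `max_heavy` heavy atoms, for exercising the pretraining pipeline."""
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    out, seen = [], set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("synthetic_corpus failed to reach target size")
        core = _CORPUS_CORES[int(rng.integers(len(_CORPUS_CORES)))]
        subs = {
            k: _CORPUS_SUBS[int(rng.integers(len(_CORPUS_SUBS)))]
            for k in ("a", "b", "c")
        }
        try:
            smi = core.format(**subs)
        except (IndexError, KeyError):
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None or not (min_heavy <= mol.GetNumHeavyAtoms() <= max_heavy):
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(smi)
    return out


def generate_fixture(spec: FixtureSpec):
    """Enumerate the combinatorial table and its yields.

    Returns ``(ReactionDataset, truth)`` where ``truth`` records the realised
    effect table, interactions, noise level and clipping fraction, keyed by
    canonical SMILES so recovery tests can assert against it.
    """
    rng = np.random.default_rng(spec.seed)
    role_vocab = list(spec.roles)
    graphs: dict[str, object] = {}
    canon: dict[tuple, str | None] = {}
    for role, vocab in spec.roles.items():
        if not vocab:
            raise ValueError(f"empty vocabulary for role {role!r}")
        for smi in vocab:
            if smi is None or str(smi).strip().lower() in ("", "none"):
                canon[(role, smi)] = None
                continue
            try:
                g = graph_from_smiles(smi)
            except SmilesParseError:
                raise SmilesParseError(smi, f"role {role!r} vocabulary")
            graphs[smi] = g
            canon[(role, smi)] = g.canonical_smiles

    # realise the effect table (seed-stable: drawn role by role, compound
    # by compound, before any yields)
    effects: dict[str, dict[str, float]] = {}
    for role, vocab in spec.roles.items():
        given = spec.effects.get(role, {})
        spread = spec.effect_ranges.get(role, _FALLBACK_EFFECT_RANGE)
        table = {}
        for smi in vocab:
            key = canon[(role, smi)] or "none"
            if smi in given:
                table[key] = float(given[smi])
            elif key in given:
                table[key] = float(given[key])
            else:
                table[key] = float(rng.uniform(-spread, spread))
        effects[role] = table

    inter = []
    for (role_a, smi_a), (role_b, smi_b), delta in spec.interactions:
        inter.append(
            (
                (role_a, canon.get((role_a, smi_a), smi_a)),
                (role_b, canon.get((role_b, smi_b), smi_b)),
                float(delta),
            )
        )

    combos = list(itertools.product(*[spec.roles[r] for r in role_vocab]))
    if spec.drop_fraction > 0:
        keep = rng.random(len(combos)) >= spec.drop_fraction
        combos = [c for c, k in zip(combos, keep) if k]

    reactions = []
    n_clipped = 0
    for idx, combo in enumerate(combos):
        comps, y = [], spec.base_yield
        chosen = {}
        for role, smi in zip(role_vocab, combo):
            key = canon[(role, smi)]
            chosen[role] = key
            y += effects[role][key or "none"]
            comps.append(
                ReactionComponent.absent(role)
                if key is None
                else ReactionComponent(role, graphs[smi])
            )
        for (ra, sa), (rb, sb), delta in inter:
            if chosen.get(ra) == sa and chosen.get(rb) == sb:
                y += delta
        if spec.noise_sd > 0:
            y += rng.normal(0.0, spec.noise_sd)
        clipped = min(max(y, 0.0), 100.0)
        if clipped != y:
            n_clipped += 1
        reactions.append(Reaction(str(idx), tuple(comps), clipped))

    ds = ReactionDataset(reactions, role_vocab)
    truth = {
        "base_yield": spec.base_yield,
        "effects": effects,
        "interactions": [
            {"a": list(a), "b": list(b), "delta": d} for a, b, d in inter
        ],
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "n_reactions": len(reactions),
        "clipped_fraction": n_clipped / max(len(reactions), 1),
    }
    return ds, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
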