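"""Train/test split constructions for HTE reaction datasets.

Four split families are provided:

* random ratio splits (e.g. 70:30 down to 1:99), optionally restricted so
  that every training-set compound also occurs in the test set (the regime
  used at extreme 1:99 ratios, where otherwise training compounds would have
  no counterpart to generalise to);
* component-out splits: all reactions containing any of a set of held-out
  structures in a given role form the test set (additive-out, organoboron-out,
  ligand-pair-out);
* the "sTest" construction: for each (ligand, halide triad) pair the test set
  is the full cross of that ligand x the triad x a fixed additive set x all
  bases, and the training set excludes every reaction containing the held-out
  ligand OR any triad halide OR any test additive.

All splits are deterministic given their seed and record a manifest of what
was held out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reaction_data import ReactionDataset


class SplitError(ValueError):
    """Raised for invalid split specifications."""


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test index sets plus the manifest that produced them."""

    train_idx: tuple
    test_idx: tuple
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.train_idx) & set(self.test_idx):
            raise SplitError("train and test indices overlap")


@dataclass(frozen=True)
class SplitSpec:
    kind: str  # random_ratio | component_out | stest | multi_component_out
    ratio: tuple | None = None
    held_out: dict | None = None  # role -> list of canonical structures
    seed: int = 0
    repeats: int = 1

    def __post_init__(self):
        if self.kind == "random_ratio":
            if self.ratio is None or len(self.ratio) != 2:
                raise SplitError("random_ratio requires a (train, test) ratio")
            a, b = self.ratio
            if a <= 0 or b <= 0 or abs(a + b - 100) > 1e-9:
                raise SplitError("ratio entries must be positive and sum to 100")


def _train_count(n: int, train_pct: float) -> int:
    # round-half-up on the train count; remainder goes to test
    return int(math.floor(train_pct / 100.0 * n + 0.5))


def _structures_in(rxn) -> set:
    return {(c.role, c.structure) for c in rxn.components if not c.is_absent}


def _coverage_ok(ds: ReactionDataset, train_idx, test_idx) -> bool:
    test_structs = set()
    for i in test_idx:
        test_structs |= _structures_in(ds.reactions[i])
    for i in train_idx:
        if not _structures_in(ds.reactions[i]) <= test_structs:
            return False
    return True


def random_split(
    ds: ReactionDataset,
    ratio: tuple,
    seed: int,
    require_test_coverage: bool = False,
    max_retries: int = 1000,
) -> SplitResult:
    """Randomly split `ds` at `ratio` (train%, test%), seeded.

    With `require_test_coverage`, resample (up to `max_retries`) until every
    compound occurring in the training partition also occurs in the test
    partition — the restriction applied to extreme ratios such as 1:99.
    """
    n = len(ds)
    if n == 0:
        raise SplitError("dataset is empty")
    a, b = ratio
    if a <= 0 or b <= 0 or abs(a + b - 100) > 1e-9:
        raise SplitError(f"invalid ratio {ratio}: must be positive, sum to 100")
    n_train = _train_count(n, a)
    if n_train == 0 or n_train == n:
        raise SplitError(f"ratio {ratio} gives an empty train or test set (n={n})")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        perm = rng.permutation(n)
        train_idx = tuple(sorted(int(i) for i in perm[:n_train]))
        test_idx = tuple(sorted(int(i) for i in perm[n_train:]))
        if not require_test_coverage or _coverage_ok(ds, train_idx, test_idx):
            manifest = {
                "kind": "random_ratio",
                "ratio": list(ratio),
                "seed": seed,
                "n_train": len(train_idx),
                "n_test": len(test_idx),
                "coverage_restricted": require_test_coverage,
                "attempts": attempt + 1,
            }
            return SplitResult(train_idx, test_idx, manifest)
    raise SplitError(
        f"could not satisfy compound coverage within {max_retries} resamples"
    )


def component_out_split(
    ds: ReactionDataset, role: str, held_out: list
) -> SplitResult:
    """Hold out all reactions containing any `held_out` structure in `role`."""
    if role not in ds.role_vocabulary:
        raise SplitError(f"unknown role {role!r}")
    known = set(ds.structures(role))
    unknown = [s for s in held_out if s not in known]
    if unknown:
        raise SplitError(f"structure(s) not in dataset under role {role!r}: {unknown}")
    held = set(held_out)
    test, train = [], []
    for i, rxn in enumerate(ds.reactions):
        (test if rxn.structure(role) in held else train).append(i)
    manifest = {
        "kind": "component_out",
        "role": role,
        "held_out": sorted(held),
        "n_train": len(train),
        "n_test": len(test),
    }
    return SplitResult(tuple(train), tuple(test), manifest)


def multi_component_out_split(ds: ReactionDataset, held_out: dict) -> SplitResult:
    """Hold out reactions containing any held-out structure in any listed role."""
    for role in held_out:
        if role not in ds.role_vocabulary:
            raise SplitError(f"unknown role {role!r}")
    held = {role: set(s) for role, s in held_out.items()}
    test, train = [], []
    for i, rxn in enumerate(ds.reactions):
        hit = any(rxn.structure(role) in ss for role, ss in held.items())
        (test if hit else train).append(i)
    manifest = {
        "kind": "multi_component_out",
        "held_out": {r: sorted(s) for r, s in held.items()},
        "n_train": len(train),
        "n_test": len(test),
    }
    return SplitResult(tuple(train), tuple(test), manifest)


def stest_splits(
    ds: ReactionDataset,
    ligand_role: str,
    halide_role: str,
    additive_role: str,
    triads: list,
    test_additives: list,
) -> list:
    """Build one split per (ligand, halide triad) pair.

    `triads` must partition the halide vocabulary into same-scaffold groups of
    three (e.g. the chloro/bromo/iodo variants of one scaffold);
    `test_additives` is the fixed additive set shared by every test set.  The
    test set of a split is every reaction with the held-out ligand AND a triad
    halide AND a test additive; the training set excludes every reaction
    containing the ligand OR any triad halide OR any test additive, so no
    held-out component leaks into training.
    """
    halides = set(ds.structures(halide_role))
    flat = [h for t in triads for h in t]
    if sorted(flat) != sorted(halides) or any(len(t) != 3 for t in triads):
        raise SplitError(
            "triads must partition the halide vocabulary into groups of 3"
        )
    unknown_add = [a for a in test_additives if a not in set(ds.structures(additive_role))]
    if unknown_add:
        raise SplitError(f"test additives not in dataset: {unknown_add}")
    add_set = set(test_additives)
    results = []
    for ligand in ds.structures(ligand_role):
        for triad in triads:
            triad_set = set(triad)
            test, train = [], []
            for i, rxn in enumerate(ds.reactions):
                lig = rxn.structure(ligand_role)
                hal = rxn.structure(halide_role)
                add = rxn.structure(additive_role)
                if lig == ligand and hal in triad_set and add in add_set:
                    test.append(i)
                elif lig != ligand and hal not in triad_set and add not in add_set:
                    train.append(i)
                # reactions sharing some but not all held-out components are
                # dropped: they belong to neither partition
            manifest = {
                "kind": "stest",
                "roles": {
                    "ligand": ligand_role,
                    "halide": halide_role,
                    "additive": additive_role,
                },
                "ligand": ligand,
                "halide_triad": sorted(triad_set),
                "test_additives": sorted(add_set),
                "n_train": len(train),
                "n_test": len(test),
            }
            results.append(SplitResult(tuple(train), tuple(test), manifest))
    return results


def leakage_scan(ds: ReactionDataset, split: SplitResult) -> list:
    """Return held-out (role, structure) pairs found in training reactions.

    Brute-force check of the no-leakage invariant for component-out style
    splits; an empty list means the split is clean.
    """
    m = split.manifest
    held: set[tuple[str, str]] = set()
    if m.get("kind") == "component_out":
        held = {(m["role"], s) for s in m["held_out"]}
    elif m.get("kind") == "multi_component_out":
        held = {(r, s) for r, ss in m["held_out"].items() for s in ss}
    elif m.get("kind") == "stest":
        roles = m["roles"]
        held = {(roles["ligand"], m["ligand"])}
        held |= {(roles["halide"], h) for h in m["halide_triad"]}
        held |= {(roles["additive"], a) for a in m["test_additives"]}
    leaks = []
    for i in split.train_idx:
        for c in ds.reactions[i].components:
            if not c.is_absent and (c.role, c.structure) in held:
                leaks.append((i, c.role, c.structure))
    return leaks
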