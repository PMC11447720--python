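"""Evaluation: coefficient of determination, seed-pool ensembling, the
evaluation workflow over split families, and outlier/correlation analyses.

The reported statistic is the coefficient of determination
R^2 = 1 - SS_res / SS_tot (not the squared correlation coefficient); it can
be negative when a model is worse than predicting the mean.

The ensemble protocol trains a pool of models differing only in their random
seed, forms ensembles by sampling members without replacement from the pool,
predicts by averaging member outputs, and reports the mean and standard
deviation of the ensemble-level R^2 values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .reaction_data import ReactionDataset
from .splitters import SplitResult

logger = logging.getLogger(__name__)


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be equal-length 1-D arrays")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: all observations identical")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class EnsembleSpec:
    pool_size: int = 50
    members_per_ensemble: int = 10
    n_ensembles: int = 5
    selection_seed: int = 0

    def __post_init__(self):
        if self.members_per_ensemble > self.pool_size:
            raise ValueError("members_per_ensemble cannot exceed pool_size")
        if self.pool_size < 1 or self.n_ensembles < 1:
            raise ValueError("pool_size and n_ensembles must be >= 1")


def ensemble_predict(members, reactions) -> np.ndarray:
    """Arithmetic mean of the member predictions."""
    if not members:
        raise ValueError("empty member list")
    return np.mean([np.asarray(m.predict(reactions), float) for m in members], axis=0)


@dataclass
class EvalReport:
    """Per-split ensemble R^2 values plus the manifest that produced them."""

    per_split: list  # [{split, ensemble_r2: [...], mean, sd}]
    manifest: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["per_split"], d["manifest"])


def run_evaluation(
    ds: ReactionDataset,
    splits,
    model_factory,
    ens: EnsembleSpec,
    split_names=None,
) -> EvalReport:
    """Train a seed pool per split, ensemble, and report R^2 mean (SD).

    `model_factory(train_reactions, seed)` must return an object with a
    ``predict(reactions) -> percent yields`` method.  The same seed list
    (0..pool_size-1 offset by the selection seed) is shared across splits and
    methods, ensembles are sampled without replacement within an ensemble,
    and the reported mean/SD are over ensemble-level R^2 values.
    """
    if isinstance(splits, SplitResult):
        splits = [splits]
    names = split_names or [f"split{i}" for i in range(len(splits))]
    seeds = list(range(ens.pool_size))
    per_split = []
    for name, split in zip(names, splits):
        train = [ds.reactions[i] for i in split.train_idx]
        test = [ds.reactions[i] for i in split.test_idx]
        obs = np.array([r.yield_pct for r in test])
        pool, pool_preds = [], []
        for seed in seeds:
            try:
                m = model_factory(train, seed)
            except Exception as exc:
                raise RuntimeError(f"training failed for split {name!r}") from exc
            pool.append(m)
            pool_preds.append(np.asarray(m.predict(test), float))
        sel_rng = np.random.default_rng(ens.selection_seed)
        r2s = []
        for _ in range(ens.n_ensembles):
            chosen = sel_rng.choice(ens.pool_size, ens.members_per_ensemble, replace=False)
            pred = np.mean([pool_preds[i] for i in chosen], axis=0)
            r2s.append(r_squared(obs, pred))
        per_split.append(
            {
                "split": name,
                "split_manifest": split.manifest,
                "ensemble_r2": r2s,
                "mean": float(np.mean(r2s)),
                "sd": float(np.std(r2s)),
            }
        )
    manifest = {"ensemble_spec": asdict(ens), "seeds": seeds, "n_splits": len(splits)}
    return EvalReport(per_split, manifest)


def component_swap_correlation(
    ds: ReactionDataset, role: str, structure_a: str, structure_b: str
):
    """Correlation of observed yields between matched reaction pairs that
    differ only in `role` (structure_a vs structure_b).

    Returns (n_pairs, pearson_r, r_squared_of_r); used to ask whether two
    structurally similar compounds behave interchangeably.
    """
    for s in (structure_a, structure_b):
        if s not in set(ds.structures(role)):
            raise ValueError(f"structure {s!r} not found under role {role!r}")

    def key(rxn):
        return tuple(
            (c.role, c.structure) for c in rxn.components if c.role != role
        )

    ya: dict[tuple, float] = {}
    yb: dict[tuple, float] = {}
    for rxn in ds.reactions:
        s = rxn.structure(role)
        if s == structure_a:
            ya[key(rxn)] = rxn.yield_pct
        elif s == structure_b:
            yb[key(rxn)] = rxn.yield_pct
    shared = sorted(set(ya) & set(yb))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} matched pairs; need >= 3")
    a = np.array([ya[k] for k in shared])
    b = np.array([yb[k] for k in shared])
    r = float(stats.pearsonr(a, b).statistic)
    return len(shared), r, r * r


def groupwise_yield_summary(
    ds: ReactionDataset, group_role: str, marker_role: str, marker_set
) -> pd.DataFrame:
    """Five-number yield summaries per `group_role` structure, split by
    whether the reaction contains a `marker_set` structure in `marker_role`.

    A tidy table for box-plot style outlier inspection (e.g. additive-wise
    yields split by halide subset).
    """
    marker_set = set(marker_set)
    rows = []
    for group in ds.structures(group_role):
        for flag in (True, False):
            ys = [
                r.yield_pct
                for r in ds.reactions
                if r.structure(group_role) == group
                and ((r.structure(marker_role) in marker_set) == flag)
            ]
            if not ys:
                logger.info(
                    "group %s marker=%s: no reactions, skipped", group, flag
                )
                rows.append(
                    {
                        "group": group,
                        "in_marker_set": flag,
                        "n": 0,
                        "min": np.nan,
                        "q1": np.nan,
                        "median": np.nan,
                        "q3": np.nan,
                        "max": np.nan,
                    }
                )
                continue
            ys = np.array(ys)
            rows.append(
                {
                    "group": group,
                    "in_marker_set": flag,
                    "n": len(ys),
                    "min": float(ys.min()),
                    "q1": float(np.percentile(ys, 25)),
                    "median": float(np.median(ys)),
                    "q3": float(np.percentile(ys, 75)),
                    "max": float(ys.max()),
                }
            )
    return pd.DataFrame(rows)
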