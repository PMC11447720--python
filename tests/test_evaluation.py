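"""R^2 metric, seed-pool ensembling, evaluation workflow, outlier analyses."""

import numpy as np
import pytest

import hteyield as hy
from hteyield.evaluation import (
    EnsembleSpec,
    EvalReport,
    component_swap_correlation,
    ensemble_predict,
    groupwise_yield_summary,
    r_squared,
    run_evaluation,
)


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, reactions):
        return np.full(len(reactions), self.value)


class _MeanModel:
    """Predicts the training mean plus a seed-dependent wiggle."""

    def __init__(self, train, seed):
        rng = np.random.default_rng(seed)
        self.mu = np.mean([r.yield_pct for r in train]) + rng.normal(0, 0.5)

    def predict(self, reactions):
        return np.full(len(reactions), self.mu)


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_gives_zero(self):
        obs = np.array([10.0, 20.0, 60.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_worked_example(self):
        # SS_res = 100 + 0 + 100 = 200; SS_tot = 2500 + 0 + 2500 = 5000
        assert r_squared([0, 50, 100], [10, 50, 90]) == pytest.approx(0.96)

    def test_can_be_negative(self):
        assert r_squared([0, 50, 100], [100, 50, 0]) < 0

    def test_matches_two_pass_brute_force(self, rng):
        for _ in range(20):
            obs = rng.normal(50, 20, size=30)
            pred = obs + rng.normal(0, 10, size=30)
            mu = sum(obs) / len(obs)
            ss_tot = sum((o - mu) ** 2 for o in obs)
            ss_res = sum((o - p) ** 2 for o, p in zip(obs, pred))
            assert r_squared(obs, pred) == pytest.approx(
                1 - ss_res / ss_tot, abs=1e-12
            )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_squared([5, 5, 5], [1, 2, 3])
        with pytest.raises(ValueError):
            r_squared([1], [1])


class TestEnsemblePredict:
    def test_single_member_identity(self, tiny_ds):
        m = _ConstantModel(40.0)
        assert np.array_equal(
            ensemble_predict([m], tiny_ds.reactions), m.predict(tiny_ds.reactions)
        )

    def test_mean_of_two_members(self, tiny_ds):
        pred = ensemble_predict(
            [_ConstantModel(40.0), _ConstantModel(60.0)], tiny_ds.reactions
        )
        assert np.allclose(pred, 50.0)

    def test_average_stays_in_member_envelope(self, tiny_ds, rng):
        members = [_ConstantModel(v) for v in rng.uniform(0, 100, size=7)]
        preds = np.stack([m.predict(tiny_ds.reactions) for m in members])
        ens = ensemble_predict(members, tiny_ds.reactions)
        assert np.all(ens >= preds.min(axis=0) - 1e-12)
        assert np.all(ens <= preds.max(axis=0) + 1e-12)

    def test_empty_member_list_rejected(self, tiny_ds):
        with pytest.raises(ValueError):
            ensemble_predict([], tiny_ds.reactions)


class TestRunEvaluation:
    def test_degenerate_spec_reports_one_r2(self, tiny_ds):
        sp = hy.random_split(tiny_ds, (50, 50), seed=0)
        ens = EnsembleSpec(pool_size=2, members_per_ensemble=2, n_ensembles=1)
        report = run_evaluation(tiny_ds, [sp], _MeanModel, ens)
        assert len(report.per_split) == 1
        assert len(report.per_split[0]["ensemble_r2"]) == 1

    def test_end_to_end_determinism(self, tiny_ds):
        sp = hy.random_split(tiny_ds, (50, 50), seed=0)
        ens = EnsembleSpec(pool_size=4, members_per_ensemble=2, n_ensembles=2)
        r1 = run_evaluation(tiny_ds, [sp], _MeanModel, ens)
        r2 = run_evaluation(tiny_ds, [sp], _MeanModel, ens)
        assert r1.per_split == r2.per_split

    def test_null_signal_method_scores_near_zero(self, additive_ds):
        """A predictor whose descriptors carry no signal has mean R^2 <= 0
        (a constant predictor cannot beat the test mean)."""
        ds, _ = additive_ds
        sp = hy.random_split(ds, (70, 30), seed=2)
        ens = EnsembleSpec(pool_size=3, members_per_ensemble=2, n_ensembles=2)
        report = run_evaluation(ds, [sp], _MeanModel, ens)
        assert report.per_split[0]["mean"] <= 0.05

    def test_invalid_ensemble_spec(self):
        with pytest.raises(ValueError):
            EnsembleSpec(pool_size=2, members_per_ensemble=5)

    def test_report_round_trips(self, tiny_ds, tmp_path):
        sp = hy.random_split(tiny_ds, (50, 50), seed=0)
        ens = EnsembleSpec(pool_size=2, members_per_ensemble=1, n_ensembles=2)
        report = run_evaluation(tiny_ds, [sp], _MeanModel, ens)
        report.to_json(tmp_path / "r.json")
        loaded = EvalReport.from_json(tmp_path / "r.json")
        assert loaded.per_split == report.per_split


def test_ensembling_does_not_hurt_pool_mean_r2(additive_ds):
    """Regression guard (not a theorem): averaging members whose errors are
    independent should not fall below the pool-mean R^2 by more than a small
    sampling tolerance."""
    ds, _ = additive_ds
    reactions = ds.reactions[:120]
    obs = np.array([r.yield_pct for r in reactions])

    class _Noisy:
        def __init__(self, seed):
            noise = np.random.default_rng(seed).normal(0, 12, size=len(obs))
            self._pred = obs + noise

        def predict(self, rxns):
            return self._pred

    members = [_Noisy(s) for s in range(10)]
    member_r2 = [r_squared(obs, m.predict(reactions)) for m in members]
    ens_r2 = r_squared(obs, ensemble_predict(members, reactions))
    assert ens_r2 >= np.mean(member_r2) - 0.02


class TestComponentSwapCorrelation:
    def _paired_fixture(self, noise_sd, seed=0):
        """Two additives over 200 matched contexts (40 substrates x 5 bases);
        each additive's yield is the shared context signal (SD 10) plus its
        own independent noise of the given SD."""
        rng = np.random.default_rng(seed)
        contexts = hy.fixtures.synthetic_corpus(40, seed=17)
        bases = hy.fixtures.BASES + ["CCN(CC)CC", "CCCN(C)C"]
        adds = ["Cc1ccon1", "CCc1ccon1"]
        graphs = {s: hy.graph_from_smiles(s) for s in contexts + bases + adds}
        rxns, k = [], 0
        for h in contexts:
            for b in bases:
                signal = rng.normal(50, 10)
                for a in adds:
                    y = signal + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                    comps = (
                        hy.ReactionComponent("substrate", graphs[h]),
                        hy.ReactionComponent("base", graphs[b]),
                        hy.ReactionComponent("additive", graphs[a]),
                    )
                    rxns.append(hy.Reaction(str(k), comps, float(np.clip(y, 0, 100))))
                    k += 1
        ds = hy.ReactionDataset(rxns, ["substrate", "base", "additive"])
        ca = graphs[adds[0]].canonical_smiles
        cb = graphs[adds[1]].canonical_smiles
        return ds, ca, cb

    def test_zero_effect_swap_gives_correlation_one(self):
        ds, a, b = self._paired_fixture(noise_sd=0.0)
        n, r, r2 = component_swap_correlation(ds, "additive", a, b)
        assert n == 200
        assert r == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_equal_variance_noise_halves_correlation(self):
        """With independent noise of the same variance as the shared signal on
        both arms, corr = var_s / (var_s + var_e) = 0.5 analytically."""
        ds, a, b = self._paired_fixture(noise_sd=10.0, seed=1)
        n, r, _ = component_swap_correlation(ds, "additive", a, b)
        assert n == 200
        assert r == pytest.approx(0.5, abs=0.1)

    def test_missing_structure_rejected(self, tiny_ds):
        adds = tiny_ds.structures("additive")
        with pytest.raises(ValueError, match="not found"):
            component_swap_correlation(tiny_ds, "additive", adds[0], "CCCCCC")

    def test_too_few_pairs_rejected(self):
        ds, a, b = self._paired_fixture(noise_sd=0.0)
        small = ds.subset(range(4))  # only 2 matched pairs
        with pytest.raises(ValueError, match="pairs"):
            component_swap_correlation(small, "additive", a, b)


class TestGroupwiseSummary:
    def test_planted_offset_recovered(self, rng):
        """Reactions whose halide is in the marker set have a +30 median
        offset planted for one additive group; the summary recovers it."""
        halides = hy.fixtures.HALIDES[:6]
        marker = {hy.graph_from_smiles(s).canonical_smiles for s in halides[:3]}
        adds = hy.fixtures.ADDITIVES[:3]
        graphs = {s: hy.graph_from_smiles(s) for s in halides + adds}
        outlier = graphs[adds[0]].canonical_smiles
        rxns, k = [], 0
        for a in adds:
            for h in halides:
                y = 40.0
                if graphs[a].canonical_smiles == outlier and graphs[h].canonical_smiles in marker:
                    y += 30.0
                rxns.append(
                    hy.Reaction(
                        str(k),
                        (
                            hy.ReactionComponent("additive", graphs[a]),
                            hy.ReactionComponent("halide", graphs[h]),
                        ),
                        y,
                    )
                )
                k += 1
        ds = hy.ReactionDataset(rxns, ["additive", "halide"])
        table = groupwise_yield_summary(ds, "additive", "halide", marker)
        grp = table[table["group"] == outlier].set_index("in_marker_set")
        assert grp.loc[True, "median"] - grp.loc[False, "median"] == 30.0
        others = table[(table["group"] != outlier)]
        assert (others["median"] == 40.0).all()

    def test_marker_covering_everything_flags_empty_complement(self, tiny_ds):
        marker = set(tiny_ds.structures("halide"))
        table = groupwise_yield_summary(tiny_ds, "additive", "halide", marker)
        empty = table[~table["in_marker_set"]]
        assert (empty["n"] == 0).all()

    def test_invariant_to_row_order(self, tiny_ds):
        marker = set(tiny_ds.structures("halide")[:1])
        t1 = groupwise_yield_summary(tiny_ds, "additive", "halide", marker)
        shuffled = hy.ReactionDataset(
            list(reversed(tiny_ds.reactions)), tiny_ds.role_vocabulary
        )
        t2 = groupwise_yield_summary(shuffled, "additive", "halide", marker)
        a = t1.sort_values(["group", "in_marker_set"]).reset_index(drop=True)
        b = t2.sort_values(["group", "in_marker_set"]).reset_index(drop=True)
        assert a.equals(b)
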