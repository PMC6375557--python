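"""Forest training, OOB tuning, intervals, probabilities, importance."""

import numpy as np
import pytest

from pairforest.forecaster import (
    ForestConfig,
    load_model,
    predict_dx,
    predict_interval,
    predict_vents_icv,
    save_model,
    train,
    tune,
    variable_importance,
)
from pairforest.pairwise import PairSample


def synth_pairs(rng, n, informative=True, task="regress", extra_noise_feature=False):
    """Pairwise samples where the target depends on feature A (or on nothing)."""
    samples = []
    for i in range(n):
        a = float(rng.uniform(0, 1))
        b = float(rng.uniform(0, 1))
        feats = {"A": a, "B": b, "TIME_DELAY": float(rng.uniform(1, 48))}
        if extra_noise_feature:
            feats["NOISE"] = float(rng.uniform(0, 1))
        if task == "regress":
            target = 10.0 * a if informative else float(rng.uniform(0, 10))
            samples.append(PairSample(rid=i, source_month=0, delta_t=feats["TIME_DELAY"],
                                      features=feats, target_value=target))
        else:
            if informative:
                dx = "AD" if a > 0.66 else ("MCI" if a > 0.33 else "NL")
            else:
                dx = ["NL", "MCI", "AD"][int(rng.integers(3))]
            samples.append(PairSample(rid=i, source_month=0, delta_t=feats["TIME_DELAY"],
                                      features=feats, target_dx=dx))
    return samples


def const_regress_pairs(value, n=60):
    rng = np.random.default_rng(0)
    return [
        PairSample(rid=i, source_month=0, delta_t=1.0,
                   features={"A": float(rng.uniform()), "TIME_DELAY": 1.0},
                   target_value=value)
        for i in range(n)
    ]


class TestTrain:
    def test_reproducible_bit_for_bit(self, rng):
        pairs = synth_pairs(rng, 120, task="classify")
        cfg = ForestConfig(n_trees=25, seed=42)
        m1 = train(pairs, cfg, "classify_dx")
        m2 = train(pairs, cfg, "classify_dx")
        p1 = predict_dx(m1, pairs[:20])
        p2 = predict_dx(m2, pairs[:20])
        assert (p1 == p2).all()
        assert m1.oob_error == m2.oob_error

    def test_single_class_predicts_it_with_certainty(self):
        pairs = [
            PairSample(rid=i, source_month=0, delta_t=1.0,
                       features={"A": float(i), "TIME_DELAY": 1.0}, target_dx="AD")
            for i in range(30)
        ]
        model = train(pairs, ForestConfig(n_trees=10, seed=0), "classify_dx")
        probs = predict_dx(model, pairs[:5])
        assert (probs == np.array([0.0, 0.0, 1.0])).all()
        assert model.oob_error == 0.0

    def test_constant_regression_target(self):
        pairs = const_regress_pairs(7.5)
        model = train(pairs, ForestConfig(n_trees=10, seed=0), "regress")
        out = predict_interval(model, pairs[:5])
        assert out == pytest.approx(np.tile([7.5, 7.5, 7.5], (5, 1)))

    def test_oob_error_nonnegative(self, rng):
        pairs = synth_pairs(rng, 100, task="regress")
        model = train(pairs, ForestConfig(n_trees=30, seed=1), "regress")
        assert model.oob_error >= 0

    def test_regression_predictions_within_training_range(self, rng):
        """Forests average training targets, so they cannot extrapolate."""
        pairs = synth_pairs(rng, 150, task="regress")
        model = train(pairs, ForestConfig(seed=2), "regress")
        lo = min(s.target_value for s in pairs)
        hi = max(s.target_value for s in pairs)
        out = predict_interval(model, synth_pairs(rng, 40, task="regress"))
        assert (out[:, 0] >= lo).all() and (out[:, 0] <= hi).all()


class TestPredictDx:
    def test_probabilities_normalized(self, rng):
        pairs = synth_pairs(rng, 150, task="classify")
        model = train(pairs, ForestConfig(n_trees=40, seed=3), "classify_dx")
        probs = predict_dx(model, synth_pairs(rng, 50, task="classify"))
        assert ((probs >= 0) & (probs <= 1)).all()
        assert probs.sum(axis=1) == pytest.approx(np.ones(50), abs=1e-9)

    def test_single_tree_pure_leaves_give_hard_probabilities(self, rng):
        pairs = synth_pairs(rng, 60, task="classify")
        model = train(pairs, ForestConfig(n_trees=1, min_leaf=1, seed=4), "classify_dx")
        probs = predict_dx(model, pairs[:30])
        assert np.isin(probs, (0.0, 1.0)).all()

    def test_feature_name_mismatch_errors(self, rng):
        pairs = synth_pairs(rng, 60, task="classify")
        model = train(pairs, ForestConfig(n_trees=5, seed=0), "classify_dx")
        bad = PairSample(rid=0, source_month=0, delta_t=1.0,
                         features={"X": 1.0, "TIME_DELAY": 1.0}, target_dx="NL")
        with pytest.raises(ValueError, match="mismatch"):
            predict_dx(model, [bad])


class TestPredictInterval:
    def test_percentiles_match_sort_and_interpolate_oracle(self, rng):
        """Per-tree predictions {1,2,3,4} at level 0.5 give [1.75, 3.25]."""
        pairs = synth_pairs(rng, 80, task="regress")
        model = train(pairs, ForestConfig(n_trees=4, seed=5), "regress")
        sample = synth_pairs(rng, 1, task="regress")
        per_tree = np.array([t.predict(np.array([[sample[0].features[n] for n in model.feature_names]]))[0]
                             for t in model.ensemble.estimators_])
        out = predict_interval(model, sample)
        lo_expect = min(np.percentile(per_tree, 25), per_tree.mean())
        hi_expect = max(np.percentile(per_tree, 75), per_tree.mean())
        assert out[0, 1] == pytest.approx(lo_expect)
        assert out[0, 2] == pytest.approx(hi_expect)
        # the documented arithmetic on a literal ensemble of {1,2,3,4}
        assert np.percentile([1, 2, 3, 4], 25) == pytest.approx(1.75)
        assert np.percentile([1, 2, 3, 4], 75) == pytest.approx(3.25)

    def test_interval_always_contains_point(self, rng):
        pairs = synth_pairs(rng, 100, task="regress")
        model = train(pairs, ForestConfig(n_trees=7, seed=6), "regress")
        out = predict_interval(model, synth_pairs(rng, 50, task="regress"))
        assert (out[:, 1] <= out[:, 0]).all()
        assert (out[:, 0] <= out[:, 2]).all()

    def test_invalid_level_errors(self, rng):
        pairs = synth_pairs(rng, 60, task="regress")
        model = train(pairs, ForestConfig(n_trees=5, seed=0), "regress")
        with pytest.raises(ValueError):
            predict_interval(model, pairs[:1], level=1.5)


class TestVentsIcvRatio:
    def test_ratio_arithmetic(self):
        vents = train(const_regress_pairs(30000.0), ForestConfig(n_trees=5, seed=0), "regress")
        icv = train(const_regress_pairs(1.5e6), ForestConfig(n_trees=5, seed=0), "regress")
        samples = const_regress_pairs(0.0)[:3]
        out = predict_vents_icv(vents, icv, samples, samples)
        assert out[:, 0] == pytest.approx(0.02)

    def test_equal_models_give_unit_ratio_degenerate_interval(self):
        m = train(const_regress_pairs(1.2e6), ForestConfig(n_trees=5, seed=0), "regress")
        samples = const_regress_pairs(0.0)[:2]
        out = predict_vents_icv(m, m, samples, samples)
        assert out == pytest.approx(np.tile([1.0, 1.0, 1.0], (2, 1)))

    def test_interval_ratio_oracle(self, rng):
        """Interval is [vents_lo/icv_hi, vents_hi/icv_lo] for positive volumes."""
        vents_pairs = [
            PairSample(rid=i, source_month=0, delta_t=1.0,
                       features={"A": float(rng.uniform()), "TIME_DELAY": 1.0},
                       target_value=float(rng.uniform(28000, 32000)))
            for i in range(80)
        ]
        icv_pairs = [
            PairSample(rid=i, source_month=0, delta_t=1.0,
                       features={"A": float(rng.uniform()), "TIME_DELAY": 1.0},
                       target_value=float(rng.uniform(1.4e6, 1.6e6)))
            for i in range(80)
        ]
        vm = train(vents_pairs, ForestConfig(n_trees=10, seed=1), "regress")
        im = train(icv_pairs, ForestConfig(n_trees=10, seed=2), "regress")
        samples = vents_pairs[:10]
        v = predict_interval(vm, samples)
        icv = predict_interval(im, samples)
        out = predict_vents_icv(vm, im, samples, samples)
        np.testing.assert_allclose(out[:, 1], np.minimum(v[:, 1] / icv[:, 2], out[:, 0]))
        np.testing.assert_allclose(out[:, 2], np.maximum(v[:, 2] / icv[:, 1], out[:, 0]))
        assert (out[:, 1] <= out[:, 0]).all() and (out[:, 0] <= out[:, 2]).all()

    def test_nonpositive_icv_errors(self):
        vents = train(const_regress_pairs(30000.0), ForestConfig(n_trees=5, seed=0), "regress")
        icv = train(const_regress_pairs(-5.0), ForestConfig(n_trees=5, seed=0), "regress")
        samples = const_regress_pairs(0.0)[:1]
        with pytest.raises(ValueError, match="intracranial"):
            predict_vents_icv(vents, icv, samples, samples)


class TestTune:
    def test_single_grid_point_returned(self, rng):
        pairs = synth_pairs(rng, 100, task="regress")
        cfg = ForestConfig(grid_n_trees=(15,), grid_min_leaf=(3,), seed=0)
        tuned = tune(pairs, cfg, "regress")
        assert (tuned.n_trees, tuned.min_leaf) == (15, 3)

    def test_fewer_than_50_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            tune(synth_pairs(rng, 20), ForestConfig(), "regress")

    def test_infeasible_grid_errors(self, rng):
        pairs = synth_pairs(rng, 60, task="regress")
        cfg = ForestConfig(grid_n_trees=(10,), grid_min_leaf=(500,), seed=0)
        with pytest.raises(ValueError, match="grid"):
            tune(pairs, cfg, "regress")

    def test_deterministic_given_seed(self, rng):
        pairs = synth_pairs(rng, 150, task="classify")
        cfg = ForestConfig(grid_n_trees=(10, 20), grid_min_leaf=(2, 8), seed=9)
        a = tune(pairs, cfg, "classify_dx")
        b = tune(pairs, cfg, "classify_dx")
        assert (a.n_trees, a.min_leaf) == (b.n_trees, b.min_leaf)

    def test_pure_noise_oob_near_no_information_rate(self):
        """On targets independent of every feature the OOB misclassification
        rate hovers at the no-information rate (Monte-Carlo over 20 seeds,
        binomial 2-SE band)."""
        n = 200
        errors = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            pairs = []
            for i in range(n):
                dx = "NL" if i % 2 == 0 else "MCI"  # exactly balanced
                pairs.append(PairSample(rid=i, source_month=0, delta_t=1.0,
                                        features={"A": float(r.uniform()),
                                                  "B": float(r.uniform()),
                                                  "TIME_DELAY": float(r.uniform(1, 48))},
                                        target_dx=dx))
            model = train(pairs, ForestConfig(n_trees=30, min_leaf=5, seed=seed), "classify_dx")
            errors.append(model.oob_error)
        se = np.sqrt(0.25 / n)
        assert abs(np.mean(errors) - 0.5) < 2 * se


class TestVariableImportance:
    def test_informative_feature_ranks_top_across_seeds(self):
        """When the target is a function of feature A only, A scores highest;
        an appended pure-noise feature scores below it (5 seeds)."""
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            pairs = synth_pairs(r, 250, informative=True, task="classify",
                                extra_noise_feature=True)
            model = train(pairs, ForestConfig(n_trees=40, seed=seed), "classify_dx")
            report = variable_importance(model, pairs)
            top, _ = report.ranked()[0]
            assert top == "A"
            assert report.scores["NOISE"] < report.scores["A"]

    def test_single_tree_falls_back_to_raw_increase(self, rng):
        pairs = synth_pairs(rng, 100, task="classify")
        model = train(pairs, ForestConfig(n_trees=1, seed=0), "classify_dx")
        report = variable_importance(model, pairs)
        assert all(np.isfinite(v) for v in report.scores.values())

    def test_seeded_and_deterministic(self, rng):
        pairs = synth_pairs(rng, 120, task="regress")
        model = train(pairs, ForestConfig(n_trees=15, seed=8), "regress")
        a = variable_importance(model, pairs).scores
        b = variable_importance(model, pairs).scores
        assert a == b


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        pairs = synth_pairs(rng, 80, task="classify")
        model = train(pairs, ForestConfig(n_trees=10, seed=1), "classify_dx")
        path = tmp_path / "m.joblib"
        save_model(model, path)
        back = load_model(path)
        assert back.feature_names == model.feature_names
        assert back.seed == model.seed
        assert (predict_dx(back, pairs[:10]) == predict_dx(model, pairs[:10])).all()

    def test_loaded_model_refuses_mismatched_schema(self, rng, tmp_path):
        pairs = synth_pairs(rng, 80, task="classify")
        model = train(pairs, ForestConfig(n_trees=5, seed=1), "classify_dx")
        path = tmp_path / "m.joblib"
        save_model(model, path)
        back = load_model(path)
        bad = PairSample(rid=0, source_month=0, delta_t=1.0,
                         features={"Z": 0.0, "TIME_DELAY": 1.0}, target_dx=None)
        with pytest.raises(ValueError, match="mismatch"):
            predict_dx(back, [bad])
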