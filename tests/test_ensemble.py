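"""Balanced subsampling, single iterations, and the aggregated ensemble."""

import numpy as np
import pandas as pd
import pytest

from eggage import (
    EnsembleConfig,
    balanced_subsample,
    predict_dataset,
    regression_forest_variance_explained,
    run_ensemble,
    train_iteration,
)
from eggage.ensemble import _iteration_rng


def _toy_table(n_young=50, n_others=500, separation=10.0, seed=0, noise=1.0):
    """Two-class table split (optionally perfectly) by VT."""
    rng = np.random.default_rng(seed)
    n = n_young + n_others
    labels = np.array(["Young"] * n_young + ["Others"] * n_others)
    vt = np.where(labels == "Young", 100.0, 100.0 + separation)
    vt = vt + rng.normal(0, noise, n)
    t = pd.DataFrame(
        {
            "nest_id": [f"T{i}" for i in range(n)],
            "age_class": labels,
            "VT": vt,
            "VM": vt / 3.0,
            "Clutch": rng.integers(1, 6, n),
        }
    )
    t.attrs["predictors"] = ["VT", "VM", "Clutch"]
    return t


class TestBalancedSubsample:
    def test_downsamples_to_minority(self):
        t = _toy_table(50, 500)
        b = balanced_subsample(t, "AGE2", np.random.default_rng(1))
        counts = b["age_class"].value_counts()
        assert counts["Young"] == 50 and counts["Others"] == 50

    def test_balanced_input_preserved(self):
        t = _toy_table(40, 40)
        b = balanced_subsample(t, "AGE2", np.random.default_rng(2))
        assert b["age_class"].value_counts().to_dict() == {"Young": 40, "Others": 40}
        assert set(b["nest_id"]) == set(t["nest_id"])

    def test_empty_class_named(self):
        t = _toy_table(50, 500)
        t = t[t["age_class"] != "Young"]
        with pytest.raises(ValueError, match="Young"):
            balanced_subsample(t, "AGE2", np.random.default_rng(3))

    def test_inclusion_frequency_hypergeometric(self):
        # with counts {A: 2, B: 1000} each B row should appear w.p. 2/1000
        rng = np.random.default_rng(4)
        t = _toy_table(2, 1000)
        first_b = t[t["age_class"] == "Others"].iloc[0]["nest_id"]
        draws = 1000
        hits = sum(
            first_b in set(balanced_subsample(t, "AGE2", rng)["nest_id"])
            for _ in range(draws)
        )
        p = 2 / 1000
        se = np.sqrt(p * (1 - p) / draws)
        assert abs(hits / draws - p) < 3 * se + 1e-12


class TestTrainIteration:
    def test_separable_case_near_zero_oob(self):
        t = _toy_table(80, 80, separation=50.0, noise=1.0)
        res = train_iteration(
            t, t, EnsembleConfig(n_iterations=1, n_trees=100, seed=0),
            np.random.default_rng(0),
        )
        assert res.oob_error <= 0.05
        assert (res.full_predictions == t["age_class"].to_numpy()).mean() > 0.95

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(5)
        t = _toy_table(150, 150, separation=5.0)
        t = t.assign(age_class=rng.permutation(t["age_class"].to_numpy()))
        t.attrs["predictors"] = ["VT", "VM", "Clutch"]
        errors = [
            train_iteration(
                balanced_subsample(t, "AGE2", _iteration_rng(6, i)),
                t,
                EnsembleConfig(n_iterations=1, n_trees=100, seed=6),
                _iteration_rng(6, i),
            ).oob_error
            for i in range(10)
        ]
        assert 0.4 <= np.mean(errors) <= 0.6

    def test_confusion_rows_sum_to_class_counts(self):
        t = _toy_table(60, 60, separation=3.0)
        res = train_iteration(
            t, t, EnsembleConfig(n_trees=200, seed=1), np.random.default_rng(1)
        )
        # all rows get an OOB vote with 200 trees, so rows sum to class sizes
        assert res.confusion.sum(axis=1).to_dict() == {"Others": 60, "Young": 60}
        assert (res.gini >= 0).all()

    def test_single_class_rejected(self):
        t = _toy_table(50, 50)
        with pytest.raises(ValueError, match="single class"):
            train_iteration(
                t[t["age_class"] == "Young"], t,
                EnsembleConfig(seed=0), np.random.default_rng(0),
            )

    def test_noise_predictor_ranks_below_signal(self):
        rng = np.random.default_rng(7)
        wins = 0
        for i in range(50):
            t = _toy_table(60, 60, separation=8.0, seed=100 + i)
            t["noise"] = rng.normal(size=len(t))
            t["VM"] = rng.normal(size=len(t))  # kill the correlated copy
            t.attrs["predictors"] = ["VT", "noise", "VM", "Clutch"]
            res = train_iteration(
                t, t, EnsembleConfig(n_trees=60, seed=i), np.random.default_rng(i)
            )
            wins += res.gini["VT"] > res.gini["noise"]
        assert wins >= 48  # >= 95%


class TestRunEnsemble:
    def test_single_iteration_equals_iteration_metrics(self):
        t = _toy_table(60, 60, separation=4.0)
        cfg = EnsembleConfig(n_iterations=1, n_trees=100, seed=9)
        res = run_ensemble(t, cfg)
        rng = _iteration_rng(cfg.seed, 0)
        bal = balanced_subsample(t, "AGE2", rng)
        it = train_iteration(bal, t, cfg, rng)
        assert res.accuracy == pytest.approx(100 * (1 - it.oob_error))
        assert res.sensitivity == pytest.approx(it.sensitivity)
        assert (res.mismatch_counts.to_numpy() == (it.full_predictions != t["age_class"].to_numpy()).astype(int)).all()

    def test_seed_determinism(self):
        t = _toy_table(50, 200, separation=4.0)
        cfg = EnsembleConfig(n_iterations=5, n_trees=50, seed=11)
        r1, r2 = run_ensemble(t, cfg), run_ensemble(t, cfg)
        assert r1.accuracy == r2.accuracy
        pd.testing.assert_series_equal(r1.gini_aggregate, r2.gini_aggregate)
        pd.testing.assert_series_equal(r1.mismatch_counts, r2.mismatch_counts)

    def test_mismatch_bounds(self):
        t = _toy_table(40, 160, separation=2.0)
        cfg = EnsembleConfig(n_iterations=8, n_trees=40, seed=12)
        res = run_ensemble(t, cfg)
        assert res.mismatch_counts.between(0, 8).all()

    def test_aggregate_stable_in_iteration_count(self):
        # the aggregate is a mean over exchangeable iterations, so shrinking
        # the loop moves it very little (scaled-down version of 3000 vs 100)
        t = _toy_table(80, 320, separation=4.0, noise=2.0, seed=8)
        cfg = EnsembleConfig(n_trees=60, seed=21)
        acc_many = run_ensemble(t, cfg.replace(n_iterations=90)).accuracy
        acc_few = run_ensemble(t, cfg.replace(n_iterations=30)).accuracy
        assert abs(acc_many - acc_few) < 1.5

    def test_sensitivity_specificity_swap_under_transposed_positive(self):
        t = _toy_table(60, 240, separation=4.0, seed=3)
        base = EnsembleConfig(n_iterations=4, n_trees=60, seed=13)
        r_young = run_ensemble(t, base)
        r_other = run_ensemble(t, base.replace(positive_class="Others"))
        assert r_young.sensitivity == pytest.approx(r_other.specificity)
        assert r_young.specificity == pytest.approx(r_other.sensitivity)


class TestRegressionForest:
    def test_self_predicting_oracle(self):
        rng = np.random.default_rng(14)
        t = pd.DataFrame(
            {
                "nest_id": range(400),
                "age": rng.integers(3, 29, 400),
            }
        )
        t["age_copy"] = t["age"].astype(float)
        t["noise"] = rng.normal(size=400)
        t.attrs["predictors"] = ["age_copy", "noise"]
        assert regression_forest_variance_explained(
            t, EnsembleConfig(scheme="CONTINUOUS", n_trees=200, seed=0)
        ) > 95.0

    def test_pure_noise_near_zero_or_negative(self):
        rng = np.random.default_rng(15)
        t = pd.DataFrame(
            {
                "nest_id": range(400),
                "age": rng.integers(3, 29, 400),
                "n1": rng.normal(size=400),
                "n2": rng.normal(size=400),
            }
        )
        t.attrs["predictors"] = ["n1", "n2"]
        assert regression_forest_variance_explained(
            t, EnsembleConfig(scheme="CONTINUOUS", n_trees=200, seed=1)
        ) < 5.0

    def test_constant_age_rejected(self):
        t = pd.DataFrame({"nest_id": [1, 2], "age": [5, 5], "x": [0.0, 1.0]})
        t.attrs["predictors"] = ["x"]
        with pytest.raises(ValueError, match="constant"):
            regression_forest_variance_explained(t, EnsembleConfig(scheme="CONTINUOUS"))


class TestPredictDataset:
    def test_single_model_vote_equals_prediction(self):
        t = _toy_table(60, 60, separation=6.0)
        cfg = EnsembleConfig(n_iterations=1, n_trees=60, seed=16, keep_models=True)
        res = run_ensemble(t, cfg)
        preds, prop = predict_dataset(res, t)
        direct = res.models[0].predict(t[list(res.predictors)].to_numpy(float))
        assert (preds["predicted_class"].to_numpy() == direct).all()

    def test_heldout_match_rate_on_strong_signal(self):
        train = _toy_table(120, 480, separation=8.0, seed=20)
        test = _toy_table(40, 160, separation=8.0, seed=21)
        cfg = EnsembleConfig(n_iterations=10, n_trees=60, seed=17, keep_models=True)
        res = run_ensemble(train, cfg)
        preds, prop = predict_dataset(res, test)
        match = (preds["predicted_class"].to_numpy() == test["age_class"].to_numpy()).mean()
        assert match >= 0.7

    def test_all_young_table_majority_young(self):
        train = _toy_table(120, 480, separation=8.0, seed=22)
        cfg = EnsembleConfig(n_iterations=6, n_trees=60, seed=18, keep_models=True)
        res = run_ensemble(train, cfg)
        young_only = _toy_table(60, 1, separation=8.0, seed=23)
        preds, prop = predict_dataset(res, young_only)
        assert prop > 0.5

    def test_missing_columns_listed(self):
        t = _toy_table(60, 60)
        cfg = EnsembleConfig(n_iterations=1, n_trees=30, seed=19, keep_models=True)
        res = run_ensemble(t, cfg)
        with pytest.raises(ValueError, match="VT"):
            predict_dataset(res, t.drop(columns=["VT"]))

    def test_models_required(self):
        t = _toy_table(60, 60)
        res = run_ensemble(t, EnsembleConfig(n_iterations=1, n_trees=30, seed=20))
        with pytest.raises(ValueError, match="keep_models"):
            predict_dataset(res, t)
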