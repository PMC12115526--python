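import numpy as np
import pandas as pd
import pytest

from glucowear.modeling import (
    fit_model,
    rank_and_select,
    run_protocol,
    split_train_test,
)


def make_table(n=500, n_feats=8, seed=0, target="linear"):
    """Synthetic feature table with a controllable glucose-generating rule."""
    rng = np.random.default_rng(seed)
    feats = {f"f{i}": rng.standard_normal(n) for i in range(n_feats)}
    if target == "linear":
        y = 2.0 * feats["f1"] + 3.0
    elif target == "step":
        y = np.where(feats["f1"] > 0, 140.0, 90.0)
    elif target == "strong_f7":
        y = 100.0 + 3.0 * feats["f7"] + 0.1 * rng.standard_normal(n)
    else:
        y = 100 + rng.standard_normal(n)
    return pd.DataFrame(
        {
            "participant_id": ["S01"] * n,
            "glucose_time": np.arange(n) * 300.0,
            "glucose": y + 100.0,
            **feats,
        }
    )


class TestSplit:
    def test_published_cohort_arithmetic(self):
        table = make_table(26380, n_feats=1, target="noise")
        split = split_train_test(table, 0.8, seed=0)
        assert len(split.train_idx) == 21104
        assert len(split.test_idx) == 5276

    def test_small_exact_fraction(self):
        split = split_train_test(make_table(10, n_feats=2), 0.8, seed=1)
        assert len(split.train_idx) == 8 and len(split.test_idx) == 2

    def test_deterministic_and_partitioning(self):
        table = make_table(101)
        s1 = split_train_test(table, seed=7)
        s2 = split_train_test(table, seed=7)
        np.testing.assert_array_equal(s1.train_idx, s2.train_idx)
        combined = np.concatenate([s1.train_idx, s1.test_idx])
        assert len(np.intersect1d(s1.train_idx, s1.test_idx)) == 0
        np.testing.assert_array_equal(np.sort(combined), np.arange(101))

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_train_test(make_table(9), 0.8, 0)

    def test_participant_level_split_keeps_participants_together(self):
        table = make_table(200, n_feats=2, target="noise")
        table["participant_id"] = np.repeat([f"S{i:02d}" for i in range(10)], 20)
        split = split_train_test(table, 0.8, seed=0, by="participant")
        train_pids = set(table.iloc[split.train_idx]["participant_id"])
        test_pids = set(table.iloc[split.test_idx]["participant_id"])
        assert train_pids.isdisjoint(test_pids)
        assert len(split.test_idx) > 0
        assert len(split.train_idx) >= 0.8 * 200


class TestSelection:
    def test_retains_exactly_k(self):
        table = make_table(300, n_feats=40)
        sel = rank_and_select(table, k=30, seed=0)
        assert len(sel.retained) == 30
        assert (sel.ranking["rank"].to_numpy() == np.arange(1, 41)).all()
        assert (sel.ranking["importance"].to_numpy() >= 0).all()

    def test_strong_predictor_ranks_first(self):
        table = make_table(500, n_feats=8, target="strong_f7")
        sel = rank_and_select(table, k=3, seed=0)
        assert sel.ranking.iloc[0]["feature_name"] == "f7"
        assert "f7" in sel.retained

    def test_noise_feature_importance_below_median(self):
        # six informative features, two pure-noise columns: the noise columns
        # must rank in the bottom half
        rng = np.random.default_rng(3)
        n = 800
        feats = {f"f{i}": rng.standard_normal(n) for i in range(8)}
        y = 100.0 + sum(feats[f"f{i}"] for i in range(6))
        table = pd.DataFrame(
            {"participant_id": ["S01"] * n, "glucose_time": np.arange(n) * 300.0,
             "glucose": y, **feats}
        )
        sel = rank_and_select(table, k=5, seed=1)
        imp = sel.ranking.set_index("feature_name")["importance"]
        median = np.median(imp)
        assert imp["f6"] < median and imp["f7"] < median

    def test_k_larger_than_features_warns_and_keeps_all(self):
        table = make_table(100, n_feats=4)
        with pytest.warns(UserWarning):
            sel = rank_and_select(table, k=30, seed=0)
        assert len(sel.retained) == 4


class TestFitModel:
    def test_lr_interpolates_linear_truth(self):
        table = make_table(200, target="linear")
        test = make_table(100, target="linear", seed=9)
        model = fit_model("LR", table, ["f1"], seed=0)
        rmse = np.sqrt(np.mean((model.predict(test) - test["glucose"]) ** 2))
        assert rmse < 1e-6

    def test_ridge_zero_penalty_reduces_to_lr(self):
        table = make_table(200, n_feats=5, target="linear")
        feats = [f"f{i}" for i in range(5)]
        lr = fit_model("LR", table, feats, seed=0)
        rr = fit_model("RR", table, feats, grid={"regressor__alpha": [1e-10]}, seed=0)
        np.testing.assert_allclose(
            lr.pipeline["regressor"].coef_, rr.pipeline["regressor"].coef_, atol=1e-8
        )

    def test_xgboost_beats_linear_on_step_function(self):
        table = make_table(600, target="step")
        test = make_table(300, target="step", seed=5)
        xr = fit_model(
            "XR", table, ["f1"],
            grid={"regressor__n_estimators": [100], "regressor__max_depth": [3]},
            seed=0,
        )
        lr = fit_model("LR", table, ["f1"], seed=0)
        rmse = lambda m: np.sqrt(np.mean((m.predict(test) - test["glucose"]) ** 2))
        assert rmse(xr) < rmse(lr)

    def test_grid_search_records_cv_table(self):
        table = make_table(120)
        model = fit_model(
            "RR", table, ["f1", "f2"], grid={"regressor__alpha": [0.1, 10.0]}, seed=0
        )
        assert len(model.cv_table) == 2
        assert np.isfinite(model.cv_table["mean_cv_rmse"]).all()

    def test_constant_target_raises(self):
        table = make_table(100)
        table["glucose"] = 100.0
        with pytest.raises(ValueError):
            fit_model("LR", table, ["f1"], seed=0)


class TestProtocol:
    def test_single_repetition_aggregate_identity(self):
        table = make_table(200, target="linear")
        report = run_protocol(table, n_reps=1, base_seed=0, families=["LR"], k=3)
        row = report.per_repetition.iloc[0]
        agg = report.aggregate.loc["LR"]
        np.testing.assert_allclose(agg[("rmse", "mean")], row["rmse"])
        assert agg[("rmse", "std")] == 0.0

    def test_aggregate_mean_is_arithmetic_mean(self):
        table = make_table(300, target="step")
        report = run_protocol(table, n_reps=3, base_seed=2, families=["LR"], k=2)
        per = report.per_repetition
        np.testing.assert_allclose(
            report.aggregate.loc["LR", ("rmse", "mean")],
            per.loc[per["model"] == "LR", "rmse"].mean(),
            rtol=1e-12,
        )

    def test_protocol_is_deterministic(self):
        table = make_table(200, target="step")
        r1 = run_protocol(table, n_reps=2, base_seed=5, families=["LR"], k=2)
        r2 = run_protocol(table, n_reps=2, base_seed=5, families=["LR"], k=2)
        pd.testing.assert_frame_equal(r1.per_repetition, r2.per_repetition)

    def test_selection_repeated_per_repetition(self):
        table = make_table(300, target="strong_f7", n_feats=10)
        report = run_protocol(table, n_reps=2, base_seed=0, families=["LR"], k=3)
        assert len(report.selections) == 2


class TestNoLeakage:
    def test_corrupting_test_rows_changes_nothing_fitted(self):
        table = make_table(400, n_feats=8, target="strong_f7")
        split = split_train_test(table, seed=3)

        def fit_artifacts(tbl):
            train = tbl.iloc[split.train_idx]
            sel = rank_and_select(train, k=4, seed=3)
            model = fit_model("LR", train, sel, seed=3)
            return sel, model

        sel_a, model_a = fit_artifacts(table)
        corrupted = table.copy()
        feat_cols = [f"f{i}" for i in range(8)]
        corrupted.loc[corrupted.index[split.test_idx], feat_cols] = 9999.0
        corrupted.loc[corrupted.index[split.test_idx], "glucose"] = 1.0
        sel_b, model_b = fit_artifacts(corrupted)

        pd.testing.assert_frame_equal(sel_a.ranking, sel_b.ranking)
        np.testing.assert_array_equal(
            model_a.pipeline["imputer"].statistics_, model_b.pipeline["imputer"].statistics_
        )
        np.testing.assert_array_equal(
            model_a.pipeline["scaler"].mean_, model_b.pipeline["scaler"].mean_
        )
        np.testing.assert_array_equal(
            model_a.pipeline["scaler"].scale_, model_b.pipeline["scaler"].scale_
        )
        np.testing.assert_array_equal(
            model_a.pipeline["regressor"].coef_, model_b.pipeline["regressor"].coef_
        )
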