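"""Splitting, logistic models and bootstrap comparison."""

import numpy as np
import pandas as pd
import pytest

from afhrv.errors import ValidationError
from afhrv.models import (SplitSpec, bootstrap_metrics, compare_models,
                          evaluate_model, fit_logistic, split_train_test)
from afhrv.synthetic import DatasetSpec, gen_labelled_dataset


@pytest.fixture(scope="module")
def table():
    _, t = gen_labelled_dataset(DatasetSpec(n_sr=90, n_af=90, seed=11,
                                            segments_per_record=10))
    return t


def _noise_table(table, seed=5):
    t = table.copy()
    t["noise"] = np.random.default_rng(seed).normal(size=len(t))
    return t


class TestSplit:
    def test_by_segment_counts_and_disjointness(self, table):
        train, test = split_train_test(table, SplitSpec(mode="by_segment", seed=1))
        assert len(train) + len(test) == len(table)
        assert len(train) == round(2 / 3 * len(table))
        assert set(train.index).isdisjoint(test.index)

    def test_by_record_keeps_records_whole(self, table):
        train, test = split_train_test(table, SplitSpec(mode="by_record", seed=1))
        assert set(train["record_id"]).isdisjoint(test["record_id"])
        assert len(train) + len(test) == len(table)

    def test_deterministic_given_seed(self, table):
        a = split_train_test(table, SplitSpec(seed=42))
        b = split_train_test(table, SplitSpec(seed=42))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValidationError):
            SplitSpec(ratio=1.5)


class TestFitLogistic:
    def test_uninformative_feature_gives_near_zero_coefficient(self, table):
        t = _noise_table(table)
        train, test = split_train_test(t, SplitSpec(mode="by_segment", seed=2))
        model = fit_logistic(train, ["noise"])
        assert abs(model.coefficients[0]) < 0.5
        # auto-orientation folds AUC above 0.5; pure noise stays near chance
        assert evaluate_model(model, test).auc <= 0.70

    def test_separated_feature_fits_af_high_with_high_auc(self, table):
        train, test = split_train_test(table, SplitSpec(seed=2))
        model = fit_logistic(train, ["pRR3.25"])
        assert model.coefficients[0] > 0  # AF has the higher pRR3.25%
        assert evaluate_model(model, test).auc >= 0.95

    def test_recovers_generating_direction_across_seeds(self):
        rng = np.random.default_rng(0)
        correct = 0
        for _ in range(100):
            x_sr = rng.normal(0, 1, 40)
            x_af = rng.normal(1.5, 1, 40)
            df = pd.DataFrame({
                "f": np.concatenate([x_sr, x_af]),
                "class_label": ["SR"] * 40 + ["AF"] * 40,
            })
            correct += fit_logistic(df, ["f"]).coefficients[0] > 0
        assert correct >= 99

    def test_constant_feature_rejected(self, table):
        t = table.copy()
        t["flat"] = 1.0
        with pytest.raises(ValidationError):
            fit_logistic(t, ["flat"])

    def test_perfect_separation_warns_and_caps(self):
        df = pd.DataFrame({"f": np.concatenate([np.zeros(30), np.ones(30)]),
                           "class_label": ["SR"] * 30 + ["AF"] * 30})
        with pytest.warns(UserWarning, match="separation"):
            model = fit_logistic(df, ["f"])
        assert np.isfinite(model.coefficients).all()
        assert np.abs(model.coefficients).max() <= 30.0


class TestEvaluate:
    def test_fp_fn_accuracy_identity(self, table):
        train, test = split_train_test(table, SplitSpec(seed=3))
        model = fit_logistic(train, ["pRR30", "HNR"])
        res = evaluate_model(model, test)
        assert res.fp_pct + res.fn_pct == pytest.approx(100.0 - res.confusion.accuracy)

    def test_two_feature_model_not_worse_than_univariates(self, table):
        train, test = split_train_test(table, SplitSpec(seed=3))
        pair = evaluate_model(fit_logistic(train, ["pRR3.25", "HNR"]), test).auc
        singles = [evaluate_model(fit_logistic(train, [f]), test).auc
                   for f in ("pRR3.25", "HNR")]
        assert pair >= max(singles) - 0.01

    def test_youden_threshold_option(self, table):
        train, test = split_train_test(table, SplitSpec(seed=3))
        model = fit_logistic(train, ["H"])
        res = evaluate_model(model, test, threshold="youden", train=train)
        assert 0 <= res.confusion.accuracy <= 100
        with pytest.raises(ValidationError):
            evaluate_model(model, test, threshold="youden")

    def test_missing_feature_column_rejected(self, table):
        train, test = split_train_test(table, SplitSpec(seed=3))
        model = fit_logistic(train, ["pRR30"])
        with pytest.raises(ValidationError):
            model.predict_proba(test.drop(columns=["pRR30"]))


class TestBootstrap:
    def test_deterministic_given_seed(self, table):
        train, test = split_train_test(table, SplitSpec(seed=4))
        models = {"a": fit_logistic(train, ["pRR3.25"])}
        r1, p1 = bootstrap_metrics(models, test, b=100, seed=9)
        r2, p2 = bootstrap_metrics(models, test, b=100, seed=9)
        for c1, c2 in zip(r1, r2):
            np.testing.assert_array_equal(c1.values, c2.values)
            assert (c1.ci_low, c1.ci_high) == (c2.ci_low, c2.ci_high)
        pd.testing.assert_frame_equal(p1, p2)

    def test_identical_models_degenerate_difference(self, table):
        train, test = split_train_test(table, SplitSpec(seed=4))
        m = fit_logistic(train, ["pRR30"])
        _, pvals = bootstrap_metrics({"a": m, "b": m}, test, b=100, seed=9)
        assert (pvals["mean_diff"] == 0).all()
        assert (pvals["p_value"] == 1.0).all()

    def test_pure_noise_addition_leaves_auc_difference_straddling_zero(self, table):
        t = _noise_table(table)
        train, test = split_train_test(t, SplitSpec(seed=4))
        models = {"base": fit_logistic(train, ["pRR3.25"]),
                  "plus_noise": fit_logistic(train, ["pRR3.25", "noise"])}
        comps, _ = bootstrap_metrics(models, test, b=200, seed=9)
        auc = {c.model_name: c for c in comps if c.metric_name == "auc"}
        diff = auc["base"].values - auc["plus_noise"].values
        lo, hi = np.percentile(diff, [2.5, 97.5])
        assert lo <= 0 <= hi

    def test_ci_bounds_are_percentiles(self, table):
        train, test = split_train_test(table, SplitSpec(seed=4))
        comps, _ = bootstrap_metrics({"a": fit_logistic(train, ["HNR"])},
                                     test, b=100, seed=9)
        for c in comps:
            assert c.ci_low == pytest.approx(np.percentile(c.values, 2.5))
            assert c.ci_high == pytest.approx(np.percentile(c.values, 97.5))


class TestCompareModels:
    def test_prr325_wins_among_singles(self, table):
        train, test = split_train_test(table, SplitSpec(seed=6))
        singles = [[f] for f in ("pRR30", "pRR3.25", "H", "HAR", "HDR", "HNR")]
        report = compare_models(singles, train, test)
        report = report.set_index("features")["auc"]
        # pRR3.25% shares the top (ties with pRR30 possible at near-perfect
        # separation) and clearly beats every entropy feature
        assert report["pRR3.25"] >= report.max() - 0.01
        assert report["pRR3.25"] >= 0.95
        assert report["pRR3.25"] >= report["H"]

    def test_duplicate_features_deduplicated_with_warning(self, table):
        train, test = split_train_test(table, SplitSpec(seed=6))
        with pytest.warns(UserWarning, match="duplicate"):
            report = compare_models([["pRR30", "pRR30"]], train, test)
        assert report.loc[0, "features"] == "pRR30"

    def test_empty_feature_set_rejected(self, table):
        train, test = split_train_test(table, SplitSpec(seed=6))
        with pytest.raises(ValidationError):
            compare_models([[]], train, test)
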