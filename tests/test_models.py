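import numpy as np
import pandas as pd
import pytest

from utfmp.models import (
    CvSpec,
    ModelSpec,
    SplitSpec,
    default_model_specs,
    fit_plsda,
    metrics_from_confusion,
    run_suite,
    stratified_split,
    suite_summary,
)


def _two_cluster_table(n_per_class=60, separation=6.0, n_features=4, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, (n_per_class, n_features))
    X1 = rng.normal(0.0, 1.0, (n_per_class, n_features))
    X1[:, :2] += separation
    table = pd.DataFrame(
        np.vstack([X0, X1]), columns=[f"f{i}" for i in range(n_features)]
    )
    table["group"] = ["control"] * n_per_class + ["malignant"] * n_per_class
    table.index = [f"S{i:03d}" for i in range(2 * n_per_class)]
    return table


class TestStratifiedSplit:
    def test_study_size_split(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"f0": rng.normal(size=173)})
        table["group"] = ["control"] * 96 + ["malignant"] * 77
        table.index = [f"S{i}" for i in range(173)]
        train, test = stratified_split(table, SplitSpec(seed=1))
        assert len(test) in (51, 52, 53)
        for g, n in (("control", 96), ("malignant", 77)):
            got = (test["group"] == g).sum()
            assert abs(got - round(n * 0.3)) <= 1
        # class proportions within 2 percentage points of 96:77
        assert abs((test["group"] == "control").mean() - 96 / 173) < 0.02

    def test_deterministic(self):
        table = _two_cluster_table(10, 1.0)
        t1 = stratified_split(table, SplitSpec(seed=5))
        t2 = stratified_split(table, SplitSpec(seed=5))
        assert list(t1[0].index) == list(t2[0].index)
        assert list(t1[1].index) == list(t2[1].index)

    def test_partitions_disjoint_exhaustive(self):
        table = _two_cluster_table(15, 1.0)
        train, test = stratified_split(table, SplitSpec(seed=2))
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(table.index)

    def test_tiny_class_rejected(self):
        table = _two_cluster_table(10, 1.0).iloc[:11]  # 10 control + 1 malignant
        with pytest.raises(ValueError, match="too small"):
            stratified_split(table, SplitSpec())

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=0.7, test_fraction=0.2)


class TestMetricsPanel:
    def test_worked_example(self):
        panel = metrics_from_confusion(tp=16, fn=4, tn=18, fp=2)
        assert panel["sensitivity"] == pytest.approx(0.8)
        assert panel["specificity"] == pytest.approx(0.9)
        assert panel["plr"] == pytest.approx(8.0)
        assert panel["nlr"] == pytest.approx(0.2 / 0.9)
        assert panel["accuracy"] == pytest.approx(0.85)

    def test_zero_fp_flags_plr(self):
        panel = metrics_from_confusion(tp=10, fn=2, tn=20, fp=0)
        assert panel["specificity"] == 1.0
        assert np.isnan(panel["plr"])

    def test_formula_oracle_on_random_counts(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 40, 4)
            if tp + fp + tn + fn == 0:
                continue
            panel = metrics_from_confusion(int(tp), int(fp), int(tn), int(fn))
            # independent recomputation of every identity
            if tp + fn:
                assert panel["sensitivity"] == tp / (tp + fn)
            if tn + fp:
                assert panel["specificity"] == tn / (tn + fp)
            if tp + fp:
                assert panel["ppv"] == tp / (tp + fp)
            if tn + fn:
                assert panel["npv"] == tn / (tn + fn)
            assert panel["accuracy"] == (tp + tn) / (tp + fp + tn + fn)
            if (tp + fn) and (tn + fp) and fp:
                assert panel["plr"] == pytest.approx(
                    panel["sensitivity"] / (1 - panel["specificity"])
                )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(-1, 0, 1, 1)


class TestPlsda:
    def test_separated_clusters(self):
        table = _two_cluster_table(100, 6.0, seed=3)
        train, test = stratified_split(table, SplitSpec(seed=3))
        res = fit_plsda(train, test, n_components=2, seed=3)
        assert res.accuracy >= 0.98
        assert res.auc >= 0.99
        assert res.r2 > 0.5
        assert res.q2 <= res.r2 + 1e-9
        supports = [d["support"] for d in res.report.values()]
        assert sum(supports) == len(test)

    def test_permutation_null_q2(self):
        rng = np.random.default_rng(0)
        table = _two_cluster_table(50, 2.0, seed=4)
        q2s = []
        for i in range(50):
            permuted = table.copy()
            permuted["group"] = rng.permutation(permuted["group"].to_numpy())
            train, test = stratified_split(permuted, SplitSpec(seed=i))
            res = fit_plsda(train, test, n_components=2, seed=i)
            q2s.append(res.q2)
        assert np.mean(q2s) <= 0.05

    def test_constant_response_rejected(self):
        table = _two_cluster_table(20, 1.0)
        table["group"] = "control"
        with pytest.raises(ValueError, match="degenerate|stratify|too small"):
            train, test = stratified_split(table, SplitSpec())
            fit_plsda(train, test)

    def test_excess_components_rejected(self):
        table = _two_cluster_table(20, 3.0, n_features=3)
        train, test = stratified_split(table, SplitSpec())
        with pytest.raises(ValueError, match="components"):
            fit_plsda(train, test, n_components=10)


@pytest.fixture(scope="module")
def reports():
    table = _two_cluster_table(40, 6.0, seed=7)
    cv = CvSpec(n_folds=5, n_repetitions=2, seed=11)
    return run_suite(table, default_model_specs(), cv, SplitSpec(seed=11)), table


class TestRunSuite:

    def test_strong_effect_all_models_high_auc(self, reports):
        reps, _ = reports
        for r in reps:
            assert r.cv_mean["auc"] >= 0.95, r.model

    def test_metric_identities_every_fold(self, reports):
        reps, _ = reports
        for r in reps:
            fm = r.fold_metrics
            mask = fm["specificity"] < 1.0
            np.testing.assert_allclose(
                fm.loc[mask, "plr"],
                fm.loc[mask, "sensitivity"] / (1 - fm.loc[mask, "specificity"]),
            )
            mask = fm["specificity"] > 0.0
            np.testing.assert_allclose(
                fm.loc[mask, "nlr"],
                (1 - fm.loc[mask, "sensitivity"]) / fm.loc[mask, "specificity"],
            )

    def test_pooled_confusion_counts(self, reports):
        reps, table = reports
        n_train = round(len(table) * 0.7)
        for r in reps:
            total = sum(r.cv_pooled_confusion.values())
            assert total == n_train * 2  # every training sample predicted once per repetition
            assert sum(r.test_confusion.values()) == len(table) - n_train

    def test_determinism(self):
        table = _two_cluster_table(30, 2.0, seed=9)
        cv = CvSpec(n_folds=5, n_repetitions=2, seed=3)
        a = suite_summary(run_suite(table, default_model_specs(), cv, SplitSpec(seed=3)))
        b = suite_summary(run_suite(table, default_model_specs(), cv, SplitSpec(seed=3)))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_model_rejected(self):
        table = _two_cluster_table(20, 2.0)
        with pytest.raises(ValueError, match="unknown model"):
            run_suite(table, [ModelSpec("MLP")])

    def test_benign_rows_dropped(self):
        table = _two_cluster_table(30, 6.0, seed=5)
        benign = table.iloc[:10].copy()
        benign["group"] = "benign"
        benign.index = [f"B{i}" for i in range(10)]
        with_benign = pd.concat([table, benign])
        reps = run_suite(with_benign, [ModelSpec("LR")], CvSpec(5, 1, 0), SplitSpec(seed=0))
        assert sum(reps[0].cv_pooled_confusion.values()) + sum(reps[0].test_confusion.values()) == len(table)

    def test_summary_shape(self, reports):
        reps, _ = reports
        summary = suite_summary(reps)
        assert len(summary) == 4 * 8  # 4 models x 8 metrics
        assert {"cv_mean", "cv_sd", "cv_pooled", "test"} <= set(summary.columns)
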