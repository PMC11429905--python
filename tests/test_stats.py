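import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from utfmp.stats import marker_roc_table, roc_analysis, significance_stars, wilson_interval
from utfmp.stats import test_group_differences as group_differences


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestWilson:
    def test_zero_successes_lower_bound_zero(self):
        ci = wilson_interval(0, 10)
        assert ci.lower == 0.0
        assert ci.estimate == 0.0
        assert ci.upper > 0.0

    def test_closed_form_5_of_10(self):
        # hand evaluation of the Wilson expression with z = 1.959964
        z = 1.959963984540054
        n, p = 10, 0.5
        denom = 1 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = (z / denom) * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
        ci = wilson_interval(5, 10)
        assert ci.lower == pytest.approx(center - half, abs=1e-12)
        assert ci.upper == pytest.approx(center + half, abs=1e-12)

    def test_converges_to_wald_for_large_n(self):
        n, k = 100_000, 37_000
        p = k / n
        wald_half = 1.959963984540054 * np.sqrt(p * (1 - p) / n)
        ci = wilson_interval(k, n)
        assert ci.lower == pytest.approx(p - wald_half, abs=1e-3)
        assert ci.upper == pytest.approx(p + wald_half, abs=1e-3)

    def test_matches_statsmodels_on_grid(self):
        from statsmodels.stats.proportion import proportion_confint

        for n in (5, 17, 50, 200):
            for k in range(0, n + 1, max(1, n // 7)):
                lo, hi = proportion_confint(k, n, method="wilson")
                ci = wilson_interval(k, n)
                assert ci.lower == pytest.approx(lo, abs=1e-10)
                assert ci.upper == pytest.approx(hi, abs=1e-10)

    @given(st.integers(1, 500), st.data())
    def test_bounds_bracket_estimate(self, n, data):
        k = data.draw(st.integers(0, n))
        ci = wilson_interval(k, n)
        assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 1.0

    def test_successes_above_n_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(11, 10)


class TestGroupDifferences:
    @staticmethod
    def _table(groups_values):
        rows = []
        for g, values in groups_values.items():
            rows += [{"group": g, "x": v} for v in values]
        return pd.DataFrame(rows)

    def test_type_i_error_near_nominal(self, rng):
        # three groups from one distribution: global test rejects ~5%
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            table = self._table(
                {g: rng.exponential(1.0, 15) for g in ("control", "benign", "malignant")}
            )
            res = group_differences(table, "x", mode="nonparametric")
            rejections += res.global_p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_identical_values_degenerate(self):
        table = self._table({"control": [5.0] * 5, "benign": [5.0] * 5, "malignant": [5.0] * 5})
        res = group_differences(table, "x")
        assert res.global_p == 1.0
        assert all(c.p_adjusted == 1.0 for c in res.pairwise)

    def test_bonferroni_multiplies_by_three(self, rng):
        # calibrate against a direct Dunn z computation on one comparison
        table = self._table(
            {
                "control": rng.normal(0, 1, 20),
                "benign": rng.normal(0.5, 1, 20),
                "malignant": rng.normal(2.0, 1, 20),
            }
        )
        res = group_differences(table, "x", mode="nonparametric")
        assert len(res.pairwise) == 3
        # recompute one raw Dunn p and check the x3 cap-at-1 adjustment
        values = table["x"].to_numpy()
        ranks = sps.rankdata(values)
        groups = table["group"].to_numpy()
        n = len(values)
        var = n * (n + 1) / 12.0
        for comp in res.pairwise:
            a, b = comp.pair
            ra = ranks[groups == a].mean()
            rb = ranks[groups == b].mean()
            z = (ra - rb) / np.sqrt(var * (1 / 20 + 1 / 20))
            raw = 2 * sps.norm.sf(abs(z))
            assert comp.p_adjusted == pytest.approx(min(1.0, raw * 3), rel=1e-9)

    def test_auto_routes_normal_data_to_anova(self, rng):
        table = self._table({g: rng.normal(0, 1, 40) for g in ("control", "malignant")})
        res = group_differences(table, "x", mode="auto")
        assert res.global_test == "anova"
        assert res.pairwise[0].adjustment == "tukey_hsd"

    def test_auto_routes_skewed_data_to_kruskal(self, rng):
        table = self._table({g: rng.lognormal(0, 1.5, 40) for g in ("control", "malignant")})
        res = group_differences(table, "x", mode="auto")
        assert res.global_test == "kruskal_wallis"
        assert res.pairwise[0].adjustment == "dunn_bonferroni"

    def test_detects_a_real_shift(self, rng):
        table = self._table(
            {"control": rng.normal(0, 1, 50), "malignant": rng.normal(2, 1, 50)}
        )
        res = group_differences(table, "x")
        assert res.global_p < 1e-4
        assert res.medians["malignant"] > res.medians["control"]

    def test_small_group_rejected(self):
        table = self._table({"control": [1.0, 2.0], "malignant": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            group_differences(table, "x")

    def test_adjusted_p_at_least_raw(self, rng):
        table = self._table(
            {g: rng.normal(i * 0.3, 1, 25) for i, g in enumerate(("control", "benign", "malignant"))}
        )
        res = group_differences(table, "x", mode="nonparametric")
        assert all(0 <= c.p_adjusted <= 1 for c in res.pairwise)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert roc_analysis(scores, labels).auc == 1.0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(500):
            n1, n0 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            scores = rng.integers(0, 6, n1 + n0).astype(float)  # many ties
            res = roc_analysis(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 300)
        labels[:2] = [0, 1]
        scores = rng.normal(labels, 1.2)
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_complement_under_sign_flip(self, rng):
        labels = np.r_[np.ones(40, int), np.zeros(60, int)]
        scores = rng.normal(labels, 1.0)  # tie-free continuous scores
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        scores = rng.normal(labels, 1.0)
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_polarity_flips_orientation(self, rng):
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        scores = rng.normal(1 - labels, 0.5)  # lower score means positive
        res = roc_analysis(scores, labels, polarity="lower_is_positive")
        assert res.auc > 0.85

    def test_ci_contains_point_estimate(self, rng):
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        scores = rng.normal(labels * 0.8, 1.0)
        res = roc_analysis(scores, labels)
        assert res.auc_ci_95[0] <= res.auc <= res.auc_ci_95[1]
        for ci in res.sensitivity + res.specificity:
            assert ci.lower <= ci.estimate <= ci.upper

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1.0, 2.0], [1, 1])

    def test_null_p_value_uniformish(self, rng):
        # under the null the AUC test should not reject wildly
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        ps = [
            roc_analysis(rng.normal(0, 1, 200), labels).p_value for _ in range(200)
        ]
        assert 0.005 <= np.mean(np.asarray(ps) < 0.05) <= 0.12


class TestMarkerTable:
    def test_two_markers_with_orientation(self, small_feature_table):
        table = marker_roc_table(small_feature_table, "malignant")
        assert set(table["marker"]) == {"Z4a_over_Z5", "Z6_over_Z7"}
        # correctly oriented markers report AUC >= 0.5 by construction
        assert (table["auc"] >= 0.5).all()


def test_significance_star_mapping():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-5) == "****"
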