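"""Feature assembly, group tests, correlation, logistic regression and ROC."""

import numpy as np
import pandas as pd
import pytest

from lungeud.stats import (
    ConvergenceError,
    build_feature_table,
    correlation_table,
    group_comparison_table,
    multivariate_logistic,
    pearson,
    physical_composite,
    roc_analysis,
    stratify,
    two_sample_t,
)


class TestPhysicalComposite:
    def test_reported_group_means_bracket_the_cutoff(self):
        """At the two groups' mean metrics the composite sits either side of 6.075."""
        grp = physical_composite(1239.87, 44.07, 32.60, 22.73, 15.87)
        gnrp = physical_composite(1094.13, 39.55, 28.17, 19.70, 13.55)
        assert grp == pytest.approx(6.43, abs=0.01)
        assert gnrp == pytest.approx(3.25, abs=0.01)
        assert gnrp < 6.075 < grp

    def test_zero_component_zeroes_score(self):
        assert physical_composite(1200.0, 0.0, 30.0, 20.0, 10.0) == 0.0

    def test_monotone_in_each_component(self):
        base = (1200.0, 40.0, 30.0, 20.0, 14.0)
        ref = physical_composite(*base)
        for i in range(5):
            bumped = list(base)
            bumped[i] *= 1.1
            assert physical_composite(*bumped) > ref

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            physical_composite(1200.0, np.nan, 30.0, 20.0, 10.0)


class TestTwoSampleT:
    def test_pooled_hand_computation(self):
        """x={1,2,3}, y={4,5,6}: pooled SE = sqrt(2/3), t = 3/SE = 3.674."""
        res = two_sample_t([1, 2, 3], [4, 5, 6], variant="pooled")
        assert res.t == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert res.p == pytest.approx(0.021312, abs=1e-4)

    def test_identical_groups_null(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_constant_equal_groups_defined(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 200)
        pvals = [two_sample_t(x, x + shift).p for shift in (0.1, 0.3, 0.6)]
        assert pvals[0] > pvals[1] > pvals[2]

    def test_sign_convention_negative_when_rp_group_larger(self):
        df = pd.DataFrame(
            {"rp2": [1] * 5 + [0] * 5, "metric": [10.0, 11, 12, 13, 14, 1, 2, 3, 4, 5]}
        )
        table = group_comparison_table(df, variables=["metric"])
        assert table.loc["metric", "t"] < 0
        assert table.loc["metric", "mean_grp"] > table.loc["metric", "mean_gnrp"]

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),
            ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_closed_form_values(self, x, y, expected):
        r, _ = pearson(x, y)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestMultivariateLogistic:
    def test_known_coefficient_recovery(self):
        """logit(p) = -1 + 2 z is recovered within +/-0.2 at n = 2000."""
        rng = np.random.default_rng(42)
        z = rng.standard_normal(2000)
        p = 1.0 / (1.0 + np.exp(1.0 - 2.0 * z))
        y = (rng.random(2000) < p).astype(int)
        out = multivariate_logistic(pd.DataFrame({"z": z}), y)
        assert out.loc["z", "B"] == pytest.approx(2.0, abs=0.2)
        assert out.loc["const", "B"] == pytest.approx(-1.0, abs=0.2)

    def test_null_feature_not_significant(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(1000)
        y = (rng.random(1000) < 0.3).astype(int)
        out = multivariate_logistic(pd.DataFrame({"z": z}), y)
        assert abs(out.loc["z", "B"]) < 0.2
        assert out.loc["z", "p"] > 0.05

    def test_wald_is_squared_z(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(400)
        y = (rng.random(400) < 1.0 / (1.0 + np.exp(-z))).astype(int)
        out = multivariate_logistic(pd.DataFrame({"z": z}), y)
        assert np.allclose(out["Wald"], (out["B"] / out["SE"]) ** 2)

    def test_gradient_vanishes_at_optimum(self):
        """The log-likelihood score at the returned estimate is numerically zero."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        z = rng.standard_normal(500)
        y = (rng.random(500) < 1.0 / (1.0 + np.exp(0.5 - z))).astype(int)
        X = pd.DataFrame({"z": (z - z.mean()) / z.std(ddof=0)})
        out = multivariate_logistic(X, y)
        model = sm.Logit(y.astype(float), sm.add_constant(X))
        score = model.score(out["B"].to_numpy())
        assert np.max(np.abs(score)) < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            multivariate_logistic(pd.DataFrame({"z": [1.0, 2.0, 3.0]}), [0, 0, 0])

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            multivariate_logistic(
                pd.DataFrame({"z": [1.0, 1.0, 1.0, 1.0]}), [0, 1, 0, 1]
            )

    def test_perfect_separation_flagged(self):
        z = np.linspace(-2, 2, 60)
        y = (z > 0).astype(int)
        with pytest.raises(ConvergenceError):
            multivariate_logistic(pd.DataFrame({"z": z}), y)


def _brute_force_auc(scores, labels):
    """Concordant-pair count over all positive x negative pairs (ties = 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


class TestRocAnalysis:
    def test_perfect_separation(self):
        res = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert 0.2 < res.cutoff < 0.8

    def test_three_quarters_concordance(self):
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0])
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(_brute_force_auc(scores, labels))
        assert res.auc == pytest.approx(0.75)

    def test_full_ties_give_half(self):
        res = roc_analysis([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n_pos = int(rng.integers(2, 30))
            n_neg = int(rng.integers(2, 30))
            scores = np.round(rng.random(n_pos + n_neg), 2)  # induce ties
            labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
            res = roc_analysis(scores, labels)
            assert res.auc == pytest.approx(
                _brute_force_auc(scores, labels), abs=1e-12
            )

    def test_ci_contains_auc_and_is_bounded(self):
        rng = np.random.default_rng(23)
        scores = rng.random(60)
        labels = (rng.random(60) < scores).astype(int)
        res = roc_analysis(scores, labels)
        lo, hi = res.ci95
        assert 0.0 <= lo <= res.auc <= hi <= 1.0
        assert res.auc_se > 0

    def test_roc_points_monotone(self, default_features):
        res = roc_analysis(default_features["lung_eud_cgy"], default_features["rp2"])
        assert np.all(np.diff(res.roc_points["fpr"]) >= 0)
        assert np.all(np.diff(res.roc_points["tpr"]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.9], [1, 1])


class TestStratify:
    def test_empty_high_group_is_reported_not_error(self, default_features):
        cutoff = default_features["lung_eud_cgy"].max() + 1.0
        res = stratify(default_features, "lung_eud_cgy", cutoff)
        assert len(res.high) == 0
        assert len(res.low) == len(default_features)

    def test_median_split_of_four_points(self):
        df = pd.DataFrame({"rp2": [0, 0, 1, 1], "x": [1.0, 2.0, 3.0, 4.0]})
        res = stratify(df, "x", 2.5)
        assert len(res.low) == 2 and len(res.high) == 2

    def test_high_risk_group_has_higher_prevalence_at_youden_cutoff(
        self, default_features
    ):
        roc = roc_analysis(default_features["ntcp_eud_sick"], default_features["rp2"])
        res = stratify(default_features, "ntcp_eud_sick", roc.cutoff)
        assert res.high["rp2"].mean() > res.low["rp2"].mean()

    def test_unknown_variable_rejected(self, default_features):
        with pytest.raises(ValueError):
            stratify(default_features, "does_not_exist", 1.0)


class TestFeatureTable:
    def test_v_metric_ordering_and_probability_bounds(self, default_features):
        df = default_features
        assert (df["v5"] >= df["v10"]).all()
        assert (df["v10"] >= df["v20"]).all()
        assert (df["v20"] >= df["v30"]).all()
        assert (df["v30"] >= 0).all()
        for col in ("ntcp_lkb_sick", "ntcp_lkb_total", "ntcp_eud_sick", "ntcp_eud_total"):
            assert df[col].between(0, 1).all()

    def test_composite_consistent_with_components(self, default_features):
        df = default_features
        manual = (
            df["mld_cgy"]
            * (df["v5"] / 100)
            * (df["v10"] / 100)
            * (df["v20"] / 100)
            * (df["v30"] / 100)
        )
        assert np.allclose(df["physical_composite"], manual)

    def test_eud_at_alpha_one_reproduces_mld(self, default_features):
        """On binned DVHs, EUD(alpha = 1) is exactly the mean lung dose."""
        df = default_features
        assert np.allclose(df["lung_eud1_cgy"], df["mld_cgy"], rtol=1e-9)

    def test_correlation_table_shape(self, default_features):
        table = correlation_table(default_features)
        assert len(table) == 10
        assert table["r"].between(-1, 1).all()
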