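"""Statistical-battery tests: agreement, ORs, AUC/DeLong, deviance, cohort
summary — checked against printed-table anchors and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mammodensity.evaluate import (bland_altman, category_or, delong_compare,
                                   deviance_table, pearson_ci, roc_auc,
                                   summarize_cohort)
from oracles import oracle_auc_paircount, oracle_delong_variance, oracle_or_2x2


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        out = pearson_ci(x, 2 * x + 1)
        assert out["r"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_ci(x, -x)["r"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        direct = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert pearson_ci(x, y)["r"] == pytest.approx(direct, abs=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        out = pearson_ci(x, y)
        assert out["ci_low"] <= out["r"] <= out["ci_high"]

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci(np.ones(10), np.arange(10.0))


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.arange(10.0)
        out = bland_altman(x, x)
        assert out["mean_diff"] == 0
        assert out["lower_limit"] == 0 and out["upper_limit"] == 0
        assert out["slope"] == 0

    def test_constant_offset(self):
        x = np.arange(10.0)
        out = bland_altman(x, x + 1)
        assert out["mean_diff"] == pytest.approx(-1.0)
        assert out["sd_diff"] == 0

    def test_limits_match_direct_computation(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        out = bland_altman(x, y)
        d = x - y
        assert out["mean_diff"] == pytest.approx(d.mean(), abs=1e-12)
        assert out["upper_limit"] == pytest.approx(
            d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
        slope, intercept = np.polyfit((x + y) / 2, d, 1)
        assert out["slope"] == pytest.approx(slope, abs=1e-12)


class TestCategoryOR:
    def test_two_by_two_matches_cross_product(self):
        # family-history-style 2x2: 207 exposed of 1,498 cases,
        # 119 exposed of 1,495 controls
        vals = np.r_[np.full(207, 50.0), np.zeros(1291),
                     np.full(119, 50.0), np.zeros(1376)]
        status = np.r_[np.ones(1498), np.zeros(1495)]
        tab = category_or(vals, status, breaks=(0, 5, 100))
        expected = oracle_or_2x2(207, 1291, 119, 1376)
        assert tab.iloc[1]["or"] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(1.85, abs=0.005)

    def test_identical_distributions_unit_ors(self):
        vals = np.r_[np.tile([2.0, 8.0, 15.0, 40.0], 25),
                     np.tile([2.0, 8.0, 15.0, 40.0], 25)]
        status = np.r_[np.ones(100), np.zeros(100)]
        tab = category_or(vals, status)
        np.testing.assert_allclose(tab["or"], 1.0, atol=1e-6)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 60, 400)
        status = (rng.random(400) < 1 / (1 + np.exp(-(vals - 20) / 30))).astype(float)
        tab = category_or(vals, status)
        for _, row in tab.iloc[1:].iterrows():
            assert row["ci_low"] <= row["or"] <= row["ci_high"]

    def test_empty_reference_rejected(self):
        vals = np.full(40, 50.0)
        status = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(ValueError):
            category_or(vals, status)


class TestROC:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        assert roc_auc(scores, labels)["auc"] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(4000)
        labels = (rng.random(4000) < 0.5).astype(int)
        assert roc_auc(scores, labels)["auc"] == pytest.approx(0.5, abs=0.03)

    def test_equals_paircount_oracle_small_inputs(self):
        """Exhaustive pair-count equality on many small score sets with
        ties, n <= 12."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 4, n).astype(float)  # heavy ties
            mine = roc_auc(scores, labels)["auc"]
            ref = oracle_auc_paircount(scores.tolist(), labels.tolist())
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, int))


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(6)
        s = rng.standard_normal(40)
        y = (rng.random(40) < 0.5).astype(int)
        out = delong_compare(s, s, y)
        assert out["diff"] == 0.0 and out["p"] == 1.0

    def test_variance_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 14
            y = np.r_[np.ones(6, int), np.zeros(8, int)]
            a = rng.integers(0, 5, n).astype(float)
            b = rng.integers(0, 5, n).astype(float)
            try:
                out = delong_compare(a, b, y)
            except FloatingPointError:
                continue
            ref_var = oracle_delong_variance(a.tolist(), b.tolist(), y.tolist())
            assert out["se"] ** 2 == pytest.approx(ref_var, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        y = (rng.random(30) < 0.5).astype(int)
        assert delong_compare(a, b, y)["p"] == \
            pytest.approx(delong_compare(b, a, y)["p"], abs=1e-12)


class TestDevianceTable:
    def test_null_deviance_at_printed_case_control_counts(self):
        """Intercept-only logistic deviance for 765 cases / 747 controls."""
        y = np.r_[np.ones(765), np.zeros(747)]
        tab = deviance_table({"null": None}, y)
        assert tab.iloc[0]["deviance"] == pytest.approx(2095.9, abs=0.05)

    def test_zero_covariate_does_not_change_deviance(self):
        rng = np.random.default_rng(9)
        y = (rng.random(200) < 0.5).astype(float)
        x = rng.standard_normal((200, 1))
        zero = np.zeros((200, 1))
        tab = deviance_table(
            {"null": None, "x": x, "x+zero": np.hstack([x, zero])}, y,
            pd_reference_models={"x+zero": "x"})
        dx = tab[tab["model"] == "x"].iloc[0]["deviance"]
        dxz = tab[tab["model"] == "x+zero"].iloc[0]["deviance"]
        assert dxz == pytest.approx(dx, abs=1e-6)
        assert tab[tab["model"] == "x+zero"].iloc[0]["p2"] == \
            pytest.approx(1.0, abs=1e-6)

    def test_p1_equals_chisquare_tail(self):
        rng = np.random.default_rng(10)
        y = (rng.random(300) < 0.5).astype(float)
        X = rng.standard_normal((300, 2))
        tab = deviance_table({"null": None, "m": X}, y)
        d0 = tab.iloc[0]["deviance"]
        d1 = tab.iloc[1]["deviance"]
        assert tab.iloc[1]["p1"] == pytest.approx(
            sps.chi2.sf(d0 - d1, 2), abs=1e-12)

    def test_deviance_nonincreasing_with_nesting(self):
        rng = np.random.default_rng(11)
        y = (rng.random(250) < 0.5).astype(float)
        X = rng.standard_normal((250, 3))
        tab = deviance_table(
            {"null": None, "m1": X[:, :1], "m2": X[:, :2], "m3": X}, y)
        devs = tab["deviance"].to_numpy()
        assert all(a >= b - 1e-9 for a, b in zip(devs, devs[1:]))

    def test_aic_definition(self):
        y = np.r_[np.ones(60), np.zeros(40)]
        tab = deviance_table({"null": None}, y)
        assert tab.iloc[0]["aic"] == pytest.approx(
            tab.iloc[0]["deviance"] + 2.0)

    def test_non_nested_reference_rejected(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        x = np.random.default_rng(1).standard_normal((60, 1))
        with pytest.raises(ValueError):
            deviance_table({"a": x, "b": x}, y,
                           pd_reference_models={"a": "b"})


class TestSummarizeCohort:
    def test_family_history_percent_formatting(self):
        """207 of 1,498 cases with the risk factor prints as 13.8%."""
        table = pd.DataFrame({
            "status": np.r_[np.ones(1498), np.zeros(1495)].astype(int),
            "fh": np.r_[np.ones(207), np.zeros(1291),
                        np.ones(119), np.zeros(1376)].astype(int),
        })
        out = summarize_cohort(table, categorical=["fh"])
        assert out.iloc[0]["cases"] == "207 (13.8)"
        assert out.iloc[0]["controls"] == "119 (8.0)"
        assert out.iloc[0]["p"] < 0.001

    def test_identical_groups_p_near_one(self):
        vals = np.tile(np.arange(20.0), 2)
        table = pd.DataFrame({"status": np.r_[np.ones(20), np.zeros(20)],
                              "v": vals})
        out = summarize_cohort(table, continuous=["v"], skewed=["v"])
        assert (out["p"] > 0.99).all()

    def test_t_statistic_matches_hand_formula(self):
        table = pd.DataFrame({
            "status": [1, 1, 1, 0, 0, 0],
            "v": [4.0, 5.0, 6.0, 1.0, 2.0, 3.0],
        })
        out = summarize_cohort(table, continuous=["v"])
        a, b = np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0])
        sp = np.sqrt(((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4)
                     * (1 / 3 + 1 / 3))
        assert out.iloc[0]["statistic"] == pytest.approx(
            (a.mean() - b.mean()) / sp, abs=1e-12)
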