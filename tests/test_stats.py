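"""Group tests, ROC/DeLong machinery, logistic modeling, stepwise
selection, calibration, and leave-one-out cross-validation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gliohab.stats import (
    binormal_auc,
    compare_groups,
    delong_compare,
    empirical_auc,
    fit_logistic,
    hosmer_lemeshow,
    loocv_auc,
    roc_auc,
    stepwise_select,
    univariable_screen,
    vif,
)


class TestCompareGroups:
    def test_identical_groups_null(self):
        vals = np.r_[[1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5]]
        grp = np.r_[np.zeros(5), np.ones(5)]
        res = compare_groups(vals, grp)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_welch_t_matches_closed_form(self):
        """Hand-worked Welch statistic for two small normal-looking samples."""
        a = np.array([4.8, 5.1, 5.6, 4.9, 5.3, 5.0])
        b = np.array([6.0, 6.4, 5.9, 6.2, 6.1, 6.5, 6.3])
        res = compare_groups(np.r_[a, b], np.r_[["a"] * 6, ["b"] * 7])
        se = math.sqrt(a.var(ddof=1) / 6 + b.var(ddof=1) / 7)
        t_hand = (a.mean() - b.mean()) / se
        df = se**4 / ((a.var(ddof=1) / 6) ** 2 / 5 + (b.var(ddof=1) / 7) ** 2 / 6)
        p_hand = 2 * sps.t.sf(abs(t_hand), df)
        assert res.test == "welch-t"
        assert res.statistic == pytest.approx(t_hand, abs=1e-6)
        assert res.pvalue == pytest.approx(p_hand, abs=1e-6)

    def test_mann_whitney_scale_invariance(self, rng):
        a = rng.exponential(1.0, 20)  # skewed -> MW branch
        b = rng.exponential(2.0, 25)
        vals = np.r_[a, b]
        grp = np.r_[np.zeros(20), np.ones(25)]
        r1 = compare_groups(vals, grp)
        r2 = compare_groups(vals * 37.5, grp)
        assert r1.test == "mann-whitney"
        assert r1.pvalue == pytest.approx(r2.pvalue, abs=1e-12)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="feat"):
            compare_groups([1, 2, 3, np.nan, np.nan], [0, 0, 0, 1, 1], feature="feat")


class TestAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_tie_example_pair_counting(self):
        # pairs: (1 vs 2)=1, (1 vs 3)=1, (2 vs 2)=0.5, (2 vs 3)=1 -> 3.5/4
        r = roc_auc([1, 2, 2, 3], [0, 0, 1, 1], orientation=1)
        assert r.auc == pytest.approx(0.875)

    def test_constant_scores(self):
        r = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5
        assert r.pvalue == 1.0

    def test_matches_pair_count_oracle(self, rng):
        """AUC equals U/(n1 n2) from exhaustive pair counting on random
        instances with ties."""
        for _ in range(20):
            n1, n0 = rng.integers(3, 100, 2)
            pos = rng.integers(0, 20, n1).astype(float)
            neg = rng.integers(0, 20, n0).astype(float)
            u = sum(1.0 if p > n else 0.5 if p == n else 0.0
                    for p in pos for n in neg)
            assert empirical_auc(pos, neg) == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        r1 = roc_auc(scores, labels, orientation=1)
        r2 = roc_auc(np.exp(scores), labels, orientation=1)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_auto_orientation(self):
        # lower score marks the positive class
        r = roc_auc([10, 9, 8, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert r.orientation == -1 and r.auc == 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_accuracy_consistent_with_confusion_counts(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        r = roc_auc(scores, labels, orientation=1)
        pred = (r.scores > r.cutoff).astype(int)
        acc = (pred == r.labels).mean()
        assert r.accuracy == pytest.approx(acc, abs=1e-12)


class TestDelong:
    def test_self_comparison_null(self, rng):
        scores = rng.normal(size=50)
        labels = np.r_[np.zeros(25), np.ones(25)].astype(int)
        r = roc_auc(scores, labels, orientation=1)
        cmp = delong_compare(r, r)
        assert cmp.auc_difference == 0.0 and cmp.pvalue == 1.0 and cmp.degenerate

    def test_antisymmetry(self, rng):
        labels = np.r_[np.zeros(30), np.ones(30)].astype(int)
        r1 = roc_auc(rng.normal(size=60) + labels, labels, orientation=1)
        r2 = roc_auc(rng.normal(size=60) + 0.5 * labels, labels, orientation=1)
        c12 = delong_compare(r1, r2)
        c21 = delong_compare(r2, r1)
        assert c12.auc_difference == pytest.approx(-c21.auc_difference)
        assert c12.pvalue == pytest.approx(c21.pvalue)

    def test_matches_paired_bootstrap_oracle(self, rng):
        """DeLong p agrees with a 10,000-resample paired bootstrap on a
        60-subject two-marker set, within +/-0.02."""
        n = 60
        labels = np.r_[np.zeros(30), np.ones(30)].astype(int)
        base = rng.normal(size=n)
        m1 = base + 1.1 * labels + 0.3 * rng.normal(size=n)
        m2 = base + 0.8 * labels + 0.3 * rng.normal(size=n)
        r1 = roc_auc(m1, labels, orientation=1)
        r2 = roc_auc(m2, labels, orientation=1)
        p_delong = delong_compare(r1, r2).pvalue
        diffs = np.empty(10_000)
        for b in range(10_000):
            idx = rng.integers(0, n, n)
            yb = labels[idx]
            if yb.min() == yb.max():
                diffs[b] = 0.0
                continue
            diffs[b] = (empirical_auc(m1[idx][yb == 1], m1[idx][yb == 0])
                        - empirical_auc(m2[idx][yb == 1], m2[idx][yb == 0]))
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert abs(p_delong - min(p_boot, 1.0)) <= 0.02

    def test_null_p_uniform(self, rng):
        """Paired DeLong p for two independent equal-AUC markers is
        uniform under the null (KS at alpha=0.01, 1000 replicates)."""
        labels = np.r_[np.zeros(30), np.ones(30)].astype(int)
        pvals = np.empty(1000)
        for i in range(1000):
            m1 = rng.normal(size=60) + labels
            m2 = rng.normal(size=60) + labels
            pvals[i] = delong_compare(roc_auc(m1, labels, orientation=1),
                                      roc_auc(m2, labels, orientation=1)).pvalue
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestLogistic:
    def test_intercept_only_balanced(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_logistic(pd.DataFrame(index=range(20)), y, check_rank=False)
        assert fit.coef["const"] == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery_large_n(self, rng):
        x = rng.normal(size=5000)
        eta = -1.0 + 0.8 * x
        y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(fit.coef["const"] + 1.0) < 3 * fit.se["const"]
        assert abs(fit.coef["x"] - 0.8) < 3 * fit.se["x"]

    def test_matches_newton_oracle_on_8_records(self):
        """Coefficients agree to 1e-6 with an independent Newton solver on
        a hand-entered 8-record dataset."""
        x = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0])
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1], dtype=float)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        X = np.column_stack([np.ones(8), x])
        beta = np.zeros(2)
        for _ in range(50):
            p = 1 / (1 + np.exp(-X @ beta))
            g = X.T @ (y - p)
            H = X.T @ (X * (p * (1 - p))[:, None])
            beta = beta + np.linalg.solve(H, g)
        assert fit.coef["const"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.coef["x"] == pytest.approx(beta[1], abs=1e-6)

    def test_fitted_deviance_not_worse_than_null(self, rng):
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(float)
        full = fit_logistic(pd.DataFrame({"x": x}), y)
        null = fit_logistic(pd.DataFrame(index=range(100)), y, check_rank=False)
        assert full.deviance <= null.deviance + 1e-9

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.normal(size=30)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(30) < 0.5).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(design, y)

    def test_or_equals_exp_coef(self, rng):
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(float)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.or_table.loc["x", "OR"] == pytest.approx(np.exp(fit.coef["x"]))


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        design = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0],
                               "c": [1, -1, -1, 1.0]})
        # orthogonal but n must exceed p: extend by repetition
        design = pd.concat([design] * 3, ignore_index=True)
        assert np.allclose(vif(design), 1.0)

    def test_correlation_0p8_closed_form(self):
        """Two variables with sample correlation exactly 0.8 give
        VIF = 1/(1-0.64) = 2.7778."""
        z1 = np.array([1.0, -1, 1, -1, 1, -1])
        z2 = np.array([1.0, 1, -1, -1, 1, -1]) - 0.0
        z2 = z2 - z2.mean()
        z2 = z2 - (z2 @ z1) / (z1 @ z1) * z1  # orthogonalize
        z1n = z1 / np.linalg.norm(z1)
        z2n = z2 / np.linalg.norm(z2)
        design = pd.DataFrame({"x": z1n, "y": 0.8 * z1n + 0.6 * z2n})
        v = vif(design)
        assert v["x"] == pytest.approx(1 / (1 - 0.64), rel=1e-9)
        assert v["y"] == pytest.approx(2.7778, abs=1e-4)

    def test_duplicated_column_infinite(self, rng):
        x = rng.normal(size=20)
        v = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(v).all()


class TestStepwise:
    def test_single_signal_retained_alone(self, rng):
        n = 200
        x = rng.normal(size=n)
        noise = pd.DataFrame(rng.normal(size=(n, 3)), columns=["n1", "n2", "n3"])
        y = (rng.random(n) < 1 / (1 + np.exp(-2.0 * x))).astype(float)
        design = pd.concat([pd.DataFrame({"x": x}), noise], axis=1)
        fit, path = stepwise_select(design, y)
        assert fit.variables == ["x"]
        assert set(path) == {"n1", "n2", "n3"}

    def test_null_retention_rate(self, rng):
        """Over 200 null cohorts with 10 noise candidates, the mean number
        of retained variables is consistent with elimination at 0.05."""
        retained = []
        for _ in range(200):
            design = pd.DataFrame(rng.normal(size=(60, 10)),
                                  columns=[f"v{j}" for j in range(10)])
            y = (rng.random(60) < 0.5).astype(float)
            fit, _ = stepwise_select(design, y)
            retained.append(len(fit.variables))
        mean_ret = np.mean(retained)
        assert 0.05 < mean_ret < 1.5  # ~10 x alpha false inclusions, not 0, not many

    def test_final_model_only_significant_terms(self, rng):
        design = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        y = (rng.random(80) < 0.5).astype(float)
        fit, _ = stepwise_select(design, y)
        if fit.variables:
            assert (fit.pvalues.drop("const") < 0.05).all()

    def test_beats_exhaustive_same_size_subsets(self, rng):
        """With <= 4 candidates the final model's deviance is no worse than
        every same-size subset found by enumeration."""
        n = 120
        design = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        eta = 1.2 * design["a"] - 0.9 * design["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit, _ = stepwise_select(design, y)
        size = len(fit.variables)
        for subset in itertools.combinations(design.columns, size):
            other = fit_logistic(design[list(subset)], y, check_rank=False)
            assert fit.deviance <= other.deviance + 1e-6

    def test_empty_candidates_intercept_only(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        fit, path = stepwise_select(pd.DataFrame(index=range(20)), y)
        assert fit.variables == [] and path == []


class TestHosmerLemeshow:
    def test_two_bin_hand_example(self):
        """chi2 matches the hand computation on a 2-bin split."""
        p = np.r_[np.full(10, 0.2), np.full(10, 0.8)]
        y = np.r_[np.ones(3), np.zeros(7), np.ones(7), np.zeros(3)]
        chi2, pval, table = hosmer_lemeshow(p, y, g=2)
        # bin1: O=3, E=2, n=10 -> (3-2)^2/(2*(1-0.2)) = 0.625; bin2 symmetric
        assert chi2 == pytest.approx(0.625 + 0.625, abs=1e-9)

    def test_calibrated_probabilities_null_distribution(self, rng):
        """When predicted probabilities equal the generating ones the HL
        statistic follows its null chi-square: with g externally given
        (unfitted) probability bins the statistic is ~chi2_g, so p-values
        referred to g degrees of freedom are uniform (mean ~0.5).  The
        reported p uses the fitted-model convention df = g-2."""
        g = 10
        stats_, pvals = [], []
        for _ in range(100):
            p = rng.uniform(0.05, 0.95, 2000)
            y = (rng.random(2000) < p).astype(float)
            chi2, _, _ = hosmer_lemeshow(p, y, g=g)
            stats_.append(chi2)
            pvals.append(sps.chi2.sf(chi2, g))
        assert abs(np.mean(stats_) - g) < 1.5  # E[chi2_g] = g
        assert abs(np.mean(pvals) - 0.5) < 0.1

    def test_few_distinct_probabilities_still_finite(self):
        p = np.r_[np.full(15, 0.3), np.full(15, 0.6)]
        y = (np.arange(30) % 3 == 0).astype(float)
        chi2, pval, _ = hosmer_lemeshow(p, y, g=10)
        assert np.isfinite(chi2) and 0 <= pval <= 1

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="2g"):
            hosmer_lemeshow(np.linspace(0.1, 0.9, 10), np.zeros(10), g=10)


class TestLoocv:
    def test_protocol_contract(self, rng):
        n = 40
        design = pd.DataFrame({"x": rng.normal(size=n)})
        y = (rng.random(n) < 1 / (1 + np.exp(-design["x"]))).astype(float)
        res = loocv_auc(design, y, ["x"])
        assert res.probabilities.shape == (n,)
        assert res.flagged_folds == []

    def test_determinism(self, rng):
        design = pd.DataFrame({"x": rng.normal(size=30)})
        y = (rng.random(30) < 0.5).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        r1 = loocv_auc(design, y, ["x"])
        r2 = loocv_auc(design, y, ["x"])
        np.testing.assert_array_equal(r1.probabilities, r2.probabilities)

    def test_recovers_binormal_auc_strong_signal(self, rng):
        """Cross-validated AUC on a strong single marker approaches the
        closed-form binormal AUC Phi(dmu / sqrt(s1^2 + s0^2)) = 0.95."""
        delta = 2.3262  # Phi(delta / sqrt(2)) = 0.95
        x = np.r_[rng.normal(0, 1, 30), rng.normal(delta, 1, 30)]
        y = np.r_[np.zeros(30), np.ones(30)]
        res = loocv_auc(pd.DataFrame({"x": x}), y, ["x"])
        assert abs(res.roc.auc - binormal_auc(delta, 1, 0, 1)) <= 0.05

    def test_held_out_subject_not_seen(self, rng):
        """Moving one subject's feature far out changes only predictions,
        not the fold that excludes it: its out-of-fold probability is
        driven by the other n-1 fits."""
        design = pd.DataFrame({"x": rng.normal(size=30)})
        y = np.r_[np.zeros(15), np.ones(15)]
        base = loocv_auc(design, y, ["x"])
        design2 = design.copy()
        design2.loc[0, "x"] += 100.0  # outlier only influences folds != 0
        moved = loocv_auc(design2, y, ["x"])
        # all other folds trained on the outlier change; fold 0 is refit on
        # unchanged data, so its coefficients are identical
        assert moved.probabilities[0] != pytest.approx(base.probabilities[0])


def test_univariable_screen_flags(rng):
    n = 150
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(float)
    screen = univariable_screen(pd.DataFrame({"x": x, "z": z}), y)
    assert bool(screen.loc["x", "selected"])
    assert screen.loc["x", "p"] < 0.05
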