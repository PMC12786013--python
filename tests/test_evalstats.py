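"""Evaluation statistics against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from idfnet import evalstats as ev


class TestConfusionMetrics:
    def test_hand_arithmetic(self):
        r = ev.confusion_metrics(ev.ConfusionCounts(tp=50, fp=10, tn=30, fn=10))
        assert np.isclose(r.precision, 50 / 60)
        assert np.isclose(r.sensitivity, 50 / 60)
        assert np.isclose(r.accuracy, 0.80)
        assert np.isclose(r.f1, 50 / 60)
        assert np.isclose(r.specificity, 0.75)

    def test_perfect_classifier(self):
        r = ev.confusion_metrics(ev.ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert r.accuracy == r.precision == r.sensitivity == r.f1 == r.specificity == 1.0

    def test_undefined_metrics_are_none_not_zero(self):
        r = ev.confusion_metrics(ev.ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert r.precision is None
        assert r.sensitivity is None

    def test_zero_recall_f1_convention(self):
        r = ev.confusion_metrics(ev.ConfusionCounts(tp=0, fp=3, tn=5, fn=4))
        assert r.sensitivity == 0.0
        assert r.f1 == 0.0

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            r = ev.confusion_metrics(ev.ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert min(r.precision, r.sensitivity) - 1e-12 <= r.f1 <= max(r.precision, r.sensitivity) + 1e-12

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionCounts(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            ev.ConfusionCounts(0, 0, 0, 0)


class TestAUC:
    def test_perfect_separation(self):
        assert ev.auc_mann_whitney([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs(self):
        assert ev.auc_mann_whitney([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_all_ties_half(self):
        assert ev.auc_mann_whitney([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.auc_mann_whitney([0.5, 0.6], [1, 1])

    def test_matches_roc_integration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            assert abs(ev.auc_mann_whitney(s, y) - roc_auc_score(y, s)) < 1e-10


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        lo, hi = ev.bootstrap_ci(lambda s, y: 0.42, rng.uniform(size=30),
                                 rng.integers(0, 2, size=30), n_boot=200, seed=0)
        assert lo == hi == 0.42

    def test_ci_brackets_point_estimate(self, rng):
        y = np.array([0, 1] * 25)
        s = np.clip(y * 0.4 + rng.uniform(size=50) * 0.6, 0, 1)
        point = ev.auc_mann_whitney(s, y)
        lo, hi = ev.bootstrap_ci(ev.auc_mann_whitney, s, y, n_boot=500, seed=1)
        assert lo <= point <= hi

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (100, 400):
            y = np.array([0, 1] * (n // 2))
            s = np.clip(0.5 * y + rng.normal(0.3, 0.2, size=n), 0, 1)
            lo, hi = ev.bootstrap_ci(ev.auc_mann_whitney, s, y, n_boot=400, seed=2)
            widths.append(hi - lo)
        ratio = widths[0] / widths[1]
        assert 1.4 <= ratio <= 2.8

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.bootstrap_ci(ev.auc_mann_whitney, rng.uniform(size=10),
                            rng.integers(0, 2, size=10), n_boot=50)


class TestMcNemar:
    def test_symmetric_discordance(self):
        a = np.array([True] * 5 + [False] * 5 + [True] * 10)
        b = np.array([False] * 5 + [True] * 5 + [True] * 10)
        r = ev.mcnemar_test(a, b)
        assert r.ancillary == {"b": 5, "c": 5}
        assert np.isclose(r.p_value, 1.0)

    def test_one_sided_discordance_tail(self):
        a = np.array([True] * 10 + [True] * 5)
        b = np.array([False] * 10 + [True] * 5)
        r = ev.mcnemar_test(a, b)
        assert np.isclose(r.p_value, 2 * 0.5 ** 10, atol=1e-12)

    def test_identical_classifiers(self):
        a = np.array([True, False, True])
        r = ev.mcnemar_test(a, a)
        assert r.p_value == 1.0

    def test_exact_matches_binomial_enumeration(self, rng):
        for _ in range(20):
            b = int(rng.integers(0, 12))
            c = int(rng.integers(0, 12))
            if b + c == 0 or b + c > 20:
                continue
            a_vec = np.array([True] * b + [False] * c + [True] * 5)
            b_vec = np.array([False] * b + [True] * c + [True] * 5)
            r = ev.mcnemar_test(a_vec, b_vec)
            n = b + c
            pmf = np.array([stats.binom.pmf(k, n, 0.5) for k in range(n + 1)])
            p_enum = pmf[pmf <= pmf[b] + 1e-12].sum()  # two-sided by pmf ordering
            assert np.isclose(r.p_value, min(p_enum, 1.0), atol=1e-9)


class TestDeLong:
    def test_identical_scores(self, rng):
        y = np.array([0, 1] * 15)
        s = rng.uniform(size=30)
        r = ev.delong_test(s, s, y)
        assert r.p_value == 1.0
        assert r.ancillary["delta_auc"] == 0.0

    def test_antisymmetry(self, rng):
        y = np.array([0, 1] * 15)
        a, b = rng.uniform(size=30), rng.uniform(size=30)
        r1 = ev.delong_test(a, b, y)
        r2 = ev.delong_test(b, a, y)
        assert np.isclose(r1.statistic, -r2.statistic)
        assert np.isclose(r1.p_value, r2.p_value)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 10)
        a = np.clip(0.4 * y + rng.uniform(size=20) * 0.8, 0, 1)
        b = np.clip(0.1 * y + rng.uniform(size=20) * 0.9, 0, 1)
        r = ev.delong_test(a, b, y)
        # permutation oracle: swap the paired scores case-wise
        obs = abs(ev.auc_mann_whitney(a, y) - ev.auc_mann_whitney(b, y))
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            swap = rng.random(20) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            d = abs(ev.auc_mann_whitney(aa, y) - ev.auc_mann_whitney(bb, y))
            count += d >= obs - 1e-12
        p_perm = count / n_perm
        assert abs(r.p_value - p_perm) < 0.05


class TestCalibration:
    def test_brier_closed_forms(self):
        b, _ = ev.brier_and_calibration([1.0, 0.0], [1, 0])
        assert b == 0.0
        b, _ = ev.brier_and_calibration([0.5, 0.5], [1, 0])
        assert b == 0.25
        b, _ = ev.brier_and_calibration([0.8, 0.4], [1, 0])
        assert np.isclose(b, 0.10)

    def test_brier_bounds(self, rng):
        p = rng.uniform(size=100)
        y = rng.integers(0, 2, size=100)
        b, _ = ev.brier_and_calibration(p, y)
        assert 0.0 <= b <= 1.0

    def test_reliability_table_omits_empty_bins(self):
        _, table = ev.brier_and_calibration([0.05, 0.95, 0.96], [0, 1, 1], n_bins=10)
        assert set(table["bin"]) == {0, 9}
        assert table.loc[table["bin"] == 9, "n"].iloc[0] == 2

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            ev.brier_and_calibration([1.2], [1])


class TestDecisionCurve:
    def test_formula_arithmetic(self):
        y = np.array([1] * 20 + [0] * 80)
        p = np.array([0.9] * 20 + [0.9] * 10 + [0.05] * 70)  # TP=20, FP=10 at t=0.2
        dca = ev.decision_curve(p, y, thresholds=[0.2])
        assert np.isclose(dca.net_benefit_model.iloc[0], 0.2 - 0.1 * 0.25)

    def test_treat_none_always_zero(self, rng):
        dca = ev.decision_curve(rng.uniform(size=50), rng.integers(0, 2, size=50))
        assert (dca.net_benefit_none == 0).all()
        assert len(dca) == 46  # 0.05..0.50 step 0.01

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        p = y.astype(float)
        dca = ev.decision_curve(p, y)
        assert np.allclose(dca.net_benefit_model, 0.3)

    def test_extreme_thresholds_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.decision_curve(rng.uniform(size=10), rng.integers(0, 2, size=10),
                              thresholds=[0.0, 0.5])


def test_metric_report_with_bootstrap_ci(rng):
    y = np.array([0, 1] * 30)
    s = np.clip(0.5 * y + rng.uniform(size=60) * 0.5, 0, 1)
    rep = ev.metric_report(s, y, n_boot=200, seed=3)
    assert rep.ci["auc"][0] <= rep.auc <= rep.ci["auc"][1]
    assert 0 <= rep.accuracy <= 1
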