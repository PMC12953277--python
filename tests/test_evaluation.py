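import math

import numpy as np
import pytest

from fractalct.evaluation import (
    decision_curve,
    delong_paired_test,
    hosmer_lemeshow,
    icc_agreement,
    km_curve,
    logrank_test,
    performance_at_cutoff,
    roc_auc_delong,
)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        res = roc_auc_delong([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_pair_count_oracle(self):
        scores, labels = [1, 2, 3, 4], [0, 0, 1, 1]
        res = roc_auc_delong(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_negation_symmetry(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = roc_auc_delong(scores, labels).auc
        b = roc_auc_delong(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_random_tied_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            res = roc_auc_delong(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_ci_contains_auc(self, rng):
        scores = rng.random(80)
        labels = (rng.random(80) < 0.4).astype(int)
        labels[:2] = [0, 1]
        res = roc_auc_delong(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc_delong([1, 2, 3], [1, 1, 1])


class TestDeLongPaired:
    def test_identical_scores(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        z, p = delong_paired_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a, b = rng.random(60), rng.random(60)
        z1, p1 = delong_paired_test(a, b, y)
        z2, p2 = delong_paired_test(b, a, y)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_detects_dominant_model(self, rng):
        y = (rng.random(400) < 0.4).astype(int)
        good = y + 0.4 * rng.standard_normal(400)
        noise = rng.standard_normal(400)
        z, p = delong_paired_test(good, noise, y)
        assert z > 0 and p < 1e-6

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2], [1, 2, 3], [0, 1, 1])


class TestPerformanceAtCutoff:
    def test_perfect(self):
        sens, spec, acc = performance_at_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_hand_2x2(self):
        # TP=8, FN=2, TN=15, FP=5
        scores = [1.0] * 8 + [0.0] * 2 + [0.0] * 15 + [1.0] * 5
        labels = [1] * 10 + [0] * 20
        sens, spec, acc = performance_at_cutoff(scores, labels, 0.5)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.75)
        assert acc == pytest.approx(23 / 30)

    def test_cutoff_above_max(self):
        sens, spec, _ = performance_at_cutoff([0.1, 0.9], [1, 0], 5.0)
        assert sens == 0.0 and spec == 1.0


class TestHosmerLemeshow:
    def test_constant_probs_at_event_rate(self):
        probs = np.full(100, 0.3)
        labels = np.array([1] * 30 + [0] * 70)
        chi2, df, p = hosmer_lemeshow(probs, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_two_bin_hand_oracle(self):
        probs = np.array([0.2] * 5 + [0.8] * 5)
        labels = np.array([1, 1, 0, 0, 0, 1, 1, 1, 0, 0])
        chi2, df, p = hosmer_lemeshow(probs, labels, g=2)
        # bin1: E1=1, O1=2 -> 1/1 + 1/4 ; bin2: E1=4, O1=3 -> 1/4 + 1/1
        assert chi2 == pytest.approx(2.5, abs=1e-12)
        assert df == 0

    def test_ten_bins_df(self, rng):
        probs = rng.uniform(0.05, 0.95, 500)
        labels = (rng.random(500) < probs).astype(int)
        chi2, df, p = hosmer_lemeshow(probs, labels, g=10)
        assert df == 8
        assert 0 <= p <= 1

    def test_probs_outside_unit_interval_raise(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.0, 0.5] * 10, [0, 1] * 10)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 5, [0, 1, 0, 1, 0], g=10)


class TestDecisionCurve:
    def test_treat_none_zero(self, rng):
        probs = rng.random(100)
        labels = rng.integers(0, 2, 100)
        tab = decision_curve(probs, labels, [0.1, 0.3, 0.5])
        assert (tab.net_benefit_none == 0).all()

    def test_perfect_predictor(self):
        labels = np.array([1] * 30 + [0] * 70)
        probs = np.clip(labels.astype(float), 0.001, 0.999)
        tab = decision_curve(probs, labels, [0.1, 0.3, 0.6])
        np.testing.assert_allclose(tab.net_benefit_model, 0.3, atol=1e-12)

    def test_treat_all_closed_form(self):
        labels = np.array([1] * 20 + [0] * 80)
        probs = np.full(100, 0.5)
        tab = decision_curve(probs, labels, [0.25])
        expect = 0.2 - 0.8 * 0.25 / 0.75
        assert tab.net_benefit_all.iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], [0.0])


class TestICC:
    def test_identical_raters(self, rng):
        col = rng.standard_normal(20)
        res = icc_agreement(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0)

    def test_constant_shift_below_one(self, rng):
        col = rng.standard_normal(30)
        res = icc_agreement(np.column_stack([col, col + 0.5]))
        assert res.icc < 1.0
        # mean-squares oracle: consistency is perfect, absolute agreement is not
        res_no_shift = icc_agreement(np.column_stack([col, col]))
        assert res.icc < res_no_shift.icc

    def test_independent_columns_near_zero(self, rng):
        x = rng.standard_normal((500, 2))
        res = icc_agreement(x)
        assert abs(res.icc) < 0.1

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        subj = rng.standard_normal(30)[:, None]
        x = subj + 0.3 * rng.standard_normal((30, 2)) + np.array([0.0, 0.2])
        res = icc_agreement(x)
        d = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(30), 2),
                "rater": np.tile(["a", "b"], 30),
                "y": x.ravel(),
            }
        )
        tab = pg.intraclass_corr(d, targets="subj", raters="rater", ratings="y")
        row = tab[tab.Type == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(row.ICC, abs=1e-9)
        assert res.ci_low == pytest.approx(row.CI95[0], abs=0.01)
        assert res.ci_high == pytest.approx(row.CI95[1], abs=0.01)

    def test_zero_between_subject_variance_flagged(self):
        res = icc_agreement(np.zeros((10, 2)))
        assert res.flag is not None

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc_agreement(np.zeros((3, 2)))


class TestKaplanMeier:
    def test_no_censoring_matches_empirical(self):
        curve = km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_censored_example(self):
        curve = km_curve([1, 2, 3, 4], [0, 1, 0, 1])
        assert curve.probability_at(2) == pytest.approx(2 / 3)
        assert curve.probability_at(4) == pytest.approx(0.0)

    def test_all_censored(self):
        curve = km_curve([1, 2, 3], [0, 0, 0])
        assert curve.probability_at(3) == 1.0
        assert math.isnan(curve.median)

    def test_empirical_equivalence_random(self, rng):
        times = rng.integers(1, 20, size=40).astype(float)
        curve = km_curve(times, np.ones(40, int))
        for t in np.unique(times):
            assert curve.probability_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(10, 100)
        events = (rng.random(100) < 0.7).astype(int)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        curve = km_curve(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(float(kmf.predict(t)), abs=1e-9)

    def test_quartile_ordering(self, rng):
        times = rng.exponential(10, 200)
        curve = km_curve(times, np.ones(200, int))
        assert curve.q25 <= curve.median <= curve.q75

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetric(self, rng):
        ta, tb = rng.exponential(5, 30), rng.exponential(9, 30)
        ea, eb = np.ones(30, int), np.ones(30, int)
        c1, p1 = logrank_test(ta, ea, tb, eb)
        c2, p2 = logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_hand_worked_instance(self):
        # A: events at 1 and 2; B: censored at 2, event at 3
        # t=1: n=4, nA=2, d=1 -> E=0.5, V=0.25
        # t=2: n=3, nA=1, d=1 -> E=1/3, V=2/9
        # t=3: n=1, nA=0, d=1 -> E=0,   V=0
        # O-E = (1-0.5) + (1-1/3) = 7/6 ; V = 0.25 + 2/9 = 17/36
        chi2, _ = logrank_test([1, 2], [1, 1], [2, 3], [0, 1])
        assert chi2 == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-12)

    def test_matches_lifelines(self, rng):
        stats_mod = pytest.importorskip("lifelines.statistics")
        ta, tb = rng.exponential(5, 50), rng.exponential(8, 60)
        ea = (rng.random(50) < 0.8).astype(int)
        eb = (rng.random(60) < 0.8).astype(int)
        chi2, p = logrank_test(ta, ea, tb, eb)
        ref = stats_mod.logrank_test(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert p == pytest.approx(ref.p_value, abs=1e-9)

    def test_no_events_flagged(self):
        chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1], [1])
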