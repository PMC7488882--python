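"""Classifier evaluation statistics against brute-force oracles and closed forms."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokeclock.evaluation import (ConfusionTable, ConvergenceError,
                                    compare_aucs, correlate,
                                    diagnostic_metrics, f1_score, fit_logistic,
                                    free_marginal_kappa, kappa_from_agreement,
                                    majority_adjudicate, predict_probability,
                                    prg_curve, roc_auc, youden_cutoff)

from _oracles import auc_pair_counting, youden_scan


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_monotone_transform_spearman(self):
        x = np.array([0.2, 1.0, 3.5, 7.0, 9.1])
        r, _ = correlate(x, np.exp(x), "spearman")
        assert r == pytest.approx(1.0)

    def test_small_set_matches_hand_ranked_spearman(self):
        # ranks of x: 1 3 2 5 4; ranks of y: 2 1 4 3 5
        # d = (-1, 2, -2, 2, -1); sum d^2 = 14; rho = 1 - 6*14/(5*24) = 0.3
        x = np.array([10.0, 30.0, 20.0, 50.0, 40.0])
        y = np.array([1.2, 1.1, 1.4, 1.3, 1.5])
        r, _ = correlate(x, y, "spearman")
        assert r == pytest.approx(0.3)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate(np.ones(5), np.arange(5.0), "pearson")

    def test_kendall_sign_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        tau, _ = correlate(x, -x, "kendall")
        assert tau == pytest.approx(-1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], "above")
        assert r.auc == 1.0

    def test_three_of_four_concordant_pairs(self):
        r = roc_auc([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0], "above")
        assert r.auc == 0.75

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        r = roc_auc(scores, labels, "above")
        assert abs(r.auc - 0.5) < 0.03

    def test_direction_below_flips(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], "below")
        assert r.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1], "above")

    def test_exhaustive_small_instances_match_pair_counting(self):
        # every labelling and every integer score vector from a small alphabet
        for n in (2, 3, 4):
            for scores in itertools.product((0, 1, 2), repeat=n):
                for labels in itertools.product((0, 1), repeat=n):
                    if 0 < sum(labels) < n:
                        got = roc_auc(np.array(scores, float), labels, "above").auc
                        want = auc_pair_counting(scores, labels)
                        assert got == pytest.approx(want)

    def test_ci_brackets_auc(self):
        r = roc_auc([0.9, 0.4, 0.8, 0.3, 0.6, 0.5], [1, 1, 1, 0, 0, 0], "above")
        assert r.ci[0] <= r.auc <= r.ci[1]


class TestCompareAucs:
    def test_classifier_vs_itself_p_one(self):
        scores = {"a": [0.9, 0.4, 0.8, 0.3], "b": [0.9, 0.4, 0.8, 0.3]}
        out = compare_aucs(scores, [1, 1, 0, 0],
                           directions={"a": "above", "b": "above"})
        assert out.loc[0, "p"] == 1.0

    def test_three_classifiers_three_pairs_bonferroni(self):
        rng = np.random.default_rng(5)
        s = rng.random(12)
        labels = np.array([1] * 6 + [0] * 6)
        scores = {k: s for k in ("a", "b", "c")}
        out = compare_aucs(scores, labels,
                           directions={k: "above" for k in scores})
        assert len(out) == 3
        assert out["alpha_adjusted"].unique() == pytest.approx(0.05 / 3)

    def test_perfect_vs_random_significant(self):
        rng = np.random.default_rng(17)
        labels = np.array([1] * 20 + [0] * 20)
        perfect = np.concatenate([rng.uniform(0.7, 1.0, 20),
                                  rng.uniform(0.0, 0.3, 20)])
        random_scores = rng.permutation(perfect)
        out = compare_aucs({"good": perfect, "noise": random_scores}, labels,
                           directions={"good": "above", "noise": "above"})
        assert out.loc[0, "p_adjusted"] < 0.05

    def test_unpaired_scores_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            compare_aucs({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2]}, [1, 0, 1],
                         directions={"a": "above", "b": "above"})


class TestYoudenCutoff:
    def test_separable_returns_midpoint(self):
        res = youden_cutoff([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0], "above")
        assert res.j == 1.0
        assert res.cutoff == pytest.approx(0.6)

    def test_direction_below_for_t2_like_ratios(self):
        # within window = ratio at or below the cutoff
        res = youden_cutoff([1.02, 1.05, 1.09, 1.12], [1, 1, 0, 0], "below")
        assert res.j == 1.0
        assert 1.05 < res.cutoff < 1.09
        assert res.confusion.tp == 2 and res.confusion.tn == 2

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(4, 20))
            scores = np.round(rng.random(n), 2)
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            direction = "below" if rng.random() < 0.5 else "above"
            res = youden_cutoff(scores, labels, direction)
            assert res.j == pytest.approx(youden_scan(scores, labels, direction))

    def test_tie_break_favors_fewer_predicted_positive(self):
        # J = 0 everywhere: every cutoff ties; safety tie-break predicts
        # as few within-window patients as possible
        res = youden_cutoff([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], "below")
        pred = np.array([0.5, 0.5, 0.5, 0.5]) <= res.cutoff
        assert pred.sum() == 0


class TestDiagnosticMetrics:
    def test_reconstructed_t2_table(self):
        m = diagnostic_metrics(ConfusionTable(tp=12, fp=5, fn=4, tn=14))
        assert m.ppv.percent == pytest.approx(70.59, abs=0.005)
        assert m.npv.percent == pytest.approx(77.78, abs=0.005)
        assert m.sensitivity.value == pytest.approx(12 / 16)
        assert m.specificity.value == pytest.approx(14 / 19)

    def test_reconstructed_adc_table(self):
        m = diagnostic_metrics(ConfusionTable(tp=16, fp=16, fn=0, tn=3))
        assert m.npv.percent == 100.0
        assert m.ppv.percent == 50.0

    def test_perfect_classifier_ci_width_zero(self):
        m = diagnostic_metrics(ConfusionTable(tp=10, fp=0, fn=0, tn=10))
        for metric in m.as_dict().values():
            assert metric.value == 1.0
            assert metric.ci == (1.0, 1.0)

    def test_exact_rational_products_are_integers(self):
        ct = ConfusionTable(tp=7, fp=3, fn=5, tn=9)
        m = diagnostic_metrics(ct)
        assert (m.sensitivity.fraction * (ct.tp + ct.fn)).denominator == 1
        assert (m.specificity.fraction * (ct.tn + ct.fp)).denominator == 1

    def test_undefined_metric_flagged(self):
        m = diagnostic_metrics(ConfusionTable(tp=0, fp=0, fn=3, tn=5))
        assert not m.ppv.defined


class TestF1:
    def test_subcohort_t2_value(self):
        f1 = f1_score(ConfusionTable(tp=4, fp=2, fn=1, tn=10))
        assert f1.value == pytest.approx(8 / 11)
        assert f1.ci[0] == pytest.approx(0.52, abs=0.01)
        assert f1.ci[1] == pytest.approx(0.94, abs=0.01)

    def test_perfect_classifier(self):
        assert f1_score(ConfusionTable(tp=5, fp=0, fn=0, tn=5)).value == 1.0

    def test_zero_tp(self):
        assert f1_score(ConfusionTable(tp=0, fp=2, fn=3, tn=5)).value == 0.0

    def test_delta_method_option_runs(self):
        f1 = f1_score(ConfusionTable(tp=4, fp=2, fn=1, tn=10), ci_method="delta")
        assert f1.ci[0] < f1.value < f1.ci[1]


class TestLogistic:
    def test_intercept_only_balanced(self):
        table = pd.DataFrame({"label": [0, 1] * 10})
        m = fit_logistic(table, [])
        assert m.params["intercept"] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(m.fitted, 0.5)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0, 1, 2000)
        logits = 2.0 - 3.0 * x
        y = rng.random(2000) < 1.0 / (1.0 + np.exp(-logits))
        m = fit_logistic(pd.DataFrame({"x": x, "label": y.astype(int)}), ["x"])
        assert abs(m.params["intercept"] - 2.0) < 3 * m.se["intercept"]
        assert abs(m.params["x"] + 3.0) < 3 * m.se["x"]

    def test_mean_fitted_probability_is_prevalence(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({"x": rng.normal(size=40),
                              "label": rng.integers(0, 2, 40)})
        m = fit_logistic(table, ["x"])
        assert m.fitted.mean() == pytest.approx(table["label"].mean())

    def test_perfect_separation_raises(self):
        table = pd.DataFrame({"x": np.arange(10.0),
                              "label": (np.arange(10) >= 5).astype(int)})
        with pytest.raises(ConvergenceError):
            fit_logistic(table, ["x"])

    def test_aicc_definition(self):
        rng = np.random.default_rng(41)
        table = pd.DataFrame({"x": rng.normal(size=35),
                              "label": rng.integers(0, 2, 35)})
        m = fit_logistic(table, ["x"])
        k, n = 2, 35
        assert m.aicc == pytest.approx(-2 * m.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1))

    def test_predicted_probability_at_reported_cutoff(self):
        # alpha=18.3, beta=-17.13 at ratio 1.072 -> Y ~ -0.063, P ~ 0.484
        model_params = {"intercept": 18.3, "t2": -17.13}
        from strokeclock.evaluation import LogisticModel

        m = LogisticModel(predictors=("t2",), params=model_params, se={},
                          tstat={}, pvalues={}, chi2=0.0, chi2_df=1,
                          chi2_p=1.0, aicc=0.0, llf=0.0, llnull=0.0, n=35,
                          fitted=np.array([]))
        p = predict_probability(m, {"t2": 1.072})
        y = 18.3 - 17.13 * 1.072
        assert p == pytest.approx(math.exp(y) / (1 + math.exp(y)))
        assert p == pytest.approx(0.484, abs=0.002)

    def test_probability_monotone_decreasing_for_negative_beta(self):
        from strokeclock.evaluation import LogisticModel

        m = LogisticModel(predictors=("t2",), params={"intercept": 18.3, "t2": -17.13},
                          se={}, tstat={}, pvalues={}, chi2=0.0, chi2_df=1,
                          chi2_p=1.0, aicc=0.0, llf=0.0, llnull=0.0, n=35,
                          fitted=np.array([]))
        ps = [predict_probability(m, {"t2": r}) for r in (1.00, 1.05, 1.10, 1.20)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestPrg:
    def test_all_positive_point(self):
        # constant scores = the always-positive classifier: (rg 1, pg 0)
        r = prg_curve(np.ones(8), [1, 1, 1, 0, 0, 0, 0, 0], "above")
        assert r.points[-1] == pytest.approx([1.0, 0.0])
        assert r.auprg == pytest.approx(0.0)

    def test_precision_gain_formula(self):
        # pi = 0.5, precision 0.75 -> gain (0.75-0.5)/(0.5*0.75) = 2/3
        pi, prec = 0.5, 0.75
        assert (prec - pi) / ((1 - pi) * prec) == pytest.approx(2 / 3)
        # realized by a ranking whose first operating point has 3 TP, 1 FP
        scores = np.array([9.0, 8.0, 7.0, 6.0, 1.0, 1.0, 1.0, 1.0])
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        r = prg_curve(scores, labels, "above")
        assert any(abs(pg - 2 / 3) < 1e-9 for pg in r.points[:, 1])

    def test_perfect_ranking_area_one(self):
        r = prg_curve([4.0, 3.0, 2.0, 1.0, 0.5], [1, 1, 0, 0, 0], "above")
        assert r.auprg == pytest.approx(1.0)

    def test_random_rankings_average_near_zero(self):
        rng = np.random.default_rng(2)
        labels = np.array([1] * 5 + [0] * 15)
        vals = [prg_curve(rng.permutation(20).astype(float), labels, "above").auprg
                for _ in range(2000)]
        assert abs(float(np.mean(vals))) < 0.1

    def test_perfect_dominates_all_rankings_small_n(self):
        # enumeration at n = 7 (3 positives): the perfect ranking maximizes AUPRG
        labels_pool = [1, 1, 1, 0, 0, 0, 0]
        scores = np.arange(7, 0, -1, dtype=float)
        best = prg_curve(scores, sorted(labels_pool, reverse=True), "above").auprg
        assert best == pytest.approx(1.0)
        for perm in set(itertools.permutations(labels_pool)):
            a = prg_curve(scores, list(perm), "above").auprg
            assert a <= best + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            prg_curve([1.0, 2.0], [1, 1], "above")


class TestKappa:
    def test_unanimous_raters(self):
        ratings = [["match"] * 4] * 10
        res = free_marginal_kappa(ratings, k=3)
        assert res.po == 1.0
        assert res.kappa == 1.0

    def test_chance_level_agreement_zero(self):
        assert kappa_from_agreement(1 / 3, 3) == pytest.approx(0.0)

    def test_published_pair(self):
        assert kappa_from_agreement(0.728, 3) == pytest.approx(0.592)
        assert round(kappa_from_agreement(0.728, 3), 2) == 0.59

    def test_po_is_mean_pairwise_agreement(self):
        # item 1: 3 match + 1 mismatch -> C(3,2)/C(4,2) = 3/6
        # item 2: 2/2 split -> (1+1)/6
        ratings = [["m", "m", "m", "x"], ["m", "m", "x", "x"]]
        res = free_marginal_kappa(ratings, k=2)
        assert res.po == pytest.approx((0.5 + 2 / 6) / 2)

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            kappa_from_agreement(0.7, 1)


class TestMajorityAdjudicate:
    def _table(self, rows, arb=None):
        df = pd.DataFrame(rows, columns=["r1", "r2", "r3", "r4"])
        df["arbitrator"] = arb if arb is not None else [None] * len(df)
        return df

    def test_simple_majority(self):
        t = self._table([["match", "match", "match", "mismatch"]])
        assert majority_adjudicate(t).iloc[0] == "match"

    def test_two_two_split_goes_to_arbitrator(self):
        t = self._table([["match", "match", "mismatch", "mismatch"]],
                        arb=["mismatch"])
        assert majority_adjudicate(t).iloc[0] == "mismatch"

    def test_majority_of_responders(self):
        t = self._table([["match", "uncertain", "uncertain", "uncertain"]])
        assert majority_adjudicate(t).iloc[0] == "match"

    def test_tie_without_arbitrator_rejected(self):
        t = self._table([["match", "match", "mismatch", "mismatch"]])
        with pytest.raises(ValueError, match="arbitrator"):
            majority_adjudicate(t)


class TestProportionInvariants:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 30), fp=st.integers(0, 30),
           fn=st.integers(0, 30), tn=st.integers(0, 30))
    def test_metric_fractions_exact(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = diagnostic_metrics(ConfusionTable(tp, fp, fn, tn))
        if m.sensitivity.defined:
            assert m.sensitivity.fraction * (tp + fn) == tp
        if m.specificity.defined:
            assert m.specificity.fraction * (tn + fp) == tn
        if m.accuracy.defined:
            assert 0 <= m.accuracy.value <= 1
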