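"""Statistics against independent oracles and hand-worked fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echofuse import evaluation as ev


def brute_force_auc(scores, labels):
    """O(n^2) concordance count: the independent AUC oracle."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestRocAuc:
    def test_hand_fixture(self):
        assert ev.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).auc == 0.75

    def test_perfect_separation(self):
        assert ev.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_all_ties_give_half(self):
        assert ev.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.roc_auc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        """Exact agreement with pairwise concordance for n <= 50,
        including heavy ties (scores on a coarse grid)."""
        n = data.draw(st.integers(4, 50))
        scores = data.draw(st.lists(
            st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0]),
            min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert ev.roc_auc(scores, labels).auc \
            == pytest.approx(brute_force_auc(scores, labels))

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        labels = (rng.random(200) < scores).astype(int)
        curve = ev.roc_auc(scores, labels)
        # roc_curve returns thresholds descending -> sensitivity ascending
        assert (np.diff(curve.sensitivity) >= 0).all()


class TestPickThreshold:
    def test_gmean_on_separable_data_returns_midpoint(self):
        thr = ev.pick_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], "gmean")
        assert thr == pytest.approx(0.5)
        rep = ev.classification_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], thr)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_fixed_sensitivity_with_one_positive(self):
        scores = [0.9] + [0.1, 0.2, 0.3, 0.4, 0.45, 0.35, 0.25, 0.15, 0.05]
        labels = [1] + [0] * 9
        thr = ev.pick_threshold(scores, labels, "fixed_sens_0.8")
        assert 0.45 < thr < 0.9
        assert ev.classification_metrics(scores, labels, thr).sensitivity == 1.0

    def test_f1_rule_matches_exhaustive_scan(self, rng):
        scores = rng.random(60)
        labels = (rng.random(60) < scores).astype(int)
        thr = ev.pick_threshold(scores, labels, "f1_dev")
        got = ev.classification_metrics(scores, labels, thr).f1
        best = max(
            (ev.classification_metrics(scores, labels, t).f1 or 0.0)
            for t in np.linspace(-0.01, 1.01, 2000))
        assert got == pytest.approx(best, abs=1e-12)

    def test_unattainable_fixed_rule_raises(self):
        # fully tied scores admit no finite operating threshold
        with pytest.raises(ValueError, match="unattainable"):
            ev.pick_threshold([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1],
                              "fixed_spec_0.8")

    def test_fixed_sens_reports_max_attainable(self):
        # at every finite candidate, at most half the positives clear it
        with pytest.raises(ValueError, match="max"):
            ev.pick_threshold([0.9, 0.9, 0.1, 0.1, 0.95], [1, 1, 1, 1, 0],
                              "fixed_sens_0.8")


class TestClassificationMetrics:
    def test_hand_2x2_fixture(self):
        """TP=8 FN=2 TN=84 FP=16 -> sens .800 spec .840 PPV .333 NPV .977."""
        scores = np.r_[np.full(8, 0.9), np.full(2, 0.1),
                       np.full(84, 0.1), np.full(16, 0.9)]
        labels = np.r_[np.ones(10), np.zeros(100)]
        rep = ev.classification_metrics(scores, labels, 0.5)
        assert rep.sensitivity == pytest.approx(0.800)
        assert rep.specificity == pytest.approx(0.840)
        assert rep.ppv == pytest.approx(1 / 3)
        assert rep.npv == pytest.approx(84 / 86, abs=5e-4)

    def test_threshold_below_all_scores(self):
        rep = ev.classification_metrics([0.2, 0.8], [0, 1], -1.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_f1_equals_common_value_when_sens_equals_ppv(self):
        # sens = ppv = 2/3: TP=2, FN=1, FP=1
        scores = [0.9, 0.9, 0.1, 0.9, 0.1]
        labels = [1, 1, 1, 0, 0]
        rep = ev.classification_metrics(scores, labels, 0.5)
        assert rep.sensitivity == rep.ppv == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_no_predicted_positives_leaves_ppv_missing(self):
        rep = ev.classification_metrics([0.1, 0.2], [0, 1], 0.9)
        assert rep.ppv is None and rep.f1 is None


class TestBootstrap:
    def test_constant_metric_gives_zero_width(self):
        lo, hi = ev.bootstrap_ci(lambda s, l: 0.7, np.arange(20) / 20.0,
                                 np.arange(20) % 2, n_boot=100, seed=0)
        assert lo == hi == 0.7

    def test_same_seed_reproduces_interval(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.5).astype(int)
        fn = lambda s, l: ev.roc_auc(s, l).auc
        assert ev.bootstrap_ci(fn, scores, labels, 200, seed=5) \
            == ev.bootstrap_ci(fn, scores, labels, 200, seed=5)

    def test_interval_brackets_point_estimate(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < scores).astype(int)
        fn = lambda s, l: ev.roc_auc(s, l).auc
        point = fn(scores, labels)
        lo, hi = ev.bootstrap_ci(fn, scores, labels, 500, seed=1)
        assert lo <= point <= hi

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            ev.bootstrap_ci(lambda s, l: 1.0, [0.1] * 5, [0, 1, 0, 1, 0])


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        res = ev.delong_test([0.1, 0.9, 0.4], [0.1, 0.9, 0.4], [0, 1, 0])
        assert res.p_raw == 1.0
        assert res.auc_a == res.auc_b

    def test_symmetric_in_model_order(self, rng):
        labels = np.r_[np.ones(20), np.zeros(20)]
        a, b = rng.random(40), rng.random(40)
        ab = ev.delong_test(a, b, labels)
        ba = ev.delong_test(b, a, labels)
        assert ab.p_raw == pytest.approx(ba.p_raw)

    def test_strong_difference_is_significant(self, rng):
        labels = np.r_[np.ones(50), np.zeros(50)]
        good = labels + rng.normal(0, 0.3, 100)
        noise = rng.random(100)
        assert ev.delong_test(good, noise, labels).p_raw < 1e-4


class TestBonferroni:
    def test_single_comparison_unchanged(self):
        assert ev.bonferroni_adjust([0.01]) == [0.01]

    def test_multiplies_by_family_size(self):
        assert ev.bonferroni_adjust([0.01, 0.02, 0.03, 0.04]) \
            == pytest.approx([0.04, 0.08, 0.12, 0.16])

    def test_caps_at_one(self):
        assert ev.bonferroni_adjust([0.5, 0.9]) == [1.0, 1.0]

    def test_compare_models_uses_family_of_comparators(self, rng):
        labels = np.r_[np.ones(30), np.zeros(30)]
        scores = {name: rng.random(60) for name in
                  ("multiview", "A4c", "A2c", "PLAX", "average")}
        res = ev.compare_models(scores, "multiview", labels)
        assert set(res) == {"A4c", "A2c", "PLAX", "average"}
        for c in res.values():
            assert c.n_comparisons == 4
            assert c.p_adjusted == pytest.approx(min(1.0, 4 * c.p_raw))


class TestStratifiedReport:
    def _data(self, rng, n=120, shift=1.0):
        labels = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        scores = rng.normal(0, 1, n) + shift * labels
        return scores, labels

    def test_identical_strata_identical_reports(self, rng):
        scores, labels = self._data(rng)
        double = np.r_[scores, scores]
        dlabels = np.r_[labels, labels]
        strata = np.r_[np.zeros_like(labels), np.ones_like(labels)]
        out = ev.stratified_report(double, dlabels, strata, threshold=0.5,
                                   with_ci=False)
        assert out["0.0"].auc == out["1.0"].auc
        assert out["0.0"].sensitivity == out["1.0"].sensitivity

    def test_whole_set_stratum_equals_unstratified(self, rng):
        scores, labels = self._data(rng)
        out = ev.stratified_report(scores, labels,
                                   np.full_like(labels, 7), 0.5, with_ci=False)
        assert out["7.0"].auc \
            == ev.classification_metrics(scores, labels, 0.5).auc

    def test_planted_easy_stratum_scores_higher(self, rng):
        easy_s, easy_l = self._data(rng, shift=2.5)
        hard_s, hard_l = self._data(rng, shift=0.5)
        scores = np.r_[easy_s, hard_s]
        labels = np.r_[easy_l, hard_l]
        strata = np.r_[np.full_like(easy_l, 0), np.full_like(hard_l, 1)]
        out = ev.stratified_report(scores, labels, strata, 0.5, with_ci=False)
        assert out["0.0"].auc > out["1.0"].auc

    def test_single_class_stratum_skipped_with_warning(self, rng):
        scores = np.r_[self._data(rng)[0], [0.5, 0.6]]
        labels = np.r_[self._data(rng)[1], [1, 1]]
        strata = np.r_[np.zeros(120), [1, 1]]
        with pytest.warns(UserWarning, match="single class"):
            out = ev.stratified_report(scores, labels, strata, 0.5,
                                       with_ci=False)
        assert set(out) == {"0.0"}
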