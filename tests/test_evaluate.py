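import numpy as np
import pandas as pd
import pytest

from mirscreen import (
    logistic_odds_ratio,
    marker_auc,
    performance_at_zero,
    roc,
    subgroup_accuracy,
)


class TestROC:
    def test_scores_equal_labels(self):
        assert roc([0, 1, 0, 1], [0, 1, 0, 1]).auc == 1.0

    def test_all_scores_identical(self):
        assert roc([3, 3, 3, 3], [0, 1, 0, 1]).auc == 0.5

    def test_brute_force_four_pairs(self):
        # pairs (case, control): 0.35>0.1, 0.35<0.4, 0.8>0.1, 0.8>0.4 -> 3/4
        assert roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).auc == pytest.approx(0.75)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2], [1, 1])

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        r = roc(scores, labels)
        assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)

    def test_agrees_with_marker_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.integers(0, 5, 40).astype(float)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        assert roc(scores, labels).auc == marker_auc(scores, labels).auc


class TestPerformanceAtZero:
    def test_perfect(self):
        p = performance_at_zero([1.0, 2.0, -1.0, -2.0], [1, 1, 0, 0])
        assert p == (1.0, 1.0, 1.0)

    def test_all_positive_calls(self):
        p = performance_at_zero([0.0, 1.0, 2.0, 3.0], [1, 1, 0, 0])
        assert p.sensitivity == 1.0 and p.specificity == 0.0

    def test_counting_example(self):
        idx = [1, 1, 1, -1] + [-1] * 9 + [1]
        labels = [1] * 4 + [0] * 10
        p = performance_at_zero(idx, labels)
        assert p.sensitivity == pytest.approx(0.75)
        assert p.specificity == pytest.approx(0.9)
        assert p.accuracy == pytest.approx(12 / 14)

    def test_accuracy_complements_errors(self):
        rng = np.random.default_rng(3)
        idx = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        p = performance_at_zero(idx, labels)
        errors = ((idx >= 0).astype(int) != labels).sum()
        assert p.accuracy == pytest.approx(1 - errors / 30)


class TestSubgroupAccuracy:
    def meta(self, stages, classes=None):
        n = len(stages)
        classes = classes or ["ovarian_cancer"] * n
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "class_label": classes,
                "stage": stages,
                "age": 50.0,
                "institute": "A",
                "flagged_probe_count": 0,
            }
        )

    def results(self, indices):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(len(indices))],
                "index": indices,
                "call": ["positive" if v >= 0 else "negative" for v in indices],
            }
        )

    def test_stage_graded_mean_index(self):
        stages = ["I"] * 5 + ["II"] * 5 + ["III_IV"] * 5
        idx = list(np.r_[np.full(5, 0.5), np.full(5, 2.0), np.full(5, 5.0)])
        tab = subgroup_accuracy(self.results(idx), self.meta(stages), by="stage")
        means = tab.set_index("stage")["mean_index"]
        assert means["I"] < means["II"] < means["III_IV"]

    def test_single_group(self):
        tab = subgroup_accuracy(self.results([1.0, -1.0]), self.meta(["I", "I"]),
                                by="stage")
        assert len(tab) == 1 and tab.loc[0, "n"] == 2

    def test_all_positive_case_group_is_100pct(self):
        tab = subgroup_accuracy(self.results([1.0, 2.0]), self.meta(["I", "I"]),
                                by="stage")
        assert tab.loc[0, "accuracy"] == 1.0

    def test_control_group_uses_negative_rate(self):
        meta = self.meta(["NA", "NA"], classes=["non_cancer", "non_cancer"])
        tab = subgroup_accuracy(self.results([-1.0, -2.0]), meta, by="class_label")
        assert tab.loc[0, "accuracy"] == 1.0

    def test_empty_group_row_with_warning(self):
        with pytest.warns(UserWarning, match="empty group"):
            tab = subgroup_accuracy(
                self.results([1.0]), self.meta(["I"]), by="stage",
                groups=["I", "II"],
            )
        assert np.isnan(tab.set_index("stage").loc["II", "accuracy"])


def logit_ll(params, x, y):
    eta = params[0] + params[1] * np.asarray(x)
    return float(y @ eta - np.logaddexp(0, eta).sum())


class TestLogisticOddsRatio:
    def make_data(self, seed=0, n=60, beta=1.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + beta * x)))
        y = (rng.random(n) < p).astype(int)
        if y.sum() < 10 or (1 - y).sum() < 10:
            return self.make_data(seed + 1, n, beta)
        return x, y

    def test_two_by_two_closed_form(self):
        # a=20 exposed cases, b=5 exposed controls, c=10, d=40
        x = np.r_[np.ones(20), np.zeros(10), np.ones(5), np.zeros(40)]
        y = np.r_[np.ones(30), np.zeros(45)].astype(int)
        fit = logistic_odds_ratio(x, y)
        assert fit.univariable.odds_ratio == pytest.approx((20 * 40) / (5 * 10),
                                                           rel=1e-6)

    def test_null_index_ci_covers_one(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=80)
        y = rng.permutation(np.r_[np.ones(40, int), np.zeros(40, int)])
        lo, hi = logistic_odds_ratio(x, y).univariable.ci
        assert lo < 1.0 < hi

    def test_uninformative_age_changes_or_little(self):
        x, y = self.make_data(seed=5, n=200, beta=1.2)
        rng = np.random.default_rng(6)
        age = rng.normal(50, 10, size=len(x))
        fit = logistic_odds_ratio(x, y, age=age)
        assert fit.age_adjusted.odds_ratio == pytest.approx(
            fit.univariable.odds_ratio, rel=0.05
        )

    def test_irls_matches_grid_maximum(self):
        x, y = self.make_data(seed=3, n=40)
        fit = logistic_odds_ratio(x, y)
        import statsmodels.api as sm

        full = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        b0, b1 = full.params
        # iterative grid refinement to ~2e-5 resolution
        c0, c1, half, step = 0.0, 0.0, 6.0, 0.12
        for _ in range(5):
            g0 = np.arange(c0 - half, c0 + half + step / 2, step)
            g1 = np.arange(c1 - half, c1 + half + step / 2, step)
            ll = np.array([[logit_ll(np.array([a, b]), x, y) for b in g1] for a in g0])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            c0, c1 = g0[i], g1[j]
            half, step = 2 * step, step / 10
        assert c1 == pytest.approx(np.log(fit.univariable.odds_ratio), abs=1e-4)

    def test_complete_separation_rejected(self):
        x = np.r_[np.linspace(1, 2, 15), np.linspace(5, 6, 15)]
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        with pytest.raises(ValueError):
            logistic_odds_ratio(x, y)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match=">=10"):
            logistic_odds_ratio([1.0, 2.0, 3.0], [0, 1, 0])
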