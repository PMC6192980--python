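import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirscreen import SearchConfig, fit_fisher_lda, loocv_metric, subset_search
from mirscreen.discriminant import (
    DegenerateSeparationError,
    DiscriminantModel,
    _loocv_predictions_fast,
    _loocv_predictions_naive,
)


# --- independent oracle: LDA and LOOCV coded from the definition -----------

def oracle_lda(X, y):
    """Pooled-covariance discriminant built with explicit loops."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mus, scatters, ns = [], [], []
    for cls in (0, 1):
        sub = X[y == cls]
        mu = sub.sum(axis=0) / len(sub)
        s = np.zeros((X.shape[1], X.shape[1]))
        for row in sub:
            d = row - mu
            s += np.outer(d, d)
        mus.append(mu)
        scatters.append(s)
        ns.append(len(sub))
    S = (scatters[0] + scatters[1]) / (ns[0] + ns[1] - 2)
    w = np.linalg.lstsq(S, mus[1] - mus[0], rcond=None)[0]
    b = -w @ (mus[0] + mus[1]) / 2
    return w, b


def oracle_loocv_balanced_accuracy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    preds = []
    for i in range(len(y)):
        keep = [j for j in range(len(y)) if j != i]
        w, b = oracle_lda(X[keep], y[keep])
        preds.append(int(X[i] @ w + b >= 0))
    preds = np.asarray(preds)
    return 0.5 * ((preds[y == 1] == 1).mean() + (preds[y == 0] == 0).mean())


def random_problem(rng, n_per_class, p, shift=1.0):
    X = np.vstack(
        [rng.normal(0, 1, (n_per_class, p)), rng.normal(shift, 1, (n_per_class, p))]
    )
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    return X, y


class TestFitFisherLDA:
    def test_1d_closed_form(self):
        # class means 0 and 2, pooled within-class variance exactly 1
        X = np.array([[-1.0], [0.0], [1.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = fit_fisher_lda(X, y)
        assert m.coefficients[0] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(-2.0)
        assert m.index([[1.5]])[0] == pytest.approx(1.0)
        assert m.predict([[1.5]])[0] == 1

    def test_symmetric_means_zero_intercept(self):
        rng = np.random.default_rng(3)
        X1 = rng.normal(1.0, 1.0, (20, 2))
        X = np.vstack([-X1, X1])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert fit_fisher_lda(X, y).intercept == pytest.approx(0.0, abs=1e-12)

    def test_identity_cov_zero_weight_on_flat_feature(self):
        rng = np.random.default_rng(4)
        # feature 0 shifted, feature 1 identical in both classes
        n = 2000
        base = rng.normal(0, 1, (2 * n, 2))
        X = base.copy()
        X[n:, 0] += 1.0
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        m = fit_fisher_lda(X, y)
        assert abs(m.coefficients[1]) < 0.1 * abs(m.coefficients[0])

    def test_identical_means_degenerate(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(DegenerateSeparationError):
            fit_fisher_lda(X, y)

    def test_singular_covariance_ridge_warns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        X = np.column_stack([x, x])  # rank-1 scatter
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        X[y == 1] += 1.0
        with pytest.warns(UserWarning, match="ridge"):
            m = fit_fisher_lda(X, y)
        assert np.all(np.isfinite(m.coefficients))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_oracle_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 4))
        X, y = random_problem(rng, int(rng.integers(p + 2, 12)), p)
        m = fit_fisher_lda(X, y)
        w, b = oracle_lda(X, y)
        np.testing.assert_allclose(m.coefficients, w, rtol=1e-8, atol=1e-10)
        assert m.intercept == pytest.approx(b, rel=1e-8, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_predictions_invariant_under_feature_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_problem(rng, 12, 3)
        scale = rng.uniform(0.1, 10.0, 3)
        shift = rng.normal(0, 5, 3)
        m1 = fit_fisher_lda(X, y)
        m2 = fit_fisher_lda(X * scale + shift, y)
        Xt = rng.normal(0.5, 1.5, (30, 3))
        np.testing.assert_array_equal(m1.predict(Xt), m2.predict(Xt * scale + shift))


class TestLOOCV:
    def test_separated_clusters_perfect(self):
        X = np.r_[np.linspace(0, 1, 5), np.linspace(10, 11, 5)][:, None]
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        assert loocv_metric(X, y) == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 2))
        y = rng.permutation(np.r_[np.zeros(10, int), np.ones(10, int)])
        assert loocv_metric(X, y) == pytest.approx(0.5, abs=0.2)

    def test_minimal_two_per_class_quantized(self):
        X = np.array([[0.0], [0.4], [1.1], [1.5]])
        y = np.array([0, 0, 1, 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = loocv_metric(X, y, cfg=SearchConfig(selection_metric="accuracy"))
        assert m in {0.0, 0.25, 0.5, 0.75, 1.0}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_fast_path_equals_per_fold_refit(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 5))
        X, y = random_problem(rng, int(rng.integers(p + 2, 12)), p, shift=0.8)
        fast = _loocv_predictions_fast(X, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            naive = _loocv_predictions_naive(X, y)
        assert fast is not None
        np.testing.assert_array_equal(fast, naive)

    def test_fast_path_matches_oracle_metric(self):
        rng = np.random.default_rng(12)
        X, y = random_problem(rng, 10, 3, shift=1.2)
        assert loocv_metric(X, y) == pytest.approx(
            oracle_loocv_balanced_accuracy(X, y)
        )


class TestSubsetSearch:
    def test_informative_feature_recovered(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            n = 20
            X = rng.normal(size=(2 * n, 5))
            y = np.r_[np.zeros(n, int), np.ones(n, int)]
            X[y == 1, 0] += 3.0
            model = subset_search(X, y, [f"f{i}" for i in range(5)],
                                  SearchConfig(max_panel=3))
            hits += "f0" in model.panel
        assert hits >= 19

    def test_duplicate_feature_smaller_panel_wins(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=20)
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        x[y == 1] += 2.5
        X = np.column_stack([x, x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = subset_search(X, y, ["a", "b"], SearchConfig(max_panel=2))
        assert model.panel_size == 1

    def test_max_panel_one_is_best_single_marker(self):
        rng = np.random.default_rng(22)
        X, y = random_problem(rng, 15, 4, shift=0.0)
        X[y == 1, 2] += 2.0
        ids = ["a", "b", "c", "d"]
        model = subset_search(X, y, ids, SearchConfig(max_panel=1))
        best = max(ids, key=lambda i: loocv_metric(X[:, [ids.index(i)]], y))
        assert model.panel == (best,)

    def test_empty_pivot_set_error(self):
        with pytest.raises(ValueError, match="empty pivot"):
            subset_search(np.zeros((4, 0)), np.array([0, 0, 1, 1]), [])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_matches_brute_force_enumeration(self, seed):
        """Winner agrees with an independently coded exhaustive search."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 5))
        X, y = random_problem(rng, int(rng.integers(6, 10)), p, shift=0.7)
        ids = [f"f{i}" for i in range(p)]
        cfg = SearchConfig(max_panel=p)
        model = subset_search(X, y, ids, cfg)

        best = None
        for k in range(1, p + 1):
            for comb in itertools.combinations(range(p), k):
                m = oracle_loocv_balanced_accuracy(X[:, comb], y)
                w, b = oracle_lda(X[:, comb], y)
                auc_scores = X[:, comb] @ w + b
                from mirscreen import rank_auc

                key = (m, -k, rank_auc(auc_scores, y))
                panel = tuple(ids[i] for i in comb)
                if best is None or key > best[0] or (
                    key == best[0] and tuple(sorted(panel)) < tuple(sorted(best[1]))
                ):
                    best = (key, panel)
        assert model.panel == best[1]

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(30)
        X, y = random_problem(rng, 10, 2)
        model = subset_search(X, y, ["a", "b"], SearchConfig(max_panel=2))
        model.to_json(tmp_path / "m.json")
        back = DiscriminantModel.from_json(tmp_path / "m.json")
        assert back.panel == model.panel
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.intercept == model.intercept
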