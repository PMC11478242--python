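import numpy as np
import pytest

from cannclass.chemometrics import (
    PlsdaClassifier,
    classify,
    fit_pls,
    fit_threshold,
    lv_weight_report,
    pca_scores,
    ward_hca,
)
from cannclass.preprocess import autoscale_apply, autoscale_fit


def autoscaled(X):
    return autoscale_apply(autoscale_fit(X), X)


class TestFitPls:
    def test_single_predictive_column(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        X = y[:, None].copy()
        m = fit_pls(X, y, 1)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-12)

    def test_full_rank_matches_least_squares(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            X = autoscaled(rng.normal(size=(12, 5)))
            y = rng.normal(size=12)
            m = fit_pls(X, y, 5)
            coef, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(12), X]), y, rcond=None
            )
            ols_pred = X @ coef[1:] + coef[0]
            np.testing.assert_allclose(m.predict(X), ols_pred, atol=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(8)
        X = autoscaled(rng.normal(size=(30, 15)))
        y = rng.normal(size=30)
        T = fit_pls(X, y, 6).scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_matches_sklearn_predictions(self):
        """Independent cross-check against scikit-learn's PLS regression."""
        sk = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(9)
        X = autoscaled(rng.normal(size=(25, 10)))
        y = rng.normal(size=25)
        for a in (1, 2, 4):
            ours = fit_pls(X, y, a)
            ref = sk.PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.predict(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_additional_lv_never_raises_rss(self):
        rng = np.random.default_rng(10)
        X = autoscaled(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        rss = [
            float(((fit_pls(X, y, a).predict(X) - y) ** 2).sum())
            for a in range(1, 8)
        ]
        assert all(b <= a + 1e-10 for a, b in zip(rss, rss[1:]))

    def test_too_many_lv_rejected(self):
        X = autoscaled(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            fit_pls(X, np.array([1.0, -1, 1, -1, 1]), 5)

    def test_constant_y_rejected(self):
        X = autoscaled(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(5), 1)


class TestThreshold:
    def test_symmetric_classes_near_zero(self):
        rng = np.random.default_rng(1)
        t = fit_threshold(rng.normal(1, 0.3, 5000), rng.normal(-1, 0.3, 5000))
        assert abs(t) < 0.05

    def test_degenerate_zero_variance_midpoint(self):
        assert fit_threshold([1.0, 1.0], [-1.0, -1.0]) == 0.0

    def test_identical_distributions_warns_midpoint(self):
        with pytest.warns(UserWarning):
            t = fit_threshold([0.5, 0.5], [0.5, 0.5])
        assert t == 0.5

    def test_unequal_variance_matches_grid_search(self):
        """Oracle: fine grid search minimizing empirical Bayes error."""
        rng = np.random.default_rng(2)
        pos = rng.normal(1.0, 0.2, 20000)
        neg = rng.normal(-1.0, 0.8, 20000)
        t = fit_threshold(pos, neg)
        grid = np.arange(-1.0, 1.0, 0.005)
        errors = [(pos < g).sum() + (neg >= g).sum() for g in grid]
        t_grid = grid[int(np.argmin(errors))]
        assert abs(t - t_grid) < 0.05


class TestClassify:
    def _clf(self, X, y, threshold=None):
        m = fit_pls(X, y, 1)
        s = m.predict(X)
        thr = fit_threshold(s[y > 0], s[y < 0]) if threshold is None else threshold
        return PlsdaClassifier(m, thr, "pos", "neg")

    def test_separable_classes_zero_errors(self):
        rng = np.random.default_rng(3)
        n = 40
        y = np.repeat([1.0, -1.0], n // 2)
        X = autoscaled(np.column_stack([y * 3 + rng.normal(0, 0.1, n),
                                        rng.normal(size=n)]))
        clf = self._clf(X, y)
        labels, _ = classify(clf, X)
        assert labels == ["pos"] * (n // 2) + ["neg"] * (n // 2)

    def test_tie_goes_to_positive(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = y[:, None].copy()
        clf = self._clf(X, y, threshold=1.0)
        labels, scores = classify(clf, np.array([[1.0]]))
        assert scores[0] == pytest.approx(1.0)
        assert labels == ["pos"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        y = np.repeat([1.0, -1.0], 10)
        X = autoscaled(rng.normal(size=(20, 5)) + y[:, None])
        clf = self._clf(X, y)
        perm = rng.permutation(20)
        l1, s1 = classify(clf, X)
        l2, s2 = classify(clf, X[perm])
        assert [l1[i] for i in perm] == l2
        np.testing.assert_allclose(s1[perm], s2)

    def test_dimension_mismatch(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        clf = self._clf(y[:, None].copy(), y)
        with pytest.raises(ValueError):
            classify(clf, np.zeros((1, 3)))


class TestLvWeights:
    def test_indole_vs_indazole_markers_top_ranked(self):
        """On core-group data the 144/145 fragment pair must carry the
        separation, with opposite signs."""
        from cannclass import SimConfig, generate_dataset
        from cannclass.cascade import _node_population

        train, _ = generate_dataset(
            SimConfig(seed=21, n_train_per_class=8, n_test_per_class=4)
        )
        idx, y = _node_population(train, "indole_vs_indazole_azaindole")
        Z = autoscaled(train.X[idx])
        scaling = autoscale_fit(train.X[idx])
        mz = train.mz_axis[scaling.kept_mask]
        m = fit_pls(Z, y, 2, mz_axis=mz)
        top = lv_weight_report(m, 1, 10)
        by_mz = {int(mzv): w for mzv, w in top}
        assert 144 in by_mz and 145 in by_mz
        assert by_mz[144] * by_mz[145] < 0

    def test_top_k_capped_at_variable_count(self):
        y = np.repeat([1.0, -1.0], 5)
        X = autoscaled(np.random.default_rng(0).normal(size=(10, 3)) + y[:, None])
        m = fit_pls(X, y, 1, mz_axis=np.array([50, 60, 70]))
        assert len(lv_weight_report(m, 1, 99)) == 3

    def test_lv_index_out_of_range(self):
        y = np.repeat([1.0, -1.0], 5)
        X = autoscaled(np.random.default_rng(0).normal(size=(10, 3)) + y[:, None])
        m = fit_pls(X, y, 1)
        with pytest.raises(ValueError):
            lv_weight_report(m, 2, 5)


class TestPca:
    def test_one_axis_explains_everything(self):
        t = np.linspace(-1, 1, 9)
        X = np.outer(t, [1.0, 2.0, -0.5])
        scores, frac = pca_scores(X, 1)
        assert frac[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_up_to_sign(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        scores, frac = pca_scores(X, 4)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        order = np.argsort(evals)[::-1]
        ref = Xc @ evecs[:, order[:4]]
        for j in range(4):
            match = min(
                np.abs(scores[:, j] - ref[:, j]).max(),
                np.abs(scores[:, j] + ref[:, j]).max(),
            )
            assert match < 1e-8

    def test_explained_fractions(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 5))
        _, frac = pca_scores(X, 4)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1.0 + 1e-12

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            pca_scores(np.random.default_rng(0).normal(size=(4, 6)), 4)


def brute_force_ward(X):
    """Exhaustive greedy Ward: at each step merge the pair with the smallest
    variance-increase distance, computed from raw cluster members."""
    X = np.asarray(X, dtype=float)
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = X[list(clusters[a])].mean(axis=0)
                cb = X[list(clusters[b])].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], d))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def linkage_to_merges(Z, n):
    sets = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_i, (i, j, d, _) in enumerate(Z):
        a, b = sets[int(i)], sets[int(j)]
        merges.append((a, b, float(d)))
        sets[n + row_i] = a | b
    return merges


class TestWardHca:
    def test_duplicates_merge_first_at_zero(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        Z = ward_hca(X)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]

    def test_close_pair_merges_before_outlier(self):
        X = np.array([[0.0], [0.1], [10.0]])
        Z = ward_hca(X)
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]

    def test_merge_heights_nondecreasing(self):
        X = np.random.default_rng(11).normal(size=(12, 3))
        Z = ward_hca(X)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_small(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 9))
        X = rng.normal(size=(n, 3))
        Z = ward_hca(X)
        got = linkage_to_merges(Z, n)
        expected = brute_force_ward(X)
        for (ga, gb, gd), (ea, eb, ed) in zip(got, expected):
            assert {ga, gb} == {ea, eb}
            assert gd == pytest.approx(ed, abs=1e-8)
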