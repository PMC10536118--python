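import numpy as np
import pytest

from rilimet.chemometrics import (KPLSModel, PLSModel, cross_validate_q2,
                                  fit_kpls, fit_pls, gaussian_gamma,
                                  one_hot, osc_filter, permutation_test,
                                  scale_matrix, unscale_matrix,
                                  venetian_folds)


def random_xy(seed, n=25, p=8, c=1, noise=0.3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, c))
    Y = X @ B + noise * rng.normal(size=(n, c))
    return X, Y


class TestScaleMatrix:
    def test_uv_gives_exact_zero_mean_unit_sd(self):
        Xs, _, _ = scale_matrix(np.array([[1.0], [2.0], [3.0]]), "uv")
        assert Xs.mean() == pytest.approx(0.0, abs=1e-15)
        assert Xs.std(ddof=1) == pytest.approx(1.0, abs=1e-15)

    def test_roundtrip_inverse(self):
        X = np.random.default_rng(0).normal(2.0, 3.0, size=(20, 5))
        for method in ("uv", "pareto", "center_only"):
            Xs, c, s = scale_matrix(X, method)
            np.testing.assert_allclose(unscale_matrix(Xs, c, s), X,
                                       atol=1e-12)

    def test_pareto_variance_equals_sd(self):
        X = np.random.default_rng(1).normal(0, 4.0, size=(200, 1))
        Xs, _, _ = scale_matrix(X, "pareto")
        assert Xs.var(ddof=1) == pytest.approx(X.std(ddof=1), rel=1e-10)

    def test_zero_variance_column_named(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="1"):
            scale_matrix(X, "uv")


class TestPLS:
    def test_one_component_matches_closed_form_direction(self):
        X, Y = random_xy(0, c=1)
        res = fit_pls(X, Y, 1)
        Xs, _, _ = scale_matrix(X, "uv")
        w_expected = Xs.T @ (Y - Y.mean())
        w_expected /= np.linalg.norm(w_expected)
        np.testing.assert_allclose(np.abs(res.W[:, 0]),
                                   np.abs(w_expected[:, 0]), atol=1e-10)

    def test_full_rank_reproduces_least_squares(self):
        X, Y = random_xy(1, n=30, p=5)
        res = fit_pls(X, Y, 5)
        Xs, _, _ = scale_matrix(X, "uv")
        Yc = Y - Y.mean(axis=0)
        beta = np.linalg.lstsq(Xs, Yc, rcond=None)[0]
        np.testing.assert_allclose(Xs @ res.coef, Xs @ beta, atol=1e-8)

    def test_y_orthogonal_to_x_gives_no_fit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=(40, 1))
        # orthogonalize y against centered, scaled X columns exactly
        Xs, _, _ = scale_matrix(X, "uv")
        y = y - y.mean()
        y -= Xs @ np.linalg.lstsq(Xs, y, rcond=None)[0]
        res = PLSModel(X, y).fit(2)
        assert res.r2y < 0.01

    def test_score_orthogonality(self):
        for seed in range(5):
            X, Y = random_xy(seed, n=30, p=10, c=2)
            res = fit_pls(X, Y, 4)
            G = res.T.T @ res.T
            off = G - np.diag(np.diag(G))
            assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_predictions_match_sklearn_cross_check(self):
        """Independent oracle: sklearn PLSRegression on the same scaled
        problem produces the same predictions."""
        from sklearn.cross_decomposition import PLSRegression
        X, Y = random_xy(7, n=40, p=6, c=1)
        res = fit_pls(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=True).fit(X, Y)
        np.testing.assert_allclose(res.predict(X), sk.predict(X),
                                   atol=1e-8)

    def test_r2y_nondecreasing_in_components(self):
        X, Y = random_xy(9, n=30, p=8)
        r2 = [fit_pls(X, Y, a).r2y for a in range(1, 6)]
        assert (np.diff(r2) >= -1e-12).all()


class TestVIP:
    def test_single_variable_vip_is_one(self):
        X, Y = random_xy(2, p=1)
        res = fit_pls(X, Y, 1)
        assert res.vip()[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_mean_square_identity(self, seed):
        X, Y = random_xy(seed, n=20 + seed, p=5 + seed,
                         c=1 + seed % 2)
        res = fit_pls(X, Y, 2 + seed % 3)
        v = res.vip()
        assert np.mean(v ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_informative_variables_rank_above_noise(self):
        wins = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=40)
            X = np.column_stack([
                y * 0.9 + rng.normal(scale=0.44, size=40),
                y * 0.9 + rng.normal(scale=0.44, size=40),
                rng.normal(size=40), rng.normal(size=40)])
            v = fit_pls(X, y, 2).vip()
            if v[0] > 1 > v[2] and v[1] > 1 > v[3]:
                wins += 1
        assert wins >= 27


class TestOSC:
    def test_scores_orthogonal_to_y(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 8))
            Y = rng.normal(size=(30, 2))
            Xs, _, _ = scale_matrix(X, "uv")
            res = osc_filter(Xs, Y, n_osc=2)
            Yc = Y - Y.mean(axis=0)
            for a in range(2):
                for j in range(2):
                    r = np.corrcoef(res.scores[:, a], Yc[:, j])[0, 1]
                    assert abs(r) < 1e-6

    def test_removes_first_pc_when_y_uncorrelated(self):
        rng = np.random.default_rng(3)
        # X with one dominant direction; Y orthogonal to it by construction
        t = rng.normal(size=(50, 1))
        X = t @ rng.normal(size=(1, 6)) + 0.05 * rng.normal(size=(50, 6))
        Xs, _, _ = scale_matrix(X, "center_only")
        u, s, vt = np.linalg.svd(Xs, full_matrices=False)
        pc1_var = s[0] ** 2 / (s ** 2).sum()
        Y = rng.normal(size=(50, 1))
        Y -= u[:, :1] @ (u[:, :1].T @ Y)  # exactly orthogonal to PC1
        res = osc_filter(Xs, Y, n_osc=1)
        assert res.removed_variance_fraction == pytest.approx(pc1_var,
                                                              abs=0.02)

    def test_improves_q2_when_structured_noise_orthogonal_to_y(self):
        rng = np.random.default_rng(11)
        n, p = 40, 12
        y = rng.normal(size=(n, 1))
        signal_dir = rng.normal(size=(1, p))
        noise_scores = rng.normal(size=(n, 1))
        noise_scores -= y @ np.linalg.lstsq(y, noise_scores, rcond=None)[0]
        noise_dir = rng.normal(size=(1, p))
        X = y @ signal_dir + 3.0 * noise_scores @ noise_dir \
            + 0.3 * rng.normal(size=(n, p))
        q2_raw = cross_validate_q2(X, y, 2, seed=0)
        Xs, _, _ = scale_matrix(X, "uv")
        Xf = osc_filter(Xs, y, n_osc=1).X_filtered
        q2_osc = cross_validate_q2(Xf, y, 2, seed=0, scale="center_only")
        assert q2_osc > q2_raw


class TestKPLS:
    def test_linear_kernel_equals_pls_on_train_and_test(self):
        X, Y = random_xy(3, n=30, p=8, c=2)
        Xte = np.random.default_rng(99).normal(size=(10, 8))
        pls = fit_pls(X, Y, 3)
        kpls = fit_kpls(X, Y, 3, kernel="linear")
        for Z in (X, Xte):
            a, b = pls.predict(Z), kpls.predict(Z)
            assert np.abs(a - b).max() <= 1e-6 * max(1.0,
                                                     np.abs(a).max())

    def test_gaussian_kernel_hand_arithmetic(self):
        # 3 points in 1-D at 0, 1, 3 with gamma 1: K entries are
        # exp(0), exp(-1), exp(-9), exp(-4)
        X = np.array([[0.0], [1.0], [3.0]])
        from rilimet.chemometrics import _kernel
        K = _kernel(X, X, "gaussian", 1.0)
        expected = np.exp(-np.array([[0, 1, 9], [1, 0, 4], [9, 4, 0]],
                                    dtype=float))
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_xor_pattern_needs_gaussian_kernel(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        labels = ["a", "a", "b", "b"]
        X = np.vstack([c + 0.05 * rng.normal(size=(10, 2))
                       for c in centers])
        y = sum(([l] * 10 for l in labels), [])
        lin = KPLSModel(X, y, kernel="linear", classes=True).fit(2)
        gau = KPLSModel(X, y, kernel="gaussian", gamma=5.0,
                        classes=True).fit(2)
        acc = lambda m: np.mean(np.array(m.predict_class(X)) == y)
        assert acc(gau) == 1.0
        assert acc(lin) <= 0.75

    def test_nonpositive_gamma_rejected(self):
        X, Y = random_xy(0)
        with pytest.raises(ValueError):
            KPLSModel(X, Y, kernel="gaussian", gamma=0.0)

    def test_median_heuristic_positive(self):
        X, _ = random_xy(1)
        assert gaussian_gamma(X) > 0


class TestQ2AndPermutation:
    def test_venetian_folds_partition(self):
        assign = venetian_folds(23, 7, seed=1)
        assert set(assign) == set(range(7))
        assert len(assign) == 23

    def test_noiseless_linear_q2_near_one(self):
        X, _ = random_xy(6, n=30, p=5)
        b = np.arange(1.0, 6.0)
        y = X @ b
        assert cross_validate_q2(X, y, 4, seed=0) > 0.99

    def test_pure_noise_q2_nonpositive_usually(self):
        neg = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 10))
            y = rng.normal(size=24)
            if cross_validate_q2(X, y, 2, seed=seed) <= 0:
                neg += 1
        assert neg >= 0.9 * 25 - 2

    def test_q2_bounded_by_r2y(self):
        for seed in range(6):
            X, Y = random_xy(seed, n=28, p=6, noise=1.0)
            r2y = fit_pls(X, Y, 2).r2y
            q2 = cross_validate_q2(X, Y, 2, seed=seed)
            assert q2 <= r2y + 1e-10

    def test_single_permutation_reproducible(self):
        X, Y = random_xy(8)
        a = permutation_test(X, Y, 2, n_perm=1, seed=5)
        b = permutation_test(X, Y, 2, n_perm=1, seed=5)
        assert a.permuted_q2[0] == b.permuted_q2[0]
        assert a.permuted_r2y[0] == b.permuted_r2y[0]

    def test_empirical_p_formula(self):
        X, Y = random_xy(10)
        rep = permutation_test(X, Y, 2, n_perm=19, seed=2)
        expect = (1 + np.sum(rep.permuted_q2 >= rep.observed_q2)) / 20
        assert rep.empirical_p_q2 == pytest.approx(expect)


def test_one_hot_encoding_order():
    Y, classes = one_hot(["b", "a", "b"])
    assert classes == ["a", "b"]
    np.testing.assert_array_equal(Y, [[0, 1], [1, 0], [0, 1]])
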