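"""UV-scaled PCA / NIPALS PLS2, metrics, VIP, and T2/SPE diagnostics."""

import numpy as np
import pytest
from scipy import stats

from fppid import latent
from fppid.latent import (PCAUV, PLSNipals, UVScaler, choose_components,
                          fit_pca, fit_pls, metrics, refine_by_vip, spe_limit,
                          t2_limit, vip)


class TestScaler:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 5, size=(20, 4))
        sc = UVScaler().fit(X)
        assert np.abs(sc.inverse_transform(sc.transform(X)) - X).max() < 1e-12

    def test_zero_variance_named(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        with pytest.raises(latent.ScalingError, match="b"):
            UVScaler().fit(X, names=["a", "b"])


class TestPCA:
    def test_exact_rank_two_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 2)) @ rng.standard_normal((2, 6))
        m = PCAUV(n_components=2, scale=False).fit(X)
        recon = m.scores_ @ m.loadings_.T
        Z = m.scaler_.transform(X)
        assert np.abs(recon - Z).max() < 1e-8

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 6))
        m = PCAUV(n_components=4).fit(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        for a in range(4):
            dot = abs(float(m.loadings_[:, a] @ Vt[a]))
            assert dot == pytest.approx(1.0, abs=1e-10)
            assert np.abs(np.abs(m.scores_[:, a]) - np.abs(U[:, a] * s[a])).max() < 1e-10

    def test_explained_variance_ordered_and_bounded(self):
        rng = np.random.default_rng(3)
        m = PCAUV(n_components=5).fit(rng.standard_normal((30, 8)))
        ev = m.explained_variance_ratio_
        assert np.all(np.diff(ev) <= 1e-15)
        assert ev.sum() <= 1 + 1e-12


class TestPLS:
    def test_rank_one_noiseless_r2y(self):
        # single-factor truth: X and Y both driven by one latent score
        rng = np.random.default_rng(4)
        t0 = rng.standard_normal(25)
        X = np.outer(t0, rng.uniform(0.5, 2.0, 6))
        Y = np.outer(t0, [1.0, -0.5])
        m = fit_pls(X, Y, 1)
        met = metrics(m, X, Y, folds=5)
        assert met.r2y_cum == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_oracle(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 2))
        m = fit_pls(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=True, tol=1e-12,
                           max_iter=10000).fit(X, Y)
        Xn = rng.standard_normal((8, 5))
        assert np.abs(m.predict(X) - sk.predict(X)).max() < 1e-6
        assert np.abs(m.predict(Xn) - sk.predict(Xn)).max() < 1e-6

    def test_full_rank_reproduces_ols(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 1))
        m = fit_pls(X, Y, 5)
        Xc = np.column_stack([np.ones(20), X])
        B, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        assert np.abs(m.predict(X) - Xc @ B).max() < 1e-6

    def test_score_orthogonality(self):
        rng = np.random.default_rng(7)
        m = fit_pls(rng.standard_normal((30, 8)),
                    rng.standard_normal((30, 2)), 4)
        G = m.x_scores_.T @ m.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((25, 6))
        Y = rng.standard_normal((25, 2))
        m1, m2 = fit_pls(X, Y, 3), fit_pls(X, Y, 3)
        assert np.array_equal(m1.x_weights_, m2.x_weights_)
        for a in range(3):
            w = m1.x_weights_[:, a]
            assert w[np.argmax(np.abs(w))] >= 0


class TestMetrics:
    def test_q2_near_one_for_noiseless_truth(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((70, 6))
        Y = np.column_stack([X @ rng.standard_normal(6),
                             X @ rng.standard_normal(6)])
        m = fit_pls(X, Y, 6)
        assert metrics(m, X, Y).q2_cum > 0.999

    def test_q2_null_distribution(self):
        """Pure-noise responses: Q2 <= 0.05 in at least 95% of seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            X = rng.standard_normal((200, 8))
            Y = rng.standard_normal((200, 2))
            m = fit_pls(X, Y, 3)
            if metrics(m, X, Y).q2_cum <= 0.05:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_q2_invariant_to_row_permutation_with_seeded_folds(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((35, 6))
        Y = np.column_stack([X @ rng.standard_normal(6)
                             + 0.3 * rng.standard_normal(35)])
        m = fit_pls(X, Y, 2)
        met1 = metrics(m, X, Y, assignment="interleaved")
        perm = rng.permutation(35)
        m2 = fit_pls(X[perm], Y[perm], 2)
        met2 = metrics(m2, X[perm], Y[perm], assignment="interleaved")
        # interleaved assignment relabels folds under permutation, but the
        # pooled Q2 stays within CV noise; the seeded-random assignment on
        # identical data is exactly reproducible
        met3 = metrics(m, X, Y, assignment="random", seed=3)
        met4 = metrics(m, X, Y, assignment="random", seed=3)
        assert met3.q2_cum == met4.q2_cum
        assert met1.q2_cum == pytest.approx(met2.q2_cum, abs=0.2)

    def test_folds_exceeding_rows_rejected(self):
        rng = np.random.default_rng(12)
        X, Y = rng.standard_normal((5, 3)), rng.standard_normal((5, 1))
        m = fit_pls(X, Y, 2)
        with pytest.raises(ValueError):
            metrics(m, X, Y, folds=6)

    def test_chosen_components_recover_planted_rank(self):
        """CV component choice lands at the true rank +-1 on planted
        three-factor data."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            T = rng.standard_normal((100, 3))
            X = T @ rng.standard_normal((3, 12)) + 0.1 * rng.standard_normal((100, 12))
            Y = T @ rng.standard_normal((3, 2)) + 0.1 * rng.standard_normal((100, 2))
            a, _ = choose_components(X, Y, 6)
            hits += (2 <= a <= 4)
        assert hits >= 4


class TestVIP:
    def test_single_predictor_vip_is_one(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((20, 1))
        Y = X * 2 + 0.1 * rng.standard_normal((20, 1))
        assert vip(fit_pls(X, Y, 1))[0] == pytest.approx(1.0)

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(14)
        m = fit_pls(rng.standard_normal((30, 9)),
                    rng.standard_normal((30, 2)), 4)
        assert (vip(m) ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_planted_drivers_have_largest_vip(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((120, 8))
        Y = (X[:, :3] @ [1.5, -1.2, 1.0])[:, None] + 0.05 * rng.standard_normal((120, 1))
        v = vip(fit_pls(X, Y, 3))
        assert set(np.argsort(v)[-3:]) == {0, 1, 2}

    def test_refine_noop_at_zero_threshold(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 2))
        refined, dropped, full = refine_by_vip(X, Y, 2, threshold=0.0)
        assert dropped == []
        assert np.allclose(refined.predict(X), full.predict(X))

    def test_refine_drops_planted_dummies(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((150, 10))
        Y = (X[:, :6] @ rng.uniform(0.8, 1.5, 6))[:, None] \
            + 0.05 * rng.standard_normal((150, 1))
        refined, dropped, _ = refine_by_vip(
            X, Y, 3, threshold=1.0,
            feature_names=[f"f{j}" for j in range(10)])
        assert set(dropped) >= {"f6", "f7", "f8", "f9"}

    def test_refine_refuses_to_drop_everything(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 1))
        with pytest.raises(ValueError, match="refus"):
            refine_by_vip(X, Y, 2, threshold=np.inf)


class TestDiagnostics:
    def test_t2_limit_reference_values(self):
        assert round(t2_limit(6, 735, 0.05), 2) == 12.75
        # 2*9/8 * F(2,8;0.95) = 2.25 * 4.459
        expected = 2.25 * stats.f.ppf(0.95, 2, 8)
        assert t2_limit(2, 10, 0.05) == pytest.approx(expected)
        assert t2_limit(2, 10, 0.05) == pytest.approx(10.03, abs=0.01)

    def test_t2_limit_monotone_in_a_and_n(self):
        grid_a = [t2_limit(a, 100, 0.05) for a in range(1, 8)]
        assert np.all(np.diff(grid_a) > 0)
        grid_n = [t2_limit(3, n, 0.05) for n in (10, 20, 50, 200, 1000)]
        assert np.all(np.diff(grid_n) < 0)

    def test_t2_empirical_coverage(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((500, 6))
        Y = np.column_stack([X @ [1, 0.5, 0, 0, 0.2, 0],
                             X @ [0, 0.3, 1, 0.2, 0, 0]]) \
            + 0.4 * rng.standard_normal((500, 2))
        m = fit_pls(X, Y, 3)
        lim = t2_limit(3, m.n_train_, 0.05)
        scores = rng.standard_normal((10_000, 3)) * np.sqrt(m.score_variance_)
        frac = float((m.hotelling_t2(scores=scores) > lim).mean())
        assert 0.04 <= frac <= 0.06

    def test_spe_matches_brute_force(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((25, 6))
        Y = rng.standard_normal((25, 2))
        m = fit_pls(X, Y, 2)
        Xn = rng.standard_normal((5, 6))
        Z = m.x_scaler_.transform(Xn)
        Zhat = m.reconstruct_x(Xn)
        brute = np.array([sum((Z[i, j] - Zhat[i, j]) ** 2 for j in range(6))
                          for i in range(5)])
        assert np.abs(m.spe(Xn) - brute).max() < 1e-10

    def test_spe_zero_at_full_rank(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 1))
        m = fit_pls(X, Y, 4)
        assert m.spe(X).max() < 1e-16

    def test_spe_limit_methods_cover_training_tail(self):
        rng = np.random.default_rng(22)
        X = rng.standard_normal((400, 10))
        Y = rng.standard_normal((400, 2))
        m = fit_pls(X, Y, 3)
        q = m.spe(X)
        for method in ("jackson-mudholkar", "chi2"):
            lim = spe_limit(m._x_residual_train_, 0.05, method=method)
            frac = float((q > lim).mean())
            assert 0.01 <= frac <= 0.10, method

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((30, 7))
        Y = rng.standard_normal((30, 2))
        m = fit_pls(X, Y, 3, feature_names=[f"x{j}" for j in range(7)],
                    response_names=["TS", "SF"])
        path = tmp_path / "model.json"
        latent.save_model(m, path)
        m2 = latent.load_model(path)
        Xn = rng.standard_normal((6, 7))
        assert np.abs(m.predict(Xn) - m2.predict(Xn)).max() < 1e-12
        assert np.abs(m.spe(Xn) - m2.spe(Xn)).max() < 1e-12
        assert np.abs(m.hotelling_t2(X=Xn) - m2.hotelling_t2(X=Xn)).max() < 1e-12
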