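"""The five genomic prediction methods: algebraic equivalences, closed
forms, sparse recovery, determinism, and the Raftery-Lewis diagnostic."""

import numpy as np
import pytest

from clonegs import markers, models
from clonegs.containers import KinshipMatrix
from clonegs.models import (
    BayesB,
    BayesianLasso,
    GBLUP,
    RKHS,
    RRBLUP,
    fit_bayesb,
    fit_blasso,
    fit_gblup,
    fit_rkhs,
    fit_rrblup,
    predict_gebv,
    raftery_lewis,
)


def _sim_additive(rng, n=200, m=600, h2=0.5, n_qtl=40):
    Z = rng.binomial(2, rng.uniform(0.1, 0.9, m), (n, m)) - 1.0
    qtl = rng.choice(m, n_qtl, replace=False)
    g = Z[:, qtl] @ rng.normal(size=n_qtl)
    g = (g - g.mean()) / g.std()
    y = g + rng.normal(0, np.sqrt((1 - h2) / h2), n)
    return Z, y, g


class TestRRBLUP:
    def test_noise_free_recovery(self, rng):
        Z, _, g = _sim_additive(rng, h2=0.999)
        fit = RRBLUP().fit(Z, g)
        assert np.corrcoef(fit.gebv_, g)[0, 1] > 0.99

    def test_equivalence_with_gblup(self, rng):
        """RR-BLUP and G-BLUP GEBVs agree to numerical precision when G is
        built from the same centered dosages."""
        Z, y, _ = _sim_additive(rng)
        rr = RRBLUP(ridge=0.0).fit(Z, y)
        p = (Z.mean(0) + 1) / 2
        Zc = Z - 2 * (p - 0.5)
        G = Zc @ Zc.T / (2 * np.sum(p * (1 - p)))
        gb = GBLUP(ridge=0.0)
        gb.expected_kind = None
        gb.fit(G, y)
        r = np.corrcoef(rr.gebv_, gb.gebv_)[0, 1]
        assert r > 1 - 1e-6
        np.testing.assert_allclose(rr.gebv_, gb.gebv_, atol=1e-6)

    def test_permuted_response_destroys_signal(self, rng):
        Z, y, g = _sim_additive(rng)
        fit = RRBLUP().fit(Z, rng.permutation(y))
        assert abs(np.corrcoef(fit.gebv_, g)[0, 1]) < 0.2

    def test_constant_response_rejected(self, rng):
        Z, _, _ = _sim_additive(rng, n=30)
        with pytest.raises(ValueError, match="constant"):
            RRBLUP().fit(Z, np.ones(30))

    def test_marker_set_mismatch_on_predict(self, rng):
        Z, y, _ = _sim_additive(rng, n=50, m=100)
        fit = RRBLUP().fit(Z, y)
        with pytest.raises(ValueError, match="marker-set mismatch"):
            fit.predict(Z[:, :50])


class TestKernelMethods:
    def test_identity_kernel_closed_form_shrinkage(self, rng):
        """K = I: one observation per effect, so BLUPs obey the closed form
        g_hat = h2 * (y - mu) at whatever variance ratio REML settles on."""
        n = 300
        y = rng.normal(0, 1.0, n)
        gb = GBLUP()
        gb.expected_kind = None
        gb.fit(np.eye(n), y)
        h2 = gb.h2_genomic_
        assert 0.0 <= h2 <= 1.0
        np.testing.assert_allclose(
            gb.gebv_, h2 * (y - gb.mu_), rtol=1e-4, atol=1e-6
        )

    def test_duplicate_individuals_same_gebv(self, rng):
        Z, y, _ = _sim_additive(rng, n=60, m=200)
        Z[1] = Z[0]
        y[1] = y[0]
        p = (Z.mean(0) + 1) / 2
        Zc = Z - 2 * (p - 0.5)
        G = Zc @ Zc.T / (2 * np.sum(p * (1 - p)))
        gb = GBLUP()
        gb.expected_kind = None
        gb.fit(G, y)
        assert gb.gebv_[0] == pytest.approx(gb.gebv_[1], abs=1e-8)

    def test_h2_recovery_simulated(self, rng):
        Z, y, _ = _sim_additive(rng, n=400, m=1500, h2=0.5)
        p = (Z.mean(0) + 1) / 2
        Zc = Z - 2 * (p - 0.5)
        G = Zc @ Zc.T / (2 * np.sum(p * (1 - p)))
        gb = GBLUP()
        gb.expected_kind = None
        gb.fit(G, y)
        assert 0.35 <= gb.h2_genomic_ <= 0.65

    def test_kernel_kind_checked(self, small_panel_qc):
        K = markers.gaussian_K(small_panel_qc)
        with pytest.raises(ValueError, match="additive_G"):
            GBLUP().fit(K, np.zeros(K.values.shape[0]))

    def test_degenerate_all_ones_kernel(self):
        with pytest.raises(ValueError, match="degenerate"):
            rk = RKHS()
            rk.expected_kind = None
            rk.fit(np.ones((20, 20)), np.arange(20.0))

    def test_linearity_in_response(self, rng):
        Z, y, _ = _sim_additive(rng, n=80, m=150)
        p = (Z.mean(0) + 1) / 2
        Zc = Z - 2 * (p - 0.5)
        G = Zc @ Zc.T / (2 * np.sum(p * (1 - p)))
        a = GBLUP()
        a.expected_kind = None
        b = GBLUP()
        b.expected_kind = None
        a.fit(G, y)
        b.fit(G, 2.0 * y)
        np.testing.assert_allclose(2.0 * a.gebv_, b.gebv_, rtol=1e-4, atol=1e-6)


class TestPrediction:
    def test_training_self_consistency_and_twin(self, small_panel_qc, rng):
        gq = small_panel_qc
        G = markers.additive_G(gq)
        n = gq.n_samples
        y = rng.normal(size=n)
        train = gq.samples[: n - 20]
        K_tt = G.submatrix(train)
        fit = fit_gblup(y[: n - 20], K_tt, ids=train)
        # predicting the training set reproduces fitted GEBVs
        again = predict_gebv(fit, K_tt)
        np.testing.assert_allclose(again, fit.gebv_train, atol=1e-8)

    def test_rrblup_gblup_out_of_sample_agreement(self, rng):
        Z, y, _ = _sim_additive(rng, n=150, m=400)
        Z_train, Z_new = Z[:120], Z[120:]
        y_train = y[:120]
        rr = fit_rrblup(y_train, Z_train)
        # kernel path built from the same centered training dosages
        p = (Z_train.mean(0) + 1) / 2
        c = 2 * np.sum(p * (1 - p))
        Zc_t = Z_train - 2 * (p - 0.5)
        Zc_n = Z_new - 2 * (p - 0.5)
        G_tt = Zc_t @ Zc_t.T / c
        gb_est = GBLUP(ridge=0.0)
        gb_est.expected_kind = None
        gb_est.fit(G_tt, y_train)
        pred_rr = predict_gebv(rr, Z_new)
        pred_gb = gb_est.predict_gebv(Zc_n @ Zc_t.T / c)
        r = np.corrcoef(pred_rr, pred_gb)[0, 1]
        assert r > 1 - 1e-6

    def test_duplicated_prediction_clone(self, rng):
        Z, y, _ = _sim_additive(rng, n=60, m=120)
        fit = fit_rrblup(y, Z)
        Z_new = np.vstack([Z[5], Z[5]])
        pred = predict_gebv(fit, Z_new)
        assert pred[0] == pytest.approx(pred[1])


class TestBayesB:
    def test_sparse_recovery_and_determinism(self, rng):
        n, m, n_qtl = 250, 1000, 20
        Z = rng.binomial(2, rng.uniform(0.1, 0.9, m), (n, m)) - 1.0
        qtl = rng.choice(m, n_qtl, replace=False)
        g = Z[:, qtl] @ rng.normal(size=n_qtl)
        g = (g - g.mean()) / g.std() * np.sqrt(0.7)
        y = g + rng.normal(0, np.sqrt(0.3), n)
        fit = fit_bayesb(y, Z, n_iter=3000, burn_in=500, thin=5, seed=9)
        mask = np.zeros(m, bool)
        mask[qtl] = True
        ratio = np.abs(fit.beta)[mask].mean() / np.abs(fit.beta)[~mask].mean()
        assert ratio > 5.0
        fit2 = fit_bayesb(y, Z, n_iter=3000, burn_in=500, thin=5, seed=9)
        assert np.array_equal(fit.beta, fit2.beta)
        assert np.array_equal(fit.chains["pi"], fit2.chains["pi"])

    def test_pi_tracks_architecture_density(self, rng):
        n, m = 200, 400
        Z = rng.binomial(2, 0.5, (n, m)) - 1.0

        def run(frac, seed):
            nq = max(int(m * frac), 2)
            qtl = np.random.default_rng(seed).choice(m, nq, replace=False)
            g = Z[:, qtl] @ np.random.default_rng(seed + 1).normal(size=nq)
            g = (g - g.mean()) / g.std()
            y = g + np.random.default_rng(seed + 2).normal(0, 0.5, n)
            return fit_bayesb(
                y, Z, n_iter=2000, burn_in=400, thin=4, seed=seed
            ).pi

        dense = np.mean([run(0.5, s) for s in (1, 2, 3)])
        sparse = np.mean([run(0.01, s) for s in (1, 2, 3)])
        assert sparse < dense

    def test_chain_lengths(self, rng):
        Z, y, _ = _sim_additive(rng, n=60, m=100)
        fit = fit_bayesb(y, Z, n_iter=1000, burn_in=200, thin=10, seed=1)
        assert len(fit.chains["sigma2_e"]) == (1000 - 200) // 10

    def test_bad_run_lengths_rejected(self, rng):
        Z, y, _ = _sim_additive(rng, n=40, m=50)
        with pytest.raises(ValueError, match="burn_in"):
            fit_bayesb(y, Z, n_iter=100, burn_in=100)


class TestBayesianLasso:
    def test_shrinks_relative_to_ols(self, rng):
        # small full-rank toy: posterior-mean effects never exceed OLS
        n, m = 60, 8
        Z = rng.binomial(2, 0.5, (n, m)) - 1.0
        beta = rng.normal(size=m)
        y = Z @ beta + rng.normal(0, 0.5, n)
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(n), Z]), y, rcond=None
        )[0][1:]
        fit = fit_blasso(y, Z, n_iter=3000, burn_in=500, thin=5, seed=3)
        assert np.abs(fit.beta).max() <= np.abs(ols).max() + 1e-9

    def test_seed_determinism(self, rng):
        Z, y, _ = _sim_additive(rng, n=80, m=150)
        a = fit_blasso(y, Z, n_iter=1000, burn_in=200, thin=5, seed=4)
        b = fit_blasso(y, Z, n_iter=1000, burn_in=200, thin=5, seed=4)
        assert np.array_equal(a.beta, b.beta)
        assert a.lam == b.lam

    def test_dense_architecture_near_rrblup(self, rng):
        """All markers causal: BLASSO and RR-BLUP predict alike."""
        diffs = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            n, m = 150, 200
            Z = r.binomial(2, 0.5, (n, m)) - 1.0
            g = Z @ r.normal(size=m)
            g = (g - g.mean()) / g.std()
            y = g + r.normal(0, 1.0, n)
            bl = fit_blasso(
                y[:120], Z[:120], n_iter=6000, burn_in=1000, thin=5, seed=seed
            )
            rr = fit_rrblup(y[:120], Z[:120])
            pa_bl = np.corrcoef(predict_gebv(bl, Z[120:]), g[120:])[0, 1]
            pa_rr = np.corrcoef(predict_gebv(rr, Z[120:]), g[120:])[0, 1]
            diffs.append(pa_bl - pa_rr)
        assert abs(np.mean(diffs)) < 0.05


class TestCrossMethodProperties:
    def test_all_methods_agree_on_additive_signal(self, rng):
        """GEBV vectors of all five methods pairwise correlated > 0.95 on
        a common additive polygenic simulation."""
        Z, y, _ = _sim_additive(rng, n=200, m=500, h2=0.6, n_qtl=200)
        p = (Z.mean(0) + 1) / 2
        Zc = Z - 2 * (p - 0.5)
        c = 2 * np.sum(p * (1 - p))
        G = KinshipMatrix(
            [f"s{i}" for i in range(200)], Zc @ Zc.T / c + np.eye(200) * 1e-6,
            kind="additive_G",
        )
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(Z, "sqeuclidean"))
        K = KinshipMatrix(
            G.samples, np.exp(-D / np.median(D[np.triu_indices(200, 1)])),
            kind="gaussian_K",
        )
        gebvs = {
            "RRBLUP": fit_rrblup(y, Z).gebv_train,
            "GBLUP": fit_gblup(y, G).gebv_train,
            "RKHS": fit_rkhs(y, K).gebv_train,
            "BAYESB": fit_bayesb(
                y, Z, n_iter=5000, burn_in=1000, thin=5, seed=2
            ).gebv_train,
            "BLASSO": fit_blasso(
                y, Z, n_iter=5000, burn_in=1000, thin=5, seed=2
            ).gebv_train,
        }
        names = list(gebvs)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = np.corrcoef(gebvs[names[i]], gebvs[names[j]])[0, 1]
                assert r > 0.95, (names[i], names[j], r)

    def test_h2_in_unit_interval(self, rng):
        Z, y, _ = _sim_additive(rng, n=100, m=200)
        for fit in (
            fit_rrblup(y, Z),
            fit_bayesb(y, Z, n_iter=1000, burn_in=200, thin=5, seed=1),
        ):
            assert 0.0 <= fit.h2_genomic <= 1.0

    def test_gibbs_split_half_stability(self, rng):
        Z, y, _ = _sim_additive(rng, n=150, m=300, h2=0.6)
        fit = fit_bayesb(y, Z, n_iter=6000, burn_in=1000, thin=5, seed=8)
        c = fit.chains["sigma2_g"]
        half = len(c) // 2
        # posterior stabilises: the two half-chains agree on the mean
        assert abs(c[:half].mean() - c[half:].mean()) / c.mean() < 0.2


class TestRafteryLewis:
    def test_iid_closed_form(self, rng):
        chain = rng.normal(size=5000)
        res = raftery_lewis(chain, q=0.025, r=0.005, s=0.95)
        assert res.nmin == 3746
        assert res.dependence_factor == pytest.approx(1.0, abs=0.5)

    def test_autocorrelated_chain_inflates(self, rng):
        x = np.empty(20000)
        x[0] = 0.0
        eps = rng.normal(size=20000)
        for t in range(1, 20000):
            x[t] = 0.99 * x[t - 1] + 0.1 * eps[t]
        res = raftery_lewis(x)
        assert res.dependence_factor > 5.0

    def test_short_chain_error_carries_nmin(self):
        with pytest.raises(ValueError, match="3746"):
            raftery_lewis(np.arange(100.0))

    def test_constant_chain_flagged(self):
        res = raftery_lewis(np.ones(5000))
        assert res.degenerate
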