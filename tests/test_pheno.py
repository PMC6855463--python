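"""Stage-1 clonal mixed model: checked against an explicit dense solve of
Henderson's mixed-model equations, plus shrinkage/deregression algebra."""

import numpy as np
import pandas as pd
import pytest

from clonegs import pheno
from clonegs._reml import MixedModelREML, SingularFixedDesignError
from clonegs.containers import ClonalEstimates


def _toy_trials(noise=None):
    """4 clones x 2 reps, one location-year."""
    clones = ["c1", "c2", "c3", "c4"]
    vals = {"c1": 10.0, "c2": 12.0, "c3": 9.0, "c4": 11.0}
    rows = []
    rng = np.random.default_rng(0)
    for r in (1, 2):
        for c in clones:
            eps = rng.normal(0, noise) if noise else 0.0
            rows.append(
                {
                    "clone": c,
                    "location": "L",
                    "year": 2020,
                    "rep": f"L_2020_r{r}",
                    "block": r,
                    "design": "RCBD",
                    "y": vals[c] + 0.5 * (r == 2) + eps,
                }
            )
    return pd.DataFrame(rows)


def _mme_oracle(y, X, Zc, Zr, s2c, s2r, s2e):
    """Independent dense assembly and solve of Henderson's equations."""
    W = np.hstack([X, Zc, Zr])
    C = W.T @ W / s2e
    p = X.shape[1]
    qc, qr = Zc.shape[1], Zr.shape[1]
    C[p : p + qc, p : p + qc] += np.eye(qc) / s2c
    C[p + qc :, p + qc :] += np.eye(qr) / s2r
    sol = np.linalg.solve(C, W.T @ y / s2e)
    Cinv = np.linalg.inv(C)
    return sol[p : p + qc], np.diag(Cinv)[p : p + qc]


class TestClonalLMM:
    def test_blups_match_explicit_mme_solve(self):
        """Engine BLUPs/PEVs equal the independent dense MME solution."""
        trials = _toy_trials(noise=0.3)
        y = trials["y"].to_numpy()
        X = np.ones((len(y), 1))
        clones = sorted(trials["clone"].unique())
        reps = sorted(trials["rep"].unique())
        Zc = (trials["clone"].to_numpy()[:, None] == np.array(clones)).astype(float)
        Zr = (trials["rep"].to_numpy()[:, None] == np.array(reps)).astype(float)
        s2c, s2r, s2e = 1.3, 0.4, 0.25  # hand-set variance ratio

        blup_oracle, pev_oracle = _mme_oracle(y, X, Zc, Zr, s2c, s2r, s2e)
        engine = MixedModelREML(X, [Zc, Zr], y)
        _, u, pev = engine.solve(np.array([s2c, s2r, s2e]))
        np.testing.assert_allclose(u[0], blup_oracle, atol=1e-8)
        np.testing.assert_allclose(pev[0], pev_oracle, atol=1e-8)

    def test_vanishing_residual_blup_is_clone_mean_deviation(self):
        """sigma_e -> 0: shrinkage vanishes, BLUP -> clone mean - grand mean
        and PEV collapses to the sigma2_c/k floor left by the clone-mean /
        intercept confounding (negligible for many clones)."""
        rng = np.random.default_rng(1)
        k = 40
        vals = rng.normal(10, 1.5, k)
        rows = [
            {
                "clone": f"c{i}",
                "location": "L",
                "year": 2020,
                "rep": f"L_2020_r{r}",
                "block": r,
                "design": "RCBD",
                "y": vals[i] + 0.5 * (r == 2) + rng.normal(0, 1e-7),
            }
            for r in (1, 2)
            for i in range(k)
        ]
        est = pheno.fit_clonal_lmm(pd.DataFrame(rows), "y")
        t = est.table.set_index("clone")
        trials = pd.DataFrame(rows)
        means = trials.groupby("clone")["y"].mean()
        dev = means - means.mean()
        np.testing.assert_allclose(t["blup"], dev.loc[t.index], atol=1e-3)
        assert (t["pev"] <= est.sigma2_clone / k * 1.5).all()
        assert (t["reliability"] > 0.95).all()

    def test_variance_recovery_on_simulated_trials(self, small_panel, small_estimates):
        cfg, _, _, truth = small_panel
        est = small_estimates
        # total genetic variance is the clone component (additive-only trait)
        v_true = truth.true_total_genetic_values["trait_1"].var()
        assert est.sigma2_clone == pytest.approx(v_true, rel=0.35)
        assert est.h2_phen == pytest.approx(truth.realized_h2["trait_1"], abs=0.10)

    def test_blups_center_to_zero(self, small_estimates):
        blups = small_estimates.table["blup"]
        assert abs(blups.sum()) < 1e-4 * blups.abs().max() * len(blups)

    def test_shrinkage_monotone_in_noise_ratio(self):
        trials = _toy_trials(noise=0.3)
        y = trials["y"].to_numpy()
        X = np.ones((len(y), 1))
        clones = sorted(trials["clone"].unique())
        Zc = (trials["clone"].to_numpy()[:, None] == np.array(clones)).astype(float)
        Zr = (trials["rep"].to_numpy()[:, None] == np.array(sorted(trials["rep"].unique()))).astype(float)
        engine = MixedModelREML(X, [Zc, Zr], y)
        prev = np.inf
        for s2e in (0.1, 1.0, 10.0, 100.0):
            _, u, _ = engine.solve(np.array([1.0, 0.3, s2e]))
            mag = np.abs(u[0]).max()
            assert mag <= prev + 1e-12
            prev = mag

    def test_confounded_fixed_levels_named(self):
        # an intercept plus a dummy spanning every row is aliased
        n = 8
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(SingularFixedDesignError) as err:
            MixedModelREML(
                X, [np.eye(n)], np.arange(n, dtype=float),
                fixed_names=["intercept", "ly[L:2020]"],
            )
        assert "ly[L:2020]" in str(err.value) or "intercept" in str(err.value)

    def test_missing_trait_column(self):
        with pytest.raises(KeyError):
            pheno.fit_clonal_lmm(_toy_trials(), "nope")

    def test_single_clone_rejected(self):
        t = _toy_trials()
        with pytest.raises(ValueError, match="2 clones"):
            pheno.fit_clonal_lmm(t[t["clone"] == "c1"], "y")

    def test_reml_matches_anova_on_balanced_one_way(self, rng):
        """Balanced 1-random-effect design: REML equals the closed-form
        ANOVA estimator."""
        k, r = 30, 4
        s2c, s2e = 2.0, 1.0
        effects = rng.normal(0, np.sqrt(s2c), k)
        y = np.repeat(effects, r) + rng.normal(0, np.sqrt(s2e), k * r)
        X = np.ones((k * r, 1))
        Z = np.kron(np.eye(k), np.ones((r, 1)))
        engine = MixedModelREML(X, [Z], y)
        res = engine.fit()
        groups = y.reshape(k, r)
        msb = r * groups.mean(1).var(ddof=1)
        msw = groups.var(1, ddof=1).mean()
        anova_c = (msb - msw) / r
        assert res.sigma2[0] == pytest.approx(anova_c, rel=1e-3, abs=1e-3)
        assert res.sigma2[1] == pytest.approx(msw, rel=1e-3)


class TestDeregression:
    def _estimates(self, blup, pev, s2c):
        table = pd.DataFrame(
            {
                "clone": [f"c{i}" for i in range(len(blup))],
                "blup": blup,
                "pev": pev,
                "reliability": np.clip(1 - np.asarray(pev) / s2c, 0, 1),
                "deregressed": np.nan,
                "flagged": False,
            }
        )
        return ClonalEstimates(
            trait="t", table=table, sigma2_clone=s2c,
            sigma2_rep=0.0, sigma2_resid=1.0, grand_mean=0.0,
        )

    @pytest.mark.parametrize(
        "blup,pev,s2c,expected",
        [
            (2.0, 0.0, 1.0, 2.0),  # full reliability: identity
            (2.0, 0.5, 1.0, 4.0),  # reliability 0.5 doubles the BLUP
        ],
    )
    def test_deregression_arithmetic(self, blup, pev, s2c, expected):
        est = pheno.deregress(self._estimates([blup], [pev], s2c))
        assert est.table["deregressed"].iloc[0] == pytest.approx(expected)

    def test_zero_information_clone_flagged_not_dropped(self):
        est = pheno.deregress(self._estimates([2.0, 1.0], [1.0, 0.1], 1.0))
        t = est.table
        assert bool(t["flagged"].iloc[0]) and len(t) == 2
        assert np.isnan(t["deregressed"].iloc[0])

    def test_deregression_inflates(self, small_estimates):
        t = small_estimates.table
        ok = t["reliability"] > 0
        assert (
            t.loc[ok, "deregressed"].abs() >= t.loc[ok, "blup"].abs() - 1e-12
        ).all()

    def test_requires_positive_clone_variance(self):
        est = self._estimates([1.0], [0.1], 1.0)
        est.sigma2_clone = 0.0
        with pytest.raises(ValueError, match="positive"):
            pheno.deregress(est)


class TestHeritability:
    def test_plot_basis_ratio(self):
        est = ClonalEstimates(
            trait="t", table=pd.DataFrame(), sigma2_clone=1.0,
            sigma2_rep=0.0, sigma2_resid=1.0, grand_mean=0.0,
        )
        assert pheno.phenotypic_heritability(est) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [0.1, 1.0, 42.0])
    def test_scale_invariance(self, k):
        est = ClonalEstimates(
            trait="t", table=pd.DataFrame(), sigma2_clone=0.337 * k,
            sigma2_rep=0.2 * 0.663 * k, sigma2_resid=0.8 * 0.663 * k,
            grand_mean=0.0,
        )
        assert pheno.phenotypic_heritability(est) == pytest.approx(0.337)

    def test_entry_mean_basis_needs_reps(self):
        est = ClonalEstimates(
            trait="t", table=pd.DataFrame(), sigma2_clone=1.0,
            sigma2_rep=0.5, sigma2_resid=1.5, grand_mean=0.0,
        )
        assert pheno.phenotypic_heritability(
            est, basis="entry_mean", n_reps=4
        ) == pytest.approx(1.0 / 1.5)
        with pytest.raises(ValueError, match="n_reps"):
            pheno.phenotypic_heritability(est, basis="entry_mean")

    def test_all_zero_components_error(self):
        est = ClonalEstimates(
            trait="t", table=pd.DataFrame(), sigma2_clone=0.0,
            sigma2_rep=0.0, sigma2_resid=0.0, grand_mean=0.0,
        )
        with pytest.raises(ValueError):
            pheno.phenotypic_heritability(est)
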