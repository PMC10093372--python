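"""GBLUP and Bayesian-alphabet samplers: exact MME solves, shrinkage
limits, prior recovery, parameter recovery and model equivalences."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gsel
from gsel.models import (
    DesignSpec,
    ModelSpec,
    fit_bayes,
    fit_gblup,
    predict,
    solve_mme,
)


def intercept_design(y, ids=None):
    n = len(y)
    ph = pd.DataFrame(
        {
            "animal_id": ids or [f"a{i}" for i in range(n)],
            "y": np.asarray(y, dtype=float),
        }
    )
    return DesignSpec.from_phenotypes(ph, "y", factors=())


def random_psd(n, rng, jitter=0.3):
    B = rng.normal(size=(n, max(n, 5)))
    G = B @ B.T / B.shape[1]
    return G + jitter * np.eye(n)


@pytest.fixture(scope="module")
def herd_design(herd400):
    design = DesignSpec.from_phenotypes(herd400.phenotypes, "trait1")
    M = herd400.genotypes.dosage
    return design, M


class TestSolveMme:
    @pytest.mark.parametrize("n", [5, 12, 20])
    def test_matches_dense_inversion(self, n):
        rng = np.random.default_rng(n)
        G = random_psd(n, rng)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        sg2, se2 = 0.7, 1.3
        b, g = solve_mme(X, y, G, sg2, se2)
        # oracle: explicit inverse of the full coefficient matrix
        lam = se2 / sg2
        C = np.block(
            [[X.T @ X, X.T], [X, np.eye(n) + np.linalg.inv(G) * lam]]
        )
        rhs = np.concatenate([X.T @ y, y])
        sol = np.linalg.inv(C) @ rhs
        assert np.allclose(b, sol[:2], atol=1e-8)
        assert np.allclose(g, sol[2:], atol=1e-8)

    def test_infinite_shrinkage_limit_is_ols(self):
        rng = np.random.default_rng(1)
        n = 15
        G = random_psd(n, rng)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        b, g = solve_mme(X, y, G, sigma_g2=1e-10, sigma_e2=1.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(g, 0.0, atol=1e-6)
        assert np.allclose(b, ols, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        n = 10
        G = random_psd(n, rng)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        b, g = solve_mme(X, y, G, 0.5, 1.0)
        perm = rng.permutation(n)
        b2, g2 = solve_mme(X[perm], y[perm], G[np.ix_(perm, perm)], 0.5, 1.0)
        assert np.allclose(b, b2, atol=1e-10)
        assert np.allclose(g[perm], g2, atol=1e-10)


class TestGblup:
    def test_recovers_heritability_and_ranks_animals(self, herd400, herd_design):
        design, _ = herd_design
        G = gsel.build_G(herd400.genotypes)
        spec = ModelSpec(method="GBLUP", chain_length=3000, burn_in=1000,
                         thin=5, seed=1)
        fit = fit_gblup(design, G, spec)
        assert abs(fit.h2 - 0.30) < 0.08
        r = np.corrcoef(fit.gebv, herd400.true_breeding_values[:, 0])[0, 1]
        assert r > 0.5

    def test_reproducible_traces(self, herd400, herd_design):
        design, _ = herd_design
        G = gsel.build_G(herd400.genotypes)
        spec = ModelSpec(method="GBLUP", chain_length=400, burn_in=100,
                         thin=2, seed=7)
        f1 = fit_gblup(design, G, spec)
        f2 = fit_gblup(design, G, spec)
        assert np.array_equal(f1.traces["h2"], f2.traces["h2"])
        assert np.array_equal(f1.gebv, f2.gebv)

    def test_h2_identity_holds_per_draw(self, herd400, herd_design):
        design, _ = herd_design
        G = gsel.build_G(herd400.genotypes)
        spec = ModelSpec(method="GBLUP", chain_length=300, burn_in=100,
                         thin=2, seed=3)
        fit = fit_gblup(design, G, spec)
        sg, se = fit.traces["sigma_g2"], fit.traces["sigma_e2"]
        assert np.allclose(fit.traces["h2"], sg / (sg + se))

    def test_non_psd_matrix_rejected(self):
        design = intercept_design(np.arange(4.0))
        G = np.diag([1.0, 1.0, 1.0, -0.5])
        spec = ModelSpec(method="GBLUP", chain_length=20, burn_in=5)
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            fit_gblup(design, G, spec, blend_weight=0.0)


class TestBayes:
    def test_prior_recovered_when_data_carry_no_signal(self):
        # residual variance pinned so high the likelihood is flat: the
        # per-SNP variance chain must reproduce its scaled-inv-chi2 prior
        rng = np.random.default_rng(0)
        n, p = 50, 30
        design = intercept_design(rng.normal(size=n))
        M = rng.integers(0, 3, size=(n, p)).astype(float)
        nu, S = 5.0, 0.02
        spec = ModelSpec(
            method="BayesA", prior_df_marker=nu, prior_scale_marker=S,
            fix_sigma_e2=1e8, chain_length=6000, burn_in=1000, thin=5, seed=9,
        )
        fit = fit_bayes(design, M, spec)
        cdf = stats.invgamma(nu / 2, scale=nu * S / 2).cdf
        ks = stats.kstest(fit.traces["marker_var0"], cdf).statistic
        assert ks < 0.05

    def test_bayesc_null_phenotype(self):
        # pure-noise phenotypes: h2 collapses and inclusion stays at 1 - pi
        cfg = gsel.default_config(seed=5, n_snps=500, residual_sd=1.0)
        herd = gsel.simulate_herd(cfg)
        rng = np.random.default_rng(3)
        ph = herd.phenotypes.copy()
        ph["trait1"] = rng.normal(size=len(ph))
        design = DesignSpec.from_phenotypes(ph, "trait1")
        spec = ModelSpec(method="BayesC", chain_length=2000, burn_in=500,
                         thin=5, seed=3)
        fit = fit_bayes(design, herd.genotypes.dosage, spec)
        assert fit.h2 < 0.1
        assert fit.inclusion_prob.mean() == pytest.approx(0.05, abs=0.02)

    def test_bayesb_recovers_large_qtl(self, herd400, herd_design):
        design, M = herd_design
        rng = np.random.default_rng(3)
        j = 123
        w = M[:, j] - M[:, j].mean()
        y = 2.0 * w + rng.normal(0, np.sqrt(2.0 * w.var()), size=len(w))
        d2 = intercept_design(y)
        spec = ModelSpec(method="BayesB", chain_length=1500, burn_in=500,
                         thin=5, seed=4)
        fit = fit_bayes(d2, M, spec)
        assert fit.inclusion_prob[j] > 0.9
        assert fit.marker_effects[j] > 0  # sign recovered

    def test_bayesa_near_ridge_matches_gblup(self, herd400, herd_design):
        design, M = herd_design
        G = gsel.build_G(herd400.genotypes)
        fg = fit_gblup(
            design, G,
            ModelSpec(method="GBLUP", chain_length=2500, burn_in=800,
                      thin=5, seed=21),
        )
        p = M.mean(axis=0) / 2.0
        denom = 2.0 * np.sum(p * (1.0 - p))
        fa = fit_bayes(
            design, M,
            ModelSpec(
                method="BayesA", prior_df_marker=1e7,
                prior_scale_marker=fg.sigma_g2 / denom,
                fix_sigma_e2=fg.sigma_e2,
                chain_length=2500, burn_in=800, thin=5, seed=22,
            ),
        )
        assert np.corrcoef(fg.gebv, fa.gebv)[0, 1] > 0.99

    def test_bayesc_h2_below_gblup_h2(self, herd400, herd_design):
        design, M = herd_design
        G = gsel.build_G(herd400.genotypes)
        fg = fit_gblup(
            design, G,
            ModelSpec(method="GBLUP", chain_length=1500, burn_in=500,
                      thin=5, seed=11),
        )
        fc = fit_bayes(
            design, M,
            ModelSpec(method="BayesC", chain_length=1500, burn_in=500,
                      thin=5, seed=11),
        )
        assert fc.h2 < fg.h2

    def test_reproducible_and_bl_runs(self, herd_design):
        design, M = herd_design
        spec = ModelSpec(method="BL", chain_length=400, burn_in=100, thin=2,
                         seed=5)
        f1 = fit_bayes(design, M, spec)
        f2 = fit_bayes(design, M, spec)
        assert np.array_equal(f1.traces["lambda2"], f2.traces["lambda2"])
        assert np.array_equal(f1.marker_effects, f2.marker_effects)
        assert 0.0 < f1.h2 < 1.0

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="degenerate"):
            ModelSpec(method="BayesB", pi=1.0)
        with pytest.raises(ValueError, match="burn_in"):
            ModelSpec(chain_length=100, burn_in=100)
        with pytest.raises(ValueError, match="unknown method"):
            ModelSpec(method="BayesZ")

    def test_missing_markers_rejected(self):
        design = intercept_design(np.arange(3.0))
        M = np.array([[0.0, np.nan], [1, 2], [2, 0]])
        with pytest.raises(ValueError, match="missing"):
            fit_bayes(design, M, ModelSpec(method="BayesA", chain_length=20,
                                           burn_in=5))


class TestPredict:
    def _marker_fit(self, herd_design):
        design, M = herd_design
        spec = ModelSpec(method="BayesC", chain_length=600, burn_in=200,
                         thin=2, seed=2)
        return fit_bayes(design, M, spec), design, M

    def test_identical_genotype_identical_gebv(self, herd_design):
        fit, design, M = self._marker_fit(herd_design)
        rows = np.vstack([M[0], M[0]])
        X = np.repeat(design.X[[0]], 2, axis=0)
        _, gebv = predict(fit, X, markers_new=rows)
        assert gebv[0] == gebv[1]

    def test_zero_effects_predict_fixed_part_only(self, herd_design):
        fit, design, M = self._marker_fit(herd_design)
        fit.marker_effects = np.zeros_like(fit.marker_effects)
        yhat, gebv = predict(fit, design.X[:5], markers_new=M[:5])
        assert np.allclose(gebv, 0.0)
        assert np.allclose(yhat, design.X[:5] @ fit.b_mean)

    def test_marker_and_gblup_predictions_agree(self, herd400, herd_design):
        design, M = herd_design
        n = design.n
        tr = np.arange(0, n - 60)
        va = np.arange(n - 60, n)
        d_tr = design.subset(tr)
        G = gsel.build_G(M).values
        fg = fit_gblup(
            d_tr, G[np.ix_(tr, tr)],
            ModelSpec(method="GBLUP", chain_length=2000, burn_in=600, thin=5,
                      seed=31),
        )
        p = M[tr].mean(axis=0) / 2.0
        denom = 2.0 * np.sum(p * (1.0 - p))
        fa = fit_bayes(
            d_tr, M[tr],
            ModelSpec(
                method="BayesA", prior_df_marker=1e7,
                prior_scale_marker=fg.sigma_g2 / denom,
                fix_sigma_e2=fg.sigma_e2,
                chain_length=2000, burn_in=600, thin=5, seed=32,
            ),
        )
        _, gebv_g = predict(fg, design.X[va], g_cross=G[np.ix_(va, tr)])
        _, gebv_m = predict(fa, design.X[va], markers_new=M[va])
        assert np.corrcoef(gebv_g, gebv_m)[0, 1] > 0.99

    def test_dimension_errors(self, herd_design):
        fit, design, M = self._marker_fit(herd_design)
        with pytest.raises(ValueError, match="marker rows"):
            predict(fit, design.X[:2], markers_new=M[:2, :10])
        with pytest.raises(ValueError, match="g_cross"):
            gfit, _, _ = self._marker_fit(herd_design)
            gfit.method = "GBLUP"
            predict(gfit, design.X[:2])


class TestDesignSpec:
    def test_reference_coding_and_unseen_levels(self, caplog):
        ph = pd.DataFrame(
            {
                "animal_id": ["a", "b", "c", "d"],
                "cg": ["c1", "c2", "c1", "c2"],
                "dam_age": ["1", "2", "3", "1"],
                "y": [1.0, 2.0, 3.0, 4.0],
            }
        )
        d = DesignSpec.from_phenotypes(ph, "y")
        assert d.coef_names[0] == "intercept"
        assert d.X.shape == (4, 4)  # 1 + 1 cg dummy + 2 dam_age dummies
        assert np.linalg.matrix_rank(d.X) == 4
        new = pd.DataFrame(
            {"animal_id": ["e"], "cg": ["c9"], "dam_age": ["2"], "y": [0.0]}
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="gsel.models"):
            X_new = d.encode(new)
        assert "unseen" in caplog.text
        assert np.array_equal(X_new[0], [1.0, 0.0, 1.0, 0.0])

    def test_subset_keeps_levels(self):
        ph = pd.DataFrame(
            {
                "animal_id": list("abcd"),
                "cg": ["c1", "c2", "c1", "c2"],
                "dam_age": ["1", "1", "2", "2"],
                "y": [1.0, 2.0, 3.0, 4.0],
            }
        )
        d = DesignSpec.from_phenotypes(ph, "y")
        sub = d.subset(np.array([0, 1]))
        assert sub.coef_names == d.coef_names
        assert np.array_equal(sub.X, d.X[:2])
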