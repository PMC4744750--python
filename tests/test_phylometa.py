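import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenodecomp.mcmc import effective_sample_size
from phenodecomp.phylometa import (fit_phylo_meta, phylo_correlation_matrix,
                                   pool_over_trees)
from phenodecomp.simulate import random_ultrametric_tree, simulate_phylo_estimates

from oracles import exact_meta_posterior


class TestCorrelationMatrix:
    def test_star_tree_identity(self):
        corr = phylo_correlation_matrix("(a:1,b:1,c:1,d:1);")
        assert np.allclose(corr.matrix, np.eye(4))

    def test_two_tip_shared_path(self):
        corr = phylo_correlation_matrix("((A:0.4,B:0.4):0.6,C:1.0);")
        i, j = corr.labels.index("A"), corr.labels.index("B")
        assert corr.matrix[i, j] == pytest.approx(0.6)
        assert corr.matrix[i, corr.labels.index("C")] == pytest.approx(0.0)
        assert np.allclose(np.diag(corr.matrix), 1.0)

    def test_positive_semidefinite(self, corr31):
        assert np.linalg.eigvalsh(corr31.matrix).min() >= -1e-10

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            phylo_correlation_matrix("((A:0.4,B),C:1.0);")

    def test_non_ultrametric_warns(self):
        with pytest.warns(UserWarning, match="ultrametric"):
            phylo_correlation_matrix("((A:0.4,B:0.9):0.6,C:1.0);")


class TestMetaFit:
    def test_reduces_to_plain_meta_analysis(self):
        """With A = I and no measurement error the posterior mean of mu sits
        at the arithmetic mean of the estimates (exchangeable design)."""
        star = "(" + ",".join(f"t{i}:1.0" for i in range(20)) + ");"
        corr = phylo_correlation_matrix(star)
        rng = np.random.default_rng(0)
        est = pd.DataFrame({"species": [f"t{i}" for i in range(20)],
                            "y": rng.normal(-5.0, 1.5, 20), "m_var": 0.0})
        res = fit_phylo_meta(est, corr, n_iter=6000, burn_in=1000, thin=5, seed=1)
        mu = res.draws["mu"]
        mcse = mu.std(ddof=1) / np.sqrt(effective_sample_size(mu))
        assert abs(mu.mean() - est["y"].mean()) < 4 * mcse

    def test_matches_exact_quadrature_posterior(self, tree31, corr31):
        """Gibbs posterior means of sigma_a2, sigma_e2 and H2 agree with the
        independent quadrature oracle."""
        est, _ = simulate_phylo_estimates(tree31, mu=-6, sigma_a2=3.0, sigma_e2=1.0,
                                          m_variances=0.05, seed=0)
        res = fit_phylo_meta(est, corr31, n_iter=20000, burn_in=2000, thin=6, seed=0)
        exact = exact_meta_posterior(est["y"].to_numpy(), corr31.matrix, 0.05)
        h2 = res.draws["h2"]
        mcse = h2.std(ddof=1) / np.sqrt(effective_sample_size(h2))
        assert abs(h2.mean() - exact["h2_mean"]) < 3 * mcse + 0.01
        for key, name in [("sigma_a2", "sigma_a2_mean"), ("sigma_e2", "sigma_e2_mean")]:
            d = res.draws[key]
            m = d.std(ddof=1) / np.sqrt(effective_sample_size(d))
            assert abs(d.mean() - exact[name]) < 3 * m + 0.05

    def test_h2_bounded_and_shrinks_without_signal(self, tree31, corr31):
        est, _ = simulate_phylo_estimates(tree31, sigma_a2=0.0, sigma_e2=1.0, seed=4)
        res = fit_phylo_meta(est, corr31, seed=4)
        h2 = res.draws["h2"]
        assert np.all((h2 >= 0) & (h2 <= 1))
        assert res.summary["h2"].mode < 0.15

    def test_trait_coefficient_recovery(self, tree31, corr31):
        """One continuous trait with beta = 1.5 and no phylogenetic signal:
        the beta HPD covers the truth, as does the mu HPD."""
        est, _ = simulate_phylo_estimates(tree31, mu=-4.0, beta=1.5, trait_sd=1.0,
                                          sigma_a2=0.0, sigma_e2=0.5, seed=5)
        traits = est[["species", "trait"]]
        res = fit_phylo_meta(est[["species", "y", "m_var"]], corr31, traits=traits, seed=5)
        b = res.summary["beta_trait"]
        assert b.hpd_low <= 1.5 <= b.hpd_high
        m = res.summary["mu"]
        assert m.hpd_low <= -4.0 <= m.hpd_high

    def test_categorical_trait_treatment_coding(self, tree31, corr31):
        est, _ = simulate_phylo_estimates(tree31, seed=6)
        traits = pd.DataFrame({"species": est["species"],
                               "voltinism": ["single", "double"] * 15 + ["single"]})
        res = fit_phylo_meta(est, corr31, traits=traits, n_iter=2000, burn_in=500,
                             thin=2, seed=6)
        assert res.fixed_names == ["voltinism[single]"]  # 'double' is baseline

    def test_huge_measurement_error_removes_influence(self, tree31, corr31):
        est, _ = simulate_phylo_estimates(tree31, mu=0.0, sigma_a2=0.5, sigma_e2=0.5,
                                          seed=7)
        est_out = est.copy()
        est_out.loc[0, "y"] = 500.0
        est_out.loc[0, "m_var"] = 1e6
        res = fit_phylo_meta(est_out, corr31, seed=7)
        # the wild estimate is fully discounted by its measurement variance
        assert abs(res.draws["mu"].mean()) < 1.0

    def test_scale_equivariance(self, tree31, corr31):
        est, _ = simulate_phylo_estimates(tree31, mu=-6, sigma_a2=3.0, sigma_e2=1.0,
                                          m_variances=0.0, seed=8)
        res1 = fit_phylo_meta(est, corr31, seed=8)
        est2 = est.assign(y=est["y"] * 2.0)  # m_var = 0 scales trivially
        res2 = fit_phylo_meta(est2, corr31, seed=8)
        assert res2.draws["mu"].mean() == pytest.approx(2 * res1.draws["mu"].mean(), abs=0.4)
        assert res2.draws["h2"].mean() == pytest.approx(res1.draws["h2"].mean(), abs=0.06)

    def test_empty_estimates_rejected(self, corr31):
        with pytest.raises(ValueError):
            fit_phylo_meta(pd.DataFrame(columns=["species", "y", "m_var"]), corr31)


class TestTreePooling:
    def _estimates(self, tree, seed=9):
        est, _ = simulate_phylo_estimates(tree, mu=-6, sigma_a2=2.0, sigma_e2=1.0,
                                          m_variances=0.1, seed=seed)
        return est

    def test_single_tree_identical_to_direct_fit(self, tree31, corr31):
        est = self._estimates(tree31)
        pooled = pool_over_trees([tree31], est, total_iter=3000, burn_in=500, thin=3, seed=2)
        direct = fit_phylo_meta(est, corr31, n_iter=3000, burn_in=500, thin=3, seed=2)
        assert np.array_equal(pooled.draws["h2"], direct.draws["h2"])

    def test_two_identical_trees_indistinguishable(self, tree31):
        est = self._estimates(tree31)
        one = pool_over_trees([tree31], est, total_iter=8000, burn_in=1000, thin=4, seed=3)
        two = pool_over_trees([tree31, tree31], est, total_iter=16000, burn_in=1000,
                              thin=4, seed=3)
        assert stats.ks_2samp(one.draws["mu"], two.draws["mu"]).pvalue > 0.01

    def test_discordant_trees_widen_pooled_interval(self):
        """Pooling a structured tree with a star tree spreads H2 mass wider
        than either component posterior."""
        deep = "((a:0.1,b:0.1):0.9,(c:0.1,d:0.1):0.9,(e:0.1,f:0.1):0.9);"
        star = "(a:1,b:1,c:1,d:1,e:1,f:1);"
        rng = np.random.default_rng(11)
        clade = rng.normal(0, 2.0, 3)
        est = pd.DataFrame({"species": list("abcdef"),
                            "y": np.repeat(clade, 2) + rng.normal(0, 0.2, 6),
                            "m_var": 0.0})
        kw = dict(burn_in=1000, thin=4)
        r_deep = pool_over_trees([deep], est, total_iter=8000, seed=4, **kw)
        r_star = pool_over_trees([star], est, total_iter=8000, seed=4, **kw)
        r_mix = pool_over_trees([deep, star], est, total_iter=16000, seed=4, **kw)
        width = lambda r: r.summary["h2"].hpd_high - r.summary["h2"].hpd_low
        assert width(r_mix) >= max(width(r_deep), width(r_star)) - 0.05

    def test_mismatched_tree_skipped(self, tree31):
        est = self._estimates(tree31)
        other = "(x:1,y:1);"
        with pytest.warns(UserWarning, match="skipped"):
            pooled = pool_over_trees([tree31, other], est, total_iter=4000,
                                     burn_in=500, thin=4, seed=5)
        assert pooled.n_draws > 0
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                pool_over_trees([other], est, total_iter=2000, burn_in=500, seed=5)
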