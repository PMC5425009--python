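"""Association models: logistic odds ratios against closed-form 2x2 values
and statsmodels, separation handling, GRM arithmetic, REML recovery, MLM
collapse to least squares, significance threshold and gene annotation."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest

from polymap import assoc
from polymap.gio import GeneInterval, VariantSite

from conftest import make_matrix


def _two_by_two(case_car, case_non, control_car, control_non):
    g = ([1] * case_car + [0] * case_non + [1] * control_car
         + [0] * control_non)
    y = np.array([1.0] * (case_car + case_non)
                 + [0.0] * (control_car + control_non))
    return make_matrix(np.array(g)[:, None]), y


class TestLogistic:
    def test_or_equals_contingency_odds_ratio(self):
        m, y = _two_by_two(30, 10, 10, 30)
        (r,) = assoc.logistic_assoc(m, y)
        assert not r.firth_used
        assert r.or_ == pytest.approx(9.0, rel=1e-6)

    def test_matches_statsmodels_with_covariates(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        g = rng.binomial(2, 0.4, size=(n, 4)).astype(np.int8)
        c = rng.standard_normal((n, 2))
        logits = -0.3 + 0.4 * g[:, 0] + 0.5 * c[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        res = assoc.logistic_assoc(make_matrix(g), y, c)
        for j, r in enumerate(res):
            x = np.column_stack([np.ones(n), g[:, j], c])
            fit = sm.Logit(y, x).fit(disp=0)
            assert r.beta == pytest.approx(fit.params[1], rel=1e-5, abs=1e-7)
            assert r.se == pytest.approx(fit.bse[1], rel=1e-4)

    def test_perfect_separation_triggers_firth(self):
        m, y = _two_by_two(40, 0, 0, 40)
        (r,) = assoc.logistic_assoc(m, y)
        assert r.firth_used and r.converged
        assert np.isfinite(r.beta) and np.isfinite(r.p_logistic)
        # Firth estimate for a 2x2 adds 1/2 to each cell
        assert r.or_ == pytest.approx((40.5 / 0.5) ** 2, rel=1e-4)

    def test_perfect_association_outranks_near_perfect(self):
        """Penalized LRT keeps the fully separating site ahead of a site
        with one discordant sample (Wald statistics would invert this)."""
        g_perfect = np.array([1] * 40 + [0] * 40)
        g_near = g_perfect.copy()
        g_near[50] = 1
        y = np.array([1.0] * 40 + [0.0] * 40)
        res = assoc.logistic_assoc(make_matrix(np.stack([g_perfect,
                                                         g_near]).T), y)
        assert res[0].p_logistic < res[1].p_logistic

    def test_null_pvalues_uniform(self, rng):
        n, s = 200, 600
        g = rng.binomial(2, rng.uniform(0.1, 0.9, s), size=(n, s))
        y = np.zeros(n)
        y[:100] = 1.0
        res = assoc.logistic_assoc(make_matrix(g), y)
        p = np.array([r.p_logistic for r in res])
        assert kstest(p, "uniform").pvalue > 0.01

    def test_constant_phenotype_rejected(self):
        m = make_matrix([[0], [1], [2]])
        with pytest.raises(ValueError, match="constant"):
            assoc.logistic_assoc(m, np.ones(3))

    def test_missing_genotypes_dropped_per_site(self, rng):
        n = 120
        g = rng.binomial(2, 0.5, size=n)
        y = (rng.random(n) < 0.5).astype(float)
        holed = g.astype(np.int8).copy()
        holed[:10] = -1
        sub = make_matrix(g[10:][:, None])
        r_holed = assoc.logistic_assoc(make_matrix(holed[:, None]), y)[0]
        r_sub = assoc.logistic_assoc(sub, y[10:])[0]
        assert r_holed.beta == pytest.approx(r_sub.beta, rel=1e-6)


class TestGrm:
    def test_hand_example(self):
        # codes [[0,2],[2,0]], p = (0.5, 0.5): standardized +-sqrt(2)
        m = make_matrix([[0, 2], [2, 0]])
        np.testing.assert_allclose(assoc.compute_grm(m),
                                   [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_hardy_weinberg_population_moments(self, rng):
        n, m_sites = 20, 10_000
        freqs = rng.uniform(0.1, 0.9, m_sites)
        g = rng.binomial(2, freqs, size=(n, m_sites))
        grm = assoc.compute_grm(make_matrix(g))
        assert abs(np.mean(np.diag(grm)) - 1.0) < 0.05
        # with allele frequencies estimated from the sample itself the
        # off-diagonals of unrelated pairs center at -1/(n-1), not 0
        off = grm[~np.eye(n, dtype=bool)] + 1.0 / (n - 1)
        assert np.max(np.abs(off)) < 6.0 / np.sqrt(m_sites)

    def test_monomorphic_only_matrix_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            assoc.compute_grm(make_matrix([[0, 2], [0, 2]]))


class TestReml:
    def test_pure_noise_recovers_zero_heritability(self, rng):
        n = 300
        g = rng.binomial(2, rng.uniform(0.2, 0.8, 800), size=(n, 800))
        grm = assoc.compute_grm(make_matrix(g))
        y = rng.standard_normal(n)
        model = assoc.reml_fit(y, grm)
        ratio = model.sigma_g2 / (model.sigma_g2 + model.sigma_e2)
        assert ratio < 0.15

    def test_matches_grid_search_oracle(self, rng):
        n = 5
        a = rng.standard_normal((n, 8))
        grm = a @ a.T / 8
        y = rng.standard_normal(n)
        x = np.ones((n, 1))

        def restricted_ll(sg, se):
            v = sg * grm + se * np.eye(n)
            sign, logdet_v = np.linalg.slogdet(v)
            if sign <= 0:
                return -np.inf
            vi = np.linalg.inv(v)
            xvx = x.T @ vi @ x
            beta = np.linalg.solve(xvx, x.T @ vi @ y)
            r = y - x @ beta
            return -0.5 * (logdet_v + np.linalg.slogdet(xvx)[1]
                           + float(r @ vi @ r))

        grid = np.linspace(0.01, 3.0, 200)
        vals = np.array([[restricted_ll(sg, se) for se in grid]
                         for sg in grid])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        model = assoc.reml_fit(y, grm)
        step = grid[1] - grid[0]
        assert restricted_ll(model.sigma_g2, model.sigma_e2) >= \
            vals[i, j] - 1e-6
        assert abs(model.sigma_g2 - grid[i]) <= 2 * step
        assert abs(model.sigma_e2 - grid[j]) <= 2 * step

    def test_non_psd_grm_shifted_with_warning(self, rng):
        n = 6
        grm = -0.5 * np.eye(n) + 0.1
        with pytest.warns(UserWarning, match="positive semidefinite"):
            assoc.reml_fit(rng.standard_normal(n), grm)


class TestMlm:
    def test_identity_grm_collapses_to_least_squares(self, rng):
        n, s = 200, 30
        g = rng.binomial(2, 0.4, size=(n, s))
        y = rng.standard_normal(n)
        m = make_matrix(g)
        model = assoc.reml_fit(y, np.eye(n))
        out = assoc.mlm_assoc(m, y, None, model)
        sigma2 = model.sigma_g2 + model.sigma_e2
        # known-variance GLS with V = sigma^2 I, computed directly
        gc = g - g.mean(axis=0)
        yc = y - y.mean()
        beta = gc.T @ yc / np.einsum("ns,ns->s", gc, gc)
        se = np.sqrt(sigma2 / np.einsum("ns,ns->s", gc, gc))
        p = chi2.sf((beta / se) ** 2, df=1)
        np.testing.assert_allclose(out["beta_mlm"], beta, rtol=1e-8)
        np.testing.assert_allclose(out["p_mlm"], p, atol=1e-6)

    def test_null_pvalues_uniform_under_fitted_model(self, rng):
        n = 300
        freqs = rng.uniform(0.1, 0.9, 800)
        g = rng.binomial(2, freqs, size=(n, 800))
        m = make_matrix(g)
        grm = assoc.compute_grm(m)
        l = np.linalg.cholesky(0.3 * (grm + 1e-8 * np.eye(n))
                               + 0.7 * np.eye(n))
        ps = []
        for _ in range(3):
            y = l @ rng.standard_normal(n)
            model = assoc.reml_fit(y, grm)
            ps.append(assoc.mlm_assoc(m, y, None, model)["p_mlm"].to_numpy())
        ps = np.concatenate(ps)
        assert kstest(ps[np.isfinite(ps)], "uniform").pvalue > 0.01

    def test_singular_v_rejected(self):
        m = make_matrix([[0, 1], [1, 0], [2, 1]])
        model = assoc.GrmModel(grm=np.zeros((3, 3)), sigma_g2=0.0,
                               sigma_e2=0.0, loglik=0.0)
        with pytest.raises(ValueError, match="singular"):
            assoc.mlm_assoc(m, np.array([0.0, 1.0, 0.0]), None, model)


class TestSignificanceAndAnnotation:
    def test_bonferroni_arithmetic(self):
        assert assoc.bonferroni_threshold(500_000) == pytest.approx(1e-7)
        assert assoc.bonferroni_threshold(476_239) == \
            pytest.approx(0.05 / 476_239)
        assert assoc.bonferroni_threshold(476_239) == \
            pytest.approx(1.0499e-7, rel=1e-4)
        assert assoc.bonferroni_threshold(1) == 0.05
        with pytest.raises(ValueError):
            assoc.bonferroni_threshold(0)

    def test_significance_is_strict_inequality(self):
        thr = 0.05
        mask = assoc.significant(np.array([0.05, 0.049, np.nan]), thr)
        np.testing.assert_array_equal(mask, [False, True, False])

    def test_nearest_gene_distances(self):
        genes = [GeneInterval("g1", "1", 100, 200),
                 GeneInterval("g2", "1", 299, 400)]
        inside = VariantSite("1", 150, "A", "G")
        assert assoc.nearest_gene(inside, genes) == ("g1", 0)
        # site at 250 sits 50 bp beyond g1 and 50 bp before g2: exact tie,
        # the first-listed gene is kept
        right = VariantSite("1", 250, "A", "G")
        assert assoc.nearest_gene(right, genes) == ("g1", 50)
        with pytest.warns(UserWarning, match="no gene"):
            assert assoc.nearest_gene(VariantSite("9", 5, "A", "G"),
                                      genes) == (None, None)

    def test_association_table_sorted(self):
        sites = [VariantSite("2", 500, "A", "G"), VariantSite("1", 900, "A", "G"),
                 VariantSite("1", 100, "A", "G")]
        results = [assoc.AssociationResult(site=s, beta=0.0, or_=1.0, se=1.0,
                                           p_logistic=0.5) for s in sites]
        df = assoc.association_table(results)
        assert list(zip(df["chrom"], df["pos"])) == \
            [("1", 100), ("1", 900), ("2", 500)]
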