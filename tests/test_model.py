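import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

import spheromap as sp
from spheromap.io import SpheromapError
from spheromap.model import (
    GeneRegulationModel,
    RegulationFunction,
    gene_log_posterior,
    init_params,
    nb_logpmf,
)
from spheromap.model import test_spatial as wald_spatial_test


class TestRegulationFunction:
    @pytest.mark.parametrize(
        "abc,r,expected",
        [((1e-3, 0.0, 0.0), 0.7, 1e-3),
         ((1e-3, 1e-3, 0.0), 1.0, 2e-3),
         ((2.0, -2.0, 1.0), 0.5, 1.25)],
    )
    def test_polynomial_evaluation(self, abc, r, expected):
        assert RegulationFunction(*abc).evaluate(r) == pytest.approx(expected)

    def test_nonpositive_value_is_domain_error(self):
        with pytest.raises(SpheromapError, match="non-positive"):
            RegulationFunction(1e-3, -2e-3, 0.0).evaluate(1.0)

    @pytest.mark.parametrize(
        "abc,expected",
        [((1.0, 0.0, 0.0), 0.0),           # constant
         ((1.0, 1.0, 0.0), 0.5),           # min 1, max 2
         ((2.0, -2.0, 1.0), 0.5)],         # vertex r*=1 on boundary: min f(1)=1
    )
    def test_magnitude_uses_analytic_extrema(self, abc, expected):
        assert RegulationFunction(*abc).magnitude == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(1e-5, 1e-2), b=st.floats(-1e-3, 1e-2),
        c=st.floats(-1e-3, 1e-2),
    )
    def test_magnitude_in_unit_interval_and_extrema_bracket_grid(self, a, b, c):
        fn = RegulationFunction(a, b, c)
        lo, hi = fn.extrema()
        grid = fn(np.linspace(0, 1, 201))
        assert lo <= grid.min() + 1e-12 and hi >= grid.max() - 1e-12
        if lo > 0:
            assert 0.0 <= fn.magnitude < 1.0


class TestNBLogPMF:
    def test_closed_form_at_zero(self):
        # P(0) = (theta/(theta+mu))^theta
        assert nb_logpmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)
        assert nb_logpmf(0, 3.0, 2.0) == pytest.approx(2 * np.log(2 / 5), abs=1e-12)

    def test_degenerate_zero_mean(self):
        assert nb_logpmf(0, 0.0, 1.0) == 0.0
        assert nb_logpmf(5, 0.0, 1.0) == -np.inf

    def test_poisson_limit_at_large_theta(self):
        assert nb_logpmf(3, 2.0, 1e8) == pytest.approx(
            poisson.logpmf(3, 2.0), abs=1e-4
        )

    def test_normalization_sums_to_one(self):
        n = np.arange(0, 400)
        total = np.exp(nb_logpmf(n, 5.0, 0.7)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(SpheromapError):
            nb_logpmf(-1, 1.0, 1.0)


class TestGeneLogPosterior:
    def test_single_cell_flat_priors_matches_nb_logpmf(self):
        val = gene_log_posterior(
            [0], (np.array([0.5]), np.array([1000.0])),
            a=1e-3, b=0.0, c=0.0, theta=1.0, priors=None,
        )
        assert val == pytest.approx(np.log(0.5), abs=1e-12)  # mu = 1, n = 0

    def test_poisson_limit_with_flat_priors(self, rng):
        r = rng.uniform(size=200)
        N = np.full(200, 1e4)
        a = 1e-3
        counts = rng.poisson(a * N)
        val = gene_log_posterior(counts, (r, N), a, 0.0, 0.0, 1e8, priors=None)
        expected = poisson.logpmf(counts, a * N).sum()
        assert val == pytest.approx(expected, abs=1e-4)

    def test_finite_under_extreme_depths_and_barrier(self, positioned_cells):
        r, N = positioned_cells
        big_N = N * 50  # depths up to ~1e6
        model = GeneRegulationModel(np.ones_like(r, dtype=int), (r, big_N))
        # f dips to the barrier floor: steeply penalized but finite
        val = gene_log_posterior(
            np.ones_like(r, dtype=int), (r, big_N),
            a=1e-12, b=0.0, c=0.0, theta=1.0, priors=model.priors,
        )
        assert np.isfinite(val)


class TestInitParams:
    def test_exact_proportional_counts_recover_abundance(self):
        r = np.linspace(0, 1, 20)
        N = np.full(20, 10_000.0)
        counts = (N * 1e-3).astype(int)
        a0, b0, c0, theta0 = init_params(counts, (r, N))
        assert a0 == pytest.approx(1e-3, rel=0.05)
        assert c0 == 0.0

    def test_underdispersed_counts_push_theta_to_upper_clip(self, rng):
        # zero-variance counts: moment denominator is negative, clamped to
        # epsilon, so theta-hat lands on the upper clip (Poisson-like)
        r = rng.uniform(size=2000)
        N = np.full(2000, 10_000.0)
        counts = np.full(2000, 10)
        model = GeneRegulationModel(counts, (r, N))
        assert model.init_params()[3] == pytest.approx(1e4)
        # random Poisson draws: theta-hat far above any overdispersed value
        counts = rng.poisson(1e-3 * N)
        theta0 = GeneRegulationModel(counts, (r, N)).init_params()[3]
        assert theta0 >= 50.0

    def test_moment_theta_recovers_truth_across_seeds(self):
        # NB gene a=1e-4, theta=2, 2000 cells: theta-hat in [1, 4] mostly
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            r = rng.uniform(size=2000) ** (1 / 3)
            N = np.full(2000, 2e4)
            mu = 1e-4 * N
            counts = rng.poisson(rng.gamma(2.0, mu / 2.0))
            theta0 = init_params(counts, (r, N))[3]
            hits += 1.0 <= theta0 <= 4.0
        assert hits >= 0.9 * n_rep


class TestFitGene:
    def test_constant_gene_recovers_pooled_abundance(self, rng):
        r = sp.sample_radial_positions(1000, seed=21)
        N = sp.sample_depths(1000, 20_000, 0.4, seed=22)
        a = 2e-4
        counts = rng.poisson(rng.gamma(5.0, a * N / 5.0))
        res = sp.fit_gene(counts, (r, N.astype(float)))
        assert res.converged and res.has_se
        pooled = counts.sum() / N.sum()
        assert abs(res.params.a - pooled) <= 3 * res.se_a

    def test_spatial_gene_recovered_within_30pct(self, rng):
        r = sp.sample_radial_positions(1500, seed=23)
        N = sp.sample_depths(1500, 20_000, 0.4, seed=24).astype(float)
        truth = RegulationFunction(5e-5, 1e-4, 0.0)
        counts = rng.poisson(rng.gamma(5.0, truth(r) * N / 5.0))
        res = sp.fit_gene(counts, (r, N))
        assert res.converged
        for rr in (0.0, 0.5, 1.0):
            assert res.predict(rr) == pytest.approx(truth(rr), rel=0.30)

    def test_fit_is_deterministic(self, rng, positioned_cells):
        r, N = positioned_cells
        counts = rng.poisson(1e-4 * N)
        res1 = sp.fit_gene(counts, (r, N))
        res2 = sp.fit_gene(counts, (r, N))
        assert res1.params == res2.params and res1.theta == res2.theta

    def test_summary_renders(self, rng, positioned_cells):
        r, N = positioned_cells
        counts = rng.poisson(2e-4 * N)
        res = sp.fit_gene(counts, (r, N), gene_id="toy")
        text = res.summary()
        assert "toy" in text and "theta" in text

    def test_gradient_matches_finite_differences(self, rng, positioned_cells):
        r, N = positioned_cells
        counts = rng.poisson(rng.gamma(2.0, 1e-4 * N / 2.0))
        model = GeneRegulationModel(counts, (r, N))
        x = np.array([1.1, 0.3, -0.2, np.log(2.0)])
        _, grad = model._neg_log_posterior(x)
        num = np.empty(4)
        for i in range(4):
            h = 1e-6 * max(1, abs(x[i]))
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (
                model._neg_log_posterior(xp)[0] - model._neg_log_posterior(xm)[0]
            ) / (2 * h)
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-6)


class TestSpatialTest:
    def _fit(self, b_over_se=None):
        rng = np.random.default_rng(3)
        r = sp.sample_radial_positions(500, seed=31)
        N = np.full(500, 2e4)
        counts = rng.poisson(1e-4 * N)
        return sp.fit_gene(counts, (r, N))

    def test_zero_coefficient_gives_p_one(self):
        res = self._fit()
        res.params = RegulationFunction(res.params.a, 0.0, res.params.c)
        p_b, _, _ = wald_spatial_test(res, method="bonferroni")
        assert p_b == 1.0

    def test_classic_normal_quantile(self):
        res = self._fit()
        res.params = RegulationFunction(
            res.params.a, 1.959964 * res.se_b, res.params.c
        )
        p_b, _, _ = wald_spatial_test(res, method="bonferroni")
        assert p_b == pytest.approx(0.05, abs=1e-4)

    def test_bonferroni_combination_is_conservative_on_null_genes(self):
        # null genes: p_gene stochastically >= uniform
        rng = np.random.default_rng(7)
        r = sp.sample_radial_positions(400, seed=41)
        N = np.full(400, 2e4)
        pvals = []
        for _ in range(60):
            counts = rng.poisson(rng.gamma(3.0, 1e-4 * N / 3.0))
            res = sp.fit_gene(counts, (r, N))
            if res.converged and res.has_se:
                pvals.append(wald_spatial_test(res, method="bonferroni")[2])
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        # conservative: empirical CDF at p should not exceed p by much
        assert (ecdf - pvals <= 0.15).all()

    def test_joint_test_agrees_with_marginals_when_orthogonal(self):
        res = self._fit()
        _, _, p_joint = wald_spatial_test(res, method="wald_joint")
        assert 0.0 <= p_joint <= 1.0
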