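import numpy as np
import pytest
from scipy import stats

from conftest import make_matrix
from nucdist.distributions import (
    FitResult,
    MODELS,
    PHI_MAX,
    bic_compare,
    binomial_logpmf,
    detect_zero_inflation,
    estimate_abundance,
    expected_variance,
    expected_zero_fraction,
    fit_model,
    gene_summaries,
    nb_logpmf,
    poisson_gof,
    poisson_logpmf,
    summary_with_expectations,
)
from nucdist.synthetic import SimCountConfig, simulate_counts


class TestGeneSummaries:
    def test_constant_gene(self):
        s = gene_summaries(make_matrix([[1, 1, 1, 1]]))
        assert s.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_hand_arithmetic(self):
        s = gene_summaries(make_matrix([[0, 0, 2, 2]]))
        mean, var, zf = s.iloc[0]
        assert mean == 1.0
        assert var == pytest.approx(4 / 3)
        assert zf == 0.5

    def test_all_zero_gene(self):
        s = gene_summaries(make_matrix([[0, 0], [1, 1]]))
        assert s.iloc[0].tolist() == [0.0, 0.0, 1.0]

    def test_needs_two_cells(self):
        with pytest.raises(ValueError, match="2 cells"):
            gene_summaries(make_matrix([[1], [2]]))


class TestEstimateAbundance:
    def test_uniform(self):
        pi = estimate_abundance(make_matrix([[1, 1], [1, 1]]))
        assert pi.tolist() == [0.5, 0.5]

    def test_single_gene(self):
        assert estimate_abundance(make_matrix([[3, 4]])).tolist() == [1.0]

    def test_scale_invariance(self):
        m1 = make_matrix([[1, 2], [3, 4]])
        m5 = make_matrix([[5, 10], [15, 20]])
        np.testing.assert_allclose(estimate_abundance(m1), estimate_abundance(m5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no counts"):
            estimate_abundance(make_matrix([[0, 0]]))


class TestLogPmfs:
    """The hand-built gammaln/xlogy log-pmfs agree with scipy.stats."""

    def test_nb_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 50, 200)
        mu = rng.uniform(0.01, 30, 200)
        phi = rng.uniform(0.1, 10, 200)
        expected = stats.nbinom.logpmf(x, n=phi, p=phi / (phi + mu))
        np.testing.assert_allclose(nb_logpmf(x, mu, phi), expected, rtol=1e-10)

    def test_poisson_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 40, 200)
        mu = rng.uniform(0.01, 30, 200)
        np.testing.assert_allclose(
            poisson_logpmf(x, mu), stats.poisson.logpmf(x, mu), rtol=1e-10
        )

    def test_binomial_matches_scipy(self):
        rng = np.random.default_rng(2)
        n = rng.integers(5, 200, 200)
        x = np.minimum(rng.integers(0, 50, 200), n)
        p = rng.uniform(0.001, 0.5, 200)
        np.testing.assert_allclose(
            binomial_logpmf(x, n, p), stats.binom.logpmf(x, n, p), rtol=1e-9
        )

    def test_nb_zero_mean(self):
        assert nb_logpmf(0, 0.0, 1.0) == 0.0
        assert nb_logpmf(3, 0.0, 1.0) == -np.inf


class TestFitModel:
    def test_poisson_closed_form_on_ones(self):
        fit = fit_model(make_matrix([[1, 1], [1, 1]]), "poisson")
        assert fit.loglik_total == pytest.approx(-4.0)
        assert fit.n_params == 2
        assert fit.n_obs == 4

    def test_nb_on_poisson_data_hits_poisson_limit(self):
        """As phi -> inf the NB collapses onto the Poisson, so on Poisson
        data the fitted NB either reaches the bound or matches the Poisson
        log-likelihood."""
        m, _ = simulate_counts(
            SimCountConfig(n_genes=200, n_cells=500, model="poisson", seed=21)
        )
        nb = fit_model(m, "nb_global")
        pois = fit_model(m, "poisson")
        assert nb.phi_global > 1e6 or abs(nb.loglik_total - pois.loglik_total) < 0.1

    def test_nb_dispersion_recovery_moderate_n(self):
        m, _ = simulate_counts(
            SimCountConfig(n_genes=200, n_cells=500, model="nb", phi=2.0, seed=22)
        )
        fit = fit_model(m, "nb_global")
        assert 1.5 <= fit.phi_global <= 2.7

    def test_genewise_degenerate_gene_warns_and_bounds(self):
        counts = np.vstack([np.full(20, 3), np.random.default_rng(0).poisson(3, 20)])
        m = make_matrix(counts)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            fit = fit_model(m, "nb_genewise")
        assert fit.phi_gene[0] == PHI_MAX

    def test_unknown_model(self, tiny_matrix):
        with pytest.raises(ValueError, match="unknown model"):
            fit_model(tiny_matrix, "gamma")

    def test_likelihood_nesting(self):
        """MLE dominance: genewise >= global >= any fixed phi."""
        m, _ = simulate_counts(
            SimCountConfig(n_genes=60, n_cells=150, model="nb", phi=0.7, seed=23)
        )
        glob = fit_model(m, "nb_global")
        gene = fit_model(m, "nb_genewise")
        pi = estimate_abundance(m)
        s = m.library_sizes.astype(float)
        mu = pi[:, None] * s[None, :]
        for phi_fixed in (0.2, 1.0, 5.0):
            ll_fixed = nb_logpmf(m.dense(), mu, phi_fixed).sum()
            assert glob.loglik_total >= ll_fixed - 1e-6
        assert gene.loglik_total >= glob.loglik_total - 1e-6

    def test_nb_poisson_limit_loglik(self):
        """|ll_NB(phi=1e8) - ll_Poisson| < 1e-3 per 1e5 observations."""
        # low-depth regime: the finite-phi error is O(mu^2 / phi) per entry
        m, _ = simulate_counts(
            SimCountConfig(
                n_genes=200, n_cells=500, model="poisson",
                mean_library_size=200.0, seed=24,
            )
        )
        pi = estimate_abundance(m)
        mu = pi[:, None] * m.library_sizes.astype(float)[None, :]
        ll_nb = nb_logpmf(m.dense(), mu, 1e8).sum()
        ll_pois = fit_model(m, "poisson").loglik_total
        assert abs(ll_nb - ll_pois) < 1e-3 * (m.n_genes * m.n_cells / 1e5 + 1)

    def test_permutation_invariance(self):
        m, _ = simulate_counts(
            SimCountConfig(n_genes=40, n_cells=80, model="nb", phi=1.0, seed=25)
        )
        rng = np.random.default_rng(0)
        mp = m.select_genes(rng.permutation(m.n_genes)).select_cells(
            rng.permutation(m.n_cells)
        )
        for model in ("poisson", "binomial", "nb_global"):
            f1, f2 = fit_model(m, model), fit_model(mp, model)
            assert f1.loglik_total == pytest.approx(f2.loglik_total, rel=1e-12)
            assert f1.bic == pytest.approx(f2.bic, rel=1e-12)


class TestExpectedCurves:
    def test_nb_variance_formula(self):
        assert expected_variance("nb", 2.0, phi=1.0) == pytest.approx(6.0)

    def test_nb_poisson_limit(self):
        assert expected_variance("nb", 3.0, phi=1e12) == pytest.approx(3.0, abs=1e-6)

    @pytest.mark.parametrize("model,kw", [
        ("poisson", {}), ("nb", {"phi": 1.0}), ("binomial", {"mean_libsize": 100}),
    ])
    def test_zero_mean_zero_variance(self, model, kw):
        assert expected_variance(model, 0.0, **kw) == 0.0

    def test_invalid_phi(self):
        with pytest.raises(ValueError):
            expected_variance("nb", 1.0, phi=0.0)

    @pytest.mark.parametrize("model,kw", [
        ("poisson", {}), ("binomial", {}), ("nb", {"phi": 2.0}),
    ])
    def test_zero_abundance_gives_all_zeros(self, model, kw):
        assert expected_zero_fraction(model, 0.0, [10, 20], **kw) == 1.0

    def test_poisson_closed_form(self):
        assert expected_zero_fraction("poisson", 1.0, [1.0]) == pytest.approx(
            np.exp(-1)
        )

    def test_nb_zero_probability_monte_carlo(self):
        """(phi/(phi+mu))^phi at phi=1, mu=1 is 1/2; cross-check by
        sampling 1e5 NB variates."""
        assert expected_zero_fraction("nb", 1.0, [1.0], phi=1.0) == pytest.approx(0.5)
        rng = np.random.default_rng(3)
        draws = rng.negative_binomial(1.0, 1.0 / 2.0, size=100_000)
        assert np.mean(draws == 0) == pytest.approx(0.5, abs=0.01)


class TestBicCompare:
    def test_single_fit_zero_loglik(self):
        fit = FitResult("poisson", np.array([1.0]), 0.0, 1, 1)
        assert bic_compare([fit])["bic"].iloc[0] == 0.0

    def test_penalty_monotonicity(self):
        pi = np.ones(4) / 4
        small = FitResult("poisson", pi, -100.0, 4, 1000)
        big = FitResult("nb_genewise", pi, -100.0, 8, 1000)
        assert bic_compare([small, big])["model"].iloc[0] == "poisson"

    def test_mismatched_n_obs_rejected(self):
        pi = np.ones(2) / 2
        a = FitResult("poisson", pi, -1.0, 2, 100)
        b = FitResult("binomial", pi, -1.0, 2, 200)
        with pytest.raises(ValueError, match="different n_obs"):
            bic_compare([a, b])


class TestPoissonGof:
    def test_exact_expectation_gives_zero(self):
        # equal library sizes, counts equal their expectations
        m = make_matrix([[1, 1], [1, 1]])
        gof = poisson_gof(m)
        assert gof.table["pearson_stat"].tolist() == [0.0, 0.0]
        assert gof.table["dof"].tolist() == [1, 1]

    def test_hand_arithmetic(self):
        # s=(2,2), pi=(0.5,0.5): mu=1 everywhere; gene counts (0,2) give 2
        m = make_matrix([[0, 2], [2, 0]])
        gof = poisson_gof(m)
        assert gof.table["pearson_stat"].tolist() == [2.0, 2.0]

    def test_zero_abundance_genes_excluded(self):
        m = make_matrix([[0, 0], [1, 2]])
        gof = poisson_gof(m)
        assert gof.excluded == ["g0"]
        assert len(gof.table) == 1

    def test_qq_pairs_sorted(self):
        m, _ = simulate_counts(
            SimCountConfig(n_genes=50, n_cells=100, model="poisson", seed=30)
        )
        gof = poisson_gof(m)
        assert gof.qq["observed"].is_monotonic_increasing
        assert gof.qq["theoretical"].is_monotonic_increasing


class TestZeroFractionConsistency:
    def test_observed_zeros_within_binomial_se_of_expected(self):
        """On model-simulated data the observed zero fraction sits within
        3 binomial standard errors of the model expectation for >= 95% of
        genes."""
        m, truth = simulate_counts(
            SimCountConfig(n_genes=300, n_cells=600, model="nb", phi=1.0, seed=31)
        )
        s = m.library_sizes
        c = m.n_cells
        summaries = gene_summaries(m)
        ok = 0
        for i in range(m.n_genes):
            exp = expected_zero_fraction("nb", truth.pi[i], s, phi=1.0)
            se = np.sqrt(max(exp * (1 - exp), 1e-12) / c)
            if abs(summaries["zero_fraction"].iloc[i] - exp) <= 3 * se + 1e-9:
                ok += 1
        assert ok / m.n_genes >= 0.95

    def test_detect_zero_inflation_requires_nb_fit(self, tiny_matrix):
        fit = fit_model(tiny_matrix, "poisson")
        with pytest.raises(ValueError, match="NB fit"):
            detect_zero_inflation(tiny_matrix, fit)


def test_summary_with_expectations_has_curve_columns():
    m, _ = simulate_counts(
        SimCountConfig(n_genes=30, n_cells=50, model="nb", phi=1.0, seed=32)
    )
    fits = [fit_model(m, name) for name in ("poisson", "nb_global")]
    out = summary_with_expectations(m, fits)
    for model in ("poisson", "nb_global"):
        assert f"expected_variance_{model}" in out.columns
        assert f"expected_zero_fraction_{model}" in out.columns
    assert out["expected_zero_fraction_poisson"].between(0, 1).all()
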