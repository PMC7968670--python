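"""Binning, grid likelihood, posteriors, model comparison."""

import numpy as np
import pytest

from cultepi import (
    BinnedCounts,
    ModelParams,
    PriorGrid,
    SampleSet,
    aic,
    bayes_factor,
    bin_samples,
    detection_ratio_epidemiological,
    evaluate_grid,
    fit_null,
    fit_proportional,
    log_likelihood,
    threshold_quantiles,
)
from cultepi.inference import InferenceError, PosteriorResult, _binned_loglik


def samples_from(densities, is_site):
    return SampleSet(density=np.asarray(densities, float),
                     is_site=np.asarray(is_site, bool))


class TestBinSamples:
    def test_counts_conserved(self, epi_samples):
        binned = bin_samples(epi_samples, n_bins=35)
        assert binned.n_bins == 35
        assert binned.site_counts.sum() == epi_samples.n_sites
        assert binned.n_total == len(epi_samples)

    def test_single_sample_lands_in_one_bin(self):
        binned = bin_samples(samples_from([7.3], [True]), n_bins=35)
        assert binned.site_counts.sum() == 1
        assert (binned.site_counts > 0).sum() == 1

    def test_uniform_unit_spacing_one_per_bin(self):
        dens = np.arange(35) + 0.5  # 0.5, 1.5, ..., 34.5 over [0, 35)
        s = samples_from(dens, np.zeros(35, bool))
        binned = bin_samples(s, n_bins=35)
        np.testing.assert_array_equal(binned.nonsite_counts, np.ones(35))

    def test_max_density_included_in_last_bin(self):
        s = samples_from([1.0, 35.0], [False, False])
        binned = bin_samples(s, n_bins=35)
        assert binned.nonsite_counts[-1] == 1

    def test_mean_representative_option(self, epi_samples):
        mid = bin_samples(epi_samples, representative="midpoint")
        mean = bin_samples(epi_samples, representative="mean")
        assert not np.allclose(mid.rep_density, mean.rep_density)
        np.testing.assert_array_equal(mid.site_counts, mean.site_counts)


class TestLogLikelihood:
    def test_single_bin_arithmetic(self):
        binned = BinnedCounts(edges=[0.0, 1.0], site_counts=[1],
                              nonsite_counts=[9], rep_density=[0.5])
        ll = log_likelihood(binned, lambda rho: np.full_like(rho, 0.1))
        assert ll == pytest.approx(np.log(0.1) + 9 * np.log(0.9))
        assert ll == pytest.approx(-3.2508, abs=1e-4)

    def test_certain_detection_with_nonsites_is_impossible(self):
        binned = BinnedCounts(edges=[0.0, 1.0], site_counts=[1],
                              nonsite_counts=[9], rep_density=[0.5])
        assert log_likelihood(binned, lambda rho: np.ones_like(rho)) == -np.inf

    def test_zero_probability_empty_bin_is_legal(self):
        binned = BinnedCounts(edges=[0.0, 1.0, 2.0], site_counts=[0, 1],
                              nonsite_counts=[5, 5], rep_density=[0.5, 1.5])
        ll = log_likelihood(binned, lambda rho: np.where(rho < 1, 0.0, 0.1))
        assert np.isfinite(ll)

    def test_null_grid_max_matches_bernoulli_mle(self, epi_samples):
        """Fine-grid null maximum equals the closed-form binomial MLE."""
        binned = bin_samples(epi_samples)
        s, n = binned.n_sites, binned.n_total
        k_hat = s / n
        ll_mle = s * np.log(k_hat) + (n - s) * np.log1p(-k_hat)
        res = fit_null(binned, k_min=k_hat / 10, k_max=k_hat * 10, n_k=4001)
        assert res.max_log_likelihood == pytest.approx(ll_mle, abs=0.01)
        assert res.max_log_likelihood <= ll_mle + 1e-9

    def test_adding_empty_bins_changes_nothing(self, epi_samples):
        binned = bin_samples(epi_samples, n_bins=35)
        model = lambda rho: np.clip(1e-5 * rho, 0, 1)
        base = log_likelihood(binned, model)
        top = binned.edges[-1]
        extended = BinnedCounts(
            edges=np.concatenate([binned.edges, top + np.arange(1, 6)]),
            site_counts=np.concatenate([binned.site_counts, np.zeros(5, int)]),
            nonsite_counts=np.concatenate([binned.nonsite_counts, np.zeros(5, int)]),
            rep_density=np.concatenate([binned.rep_density, top + np.arange(1, 6)]),
        )
        assert log_likelihood(extended, model) == pytest.approx(base)


class TestEvaluateGrid:
    def test_marginals_normalised(self, epi_samples):
        binned = bin_samples(epi_samples)
        res = evaluate_grid(binned, PriorGrid(2, 5, 1e-7, 1e-3, 0, 5e-6,
                                              n_gamma=20, n_zeta=20, n_eps=10))
        for marg in res.marginals.values():
            assert marg.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_node_grid_is_map_with_mass_one(self, epi_samples):
        binned = bin_samples(epi_samples)
        prior = PriorGrid(3.5, 3.5, 5e-5, 5e-5, 1e-6, 1e-6,
                          n_gamma=1, n_zeta=1, n_eps=1)
        res = evaluate_grid(binned, prior)
        assert res.posterior.ravel()[0] == pytest.approx(1.0)
        assert res.map_params["gamma"] == 3.5
        assert res.log_marginal_likelihood == pytest.approx(res.max_log_likelihood)

    def test_all_impossible_grid_raises(self):
        binned = BinnedCounts(edges=[0.0, 1.0], site_counts=[3],
                              nonsite_counts=[0], rep_density=[0.5])
        # every epidemiological node has P(0.5) = eps = 0 but sites exist
        prior = PriorGrid(2, 5, 1e-7, 1e-4, 0.0, 0.0, n_gamma=5, n_zeta=5)
        with pytest.raises(InferenceError):
            evaluate_grid(binned, prior)

    def test_grid_refinement_stability(self, epi_samples):
        """Doubling resolution moves the threshold median by less than the
        inter-quantile spread."""
        binned = bin_samples(epi_samples)
        coarse = evaluate_grid(binned, PriorGrid(2, 5, 1e-7, 1e-3, 0, 5e-6,
                                                 n_gamma=25, n_zeta=25, n_eps=13))
        fine = evaluate_grid(binned, PriorGrid(2, 5, 1e-7, 1e-3, 0, 5e-6,
                                               n_gamma=50, n_zeta=50, n_eps=25))
        q_coarse = threshold_quantiles(coarse)
        q_fine = threshold_quantiles(fine)
        spread = q_fine[3] - q_fine[1]  # interquartile range
        assert abs(q_fine[2] - q_coarse[2]) < spread

    def test_boundary_warning_reported(self, epi_samples):
        """A prior that caps gamma below the truth concentrates posterior
        mass at the bound and must say so."""
        binned = bin_samples(epi_samples)
        res = evaluate_grid(binned, PriorGrid(2, 2.5, 1e-7, 1e-3, 0, 5e-6,
                                              n_gamma=10, n_zeta=30, n_eps=5))
        assert any("gamma" in w and "upper" in w for w in res.boundary_warnings)


class TestThresholdQuantiles:
    def point_mass_result(self, gamma=3.5, phi=2.0):
        return PosteriorResult(
            family="epidemiological", param_names=("gamma",),
            param_values=(np.array([gamma]),), log_lik=np.zeros(1),
            posterior=np.ones(1), map_params={"gamma": gamma},
            max_log_likelihood=0.0, marginals={"gamma": np.ones(1)},
            log_marginal_likelihood=0.0, phi=phi,
            threshold_values=np.array([gamma ** phi]),
            threshold_posterior=np.array([1.0]),
        )

    def test_point_mass(self):
        q = threshold_quantiles(self.point_mass_result())
        np.testing.assert_allclose(q, 12.25)

    def test_symmetric_two_atom_median(self):
        res = self.point_mass_result()
        res.threshold_values = np.array([10.0, 20.0])
        res.threshold_posterior = np.array([0.5, 0.5])
        q = threshold_quantiles(res, probs=(0.5,))
        assert q[0] == pytest.approx(15.0)

    def test_quantiles_nondecreasing(self, epi_samples):
        binned = bin_samples(epi_samples)
        res = evaluate_grid(binned, PriorGrid(2, 5, 1e-7, 1e-3, 0, 5e-6,
                                              n_gamma=30, n_zeta=30, n_eps=10))
        q = threshold_quantiles(res)
        assert np.all(np.diff(q) >= 0)


class TestModelComparison:
    def test_bayes_factor_identities(self):
        assert bayes_factor(3.0, 3.0) == pytest.approx(1.0)
        assert bayes_factor(np.log(10), 0.0) == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "ll, k, expected", [(-1404, 3, 2814), (0, 0, 0), (-100, 2, 204)]
    )
    def test_aic(self, ll, k, expected):
        assert aic(ll, k) == pytest.approx(expected)

    def test_two_equal_nodes_marginal(self):
        binned = BinnedCounts(edges=[0.0, 1.0], site_counts=[1],
                              nonsite_counts=[9], rep_density=[0.5])
        res = fit_null(binned, k_min=0.1, k_max=0.1, n_k=2)
        assert res.log_marginal_likelihood == pytest.approx(
            np.log(0.1) + 9 * np.log(0.9))

    def test_epidemiological_beats_null_on_epidemic_data(self, epi_samples):
        binned = bin_samples(epi_samples)
        epi = evaluate_grid(binned, PriorGrid(2, 5, 1e-7, 1e-3, 0, 5e-6,
                                              n_gamma=30, n_zeta=30, n_eps=10))
        null = fit_null(binned)
        assert bayes_factor(epi.log_marginal_likelihood,
                            null.log_marginal_likelihood) > 1.0

    def test_trapezoid_weights_close_to_equal(self, epi_samples):
        binned = bin_samples(epi_samples)
        prior = PriorGrid(2, 5, 1e-7, 1e-3, 0, 5e-6,
                          n_gamma=20, n_zeta=20, n_eps=10)
        eq = evaluate_grid(binned, prior, weights="equal")
        tr = evaluate_grid(binned, prior, weights="trapezoid")
        assert abs(eq.log_marginal_likelihood - tr.log_marginal_likelihood) < 1.0


class TestProportionalFit:
    def test_recovers_slope_on_proportional_data(self):
        rng = np.random.default_rng(31)
        dens = np.minimum(rng.lognormal(np.log(15), 1.0, 200_000), 150.0)
        zeta_true = 3e-4
        is_site = rng.random(dens.size) < np.clip(zeta_true * dens, 0, 1)
        binned = bin_samples(SampleSet(density=dens, is_site=is_site))
        res = fit_proportional(binned, zeta_min=1e-6, zeta_max=1e-2,
                               n_zeta=100, eps_min=0.0, eps_max=0.0)
        assert res.map_params["zeta"] == pytest.approx(zeta_true, rel=0.15)
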