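import numpy as np
import pytest

from isonicheweb import (
    ChainConfig,
    MixingProblem,
    POST_TEF,
    SourceSpec,
    fit_by_category,
    fit_mixing,
    gelman_rubin,
    summarize_posterior,
)
from isonicheweb.errors import ConfigError, InsufficientDataError

THREE_SOURCES = (
    SourceSpec("A", -20.0, 0.5, 0.5, 0.5),
    SourceSpec("B", -15.0, 0.5, 3.0, 0.5),
    SourceSpec("C", -9.0, 0.5, 1.0, 0.5),
)

SHORT = ChainConfig(iterations=12_000, burn_in=2_000, thin=5)


def forward_consumers(p, sources, tef=POST_TEF, n=30, residual=0.3, seed=7):
    """Independent forward draw from the model's own likelihood at TP 2."""
    p = np.asarray(p, dtype=float)
    mu = np.array([[s.mean_c, s.mean_n] for s in sources])
    var_src = np.array([[s.sd_c**2 + tef.sd_c**2, s.sd_n**2 + tef.sd_n**2] for s in sources])
    mean = p @ mu + np.array([tef.mean_c, tef.mean_n])
    var = (p**2) @ var_src + residual**2
    rng = np.random.default_rng(seed)
    return rng.normal(mean, np.sqrt(var), size=(n, 2))


class TestFitMixing:
    def test_single_source_posterior_is_point_mass(self):
        problem = MixingProblem(
            consumers=[[-14.6, 5.4]], sources=(THREE_SOURCES[0],), tef=POST_TEF
        )
        post = fit_mixing(problem, ChainConfig(iterations=2_000, burn_in=500, thin=5), seed=0)
        assert np.all(post.draws == 1.0)

    def test_symmetric_two_source_problem_splits_evenly(self):
        sources = (SourceSpec("L", -20.0, 1.0, 2.0, 0.5), SourceSpec("R", -10.0, 1.0, 2.0, 0.5))
        x = forward_consumers([0.5, 0.5], sources, n=40, seed=3)
        post = fit_mixing(MixingProblem(x, sources, POST_TEF), SHORT, seed=4)
        assert post.means == pytest.approx([0.5, 0.5], abs=0.03)

    def test_draws_stay_on_simplex(self):
        x = forward_consumers([0.6, 0.3, 0.1], THREE_SOURCES)
        post = fit_mixing(MixingProblem(x, THREE_SOURCES, POST_TEF), SHORT, seed=5)
        assert np.all(post.draws >= 0)
        np.testing.assert_allclose(post.draws.sum(axis=1), 1.0, atol=1e-9)
        assert post.means.sum() == pytest.approx(1.0, abs=1e-9)

    def test_seeded_determinism(self):
        x = forward_consumers([0.6, 0.3, 0.1], THREE_SOURCES)
        a = fit_mixing(MixingProblem(x, THREE_SOURCES, POST_TEF), SHORT, seed=6)
        b = fit_mixing(MixingProblem(x, THREE_SOURCES, POST_TEF), SHORT, seed=6)
        assert np.array_equal(a.draws, b.draws)
        assert a.config.n_retained == a.draws.shape[0]

    def test_parameter_recovery_short_chain(self):
        truth = np.array([0.6, 0.3, 0.1])
        x = forward_consumers(truth, THREE_SOURCES, n=30, seed=7)
        post = fit_mixing(MixingProblem(x, THREE_SOURCES, POST_TEF), SHORT, seed=11)
        assert post.means == pytest.approx(truth, abs=0.10)
        summary = summarize_posterior(post)
        for name, true_p in zip(post.source_names, truth):
            lo, hi = summary[name]["intervals"][95]
            assert lo <= true_p <= hi

    def test_prior_only_marginals_are_uniform(self):
        x = forward_consumers([0.6, 0.3, 0.1], THREE_SOURCES, n=5)
        post = fit_mixing(
            MixingProblem(x, THREE_SOURCES, POST_TEF),
            ChainConfig(iterations=42_000, burn_in=2_000, thin=4),
            seed=13,
            prior_only=True,
        )
        assert post.means == pytest.approx([1 / 3] * 3, abs=0.02)

    def test_label_permutation_equivariance(self):
        truth = np.array([0.6, 0.3, 0.1])
        x = forward_consumers(truth, THREE_SOURCES, n=30, seed=7)
        perm = [2, 0, 1]
        permuted_sources = tuple(THREE_SOURCES[i] for i in perm)
        post = fit_mixing(MixingProblem(x, THREE_SOURCES, POST_TEF), SHORT, seed=11)
        post_perm = fit_mixing(MixingProblem(x, permuted_sources, POST_TEF), SHORT, seed=11)
        # same posterior (up to Monte-Carlo error) with permuted labels
        assert post_perm.means == pytest.approx(post.means[perm], abs=0.03)
        assert post_perm.source_names == tuple(THREE_SOURCES[i].name for i in perm)

    def test_gelman_rubin_across_four_chains(self):
        x = forward_consumers([0.6, 0.3, 0.1], THREE_SOURCES, n=30, seed=7)
        chains = [
            fit_mixing(MixingProblem(x, THREE_SOURCES, POST_TEF), SHORT, seed=s).draws
            for s in range(4)
        ]
        for param in range(3):
            assert gelman_rubin([c[:, param] for c in chains]) < 1.05

    def test_bad_chain_config_rejected(self):
        with pytest.raises(ConfigError):
            ChainConfig(iterations=100, burn_in=100)
        with pytest.raises(ConfigError):
            MixingProblem(consumers=[[0.0, 0.0]], sources=THREE_SOURCES, tef=POST_TEF,
                          prior_alpha=(1.0, 1.0))


class TestSummarize:
    def test_constant_draws_degenerate_intervals(self):
        post = fit_mixing(
            MixingProblem([[-14.6, 5.4]], (THREE_SOURCES[0],), POST_TEF),
            ChainConfig(iterations=1_500, burn_in=400, thin=1),
            seed=0,
        )
        summary = summarize_posterior(post)
        for level, (lo, hi) in summary["A"]["intervals"].items():
            assert lo == hi == 1.0

    def test_intervals_nested_and_match_quantile_oracle(self):
        x = forward_consumers([0.6, 0.3, 0.1], THREE_SOURCES)
        post = fit_mixing(MixingProblem(x, THREE_SOURCES, POST_TEF), SHORT, seed=21)
        summary = summarize_posterior(post)
        m = post.draws.shape[0]
        for idx, name in enumerate(post.source_names):
            draws = np.sort(post.draws[:, idx])
            i50 = summary[name]["intervals"][50]
            i75 = summary[name]["intervals"][75]
            i95 = summary[name]["intervals"][95]
            assert i50[0] >= i75[0] >= i95[0] and i50[1] <= i75[1] <= i95[1]
            for level, (lo, hi) in summary[name]["intervals"].items():
                tail = (100 - level) / 200.0
                # endpoints within one order-statistic position of sorted draws
                lo_idx = np.searchsorted(draws, lo)
                assert abs(lo_idx - tail * m) <= 2
                hi_idx = np.searchsorted(draws, hi)
                assert abs(hi_idx - (1 - tail) * m) <= 2

    def test_too_few_draws_rejected(self):
        post = fit_mixing(
            MixingProblem([[-14.6, 5.4]], (THREE_SOURCES[0],), POST_TEF),
            ChainConfig(iterations=600, burn_in=500, thin=5),
            seed=0,
        )
        with pytest.raises(InsufficientDataError):
            summarize_posterior(post)


class TestFitByCategory:
    def test_grouped_fits_recover_pathway_contrast(self, scenario, dataset):
        """Coral-site carnivores sit on the benthic turf pathway, degraded-site
        carnivores on the POM pathway: each posterior maximum matches."""
        from isonicheweb.data_model import pool_sources
        from isonicheweb.synthetic_reef import DEFAULT_SOURCE_GROUPING

        sources_by_site = {
            site: pool_sources(
                [s for s in dataset.samples if s.site == site and s.taxon in DEFAULT_SOURCE_GROUPING],
                DEFAULT_SOURCE_GROUPING,
            )
            for site in scenario.sites
        }
        posteriors, warnings = fit_by_category(
            dataset.samples,
            sources_by_site,
            scenario.tef,
            dataset.category_map,
            mcmc=ChainConfig(iterations=8_000, burn_in=1_500, thin=5),
            seed=31,
        )
        assert not warnings
        def argmax_source(post):
            return post.source_names[int(np.argmax(post.means))]

        assert argmax_source(posteriors[("Limones", "carnivore")]) == "turf+epiphytes"
        assert argmax_source(posteriors[("Limones", "herbivore")]) == "turf+epiphytes"
        assert argmax_source(posteriors[("Bonanza", "carnivore")]) == "POM"

    def test_empty_category_skipped_with_warning(self, dataset):
        from isonicheweb.data_model import pool_sources
        from isonicheweb.synthetic_reef import DEFAULT_SOURCE_GROUPING

        herb_only = [
            s
            for s in dataset.samples
            if s.site == "Limones"
            and (s.role.value == "source" or s.trophic_category.value == "herbivore")
        ]
        sources = {
            "Limones": pool_sources(
                [s for s in herb_only if s.taxon in DEFAULT_SOURCE_GROUPING],
                DEFAULT_SOURCE_GROUPING,
            )
        }
        posteriors, warnings = fit_by_category(
            herb_only,
            sources,
            POST_TEF,
            mcmc=ChainConfig(iterations=2_000, burn_in=500, thin=5),
            seed=1,
        )
        assert set(posteriors) == {("Limones", "herbivore")}
        assert any("omnivore" in w for w in warnings)
        assert any("carnivore" in w for w in warnings)
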