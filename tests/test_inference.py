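"""Trend pseudo-observations, state-space fitting, and trend updating."""

import numpy as np
import pytest

from mpva.demography import InvalidParameterError, VitalRates, build_matrix
from mpva.fixtures import WorldSpec, make_removal_experiment, make_world
from mpva.hazards import InvasiveAssemblage
from mpva.inference import (
    TREND_LAMBDA_GRID,
    TREND_WEIGHTS,
    CountSeries,
    MCMCConfig,
    build_trend_pseudo_observations,
    fit_state_space,
    update_with_trends,
)
from mpva.priors import fit_all_priors

SMALL_MCMC = MCMCConfig(chains=2, burn=400, samples=400)


def world_priors(world):
    return fit_all_priors(
        world.records, (world.spec.species, world.spec.genus, world.spec.family)
    )


class TestTrendPseudoObservations:
    @pytest.mark.parametrize("status", ["Increasing", "Stable", "Decreasing", "Unknown"])
    def test_weights_tally_to_100(self, status):
        assert sum(TREND_WEIGHTS[status]) == 100
        trend = build_trend_pseudo_observations(status)
        assert trend.pseudo_obs.shape == (100,)

    @pytest.mark.parametrize(
        "status,mode,weight",
        [("Increasing", 1.02, 13), ("Stable", 1.00, 14), ("Decreasing", 0.98, 13)],
    )
    def test_modal_lambdas(self, status, mode, weight):
        trend = build_trend_pseudo_observations(status)
        values, counts = np.unique(trend.pseudo_obs, return_counts=True)
        assert values[np.argmax(counts)] == pytest.approx(mode)
        assert counts.max() == weight

    def test_values_confined_to_grid(self):
        trend = build_trend_pseudo_observations("Unknown")
        assert set(np.round(trend.pseudo_obs, 2)) <= set(TREND_LAMBDA_GRID)
        assert trend.pseudo_obs.min() >= 0.9 and trend.pseudo_obs.max() <= 1.1

    def test_unknown_status_string_rejected(self):
        with pytest.raises(InvalidParameterError, match="Increasing"):
            build_trend_pseudo_observations("Booming")


class TestCountSeries:
    def test_validation(self):
        asm = InvasiveAssemblage(["rat"], 1.0)
        with pytest.raises(InvalidParameterError):
            CountSeries("a", np.array([3, 2, 1]), np.array([5, 5, 5]), asm)
        with pytest.raises(InvalidParameterError):
            CountSeries("a", np.array([1, 2]), np.array([5, -1]), asm)

    def test_invasion_window(self):
        asm = InvasiveAssemblage(["rat"], 1.0)
        s = CountSeries("a", np.arange(5), np.full(5, 9), asm, removal_year=3)
        assert s.invaded_in(2) and not s.invaded_in(3)
        clean = CountSeries("b", np.arange(5), np.full(5, 9), InvasiveAssemblage([], 1.0))
        assert not clean.invaded_in(0)


class TestStateSpaceFit:
    def test_reproducible_draws(self):
        w = make_removal_experiment(seed=5)
        pri = world_priors(w)
        with pytest.warns(RuntimeWarning):
            a = fit_state_space(w.series, w.species_meta, pri, SMALL_MCMC, seed=1)
        with pytest.warns(RuntimeWarning):
            b = fit_state_space(w.series, w.species_meta, pri, SMALL_MCMC, seed=1)
        assert a.samples.equals(b.samples)

    def test_baseline_lambda_recovered_without_invasives(self):
        # growth observed on clean islands should pin the implied growth rate
        spec = WorldSpec(n_islands=2, invaded_islands=(), years=25)
        w = make_world(spec, seed=8)
        pri = world_priors(w)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_state_space(
                w.series, w.species_meta, pri, MCMCConfig(chains=2, burn=800, samples=600),
                seed=2,
            )
        lams = np.array([
            build_matrix(VitalRates(
                s0=r.s0, s1=r.s1, s2=r.s2, s3=r.s3, b=r.b, e=r.e, h=r.h, f=r.f,
                afr=int(r.AFR),
            )).lam
            for r in post.samples.sample(150, random_state=0).itertuples()
        ])
        lo, hi = np.quantile(lams, [0.05, 0.95])
        assert lo <= w.true_lambda <= hi

    def test_removal_series_shows_growth_rebound(self):
        # posterior-mean parameters must reproduce the qualitative signature:
        # faster growth after eradication than before
        w = make_removal_experiment(seed=9)
        s = next(s for s in w.series if s.removal_year is not None)
        pre = s.counts[: s.removal_year]
        post_counts = s.counts[s.removal_year :]
        g_pre = np.polyfit(np.arange(pre.size), np.log(np.maximum(pre, 1)), 1)[0]
        g_post = np.polyfit(np.arange(post_counts.size), np.log(np.maximum(post_counts, 1)), 1)[0]
        assert g_post > g_pre

    def test_empty_series_rejected(self):
        w = make_removal_experiment(seed=1)
        with pytest.raises(InvalidParameterError):
            fit_state_space([], w.species_meta, world_priors(w))


@pytest.fixture(scope="module")
def priors():
    w = make_world(WorldSpec(n_islands=2, invaded_islands=()), seed=4)
    return world_priors(w)


class TestUpdateWithTrends:
    def test_stable_status_centers_lambda_near_one(self, priors):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = update_with_trends(
                priors, build_trend_pseudo_observations("Stable"),
                mcmc_config=MCMCConfig(chains=2, burn=600, samples=800), seed=3,
            )
        med = post.samples["lambda_hat"].median()
        assert 0.99 <= med <= 1.01

    def test_decreasing_pulls_below_prior(self, priors):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = update_with_trends(
                priors, build_trend_pseudo_observations("Decreasing"),
                mcmc_config=MCMCConfig(chains=2, burn=600, samples=800), seed=3,
            )
        # prior on these vitals implies growth ~ 1.0; Decreasing data pull it down
        assert post.samples["lambda_hat"].median() < 1.0

    def test_unknown_status_barely_moves_prior(self, priors):
        import warnings

        from mpva.priors import sample_prior

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = update_with_trends(
                priors, build_trend_pseudo_observations("Unknown"),
                mcmc_config=MCMCConfig(chains=2, burn=600, samples=800), seed=5,
            )
        # the nearly flat Unknown weights admit most growth rates; the
        # posterior of a well-supported vital rate stays close to its prior
        prior_draws = sample_prior(priors["s2"], 4000, seed=0)
        post_s2 = post.samples["s2"]
        assert abs(post_s2.mean() - prior_draws.mean()) < 0.05

    def test_default_saves_5000(self, priors):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = update_with_trends(
                priors, build_trend_pseudo_observations("Stable"),
                mcmc_config=MCMCConfig(samples=5000, burn=300), seed=1,
            )
        assert len(post.samples) == 5000
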