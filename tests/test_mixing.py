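"""Bayesian mixing model: priors, moments, likelihood, MCMC, diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from isodiet.mixing import (
    MCMCSettings,
    DirichletPrior,
    SourceSet,
    TDF,
    apply_time_lag,
    build_prior,
    compare_tracer_sets,
    gelman_rubin,
    log_likelihood,
    mixture_moments,
    sample_posterior,
)
from isodiet.synthetic import IsotopeScenario, default_source_set, generate_consumers

FAST = MCMCSettings(n_iter=6000, n_burn=3000, thin=5, n_chains=4, seed=0)


class TestBuildPrior:
    def test_equal_shares_uninformative(self):
        prior = build_prior([1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(prior.alpha, 1.0)

    def test_sub_adult_printed_vector_consistent(self):
        """The printed sub-adult alpha vector obeys alpha = K * share."""
        alpha = np.array([0.06, 2.02, 0.91])
        assert alpha.sum() == pytest.approx(3.0, abs=0.015)
        rebuilt = build_prior(alpha / alpha.sum())
        assert np.allclose(rebuilt.alpha, alpha * 3.0 / alpha.sum(), atol=1e-12)

    def test_adult_vector_from_shares(self):
        shares = np.array([0.12, 1 - 0.12 - 0.32 / 3, 0.32 / 3])
        prior = build_prior(shares)
        assert np.allclose(prior.alpha, [0.36, 2.32, 0.32], atol=5e-3)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=6)
        .filter(lambda v: sum(v) > 0)
    )
    def test_alpha_sums_to_n_sources(self, raw):
        prior = build_prior(np.asarray(raw) / np.sum(raw))
        assert prior.alpha.sum() == pytest.approx(len(raw), abs=1e-9)
        assert (prior.alpha > 0).all()

    def test_zero_share_floored(self):
        prior = build_prior([0.0, 0.5, 0.5])
        assert prior.alpha[0] > 0
        assert prior.alpha.sum() == pytest.approx(3.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            build_prior([0.0, 0.0])


class TestMixtureMoments:
    def test_single_source_degenerate(self):
        s = SourceSet(["a"], ["x", "y"], [[1.0, 5.0]], [[0.3, 0.4]], [[0.4, 0.1]])
        t = TDF(["x", "y"], [1.0, 2.0], [0.5, 0.6])
        mean, var = mixture_moments(np.array([1.0]), s, t)
        assert np.allclose(mean, [2.0, 7.0])
        assert np.allclose(var, [0.3 ** 2 + 0.5 ** 2, 0.4 ** 2 + 0.6 ** 2])

    def test_equal_concentrations_cancel(self):
        s = SourceSet(["a", "b"], ["x"], [[0.0], [10.0]], [[0.0], [0.0]],
                      [[0.3], [0.3]])
        t = TDF(["x"], [1.0], [0.0])
        mean, _ = mixture_moments(np.array([0.25, 0.75]), s, t)
        assert mean[0] == pytest.approx(0.25 * 1.0 + 0.75 * 11.0)

    def test_hand_example(self):
        s = SourceSet(["a", "b"], ["x"], [[0.0], [10.0]], [[0.0], [0.0]],
                      [[0.02], [0.04]])
        t = TDF(["x"], [1.0], [0.0])
        mean, _ = mixture_moments(np.array([0.5, 0.5]), s, t)
        assert mean[0] == pytest.approx(0.23 / 0.03)

    def test_off_simplex_rejected(self):
        s = default_source_set()
        t = TDF.tuna_default()
        with pytest.raises(ValueError):
            mixture_moments(np.array([0.5, 0.5, 0.5]), s, t)


class TestLogLikelihood:
    def _unit_setup(self):
        # one source whose mixture variance is exactly 1
        s = SourceSet(["a"], ["x"], [[0.0]], [[1.0]], [[0.5]])
        t = TDF(["x"], [0.0], [0.0])
        return s, t

    def test_at_mode_value(self):
        s, t = self._unit_setup()
        ll = log_likelihood(np.array([[0.0]]), np.array([1.0]), s, t)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_inflating_variance_lowers_mode_density(self):
        s, t = self._unit_setup()
        ll1 = log_likelihood(np.array([[0.0]]), np.array([1.0]), s, t, 1.0)
        ll2 = log_likelihood(np.array([[0.0]]), np.array([1.0]), s, t, 2.0)
        assert ll2 < ll1

    def test_matches_bruteforce_density(self, rng):
        s = default_source_set()
        t = TDF.tuna_default()
        p = np.array([0.2, 0.5, 0.3])
        xi = np.array([1.3, 0.8])
        consumers = rng.normal(-17.5, 1.0, (3, 2))
        mean, procvar = mixture_moments(p, s, t)
        ref = 0.0
        for i in range(3):
            for j in range(2):
                ref += stats.norm.logpdf(
                    consumers[i, j], mean[j], np.sqrt(xi[j] * procvar[j])
                )
        assert log_likelihood(consumers, p, s, t, xi) == pytest.approx(
            ref, abs=1e-10
        )


class TestSampler:
    def test_prior_only_recovers_prior_mean(self):
        s = default_source_set()
        t = TDF.tuna_default()
        prior = DirichletPrior(np.array([0.5, 2.0, 0.5]))
        post = sample_posterior(np.empty((0, 2)), s, t, prior, FAST)
        import arviz as az

        for k in range(3):
            draws = post.p_draws[:, :, k]  # (chain, draw)
            ess = max(float(np.asarray(az.ess(draws))), 50.0)
            mcse = draws.std() / np.sqrt(ess)
            assert abs(draws.mean() - prior.mean[k]) < 3 * mcse + 0.01

    def test_draws_on_simplex(self):
        cons, s, t = generate_consumers(IsotopeScenario(seed=5))
        post = sample_posterior(cons[["d13C", "d15N"]].to_numpy(), s, t,
                                mcmc=FAST)
        flat = post.flat_p
        assert (flat >= 0).all()
        assert np.allclose(flat.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_seed_identical_draws(self):
        cons, s, t = generate_consumers(IsotopeScenario(seed=2))
        c = cons[["d13C", "d15N"]].to_numpy()
        p1 = sample_posterior(c, s, t, mcmc=FAST)
        p2 = sample_posterior(c, s, t, mcmc=FAST)
        assert np.array_equal(p1.p_draws, p2.p_draws)

    def test_parameter_recovery_single_replicate(self):
        sc = IsotopeScenario(true_p=(0.2, 0.5, 0.3), seed=7)
        cons, s, t = generate_consumers(sc)
        post = sample_posterior(
            cons[["d13C", "d15N"]].to_numpy(), s, t, mcmc=MCMCSettings(seed=7)
        )
        summ = post.summary()
        truth = np.array(sc.true_p)
        # a single replicate's median scatters by ~0.2 at n = 30; the
        # sharp bias/coverage checks live in the 20-replicate suite
        assert np.abs(summ["median"].to_numpy() - truth).max() < 0.3
        assert (
            (summ["ci_low"].to_numpy() <= truth)
            & (truth <= summ["ci_high"].to_numpy())
        ).all()
        assert post.converged

    def test_identifiability_corner(self):
        """Overwhelmingly precise data at one source pins the posterior."""
        names = ["a", "b", "c"]
        s = SourceSet(
            names, ["x", "y"],
            mu=[[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]],
            sigma=np.full((3, 2), 0.05),
            conc=np.full((3, 2), 0.3),
        )
        t = TDF(["x", "y"], [0.0, 0.0], [0.0, 0.0])
        consumers = np.tile([10.0, 0.0], (40, 1))  # exactly at source b
        post = sample_posterior(consumers, s, t, mcmc=FAST)
        assert post.summary().set_index("source").loc["b", "median"] > 0.9


class TestGelmanRubin:
    def test_identical_chains_unity(self):
        x = np.tile(np.sin(np.arange(100.0)), (4, 1))
        assert gelman_rubin(x) == pytest.approx(1.0, abs=0.05)

    def test_constant_chains_defined_as_one(self):
        assert gelman_rubin(np.ones((4, 50))) == 1.0

    def test_disjoint_chains_flagged(self, rng):
        a = rng.normal(0.0, 1.0, 1000)
        b = rng.normal(10.0, 1.0, 1000)
        assert gelman_rubin(np.stack([a, b])) > 1.1

    def test_iid_chains_near_one(self, rng):
        x = rng.standard_normal((4, 2000))
        assert gelman_rubin(x) < 1.01

    def test_split_detects_trend(self, rng):
        # one long trending chain split in half is flagged even though
        # the two original chains look alike
        trend = np.linspace(0, 5, 2000) + rng.standard_normal(2000) * 0.1
        assert gelman_rubin(np.stack([trend, trend])) > 1.1


class TestTracerComparison:
    def test_duplicated_set_scores_equal(self):
        cons, s, t = generate_consumers(IsotopeScenario(seed=3))
        out = compare_tracer_sets(
            cons, s, t, tracer_sets=[("d13C", "d15N"), ("d13C", "d15N")],
            mcmc=FAST,
        )
        assert abs(out["looic"].iloc[0] - out["looic"].iloc[1]) < 2.0

    def test_ranking_invariant_to_order(self):
        sc = IsotopeScenario(tracers=("d13C", "d15N", "d34S"), seed=4)
        cons, s, t3 = generate_consumers(sc)
        t = TDF(["d13C", "d15N", "d34S"],
                [0.82, 2.1, 0.0], [1.13, 1.0, 0.5])
        sets = [("d13C", "d15N"), ("d13C", "d15N", "d34S")]
        out1 = compare_tracer_sets(cons, s, t, tracer_sets=sets, mcmc=FAST)
        out2 = compare_tracer_sets(cons, s, t, tracer_sets=sets[::-1], mcmc=FAST)
        assert list(out1.sort_values("tracers")["looic"].round(6)) == list(
            out2.sort_values("tracers")["looic"].round(6)
        )

    def test_noise_tracer_penalized(self):
        """A pure-noise tracer should usually lose to the clean set."""
        wins = 0
        reps = 8
        for seed in range(reps):
            sc = IsotopeScenario(seed=seed)
            cons, s, t = generate_consumers(sc)
            rng = np.random.default_rng(1000 + seed)
            cons = cons.copy()
            cons["noise"] = rng.normal(0.0, 3.0, len(cons))
            s_aug = SourceSet(
                s.names, s.tracers + ["noise"],
                np.hstack([s.mu, np.zeros((3, 1))]),
                np.hstack([s.sigma, np.full((3, 1), 0.1)]),
                np.hstack([s.conc, np.full((3, 1), 0.1)]),
            )
            t_aug = TDF(t.tracers + ["noise"],
                        np.append(t.delta_mu, 0.0),
                        np.append(t.delta_sigma, 0.1))
            out = compare_tracer_sets(
                cons, s_aug, t_aug,
                tracer_sets=[("d13C", "d15N"), ("d13C", "d15N", "noise")],
                mcmc=MCMCSettings(n_iter=4000, n_burn=2000, thin=5,
                                  n_chains=4, seed=seed),
            )
            if out.iloc[0]["tracers"] == "d13C+d15N":
                wins += 1
        assert wins >= int(0.8 * reps)


class TestTimeLag:
    @pytest.mark.parametrize(
        "season,size_class,expected",
        [
            ("winter", "sub_adult", "summer"),  # 6-month lag
            ("winter", "adult", "spring"),      # 9-month lag
            ("spring", "sub_adult", "fall"),
            ("summer", "adult", "fall"),
        ],
    )
    def test_lag_mapping(self, season, size_class, expected):
        assert apply_time_lag(season, size_class) == expected

    def test_twelve_month_identity(self):
        seasons = ["spring", "summer", "fall", "winter"]
        assert apply_time_lag(seasons, "sub_adult", lag_months=12) == seasons

    def test_non_quarter_lag_rejected(self):
        with pytest.raises(ValueError):
            apply_time_lag("spring", "adult", lag_months=4)
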