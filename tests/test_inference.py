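import numpy as np
import pytest
from scipy import stats

from hicmrf.inference import (
    Chain,
    MCMCConfig,
    PriorConfig,
    empirical_bayes_hyperpriors,
    informative_prior,
    label_components,
    posterior_summaries,
    run_mcmc,
    update_betas,
    update_gamma_abc,
    update_tau,
)
from hicmrf.lattice import PairLattice
from hicmrf.model import emission_log_probs, potts_gibbs_sweep, simulate_potts_field
from hicmrf.observations import Observations
from hicmrf.synthetic import CovariateSpec, SimulationConfig, preset_config, simulate_dataset


def _flat_prior(K=2):
    return PriorConfig(
        mode="fixed",
        beta_prior_means=np.zeros((K, 5)),
        beta_prior_sds=np.ones((K, 5)),
    )


def _tiny_obs(rng, n=60):
    return Observations(
        i=np.zeros(n, dtype=np.int64), j=np.arange(n, dtype=np.int64),
        y=rng.poisson(3.0, n),
        D=rng.uniform(1, 10, n), GC=rng.uniform(0.3, 0.7, n),
        TE=rng.uniform(1, 4, n), ACC=rng.uniform(0.5, 2, n),
    )


class TestEmpiricalBayes:
    def test_deterministic(self, noise_heavy_dataset):
        obs = noise_heavy_dataset.observations
        a = empirical_bayes_hyperpriors(obs, 2)
        b = empirical_bayes_hyperpriors(obs, 2)
        assert np.array_equal(a.beta_prior_means, b.beta_prior_means)
        assert np.array_equal(a.beta_prior_sds, b.beta_prior_sds)

    def test_identical_counts_refused(self, rng):
        obs = _tiny_obs(rng)
        obs = Observations(i=obs.i, j=obs.j, y=np.full(len(obs), 4, dtype=np.int64),
                           D=obs.D, GC=obs.GC, TE=obs.TE, ACC=obs.ACC)
        with pytest.raises(ValueError, match="identical"):
            empirical_bayes_hyperpriors(obs, 2)

    def test_degenerate_covariate_named(self, rng):
        obs = _tiny_obs(rng)
        obs = Observations(i=obs.i, j=obs.j, y=obs.y, D=obs.D,
                           GC=np.full(len(obs), 0.5), TE=obs.TE, ACC=obs.ACC)
        with pytest.raises(ValueError, match="GC"):
            empirical_bayes_hyperpriors(obs, 2)

    def test_too_few_observations(self, rng):
        with pytest.raises(ValueError, match="50"):
            empirical_bayes_hyperpriors(_tiny_obs(rng, n=20), 2)

    def test_calibration_on_simulated_truth(self):
        # prior means within 2 prior sds of truth for >= 80% of coefficients
        hits = tot = 0
        for seed in range(20):
            cfg = preset_config("noise-heavy", seed=seed)
            ds = simulate_dataset(cfg)
            pr = empirical_bayes_hyperpriors(ds.observations, 2)
            ok = np.abs(pr.beta_prior_means - np.asarray(cfg.betas)) <= 2 * pr.beta_prior_sds
            hits += int(ok.sum())
            tot += ok.size
        assert hits / tot >= 0.8


class TestBetaUpdate:
    def test_zero_proposal_sd_keeps_chain_constant_with_full_acceptance(self, rng):
        obs = _tiny_obs(rng)
        betas = np.zeros((2, 5))
        z = rng.integers(1, 3, len(obs))
        new, acc = update_betas(betas, z, 0.2, obs, _flat_prior(), np.zeros((2, 5)), rng)
        assert np.array_equal(new, betas)
        assert acc.all()

    def test_tight_prior_pins_chain_at_prior_mean(self, rng):
        obs = _tiny_obs(rng)
        prior = PriorConfig(mode="fixed", beta_prior_means=np.zeros((2, 5)),
                            beta_prior_sds=np.full((2, 5), 1e-8))
        betas = np.zeros((2, 5))
        z = rng.integers(1, 3, len(obs))
        moved = 0
        for _ in range(50):
            betas, acc = update_betas(betas, z, 0.2, obs, prior, np.full((2, 5), 0.05), rng)
            moved += acc.sum()
        assert np.abs(betas).max() < 1e-3
        assert moved / (50 * 10) < 0.1  # moves away from the prior mean nearly all rejected


class TestTauUpdate:
    def test_no_noise_sites_draws_from_prior(self, rng):
        prior = PriorConfig(mode="fixed", beta_prior_means=np.zeros((2, 5)),
                            beta_prior_sds=np.ones((2, 5)), tau_prior=(8.0, 2.0))
        z = np.full(100, 2, dtype=np.int64)
        draws = [update_tau(0.5, z, np.ones(100), np.zeros(100, dtype=np.int64), prior, rng)
                 for _ in range(4000)]
        ks = stats.kstest(np.array(draws), lambda x: stats.beta.cdf(x, 8.0, 2.0))
        assert ks.pvalue > 0.01

    def test_all_zero_noise_with_huge_lambda_pushes_tau_to_one(self, rng):
        prior = _flat_prior()
        z = np.ones(500, dtype=np.int64)
        y = np.zeros(500, dtype=np.int64)
        lam = np.full(500, 50.0)  # Poisson zeros impossible: all zeros are "extra"
        tau = 0.5
        draws = [tau := update_tau(tau, z, lam, y, prior, rng) for _ in range(200)]
        assert np.mean(draws[50:]) > 0.95

    def test_recovery_of_true_tau(self):
        devs = []
        for seed in range(3):
            cfg = preset_config("noise-heavy", seed=seed, tau=0.4)
            ds = simulate_dataset(cfg)
            mc = MCMCConfig(iterations=600, burn_in=300, seed=seed)
            ch = run_mcmc(ds.observations, ds.lattice, 2, informative_prior(cfg.betas), mc)
            devs.append(abs(float(ch.tau.mean()) - 0.4))
        assert np.mean(devs) < 0.05


class TestGammaABC:
    def test_point_mass_prior_never_moves(self, rng):
        lat = PairLattice.rectangle(10, 10)
        z = rng.integers(1, 3, 100)
        prior = PriorConfig(mode="fixed", beta_prior_means=np.zeros((2, 5)),
                            beta_prior_sds=np.ones((2, 5)),
                            gamma_prior=(1e7, 1e7))  # essentially a point mass at 1/2
        cfg = MCMCConfig(iterations=10, burn_in=0, abc_pilot_draws=2, abc_sweeps=3)
        vals = set()
        g = 0.5
        for _ in range(50):
            g, _ = update_gamma_abc(g, z, 2, lat, prior, cfg, rng)
            vals.add(round(g, 3))
        assert vals == {0.5}

    def test_tolerance_infinite_reproduces_prior(self, rng):
        # quantile 1.0 removes the data constraint: accepts are prior draws
        lat = PairLattice.rectangle(10, 10)
        z = simulate_potts_field(lat, 0.5, 2, rng, 50)
        prior = _flat_prior()
        cfg = MCMCConfig(iterations=10, burn_in=0, abc_quantile=1.0,
                         abc_pilot_draws=2, abc_sweeps=2)
        acc = []
        g = 0.5
        for _ in range(5000):
            g, ok = update_gamma_abc(g, z, 2, lat, prior, cfg, rng)
            assert ok
            acc.append(g)
        ks = stats.kstest(np.array(acc), lambda x: stats.beta.cdf(x, 10, 5))
        assert ks.pvalue > 0.01


class TestRunMcmc:
    def test_bit_identical_under_seed(self, noise_heavy_dataset):
        ds = noise_heavy_dataset
        prior = informative_prior(ds.true_params.betas)
        cfg = MCMCConfig(iterations=120, burn_in=60, seed=99)
        a = run_mcmc(ds.observations, ds.lattice, 2, prior, cfg)
        b = run_mcmc(ds.observations, ds.lattice, 2, prior, cfg)
        assert np.array_equal(a.betas, b.betas)
        assert np.array_equal(a.tau, b.tau)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.label_freq, b.label_freq)

    def test_retained_draw_count_and_label_freq_rows(self, short_chain):
        cfg = short_chain.config
        assert short_chain.n_draws == (cfg.iterations - cfg.burn_in) // cfg.thinning
        assert np.allclose(short_chain.label_freq.sum(axis=1), 1.0, atol=1e-9)

    def test_posterior_means_stable_across_chains(self, noise_heavy_dataset, short_chain):
        """Independent chains (different proposal/update randomness) agree on
        the posterior means of the regression coefficients within 0.05."""
        ds = noise_heavy_dataset
        prior = informative_prior(ds.true_params.betas)
        cfg = MCMCConfig(iterations=600, burn_in=300, seed=901)
        other = run_mcmc(ds.observations, ds.lattice, 2, prior, cfg)
        assert np.abs(other.beta_means() - short_chain.beta_means()).max() < 0.05

    def test_prior_K_mismatch_rejected(self, noise_heavy_dataset):
        ds = noise_heavy_dataset
        with pytest.raises(ValueError, match="prior"):
            run_mcmc(ds.observations, ds.lattice, 3,
                     informative_prior(ds.true_params.betas), MCMCConfig(iterations=10, burn_in=5))

    def test_label_posterior_matches_enumeration_on_3x3(self, rng):
        """With parameters held fixed, long-run label occupancy must match the
        exact posterior enumerated over all 2^9 configurations (TV < 0.02)."""
        import itertools

        lat = PairLattice.rectangle(3, 3)
        tau, gamma = 0.3, 0.6
        y = np.array([0, 1, 0, 5, 8, 0, 2, 7, 1])
        lams = np.column_stack([np.full(9, 0.8), np.full(9, 6.0)])
        le = emission_log_probs(y, tau, lams)
        configs = np.array(list(itertools.product((1, 2), repeat=9)))
        logp = np.array(
            [gamma * lat.concordant_pairs(z) + le[np.arange(9), z - 1].sum() for z in configs]
        )
        p = np.exp(logp - logp.max())
        p /= p.sum()
        pw = 2 ** np.arange(8, -1, -1)
        z = rng.integers(1, 3, 9)
        counts = np.zeros(len(p))
        sweeps = 30_000
        for _ in range(sweeps):
            potts_gibbs_sweep(z, gamma, lat, 2, rng, log_emissions=le)
            counts[int(((z - 1) * pw).sum())] += 1
        tv = 0.5 * np.abs(counts / sweeps - p).sum()
        assert tv < 0.02


class TestChainSummaries:
    def _const_chain(self, value=1.5, n=200, K=2):
        return Chain(
            tau=np.full(n, 0.3), betas=np.full((n, K, 5), value), gamma=np.full(n, 0.4),
            complete_loglik=np.zeros(n), label_freq=np.full((10, K), 1.0 / K),
            acceptance_rates={}, prior=_flat_prior(K),
            config=MCMCConfig(iterations=2 * n, burn_in=n),
        )

    def test_constant_chain_degenerate_interval(self):
        df = posterior_summaries(self._const_chain(1.5))
        row = df[df.parameter == "b0_k1"].iloc[0]
        assert row["mean"] == row.ci_low == row.ci_high == 1.5

    def test_normal_sample_interval(self, rng):
        n = 100_000
        ch = self._const_chain(n=n)
        ch = Chain(tau=ch.tau[:n], betas=ch.betas, gamma=rng.normal(size=n),
                   complete_loglik=ch.complete_loglik, label_freq=ch.label_freq,
                   acceptance_rates={}, prior=ch.prior, config=ch.config)
        row = posterior_summaries(ch).set_index("parameter").loc["gamma"]
        assert row.ci_low == pytest.approx(-1.96, abs=0.05)
        assert row.ci_high == pytest.approx(1.96, abs=0.05)
        assert not row.significant  # interval covers 0 -> not significant

    def test_interval_excluding_zero_flagged(self):
        df = posterior_summaries(self._const_chain(0.7))
        assert bool(df[df.parameter == "b0_k1"].significant.iloc[0])

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="100"):
            posterior_summaries(self._const_chain(n=50))


class TestRoleMapping:
    def _chain_with_means(self, intercepts):
        K = len(intercepts)
        n = 150
        betas = np.zeros((n, K, 5))
        for k, b0 in enumerate(intercepts):
            betas[:, k, 0] = b0
        return Chain(
            tau=np.full(n, 0.2), betas=betas, gamma=np.zeros(n),
            complete_loglik=np.zeros(n), label_freq=np.full((4, K), 1.0 / K),
            acceptance_rates={}, prior=_flat_prior(K),
            config=MCMCConfig(iterations=300, burn_in=150),
        )

    def _obs4(self, rng):
        return _tiny_obs(rng, n=4)

    def test_two_component_ordering(self, rng):
        ch = self._chain_with_means([np.log(0.5), np.log(20)])
        roles = label_components(ch, self._obs4(rng))
        assert roles["role_of_component"] == {0: "noise", 1: "signal"}

    def test_three_component_ordering(self, rng):
        ch = self._chain_with_means([np.log(20), np.log(0.5), np.log(900)])
        roles = label_components(ch, self._obs4(rng))
        assert roles["role_of_component"] == {1: "noise", 0: "signal", 2: "false_signal"}

    def test_permutation_invariance(self, rng):
        obs = self._obs4(rng)
        ch = self._chain_with_means([np.log(0.5), np.log(900), np.log(20)])
        perm = [2, 0, 1]
        ch2 = Chain(tau=ch.tau, betas=ch.betas[:, perm, :], gamma=ch.gamma,
                    complete_loglik=ch.complete_loglik, label_freq=ch.label_freq[:, perm],
                    acceptance_rates={}, prior=_flat_prior(3), config=ch.config)
        r1 = label_components(ch, obs)
        r2 = label_components(ch2, obs)
        assert sorted(r1["lam_bar"]) == pytest.approx(sorted(r2["lam_bar"]))
        roles1 = [r1["role_of_component"][int(k)] for k in r1["order"]]
        roles2 = [r2["role_of_component"][int(k)] for k in r2["order"]]
        assert roles1 == roles2 == ["noise", "signal", "false_signal"]

    def test_tied_means_unidentifiable(self, rng):
        ch = self._chain_with_means([1.0, 1.0])
        with pytest.raises(ValueError, match="tie"):
            label_components(ch, self._obs4(rng))
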