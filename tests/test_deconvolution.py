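"""Bayesian deconvolution: convolution, likelihood, MCMC and oracles."""

import itertools

import numpy as np
import pytest

from burstdecon import _mcmc
from burstdecon.deconvolution import (
    ActivityTrace,
    InitiationConfig,
    TraceDeconvolver,
    build_prior,
    convolve,
    infer_elongation_joint,
    log_likelihood,
    rate_from_samples,
    sample_posterior,
)
from burstdecon.gene_model import GeneModel, build_kernel
from burstdecon.noise_model import NoiseModel
from burstdecon.synthetic import (
    _events_to_fine_counts,
    simulate_gillespie,
    synthesize_activity,
)
from burstdecon.two_state import TwoStateParams


@pytest.fixture(scope="module")
def toy():
    """12-fine-step setting (coarse = fine grid) for exhaustive oracles."""
    gm = GeneModel(100.0, np.array([30.0]), 0.2)  # 3-step boxcar kernel
    nm = NoiseModel(sigma_b=0.6, beta1=0.1)
    n_t, dt_fine = 13, 10.0
    kern = build_kernel(gm, dt_fine)
    return gm, nm, kern, n_t, dt_fine


def _brute_force_marginals(A, kern, nm, p_prior, n_t, u=1):
    logZ = -np.inf
    marg = np.zeros(len(p_prior))
    weights = []
    configs = []
    for bits in itertools.product([0, 1], repeat=len(p_prior)):
        I = np.array(bits, dtype=np.uint8)
        G = _mcmc.compute_g(I, kern.weights, kern.n_steps, u, n_t)
        ll = _mcmc.gaussian_loglik(A, G, nm.sigma_b**2, nm.beta1)
        lp = float(np.sum(np.where(I == 1, np.log(p_prior), np.log(1 - p_prior))))
        weights.append(ll + lp)
        configs.append(I)
    weights = np.asarray(weights)
    w = np.exp(weights - weights.max())
    w /= w.sum()
    marg = np.sum(w[:, None] * np.asarray(configs), axis=0)
    return marg, configs[int(np.argmax(weights))]


class TestConvolve:
    def test_zero_config_gives_zero_signal(self, toy):
        gm, nm, kern, n_t, dt_fine = toy
        cfg = InitiationConfig(dt_fine, np.zeros(n_t - 1, dtype=np.uint8))
        np.testing.assert_array_equal(convolve(cfg, kern, n_t, 1), 0.0)

    def test_single_event_is_shifted_kernel(self, toy):
        gm, nm, kern, n_t, dt_fine = toy
        ev = np.zeros(n_t - 1, dtype=np.uint8)
        ev[4] = 1
        G = convolve(InitiationConfig(dt_fine, ev), kern, n_t, 1)
        expected = np.zeros(n_t)
        for j in range(kern.n_steps):
            if 5 + j < n_t:
                expected[5 + j] = kern.weights[j]
        np.testing.assert_allclose(G, expected)

    def test_superposition(self, toy):
        gm, nm, kern, n_t, dt_fine = toy
        e1 = np.zeros(n_t - 1, dtype=np.uint8)
        e2 = np.zeros(n_t - 1, dtype=np.uint8)
        e1[2] = 1
        e2[7] = 1
        both = (e1 | e2).astype(np.uint8)
        G = convolve(InitiationConfig(dt_fine, both), kern, n_t, 1)
        G1 = convolve(InitiationConfig(dt_fine, e1), kern, n_t, 1)
        G2 = convolve(InitiationConfig(dt_fine, e2), kern, n_t, 1)
        np.testing.assert_allclose(G, G1 + G2)

    def test_mismatched_dt_raises(self, toy):
        gm, nm, kern, n_t, dt_fine = toy
        cfg = InitiationConfig(2.0, np.zeros(n_t - 1, dtype=np.uint8))
        with pytest.raises(ValueError):
            convolve(cfg, kern, n_t, 1)


class TestLogLikelihood:
    def test_flat_zero_trace_exact_value(self, toy):
        gm, nm, kern, n_t, dt_fine = toy
        times = np.arange(n_t) * dt_fine / 60.0
        tr = ActivityTrace(times, np.zeros(n_t))
        cfg = InitiationConfig(dt_fine, np.zeros(n_t - 1, dtype=np.uint8))
        ll = log_likelihood(tr, cfg, kern, nm)
        expected = n_t * (-0.5 * np.log(2 * np.pi * nm.sigma_b**2))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_spurious_event_lowers_likelihood(self, toy):
        gm, nm, kern, n_t, dt_fine = toy
        true = np.zeros(n_t - 1, dtype=np.uint8)
        true[3] = 1
        G = _mcmc.compute_g(true, kern.weights, kern.n_steps, 1, n_t)
        times = np.arange(n_t) * dt_fine / 60.0
        tr = ActivityTrace(times, G)  # noiseless observation
        ll_true = log_likelihood(tr, InitiationConfig(dt_fine, true), kern, nm)
        extra = true.copy()
        extra[8] = 1
        ll_extra = log_likelihood(tr, InitiationConfig(dt_fine, extra), kern, nm)
        assert ll_extra < ll_true


class TestPrior:
    def test_constant_half_corresponds_to_half_max_rate(self, gap_gene):
        # p_i = R dt' with R = 30 mRNA/min and dt' = 1 s gives 1/2
        assert 30.0 * (1.0 / 60.0) == pytest.approx(0.5)

    def test_zero_mean_floors(self, gap_gene):
        p = build_prior(np.zeros(30), gap_gene, 1 / 6, 1.0, 30)
        np.testing.assert_allclose(p, 1e-4)

    def test_constant_mean_maps_to_rate(self, gap_gene):
        R0 = 4.0
        tau = gap_gene.elongation_time_min
        p = build_prior(np.full(30, tau * R0), gap_gene, 1 / 6, 1.0, 30)
        np.testing.assert_allclose(p, R0 / 60.0, rtol=1e-9)


class TestMCMCOracle:
    def test_marginals_match_exhaustive_enumeration(self, toy):
        gm, nm, kern, n_t, dt_fine = toy
        rng = np.random.default_rng(0)
        true = np.zeros(n_t - 1, dtype=np.uint8)
        true[[2, 3, 7]] = 1
        G = _mcmc.compute_g(true, kern.weights, kern.n_steps, 1, n_t)
        A = G + 0.5 * nm.sd(G) * rng.standard_normal(n_t)
        times = np.arange(n_t) * dt_fine / 60.0
        prior_mean = np.full(n_t, 0.5)
        p_prior = build_prior(prior_mean, gm, dt_fine / 60.0, dt_fine, n_t)
        marg_exact, _ = _brute_force_marginals(A, kern, nm, p_prior, n_t)

        dec = TraceDeconvolver(
            gm, nm, dt_fine=dt_fine, n_samples=10500, n_burn=500,
            n_keep=10000, random_state=11,
        )
        dec.fit(ActivityTrace(times, A), prior_mean=prior_mean)
        marg_mcmc = dec.samples_[0].marginal()
        # per-step Bernoulli total-variation distance
        assert np.abs(marg_mcmc - marg_exact).max() < 0.05

    def test_event_recovery_on_clean_sparse_trace(self, toy):
        gm, nm_loud, kern, n_t_small, dt_fine = toy
        nm = NoiseModel(sigma_b=0.15, beta1=0.01)
        n_t = 40
        rng = np.random.default_rng(5)
        true = np.zeros(n_t - 1, dtype=np.uint8)
        true[[5, 14, 27]] = 1
        G = _mcmc.compute_g(true, kern.weights, kern.n_steps, 1, n_t)
        A = G + nm.sd(G) * rng.standard_normal(n_t)
        times = np.arange(n_t) * dt_fine / 60.0
        ps = sample_posterior(
            ActivityTrace(times, A), gm, nm, dt_fine=dt_fine,
            prior_mean=np.full(n_t, 0.3), n_samples=2000, n_burn=300,
            n_keep=1000, seed=3,
        )
        marg = ps.marginal()
        assert np.all(marg[[5, 14, 27]] > 0.9)
        mask = np.ones(n_t - 1, bool)
        mask[[5, 14, 27]] = False
        assert np.all(marg[mask] < 0.1)

    def test_acceptance_rate_in_band(self, gap_gene, noise):
        p1 = TwoStateParams.from_occupancy(8.0, 0.4, 2.0)
        rng = np.random.default_rng(1)
        n_t = 121
        counts = [
            _events_to_fine_counts(
                simulate_gillespie(p1, 20.0, rng)[0], n_t * 10 - 1, 1.0
            )
            for _ in range(2)
        ]
        A = synthesize_activity(counts, gap_gene, noise, n_t, 10.0, 1.0, rng)
        tr = ActivityTrace(np.arange(n_t) / 6.0, A)
        ps = sample_posterior(tr, gap_gene, noise, n_samples=800, n_burn=200,
                              n_keep=200, seed=2)
        assert 0.10 <= ps.acceptance_rate <= 0.70

    def test_posterior_predictive_coverage(self, gap_gene, noise):
        p1 = TwoStateParams.from_occupancy(8.0, 0.5, 2.0)
        rng = np.random.default_rng(8)
        n_t = 121
        counts = [
            _events_to_fine_counts(
                simulate_gillespie(p1, 20.0, rng)[0], n_t * 10 - 1, 1.0
            )
            for _ in range(2)
        ]
        A = synthesize_activity(counts, gap_gene, noise, n_t, 10.0, 1.0, rng)
        tr = ActivityTrace(np.arange(n_t) / 6.0, A)
        ps = sample_posterior(tr, gap_gene, noise, n_samples=1200, n_burn=300,
                              n_keep=300, seed=4)
        kern = build_kernel(gap_gene, 1.0)
        within = 0
        total = 0
        for cfg in ps.configs[::30]:
            G = _mcmc.compute_g(cfg, kern.weights, kern.n_steps, 10, n_t)
            z = (A - G) / noise.sd(G)
            within += np.sum(np.abs(z) <= 2.0)
            total += n_t
        assert within / total >= 0.90

    def test_determinism(self, toy):
        gm, nm, kern, n_t, dt_fine = toy
        rng = np.random.default_rng(2)
        A = np.abs(rng.standard_normal(n_t))
        tr = ActivityTrace(np.arange(n_t) * dt_fine / 60.0, A)
        kwargs = dict(dt_fine=dt_fine, n_samples=300, n_burn=50, n_keep=100)
        a = sample_posterior(tr, gm, nm, seed=9, **kwargs)
        b = sample_posterior(tr, gm, nm, seed=9, **kwargs)
        np.testing.assert_array_equal(a.configs, b.configs)


class TestRates:
    def test_window_arithmetic(self):
        configs = np.zeros((1, 29), dtype=np.uint8)
        configs[0, [10, 12, 14]] = 1  # three events in (t1, t2] window
        from burstdecon.deconvolution import PosteriorSamples

        ps = PosteriorSamples(
            configs=configs, proposal_probs=np.zeros(29), dt_fine=1.0,
            dt=10 / 60.0, n_t=3,
        )
        rates, mean, sd = rate_from_samples(ps, v=1)
        assert rates[0, 2] == pytest.approx(3 / (10 / 60.0))  # 18 mRNA/min
        assert rates[0, 0] == 0.0

    def test_empty_config_zero_everywhere(self):
        from burstdecon.deconvolution import PosteriorSamples

        ps = PosteriorSamples(
            configs=np.zeros((2, 59), dtype=np.uint8),
            proposal_probs=np.zeros(59), dt_fine=1.0, dt=1 / 6.0, n_t=6,
        )
        rates, _, _ = rate_from_samples(ps, v=1)
        np.testing.assert_array_equal(rates, 0.0)

    def test_one_minute_window_granularity(self):
        rng = np.random.default_rng(0)
        from burstdecon.deconvolution import PosteriorSamples

        configs = (rng.random((5, 119)) < 0.2).astype(np.uint8)
        ps = PosteriorSamples(
            configs=configs, proposal_probs=np.zeros(119), dt_fine=1.0,
            dt=10 / 60.0, n_t=12,
        )
        rates, _, _ = rate_from_samples(ps, v=6)
        # with a 1-min window the possible rates are whole events per minute
        frac = rates - np.round(rates)
        np.testing.assert_allclose(frac, 0.0, atol=1e-9)


class TestDualColorElongation:
    @pytest.fixture(scope="class")
    def cassette_pair(self):
        gm_5p = GeneModel(3600.0, np.linspace(150, 1450, 24), 1.8)
        gm_3p = GeneModel(3600.0, np.linspace(2100, 3400, 24), 1.8)
        return gm_5p, gm_3p

    def test_noiseless_delay_between_channels(self, cassette_pair):
        # a single transcript lights up the 3' cassette (l_1r - l_1g)/K_elo
        # minutes after the 5' one; the kernel centroids differ by the
        # mean-loop separation over 2 K_elo (each loop's boxcar is centered
        # midway between its end position and the gene end)
        gm_5p, gm_3p = cassette_pair
        n_fine = 1500
        ev = np.zeros(n_fine, dtype=np.int64)
        ev[0] = 1
        Ag = synthesize_activity(ev, gm_5p, None, 150, 10.0, 1.0)
        Ar = synthesize_activity(ev, gm_3p, None, 150, 10.0, 1.0)
        onset_g = np.flatnonzero(Ag > 0)[0] / 6.0
        onset_r = np.flatnonzero(Ar > 0)[0] / 6.0
        onset_pred = (gm_3p.loop_ends_bp[0] - gm_5p.loop_ends_bp[0]) / 1.8e3
        assert onset_r - onset_g == pytest.approx(onset_pred, abs=1 / 6.0)
        t = np.arange(150) / 6.0
        centroid_delay = np.sum(t * Ar) / Ar.sum() - np.sum(t * Ag) / Ag.sum()
        mean_sep = (
            np.mean(gm_3p.loop_ends_bp) - np.mean(gm_5p.loop_ends_bp)
        ) / 1.8e3
        assert centroid_delay == pytest.approx(mean_sep / 2.0, abs=1 / 6.0)

    def test_recovers_elongation_rate(self, cassette_pair):
        gm_5p, gm_3p = cassette_pair
        nm = NoiseModel()
        p1 = TwoStateParams.from_occupancy(8.0, 0.4, 2.0)
        rng = np.random.default_rng(2024)
        n_t = 301
        times = np.arange(n_t) / 6.0
        means = []
        for pair in range(20):
            counts = [
                _events_to_fine_counts(
                    simulate_gillespie(p1, 50.0, rng)[0], n_t * 10 - 1, 1.0
                )
                for _ in range(2)
            ]
            Ag = synthesize_activity(counts, gm_5p, nm, n_t, 10.0, 1.0, rng)
            Ar = synthesize_activity(counts, gm_3p, nm, n_t, 10.0, 1.0, rng)
            gm_g0 = GeneModel(3600.0, gm_5p.loop_ends_bp, 1.4)
            gm_r0 = GeneModel(3600.0, gm_3p.loop_ends_bp, 1.4)
            ks, _, flagged = infer_elongation_joint(
                ActivityTrace(times, Ag), ActivityTrace(times, Ar),
                gm_g0, gm_r0, nm, nm, seed=1000 + pair,
                n_samples=400, n_burn=120,
            )
            assert not flagged
            means.append(ks.mean())
        assert np.mean(means) == pytest.approx(1.8, rel=0.15)

    def test_identical_kernels_flagged(self, cassette_pair):
        gm_5p, _ = cassette_pair
        nm = NoiseModel()
        rng = np.random.default_rng(4)
        n_t = 61
        times = np.arange(n_t) / 6.0
        A = np.abs(rng.standard_normal(n_t)) * 3
        _, _, flagged = infer_elongation_joint(
            ActivityTrace(times, A), ActivityTrace(times, A),
            gm_5p, gm_5p, nm, nm, seed=0, n_samples=10, n_burn=5,
        )
        assert flagged

    def test_inconsistent_time_bases_raise(self, cassette_pair):
        gm_5p, gm_3p = cassette_pair
        nm = NoiseModel()
        a = ActivityTrace(np.arange(20) / 6.0, np.zeros(20))
        b = ActivityTrace(np.arange(30) / 6.0, np.zeros(30))
        with pytest.raises(ValueError):
            infer_elongation_joint(a, b, gm_5p, gm_3p, nm, nm)
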