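"""Telegraph-model analytics against simulation and closed-form oracles."""

import numpy as np
import pytest

from burstdecon.synthetic import simulate_gillespie
from burstdecon.two_state import (
    PropagatorSet,
    TwoStateParams,
    build_propagator,
    expected_on_off_times,
    expected_pon,
    model_autocorrelation,
    residence_distributions,
    sigma_ac,
    stationary_moments,
    telegraph_propagator_closed_form,
    two_copy_stationary_times,
)


def _gillespie_counts(p, duration, n_runs, seed, window=None):
    """Event counts per run (or per window) from exact simulation."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_runs):
        ev, _, _ = simulate_gillespie(p, duration, rng)
        if window is None:
            out.append(ev.size)
        else:
            out.append(np.histogram(ev, bins=np.arange(0, duration + 1e-9, window))[0])
    return np.asarray(out)


class TestStationaryMoments:
    def test_zero_time(self):
        p = TwoStateParams.from_occupancy(8.0, 0.4, 2.0)
        assert stationary_moments(p, 0.0) == (0.0, 0.0, 0.0, 0.0)

    def test_fast_switching_poisson_limit(self):
        p = TwoStateParams.from_occupancy(8.0, 0.5, 1e-7)
        g, _, _, g2 = stationary_moments(p, 3.0)
        var = g2 - g**2
        assert var == pytest.approx(g, rel=1e-4)

    def test_conditional_means_sum(self):
        p = TwoStateParams.from_occupancy(8.0, 0.3, 1.5)
        g, g1, g0, _ = stationary_moments(p, 2.5)
        assert g1 + g0 == pytest.approx(g, rel=1e-12)

    def test_against_gillespie(self):
        p = TwoStateParams.from_occupancy(8.0, 0.5, 1.0)
        counts = _gillespie_counts(p, 2.0, 20000, seed=5)
        g, _, _, g2 = stationary_moments(p, 2.0)
        var = g2 - g**2
        se_mean = counts.std() / np.sqrt(counts.size)
        assert counts.mean() == pytest.approx(g, abs=3 * se_mean)
        # variance SE from the fourth moment
        m4 = np.mean((counts - counts.mean()) ** 4)
        se_var = np.sqrt((m4 - counts.var() ** 2) / counts.size)
        assert counts.var() == pytest.approx(var, abs=3 * se_var)


class TestModelAutocorrelation:
    def test_unity_at_zero_lag(self):
        p = TwoStateParams.from_occupancy(8.0, 0.3, 2.0)
        for w in (1 / 6, 1.4):
            assert model_autocorrelation(p, w, 0.0) == pytest.approx(1.0, rel=1e-9)

    def test_pure_exponential_beyond_window(self):
        p = TwoStateParams.from_occupancy(8.0, 0.3, 2.0)
        w = 0.5
        r1 = model_autocorrelation(p, w, 1.0)
        r2 = model_autocorrelation(p, w, 3.0)
        assert r2 / r1 == pytest.approx(np.exp(-2.0 / p.T), rel=1e-9)

    def test_matches_sigma_ac_at_first_lag(self):
        p = TwoStateParams.from_occupancy(8.0, 0.3, 2.0)
        dt = 1 / 6
        assert model_autocorrelation(p, dt, dt) == pytest.approx(
            sigma_ac(p, dt), rel=1e-9
        )

    def test_against_gillespie_windowed_counts(self):
        p = TwoStateParams.from_occupancy(8.0, 0.3, 2.0)
        dt = 1 / 6
        counts = _gillespie_counts(p, 20.0, 1500, seed=9, window=dt)
        dev = counts - counts.mean(axis=0)
        sd = counts.std(axis=0)
        for lag in (1, 3, 6):
            emp = np.mean(dev[:, :-lag] * dev[:, lag:], axis=0) / (
                sd[:-lag] * sd[lag:]
            )
            se = emp.std() / np.sqrt(emp.size) + 1.0 / np.sqrt(counts.shape[0])
            assert np.mean(emp) == pytest.approx(
                model_autocorrelation(p, dt, lag * dt), abs=3 * se
            )


class TestSigmaAC:
    def test_vanishes_at_small_dt(self):
        p = TwoStateParams.from_occupancy(8.0, 0.3, 2.0)
        assert sigma_ac(p, 1e-6) < 1e-5

    def test_filter_function_values(self):
        # phi2(1) = (1-1/e)^2
        p = TwoStateParams.from_occupancy(0.0, 0.5, 1.0)  # k=0: numerator 0
        assert sigma_ac(p, 1.0) == 0.0
        from burstdecon.two_state import _phi1, _phi2

        assert _phi2(np.array([1.0]))[0] == pytest.approx(0.39958, abs=1e-4)
        assert _phi1(np.array([1e-9]))[0] == pytest.approx(1.0, abs=1e-6)
        assert _phi2(np.array([1e-9]))[0] == pytest.approx(1.0, abs=1e-6)

    def test_scaling_with_k_and_eta(self):
        # amplitude grows with k at fixed eta, falls with eta at fixed R
        dt, T = 1 / 6, 2.0
        vals_k = [
            sigma_ac(TwoStateParams.from_occupancy(k, 0.3, T), dt)
            for k in (2.0, 6.0, 12.0)
        ]
        assert np.all(np.diff(vals_k) > 0)
        R = 4.0
        vals_eta = [
            sigma_ac(TwoStateParams.from_occupancy(R / eta, eta, T), dt)
            for eta in (0.2, 0.5, 0.8)
        ]
        assert np.all(np.diff(vals_eta) < 0)


class TestPropagators:
    def test_matches_single_copy_closed_form(self):
        p = TwoStateParams.from_occupancy(8.0, 0.35, 1.3)
        times = np.array([0.0, 0.7])
        ps = build_propagator(p.k_on, p.k_off, times, n_copies=1)
        U_exact = telegraph_propagator_closed_form(p, 0.7)
        np.testing.assert_allclose(ps.steps[0], U_exact, atol=1e-8)

    def test_zero_lag_identity(self):
        ps = build_propagator(1.0, 2.0, np.array([0.0, 1e-12]), n_copies=2)
        np.testing.assert_allclose(ps.steps[0], np.eye(3), atol=1e-9)

    def test_columns_stochastic_after_composition(self):
        times = np.linspace(0, 10, 61)
        k_on = 0.5 + 0.4 * np.sin(times)
        k_off = 0.8 + 0.2 * np.cos(times / 2)
        ps = build_propagator(k_on, k_off, times, n_copies=2)
        U = ps.compose()
        np.testing.assert_allclose(U.sum(axis=0), 1.0, atol=1e-10)
        assert np.all((U >= -1e-12) & (U <= 1 + 1e-12))

    def test_two_copy_stationary_is_binomial(self):
        eta = 0.3
        p = TwoStateParams.from_occupancy(1.0, eta, 1.0)
        ps = build_propagator(p.k_on, p.k_off, np.linspace(0, 200, 101), 2)
        U = ps.compose()
        stat = U @ np.array([1.0, 0.0, 0.0])
        expected = [(1 - eta) ** 2, 2 * eta * (1 - eta), eta**2]
        np.testing.assert_allclose(stat, expected, atol=1e-8)


class TestExpectedPon:
    def test_stationary_start_stays_flat(self):
        eta = 0.4
        p = TwoStateParams.from_occupancy(1.0, eta, 1.0)
        ps = build_propagator(p.k_on, p.k_off, np.linspace(0, 5, 31), 1)
        pon = expected_pon(ps, np.array([1 - eta, eta]))
        np.testing.assert_allclose(pon, eta, atol=1e-10)

    def test_relaxation_from_off_closed_form(self):
        p = TwoStateParams.from_occupancy(1.0, 0.6, 0.8)
        times = np.linspace(0, 4, 25)
        ps = build_propagator(p.k_on, p.k_off, times, 1)
        pon = expected_pon(ps, np.array([1.0, 0.0]))
        expected = p.eta * (1 - np.exp(-times / p.T))
        np.testing.assert_allclose(pon, expected, atol=1e-8)

    def test_two_copies_from_all_off_independence(self):
        p = TwoStateParams.from_occupancy(1.0, 0.6, 0.8)
        times = np.linspace(0, 4, 25)
        ps1 = build_propagator(p.k_on, p.k_off, times, 1)
        ps2 = build_propagator(p.k_on, p.k_off, times, 2)
        pon1 = expected_pon(ps1, np.array([1.0, 0.0]))
        pon2 = expected_pon(ps2, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(pon2, 1 - (1 - pon1) ** 2, atol=1e-8)

    def test_unnormalized_initial_raises(self):
        ps = build_propagator(1.0, 1.0, np.array([0.0, 1.0]), 1)
        with pytest.raises(ValueError):
            expected_pon(ps, np.array([0.6, 0.6]))


class TestResidenceTimes:
    @staticmethod
    def _stationary_setup(k_on, k_off, t_max, dt, n_copies=2):
        p = TwoStateParams(1.0, k_on, k_off)
        times = np.arange(0.0, t_max + 1e-9, dt)
        ps = build_propagator(k_on, k_off, times, n_copies)
        eta = p.eta
        if n_copies == 2:
            p0 = np.array([(1 - eta) ** 2, 2 * eta * (1 - eta), eta**2])
        else:
            p0 = np.array([1 - eta, eta])
        return ps, p0, times

    def test_normalization_and_no_zero_durations(self):
        ps, p0, _ = self._stationary_setup(1.0, 1.0, 20.0, 1 / 6)
        W, Z = residence_distributions(ps, (1, 2), (0,), p0)
        n_t = W.shape[0]
        np.testing.assert_allclose(W.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(np.diag(W)[: n_t - 1] == 0.0)
        assert np.all(W >= -1e-12)

    def test_overlapping_sets_raise(self):
        ps, p0, _ = self._stationary_setup(1.0, 1.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            residence_distributions(ps, (0, 1), (1, 2), p0)

    def test_single_copy_mean_on_residence(self):
        # fine grid: mean ON first-passage approaches 1/k_off
        k_off = 0.5
        ps, p0, times = self._stationary_setup(1.0, k_off, 40.0, 0.02, n_copies=1)
        W, Z = residence_distributions(ps, (1,), (0,), p0)
        i = 50
        mean_dur = np.sum(W[:, i] * (times - times[i]))
        assert mean_dur == pytest.approx(1 / k_off, rel=0.05)

    def test_censoring_bends_durations_down_at_edges(self):
        ps, p0, times = self._stationary_setup(0.5, 0.5, 60.0, 1 / 6)
        W, Z = residence_distributions(ps, (1, 2), (0,), p0)
        T = expected_on_off_times(W, Z, times)
        interior = np.nanmedian(T[len(T) // 3 : 2 * len(T) // 3])
        assert T[2] < interior
        assert np.nanmean(T[2:5]) < interior

    def test_interior_matches_two_copy_closed_forms_fine_grid(self):
        # small steps and a long grid: the settling-weighted durations
        # converge to the stationary phase-type means
        k_on, k_off = 1.0, 1.0
        t_off_cf, t_on_cf = two_copy_stationary_times(k_on, k_off)
        ps, p0, times = self._stationary_setup(k_on, k_off, 60.0, 0.01)
        W_on, Z_on = residence_distributions(ps, (1, 2), (0,), p0)
        W_off, Z_off = residence_distributions(ps, (0,), (1, 2), p0)
        t_on = expected_on_off_times(W_on, Z_on, times)
        t_off = expected_on_off_times(W_off, Z_off, times)
        mid = slice(len(times) // 3, 2 * len(times) // 3)
        assert np.nanmedian(t_on[mid]) == pytest.approx(t_on_cf, rel=0.02)
        assert np.nanmedian(t_off[mid]) == pytest.approx(t_off_cf, rel=0.02)


class TestTwoCopyStationaryTimes:
    def test_plug_in_values(self):
        t_off, t_on = two_copy_stationary_times(1.0, 1.0)
        assert t_off == pytest.approx(0.5, abs=1e-12)
        assert t_on == pytest.approx(1.5, abs=1e-12)

    def test_phase_type_oracle(self):
        # independent CTMC mean-absorption oracle: solve (Q_rr) m = -1
        k_on, k_off = 0.7, 1.9
        # ON set {1,2}, absorbing {0}; generator restricted to {1,2}
        Q = np.array(
            [[-(k_off + k_on), 2 * k_off], [k_on, -2 * k_off]]
        )
        m = np.linalg.solve(Q.T, -np.ones(2))
        # entry distribution into ON: from state 0 -> state 1 always
        t_on_oracle = m[0]
        _, t_on = two_copy_stationary_times(k_on, k_off)
        assert t_on == pytest.approx(t_on_oracle, rel=1e-9)

    def test_fast_off_limit(self):
        _, t_on = two_copy_stationary_times(1.0, 1e6)
        assert t_on < 1e-5

    def test_consistency_with_single_copy_correlation_time(self):
        k_on, k_off = 0.8, 1.3
        t_off, t_on = two_copy_stationary_times(k_on, k_off)
        tc1 = 1.0 / (k_on + k_off)
        pon1 = k_on / (k_on + k_off)
        lhs = t_on * t_off / (t_on + t_off)
        assert lhs == pytest.approx(tc1 * (2 - pon1) / 2, rel=1e-9)

    def test_zero_rates_raise(self):
        with pytest.raises(ValueError):
            two_copy_stationary_times(0.0, 1.0)
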