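"""Closed-form and propagator-based predictions for the telegraph model.

A promoter toggles between OFF (n=0) and ON (n=1) with rates ``k_on`` and
``k_off`` (1/min) and initiates transcripts at rate ``k`` (mRNA/min) while
ON.  Derived quantities: stationary occupancy ``eta = k_on/(k_on+k_off)``
and switching correlation time ``T = 1/(k_on+k_off)``.

The module provides

* stationary moments of the event count over a window,
* the closed-form autocorrelation of windowed event counts (two regimes:
  lag below / above the integration window),
* the one-lag correlated-fluctuation amplitude ``Sigma_AC``,
* time-ordered-exponential propagators for one or two independent gene
  copies with (possibly) time-dependent rates,
* censoring-aware first-passage (residence-time) distributions on a finite
  grid, matching the empirical ON/OFF-duration estimator, and their
  expected ON/OFF times,
* closed-form stationary two-copy residence times.

These are the ground-truth oracles against which the deconvolution and
burst-calling pipeline is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "TwoStateParams",
    "PropagatorSet",
    "stationary_moments",
    "telegraph_propagator_closed_form",
    "model_autocorrelation",
    "sigma_ac",
    "generator_matrix",
    "build_propagator",
    "expected_pon",
    "residence_distributions",
    "expected_on_off_times",
    "two_copy_stationary_times",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Telegraph-model rates; ``k`` in mRNA/min, switching rates in 1/min."""

    k: float
    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be non-negative")

    @property
    def eta(self) -> float:
        """Stationary ON-occupancy ``k_on / (k_on + k_off)``."""
        return self.k_on / (self.k_on + self.k_off)

    @property
    def T(self) -> float:
        """Switching correlation time ``1 / (k_on + k_off)`` (min)."""
        return 1.0 / (self.k_on + self.k_off)

    @classmethod
    def from_occupancy(cls, k: float, eta: float, T: float) -> "TwoStateParams":
        """Build from ``(k, eta, T)``: ``k_on = eta/T``, ``k_off = (1-eta)/T``."""
        return cls(k=k, k_on=eta / T, k_off=(1.0 - eta) / T)


@dataclass(frozen=True)
class PropagatorSet:
    """Per-step column-stochastic transition matrices on a time grid.

    ``steps[j]`` maps the state distribution at ``times[j]`` to the one at
    ``times[j+1]``; states are ordered by the number of active copies.
    """

    times: np.ndarray
    steps: np.ndarray  # (n_t - 1, d, d)

    @property
    def n_states(self) -> int:
        return self.steps.shape[1]

    def compose(self, i: int = 0, j: int | None = None) -> np.ndarray:
        """Cumulative propagator ``U(t_j, t_i)``."""
        if j is None:
            j = len(self.times) - 1
        out = np.eye(self.n_states)
        for s in range(i, j):
            out = self.steps[s] @ out
        return out


def stationary_moments(p: TwoStateParams, t: float):
    """Moments of the event count ``g`` over ``[0, t]`` at stationarity.

    Returns ``(<g>, <g(1,t)>, <g(0,t)>, <g^2>)`` where ``<g(n,t)>`` is the
    mean count restricted to trajectories ending in state ``n``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    k, eta, T = p.k, p.eta, p.T
    e = np.exp(-t / T)
    g = k * eta * t
    g1 = k * eta**2 * t + k * eta * (1 - eta) * T * (1 - e)
    g0 = k * eta * (1 - eta) * t - k * eta * (1 - eta) * T * (1 - e)
    g2 = (
        k * eta * t
        + k**2 * eta**2 * t**2
        + 2 * k**2 * eta * (1 - eta) * (T**2 * e + t * T - T**2)
    )
    return g, g1, g0, g2


def telegraph_propagator_closed_form(p: TwoStateParams, t: float) -> np.ndarray:
    """Single-copy transition matrix ``P(n | n'; t)`` (columns indexed by n').

    ``P(n|n';t) = (n eta + (1-n)(1-eta)) (1 - e^{-t/T}) + delta_{nn'} e^{-t/T}``.
    """
    eta, T = p.eta, p.T
    e = np.exp(-t / T)
    U = np.empty((2, 2))
    for n in (0, 1):
        for n0 in (0, 1):
            stat = n * eta + (1 - n) * (1 - eta)
            U[n, n0] = stat * (1 - e) + (1.0 if n == n0 else 0.0) * e
    return U


def _corr_num(p: TwoStateParams, tau_tilde: float, tau: float) -> float:
    """Covariance ``<g g'> - mu^2`` of counts in windows ``tau_tilde`` at lag ``tau``."""
    k, eta, T = p.k, p.eta, p.T
    w = tau_tilde
    if tau < w:
        return k * eta * (
            (w - tau)
            + k * (1 - eta)
            * (
                2 * (w - tau) * T
                + T**2
                * (
                    np.exp(-(w + tau) / T)
                    + np.exp(-(w - tau) / T)
                    - 2 * np.exp(-tau / T)
                )
            )
        )
    # disjoint windows: covariance of the occupancy integrated over two
    # w-windows a gap tau - w apart decays from the adjacent-window value
    return (
        k**2
        * eta
        * (1 - eta)
        * T**2
        * (1 - np.exp(-w / T)) ** 2
        * np.exp(-(tau - w) / T)
    )


def model_autocorrelation(p: TwoStateParams, tau_tilde: float, tau) -> float | np.ndarray:
    """Normalized autocorrelation of event counts integrated over ``tau_tilde``.

    Two-branch closed form; ``rho(0) = 1`` and for ``tau >= tau_tilde`` the
    decay is exactly ``exp(-tau/T)``.  With ``tau_tilde`` equal to the
    elongation time this is the activity autocorrelation; with the sampling
    time it is the rate autocorrelation.
    """
    g_mean, _, _, g2 = stationary_moments(p, tau_tilde)
    var = g2 - g_mean**2
    taus = np.atleast_1d(np.asarray(tau, dtype=float))
    out = np.array([_corr_num(p, tau_tilde, tt) for tt in taus]) / var
    return float(out[0]) if np.isscalar(tau) else out


def _phi1(x):
    x = np.asarray(x, dtype=float)
    small = x < 1e-6
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 2 * (np.exp(-x) + x - 1) / x**2
    return np.where(small, 1.0 - x / 3.0, val)


def _phi2(x):
    x = np.asarray(x, dtype=float)
    small = x < 1e-6
    with np.errstate(invalid="ignore", divide="ignore"):
        val = (1 - np.exp(-x)) ** 2 / x**2
    return np.where(small, 1.0 - x, val)


def sigma_ac(p: TwoStateParams, dt: float) -> float:
    """One-lag correlated-fluctuation amplitude of the sampled rate.

    ``Sigma_AC = k dt (1-eta) phi2(dt/T) / (1 + k dt (1-eta) phi1(dt/T))``
    with ``phi1(x) = 2(e^{-x}+x-1)/x^2`` and ``phi2(x) = (1-e^{-x})^2/x^2``.
    Vanishes as ``dt -> 0``; identical for any number of independent copies.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = dt / p.T
    a = p.k * dt * (1 - p.eta)
    return float(a * _phi2(x) / (1 + a * _phi1(x)))


def generator_matrix(k_on: float, k_off: float, n_copies: int) -> np.ndarray:
    """CTMC generator over the number of active copies (columns sum to 0)."""
    if n_copies == 1:
        return np.array([[-k_on, k_off], [k_on, -k_off]])
    if n_copies == 2:
        return np.array(
            [
                [-2 * k_on, k_off, 0.0],
                [2 * k_on, -(k_off + k_on), 2 * k_off],
                [0.0, k_on, -2 * k_off],
            ]
        )
    raise ValueError("n_copies must be 1 or 2")


def build_propagator(
    k_on, k_off, times, n_copies: int = 1
) -> PropagatorSet:
    """Per-step propagators via trapezoid-averaged matrix exponentials.

    ``U(t_{j+1}, t_j) = expm(0.5 (M(t_{j+1}) + M(t_j)) dt)``; composing the
    steps approximates the time-ordered exponential.  ``k_on``/``k_off``
    may be scalars or arrays tabulated on ``times``.
    """
    times = np.asarray(times, dtype=float)
    n_t = times.size
    k_on = np.broadcast_to(np.asarray(k_on, dtype=float), (n_t,))
    k_off = np.broadcast_to(np.asarray(k_off, dtype=float), (n_t,))
    if np.any(k_on < 0) or np.any(k_off < 0):
        raise ValueError("switching rates must be non-negative")
    d = n_copies + 1
    steps = np.empty((n_t - 1, d, d))
    const = np.all(k_on == k_on[0]) and np.all(k_off == k_off[0]) and np.all(
        np.abs(np.diff(times, 2)) < 1e-12 * max(times[-1] - times[0], 1.0)
    )
    if const:
        U = expm(generator_matrix(k_on[0], k_off[0], n_copies) * (times[1] - times[0]))
        steps[:] = U
    else:
        for j in range(n_t - 1):
            M = 0.5 * (
                generator_matrix(k_on[j + 1], k_off[j + 1], n_copies)
                + generator_matrix(k_on[j], k_off[j], n_copies)
            )
            steps[j] = expm(M * (times[j + 1] - times[j]))
    return PropagatorSet(times=times, steps=steps)


def expected_pon(ps: PropagatorSet, p0: np.ndarray) -> np.ndarray:
    """ON-probability ``P_ON(t) = sum_{n>0} P_n(t)`` on the propagator grid."""
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-8 or np.any(p0 < -1e-12):
        raise ValueError("initial distribution must be normalized")
    occ = _occupancies(ps, p0)
    return occ[:, 1:].sum(axis=1)


def _occupancies(ps: PropagatorSet, p0: np.ndarray) -> np.ndarray:
    out = np.empty((len(ps.times), ps.n_states))
    out[0] = p0
    for j in range(len(ps.times) - 1):
        out[j + 1] = ps.steps[j] @ out[j]
    return out


def residence_distributions(
    ps: PropagatorSet,
    residence: tuple[int, ...],
    absorbing: tuple[int, ...],
    p0: np.ndarray,
):
    """Censoring-aware first-passage distributions on the finite grid.

    ``W[j, i]`` is the probability that a period which settled into the
    residence set at ``t_i`` first reaches the absorbing set after duration
    ``t_j - t_i``; the last row carries the truncation mass so each column
    sums to 1.  Also returns the settling weights ``Z_i``.
    """
    residence = tuple(residence)
    absorbing = tuple(absorbing)
    if set(residence) & set(absorbing):
        raise ValueError("residence and absorbing sets must be disjoint")
    if set(residence) | set(absorbing) != set(range(ps.n_states)):
        raise ValueError("residence and absorbing sets must cover the state space")
    n_t = len(ps.times)
    occ = _occupancies(ps, np.asarray(p0, dtype=float))
    res = np.array(residence)
    absb = np.array(absorbing)

    W = np.zeros((n_t, n_t))
    Z = np.zeros(n_t)
    # Qres[:, i] holds the still-resident distribution of the period that
    # settled at t_i; all active columns advance together through each step
    Qres = np.zeros((res.size, n_t))
    Z[0] = occ[0, res].sum()
    if Z[0] > 0:
        Qres[:, 0] = occ[0, res] / Z[0]
    step_rr = [s[np.ix_(res, res)] for s in ps.steps]
    step_ar = [s[np.ix_(absb, res)] for s in ps.steps]
    step_ra = [s[np.ix_(res, absb)] for s in ps.steps]
    for j in range(1, n_t):
        # propagate columns 0..j-1 with absorbing boundary; record the mass
        # absorbed during this step
        W[j, :j] = (step_ar[j - 1] @ Qres[:, :j]).sum(axis=0)
        Qres[:, :j] = step_rr[j - 1] @ Qres[:, :j]
        # column j settles now, out of the absorbing occupancy
        settle = step_ra[j - 1] @ occ[j - 1, absb]
        Z[j] = settle.sum()
        if Z[j] > 0:
            Qres[:, j] = settle / Z[j]
    # truncation row: leftover (censored) mass closes each column
    W[n_t - 1, :] = 1.0 - W[: n_t - 1, :].sum(axis=0)
    return W, Z


def expected_on_off_times(W: np.ndarray, Z: np.ndarray, times) -> np.ndarray:
    """Expected period duration at each grid point from the residence matrix.

    ``T(t_j)`` is the settling-weighted mean duration of periods ending
    (or censored) at ``t_j``: ``sum_{i<j} W_ji Z_i (t_j - t_i) / sum_{i<j}
    W_ji Z_i``.  Because a period's duration is sampled once per period,
    this matches the empirical estimator, whose inverse-period-length
    weights exactly cancel the length bias of sampling periods at a fixed
    time point.  Near the grid ends the values bend downward (censoring).
    """
    times = np.asarray(times, dtype=float)
    n_t = len(times)
    T = np.full(n_t, np.nan)
    for j in range(1, n_t):
        wji = W[j, :j] * Z[:j]
        z = wji.sum()
        if z > 0:
            T[j] = np.sum(wji * (times[j] - times[:j])) / z
    return T


def two_copy_stationary_times(k_on: float, k_off: float) -> tuple[float, float]:
    """Stationary effective (T_OFF, T_ON) for two independent copies.

    Phase-type means of the 3-state chain: ``T_OFF = 1/(2 k_on)`` and
    ``T_ON = (k_on + 2 k_off) / (2 k_off^2)``.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    return 1.0 / (2 * k_on), (k_on + 2 * k_off) / (2 * k_off**2)
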