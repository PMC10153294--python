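"""Distributional and temporal characterization of deconvolved rates.

Pools single-allele rate distributions conditioned on the bin-mean rate,
compares them against the constitutive (footprint-corrected binomial)
reference, computes rate cumulants, the ensemble-normalized empirical
autocorrelation of instantaneous rates over MCMC samples, its
exponential-with-floor fit (amplitude ``Sigma_AC``, correlation time
``tau_AC``, noise floor ``beta``), and a weighted between/within group
variance decomposition for replicate ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "RateDistribution",
    "ACFit",
    "pool_conditional",
    "pooling_homogeneity",
    "constitutive_binomial",
    "rate_cumulants",
    "empirical_autocorrelation",
    "fit_ac",
    "group_variance_decomposition",
]


@dataclass
class RateDistribution:
    """Discrete distribution of the windowed single-allele rate."""

    support: np.ndarray  # mRNA/min, multiples of 1/(v dt)
    probs: np.ndarray
    R0: float = np.nan
    eps: float = np.nan
    members: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.support < 0):
            raise ValueError("support must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-8:
            raise ValueError("probabilities must sum to 1")


@dataclass
class ACFit:
    """Exponential-with-floor autocorrelation fit."""

    sigma_ac: float
    tau_ac: float  # min
    beta: float
    sigma_ac_err: float = np.nan
    tau_ac_err: float = np.nan
    flagged: bool = False


def pool_conditional(
    probs: np.ndarray,
    counts: np.ndarray,
    R: np.ndarray,
    support: np.ndarray,
    R0: float,
    eps: float,
) -> RateDistribution:
    """Allele-count-weighted mixture of bin distributions with mean near R0.

    ``probs[b]`` is the rate distribution of bin ``b`` on the common
    ``support``; bins with ``|R[b] - R0| <= eps`` enter the mixture with
    weight proportional to their allele count.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    counts = np.asarray(counts, dtype=float)
    R = np.asarray(R, dtype=float)
    members = np.flatnonzero(np.abs(R - R0) <= eps)
    if members.size == 0:
        raise ValueError(f"no bins with |R - {R0}| <= {eps}")
    wts = counts[members] / counts[members].sum()
    mix = wts @ probs[members]
    return RateDistribution(
        support=np.asarray(support, float), probs=mix, R0=R0, eps=eps,
        members=members,
    )


def pooling_homogeneity(
    rd: RateDistribution, probs: np.ndarray, counts: np.ndarray
) -> float:
    """Fraction of member bins consistent with the pooled distribution.

    A member bin counts as consistent when its CDF stays within the 95%
    Kolmogorov-Smirnov envelope ``1.36/sqrt(N_bin)`` of the pooled CDF.
    Pooling is considered valid when most members are inside (callers
    typically warn below 80%).
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    counts = np.asarray(counts, dtype=float)
    pooled_cdf = np.cumsum(rd.probs)
    inside = 0
    for b in rd.members:
        dev = np.abs(np.cumsum(probs[b]) - pooled_cdf).max()
        if dev <= 1.36 / np.sqrt(max(counts[b], 1.0)):
            inside += 1
    return inside / max(len(rd.members), 1)


def constitutive_binomial(R: float, tau_min: float, dt_fine_s: float):
    """Constitutive (Poisson-with-footprint) reference distribution.

    Initiation as independent Bernoulli trials in each footprint-limited
    slot: ``g ~ Binomial(n_t = tau/dt', p = R dt')``, rate ``r = g/tau``.
    Returns ``(RateDistribution, (var, kappa3, kappa4))`` with the
    closed-form cumulants of ``r``.
    """
    dt_fine_min = dt_fine_s / 60.0
    p = R * dt_fine_min
    if p > 1 + 1e-12:
        raise ValueError("R exceeds the maximal physical rate 1/dt_fine")
    p = min(p, 1.0)
    n = int(round(tau_min / dt_fine_min))
    g = np.arange(n + 1)
    probs = stats.binom.pmf(g, n, p)
    var = n * p * (1 - p) / tau_min**2
    k3 = n * p * (1 - p) * (1 - 2 * p) / tau_min**3
    k4 = n * p * (1 - p) * (1 - 6 * p * (1 - p)) / tau_min**4
    rd = RateDistribution(support=g / tau_min, probs=probs / probs.sum(), R0=R)
    return rd, (var, k3, k4)


def rate_cumulants(rd: RateDistribution):
    """First four cumulants (mean, variance, kappa3, kappa4) of ``r``."""
    r, p = rd.support, rd.probs
    m = [float(np.sum(r**k * p)) for k in range(1, 5)]
    mean = m[0]
    var = m[1] - mean**2
    k3 = m[2] - 3 * m[1] * mean + 2 * mean**3
    k4 = m[3] - 4 * m[2] * mean - 3 * m[1] ** 2 + 12 * m[1] * mean**2 - 6 * mean**4
    return mean, var, k3, k4


def empirical_autocorrelation(
    rates: np.ndarray, max_lag: int | None = None
):
    """Ensemble-normalized rate autocorrelation, averaged over MCMC samples.

    ``rates`` has shape ``(n_alleles, n_samples, n_t)``.  Per sample the
    across-allele covariance at each ``(t, t+tau)`` is normalized by the
    two across-allele SDs and averaged over ``t`` (time points with zero
    variance are masked); the sample mean and SD give ``rho(tau)`` and
    ``sigma_rho(tau)``.  Returns ``(lags, rho, sigma_rho, rho_s)``.
    """
    rates = np.asarray(rates, dtype=float)
    n_a, n_s, n_t = rates.shape
    if n_a < 2:
        raise ValueError("need at least 2 alleles")
    if max_lag is None:
        max_lag = n_t - 2
    max_lag = min(max_lag, n_t - 2)
    rho_s = np.full((n_s, max_lag + 1), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in range(n_s):
            x = rates[:, s, :]
            mu = x.mean(axis=0)
            dev = x - mu
            sd = np.sqrt(np.mean(dev**2, axis=0))
            sd_safe = np.where(sd > 0, sd, np.nan)
            for lag in range(max_lag + 1):
                cov = np.mean(dev[:, : n_t - lag] * dev[:, lag:], axis=0)
                vals = cov / (sd_safe[: n_t - lag] * sd_safe[lag:])
                rho_s[s, lag] = np.nanmean(vals)
        rho = np.nanmean(rho_s, axis=0)
        sig = np.nanstd(rho_s, axis=0)
    lags = np.arange(max_lag + 1)
    return lags, rho, sig, rho_s


def fit_ac(
    rho: np.ndarray,
    sigma_rho: np.ndarray,
    dt: float,
    fit_max_min: float = 10.0,
    rho_s: np.ndarray | None = None,
) -> ACFit:
    """Fit ``rho(tau) = Sigma_AC [(1-beta) exp(-(tau-dt)/tau_AC) + beta]``.

    ``Sigma_AC`` is read off at the first lag; ``tau_AC`` and the noise
    floor ``beta`` are fitted by weighted least squares over
    ``dt <= tau < fit_max_min``.  If per-sample curves ``rho_s`` are
    given, bootstrap errors over samples are reported.  A non-decaying
    curve is flagged.
    """
    rho = np.asarray(rho, dtype=float)
    lags_min = np.arange(rho.size) * dt
    sel = (lags_min >= dt - 1e-9) & (lags_min < fit_max_min)
    if sel.sum() < 5:
        raise ValueError("need at least 5 lags in the fit range")
    sigma_ac = float(rho[1])
    taus = lags_min[sel]
    y = rho[sel]
    w = np.asarray(sigma_rho, dtype=float)[sel]
    w = np.where((w > 0) & np.isfinite(w), w, np.nanmax(w[w > 0]) if np.any(w > 0) else 1.0)

    def model(tau, tau_ac, beta):
        return sigma_ac * ((1 - beta) * np.exp(-(tau - dt) / tau_ac) + beta)

    def _one_fit(yv):
        try:
            popt, _ = curve_fit(
                model, taus, yv, p0=[max(2 * dt, 0.5), 0.04],
                sigma=w, bounds=([1e-3, 0.0], [1e3, 0.999]), maxfev=5000,
            )
            return popt
        except RuntimeError:
            return np.array([np.nan, np.nan])

    tau_ac, beta = _one_fit(y)
    flagged = (not np.isfinite(tau_ac)) or tau_ac > 0.9e3 or y[-1] > y[0]
    tau_err = sig_err = np.nan
    if rho_s is not None and rho_s.shape[0] >= 8:
        boots = []
        for s in range(rho_s.shape[0]):
            ys = rho_s[s, : rho.size][sel]
            if np.all(np.isfinite(ys)):
                sa = rho_s[s, 1]
                def model_s(tau, tau_ac_, beta_):
                    return sa * ((1 - beta_) * np.exp(-(tau - dt) / tau_ac_) + beta_)
                try:
                    popt, _ = curve_fit(
                        model_s, taus, ys, p0=[max(tau_ac, 0.2) if np.isfinite(tau_ac) else 1.0, 0.04],
                        sigma=w, bounds=([1e-3, 0.0], [1e3, 0.999]), maxfev=2000,
                    )
                    boots.append((sa, popt[0]))
                except RuntimeError:
                    pass
        if boots:
            arr = np.array(boots)
            sig_err = float(arr[:, 0].std())
            tau_err = float(arr[:, 1].std())
    return ACFit(
        sigma_ac=sigma_ac, tau_ac=float(tau_ac), beta=float(beta),
        sigma_ac_err=sig_err, tau_ac_err=tau_err, flagged=bool(flagged),
    )


def group_variance_decomposition(groups):
    """Weighted between/within variance decomposition over replicates.

    ``groups`` is a sequence of 1-d sample arrays (e.g. per-embryo allele
    activities).  Group weights are proportional to ``1/N_i`` and
    normalized; the between component is the weighted variance of group
    means around the weighted grand mean, the within component the
    weighted mean of group variances.  Returns
    ``(sigma_between2, sigma_within2, ratio)`` with
    ``ratio = between/(between+within) <= 1``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.size for g in groups], dtype=float)
    if np.any(n < 1):
        raise ValueError("empty group")
    w = (1.0 / n) / np.sum(1.0 / n)
    mu_i = np.array([g.mean() for g in groups])
    var_i = np.array([g.var() for g in groups])
    mu = float(np.sum(w * mu_i))
    between = float(np.sum(w * (mu_i - mu) ** 2))
    within = float(np.sum(w * var_i))
    total = between + within
    ratio = between / total if total > 0 else 0.0
    return between, within, ratio
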