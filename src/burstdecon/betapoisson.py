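"""Beta-Poisson burst inference from steady-state mRNA count data.

At steady state the telegraph model's mature-mRNA count distribution is a
Poisson mixed over a Beta-distributed burst fraction: with rates
nondimensionalized by the mRNA lifetime ``T_M``,
``m ~ Poisson(K T_M u)`` with ``u ~ Beta(k_on T_M, k_off T_M)``.
Mature counts barely constrain the switching correlation time ``T_C``
when ``T_C << T_M``, so the fit maximizes an effective log-likelihood
with a Gaussian prior on ``log10 T_C`` (mean 0, SD 0.5, i.e. centered on
1 min and spanning ~0.1-10 min at 95%).  Genes with wide bootstrap
intervals or sub-unity burst size are filtered from reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp, roots_jacobi

__all__ = [
    "BetaPoissonFit",
    "beta_poisson_logpmf",
    "loglik_with_prior",
    "BetaPoissonEstimator",
    "fit_gene",
    "filter_genes",
]

#: optimization box in log10 space: (P_ON, T_C [min], K [1/min])
BOX_LOG10 = {"P_ON": (-5.0, 0.0), "T_C": (-2.0, 3.0), "K": (-2.5, 2.5)}
PRIOR_MU, PRIOR_SIGMA = 0.0, 0.5


@dataclass
class BetaPoissonFit:
    """Fitted burst parameters for one gene."""

    K: float  # 1/min
    P_ON: float
    T_C: float  # min
    T_M: float  # min, fixed input
    loglik: float
    prior_penalty: float
    sd_log10: dict  # parameter -> bootstrap SD of log10 value
    n_cells: int = 0

    @property
    def R(self) -> float:
        return self.K * self.P_ON

    @property
    def F(self) -> float:
        return self.P_ON * (1 - self.P_ON) / self.T_C

    @property
    def B(self) -> float:
        return self.K * self.T_C / (1 - self.P_ON)


def _rates_from_params(K, P_ON, T_C, T_M):
    """Dimensionless (a, b, lam) = (k_on T_M, k_off T_M, K T_M)."""
    k_on = P_ON / T_C
    k_off = (1.0 - P_ON) / T_C
    return k_on * T_M, k_off * T_M, K * T_M


def beta_poisson_logpmf(m, K, P_ON, T_C, T_M, n_quad: int = 60):
    """Log-pmf of the telegraph steady-state count distribution.

    Gauss-Jacobi quadrature over the Beta mixing density; for a very
    concentrated Beta (fast switching relative to the lifetime) the
    mixture is evaluated with Gauss-Hermite nodes around the occupancy.
    """
    m = np.atleast_1d(np.asarray(m, dtype=int))
    a, b, lam = _rates_from_params(K, P_ON, T_C, T_M)
    if min(a, b) <= 0 or lam < 0:
        raise ValueError("invalid parameters")
    if max(a, b) <= 300.0:
        x, w = roots_jacobi(n_quad, b - 1.0, a - 1.0)
        u = (1.0 + x) / 2.0
        # near the box edges a or b approach 0 and high-degree weights can
        # underflow to tiny negatives; clip before taking logs
        logw = (
            np.log(np.maximum(w, 1e-300))
            - (a + b - 1.0) * np.log(2.0)
            - betaln(a, b)
        )
    else:
        # near-deterministic occupancy: Gaussian approximation to the Beta
        mu = a / (a + b)
        sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
        x, w = np.polynomial.hermite_e.hermegauss(31)
        u = np.clip(mu + sd * x, 1e-12, 1.0 - 1e-12)
        logw = np.log(w) - 0.5 * np.log(2 * np.pi)
    lam_u = np.maximum(lam * u, 1e-300)
    # log Poisson(m | lam*u) at every node
    ll = (
        m[:, None] * np.log(lam_u)[None, :]
        - lam_u[None, :]
        - gammaln(m + 1.0)[:, None]
    )
    return logsumexp(ll + logw[None, :], axis=1)


def loglik_with_prior(counts, K, P_ON, T_C, T_M) -> float:
    """Effective log-likelihood: Beta-Poisson term minus the T_C prior.

    The penalty is ``0.5 ((log10 T_C - 0)/0.5)^2`` (zero at T_C = 1 min).
    """
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative integers")
    if T_M <= 0:
        raise ValueError("T_M must be positive")
    for name, val in (("P_ON", P_ON), ("T_C", T_C), ("K", K)):
        lo, hi = BOX_LOG10[name]
        if not (10**lo - 1e-12 <= val <= 10**hi + 1e-9):
            raise ValueError(f"{name}={val} outside the optimization box")
    support, inv = np.unique(counts, return_inverse=True)
    lp = beta_poisson_logpmf(support, K, P_ON, T_C, T_M)
    ll = float(np.sum(lp[inv]))
    penalty = 0.5 * ((np.log10(T_C) - PRIOR_MU) / PRIOR_SIGMA) ** 2
    return ll - penalty


class BetaPoissonEstimator:
    """Maximum effective-likelihood Beta-Poisson fit with bootstrap errors.

    Multi-start box-constrained optimization in log10 parameter space
    (ridge-shaped likelihoods are common); bootstrap resampling of the
    counts yields log-space SDs used by the reporting filter.
    """

    def __init__(
        self,
        T_M: float,
        n_starts: int = 8,
        n_boot: int = 20,
        min_cells: int = 30,
        random_state: int = 0,
    ):
        self.T_M = T_M
        self.n_starts = n_starts
        self.n_boot = n_boot
        self.min_cells = min_cells
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in ("T_M", "n_starts", "n_boot", "min_cells", "random_state")
        }

    def set_params(self, **params) -> "BetaPoissonEstimator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _optimize(self, counts, rng, x0=None, n_starts=None):
        lo = np.array([BOX_LOG10[p][0] for p in ("P_ON", "T_C", "K")])
        hi = np.array([BOX_LOG10[p][1] for p in ("P_ON", "T_C", "K")])
        support, inv_counts = np.unique(counts, return_inverse=True)
        n_per = np.bincount(inv_counts)

        def nll(theta):
            pon, tc, k = 10.0**theta
            pon = min(pon, 1.0 - 1e-12)
            try:
                lp = beta_poisson_logpmf(support, k, pon, tc, self.T_M)
            except (ValueError, FloatingPointError):
                return 1e12
            if not np.all(np.isfinite(lp)):
                return 1e12
            pen = 0.5 * ((theta[1] - PRIOR_MU) / PRIOR_SIGMA) ** 2
            return -(float(n_per @ lp) - pen)

        mean_c = max(np.mean(counts), 1e-3)
        starts = []
        if x0 is not None:
            starts.append(np.asarray(x0))
        base = np.array([-0.5, 0.0, np.log10(mean_c / self.T_M) + 0.5])
        base = np.clip(base, lo + 0.05, hi - 0.05)
        starts.append(base)
        n_starts = self.n_starts if n_starts is None else n_starts
        while len(starts) < n_starts:
            starts.append(lo + (hi - lo) * rng.random(3))
        best = None
        for s in starts:
            res = minimize(
                nll, s, method="L-BFGS-B", bounds=list(zip(lo, hi)),
                options={"maxiter": 300},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    def fit(self, counts) -> "BetaPoissonEstimator":
        counts = np.asarray(counts, dtype=int)
        if counts.size < self.min_cells:
            raise ValueError(f"need at least {self.min_cells} cells")
        if np.all(counts == 0):
            self.fit_ = None
            warnings.warn("all-zero counts: no fit", RuntimeWarning)
            return self
        rng = np.random.default_rng(self.random_state)
        best = self._optimize(counts, rng)
        theta = best.x
        pon, tc, k = 10.0**theta
        pon = min(pon, 1.0 - 1e-12)
        penalty = 0.5 * ((theta[1] - PRIOR_MU) / PRIOR_SIGMA) ** 2
        boots = []
        for _ in range(self.n_boot):
            resample = rng.choice(counts, size=counts.size, replace=True)
            if np.all(resample == 0):
                continue
            b = self._optimize(resample, rng, x0=theta, n_starts=3)
            boots.append(b.x)
        if boots:
            sds = np.std(np.asarray(boots), axis=0)
        else:
            sds = np.full(3, np.nan)
        self.fit_ = BetaPoissonFit(
            K=float(k),
            P_ON=float(pon),
            T_C=float(tc),
            T_M=self.T_M,
            loglik=-float(best.fun),
            prior_penalty=float(penalty),
            sd_log10={"P_ON": sds[0], "T_C": sds[1], "K": sds[2]},
            n_cells=int(counts.size),
        )
        return self


def fit_gene(counts, T_M: float, seed: int = 0, **kwargs) -> BetaPoissonFit | None:
    """Fit one gene's counts; returns None for all-zero input."""
    est = BetaPoissonEstimator(T_M=T_M, random_state=seed, **kwargs).fit(counts)
    return est.fit_


def filter_genes(fits, sd_threshold: float = 0.5, min_burst: float = 1.0):
    """Reporting filter: ``2 sigma_Theta < 0.5`` (log10) and ``B > 1``.

    Returns ``(retained_fits, retained_fraction)``.
    """
    fits = [f for f in fits if f is not None]
    keep = []
    for f in fits:
        sd_ok = all(
            np.isfinite(sd) and 2 * sd < sd_threshold
            for sd in f.sd_log10.values()
        )
        if sd_ok and f.B > min_burst:
            keep.append(f)
    frac = len(keep) / len(fits) if fits else 0.0
    return keep, frac
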