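"""Heteroscedastic measurement-noise model for calibrated activity traces.

The measured activity ``A`` of a transcription site is the true signal
``G`` (in cytoplasmic units, C.U.) plus Gaussian noise whose variance grows
linearly with the signal: ``sigma^2(G) = sigma_b^2 + beta1 * G``, i.e. a
constant background term plus a Poisson-like shot-noise term.  The slope
and background can be fitted from interlaced dual-color measurements of the
same allele, or estimated from the lag-1 autocovariance of trace ensembles
(elongation makes the biological signal strongly time-correlated, so the
variability that decorrelates within one sampling step is imaging noise).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "NoiseModel",
    "noise_sd",
    "DualColorNoiseFitter",
    "fit_dual_color",
    "uncorrelated_variability",
]


@dataclass(frozen=True)
class NoiseModel:
    """``sigma(G) = sqrt(sigma_b^2 + beta1 * G)`` in C.U."""

    sigma_b: float = 1.22
    beta1: float = 0.16

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.beta1 < 0:
            raise ValueError("sigma_b and beta1 must be non-negative")

    def sd(self, G):
        return noise_sd(G, self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"sigma_b": self.sigma_b, "beta1": self.beta1})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NoiseModel":
        data = json.loads(Path(path).read_text())
        return cls(sigma_b=float(data["sigma_b"]), beta1=float(data["beta1"]))


def noise_sd(G, nm: NoiseModel):
    """Measurement SD at true signal ``G`` (C.U.); monotone in ``G``."""
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("true signal G must be non-negative")
    out = np.sqrt(nm.sigma_b**2 + nm.beta1 * G)
    return float(out) if out.ndim == 0 else out


class DualColorNoiseFitter:
    """Fit the noise law from interlaced dual-color pairs.

    The two channels measure the same underlying signal; the scatter of
    ``y`` against ``x`` around the line ``y = alpha x + gamma`` is pure
    measurement noise.  The variance is expanded along the projection ``v``
    on the line, ``sigma^2(v) = sigma_b^2 + beta_1 v + beta_2 v^2``, and the
    likelihood assumes the same error in both channels.  Nested models
    (free subsets of ``{alpha, gamma, beta_1, beta_2}``) are compared by
    AIC, ties broken toward the smaller model.  The per-channel shot-noise
    slope follows the ``beta1_tilde = 2 beta_1`` convention.

    Attributes (after ``fit``):  ``noise_model_``, ``alpha_``, ``gamma_``,
    ``beta2_``, ``aic_``, ``model_terms_``, ``aic_table_``.
    """

    #: candidate free-parameter sets on top of sigma_b (always free)
    _CANDIDATES = [
        frozenset(s)
        for r in range(5)
        for s in itertools.combinations(("alpha", "gamma", "beta1", "beta2"), r)
        if not ("beta2" in s and "beta1" not in s)  # keep the ladder nested
    ]

    def __init__(self, min_pairs: int = 50):
        self.min_pairs = min_pairs

    def get_params(self, deep: bool = True) -> dict:
        return {"min_pairs": self.min_pairs}

    def set_params(self, **params) -> "DualColorNoiseFitter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _negloglik(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
        alpha, gamma, log_sb, beta1, beta2 = theta
        sb2 = np.exp(2 * log_sb)
        # scalar projection onto the line (unit direction)
        v = (x + alpha * (y - gamma)) / np.sqrt(1 + alpha**2)
        var = sb2 + beta1 * v + beta2 * v**2
        if np.any(var <= 0):
            return np.inf
        resid2 = (y - alpha * x - gamma) ** 2 / (1 + alpha**2)
        return float(0.5 * np.sum(np.log(2 * np.pi * var) + resid2 / var))

    def fit(self, X, y=None) -> "DualColorNoiseFitter":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of (x, y) pairs")
        if X.shape[0] < self.min_pairs:
            raise ValueError(f"need at least {self.min_pairs} pairs")
        x, yy = X[:, 0], X[:, 1]
        if np.var(x) == 0 or np.var(yy) == 0:
            raise ValueError("degenerate pairs: zero variance in a channel")

        full = {"alpha": 1.0, "gamma": 0.0, "beta1": 0.0, "beta2": 0.0}
        resid0 = yy - x
        sb0 = max(np.std(resid0) / np.sqrt(2), 1e-3)

        results = []
        for free in self._CANDIDATES:
            x0, idx = [np.log(sb0)], {"log_sb": 0}
            for name in ("alpha", "gamma", "beta1", "beta2"):
                if name in free:
                    idx[name] = len(x0)
                    x0.append({"alpha": 1.0}.get(name, 0.0))

            def unpack(t):
                th = np.array(
                    [
                        t[idx["alpha"]] if "alpha" in idx else full["alpha"],
                        t[idx["gamma"]] if "gamma" in idx else full["gamma"],
                        t[idx["log_sb"]],
                        t[idx["beta1"]] if "beta1" in idx else full["beta1"],
                        t[idx["beta2"]] if "beta2" in idx else full["beta2"],
                    ]
                )
                return th

            res = minimize(
                lambda t: self._negloglik(unpack(t), x, yy),
                np.array(x0),
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8},
            )
            k = len(x0)
            aic = 2 * k + 2 * res.fun
            results.append((aic, k, free, unpack(res.x)))

        # smallest AIC; ties (within 1e-9) toward fewer parameters
        results.sort(key=lambda r: (round(r[0], 9), r[1]))
        aic, _, free, theta = results[0]
        alpha, gamma, log_sb, beta1, beta2 = theta
        self.alpha_ = float(alpha)
        self.gamma_ = float(gamma)
        self.beta2_ = float(beta2)
        self.aic_ = float(aic)
        self.model_terms_ = sorted(free)
        self.aic_table_ = [(sorted(f), a) for a, _, f, _ in results]
        # per-channel shot-noise slope: the projection v runs sqrt(1+alpha^2)
        # times faster than the channel signal, so beta1_tilde = sqrt(2) beta1
        # on the calibrated diagonal (alpha = 1)
        self.noise_model_ = NoiseModel(
            sigma_b=float(np.exp(log_sb)),
            beta1=float(max(np.sqrt(1 + alpha**2) * beta1, 0.0)),
        )
        return self


def fit_dual_color(pairs) -> DualColorNoiseFitter:
    """Convenience wrapper: fit the dual-color noise model on (x, y) pairs."""
    return DualColorNoiseFitter().fit(np.asarray(pairs, dtype=float))


def uncorrelated_variability(values: np.ndarray):
    """Time-resolved mean and uncorrelated variance of a trace ensemble.

    Parameters
    ----------
    values
        Array of shape ``(n_alleles, n_t)`` of activity traces sampled on a
        common grid.

    Returns
    -------
    mu, sigma_u2
        ``mu[t]`` is the across-allele mean; ``sigma_u2[t]`` is the total
        across-allele variance minus the lag-1 autocovariance,
        ``sigma^2(t) - Cov(t, t+dt)``, an estimate of the temporally
        uncorrelated (imaging) variance.  ``sigma_u2`` has length
        ``n_t - 1``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 alleles (rows)")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    mu = values.mean(axis=0)
    dev = values - mu
    var = np.mean(dev**2, axis=0)
    cov = np.mean(dev[:, :-1] * dev[:, 1:], axis=0)
    return mu, var[:-1] - cov
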