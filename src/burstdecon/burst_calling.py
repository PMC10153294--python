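"""ON/OFF burst calling and bursting-parameter estimation.

Deconvolved initiation configurations are clustered into bursts by
thresholding a super-Gaussian moving average of the instantaneous rate:
the allele is ON at ``t`` when at least ``g_b`` initiation events fall in
the ``w``-wide window (threshold ``r_b = g_b / w``).  Across alleles of a
spatiotemporal bin, and across MCMC samples, the module estimates the
mean rate ``R``, ON-probability ``P_ON``, ON/OFF-conditioned initiation
rates ``K`` and ``K_L``, the inverse-length-weighted mean ON/OFF
durations ``T_ON``/``T_OFF``, and the derived switching correlation time
``T_C = T_ON T_OFF/(T_ON+T_OFF)``, burst size ``B = K T_ON`` and burst
frequency ``F = 1/(T_ON+T_OFF)``, each with an MCMC-propagated SD.
Effective (two-sister-chromatid) parameters can be converted to
single-gene-copy ones under the identical-and-independent-copies
assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .deconvolution import PosteriorSamples, rate_from_samples

__all__ = [
    "smoothing_kernel",
    "call_bursts",
    "OnStateTrace",
    "BurstingParams",
    "BurstParameterEstimator",
    "estimate_params",
    "derived_params",
    "to_single_copy",
]

PARAM_NAMES = ("R", "P_ON", "K", "K_L", "T_ON", "T_OFF", "T_C", "B", "F")


@dataclass
class OnStateTrace:
    """Binary ON state on the coarse grid, one row per MCMC sample."""

    times: np.ndarray
    states: np.ndarray  # (n_s, n_t) uint8


@dataclass
class BurstingParams:
    """Point estimates and MCMC SDs of the bursting parameters over time."""

    times: np.ndarray
    values: dict = field(default_factory=dict)  # name -> array over time
    errors: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.values:
            for t, v, e in zip(self.times, self.values[name], self.errors[name]):
                rows.append((t, name, v, e))
        return pd.DataFrame(rows, columns=["t_min", "param", "value", "sd"])

    def median(self, name: str) -> float:
        return float(np.nanmedian(self.values[name]))


def smoothing_kernel(w: float, dt: float) -> np.ndarray:
    """Centered super-Gaussian weights ``exp(-(2t/w)^4)`` summing to 1.

    ``w`` and ``dt`` in the same time unit; support truncated where the
    weights are numerically zero.
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    half = int(np.ceil(1.5 * w / dt))
    t = np.arange(-half, half + 1) * dt
    wts = np.exp(-((2.0 * t / w) ** 4))
    return wts / wts.sum()


def call_bursts(
    rates: np.ndarray,
    dt: float,
    w: float | None = None,
    g_b: float = 2.0,
) -> np.ndarray:
    """ON state per sample: moving-average rate at or above ``g_b / w``.

    ``rates`` is ``(n_s, n_t)`` in events/min from a ``v=1`` window;
    ``w`` defaults to ``5 dt``.  The moving average is a discrete
    convolution with the super-Gaussian kernel normalized over its full
    support (windows truncated at the trace ends are biased low, one
    source of the censoring bias near the ends).  Ties count as ON.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if w is None:
        w = 5.0 * dt
    kern = smoothing_kernel(w, dt)
    r_b = g_b / w
    half = (kern.size - 1) // 2
    n_t = rates.shape[1]
    padded = np.pad(rates, ((0, 0), (half, half)))
    rw = np.empty_like(rates)
    for s in range(rates.shape[0]):
        rw[s] = np.convolve(padded[s], kern, mode="valid")[:n_t]
    return (rw >= r_b - 1e-12).astype(np.uint8)


@njit(cache=True)
def _accumulate_bin(rates, states, acc):
    """Accumulate per-(sample, time) sums across alleles.

    ``acc`` rows: 0 R_sum, 1 n_on, 2 K_num, 3 KL_num, 4 inv_pi_on,
    5 inv_pi_off.  Period lengths use boundaries where the state changes,
    with forced boundaries at both trace ends; the first point belongs to
    the first period.
    """
    n_a, n_s, n_t = rates.shape
    pi = np.empty(n_t)
    for a in range(n_a):
        for s in range(n_s):
            # boundary at i when the state changes between i and i+1, with
            # forced boundaries at both ends; the period (prev, i] covers
            # points prev+1..i and the first point inherits the first period
            prev = 0
            first = True
            for i in range(1, n_t):
                if i == n_t - 1 or states[a, s, i + 1] != states[a, s, i]:
                    length = i - prev
                    for tt in range(prev + 1, i + 1):
                        pi[tt] = length
                    if first:
                        pi[0] = length
                        first = False
                    prev = i
            if n_t == 1:
                pi[0] = 1.0
            for t in range(n_t):
                r = rates[a, s, t]
                acc[0, s, t] += r
                if states[a, s, t] != 0:
                    acc[1, s, t] += 1.0
                    acc[2, s, t] += r
                    acc[4, s, t] += 1.0 / pi[t]
                else:
                    acc[3, s, t] += r
                    acc[5, s, t] += 1.0 / pi[t]


def _gaussian_fill(times: np.ndarray, y: np.ndarray, sd_min: float) -> np.ndarray:
    """Replace NaNs by a Gaussian-kernel weighted average of valid points."""
    out = y.copy()
    bad = ~np.isfinite(y)
    good = ~bad
    if not bad.any() or not good.any():
        return out
    tg, yg = times[good], y[good]
    for i in np.flatnonzero(bad):
        wts = np.exp(-0.5 * ((times[i] - tg) / sd_min) ** 2)
        if wts.sum() > 0:
            out[i] = np.sum(wts * yg) / wts.sum()
    return out


class BurstParameterEstimator:
    """Estimate bursting parameters for one spatiotemporal bin.

    Parameters
    ----------
    w_minutes
        Moving-average window for burst calling; default ``5 dt``
        (about 50 s at 10-s sampling, threshold ``r_b = g_b/w = 2.4``
        events/min).
    g_b
        Minimum number of initiation events per window for a burst.
    smooth_sd_min
        SD (min) of the Gaussian kernel used to interpolate missing
        values in the time-resolved point estimates.

    ``fit`` takes a list of :class:`PosteriorSamples` (one per allele of
    the bin); ``params_`` then holds a :class:`BurstingParams`.
    """

    def __init__(
        self,
        w_minutes: float | None = None,
        g_b: float = 2.0,
        smooth_sd_min: float = 1.0,
        single_copy: bool = False,
    ):
        self.w_minutes = w_minutes
        self.g_b = g_b
        self.smooth_sd_min = smooth_sd_min
        self.single_copy = single_copy

    def get_params(self, deep: bool = True) -> dict:
        return {
            "w_minutes": self.w_minutes,
            "g_b": self.g_b,
            "smooth_sd_min": self.smooth_sd_min,
            "single_copy": self.single_copy,
        }

    def set_params(self, **params) -> "BurstParameterEstimator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, posteriors: list[PosteriorSamples]) -> "BurstParameterEstimator":
        if len(posteriors) == 0:
            raise ValueError("empty bin: no posterior samples given")
        dt = posteriors[0].dt
        rates = np.stack([rate_from_samples(ps, v=1)[0] for ps in posteriors])
        states = np.stack(
            [call_bursts(r, dt, self.w_minutes, self.g_b) for r in rates]
        )
        self.params_ = estimate_params(
            rates, states, dt, smooth_sd_min=self.smooth_sd_min
        )
        return self

    def fit_rates(self, rates: np.ndarray, dt: float) -> "BurstParameterEstimator":
        """Fit from precomputed per-allele rate samples ``(n_a, n_s, n_t)``."""
        states = np.stack(
            [call_bursts(r, dt, self.w_minutes, self.g_b) for r in rates]
        )
        self.params_ = estimate_params(
            rates, states, dt, smooth_sd_min=self.smooth_sd_min
        )
        return self


def estimate_params(
    rates: np.ndarray,
    states: np.ndarray,
    dt: float,
    smooth_sd_min: float = 1.0,
) -> BurstingParams:
    """Bin-level bursting parameters from rate and state sample arrays.

    ``rates``/``states`` have shape ``(n_alleles, n_samples, n_t)``.
    Per MCMC sample: across-allele means give ``R`` and ``P_ON``; ``K``
    (``K_L``) averages the rate over ON (OFF) alleles; ``T_ON``/``T_OFF``
    weight each allele's current period duration by the inverse of its
    length in grid points, correcting for long periods spanning many time
    points.  Sample means and SDs give the point estimates and errors;
    remaining gaps are interpolated with a 1-min Gaussian kernel.
    """
    rates = np.asarray(rates, dtype=float)
    states = np.asarray(states, dtype=np.uint8)
    if rates.ndim != 3:
        raise ValueError("rates must be (n_alleles, n_samples, n_t)")
    n_a, n_s, n_t = rates.shape
    if n_a == 0 or n_s == 0 or n_t == 0:
        raise ValueError("empty bin")
    acc = np.zeros((6, n_s, n_t))
    _accumulate_bin(rates, states, acc)
    r_sum, n_on, k_num, kl_num, inv_pi_on, inv_pi_off = acc
    n_off = n_a - n_on

    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample = {
            "R": r_sum / n_a,
            "P_ON": n_on / n_a,
            "K": np.where(n_on > 0, k_num / np.maximum(n_on, 1), np.nan),
            "K_L": np.where(n_off > 0, kl_num / np.maximum(n_off, 1), np.nan),
            "T_ON": np.where(n_on > 0, dt * n_on / inv_pi_on, np.nan),
            "T_OFF": np.where(n_off > 0, dt * n_off / inv_pi_off, np.nan),
        }
        ton, toff = per_sample["T_ON"], per_sample["T_OFF"]
        per_sample["T_C"] = ton * toff / (ton + toff)
        per_sample["B"] = per_sample["K"] * ton
        per_sample["F"] = 1.0 / (ton + toff)

    times = np.arange(n_t) * dt
    values, errors = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for name, arr in per_sample.items():
            v = np.nanmean(arr, axis=0)
            e = np.nanstd(arr, axis=0)
            values[name] = _gaussian_fill(times, v, smooth_sd_min)
            errors[name] = _gaussian_fill(times, e, smooth_sd_min)
    return BurstingParams(times=times, values=values, errors=errors)


def derived_params(K: float, T_on: float, T_off: float):
    """Switching correlation time, burst size and frequency.

    ``T_C = T_ON T_OFF/(T_ON+T_OFF)``, ``B = K T_ON``,
    ``F = 1/(T_ON+T_OFF)``.
    """
    if T_on <= 0 or T_off <= 0:
        raise ValueError("durations must be positive")
    return T_on * T_off / (T_on + T_off), K * T_on, 1.0 / (T_on + T_off)


def to_single_copy(P_on: float, K: float, T_c: float):
    """Effective (two unresolved sister chromatids) to single-gene-copy.

    Assumes two identical, independent copies near steady state:
    ``P_ON(1) = 1 - sqrt(1-P_ON)``, ``K(1) = K (1+sqrt(1-P_ON))/2``,
    ``T_C(1) = 2 T_C / (1+sqrt(1-P_ON))``.
    """
    if P_on > 1 or P_on < 0:
        raise ValueError("P_ON must lie in [0, 1]")
    s = np.sqrt(1.0 - P_on)
    return 1.0 - s, K * (1.0 + s) / 2.0, 2.0 * T_c / (1.0 + s)
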