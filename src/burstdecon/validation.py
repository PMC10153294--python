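"""End-to-end synthetic validation studies.

Two drivers reproduce the package's self-validation:

* :func:`validation_grid` simulates two-sister-chromatid telegraph traces
  over a grid of single-gene-copy parameters, runs deconvolution and
  burst calling, and compares the recovered effective bursting parameters
  against censoring-aware propagator predictions (median relative
  errors per parameter and globally).
* :func:`kernel_misspecification_study` quantifies the robustness of the
  autocorrelation amplitude ``Sigma_AC`` and correlation time ``tau_AC``
  to a mis-specified elongation rate in the deconvolution kernel.

Grid sizes default to a desk-scale subset of the full study (200 alleles,
7 x 8 parameter combinations); the full ranges are
``P_ON(1) in {0.03..0.90}`` and ``T_C(1) in {0.5..10} min`` at
``K(1) = 8`` mRNA/min.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .burst_calling import BurstParameterEstimator
from .deconvolution import TraceDeconvolver, rate_from_samples
from .fluctuation import empirical_autocorrelation, fit_ac
from .gene_model import synthetic_gap_gene
from .noise_model import NoiseModel
from .synthetic import SimulationSpec, simulate_dataset
from .two_state import (
    TwoStateParams,
    build_propagator,
    expected_on_off_times,
    expected_pon,
    residence_distributions,
)

__all__ = [
    "predicted_effective_params",
    "validation_grid",
    "kernel_misspecification_study",
]

COMPARE_PARAMS = ("R", "P_ON", "K", "T_ON", "T_OFF", "T_C")


def predicted_effective_params(
    p1: TwoStateParams, times_min: np.ndarray, n_copies: int = 2
) -> dict:
    """Ground-truth effective parameters on a finite grid.

    ``R``, ``P_ON`` and ``K`` follow from the stationary occupancy of the
    two-copy chain; ``T_ON(t)``/``T_OFF(t)`` come from the first-passage
    (residence-time) machinery on the same finite grid, so they carry the
    same discreteness and censoring biases as the empirical estimator.
    """
    eta = p1.eta
    ps = build_propagator(p1.k_on, p1.k_off, times_min, n_copies=n_copies)
    if n_copies == 2:
        p0 = np.array([(1 - eta) ** 2, 2 * eta * (1 - eta), eta**2])
        on_states, off_states = (1, 2), (0,)
        K_eff = 2 * p1.k / (2 - eta)
        R_eff = 2 * p1.k * eta
    else:
        p0 = np.array([1 - eta, eta])
        on_states, off_states = (1,), (0,)
        K_eff = p1.k
        R_eff = p1.k * eta
    pon = expected_pon(ps, p0)
    W_on, Z_on = residence_distributions(ps, on_states, off_states, p0)
    W_off, Z_off = residence_distributions(ps, off_states, on_states, p0)
    t_on = expected_on_off_times(W_on, Z_on, times_min)
    t_off = expected_on_off_times(W_off, Z_off, times_min)
    with np.errstate(invalid="ignore"):
        t_c = t_on * t_off / (t_on + t_off)
    return {
        "times": times_min,
        "R": np.full_like(pon, R_eff),
        "P_ON": pon,
        "K": np.full_like(pon, K_eff),
        "T_ON": t_on,
        "T_OFF": t_off,
        "T_C": t_c,
    }


def _run_combo(
    pon1: float,
    tc1: float,
    k1: float,
    n_alleles: int,
    duration_min: float,
    seed: int,
    gene_model,
    noise_model,
    deconvolver_kwargs: dict,
    estimator_kwargs: dict,
):
    p1 = TwoStateParams.from_occupancy(k1, pon1, tc1)
    spec = SimulationSpec(
        params=p1,
        n_alleles=n_alleles,
        duration_min=duration_min,
        gene_model=gene_model,
        noise_model=noise_model,
        seed=seed,
    )
    traces, _ = simulate_dataset(spec)
    dec = TraceDeconvolver(
        gene_model, noise_model, random_state=seed + 1, **deconvolver_kwargs
    ).fit(traces)
    est = BurstParameterEstimator(**estimator_kwargs).fit(dec.samples_).params_
    return spec, traces, dec, est


def validation_grid(
    pon1_values=(0.23, 0.52),
    tc1_values=(0.5, 2.0, 5.0, 10.0),
    k1: float = 8.0,
    n_alleles: int = 20,
    duration_min: float = 50.0,
    seed: int = 0,
    n_samples: int = 3500,
    n_burn: int = 500,
    n_keep: int = 300,
    gene_model=None,
    noise_model=None,
) -> dict:
    """Simulate, deconvolve and burst-call over a parameter grid.

    Returns ``{"table": DataFrame, "global_median_rel_err": float,
    "per_param": Series}``; relative errors compare the time-median of
    each estimated effective parameter with the time-median of its
    propagator-based prediction.
    """
    gene_model = gene_model or synthetic_gap_gene(elongation_rate=2.0)
    noise_model = noise_model or NoiseModel()
    ss = np.random.SeedSequence(seed)
    combos = [(e, t) for e in pon1_values for t in tc1_values]
    seeds = [int(s) % (2**31 - 3) for s in ss.generate_state(len(combos))]
    rows = []
    for (pon1, tc1), cseed in zip(combos, seeds):
        _, _, _, est = _run_combo(
            pon1, tc1, k1, n_alleles, duration_min, cseed,
            gene_model, noise_model,
            {"n_samples": n_samples, "n_burn": n_burn, "n_keep": n_keep},
            {},
        )
        pred = predicted_effective_params(
            TwoStateParams.from_occupancy(k1, pon1, tc1), est.times
        )
        for name in COMPARE_PARAMS:
            mv = float(np.nanmedian(est.values[name]))
            pv = float(np.nanmedian(pred[name]))
            rows.append(
                {
                    "pon1": pon1,
                    "tc1": tc1,
                    "param": name,
                    "estimate": mv,
                    "prediction": pv,
                    "rel_err": abs(mv - pv) / abs(pv) if pv != 0 else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "global_median_rel_err": float(np.nanmedian(table["rel_err"])),
        "per_param": table.groupby("param")["rel_err"].median(),
    }


def kernel_misspecification_study(
    tc1: float = 2.0,
    pon1_values=(0.12, 0.36, 0.52, 0.78),
    k1: float = 8.0,
    n_alleles: int = 48,
    duration_min: float = 50.0,
    kelo_true: float = 2.0,
    kelo_alternatives=(1.5, 2.5),
    seed: int = 0,
    n_samples: int = 3500,
    n_burn: int = 500,
    n_keep: int = 250,
    noise_model=None,
    ac_fit_max_min: float = 10.0,
) -> dict:
    """Deconvolve the same traces with correct and +-25% kernels.

    Simulates the ``T_C(1) = tc1`` grid subset with the kernel built at
    ``kelo_true`` kb/min, deconvolves with kernels built at each rate in
    ``(kelo_true,) + kelo_alternatives``, and fits the empirical rate
    autocorrelation in each case.  Returns the per-condition fits and the
    mean relative deviations of ``Sigma_AC`` and ``tau_AC`` from the
    correct-kernel estimates (in %).
    """
    noise_model = noise_model or NoiseModel()
    gm_true = synthetic_gap_gene(elongation_rate=kelo_true)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31 - 3) for s in ss.generate_state(len(pon1_values))]
    kelos = (kelo_true,) + tuple(kelo_alternatives)
    rows = []
    for pon1, cseed in zip(pon1_values, seeds):
        p1 = TwoStateParams.from_occupancy(k1, pon1, tc1)
        spec = SimulationSpec(
            params=p1, n_alleles=n_alleles, duration_min=duration_min,
            gene_model=gm_true, noise_model=noise_model, seed=cseed,
        )
        traces, _ = simulate_dataset(spec)
        dt = traces[0].dt
        max_lag = int(ac_fit_max_min / dt)
        for kelo in kelos:
            gm = synthetic_gap_gene(elongation_rate=kelo)
            dec = TraceDeconvolver(
                gm, noise_model, n_samples=n_samples, n_burn=n_burn,
                n_keep=n_keep, random_state=cseed + 1,
            ).fit(traces)
            rates = np.stack(
                [rate_from_samples(psamp, v=1)[0] for psamp in dec.samples_]
            )
            lags, rho, sig, _ = empirical_autocorrelation(rates, max_lag)
            fit = fit_ac(rho, sig, dt, fit_max_min=ac_fit_max_min)
            rows.append(
                {
                    "pon1": pon1,
                    "kelo": kelo,
                    "sigma_ac": fit.sigma_ac,
                    "tau_ac": fit.tau_ac,
                    "beta": fit.beta,
                    "flagged": fit.flagged,
                }
            )
    table = pd.DataFrame(rows)
    ref = table[table["kelo"] == kelo_true].set_index("pon1")
    out = {"table": table}
    sig_errs, tau_errs = {}, {}
    for kelo in kelo_alternatives:
        sub = table[table["kelo"] == kelo].set_index("pon1")
        sig_errs[kelo] = float(
            np.mean(
                np.abs(sub["sigma_ac"] - ref["sigma_ac"]) / ref["sigma_ac"]
            )
            * 100.0
        )
        tau_errs[kelo] = float(
            np.mean(np.abs(sub["tau_ac"] - ref["tau_ac"]) / ref["tau_ac"])
            * 100.0
        )
    out["sigma_ac_rel_err_pct"] = sig_errs
    out["tau_ac_rel_err_pct"] = tau_errs
    out["sigma_ac_rel_err_mean_pct"] = float(np.mean(list(sig_errs.values())))
    return out
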