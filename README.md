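# burstdecon

Transcriptional-bursting inference from calibrated live-imaging traces
of nascent-RNA fluorescence.

Genes are transcribed in bursts: a promoter stochastically toggles
between an ON state, during which polymerases initiate at rate `K`, and
a silent OFF state.  MS2/PP7 stem-loop imaging measures the total
fluorescence of nascent transcripts at a locus — a signal that lags and
smears the underlying initiation events, because every transcript keeps
emitting until it is released.  `burstdecon` inverts that smearing.  It
is written for quantitative biologists analyzing single-allele
transcription time series (e.g. gap genes in fly embryos, MS2 reporters
in mammalian cells) and for modelers who need a telegraph-model
analytics and simulation toolbox with honest, censoring-aware finite-
trace predictions.

The pipeline:

1. **Calibration** (`burstdecon.calibration`) — convert arbitrary
   fluorescence to absolute transcript counts (C.U.) by profile matching
   against calibrated reference profiles, or by mixture-fitting an
   intensity histogram against a known count distribution; normalize
   activity cumulants across constructs.
2. **Noise model** (`burstdecon.noise_model`) — heteroscedastic
   measurement noise `sigma^2(G) = sigma_b^2 + beta1 G`, fitted from
   dual-color controls or from the lag-1-decorrelated trace variance.
3. **Deconvolution** (`burstdecon.deconvolution`) — Bayesian
   reconstruction of the binary initiation sequence at 1-s resolution
   (the polymerase-footprint limit for two unresolved sister chromatids)
   by adaptive block MCMC under an elongation-kernel likelihood; the
   posterior ensemble propagates uncertainty to everything downstream.
   Dual-color trace pairs additionally yield the elongation rate.
4. **Burst calling** (`burstdecon.burst_calling`) — super-Gaussian
   moving-average clustering of initiation events into ON/OFF periods;
   estimation of `R`, `P_ON`, `K`, `T_ON`, `T_OFF`, `T_C = T_ON T_OFF /
   (T_ON+T_OFF)`, burst size `B = K T_ON` and frequency
   `F = 1/(T_ON+T_OFF)` per spatiotemporal bin, with MCMC-propagated
   errors, plus conversion of effective (two-chromatid) parameters to
   single-gene-copy ones.
5. **Fluctuation analysis** (`burstdecon.fluctuation`) — conditional
   rate distributions `P(r|R)` with a footprint-corrected binomial
   constitutive reference, rate cumulants, and the ensemble-normalized
   rate autocorrelation with its exponential fit (`Sigma_AC`,
   `tau_AC`).
6. **Analytics & synthesis** (`burstdecon.two_state`,
   `burstdecon.synthetic`, `burstdecon.validation`) — closed-form
   telegraph moments and autocorrelation, time-ordered-exponential
   propagators, censoring-aware first-passage residence times, exact
   Gillespie and propagator-based trace generation, and end-to-end
   validation drivers.

See `docs/methods.md` for the model, estimators and numerical choices.

## Worked example

Simulate a bursty gene (two sister chromatids, telegraph kinetics with
single-copy `K(1) = 8` mRNA/min, `P_ON(1) = 0.52`, `T_C(1) = 2` min),
deconvolve, and recover the effective bursting parameters:

```python
import numpy as np
from burstdecon import (
    BurstParameterEstimator, SimulationSpec, TraceDeconvolver,
    TwoStateParams, simulate_dataset,
)

spec = SimulationSpec(
    params=TwoStateParams.from_occupancy(k=8.0, eta=0.52, T=2.0),
    n_alleles=20, duration_min=50.0, seed=11,
)
traces, _ = simulate_dataset(spec)

dec = TraceDeconvolver(spec.gene_model, spec.noise_model,
                       random_state=1).fit(traces)
est = BurstParameterEstimator().fit(dec.samples_).params_
for name in ("R", "P_ON", "K", "T_ON", "T_OFF", "T_C"):
    print(f"{name:6s} {est.median(name):6.2f}")
```

```
R        8.79
P_ON     0.81
K       10.57
T_ON     8.99
T_OFF    2.59
T_C      1.92
```

The effective (two-chromatid) references are `R = 2 K(1) P_ON(1) =
8.32` mRNA/min, `P_ON = 1-(1-0.52)^2 = 0.77` and `K = 2 K(1)/
(2-P_ON(1)) = 10.8` mRNA/min; the censoring-aware propagator
predictions for this 50-min grid put the median `T_ON`, `T_OFF` and
`T_C` at 6.6, 2.0 and 1.6 min.  At 20 alleles the rate-like parameters
land within a few percent and the duration estimates within tens of
percent (the burst-caller window merges the shortest OFF gaps, an
effect the validation grid quantifies).  `to_single_copy(0.81, 10.57,
1.92)` maps the effective values back to single-copy parameters.

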