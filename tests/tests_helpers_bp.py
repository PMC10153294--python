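"""Shared birth-death Gillespie oracle for Beta-Poisson tests."""

import numpy as np


def telegraph_bd_counts(K, P_ON, T_C, T_M, n_cells, seed):
    """Steady-state mRNA counts from an exact telegraph birth-death run."""
    rng = np.random.default_rng(seed)
    kon, koff, deg = P_ON / T_C, (1 - P_ON) / T_C, 1.0 / T_M
    out = np.empty(n_cells, dtype=int)
    for c in range(n_cells):
        t, m = 0.0, int(K * P_ON * T_M)  # warm start near the mean
        s = rng.random() < P_ON
        t_end = 6 * T_M
        while t < t_end:
            r = (kon if not s else koff) + (K if s else 0.0) + deg * m
            t += rng.exponential(1.0 / r)
            if t >= t_end:
                break
            u = rng.random() * r
            sw = kon if not s else koff
            if u < sw:
                s = not s
            elif u < sw + (K if s else 0.0):
                m += 1
            else:
                m -= 1
        out[c] = m
    return out
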