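"""Numba kernels for the adaptive block MCMC over binary initiation vectors.

Shared grid conventions (0-based):

* coarse trace points ``c = 0 .. n_t-1`` at spacing ``dt``;
* fine initiation steps ``f = 0 .. n_i-1`` at spacing ``dt_fine`` with
  ``u = dt/dt_fine`` an integer and ``n_i = n_t*u - 1``;
* the noise-free signal at coarse point ``c`` is
  ``G[c] = sum_j I[c*u - 1 - j] * kappa[j]`` (``G[0] = 0``: the first
  coarse sample carries no preceding fine steps).

The sampler uses an independence proposal ``q`` per fine step, updated by
block; ``q`` adapts toward the running configuration with learning rate
``1/(3 j)`` and is clipped away from 0/1 so every step keeps being
proposed.  Multi-channel likelihoods (dual-color traces) are supported by
stacking channels in the leading axis of ``A`` and the kernel array.
"""

import numpy as np
from numba import njit

LOG2PI = float(np.log(2 * np.pi))


@njit(cache=True)
def set_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def compute_g(I, kern, klen, u, n_t):
    """Noise-free signal at coarse resolution for one channel."""
    G = np.zeros(n_t)
    for c in range(1, n_t):
        base = c * u - 1
        jmax = klen if klen <= base + 1 else base + 1
        s = 0.0
        for j in range(jmax):
            if I[base - j] != 0:
                s += kern[j]
        G[c] = s
    return G


@njit(cache=True)
def gaussian_loglik(A, G, sb2, b1):
    ll = 0.0
    for c in range(A.size):
        var = sb2 + b1 * G[c]
        ll += -0.5 * (LOG2PI + np.log(var)) - (A[c] - G[c]) ** 2 / (2.0 * var)
    return ll


@njit(cache=True)
def total_loglik(A, I, kerns, klens, sb2, b1, u):
    """Data log-likelihood of configuration ``I`` summed over channels."""
    n_ch, n_t = A.shape
    ll = 0.0
    for ch in range(n_ch):
        G = compute_g(I, kerns[ch], klens[ch], u, n_t)
        ll += gaussian_loglik(A[ch], G, sb2[ch], b1[ch])
    return ll


@njit(cache=True)
def run_chain(
    A,
    kerns,
    klens,
    sb2,
    b1,
    p_prior,
    q,
    I,
    u,
    w_block,
    n_sweeps,
    n_burn,
    stride,
    samples,
    j_start,
    adapt_block,
    q_floor,
):
    """Run the adaptive block sampler in place.

    ``samples`` is a preallocated ``(n_keep, n_i)`` uint8 array filled with
    every ``stride``-th post-burn sweep.  Returns
    ``(acceptance_rate, final_block_width, j_end)``.
    """
    n_ch, n_t = A.shape
    n_i = I.size
    kmax = 0
    for ch in range(n_ch):
        if klens[ch] > kmax:
            kmax = klens[ch]

    G = np.zeros((n_ch, n_t))
    for ch in range(n_ch):
        G[ch] = compute_g(I, kerns[ch], klens[ch], u, n_t)

    dG = np.zeros((n_ch, n_t))
    flips = np.empty(n_i, np.int64)
    newvals = np.empty(n_i, np.uint8)

    n_acc = 0
    n_prop = 0
    acc_win = 0
    prop_win = 0
    j = j_start
    ks = 0
    w = w_block if w_block <= n_i else n_i

    # Lazy full-vector adaptation: the update q <- q (1-l) + l I applied at
    # every iteration is a geometric pull toward I, so for entries whose I
    # did not change since their last materialization it can be applied in
    # closed form with the running product C = prod(1 - l_j).  Entries are
    # materialized whenever they enter a proposal block, which is also the
    # only time I can change, so the lazy scheme is exact up to the timing
    # of the clip to [q_floor, 1-q_floor] (enforced at every proposal).
    C = 1.0
    lastC = np.full(n_i, C)

    for sweep in range(n_sweeps):
        iters = (n_i + w - 1) // w
        for _ in range(iters):
            j += 1
            n_prop += 1
            prop_win += 1
            b = np.random.randint(0, n_i - w + 1) if n_i > w else 0

            nf = 0
            logratio = 0.0
            for f in range(b, b + w):
                ratio = C / lastC[f]
                v = q[f] * ratio + I[f] * (1.0 - ratio)
                if v < q_floor:
                    v = q_floor
                elif v > 1.0 - q_floor:
                    v = 1.0 - q_floor
                q[f] = v
                lastC[f] = C
                newv = 1 if np.random.random() < q[f] else 0
                if newv != I[f]:
                    flips[nf] = f
                    newvals[nf] = newv
                    nf += 1
                    p = p_prior[f]
                    qq = q[f]
                    if newv == 1:
                        logratio += np.log(p / (1.0 - p)) + np.log(
                            (1.0 - qq) / qq
                        )
                    else:
                        logratio += np.log((1.0 - p) / p) + np.log(
                            qq / (1.0 - qq)
                        )

            accepted = False
            if nf == 0:
                accepted = True  # I' == I
            else:
                c_lo = flips[0] // u + 1
                c_hi = (flips[nf - 1] + kmax) // u
                if c_hi > n_t - 1:
                    c_hi = n_t - 1
                if c_lo <= c_hi:
                    for ch in range(n_ch):
                        for c in range(c_lo, c_hi + 1):
                            dG[ch, c] = 0.0
                    for ch in range(n_ch):
                        kl = klens[ch]
                        for idx in range(nf):
                            f = flips[idx]
                            sgn = 1.0 if newvals[idx] == 1 else -1.0
                            c1 = f // u + 1
                            c2 = (f + kl) // u
                            if c2 > n_t - 1:
                                c2 = n_t - 1
                            for c in range(c1, c2 + 1):
                                dG[ch, c] += sgn * kerns[ch, c * u - 1 - f]
                    dll = 0.0
                    for ch in range(n_ch):
                        for c in range(c_lo, c_hi + 1):
                            g_old = G[ch, c]
                            g_new = g_old + dG[ch, c]
                            if g_new < 0.0:
                                g_new = 0.0
                            var_o = sb2[ch] + b1[ch] * g_old
                            var_n = sb2[ch] + b1[ch] * g_new
                            a = A[ch, c]
                            dll += (
                                -0.5 * np.log(var_n)
                                - (a - g_new) ** 2 / (2.0 * var_n)
                                + 0.5 * np.log(var_o)
                                + (a - g_old) ** 2 / (2.0 * var_o)
                            )
                    logratio += dll
                if np.log(np.random.random()) < logratio:
                    accepted = True
                    for idx in range(nf):
                        I[flips[idx]] = newvals[idx]
                    for ch in range(n_ch):
                        for c in range(c_lo, c_hi + 1):
                            G[ch, c] += dG[ch, c]
                            if G[ch, c] < 0.0:
                                G[ch, c] = 0.0
            if accepted:
                n_acc += 1
                acc_win += 1

            # advance the shared adaptation product (learning rate 1/(3 j))
            C *= 1.0 - 1.0 / (3.0 * j)

            # during burn-in, optionally tune the block width toward the
            # 10-70% acceptance band (never above the requested width)
            if adapt_block and sweep < n_burn and prop_win >= 50:
                rate = acc_win / prop_win
                if rate < 0.10 and w > u:
                    w = int(w * 0.8)
                    if w < u:
                        w = u
                elif rate > 0.70 and w < w_block:
                    w = int(w * 1.25)
                    if w > w_block:
                        w = w_block
                acc_win = 0
                prop_win = 0

        # periodic exact refresh prevents floating-point drift in G
        if sweep % 50 == 49:
            for ch in range(n_ch):
                G[ch] = compute_g(I, kerns[ch], klens[ch], u, n_t)

        if sweep >= n_burn and (sweep - n_burn) % stride == 0:
            if ks < samples.shape[0]:
                for f in range(n_i):
                    samples[ks, f] = I[f]
                ks += 1

    # materialize the adapted proposal before returning
    for f in range(n_i):
        ratio = C / lastC[f]
        v = q[f] * ratio + I[f] * (1.0 - ratio)
        if v < q_floor:
            v = q_floor
        elif v > 1.0 - q_floor:
            v = 1.0 - q_floor
        q[f] = v
        lastC[f] = C

    return n_acc / max(n_prop, 1), w, j


@njit(cache=True)
def rates_from_configs(samples, u, n_t, v, dt):
    """Windowed rates ``r_s(t_c)``: events in the trailing ``v``-step window.

    Returns an ``(n_s, n_t)`` array in events per minute (``dt`` in min);
    windows at the start of the trace are clipped to the available steps.
    """
    n_s = samples.shape[0]
    out = np.zeros((n_s, n_t))
    for s in range(n_s):
        for c in range(1, n_t):
            hi = c * u  # exclusive
            lo = (c - v) * u
            if lo < 0:
                lo = 0
            g = 0
            for f in range(lo, hi):
                if f < samples.shape[1] and samples[s, f] != 0:
                    g += 1
            out[s, c] = g / (v * dt)
    return out
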