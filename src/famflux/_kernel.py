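"""Compiled inner loop of the collisional dynamics.

The per-collision update is sequential (every collision sees the abundances
left by the previous one), so the loop cannot be vectorised; it is
numba-compiled instead.  The RNG is numba's per-thread NumPy-legacy
generator, seeded once per run, which makes trajectories bit-reproducible
for a fixed seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _moments(V):
    # population mean / variance / skewness of the ensemble
    N = V.shape[0]
    m = 0.0
    for i in range(N):
        m += V[i]
    m /= N
    m2 = 0.0
    m3 = 0.0
    for i in range(N):
        d = V[i] - m
        m2 += d * d
        m3 += d * d * d
    m2 /= N
    m3 /= N
    sk = m3 / m2 ** 1.5 if m2 > 0.0 else 0.0
    return m, m2, sk


@njit(cache=True)
def _binom(n, p):
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    return np.random.binomial(n, p)


@njit(cache=True)
def run_collisions(V, p_h, p_d, p_l, n_sweeps, record_every, seed,
                   use_kernel, cum_w, pair_i, pair_j):
    """Run n_sweeps * N collisions in place, recording ensemble moments.

    With ``use_kernel`` the colliding pair is drawn proportionally to the
    pair weights whose cumulative sums are in ``cum_w`` (aligned with
    ``pair_i``/``pair_j``); otherwise uniformly over unordered pairs.
    """
    np.random.seed(seed)
    N = V.shape[0]
    n_rec = n_sweeps // record_every + 1
    times = np.empty(n_rec, dtype=np.int64)
    means = np.empty(n_rec)
    variances = np.empty(n_rec)
    skews = np.empty(n_rec)
    m, v, s = _moments(V)
    times[0] = 0
    means[0] = m
    variances[0] = v
    skews[0] = s
    k = 1
    # exclusive per-copy outcomes: loss first, then duplication among survivors
    p_dup = p_d / (1.0 - p_l) if p_l < 1.0 else 0.0
    total_w = cum_w[cum_w.shape[0] - 1] if use_kernel else 0.0
    for sweep in range(n_sweeps):
        for _ in range(N):
            if use_kernel:
                u = np.random.random() * total_w
                idx = np.searchsorted(cum_w, u)
                if idx >= cum_w.shape[0]:
                    idx = cum_w.shape[0] - 1
                i = pair_i[idx]
                j = pair_j[idx]
            else:
                i = np.random.randint(0, N)
                j = np.random.randint(0, N - 1)
                if j >= i:
                    j += 1
            vi = V[i]
            vj = V[j]
            # all draws use pre-collision abundances; applied simultaneously
            gain_i = _binom(vj, p_h)
            gain_j = _binom(vi, p_h)
            loss_i = _binom(vi, p_l)
            dup_i = _binom(vi - loss_i, p_dup)
            loss_j = _binom(vj, p_l)
            dup_j = _binom(vj - loss_j, p_dup)
            V[i] = vi + gain_i + dup_i - loss_i
            V[j] = vj + gain_j + dup_j - loss_j
        if (sweep + 1) % record_every == 0:
            m, v, s = _moments(V)
            times[k] = sweep + 1
            means[k] = m
            variances[k] = v
            skews[k] = s
            k += 1
    return times, means, variances, skews, V
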