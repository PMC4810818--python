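"""Numba-compiled kernels for the DES likelihood and the MCMC sampler.

These implement exactly the algorithm of :mod:`fossildes.likelihood`
(pruning recursion over bins) and :mod:`fossildes.mcmc` (block
Metropolis-Hastings with a Gibbs hyper-prior update), specialised to
packed arrays so that full chains run in compiled code.  Agreement with
the scipy-based reference path is enforced by the test suite.

State packing per chain: ``rates`` is (F, 4) ordered (d_AB, d_BA, e_A,
e_B) per frame, ``s`` is (F, 2) false-absence probabilities (s_A, s_B),
``g`` the shared exponential hyper-rate.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_RATE_BLOCK = 4  # d_AB, d_BA, e_A, e_B


@njit(cache=True)
def expm4(m):
    """exp(M) for a 4x4 matrix by scaling-and-squaring with a Taylor core."""
    norm = 0.0
    for r in range(4):
        row = abs(m[r, 0]) + abs(m[r, 1]) + abs(m[r, 2]) + abs(m[r, 3])
        if row > norm:
            norm = row
    j = 0
    while norm > 0.25:
        norm *= 0.5
        j += 1
    a = m / (2.0 ** j)
    e = np.eye(4) + a
    term = a.copy()
    for n in range(2, 18):
        term = (term @ a) / n
        e = e + term
    for _ in range(j):
        e = e @ e
    return e


@njit(cache=True)
def _frame_transition(rates, dt, out):
    """Fill ``out`` with expm(Q dt) for one frame's rate quartet."""
    d_ab, d_ba, e_a, e_b = rates[0], rates[1], rates[2], rates[3]
    q = np.zeros((4, 4))
    q[1, 0] = e_a
    q[1, 1] = -(e_a + d_ab)
    q[1, 3] = d_ab
    q[2, 0] = e_b
    q[2, 2] = -(e_b + d_ba)
    q[2, 3] = d_ba
    q[3, 1] = e_b
    q[3, 2] = e_a
    q[3, 3] = -(e_a + e_b)
    out[:, :] = expm4(q * dt)


@njit(cache=True)
def dataset_loglik(codes, present, first, frame_of_bin, p, s_a, s_b):
    """Sum of per-lineage pruning log-likelihoods.

    ``codes`` (N, K) int8 observed codes (-1 = not yet appeared),
    ``present`` (N,) present-day states, ``first`` (N,) first-appearance
    bin, ``frame_of_bin`` (K,), ``p`` (F, 4, 4) per-frame transition
    matrices, ``s_a``/``s_b`` (F,) per-frame false-absence probabilities.
    """
    n, k_bins = codes.shape
    total = 0.0
    v = np.empty(4)
    tmp = np.empty(4)
    for i in range(n):
        for j in range(4):
            v[j] = 0.0
        v[present[i]] = 1.0
        log_scale = 0.0
        for k in range(k_bins - 1, first[i], -1):
            f = frame_of_bin[k]
            pf = p[f]
            for r in range(4):
                tmp[r] = (pf[r, 0] * v[0] + pf[r, 1] * v[1]
                          + pf[r, 2] * v[2] + pf[r, 3] * v[3])
            c = codes[i, k]
            sa = s_a[f]
            sb = s_b[f]
            if c == 0:
                v[0] = tmp[0]
                v[1] = tmp[1] * sa
                v[2] = tmp[2] * sb
                v[3] = tmp[3] * sa * sb
            elif c == 1:
                v[0] = 0.0
                v[1] = tmp[1] * (1.0 - sa)
                v[2] = 0.0
                v[3] = tmp[3] * (1.0 - sa) * sb
            elif c == 2:
                v[0] = 0.0
                v[1] = 0.0
                v[2] = tmp[2] * (1.0 - sb)
                v[3] = tmp[3] * sa * (1.0 - sb)
            else:
                v[0] = 0.0
                v[1] = 0.0
                v[2] = 0.0
                v[3] = tmp[3] * (1.0 - sa) * (1.0 - sb)
            peak = v[0]
            for j in range(1, 4):
                if v[j] > peak:
                    peak = v[j]
            if peak <= 0.0:
                return -np.inf
            inv = 1.0 / peak
            for j in range(4):
                v[j] *= inv
            log_scale += math.log(peak)
        # first appearance: average over the ancestral-state prior
        # P[true range | observed range] instead of emitting
        f = frame_of_bin[first[i]]
        pf = p[f]
        for r in range(4):
            tmp[r] = (pf[r, 0] * v[0] + pf[r, 1] * v[1]
                      + pf[r, 2] * v[2] + pf[r, 3] * v[3])
        c = codes[i, first[i]]
        sa = s_a[f]
        sb = s_b[f]
        if c == 0:
            tot = ((1.0 - sa) * (1.0 - sb) * tmp[0]
                   + sa * (1.0 - sb) * tmp[1]
                   + (1.0 - sa) * sb * tmp[2] + sa * sb * tmp[3])
        elif c == 1:
            tot = (1.0 - sb) * tmp[1] + sb * tmp[3]
        elif c == 2:
            tot = (1.0 - sa) * tmp[2] + sa * tmp[3]
        else:
            tot = tmp[3]
        if tot <= 0.0:
            return -np.inf
        total += log_scale + math.log(tot)
    return total


@njit(cache=True)
def _log_prior(rates, g, a, b):
    """Exp(g) on all dispersal/extinction rates + Gamma(a,b) on g.

    The flat Beta(1,1) prior on each s contributes zero.
    """
    n_frames = rates.shape[0]
    total = 0.0
    for f in range(n_frames):
        for p_idx in range(N_RATE_BLOCK):
            total += math.log(g) - g * rates[f, p_idx]
    total += (a * math.log(b) - math.lgamma(a)
              + (a - 1.0) * math.log(g) - b * g)
    return total


@njit(cache=True)
def _reflect01(x):
    while x < 0.0 or x > 1.0:
        if x < 0.0:
            x = -x
        else:
            x = 2.0 - x
    return x


@njit(cache=True)
def run_chain(codes, present, first, frame_of_bin, n_frames, dt,
              rates_init, s_init, g_init, a, b,
              mult_window, slide_window,
              n_iter, sample_freq, beta, seed):
    """Run one Metropolis-Hastings chain; returns (samples, rates, s, g).

    One uniformly chosen parameter block is updated per iteration: a
    single anagenetic rate (multiplier proposal), a single false-absence
    probability (sliding-window proposal reflected at 0 and 1), or the
    hyper-rate g (conjugate Gibbs draw) — 6F + 1 blocks for F frames.
    ``beta`` powers the likelihood for thermodynamic integration
    (1 = plain posterior).  Samples rows: iteration, log-likelihood,
    log-prior, then per frame (d_AB, d_BA, e_A, e_B, s_A, s_B), then g.
    """
    np.random.seed(seed)
    f_count = n_frames
    rates = rates_init.copy()
    s = s_init.copy()
    g = g_init
    p = np.empty((f_count, 4, 4))
    for f in range(f_count):
        _frame_transition(rates[f], dt, p[f])
    s_a = s[:, 0].copy()
    s_b = s[:, 1].copy()
    ll = dataset_loglik(codes, present, first, frame_of_bin, p, s_a, s_b)

    n_cols = 3 + 6 * f_count + 1
    n_samples = n_iter // sample_freq
    out = np.empty((n_samples, n_cols))
    row = 0
    n_blocks = 6 * f_count + 1
    old_p = np.empty((4, 4))

    for it in range(1, n_iter + 1):
        block = int(np.random.random() * n_blocks)
        if block >= n_blocks:  # guard against u == 1.0
            block = n_blocks - 1
        if block < 4 * f_count:
            f = block // N_RATE_BLOCK
            p_idx = block % N_RATE_BLOCK
            old_rate = rates[f, p_idx]
            mult = math.exp(mult_window * (np.random.random() - 0.5))
            rates[f, p_idx] = old_rate * mult
            hastings = math.log(mult)
            old_p[:, :] = p[f]
            _frame_transition(rates[f], dt, p[f])
            ll_new = dataset_loglik(codes, present, first, frame_of_bin,
                                    p, s_a, s_b)
            if beta == 0.0:
                d_post = 0.0 if ll_new > -np.inf else -np.inf
            else:
                d_post = beta * (ll_new - ll)
            d_post += -g * (rates[f, p_idx] - old_rate) + hastings
            if math.log(np.random.random()) < d_post:
                ll = ll_new
            else:
                rates[f, p_idx] = old_rate
                p[f][:, :] = old_p
        elif block < 6 * f_count:
            sub = block - 4 * f_count
            f = sub // 2
            which = sub % 2
            if which == 0:
                old_s = s_a[f]
                s_a[f] = _reflect01(old_s + slide_window
                                    * (np.random.random() - 0.5))
            else:
                old_s = s_b[f]
                s_b[f] = _reflect01(old_s + slide_window
                                    * (np.random.random() - 0.5))
            ll_new = dataset_loglik(codes, present, first, frame_of_bin,
                                    p, s_a, s_b)
            if beta == 0.0:
                d_post = 0.0 if ll_new > -np.inf else -np.inf
            else:
                d_post = beta * (ll_new - ll)
            if math.log(np.random.random()) < d_post:
                ll = ll_new
                s[f, 0] = s_a[f]
                s[f, 1] = s_b[f]
            else:
                if which == 0:
                    s_a[f] = old_s
                else:
                    s_b[f] = old_s
        else:
            # conjugate Gibbs draw for the hyper-rate g
            total_rate = 0.0
            for f in range(f_count):
                for p_idx in range(N_RATE_BLOCK):
                    total_rate += rates[f, p_idx]
            shape = a + N_RATE_BLOCK * f_count
            g = np.random.standard_gamma(shape) / (b + total_rate)

        if it % sample_freq == 0:
            out[row, 0] = it
            out[row, 1] = ll
            out[row, 2] = _log_prior(rates, g, a, b)
            col = 3
            for f in range(f_count):
                for p_idx in range(N_RATE_BLOCK):
                    out[row, col] = rates[f, p_idx]
                    col += 1
                out[row, col] = s_a[f]
                out[row, col + 1] = s_b[f]
                col += 2
            out[row, col] = g
            row += 1
    return out[:row], rates, s, g
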