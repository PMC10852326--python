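"""Numba-compiled inner loops: forward-time Moran simulator and pair-HMM passes.

These kernels are deliberately free of Python objects: plain arrays in,
plain arrays out.  Randomness inside kernels uses numpy's legacy global
generator, seeded explicitly per call, so seeded runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Moran model with gene conversion
# ---------------------------------------------------------------------------


@njit(cache=True)
def _geometric(mean_len: float) -> int:
    # Geometric on {1,2,...} with mean mean_len, by inversion.
    if mean_len <= 1.0:
        return 1
    u = np.random.random()
    k = int(np.floor(np.log(u) / np.log1p(-1.0 / mean_len))) + 1
    return max(k, 1)


@njit(cache=True)
def _copy_fragment(pop, child, start, mean_frag, N, L):
    donor = np.random.randint(N)
    while donor == child:
        donor = np.random.randint(N)
    length = _geometric(mean_frag)
    end = min(start + length, L)
    pop[child, start:end] = pop[donor, start:end]


@njit(cache=True)
def _moran_kernel(
    pop,  # (N, Lpad) int8, row-contiguous
    pop64,  # int64 view of the same buffer, (N, Lpad // 8)
    L: int,
    mu: float,
    rho: float,
    mean_frag: float,
    n_events: int,
    hot_lo: int,
    hot_hi: int,
    hot_mult: float,
    seed: int,
) -> None:
    np.random.seed(seed)
    N = pop.shape[0]
    hot_len = hot_hi - hot_lo
    exp_mut = mu * L
    exp_conv_bg = rho * (L - hot_len)
    exp_conv_hot = rho * hot_mult * hot_len
    for _ in range(n_events):
        child = np.random.randint(N)
        parent = np.random.randint(N)
        if parent != child:
            pop64[child, :] = pop64[parent, :]  # 8-byte-wide row copy
        n_mut = np.random.poisson(exp_mut)
        for _m in range(n_mut):
            s = np.random.randint(L)
            pop[child, s] = (pop[child, s] + 1 + np.random.randint(3)) % 4
        if exp_conv_bg > 0.0:
            n_conv = np.random.poisson(exp_conv_bg)
            for _c in range(n_conv):
                s = np.random.randint(L - hot_len)
                if s >= hot_lo:
                    s += hot_len
                _copy_fragment(pop, child, s, mean_frag, N, L)
        if exp_conv_hot > 0.0:
            n_conv = np.random.poisson(exp_conv_hot)
            for _c in range(n_conv):
                s = hot_lo + np.random.randint(hot_len)
                _copy_fragment(pop, child, s, mean_frag, N, L)


def moran_simulate(
    N: int,
    L: int,
    mu: float,
    rho: float,
    mean_frag: float,
    n_events: int,
    hot_lo: int,
    hot_hi: int,
    hot_mult: float,
    seed: int,
) -> np.ndarray:
    """Forward Moran model with point mutation and gene conversion.

    Each event replaces a uniformly chosen individual with the offspring of a
    uniformly chosen parent; the newborn acquires Poisson(mu*L) point
    mutations and Poisson(rho-weighted) gene conversions whose fragments have
    geometric length with mean ``mean_frag`` and are copied from a uniformly
    chosen other individual.  Conversion initiation rate is ``rho`` per site,
    multiplied by ``hot_mult`` inside [hot_lo, hot_hi).

    Rows are padded to a multiple of 8 bytes internally so the row copy (the
    hot path) runs through an int64 view of the same buffer.
    """
    Lpad = ((L + 7) // 8) * 8
    pop = np.zeros((N, Lpad), dtype=np.int8)
    pop64 = pop.view(np.int64).reshape(N, Lpad // 8)
    _moran_kernel(pop, pop64, L, mu, rho, mean_frag, n_events,
                  hot_lo, hot_hi, hot_mult, seed)
    return np.ascontiguousarray(pop[:, :L])


# ---------------------------------------------------------------------------
# Pair HMM: one clonal state + K recombined sub-states (no bin-to-bin moves)
# ---------------------------------------------------------------------------
#
# State 0 is clonal (Bernoulli d_clonal emissions).  States 1..K are
# recombined sub-states with fixed Bernoulli emission probabilities (one per
# empirical-divergence bin); entry from clonal is t_enter * w[k], exit back to
# clonal is t_exit, self-transition 1 - t_exit.  All passes use scaled
# probabilities.


@njit(cache=True)
def hmm_forward_backward(obs, d_clonal, t_enter, t_exit, w, divs):
    """One E-step pass.  Returns
    (loglik, gamma0_sum, gamma0_x_sum, xi_cr_sum, xi_rc_sum,
     gammaR_sum, gamma0_last_excl, gammaR_last_excl, post_recomb)
    where gamma* are posterior occupancy sums for the clonal state (0) and
    the pooled recombined states, xi_* are expected transition counts, the
    *_last_excl sums exclude the final site (transition denominators), and
    post_recomb is the per-site posterior probability of being recombined.
    """
    T = obs.shape[0]
    K = w.shape[0]
    nstate = K + 1
    e1 = np.empty(nstate)
    e0 = np.empty(nstate)
    e1[0] = d_clonal
    e0[0] = 1.0 - d_clonal
    for k in range(K):
        e1[k + 1] = divs[k]
        e0[k + 1] = 1.0 - divs[k]

    alpha = np.empty((T, nstate))
    scale = np.empty(T)

    # initial distribution: quasi-stationary split between clonal/recombined
    pi_r = t_enter / (t_enter + t_exit) if (t_enter + t_exit) > 0 else 0.0
    s = 0.0
    for k in range(nstate):
        e = e1[k] if obs[0] == 1 else e0[k]
        p = (1.0 - pi_r) * e if k == 0 else pi_r * w[k - 1] * e
        alpha[0, k] = p
        s += p
    scale[0] = s
    for k in range(nstate):
        alpha[0, k] /= s

    stay_c = 1.0 - t_enter
    stay_r = 1.0 - t_exit
    for t in range(1, T):
        # mass flowing into clonal: from clonal stay + any recombined exit
        sum_r = 0.0
        for k in range(1, nstate):
            sum_r += alpha[t - 1, k]
        o = obs[t]
        a0 = (alpha[t - 1, 0] * stay_c + sum_r * t_exit) * (e1[0] if o == 1 else e0[0])
        s = a0
        alpha[t, 0] = a0
        enter_mass = alpha[t - 1, 0] * t_enter
        for k in range(1, nstate):
            ak = (enter_mass * w[k - 1] + alpha[t - 1, k] * stay_r) * (
                e1[k] if o == 1 else e0[k]
            )
            alpha[t, k] = ak
            s += ak
        scale[t] = s
        inv = 1.0 / s
        for k in range(nstate):
            alpha[t, k] *= inv

    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t])

    # backward pass with on-the-fly accumulation
    beta = np.ones(nstate)
    post_recomb = np.empty(T)
    gamma0_sum = 0.0
    gamma0_x = 0.0
    gammaR_sum = 0.0
    xi_cr = 0.0
    xi_rc = 0.0
    gamma0_last_excl = 0.0
    gammaR_last_excl = 0.0

    # site T-1 occupancies
    g0 = alpha[T - 1, 0]
    gamma0_sum += g0
    if obs[T - 1] == 1:
        gamma0_x += g0
    gammaR_sum += 1.0 - g0
    post_recomb[T - 1] = 1.0 - g0

    newbeta = np.empty(nstate)
    for t in range(T - 2, -1, -1):
        o = obs[t + 1]
        # eb[k] = emission(obs[t+1], k) * beta[k]
        # clonal next contribution
        eb0 = (e1[0] if o == 1 else e0[0]) * beta[0]
        # recombined next contributions weighted for entry
        enter_next = 0.0
        for k in range(1, nstate):
            enter_next += w[k - 1] * (e1[k] if o == 1 else e0[k]) * beta[k]
        inv_scale = 1.0 / scale[t + 1]
        newbeta[0] = (stay_c * eb0 + t_enter * enter_next) * inv_scale
        for k in range(1, nstate):
            ebk = (e1[k] if o == 1 else e0[k]) * beta[k]
            newbeta[k] = (t_exit * eb0 + stay_r * ebk) * inv_scale

        # occupancy at t
        g0 = alpha[t, 0] * newbeta[0]
        norm = g0
        for k in range(1, nstate):
            norm += alpha[t, k] * newbeta[k]
        # norm should be ~1 by scaling; normalize to be safe
        g0 /= norm
        gamma0_sum += g0
        if obs[t] == 1:
            gamma0_x += g0
        gR = 1.0 - g0
        gammaR_sum += gR
        post_recomb[t] = gR
        gamma0_last_excl += g0
        gammaR_last_excl += gR

        # expected transitions t -> t+1
        xi_cr_t = alpha[t, 0] * t_enter * enter_next * inv_scale
        exit_mass = 0.0
        for k in range(1, nstate):
            exit_mass += alpha[t, k]
        xi_rc_t = exit_mass * t_exit * eb0 * inv_scale
        xi_cr += xi_cr_t / norm
        xi_rc += xi_rc_t / norm

        for k in range(nstate):
            beta[k] = newbeta[k]

    return (
        loglik,
        gamma0_sum,
        gamma0_x,
        xi_cr,
        xi_rc,
        gammaR_sum,
        gamma0_last_excl,
        gammaR_last_excl,
        post_recomb,
    )


@njit(cache=True)
def hmm_viterbi(obs, d_clonal, t_enter, t_exit, w, divs):
    """Viterbi path; returns int8 array (0 = clonal, 1 = recombined).

    Sub-state identity is collapsed: downstream statistics re-estimate each
    event's divergence from the data.  Ties prefer the clonal state.
    """
    T = obs.shape[0]
    K = w.shape[0]
    nstate = K + 1
    le1 = np.empty(nstate)
    le0 = np.empty(nstate)
    tiny = 1e-300
    le1[0] = np.log(d_clonal + tiny)
    le0[0] = np.log(1.0 - d_clonal + tiny)
    for k in range(K):
        le1[k + 1] = np.log(divs[k] + tiny)
        le0[k + 1] = np.log(1.0 - divs[k] + tiny)
    l_stay_c = np.log(1.0 - t_enter + tiny)
    l_stay_r = np.log(1.0 - t_exit + tiny)
    l_exit = np.log(t_exit + tiny)
    l_enter = np.empty(K)
    for k in range(K):
        l_enter[k] = np.log(t_enter * w[k] + tiny)

    delta = np.empty(nstate)
    pi_r = t_enter / (t_enter + t_exit) if (t_enter + t_exit) > 0 else 0.0
    for k in range(nstate):
        e = le1[k] if obs[0] == 1 else le0[k]
        if k == 0:
            delta[k] = np.log(1.0 - pi_r + tiny) + e
        else:
            delta[k] = np.log(pi_r * w[k - 1] + tiny) + e

    back = np.empty((T, nstate), dtype=np.uint8)  # predecessor state index
    newdelta = np.empty(nstate)
    for t in range(1, T):
        o = obs[t]
        # best predecessor for clonal: clonal stay vs best recombined exit
        best_r = delta[1]
        best_rk = 1
        for k in range(2, nstate):
            if delta[k] > best_r:
                best_r = delta[k]
                best_rk = k
        from_c = delta[0] + l_stay_c
        from_r = best_r + l_exit
        if from_c >= from_r:  # tie -> clonal origin
            newdelta[0] = from_c
            back[t, 0] = 0
        else:
            newdelta[0] = from_r
            back[t, 0] = best_rk
        e = le1[0] if o == 1 else le0[0]
        newdelta[0] += e
        for k in range(1, nstate):
            enter = delta[0] + l_enter[k - 1]
            stay = delta[k] + l_stay_r
            if enter > stay:
                newdelta[k] = enter
                back[t, k] = 0
            else:  # tie -> stay (conservative: fewer event entries)
                newdelta[k] = stay
                back[t, k] = k
            e = le1[k] if o == 1 else le0[k]
            newdelta[k] += e
        for k in range(nstate):
            delta[k] = newdelta[k]

    # terminal state: prefer clonal on ties
    best_k = 0
    best_v = delta[0]
    for k in range(1, nstate):
        if delta[k] > best_v:
            best_v = delta[k]
            best_k = k

    path = np.empty(T, dtype=np.int8)
    state = best_k
    for t in range(T - 1, -1, -1):
        path[t] = 0 if state == 0 else 1
        if t > 0:
            state = back[t, state]
    return path
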