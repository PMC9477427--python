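"""Numba inner loop of the Gillespie simulation.

One call advances a single trajectory through a time segment during which the
kinetic parameters, the enzyme profile and the contact kernel are constant and
no replication or protocol event occurs (the driver in :mod:`.engine` cuts the
timeline at those boundaries and applies them itself).

The statistically exact algorithm: the total propensity A is the sum of
per-site outflow rates a_i; waiting times are Exp(A)-distributed; the firing
site is drawn proportionally to a_i and the reaction within the site
proportionally to its components.  The spreading field
S(i) = sum_j P(i,j) psi_suz12(j) [j is me3] is cached and updated only when a
site enters or leaves me3; per-site rates are kept incrementally with a
periodic full refresh to cancel floating-point drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# state codes, kept in sync with kinetics.py
_U, _AC, _ME1, _ME2, _ME3 = 0, 1, 2, 3, 4

_REFRESH_EVERY = 4096


@njit(cache=False)
def _site_rate(i, s, psi_s, psi_p, psi_u, S,
               kme1, kme2, kme3, eps1, eps2, eps3,
               gamma_me, k_ac, gamma_ac, gamma_turn):
    if s == _U:
        return kme1 * psi_s[i] + eps1 * S[i] + k_ac * psi_p[i]
    if s == _AC:
        return gamma_ac + gamma_turn
    if s == _ME1:
        return kme2 * psi_s[i] + eps2 * S[i] + gamma_me * psi_u[i] + gamma_turn
    if s == _ME2:
        return kme3 * psi_s[i] + eps3 * S[i] + gamma_me * psi_u[i] + gamma_turn
    return gamma_me * psi_u[i] + gamma_turn  # me3


@njit(cache=False)
def run_segment(state, pools, t0, t1,
                psi_s, psi_p, psi_u, P,
                kme1, kme2, kme3, eps1, eps2, eps3,
                gamma_me, k_ac, gamma_ac, gamma_turn,
                rec_times, rec_states, rec_pools, rec_offset,
                label_active, seed):
    """Advance ``state`` in place from t0 to t1; snapshot at ``rec_times``.

    ``rec_times`` must lie in (t0, t1]; snapshots are written to
    ``rec_states[rec_offset + k]`` / ``rec_pools[rec_offset + k]``.  When
    ``label_active`` a histone lost to turnover is relabeled pool 1 ("new").
    Returns the number of snapshots taken (always ``len(rec_times)``).
    """
    np.random.seed(seed)
    n = state.shape[0]

    # spreading field from the current me3 set
    S = np.zeros(n)
    for j in range(n):
        if state[j] == _ME3:
            w = psi_s[j]
            for i in range(n):
                S[i] += P[i, j] * w

    a = np.empty(n)
    for i in range(n):
        a[i] = _site_rate(i, state[i], psi_s, psi_p, psi_u, S,
                          kme1, kme2, kme3, eps1, eps2, eps3,
                          gamma_me, k_ac, gamma_ac, gamma_turn)
    A = a.sum()

    t = t0
    rec_ptr = 0
    n_rec = rec_times.shape[0]
    since_refresh = 0

    while True:
        if A <= 1e-300:
            t_next = t1 + 1.0  # no reaction can fire
        else:
            t_next = t - np.log(np.random.random()) / A

        # snapshots strictly before the next reaction (state is constant there)
        while rec_ptr < n_rec and rec_times[rec_ptr] <= min(t_next, t1):
            for i in range(n):
                rec_states[rec_offset + rec_ptr, i] = state[i]
                rec_pools[rec_offset + rec_ptr, i] = pools[i]
            rec_ptr += 1

        if t_next > t1:
            break
        t = t_next

        # pick the firing site proportionally to a_i
        r = np.random.random() * A
        acc = 0.0
        site = n - 1
        for i in range(n):
            acc += a[i]
            if r < acc:
                site = i
                break

        # pick the reaction within the site
        s = state[site]
        me3_changed = False
        if s == _U:
            meth = kme1 * psi_s[site] + eps1 * S[site]
            tot = meth + k_ac * psi_p[site]
            if np.random.random() * tot < meth:
                state[site] = _ME1
            else:
                state[site] = _AC
        elif s == _AC:
            tot = gamma_ac + gamma_turn
            if np.random.random() * tot < gamma_ac:
                state[site] = _U
            else:
                state[site] = _U
                if label_active:
                    pools[site] = 1
        elif s == _ME1:
            meth = kme2 * psi_s[site] + eps2 * S[site]
            down = gamma_me * psi_u[site]
            r2 = np.random.random() * (meth + down + gamma_turn)
            if r2 < meth:
                state[site] = _ME2
            elif r2 < meth + down:
                state[site] = _U
            else:
                state[site] = _U
                if label_active:
                    pools[site] = 1
        elif s == _ME2:
            meth = kme3 * psi_s[site] + eps3 * S[site]
            down = gamma_me * psi_u[site]
            r2 = np.random.random() * (meth + down + gamma_turn)
            if r2 < meth:
                state[site] = _ME3
                me3_changed = True
            elif r2 < meth + down:
                state[site] = _ME1
            else:
                state[site] = _U
                if label_active:
                    pools[site] = 1
        else:  # me3
            down = gamma_me * psi_u[site]
            r2 = np.random.random() * (down + gamma_turn)
            if r2 < down:
                state[site] = _ME2
            else:
                state[site] = _U
                if label_active:
                    pools[site] = 1
            me3_changed = True

        # update cached rates
        if me3_changed:
            w = psi_s[site]
            sign = 1.0 if state[site] == _ME3 else -1.0
            for i in range(n):
                S[i] += sign * P[i, site] * w
            for i in range(n):
                a[i] = _site_rate(i, state[i], psi_s, psi_p, psi_u, S,
                                  kme1, kme2, kme3, eps1, eps2, eps3,
                                  gamma_me, k_ac, gamma_ac, gamma_turn)
            A = a.sum()
        else:
            old = a[site]
            a[site] = _site_rate(site, state[site], psi_s, psi_p, psi_u, S,
                                 kme1, kme2, kme3, eps1, eps2, eps3,
                                 gamma_me, k_ac, gamma_ac, gamma_turn)
            A += a[site] - old
            since_refresh += 1
            if since_refresh >= _REFRESH_EVERY:
                A = a.sum()
                since_refresh = 0

    return rec_ptr
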