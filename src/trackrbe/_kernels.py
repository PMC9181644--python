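"""Numba kernels for the Monte Carlo survival engines.

These mirror the pure-Python reference path (``DamageState`` + the repair
ops) exactly in distribution; a statistical-equivalence test keeps the two
honest.  Damage is stored per iteration as flat arrays (domain index,
absolute expiry time) with swap-removal; ``single_idx`` caches the damage
index of every domain currently holding exactly one break so the
isolated→clustered lifetime redraw is O(1).

Within one advance, removals are processed in array order rather than expiry
order; the classification of each removal depends only on the domain count
at the moment of removal, and the multiset of classes per domain is
invariant under removal order, so the sampled distribution is unchanged.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _exp_lifetime(mean):
    if mean == np.inf:
        return np.inf
    return np.random.exponential(mean)


@njit(cache=True)
def _add_break(d, now, counts, single_idx, dom, exp_t, n_active, tau_i, tau_c):
    """Insert one break into domain d at time ``now``; returns new n_active."""
    c = counts[d]
    if c == 0:
        e = now + _exp_lifetime(tau_i)
        single_idx[d] = n_active
    else:
        if c == 1:
            j = single_idx[d]
            exp_t[j] = now + _exp_lifetime(tau_c)
        e = now + _exp_lifetime(tau_c)
    dom[n_active] = d
    exp_t[n_active] = e
    counts[d] = c + 1
    return n_active + 1


@njit(cache=True)
def _advance(
    t_end, counts, single_idx, dom, exp_t, n_active, k_i, k_c, sample_mode, weight
):
    """Repair every break with expiry <= t_end.

    Returns (n_active, weight, flagged).  In sample mode a failed repair sets
    ``flagged`` and aborts immediately (the iteration scores zero anyway).
    """
    flagged = False
    j = 0
    while j < n_active:
        if exp_t[j] <= t_end:
            d = dom[j]
            if counts[d] >= 2:
                k = k_c
            else:
                k = k_i
            if sample_mode:
                if np.random.random() < k:
                    flagged = True
            else:
                weight *= 1.0 - k
            counts[d] -= 1
            n_active -= 1
            dom[j] = dom[n_active]
            exp_t[j] = exp_t[n_active]
            if counts[d] == 1:
                for m in range(n_active):
                    if dom[m] == d:
                        single_idx[d] = m
                        break
            dm = dom[j]
            if counts[dm] == 1 and single_idx[dm] == n_active:
                single_idx[dm] = j
            if flagged:
                return n_active, weight, True
        else:
            j += 1
    return n_active, weight, False


@njit(cache=True)
def _score_and_reset(counts, dom, n_active, k_i, k_c, weight):
    """Survival-law factor for the residual pattern; zeroes counts as it goes."""
    n_i = 0
    n_c = 0
    for j in range(n_active):
        d = dom[j]
        c = counts[d]
        if c == 1:
            n_i += 1
            counts[d] = 0
        elif c >= 2:
            n_c += 1
            counts[d] = 0
    return weight * (1.0 - k_i) ** n_i * (1.0 - k_c) ** n_c


@njit(cache=True)
def _clear_counts(counts, dom, n_active):
    for j in range(n_active):
        counts[dom[j]] = 0


@njit(cache=True)
def photon_kernel(
    n_iter,
    n_domains,
    mu_total,
    n_steps,
    total_time,
    tau_i,
    tau_c,
    k_i,
    k_c,
    sample_mode,
    seed,
):
    """Sparsely-ionizing (photon) engine, acute when total_time == 0.

    Per time step: Poisson(mu_total/n_steps) breaks are allocated uniformly
    over domains at the step start, then repair advances to the step end.
    Returns one survival value per iteration.
    """
    np.random.seed(seed)
    out = np.empty(n_iter)
    counts = np.zeros(n_domains, np.int32)
    single_idx = np.zeros(n_domains, np.int32)
    cap = int(mu_total + 12.0 * math.sqrt(mu_total + 1.0)) + 64
    dom = np.empty(cap, np.int32)
    exp_t = np.empty(cap, np.float64)
    mu_part = mu_total / n_steps
    dt = total_time / n_steps
    for it in range(n_iter):
        n_active = 0
        weight = 1.0
        flagged = False
        for step in range(n_steps):
            t_now = step * dt
            n_new = np.random.poisson(mu_part)
            for _ in range(n_new):
                if n_active >= cap:
                    raise RuntimeError("damage capacity exceeded")
                d = np.random.randint(0, n_domains)
                n_active = _add_break(
                    d, t_now, counts, single_idx, dom, exp_t, n_active, tau_i, tau_c
                )
            n_active, weight, flagged = _advance(
                (step + 1) * dt,
                counts,
                single_idx,
                dom,
                exp_t,
                n_active,
                k_i,
                k_c,
                sample_mode,
                weight,
            )
            if flagged:
                break
        if flagged:
            _clear_counts(counts, dom, n_active)
            out[it] = 0.0
        else:
            out[it] = _score_and_reset(counts, dom, n_active, k_i, k_c, weight)
    return out


@njit(cache=True)
def ion_kernel(
    n_iter,
    col_x,
    col_y,
    n_z,
    mean_tracks,
    n_steps,
    total_time,
    r_sample,
    dose_table,
    inv_dr,
    cutoff_sq,
    yield_per_gy,
    tau_i,
    tau_c,
    k_i,
    k_c,
    sample_mode,
    seed,
    cap,
):
    """Ion engine: per step, Poisson track count, uniform positions in the
    sampling disk, radial-lookup deposit onto domain columns, per-domain
    Poisson breaks from the (enhancement-weighted) column dose, then repair.

    ``dose_table[i]`` is the effective (enhancement-weighted) domain dose for
    a track whose axis passes at distance ``i/inv_dr`` from the column centre
    — the area average of the three-step profile over the domain
    cross-section — so ``yield_per_gy * column_sum`` is directly the
    per-domain DSB expectation.  Acute when total_time == 0.
    """
    np.random.seed(seed)
    n_cols = col_x.size
    n_domains = n_cols * n_z
    n_table = dose_table.size
    out = np.empty(n_iter)
    counts = np.zeros(n_domains, np.int32)
    single_idx = np.zeros(n_domains, np.int32)
    dom = np.empty(cap, np.int32)
    exp_t = np.empty(cap, np.float64)
    col_eff = np.zeros(n_cols, np.float64)
    mu_tracks_part = mean_tracks / n_steps
    dt = total_time / n_steps
    for it in range(n_iter):
        n_active = 0
        weight = 1.0
        flagged = False
        for step in range(n_steps):
            t_now = step * dt
            for ci in range(n_cols):
                col_eff[ci] = 0.0
            n_tr = np.random.poisson(mu_tracks_part)
            for _ in range(n_tr):
                # uniform position in the sampling disk (rejection sampling)
                while True:
                    x = (2.0 * np.random.random() - 1.0) * r_sample
                    y = (2.0 * np.random.random() - 1.0) * r_sample
                    if x * x + y * y <= r_sample * r_sample:
                        break
                for ci in range(n_cols):
                    dx = x - col_x[ci]
                    dy = y - col_y[ci]
                    dsq = dx * dx + dy * dy
                    if dsq <= cutoff_sq:
                        idx = int(math.sqrt(dsq) * inv_dr)
                        if idx < n_table:
                            col_eff[ci] += dose_table[idx]
            for ci in range(n_cols):
                ce = col_eff[ci]
                if ce > 0.0:
                    # Poisson splitting over the n_z domains of the column
                    n_new = np.random.poisson(yield_per_gy * ce * n_z)
                    for _ in range(n_new):
                        if n_active >= cap:
                            raise RuntimeError("damage capacity exceeded")
                        d = ci * n_z + np.random.randint(0, n_z)
                        n_active = _add_break(
                            d,
                            t_now,
                            counts,
                            single_idx,
                            dom,
                            exp_t,
                            n_active,
                            tau_i,
                            tau_c,
                        )
            n_active, weight, flagged = _advance(
                (step + 1) * dt,
                counts,
                single_idx,
                dom,
                exp_t,
                n_active,
                k_i,
                k_c,
                sample_mode,
                weight,
            )
            if flagged:
                break
        if flagged:
            _clear_counts(counts, dom, n_active)
            out[it] = 0.0
        else:
            out[it] = _score_and_reset(counts, dom, n_active, k_i, k_c, weight)
    return out
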