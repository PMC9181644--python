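"""Repair kinetics: exponential lifetimes, cluster upgrades, misrepair.

Every DSB carries an absolute expiry time drawn from an exponential
distribution whose *median* equals the repair half-life of its class at
creation (rate λ = ln2 / T½).  A break landing in a domain that already
holds exactly one DSB upgrades that domain to a cluster and the pre-existing
break's lifetime is redrawn from the slow (clustered) distribution.  When a
break's lifetime expires it is removed; each removal fails ("misrepair")
with probability K_i or K_c according to the domain's classification *at
removal time*, and any misrepair inactivates the cell.  When a cluster
shrinks back to a single break the domain reclassifies as isolated but the
surviving break keeps its current (slow) lifetime — redraws happen only on
upgrade.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import LN2
from .damage import (
    DamageState,
    EndpointParams,
    classify_domains,
    survival_probability,
)

__all__ = ["sample_lifetime", "add_damage", "advance_state", "finalize_survival"]


def sample_lifetime(t_half: float, rng: np.random.Generator) -> float:
    """Exponential lifetime with median ``t_half`` (mean ``t_half/ln 2``)."""
    if not t_half > 0:
        raise ValueError("t_half must be positive")
    if math.isinf(t_half):
        return math.inf
    return rng.exponential(t_half / LN2)


def add_damage(
    state: DamageState,
    new_dsb: np.ndarray,
    params: EndpointParams,
    rng: np.random.Generator,
) -> DamageState:
    """Deposit new per-domain DSB counts at the state's current time.

    Mutates and returns ``state``.  Breaks are inserted one at a time so a
    second break arriving in the same call still triggers the isolated→
    clustered upgrade (with lifetime redraw) for the first.
    """
    new_dsb = np.asarray(new_dsb)
    if (new_dsb < 0).any():
        raise ValueError("new_dsb counts must be >= 0")
    now = state.elapsed_time
    for d in np.flatnonzero(new_dsb):
        for _ in range(int(new_dsb[d])):
            c = int(state.counts[d])
            if c == 0:
                expiry = now + sample_lifetime(params.t_half_idsb, rng)
            else:
                if c == 1:  # upgrade: redraw the resident break's lifetime
                    for j in range(len(state.dmg_domain) - 1, -1, -1):
                        if state.dmg_domain[j] == d:
                            state.dmg_expiry[j] = now + sample_lifetime(
                                params.t_half_cdsb, rng
                            )
                            break
                expiry = now + sample_lifetime(params.t_half_cdsb, rng)
            state.dmg_domain.append(int(d))
            state.dmg_expiry.append(float(expiry))
            state.counts[d] = c + 1
    return state


def advance_state(
    state: DamageState,
    dt: float,
    params: EndpointParams,
    rng: np.random.Generator,
    misrepair: str = "sample",
) -> DamageState:
    """Advance time by ``dt`` minutes, repairing every break whose expiry
    falls inside the interval (processed in expiry order).

    ``misrepair="sample"`` draws a Bernoulli failure per removal and sets the
    misrepair flag (the defining algorithm); ``misrepair="weight"`` instead
    multiplies the state's survival weight by (1 - K_class) — the exact
    conditional expectation over those Bernoulli draws, useful as a
    variance-reduced estimator.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if misrepair not in ("sample", "weight"):
        raise ValueError("misrepair must be 'sample' or 'weight'")
    t_end = state.elapsed_time + dt
    while True:
        due = [j for j, t in enumerate(state.dmg_expiry) if t <= t_end]
        if not due:
            break
        j = min(due, key=state.dmg_expiry.__getitem__)
        d = state.dmg_domain[j]
        k = params.k_cdsb if state.counts[d] >= 2 else params.k_idsb
        if misrepair == "sample":
            if rng.random() < k:
                state.misrepair_flag = True
        else:
            state.weight *= 1.0 - k
        del state.dmg_domain[j]
        del state.dmg_expiry[j]
        state.counts[d] -= 1
    state.elapsed_time = t_end
    return state


def finalize_survival(state: DamageState, params: EndpointParams) -> float:
    """Survival of one iteration: 0 on misrepair, else the survival law on
    the residual damage pattern (times any accumulated survival weight)."""
    if state.misrepair_flag:
        return 0.0
    n_i, n_c = classify_domains(state)
    return state.weight * survival_probability(n_i, n_c, params)
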