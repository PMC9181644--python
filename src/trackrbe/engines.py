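"""Monte Carlo survival engines for photon and ion irradiation.

Two interchangeable implementations exist for every stochastic engine:

* ``method="numba"`` (default) — compiled kernels in :mod:`trackrbe._kernels`,
  fast enough for iso-effect solving at full problem sizes;
* ``method="python"`` — a literal composition of the ``DamageState`` /
  repair-kinetics operations, kept as the readable reference semantics.

Both are exercised against each other and against exact expectations
(closed-form photon survival, compound-Poisson single-domain ion survival)
in the test suite.  Time-resolved engines divide the irradiation time into
``n_timesteps`` equal sub-intervals and deposit each partial dose at the
sub-interval start; ``dose_rate = inf`` (or total_time 0) is the acute limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels
from .constants import LN2, RHO_WATER, fluence_per_gy
from .damage import (
    DamageState,
    EndpointParams,
    NucleusModel,
    allocate_dsb_uniform,
)
from .repair import add_damage, advance_state, finalize_survival
from .track import (
    DEFAULT_SIGMA_UM,
    IdentityEnhancement,
    ParticleState,
    StepProfile,
    build_profile,
    diffuse_profile,
    step_area_average,
    three_step_parametrization,
)

__all__ = [
    "IrradiationProtocol",
    "SurvivalEstimate",
    "photon_survival_closed_form",
    "simulate_photon_acute",
    "simulate_photon_timed",
    "expected_track_count",
    "deposit_track",
    "simulate_ion_acute",
    "simulate_ion_timed",
    "ion_step_profile",
]


@dataclass(frozen=True)
class IrradiationProtocol:
    """One delivery: total dose, dose rate, fractionation, time resolution.

    ``dose_rate`` is in Gy/min; ``math.inf`` means acute delivery.
    ``particle=None`` marks sparsely ionizing (photon) irradiation.
    """

    total_dose: float
    dose_rate: float = math.inf
    n_fractions: int = 1
    n_timesteps: int = 100
    particle: ParticleState | None = None
    reference: bool = False

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise ValueError("total_dose must be >= 0")
        if not self.dose_rate > 0:
            raise ValueError("dose_rate must be positive (inf = acute)")
        if self.n_fractions < 1 or self.n_timesteps < 1:
            raise ValueError("n_fractions and n_timesteps must be >= 1")

    @property
    def fraction_dose(self) -> float:
        return self.total_dose / self.n_fractions

    @property
    def fraction_time(self) -> float:
        """Irradiation time of one fraction, minutes (0 if acute)."""
        if math.isinf(self.dose_rate):
            return 0.0
        return self.fraction_dose / self.dose_rate


@dataclass(frozen=True)
class SurvivalEstimate:
    mean: float
    se: float
    n_iterations: int
    seed: int
    protocol: IrradiationProtocol | None = None

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.mean <= 1.0 + 1e-12):
            raise ValueError("mean survival outside [0, 1]")
        if self.se < 0 or self.n_iterations < 1:
            raise ValueError("invalid estimate metadata")


def _estimate(survivals: np.ndarray, seed: int, protocol=None) -> SurvivalEstimate:
    n = survivals.size
    mean = float(survivals.mean())
    se = float(survivals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return SurvivalEstimate(mean, se, n, seed, protocol)


def _mask_seed(seed: int) -> int:
    return int(seed) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# photon engines
# ---------------------------------------------------------------------------

def photon_survival_closed_form(
    dose: float, params: EndpointParams, nucleus: NucleusModel
) -> float:
    """Exact expectation of acute photon survival.

    Uniform allocation of a Poisson number of breaks makes the per-domain
    counts independent Poisson(mu) with mu = alpha_dsb·dose/n_domains, so

        E[S] = [e^-mu + mu e^-mu (1-K_i) + (1 - e^-mu - mu e^-mu)(1-K_c)]^N.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    n = nucleus.n_domains
    mu = params.alpha_dsb * dose / n
    p0 = math.exp(-mu)
    p1 = mu * p0
    f = p0 + p1 * (1.0 - params.k_idsb) + (1.0 - p0 - p1) * (1.0 - params.k_cdsb)
    return f**n


def _photon_python(
    mu_total, n_domains, n_steps, total_time, params, n_iter, seed, misrepair
):
    rng = np.random.default_rng(seed)
    nuc = _DomainsOnly(n_domains)
    dt = total_time / n_steps
    out = np.empty(n_iter)
    for it in range(n_iter):
        state = DamageState(n_domains=n_domains)
        for step in range(n_steps):
            n_new = rng.poisson(mu_total / n_steps)
            new = allocate_dsb_uniform(int(n_new), nuc, rng)
            add_damage(state, new, params, rng)
            advance_state(state, dt, params, rng, misrepair=misrepair)
            if state.misrepair_flag:
                break
        out[it] = finalize_survival(state, params)
    return out


class _DomainsOnly:
    """Minimal stand-in exposing n_domains for allocation helpers."""

    def __init__(self, n_domains: int) -> None:
        self.n_domains = n_domains


def simulate_photon_acute(
    dose: float,
    params: EndpointParams,
    nucleus: NucleusModel,
    n_iter: int = 10_000,
    seed: int = 0,
    method: str = "numba",
) -> SurvivalEstimate:
    """Acute photon survival: Poisson total damage, uniform allocation,
    survival law per iteration, averaged."""
    proto = IrradiationProtocol(total_dose=dose)
    return simulate_photon_timed(
        proto, params, nucleus, n_iter=n_iter, seed=seed, method=method
    )


def simulate_photon_timed(
    protocol: IrradiationProtocol,
    params: EndpointParams,
    nucleus: NucleusModel,
    n_iter: int = 10_000,
    seed: int = 0,
    misrepair: str = "sample",
    method: str = "numba",
) -> SurvivalEstimate:
    """Time-resolved photon survival for a single fraction of the protocol."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    mu_total = params.alpha_dsb * protocol.fraction_dose
    total_time = protocol.fraction_time
    n_steps = protocol.n_timesteps if total_time > 0 else 1
    seed = _mask_seed(seed)
    tau_i = params.t_half_idsb / LN2
    tau_c = params.t_half_cdsb / LN2
    if method == "numba":
        surv = _kernels.photon_kernel(
            n_iter,
            nucleus.n_domains,
            mu_total,
            n_steps,
            total_time,
            tau_i,
            tau_c,
            params.k_idsb,
            params.k_cdsb,
            misrepair == "sample",
            seed,
        )
    elif method == "python":
        surv = _photon_python(
            mu_total,
            nucleus.n_domains,
            n_steps,
            total_time,
            params,
            n_iter,
            seed,
            misrepair,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return _estimate(surv, seed, protocol)


# ---------------------------------------------------------------------------
# ion engines
# ---------------------------------------------------------------------------

def expected_track_count(
    dose: float, let: float, sampling_area: float, rho: float = RHO_WATER
) -> float:
    """Expected number of tracks through ``sampling_area`` (µm²) for a mean
    dose in Gy at the given LET (keV/µm), via the fluence–dose relation."""
    if dose < 0 or let <= 0 or sampling_area <= 0:
        raise ValueError("need dose >= 0, let > 0, sampling_area > 0")
    return dose * fluence_per_gy(let, rho) * sampling_area


def deposit_track(
    position: tuple[float, float], step_profile: StepProfile, nucleus: NucleusModel
) -> np.ndarray:
    """Per-domain dose (Gy) from one track at ``position`` (µm, nucleus
    centre at the origin).

    The dose to a domain is the area average of the step profile over the
    domain's cross-section (equal-area circle), i.e. the energy the track
    deposits inside the domain divided by the domain mass; tracks run
    parallel to the cylinder axis so all domains of a column receive the
    same dose.  Domains are ordered column-major: domain ``ci*n_z + iz``.
    """
    a_eq = nucleus.domain_side / math.sqrt(math.pi)
    dr, table = step_area_average(step_profile, a_eq)
    x, y = position
    d = np.hypot(nucleus.col_x - x, nucleus.col_y - y)
    col_dose = _table_lookup(d, dr, table)
    return np.repeat(col_dose, nucleus.n_z)


def _table_lookup(d: np.ndarray, dr: float, table: np.ndarray) -> np.ndarray:
    idx = (np.asarray(d, dtype=float) / dr).astype(np.int64)
    out = np.zeros(idx.shape)
    ok = idx < table.size
    out[ok] = table[idx[ok]]
    return out


@lru_cache(maxsize=32)
def _cached_step_profile(particle: ParticleState, sigma: float) -> StepProfile:
    prof = build_profile(particle)
    if sigma > 0:
        prof = diffuse_profile(prof, sigma)
    return three_step_parametrization(prof)


def ion_step_profile(
    particle: ParticleState, sigma: float = DEFAULT_SIGMA_UM
) -> StepProfile:
    """Raw profile → radical diffusion → three-step parametrization."""
    return _cached_step_profile(particle, float(sigma))


def _ion_setup(protocol, params, nucleus, enhancement, sigma, step_profile):
    particle = protocol.particle
    if particle is None:
        raise ValueError("ion engine requires protocol.particle")
    sp = step_profile or ion_step_profile(particle, sigma)
    r1, r2, r3 = sp.radii
    weights = tuple(float(w) for w in enhancement.factor(np.asarray(sp.levels)))
    a_eq = nucleus.domain_side / math.sqrt(math.pi)
    dr, eff_table = step_area_average(sp, a_eq, weights)
    cutoff = r3 + a_eq
    r_sample = nucleus.radius + cutoff
    area = math.pi * r_sample**2
    mean_tracks = expected_track_count(protocol.fraction_dose, particle.let, area)
    yield_per_gy = params.alpha_dsb / nucleus.n_domains
    # capacity: expected breaks/iteration from the mean effective deposit
    eff_line = math.pi * sum(
        w * l * (b**2 - a**2)
        for w, l, a, b in zip(weights, sp.levels, (0.0, r1, r2), sp.radii)
    )
    per_track = nucleus.n_columns * nucleus.n_z * eff_line / area
    mu_breaks = mean_tracks * per_track * yield_per_gy
    # capacity bound: a single track can deposit at most its full line
    # energy into one column stack, so budget for a high quantile of the
    # track count at that worst-case multiplicity (allocation only; cheap)
    max_per_track = (
        yield_per_gy * nucleus.n_z * eff_line / nucleus.domain_side**2
    )
    n_tr_hi = mean_tracks + 8.0 * math.sqrt(mean_tracks + 1.0) + 8.0
    cap = (
        int(mu_breaks + 12.0 * math.sqrt(mu_breaks + 1.0))
        + int(1.5 * max_per_track * n_tr_hi)
        + 256
    )
    return sp, dr, eff_table, cutoff, r_sample, mean_tracks, yield_per_gy, cap


def _ion_python(
    protocol, params, nucleus, n_iter, seed, misrepair, dr, eff_table, r_sample,
    mean_tracks, yield_per_gy, n_steps, total_time,
):
    rng = np.random.default_rng(seed)
    out = np.empty(n_iter)
    n_z = nucleus.n_z
    dt = total_time / n_steps
    for it in range(n_iter):
        state = DamageState(n_domains=nucleus.n_domains)
        for step in range(n_steps):
            n_tr = rng.poisson(mean_tracks / n_steps)
            col_eff = np.zeros(nucleus.n_columns)
            for _ in range(int(n_tr)):
                while True:
                    x, y = rng.uniform(-r_sample, r_sample, size=2)
                    if x * x + y * y <= r_sample * r_sample:
                        break
                d = np.hypot(nucleus.col_x - x, nucleus.col_y - y)
                col_eff += _table_lookup(d, dr, eff_table)
            mu_dom = np.repeat(col_eff * yield_per_gy, n_z)
            new = rng.poisson(mu_dom)
            add_damage(state, new, params, rng)
            advance_state(state, dt, params, rng, misrepair=misrepair)
            if state.misrepair_flag:
                break
        out[it] = finalize_survival(state, params)
    return out


def simulate_ion_timed(
    protocol: IrradiationProtocol,
    params: EndpointParams,
    nucleus: NucleusModel,
    n_iter: int = 10_000,
    seed: int = 0,
    enhancement=IdentityEnhancement(),
    sigma: float = DEFAULT_SIGMA_UM,
    step_profile: StepProfile | None = None,
    misrepair: str = "sample",
    method: str = "numba",
) -> SurvivalEstimate:
    """Time-resolved ion survival for a single fraction of the protocol."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sp, dr, eff_table, cutoff, r_sample, mean_tracks, yield_per_gy, cap = _ion_setup(
        protocol, params, nucleus, enhancement, sigma, step_profile
    )
    total_time = protocol.fraction_time
    n_steps = protocol.n_timesteps if total_time > 0 else 1
    seed = _mask_seed(seed)
    tau_i = params.t_half_idsb / LN2
    tau_c = params.t_half_cdsb / LN2
    if method == "numba":
        surv = _kernels.ion_kernel(
            n_iter,
            np.ascontiguousarray(nucleus.col_x),
            np.ascontiguousarray(nucleus.col_y),
            nucleus.n_z,
            mean_tracks,
            n_steps,
            total_time,
            r_sample,
            np.ascontiguousarray(eff_table),
            1.0 / dr,
            cutoff * cutoff,
            yield_per_gy,
            tau_i,
            tau_c,
            params.k_idsb,
            params.k_cdsb,
            misrepair == "sample",
            seed,
            cap,
        )
    elif method == "python":
        surv = _ion_python(
            protocol, params, nucleus, n_iter, seed, misrepair, dr, eff_table,
            r_sample, mean_tracks, yield_per_gy, n_steps, total_time,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return _estimate(surv, seed, protocol)


def simulate_ion_acute(
    protocol: IrradiationProtocol,
    params: EndpointParams,
    nucleus: NucleusModel,
    n_iter: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> SurvivalEstimate:
    """Acute ion survival (no time structure, no repair)."""
    acute = IrradiationProtocol(
        total_dose=protocol.fraction_dose,
        dose_rate=math.inf,
        n_fractions=1,
        n_timesteps=1,
        particle=protocol.particle,
    )
    return simulate_ion_timed(acute, params, nucleus, n_iter=n_iter, seed=seed, **kwargs)
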