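"""Dose–response assembly: iso-effect solving, TD50 ratios and RBE.

Endpoint probability is mapped from survival as P = 1 - S (with independent,
fully resolved fractions multiplying their survivals), TD50 is the total
dose with P = 0.5, and three RBE definitions are provided:

* fixed-reference — photon reference delivered at a fixed dose rate δ̇,
  RBE = D_EL^γ(δ̇) / D_EL^p(Ḋ);
* dose-rate adapted — photon reference at the ion's own dose rate,
  RBE = D_EL^γ(Ḋ) / D_EL^p(Ḋ);
* no-repair — both modalities acute, RBE = D_EL^γ(∞) / D_EL^p(∞).

R_TD50 = TD50^γ(ref rate)/TD50^γ(Ḋ) is the photon dose-rate correction
factor; multiplied by the no-repair RBE it approximates the measured
fixed-reference RBE of a mixed field when the dose-rate adapted RBE has
already saturated at the no-repair value.

All stochastic solvers use common random numbers: every survival evaluation
inside one solve re-uses the same seed, so the solved dose is a
deterministic function of (seed, settings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .damage import EndpointParams, NucleusModel
from .engines import (
    IrradiationProtocol,
    photon_survival_closed_form,
    simulate_ion_timed,
    simulate_photon_timed,
)
from .track import DEFAULT_SIGMA_UM, ParticleState, SSBPairingEnhancement

__all__ = [
    "EngineSettings",
    "TD50Result",
    "RBEResult",
    "LQParams",
    "endpoint_probability",
    "solve_td50",
    "r_td50",
    "rbe_fixed_reference",
    "rbe_dose_rate_adapted",
    "rbe_no_repair",
    "rbe_sobp_approx",
    "lq_decreasing_rbe",
]


@dataclass(frozen=True)
class EngineSettings:
    """Monte Carlo settings shared by the response-layer solvers.

    ``misrepair="weight"`` (the Rao-Blackwellised estimator, identical in
    expectation to Bernoulli misrepair sampling) is the default here because
    iso-effect solving at high doses needs the variance reduction; the
    engines themselves default to the literal sampling algorithm.
    ``photon_acute_closed_form`` replaces acute-photon MC by its exact
    expectation inside solvers.
    """

    n_iter: int = 10_000
    n_iter_ion: int | None = None
    n_timesteps: int = 100
    seed: int = 12345
    misrepair: str = "weight"
    method: str = "numba"
    enhancement: object = field(default_factory=SSBPairingEnhancement)
    sigma: float = DEFAULT_SIGMA_UM
    photon_acute_closed_form: bool = True

    @property
    def iter_ion(self) -> int:
        return self.n_iter_ion if self.n_iter_ion is not None else self.n_iter


@dataclass(frozen=True)
class TD50Result:
    td50: float
    dose_rate: float
    n_fractions: int
    tol: float
    settings: EngineSettings

    def __post_init__(self) -> None:
        if not self.td50 > 0:
            raise ValueError("td50 must be positive")


@dataclass(frozen=True)
class RBEResult:
    value: float
    definition: str  # fixed_reference | dose_rate_adapted | no_repair | sobp_approx
    ion_dose: float | None = None
    ion_dose_rate: float | None = None
    ref_dose_rate: float | None = None
    effect_level: float | None = None

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("RBE must be positive")
        tags = {"fixed_reference", "dose_rate_adapted", "no_repair", "sobp_approx"}
        if self.definition not in tags:
            raise ValueError(f"unknown RBE definition {self.definition!r}")


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic coefficients of a survival curve at one dose rate."""

    alpha: float  # 1/Gy
    beta: float  # 1/Gy²
    dose_rate: float = math.inf

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


# ---------------------------------------------------------------------------
# survival / endpoint probability
# ---------------------------------------------------------------------------

def _fraction_ln_survival(
    fraction_dose: float,
    dose_rate: float,
    particle: ParticleState | None,
    params: EndpointParams,
    nucleus: NucleusModel,
    settings: EngineSettings,
) -> float:
    """ln E[S] for a single fraction (CRN: settings.seed every call)."""
    if fraction_dose == 0.0:
        return 0.0
    proto = IrradiationProtocol(
        total_dose=fraction_dose,
        dose_rate=dose_rate,
        n_timesteps=settings.n_timesteps,
        particle=particle,
    )
    if particle is None:
        if math.isinf(dose_rate) and settings.photon_acute_closed_form:
            s = photon_survival_closed_form(fraction_dose, params, nucleus)
        else:
            s = simulate_photon_timed(
                proto,
                params,
                nucleus,
                n_iter=settings.n_iter,
                seed=settings.seed,
                misrepair=settings.misrepair,
                method=settings.method,
            ).mean
    else:
        s = simulate_ion_timed(
            proto,
            params,
            nucleus,
            n_iter=settings.iter_ion,
            seed=settings.seed,
            enhancement=settings.enhancement,
            sigma=settings.sigma,
            misrepair=settings.misrepair,
            method=settings.method,
        ).mean
    if s <= 0.0:
        return -math.inf
    return math.log(s)


def endpoint_probability(
    total_dose: float,
    protocol: IrradiationProtocol,
    params: EndpointParams,
    nucleus: NucleusModel,
    settings: EngineSettings | None = None,
) -> float:
    """P(endpoint) = 1 - S_fraction^n_fractions at the protocol's dose rate.

    Fractions are independent with complete inter-fraction damage
    resolution, so equal fractions multiply their survivals.
    """
    settings = settings or EngineSettings()
    if total_dose < 0:
        raise ValueError("total_dose must be >= 0")
    if total_dose == 0.0:
        return 0.0
    ln_s = _fraction_ln_survival(
        total_dose / protocol.n_fractions,
        protocol.dose_rate,
        protocol.particle,
        params,
        nucleus,
        settings,
    )
    return 1.0 - math.exp(protocol.n_fractions * ln_s)


# ---------------------------------------------------------------------------
# iso-effect solvers
# ---------------------------------------------------------------------------

def solve_td50(
    protocol: IrradiationProtocol,
    params: EndpointParams,
    nucleus: NucleusModel,
    settings: EngineSettings | None = None,
    tol: float = 0.05,
) -> TD50Result:
    """Bisect the total dose to the 50% endpoint probability.

    Common random numbers make P(D) a deterministic, effectively monotone
    function of dose; the initial bracket auto-expands (error after 60
    doublings).
    """
    settings = settings or EngineSettings()

    def p_of(d: float) -> float:
        return endpoint_probability(d, protocol, params, nucleus, settings)

    lo, hi = 0.0, 1.0
    for _ in range(60):
        if p_of(hi) >= 0.5:
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise RuntimeError("TD50 bracket expansion failed after 60 doublings")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if p_of(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return TD50Result(
        td50=0.5 * (lo + hi),
        dose_rate=protocol.dose_rate,
        n_fractions=protocol.n_fractions,
        tol=tol,
        settings=settings,
    )


def r_td50(
    dose_rate: float,
    ref_rate: float,
    n_fractions: int = 1,
    params: EndpointParams | None = None,
    nucleus: NucleusModel | None = None,
    settings: EngineSettings | None = None,
    tol: float = 0.05,
) -> float:
    """Photon dose-rate factor TD50(ref_rate) / TD50(dose_rate).

    Both solves share n_fractions, settings and seed (common random
    numbers), so most Monte Carlo noise cancels in the ratio.
    """
    if params is None or nucleus is None:
        raise ValueError("params and nucleus are required")
    if not (dose_rate > 0 and ref_rate > 0):
        raise ValueError("dose rates must be positive")
    settings = settings or EngineSettings()

    def one(rate: float) -> float:
        proto = IrradiationProtocol(
            total_dose=1.0,
            dose_rate=rate,
            n_fractions=n_fractions,
            n_timesteps=settings.n_timesteps,
        )
        return solve_td50(proto, params, nucleus, settings, tol=tol).td50

    return one(ref_rate) / one(dose_rate)


def _solve_photon_iso_dose(
    target_ln_s: float,
    ref_rate: float,
    params: EndpointParams,
    nucleus: NucleusModel,
    settings: EngineSettings,
    tol: float,
) -> float:
    """Photon dose at ``ref_rate`` whose ln-survival equals target_ln_s."""
    if not target_ln_s < 0.0:
        raise ValueError("effect level outside the achievable photon range")

    if math.isinf(ref_rate) and settings.photon_acute_closed_form:
        def g(d: float) -> float:
            return math.log(photon_survival_closed_form(d, params, nucleus)) - target_ln_s

        hi = 1.0
        for _ in range(60):
            if g(hi) <= 0.0:
                break
            hi *= 2.0
        else:
            raise RuntimeError("iso-dose bracket expansion failed")
        return float(brentq(g, 0.0, hi, xtol=min(tol, 1e-4)))

    def g_mc(d: float) -> float:
        return (
            _fraction_ln_survival(d, ref_rate, None, params, nucleus, settings)
            - target_ln_s
        )

    lo, hi = 0.0, 1.0
    for _ in range(60):
        if g_mc(hi) <= 0.0:
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise RuntimeError("iso-dose bracket expansion failed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g_mc(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ion_ln_survival(
    ion_dose, ion_rate, particle, params, nucleus, settings
) -> float:
    ln_s = _fraction_ln_survival(
        ion_dose, ion_rate, particle, params, nucleus, settings
    )
    if not math.isfinite(ln_s):
        raise RuntimeError(
            "ion survival estimate vanished; increase n_iter or use the "
            "weighted misrepair estimator"
        )
    return ln_s


def rbe_fixed_reference(
    ion_dose: float,
    ion_rate: float,
    ref_rate: float,
    particle: ParticleState | None,
    params: EndpointParams,
    nucleus: NucleusModel,
    settings: EngineSettings | None = None,
    tol: float = 0.05,
) -> RBEResult:
    """RBE with the photon reference at a fixed dose rate ``ref_rate``."""
    settings = settings or EngineSettings()
    ln_s = _ion_ln_survival(ion_dose, ion_rate, particle, params, nucleus, settings)
    d_gamma = _solve_photon_iso_dose(ln_s, ref_rate, params, nucleus, settings, tol)
    return RBEResult(
        value=d_gamma / ion_dose,
        definition="fixed_reference",
        ion_dose=ion_dose,
        ion_dose_rate=ion_rate,
        ref_dose_rate=ref_rate,
        effect_level=1.0 - math.exp(ln_s),
    )


def rbe_dose_rate_adapted(
    ion_dose: float,
    ion_rate: float,
    particle: ParticleState | None,
    params: EndpointParams,
    nucleus: NucleusModel,
    settings: EngineSettings | None = None,
    tol: float = 0.05,
) -> RBEResult:
    """RBE with the photon reference delivered at the ion's dose rate."""
    settings = settings or EngineSettings()
    ln_s = _ion_ln_survival(ion_dose, ion_rate, particle, params, nucleus, settings)
    d_gamma = _solve_photon_iso_dose(ln_s, ion_rate, params, nucleus, settings, tol)
    return RBEResult(
        value=d_gamma / ion_dose,
        definition="dose_rate_adapted",
        ion_dose=ion_dose,
        ion_dose_rate=ion_rate,
        ref_dose_rate=ion_rate,
        effect_level=1.0 - math.exp(ln_s),
    )


def rbe_no_repair(
    ion_dose: float,
    particle: ParticleState | None,
    params: EndpointParams,
    nucleus: NucleusModel,
    settings: EngineSettings | None = None,
    tol: float = 0.05,
) -> RBEResult:
    """RBE with both modalities delivered acutely (no repair at all)."""
    settings = settings or EngineSettings()
    ln_s = _ion_ln_survival(
        ion_dose, math.inf, particle, params, nucleus, settings
    )
    d_gamma = _solve_photon_iso_dose(ln_s, math.inf, params, nucleus, settings, tol)
    return RBEResult(
        value=d_gamma / ion_dose,
        definition="no_repair",
        ion_dose=ion_dose,
        ion_dose_rate=math.inf,
        ref_dose_rate=math.inf,
        effect_level=1.0 - math.exp(ln_s),
    )


def rbe_sobp_approx(no_repair_rbe: float, r_td50_factor: float) -> RBEResult:
    """Mixed-field approximation: no-repair RBE × R_TD50."""
    if no_repair_rbe <= 0 or r_td50_factor <= 0:
        raise ValueError("both factors must be positive")
    return RBEResult(value=no_repair_rbe * r_td50_factor, definition="sobp_approx")


def lq_decreasing_rbe(lq_ref: LQParams, lq_inf: LQParams) -> bool:
    """True iff the LQ model predicts RBE decreasing with dose, i.e.
    alpha_inf/alpha_ref > beta_inf/beta_ref (strict)."""
    if lq_ref.alpha == 0 or lq_ref.beta == 0:
        raise ValueError("reference alpha and beta must be non-zero")
    return lq_inf.alpha / lq_ref.alpha > lq_inf.beta / lq_ref.beta
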