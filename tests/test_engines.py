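"""Monte Carlo engines against exact oracles and each other.

The photon closed form is checked against brute-force enumeration; the
acute photon MC against the closed form; the time-resolved photon engine
against a semi-analytic pair-dynamics oracle; the ion engine against a
compound-Poisson oracle on a single-domain nucleus; and the numba kernels
against the literal pure-Python reference path.
"""

import math
from itertools import product

import numpy as np
import pytest
from scipy import stats

from trackrbe import (
    EndpointParams,
    IdentityEnhancement,
    IrradiationProtocol,
    NucleusModel,
    deposit_track,
    expected_track_count,
    ion_step_profile,
    photon_survival_closed_form,
    proton_for_let,
    simulate_ion_acute,
    simulate_ion_timed,
    simulate_photon_acute,
    simulate_photon_timed,
)
from trackrbe.constants import GY_PER_KEV_UM3


def _enumeration_survival(mu_total, n_domains, k_i, k_c, n_max=40):
    """Brute force: Poisson total count × multinomial allocation."""
    total = 0.0
    for n in range(n_max + 1):
        p_n = stats.poisson.pmf(n, mu_total)
        # enumerate occupancies of 3 domains
        sub = 0.0
        for n1 in range(n + 1):
            for n2 in range(n - n1 + 1):
                n3 = n - n1 - n2
                w = (
                    math.comb(n, n1)
                    * math.comb(n - n1, n2)
                    / n_domains**n
                )
                counts = (n1, n2, n3)
                fi = sum(1 for c in counts if c == 1)
                fc = sum(1 for c in counts if c >= 2)
                sub += w * (1 - k_i) ** fi * (1 - k_c) ** fc
        total += p_n * sub
    return total


class TestPhotonClosedForm:
    def test_zero_dose(self, du145, nucleus):
        assert photon_survival_closed_form(0.0, du145, nucleus) == 1.0

    def test_zero_lethality(self, nucleus):
        p = EndpointParams(k_idsb=0.0, k_cdsb=0.0)
        assert photon_survival_closed_form(10.0, p, nucleus) == 1.0

    def test_matches_brute_force_enumeration(self):
        nuc = NucleusModel(radius=0.6, height=1.9, n_domains=3)
        assert nuc.n_domains == 3
        p = EndpointParams(k_idsb=0.1, k_cdsb=0.5, alpha_dsb=30.0)
        dose = 2.0 / 30.0  # alpha_dsb * dose = 2
        expected = _enumeration_survival(2.0, 3, 0.1, 0.5)
        got = photon_survival_closed_form(dose, p, nuc)
        assert got == pytest.approx(expected, rel=1e-9)


class TestPhotonAcuteMC:
    def test_zero_dose_exact(self, du145, small_nucleus):
        est = simulate_photon_acute(0.0, du145, small_nucleus, n_iter=50, seed=1)
        assert est.mean == 1.0 and est.se == 0.0

    def test_agrees_with_closed_form_on_grid(self, small_nucleus):
        """4-standard-error agreement over a 3x3 dose × parameter grid."""
        param_grid = [
            EndpointParams(k_idsb=5.9e-3, k_cdsb=0.17),
            EndpointParams(k_idsb=1e-3, k_cdsb=0.05),
            EndpointParams(k_idsb=0.05, k_cdsb=0.4),
        ]
        for dose, p in product((1.0, 2.0, 4.0), param_grid):
            est = simulate_photon_acute(dose, p, small_nucleus, n_iter=4000, seed=3)
            exact = photon_survival_closed_form(dose, p, small_nucleus)
            assert abs(est.mean - exact) < 4 * max(est.se, 1e-6)

    def test_seed_determinism(self, du145, small_nucleus):
        a = simulate_photon_acute(2.0, du145, small_nucleus, n_iter=500, seed=42)
        b = simulate_photon_acute(2.0, du145, small_nucleus, n_iter=500, seed=42)
        c = simulate_photon_acute(2.0, du145, small_nucleus, n_iter=500, seed=43)
        assert a.mean == b.mean and a.se == b.se
        assert a.mean != c.mean

    def test_se_scales_with_iterations(self, du145, small_nucleus):
        a = simulate_photon_acute(2.0, du145, small_nucleus, n_iter=2000, seed=1)
        b = simulate_photon_acute(2.0, du145, small_nucleus, n_iter=8000, seed=1)
        assert 1.5 < a.se / b.se < 2.7  # expect ≈ 2


class TestPhotonTimed:
    def test_high_rate_equals_acute(self, du145, small_nucleus):
        proto = IrradiationProtocol(total_dose=3.0, dose_rate=1e4)
        timed = simulate_photon_timed(proto, du145, small_nucleus, n_iter=4000, seed=2)
        acute = simulate_photon_acute(3.0, du145, small_nucleus, n_iter=4000, seed=9)
        se = math.hypot(timed.se, acute.se)
        assert abs(timed.mean - acute.mean) < 4 * se

    def test_low_rate_limit_all_breaks_isolated(self, du145, nucleus):
        """When irradiation lasts far beyond both half-lives every break
        lives and dies alone: E[S] -> exp(-alpha·D·K_i)."""
        proto = IrradiationProtocol(total_dose=2.0, dose_rate=0.002)
        est = simulate_photon_timed(proto, du145, nucleus, n_iter=3000, seed=4)
        limit = math.exp(-du145.alpha_dsb * 2.0 * du145.k_idsb)
        assert est.mean == pytest.approx(limit, rel=0.03)

    def test_survival_monotone_in_dose_rate(self, du145, nucleus):
        means = []
        for rate in (1e4, 2.0, 0.1):
            proto = IrradiationProtocol(total_dose=3.0, dose_rate=rate)
            est = simulate_photon_timed(
                proto, du145, nucleus, n_iter=4000, seed=6, misrepair="weight"
            )
            means.append((est.mean, est.se))
        for (s_fast, se_f), (s_slow, se_s) in zip(means, means[1:]):
            assert s_slow >= s_fast - 4 * math.hypot(se_f, se_s)

    def test_pair_dynamics_oracle(self, du145, nucleus):
        """Semi-analytic oracle: per-domain independence plus exact
        two-break dynamics (coexistence, upgrade, declassification)."""
        D, rate = 3.0, 0.5
        T = D / rate
        ki, kc = du145.k_idsb, du145.k_cdsb
        li = math.log(2) / du145.t_half_idsb
        lc = math.log(2) / du145.t_half_cdsb
        mu = du145.alpha_dsb * D / nucleus.n_domains
        steps = np.arange(100) * (T / 100.0)
        t1, t2 = np.meshgrid(steps, steps)
        a, b = np.minimum(t1, t2), np.maximum(t1, t2)
        p_coex = np.exp(-li * (b - a))
        q_intact = np.exp(-2 * lc * (T - b))
        f_cluster = (1 - kc) * (q_intact + (1 - q_intact) * (1 - ki))
        ef2 = float(np.mean(p_coex * f_cluster + (1 - p_coex) * (1 - ki) ** 2))
        p0 = math.exp(-mu)
        p1 = mu * p0
        f = p0 + p1 * (1 - ki) + (1 - p0 - p1) * ef2
        oracle = f**nucleus.n_domains
        proto = IrradiationProtocol(total_dose=D, dose_rate=rate)
        est = simulate_photon_timed(
            proto, du145, nucleus, n_iter=20_000, seed=5, misrepair="weight"
        )
        assert abs(est.mean - oracle) < max(4 * est.se, 0.004)

    def test_weight_and_sample_estimators_agree(self, du145, nucleus):
        proto = IrradiationProtocol(total_dose=3.0, dose_rate=0.5)
        w = simulate_photon_timed(
            proto, du145, nucleus, n_iter=8000, seed=8, misrepair="weight"
        )
        s = simulate_photon_timed(
            proto, du145, nucleus, n_iter=8000, seed=9, misrepair="sample"
        )
        assert abs(w.mean - s.mean) < 4 * math.hypot(w.se, s.se)

    def test_python_reference_matches_numba(self, du145, small_nucleus):
        proto = IrradiationProtocol(total_dose=3.0, dose_rate=0.5)
        py = simulate_photon_timed(
            proto, du145, small_nucleus, n_iter=400, seed=11, method="python"
        )
        nb = simulate_photon_timed(
            proto, du145, small_nucleus, n_iter=4000, seed=12, method="numba"
        )
        assert abs(py.mean - nb.mean) < 4 * math.hypot(py.se, nb.se)


class TestTrackCount:
    def test_zero_dose(self):
        assert expected_track_count(0.0, 8.0, 100.0) == 0.0

    def test_inverse_in_let(self):
        n1 = expected_track_count(2.0, 2.0, 100.0)
        n2 = expected_track_count(2.0, 4.0, 100.0)
        assert n1 == pytest.approx(2 * n2)

    def test_hand_computed_fluence(self):
        """2 Gy at 2 keV/µm: fluence = D/(0.1602·LET) per µm²."""
        r_max = 0.062 * 27.7**1.7
        area = math.pi * (5.0 + r_max) ** 2
        expected = 2.0 / (GY_PER_KEV_UM3 * 2.0) * area
        assert expected_track_count(2.0, 2.0, area) == pytest.approx(expected)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            expected_track_count(1.0, 0.0, 100.0)


class TestDepositTrack:
    def test_distant_track_deposits_nothing(self, nucleus):
        sp = ion_step_profile(proton_for_let(25.0))
        doses = deposit_track((50.0, 0.0), sp, nucleus)
        assert doses.shape == (nucleus.n_domains,)
        assert not doses.any()

    def test_central_track_through_tiny_domain_sees_core_level(self):
        """A domain smaller than the core annulus receives the core level."""
        nuc = NucleusModel(radius=0.007, height=0.007, n_domains=1)
        sp = ion_step_profile(proton_for_let(25.0))
        assert nuc.domain_side / math.sqrt(math.pi) < sp.radii[0]
        dose = deposit_track((0.0, 0.0), sp, nuc)
        assert dose[0] == pytest.approx(sp.levels[0], rel=1e-6)

    def test_energy_bookkeeping_against_macroscopic_dose(self, nucleus):
        """Averaged over uniform track positions, deposited energy per
        nucleus equals macroscopic dose × nucleus mass within 3%."""
        particle = proton_for_let(8.0)
        sp = ion_step_profile(particle)
        a_eq = nucleus.domain_side / math.sqrt(math.pi)
        r_sample = nucleus.radius + sp.radii[2] + a_eq
        area = math.pi * r_sample**2
        # uniform coverage of the sampling disk via a golden-angle spiral
        # (stratified quadrature over track positions)
        n_tracks, mean_dose = 2000, 0.0
        golden = math.pi * (3.0 - math.sqrt(5.0))
        for i in range(n_tracks):
            rad = r_sample * math.sqrt((i + 0.5) / n_tracks)
            x, y = rad * math.cos(golden * i), rad * math.sin(golden * i)
            mean_dose += deposit_track((x, y), sp, nucleus).sum() / nucleus.n_domains
        mean_dose /= n_tracks
        dose = 2.0
        n_exp = expected_track_count(dose, particle.let, area)
        assert mean_dose * n_exp == pytest.approx(dose, rel=0.03)


class TestIonEngine:
    def _single_domain_setup(self):
        nuc = NucleusModel(radius=0.3, height=0.3, n_domains=1)
        particle = proton_for_let(25.0)
        sp = ion_step_profile(particle)
        return nuc, particle, sp

    def _compound_poisson_oracle(self, nuc, particle, sp, dose, params):
        """Literal summation over track counts with iid radial positions."""
        a_eq = nuc.domain_side / math.sqrt(math.pi)
        r_sample = nuc.radius + sp.radii[2] + a_eq
        lam = expected_track_count(dose, particle.let, math.pi * r_sample**2)
        y = params.alpha_dsb / nuc.n_domains
        # independent 2-D quadrature of the area-averaged step dose
        d_grid = np.linspace(0.0, r_sample, 600)
        phi = np.linspace(0.0, 2 * math.pi, 181)
        rho = np.linspace(0.0, a_eq, 60)
        rr, pp = np.meshgrid(rho, phi)
        g = np.empty_like(d_grid)
        for i, d in enumerate(d_grid):
            pts = np.hypot(d + rr * np.cos(pp), rr * np.sin(pp))
            vals = sp.dose(pts) * rr
            g[i] = np.trapezoid(np.trapezoid(vals, rho, axis=1), phi) / (
                math.pi * a_eq**2
            )
        w = 2 * d_grid / r_sample**2  # radial density of a uniform position
        phi1 = np.trapezoid(w * np.exp(-y * g), d_grid)
        psi = np.trapezoid(w * y * g * np.exp(-y * g), d_grid)
        e_em, e_mem = 0.0, 0.0
        for k in range(0, 60):
            pk = stats.poisson.pmf(k, lam)
            e_em += pk * phi1**k
            if k >= 1:
                e_mem += pk * k * psi * phi1 ** (k - 1)
        ki, kc = params.k_idsb, params.k_cdsb
        return (1 - kc) + kc * e_em + (kc - ki) * e_mem

    def test_zero_dose(self, du145):
        nuc, particle, _ = self._single_domain_setup()
        proto = IrradiationProtocol(total_dose=0.0, particle=particle)
        est = simulate_ion_acute(proto, du145, nuc, n_iter=100, seed=1)
        assert est.mean == 1.0

    @pytest.mark.parametrize("method,n_iter", [("numba", 6000), ("python", 800)])
    def test_single_domain_compound_poisson_oracle(self, method, n_iter):
        nuc, particle, sp = self._single_domain_setup()
        params = EndpointParams(k_idsb=0.02, k_cdsb=0.3, alpha_dsb=30.0)
        dose = 4.0
        oracle = self._compound_poisson_oracle(nuc, particle, sp, dose, params)
        proto = IrradiationProtocol(total_dose=dose, particle=particle)
        est = simulate_ion_acute(
            proto, params, nuc, n_iter=n_iter, seed=17,
            enhancement=IdentityEnhancement(), method=method,
        )
        assert abs(est.mean - oracle) < 4 * max(est.se, 1e-4)

    def test_high_rate_equals_acute(self, du145, nucleus):
        particle = proton_for_let(25.0)
        timed = simulate_ion_timed(
            IrradiationProtocol(total_dose=2.0, dose_rate=1e4, particle=particle),
            du145, nucleus, n_iter=1200, seed=3,
        )
        acute = simulate_ion_acute(
            IrradiationProtocol(total_dose=2.0, particle=particle),
            du145, nucleus, n_iter=1200, seed=30,
        )
        assert abs(timed.mean - acute.mean) < 4 * math.hypot(timed.se, acute.se)

    def test_survival_monotone_in_dose_rate(self, du145, nucleus):
        particle = proton_for_let(25.0)
        means = []
        for rate in (600.0, 2.0, 0.2):
            est = simulate_ion_timed(
                IrradiationProtocol(total_dose=6.0, dose_rate=rate, particle=particle),
                du145, nucleus, n_iter=1200, seed=7, misrepair="weight",
            )
            means.append((est.mean, est.se))
        for (s_fast, se_f), (s_slow, se_s) in zip(means, means[1:]):
            assert s_slow >= s_fast - 4 * math.hypot(se_f, se_s)

    def test_low_let_converges_to_photon(self, du145, nucleus):
        """At 2 keV/µm the track structure is so dilute that ion survival
        approaches the uniform-dose photon limit (within 5% relative)."""
        proto = IrradiationProtocol(total_dose=2.0, particle=proton_for_let(2.0))
        est = simulate_ion_acute(
            proto, du145, nucleus, n_iter=300, seed=13,
            enhancement=IdentityEnhancement(),
        )
        photon = photon_survival_closed_form(2.0, du145, nucleus)
        assert est.mean == pytest.approx(photon, rel=0.05)

    def test_seed_determinism(self, du145):
        nuc, particle, _ = self._single_domain_setup()
        proto = IrradiationProtocol(total_dose=4.0, particle=particle)
        a = simulate_ion_acute(proto, du145, nuc, n_iter=300, seed=5)
        b = simulate_ion_acute(proto, du145, nuc, n_iter=300, seed=5)
        assert a.mean == b.mean

    def test_python_reference_matches_numba_timed(self, du145):
        nuc, particle, _ = self._single_domain_setup()
        proto = IrradiationProtocol(
            total_dose=4.0, dose_rate=0.5, particle=particle, n_timesteps=20
        )
        py = simulate_ion_timed(
            proto, du145, nuc, n_iter=400, seed=19, method="python"
        )
        nb = simulate_ion_timed(
            proto, du145, nuc, n_iter=4000, seed=20, method="numba"
        )
        assert abs(py.mean - nb.mean) < 4 * math.hypot(py.se, nb.se)


def test_protocol_validation():
    with pytest.raises(ValueError):
        IrradiationProtocol(total_dose=-1.0)
    with pytest.raises(ValueError):
        IrradiationProtocol(total_dose=1.0, dose_rate=0.0)
    with pytest.raises(ValueError):
        IrradiationProtocol(total_dose=1.0, n_fractions=0)
    acute = IrradiationProtocol(total_dose=4.0, n_fractions=2)
    assert acute.fraction_dose == 2.0 and acute.fraction_time == 0.0
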