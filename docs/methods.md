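# Methods

## Model

`trackrbe` implements a mechanistic Monte Carlo model of cell survival in
which the biological effect of ionizing radiation is carried entirely by the
number and spatial clustering of DNA double-strand breaks (DSB).

**Damage geometry.** The nucleus is a water cylinder (default radius 5 µm,
height 10 µm) packed with cubic chromatin domains of ~2 Mbp ("giant
loops"); the default target of 3000 domains corresponds to a 6 Gbp genome.
Domains are arranged in vertical columns on a square grid; a deterministic
search over the grid spacing picks the layout whose realised domain count is
closest to the nominal one while fitting inside the cylinder (the default
realises 2895 = 193 columns × 15 layers, side 0.625 µm). The realised
count — not the nominal — enters every yield calculation and is echoed in
all outputs.

**Survival law.** A domain with exactly one DSB is an isolated damage
(iDSB), a domain with two or more is clustered (cDSB). With per-damage
lethality probabilities K_i and K_c,

    S = (1 − K_i)^N_iDSB · (1 − K_c)^N_cDSB.

For endpoints beyond clonogenic survival (e.g. rat-spinal-cord paresis) the
same machinery is used with K_i, K_c reinterpreted as endpoint-trigger
probabilities and P(endpoint) = 1 − S.

**Photon (sparsely ionizing) engine.** Dose is uniform over the nucleus.
Each iteration draws the total DSB count from Poisson(α·D) (α = 30
DSB/Gy/cell by default) and assigns each break to a uniformly random
domain; survival follows from the law above and is averaged over
iterations. The acute engine also has an exact closed form — uniform
allocation of a Poisson total makes per-domain counts independent
Poisson(α·D/N) — which the solvers use for acute photon iso-effect doses
and the tests use as an oracle.

**Ion engine.** Tracks travel parallel to the cylinder axis. The radial
dose profile is the Kiefer–Chatterjee amorphous-track parametrization: a
core of radius r_min = β·11.6 nm at constant dose and a penumbra
D_p(r) = K_p/r² with K_p = 1.25×10⁻⁴ (z*/β)² Gy·µm², out to
r_max = 0.062·E^1.7 µm (E in MeV/u); z* is the Barkas effective charge.
The core dose is fixed by energy conservation: ρ∫D(r)2πr dr must equal the
unrestricted LET (0.1602 Gy·µm³ per keV at unit density). Radical
diffusion convolves the profile with a radially symmetric Gaussian
(evaluated through the exponentially-scaled modified Bessel kernel to avoid
overflow), and the diffused profile is collapsed onto a three-step annular
approximation used by the deposition kernel. The expected number of tracks
through the sampling disk (nucleus radius + profile support) follows from
the fluence–dose relation Φ = D/(0.1602·LET) µm⁻²; track counts are
Poisson, positions uniform. Per-domain DSB expectations are Poisson-sampled
from the deposited dose times the (optionally LET-enhanced) yield.

**Repair kinetics and dose rate.** A delivery at dose rate Ḋ is divided
into N_t = 100 equal time steps; each step deposits D/N_t at its start
(damage therefore gets the full sub-interval to repair, making the acute
limit exact as the interval length vanishes). Every DSB carries an
exponential lifetime whose *median* is the repair half-life of its class
(fast T½_i for isolated, slow T½_c for clustered; rate λ = ln2/T½). A break
landing on an isolated one upgrades the domain to a cluster and the
resident break's lifetime is redrawn from the slow distribution. Breaks
whose lifetime expires are removed; each removal misrepairs with
probability K_i or K_c according to the domain's classification *at removal
time*, and a misrepair kills the cell outright. When a cluster shrinks back
to a single break the domain reclassifies as isolated but keeps its slow
lifetime (redraw only on upgrade). These two conventions — classification
at removal, no redraw on declassification — are interpretation choices
where the algorithm's verbal definition is silent; both are localized in
`repair.advance_state` if sensitivity tests are wanted. The construction
guarantees the timing-consistency property: a break that is never joined
contributes an expected factor (1 − K_i) regardless of how long repair
operates, because the repaired-then-misrepair and unrepaired-then-scored
paths integrate to the same factor.

**Iso-effect layer.** Fractions are independent with complete
inter-fraction damage resolution, so equal fractions multiply survivals
(an interval parameter would be vacuous under the misrepair bookkeeping).
TD50 is the total dose with P = 0.5, solved by bisection under common
random numbers (every evaluation reuses the same seed, making the solved
dose a deterministic function of the settings; default tolerance 0.05 Gy,
0.02 Gy in the shipped analyses). Three RBE definitions are provided:
fixed-reference (photon reference at a fixed rate δ̇), dose-rate adapted
(photon reference at the ion's rate), and no-repair (both modalities
acute). R_TD50 = TD50^γ(ref)/TD50^γ(Ḋ) is the photon dose-rate factor; the
mixed-field shortcut RBE ≈ no-repair RBE × R_TD50 is valid exactly when
the dose-rate adapted RBE has saturated at the no-repair value (high ion
dose rates), and a test verifies that internal consistency at 2%.

## Key parameters

| parameter | default | units | provenance |
|---|---|---|---|
| K_iDSB, K_cDSB | per preset (e.g. DU145: 5.9e-3, 0.17) | — | endpoint presets |
| T½_iDSB, T½_cDSB | per preset (e.g. DU145: 4, 100) | min | endpoint presets |
| α_DSB | 30 | DSB/(Gy·cell) | standard photon yield |
| nucleus radius, height | 5, 10 | µm | typical mammalian scale; open in the model family |
| n_domains (nominal) | 3000 | — | 6 Gbp / 2 Mbp per giant loop |
| N_t (time steps) | 100 | — | model definition |
| σ (radical diffusion) | 0.004 | µm | few-nm radical range; open in the model family |
| r_c | 0.0116 | µm | core-radius coefficient |
| ϵ, δ (penumbra extent) | 0.062, 1.7 | µm·(MeV/u)^−δ, — | track parametrization |
| d_double, d_sat (yield enhancement) | 14 400, 5 000 | Gy | see below |
| n_iter | 10⁴ (engines) | — | scaled per analysis, see below |

Proton presets pair each nominal LET with a kinetic energy read from
standard stopping-power tables (2 keV/µm ↔ 27.7 MeV, 8 ↔ 4.9, 25 ↔ 1.05);
these pairings are implementer-derived, not model constants. Explicitly
supplied (LET, E) pairs are taken at face value — no stopping-power table
is bundled — with a warning only if β disagrees with E.

**DSB-yield enhancement.** The high local doses inside a track core
(≫100 Gy) convert dense single-strand-break pairs into extra DSB. The
default plug-in derives the low-dose slope from SSB pairing statistics
(1000 SSB/Gy/cell, 25 bp pairing range, 2 Mbp domains → doubling dose
d_double ≈ 14.4 kGy) and damps it with a Michaelis factor, enh(d) = 1 +
(d/d_double)/(1 + d/d_sat) with d_sat = 5 kGy. The saturation is required
physically (radical recombination makes SSB production sublinear in the
multi-kGy core) and is calibrated so the track-integrated DSB-yield ratio
is ≈1.05/1.10/1.19 at 2/8/25 keV/µm, the range reported by nanometre-scale
damage simulations for protons; the unsaturated law would give ≈1.7 at
25 keV/µm, well outside that range. Enhancement multiplies each *track's*
contribution (effective step levels L_k·enh(L_k)) because the pairing is an
intra-track radical effect; this also keeps the acute and time-resolved
engines exactly consistent at high dose rate. An identity plug-in is
available and is what every oracle test uses.

## Numerical choices

* **Domain dose from a track.** The step profile is averaged over the
  domain cross-section (equal-area circle, analytic annulus-overlap lookup
  table, 8192 radial bins): the dose to a domain is the energy the track
  deposits inside it divided by its mass. Averaged over uniform track
  positions this reproduces the profile's radial energy integral exactly,
  and it preserves the physical Poisson multiplicity of breaks per
  crossing. Evaluating the step profile at the column centre line instead
  would assign multi-kGy core levels to entire 15-domain columns with
  ~(8 nm/0.35 µm)² probability — an energy-conserving but
  statistically pathological discretization that suppresses low-LET ion
  survival ~20% below the photon limit.
* **Misrepair estimator.** The defining algorithm (survival := 0 on a
  sampled misrepair) is the engine default. The response-layer solvers use
  the conditional expectation over those Bernoulli draws instead
  (multiply the iteration's survival weight by 1 − K_class at every repair
  event): identical in expectation — both paths of the timing-consistency
  argument integrate to the same factor — but with bounded relative
  variance where the sampled estimator's clean-iteration probability falls
  below 10⁻³ (photon iso-effect doses ≳ 30 Gy for DU145). The two
  estimators are cross-checked statistically in the tests.
* **Common random numbers everywhere.** All bisections (TD50, iso-effect
  photon dose) fix one seed per solve; ratios of two solves (R_TD50, RBE)
  share settings so most Monte Carlo noise cancels.
* **Diffusion quadrature.** The Hankel-form convolution is integrated on a
  locally refined grid (dense log-spaced nodes across the 1/r² onset just
  outside the core); the radial energy integral of the diffused profile is
  conserved to ≲0.25% for σ ≤ r_max/15, within the 0.5% the tests demand.
  The outward Gaussian tail is truncated where it falls below 10⁻⁶ of the
  peak; the interior profile is never truncated (the penumbra edge dose is
  ~10⁻⁹ of the diffused core and must survive for energy conservation).
* **Three-step construction.** r₁ = max(r_min, 2σ) covers the diffused
  core, r₃ is the support end, r₂ = √(r₁r₃); levels are annulus energy
  averages, so per-annulus energy is conserved exactly. Only the existence
  of a three-step approximation is fixed by the model family; this is one
  admissible construction.
* **Degenerate inputs.** Zero dose returns survival 1 exactly; dose rate ∞
  is the acute path (no time structure); a profile whose support does not
  exceed its core, inconsistent (LET, E) pairs with negative core dose, and
  non-bracketing iso-effect solves (after 60 bracket doublings) raise.

## Problem sizes in the shipped analyses

The acceptance script and headline tests solve photon TD50s with 2500–5000
iterations (bisection tolerance 0.02 Gy) and run the ion engine with
400–3000 iterations depending on LET: at 2 keV/µm each iteration transports
~10⁵ tracks, so the per-iteration variance is small and a few hundred
iterations give sub-percent precision, while at 25 keV/µm (hundreds of
tracks per iteration) a few thousand are used. Seed-to-seed spread of every
reported quantity is well under one percentage point at these sizes.

## What the synthetic TD50 generator does and does not emulate

`make_synthetic_td50` produces (n_fractions, TD50) tables by solving the
model's own dose–response at a reference dose rate and multiplying by
lognormal noise exp(N(0, sd)). It emulates the *structure* of fractionated
tolerance-dose series (monotone sparing with fraction number,
multiplicative measurement error) but not their biology: real series carry
inter-animal variability, probit-style response widths, and correlated
dosimetry errors. Parameter-recovery results on these tables therefore
demonstrate identifiability of (K_i, K_c) under the model's own assumptions,
not accuracy against laboratory data. With noise-free tables and shared
seeds the fit objective vanishes at the truth, so the 10% recovery check is
a test of the optimizer and solver plumbing, not of statistical power.

## Known limitations

* Mixed-LET fields are not transported: dose-weighted LET and per-position
  dose rates of a spread-out Bragg peak enter as printed inputs to the
  R_TD50 × no-repair approximation (`rbe-sobp`), which itself fails at low
  dose rates where the dose-rate adapted RBE has not saturated.
* No nuclear fragmentation, energy-loss straggling or track-segment
  spectra; one (LET, E) pair per field.
* Repair is single-exponential per damage class; no cell-cycle or
  saturable-enzyme kinetics, no inter-fraction incomplete repair (fractions
  fully resolve by construction).
* The nucleus geometry, diffusion length and yield-enhancement constants
  are open parameters of the model family; the shipped defaults are
  documented choices, and quantities that depend on them (notably the
  high-LET discrepancy values) inherit that uncertainty.
* Ultra-high dose-rate (FLASH-type) sparing mechanisms are outside the
  model's scope; dose-rate effects arise solely from repair during
  delivery.
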