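"""Physical constants and unit conventions.

Internal units: dose in Gy, length in µm, time in minutes, LET in keV/µm,
dose rate in Gy/min.  The single bookkeeping constant is the keV→Gy
conversion in a 1 µm³ voxel of unit-density water:

    1 keV / µm³ / (1 g/cm³) = 1.602e-16 J / 1e-15 kg = 0.1602 Gy

Equivalently, with fluence in cm⁻² this is the familiar
D[Gy] = 1.602e-9 · LET[keV/µm] · Φ[cm⁻²] / ρ[g/cm³].
"""

#: Gy per (keV/µm³) at unit density — energy-to-dose conversion.
GY_PER_KEV_UM3 = 1.602e-1

#: Proton rest energy per nucleon used for relativistic kinematics, MeV/u.
AMU_MEV = 931.494

#: Density of water, g/cm³.
RHO_WATER = 1.0

#: ln(2), the half-life/rate conversion.
import math

LN2 = math.log(2.0)


def fluence_per_gy(let_kev_um: float, rho: float = RHO_WATER) -> float:
    """Particle fluence (µm⁻²) delivering 1 Gy at the given track-averaged LET."""
    return rho / (GY_PER_KEV_UM3 * let_kev_um)
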