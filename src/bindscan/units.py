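"""Physical constants in the package-wide unit system.

Lengths in Å, energies in kcal/mol, charges in elementary charge units,
masses in amu, times in ps, temperatures in K.
"""

from scipy import constants as _c

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻² (community-standard value).
COULOMB_CONSTANT = 332.0637

#: Boltzmann constant, kcal/(mol·K).
KB = _c.k * _c.N_A / (_c.calorie * 1000.0)

#: Default analysis temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Converts sqrt(k/mu) with k in kcal/(mol·Å²) and mu in amu to a
#: wavenumber in cm⁻¹ (includes the 1/2πc factor).
_OMEGA_SI = (1000.0 * _c.calorie / _c.N_A / 1e-20 / _c.atomic_mass) ** 0.5
FREQ_TO_WAVENUMBER = _OMEGA_SI / (2.0 * _c.pi * _c.c * 100.0)

#: h·c·(1 cm⁻¹) / kB in K — converts wavenumbers to vibrational temperatures.
WAVENUMBER_TO_KELVIN = _c.h * _c.c * 100.0 / _c.k

#: Gas constant, cal/(mol·K) (entropies are reported in cal/(mol·K)).
R_CAL = _c.R / _c.calorie

#: Planck constant and friends in SI, re-exported for the partition functions.
PLANCK = _c.h
BOLTZMANN_SI = _c.k
AVOGADRO = _c.N_A
ATOMIC_MASS = _c.atomic_mass


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB * temperature
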