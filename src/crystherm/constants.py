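"""Physical constants (CODATA 2018) and unit conversions.

All internal computation uses K, Pa, J mol^-1, Angstrom; kJ mol^-1 and
degrees Celsius appear only at I/O boundaries.
"""

# CODATA 2018 exact values
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT_CM = 2.99792458e10  # cm s^-1  (wavenumbers are per cm)
BOLTZMANN_KB = 1.380649e-23  # J K^-1
AVOGADRO_NA = 6.02214076e23  # mol^-1
GAS_R = 8.314462618  # J mol^-1 K^-1

# h*c in J cm: multiply by a wavenumber in cm^-1 to get a mode quantum in J
HC_JCM = PLANCK_H * SPEED_OF_LIGHT_CM

CELSIUS_OFFSET = 273.15
ATM_PA = 101325.0

A3_TO_M3 = 1e-30  # cubic Angstrom to cubic metre


def c_to_k(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET


def k_to_c(t_kelvin: float) -> float:
    return t_kelvin - CELSIUS_OFFSET
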