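"""Physical constants used throughout the package.

Energies are in kcal, amounts in mol, temperatures in Kelvin internally
(Celsius at every I/O boundary). The gas constant is fixed in kcal units and
deliberately not configurable so that free energies, enthalpies and m-values
can never silently mix unit systems.
"""

#: Gas constant, kcal mol-1 K-1.
R_KCAL: float = 1.987204e-3

#: Celsius <-> Kelvin offset.
T0_CELSIUS: float = 273.15

#: Default evaluation temperature for chemical (isothermal) denaturation, K.
#: Samples are equilibrated and measured at 25 degC.
T_CHEM_DEFAULT: float = 298.15

#: Density of pure water at 20 degC, g mL-1 (standard s20,w reference).
RHO_WATER_20C: float = 0.99823

#: Viscosity of pure water at 20 degC, mPa s.
ETA_WATER_20C: float = 1.002

#: Density / viscosity of pure water at 25 degC (convenience defaults only).
RHO_WATER_25C: float = 0.99705
ETA_WATER_25C: float = 0.8902

#: Avogadro constant, mol-1.
N_AVOGADRO: float = 6.02214076e23

#: Svedberg unit, seconds.
SVEDBERG: float = 1e-13


def celsius_to_kelvin(t_c):
    return t_c + T0_CELSIUS


def kelvin_to_celsius(t_k):
    return t_k - T0_CELSIUS
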