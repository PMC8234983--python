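"""Three-state unfolding equilibrium models (N <=> I <=> U).

The observable (tryptophan fluorescence intensity) is modelled as the
population-weighted sum of three state-specific signals, each linear in the
perturbation variable (denaturant concentration ``D`` or temperature ``T``):

    F = fN * (FN0 + mN*x) + fI * (FI0 + mI*x) + fU * (FU0 + mU*x)

with Boltzmann populations derived from the two transition free energies.

Chemical (urea) denaturation uses the linear extrapolation method (LEM),

    dG1 = m1 * (Um1 - D),    dG2 = m2 * (Um2 - D),

where ``Um`` is the mid-transition denaturant concentration and ``m`` the
free-energy slope (kcal mol-1 M-1). Thermal denaturation uses the
Gibbs-Helmholtz expression per transition,

    dG(T) = dH * (1 - T/Tm) + dCp * [T - Tm - T*ln(T/Tm)].

No subunit dissociation or aggregation is contemplated: the three states are
macroscopic ensembles and the fitted parameters are apparent quantities.

Populations are evaluated in log space (log-sum-exp) so that fits may probe
extreme parameter values without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import R_KCAL, T_CHEM_DEFAULT
from .errors import InvalidInputError

__all__ = [
    "ChemThermoParams",
    "ThermalThermoParams",
    "SignalBaselines",
    "chem_free_energies",
    "species_fractions",
    "chem_signal",
    "thermal_free_energy",
    "thermal_signal",
]


@dataclass(frozen=True)
class ChemThermoParams:
    """Apparent thermodynamic parameters of the two urea transitions.

    Um1, Um2 : mid-transition urea concentrations, M (Um2 > Um1 when both
    transitions are resolved); m1, m2 : LEM free-energy slopes,
    kcal mol-1 M-1, both positive.
    """

    Um1: float
    Um2: float
    m1: float
    m2: float

    def __post_init__(self):
        vals = (self.Um1, self.Um2, self.m1, self.m2)
        if not all(np.isfinite(vals)):
            raise InvalidInputError(f"non-finite thermodynamic parameters: {vals}")
        if self.Um1 <= 0 or self.m1 <= 0 or self.m2 <= 0:
            raise InvalidInputError(
                "Um1, m1 and m2 must be positive "
                f"(got Um1={self.Um1}, m1={self.m1}, m2={self.m2})"
            )


@dataclass(frozen=True)
class ThermalThermoParams:
    """Apparent thermodynamic parameters of the two thermal transitions.

    Tm1, Tm2 : mid-denaturation temperatures, K (Tm2 >= Tm1);
    dH1, dH2 : unfolding enthalpy changes at Tm, kcal mol-1, positive;
    dCp1, dCp2 : unfolding heat-capacity changes, kcal mol-1 K-1,
    non-negative (default 0; rarely determined accurately from optical data).
    """

    Tm1: float
    Tm2: float
    dH1: float
    dH2: float
    dCp1: float = 0.0
    dCp2: float = 0.0

    def __post_init__(self):
        vals = (self.Tm1, self.Tm2, self.dH1, self.dH2, self.dCp1, self.dCp2)
        if not all(np.isfinite(vals)):
            raise InvalidInputError(f"non-finite thermodynamic parameters: {vals}")
        if self.Tm1 <= 0:
            raise InvalidInputError(f"Tm1 must be a positive absolute temperature, got {self.Tm1}")
        if self.dH1 <= 0 or self.dH2 <= 0:
            raise InvalidInputError("unfolding enthalpies must be positive")
        if self.dCp1 < 0 or self.dCp2 < 0:
            raise InvalidInputError("heat-capacity changes must be non-negative")


@dataclass(frozen=True)
class SignalBaselines:
    """Linear state signals F_state(x) = F0_state + m_state * x.

    ``x_kind`` tags the abscissa the slopes refer to: "chemical" (per M urea)
    or "thermal" (per K). Evaluating a model against baselines of the wrong
    kind is an error, not a unit conversion.
    """

    FN0: float
    mN: float
    FI0: float
    mI: float
    FU0: float
    mU: float
    x_kind: str = "chemical"

    def __post_init__(self):
        if self.x_kind not in ("chemical", "thermal"):
            raise InvalidInputError(f"x_kind must be 'chemical' or 'thermal', got {self.x_kind!r}")
        vals = (self.FN0, self.mN, self.FI0, self.mI, self.FU0, self.mU)
        if not all(np.isfinite(vals)):
            raise InvalidInputError(f"non-finite baseline parameters: {vals}")

    def native(self, x):
        return self.FN0 + self.mN * np.asarray(x, dtype=float)

    def intermediate(self, x):
        return self.FI0 + self.mI * np.asarray(x, dtype=float)

    def unfolded(self, x):
        return self.FU0 + self.mU * np.asarray(x, dtype=float)


def chem_free_energies(D, thermo: ChemThermoParams):
    """LEM free energies of the two transitions at denaturant concentration D.

    Returns ``(dG1, dG2) = (m1*(Um1 - D), m2*(Um2 - D))`` in kcal mol-1;
    vectorized over D.
    """
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)) or np.any(D < 0):
        raise InvalidInputError("denaturant concentration must be finite and >= 0")
    return thermo.m1 * (thermo.Um1 - D), thermo.m2 * (thermo.Um2 - D)


def species_fractions(dG1, dG2, T=T_CHEM_DEFAULT):
    """Boltzmann populations (fN, fI, fU) of the three macrostates.

    Statistical weights are 1, exp(-dG1/RT) and exp(-(dG1+dG2)/RT); the
    normalization is done in log space so extreme free energies yield 0/1
    fractions instead of overflow. The three fractions sum to 1 exactly
    (the normalized vector is renormalized once in linear space).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise InvalidInputError("absolute temperature must be positive")
    dG1 = np.asarray(dG1, dtype=float)
    dG2 = np.asarray(dG2, dtype=float)
    if not (np.all(np.isfinite(dG1)) and np.all(np.isfinite(dG2))):
        raise InvalidInputError("free energies must be finite")
    rt = R_KCAL * T
    logw = np.stack(np.broadcast_arrays(
        np.zeros_like(dG1 / rt), -dG1 / rt, -(dG1 + dG2) / rt))
    logz = logsumexp(logw, axis=0)
    frac = np.exp(logw - logz)
    frac /= frac.sum(axis=0)
    return frac[0], frac[1], frac[2]


def chem_signal(D, thermo: ChemThermoParams, baselines: SignalBaselines,
                T: float = T_CHEM_DEFAULT):
    """Observed fluorescence of the three-state chemical unfolding model.

    Population-weighted sum of the three denaturant-linear state signals;
    ``T`` is the (isothermal) equilibration temperature, 298.15 K by default.
    """
    if baselines.x_kind != "chemical":
        raise InvalidInputError("chemical model requires baselines with x_kind='chemical'")
    dG1, dG2 = chem_free_energies(D, thermo)
    fN, fI, fU = species_fractions(dG1, dG2, T)
    return (fN * baselines.native(D)
            + fI * baselines.intermediate(D)
            + fU * baselines.unfolded(D))


def thermal_free_energy(T, Tm, dH, dCp=0.0):
    """Gibbs-Helmholtz unfolding free energy of one transition, kcal mol-1.

    dG(T) = dH*(1 - T/Tm) + dCp*[T - Tm - T*ln(T/Tm)]; zero at T = Tm by
    construction.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or Tm <= 0:
        raise InvalidInputError("temperatures must be positive (Kelvin)")
    return dH * (1.0 - T / Tm) + dCp * (T - Tm - T * np.log(T / Tm))


def thermal_signal(T, thermo: ThermalThermoParams, baselines: SignalBaselines):
    """Observed fluorescence of the three-state thermal unfolding model."""
    if baselines.x_kind != "thermal":
        raise InvalidInputError("thermal model requires baselines with x_kind='thermal'")
    dG1 = thermal_free_energy(T, thermo.Tm1, thermo.dH1, thermo.dCp1)
    dG2 = thermal_free_energy(T, thermo.Tm2, thermo.dH2, thermo.dCp2)
    fN, fI, fU = species_fractions(dG1, dG2, T)
    return (fN * baselines.native(T)
            + fI * baselines.intermediate(T)
            + fU * baselines.unfolded(T))
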