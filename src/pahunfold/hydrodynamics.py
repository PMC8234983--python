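"""Hydrodynamic arithmetic downstream of sedimentation-velocity c(s) analysis.

The c(s) distributions themselves (Lamm-equation inversion) and the solvent
physical properties are inputs: this module standardizes observed
sedimentation coefficients to water at 20 degC (s20,w), computes frictional
ratios from s20,w, molar mass and partial specific volume, and integrates
c(s) peaks into species signal fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import (
    ETA_WATER_20C,
    ETA_WATER_25C,
    N_AVOGADRO,
    RHO_WATER_20C,
    RHO_WATER_25C,
    SVEDBERG,
)
from .errors import InvalidInputError

__all__ = ["SolventConditions", "CsDistribution", "SpeciesAssignment",
           "s20w", "frictional_ratio", "integrate_peaks",
           "WATER_20C", "WATER_25C"]

#: Default partial specific volume for a typical protein, mL g-1.
VBAR_DEFAULT = 0.73


@dataclass(frozen=True)
class SolventConditions:
    """Solvent density (g mL-1), viscosity (mPa s) and temperature (K).

    Values for urea buffers are expected to come from tabulations external
    to this package (they are experiment inputs, not computed here)."""

    density: float
    viscosity: float
    temperature: float

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0 or self.temperature <= 0:
            raise InvalidInputError("solvent density, viscosity and temperature must be positive")


WATER_20C = SolventConditions(density=RHO_WATER_20C, viscosity=ETA_WATER_20C,
                              temperature=293.15)
WATER_25C = SolventConditions(density=RHO_WATER_25C, viscosity=ETA_WATER_25C,
                              temperature=298.15)


@dataclass
class CsDistribution:
    """A c(s) sedimentation-coefficient distribution: s (Svedberg, strictly
    increasing) vs. signal density per S (>= 0)."""

    s: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.s.ndim != 1 or self.s.shape != self.signal.shape:
            raise InvalidInputError("s and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.s) <= 0):
            raise InvalidInputError("s grid must be strictly increasing")
        if np.any(self.signal < 0):
            raise InvalidInputError("c(s) signal must be non-negative")


@dataclass(frozen=True)
class SpeciesAssignment:
    """One integrated c(s) window: species label, signal-weighted mean
    sedimentation coefficient (S) and fraction of the total signal."""

    label: str
    s20w: float
    fraction: float


def s20w(s_obs: float, solvent: SolventConditions, vbar: float = VBAR_DEFAULT) -> float:
    """Standardize an observed sedimentation coefficient to water at 20 degC.

    s20,w = s_obs * (eta_solvent / eta_w20) * (1 - vbar*rho_w20) / (1 - vbar*rho_solvent)

    vbar is the protein partial specific volume in mL g-1. Raises on neutral
    or negative buoyancy in either solvent.
    """
    buoy_w = 1.0 - vbar * RHO_WATER_20C
    buoy_s = 1.0 - vbar * solvent.density
    if buoy_w <= 0 or buoy_s <= 0:
        raise InvalidInputError(
            f"non-positive buoyancy factor (vbar={vbar}, rho={solvent.density})")
    return s_obs * (solvent.viscosity / ETA_WATER_20C) * buoy_w / buoy_s


def frictional_ratio(s20w_val: float, M: float, vbar: float = VBAR_DEFAULT):
    """Frictional ratio f/f0 from s20,w (S), molar mass M (g mol-1) and vbar
    (mL g-1).

    f/f0 = Rs/R0 with Rs the Stokes radius implied by s20,w and R0 the
    radius of the equivalent anhydrous sphere. Returns ``(ratio, warning)``
    where ``warning`` is True for non-physical values below 1 - 0.02.
    """
    if s20w_val <= 0 or M <= 0 or vbar <= 0:
        raise InvalidInputError("s20w, M and vbar must be positive")
    buoy = 1.0 - vbar * RHO_WATER_20C
    if buoy <= 0:
        raise InvalidInputError("non-positive buoyancy factor")
    M_kg = M * 1e-3                      # kg mol-1
    vbar_si = vbar * 1e-3                # m3 kg-1
    eta = ETA_WATER_20C * 1e-3           # Pa s
    s_sec = s20w_val * SVEDBERG
    r_stokes = M_kg * buoy / (N_AVOGADRO * 6.0 * np.pi * eta * s_sec)
    r_sphere = (3.0 * M_kg * vbar_si / (4.0 * np.pi * N_AVOGADRO)) ** (1.0 / 3.0)
    ratio = float(r_stokes / r_sphere)
    return ratio, ratio < 1.0 - 0.02


def integrate_peaks(dist: CsDistribution,
                    boundaries: Sequence[tuple],
                    labels: Optional[Sequence[str]] = None) -> list:
    """Integrate c(s) windows into species signal fractions.

    Each ``(s_lo, s_hi)`` window is integrated by the trapezoidal rule
    (with the window edges inserted by linear interpolation) and divided by
    the integral over the full range; the species s20,w is the
    signal-weighted mean s within the window. Windows must be
    non-overlapping and inside the s-range. An empty window yields a
    zero-fraction assignment.
    """
    prev_hi = -np.inf
    for lo, hi in sorted(boundaries):
        if lo >= hi:
            raise InvalidInputError(f"empty or inverted window ({lo}, {hi})")
        if lo < prev_hi:
            raise InvalidInputError("windows overlap")
        if lo < dist.s[0] - 1e-9 or hi > dist.s[-1] + 1e-9:
            raise InvalidInputError(f"window ({lo}, {hi}) outside the s-range")
        prev_hi = hi

    total = np.trapezoid(dist.signal, dist.s)
    if total <= 0:
        raise InvalidInputError("distribution has zero total signal")
    if labels is None:
        labels = [f"peak{i+1}" for i in range(len(boundaries))]

    out = []
    for (lo, hi), label in zip(boundaries, labels):
        grid = np.unique(np.concatenate([[lo], dist.s[(dist.s > lo) & (dist.s < hi)], [hi]]))
        sig = np.interp(grid, dist.s, dist.signal)
        area = np.trapezoid(sig, grid)
        if area <= 0:
            out.append(SpeciesAssignment(label=label, s20w=0.5 * (lo + hi), fraction=0.0))
            continue
        s_mean = np.trapezoid(sig * grid, grid) / area
        out.append(SpeciesAssignment(label=label, s20w=float(s_mean),
                                     fraction=float(area / total)))
    return out
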