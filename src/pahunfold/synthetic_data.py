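"""Synthetic inputs for every stage of the pipeline.

Generates noisy two-transition chemical and thermal unfolding curves, two-
peak DSC excess-heat-capacity thermograms, single-band tryptophan emission
spectra (log-normal lineshape) and Gaussian-mixture c(s) distributions, all
deterministic under a fixed seed and all carrying their generating truth in
``meta`` so recovery tests can close the loop.

Named presets encode the published apparent parameters for the two protein
constructions (full-length tetramer PAHt, catalytic-domain dimer PAHd) at
the studied subunit concentrations. Baseline amplitudes and slopes are not
published; the preset values are invented plausible constants chosen so the
first chemical transition of PAHt raises fluorescence by about 90% (about
20% for PAHd), the second lowers it, and thermal native baselines decline
with temperature, mirroring the qualitative look of the real curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import celsius_to_kelvin
from .curve_fitting import DenaturationCurve
from .dsc import DSCThermogram, DSCTransition, vanthoff_excess_cp
from .equilibrium_models import (
    ChemThermoParams,
    SignalBaselines,
    ThermalThermoParams,
    chem_signal,
    thermal_signal,
)
from .errors import InvalidInputError
from .hydrodynamics import CsDistribution
from .spectra import EmissionSpectrum

__all__ = [
    "NoiseModel",
    "ScenarioPreset",
    "PRESETS",
    "get_preset",
    "simulate_chem_curve",
    "simulate_thermal_curve",
    "simulate_dsc",
    "simulate_spectrum",
    "simulate_cs",
    "simulate_preset",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise.

    ``sigma`` is an absolute standard deviation when ``relative`` is False,
    otherwise a fraction of the generator's characteristic amplitude (the
    native-to-intermediate signal change for unfolding curves; the tallest
    peak height for DSC, spectra and c(s)). Identical seeds give identical
    draws.
    """

    sigma: float = 0.01
    relative: bool = True
    seed: int = 0
    kind: str = "gaussian"

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")
        if self.kind != "gaussian":
            raise InvalidInputError(f"unsupported noise kind {self.kind!r}")

    def draw(self, n: int, amplitude: float = 1.0) -> np.ndarray:
        scale = self.sigma * (amplitude if self.relative else 1.0)
        if scale == 0:
            return np.zeros(n)
        return np.random.default_rng(self.seed).normal(0.0, scale, n)


# invented plausible baselines (a.u.); not published quantities
CHEM_BASELINES = {
    "PAHt": SignalBaselines(FN0=100.0, mN=1.5, FI0=190.0, mI=-2.0,
                            FU0=120.0, mU=1.0, x_kind="chemical"),
    "PAHd": SignalBaselines(FN0=100.0, mN=1.5, FI0=120.0, mI=-1.5,
                            FU0=90.0, mU=1.0, x_kind="chemical"),
}
THERMAL_BASELINES = SignalBaselines(FN0=220.0, mN=-0.40, FI0=230.0, mI=-0.30,
                                    FU0=280.0, mU=-0.35, x_kind="thermal")

CHEM_GRID_DEFAULT = np.linspace(0.0, 7.8, 40)                  # M urea
THERMAL_GRID_DEFAULT = celsius_to_kelvin(np.arange(20.0, 90.0 + 0.5, 1.0))
DSC_GRID_DEFAULT = celsius_to_kelvin(np.arange(20.0, 90.0 + 1e-9, 0.1))
SPECTRUM_GRID_DEFAULT = np.arange(300.0, 460.0 + 1e-9, 1.0)    # nm
CS_GRID_DEFAULT = np.arange(0.5, 20.0 + 1e-9, 0.05)            # Svedberg


@dataclass(frozen=True)
class ScenarioPreset:
    """An immutable named scenario: model family, true parameters and the
    source of those parameters (published table/section, or 'invented')."""

    name: str
    family: str          # chemical | thermal | dsc | spectrum | cs
    params: tuple        # family-specific (see simulate_preset)
    source: str
    default_sigma: float = 0.01


def _chem(name, Um1, m1, Um2, m2, construction, source):
    return ScenarioPreset(
        name=name, family="chemical",
        params=(ChemThermoParams(Um1=Um1, m1=m1, Um2=Um2, m2=m2),
                CHEM_BASELINES[construction]),
        source=source)


def _thermal(name, Tm1_c, Tm2_c, source, dH1=80.0, dH2=120.0):
    return ScenarioPreset(
        name=name, family="thermal",
        params=(ThermalThermoParams(Tm1=celsius_to_kelvin(Tm1_c), dH1=dH1,
                                    Tm2=celsius_to_kelvin(Tm2_c), dH2=dH2),
                THERMAL_BASELINES),
        source=source)


def _dsc(name, Tm1_c, Tm2_c, source, dH1=100.0, dH2=150.0):
    return ScenarioPreset(
        name=name, family="dsc",
        params=(DSCTransition(Tm=celsius_to_kelvin(Tm1_c), dHvH=dH1),
                DSCTransition(Tm=celsius_to_kelvin(Tm2_c), dHvH=dH2)),
        source=source)


PRESETS = {p.name: p for p in [
    # chemical urea denaturation, apparent global-fit parameters
    _chem("PAHt_0.8uM_urea", 2.70, 1.91, 5.48, 2.12, "PAHt",
          "published apparent parameters, PAHt 0.8 uM"),
    _chem("PAHt_8uM_urea", 2.73, 1.23, 6.38, 1.21, "PAHt",
          "published apparent parameters, PAHt 8 uM"),
    _chem("PAHd_0.8uM_urea", 2.59, 2.37, 4.97, 1.02, "PAHd",
          "published apparent parameters, PAHd 0.8 uM"),
    _chem("PAHd_8uM_urea", 4.20, 4.61, 6.54, 2.47, "PAHd",
          "published apparent parameters, PAHd 8 uM"),
    # thermal denaturation mid-temperatures (dH values invented plausible)
    _thermal("PAHd_0.8uM_thermal", 43.1, 54.1, "published Tm pair, PAHd 0.8 uM"),
    _thermal("PAHd_5uM_thermal", 43.6, 54.1, "published Tm pair, PAHd 5 uM"),
    _thermal("PAHt_0.8uM_thermal", 46.8, 56.1, "published Tm pair, PAHt 0.8 uM"),
    _thermal("PAHt_5uM_thermal", 46.7, 56.6, "published Tm pair, PAHt 5 uM"),
    # DSC first-derivative mid-temperatures (dHvH invented plausible)
    _dsc("PAHt_DSC", 44.0, 55.6, "published DSC Tm pair, PAHt 5 uM"),
    _dsc("PAHd_DSC", 45.0, 54.4, "published DSC Tm pair, PAHd 5 uM"),
    # emission maxima at representative urea concentrations
    ScenarioPreset("PAHt_native_spectrum", "spectrum", (330.0, 55.0, 100.0),
                   "published emission maximum, PAHt 0 M urea"),
    ScenarioPreset("PAHt_4M_spectrum", "spectrum", (335.0, 55.0, 190.0),
                   "published 5 nm red shift at 4 M urea"),
    ScenarioPreset("PAHt_7.6M_spectrum", "spectrum", (355.0, 55.0, 120.0),
                   "published emission maximum, PAHt 7.6 M urea"),
    ScenarioPreset("PAHd_native_spectrum", "spectrum", (347.0, 55.0, 100.0),
                   "published emission maximum, PAHd 0 M urea"),
    ScenarioPreset("PAHd_5M_spectrum", "spectrum", (340.0, 55.0, 120.0),
                   "published 7 nm blue shift at 5 M urea"),
    ScenarioPreset("PAHd_7.6M_spectrum", "spectrum", (356.0, 55.0, 110.0),
                   "published emission maximum, PAHd 7.6 M urea"),
    # native c(s) profiles (peak widths invented plausible)
    # c(s) is a regularized inversion output, hence nearly smooth: tiny noise
    ScenarioPreset("PAHt_native_AUC", "cs",
                   ((9.6, 0.40, 0.81), (6.5, 0.35, 0.12), (12.8, 0.60, 0.06)),
                   "published species fractions, PAHt 0 M urea",
                   default_sigma=0.002),
    ScenarioPreset("PAHd_native_AUC", "cs",
                   ((4.2, 0.30, 0.70), (3.3, 0.25, 0.26),
                    (7.5, 0.40, 0.02), (6.0, 0.35, 0.02)),
                   "published species fractions, PAHd 0 M urea",
                   default_sigma=0.002),
]}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def _truth_meta(**kwargs) -> dict:
    return {"synthetic": True, "truth": kwargs}


def simulate_chem_curve(thermo: ChemThermoParams, baselines: SignalBaselines,
                        grid: Optional[np.ndarray] = None,
                        noise: NoiseModel = NoiseModel()) -> DenaturationCurve:
    """Noisy chemical unfolding curve on a urea grid (default 0-7.8 M, 40
    points). Noise amplitude reference: |intermediate - native| at Um1."""
    grid = CHEM_GRID_DEFAULT if grid is None else np.asarray(grid, dtype=float)
    y = chem_signal(grid, thermo, baselines)
    amp = abs(float(baselines.intermediate(thermo.Um1) - baselines.native(thermo.Um1)))
    y = y + noise.draw(len(grid), amp)
    return DenaturationCurve(grid, y, mode="chemical",
                             meta=_truth_meta(thermo=thermo, baselines=baselines,
                                              noise=noise))


def simulate_thermal_curve(thermo: ThermalThermoParams, baselines: SignalBaselines,
                           grid: Optional[np.ndarray] = None,
                           noise: NoiseModel = NoiseModel()) -> DenaturationCurve:
    """Noisy thermal unfolding curve on a Kelvin grid (default 20-90 degC at
    1 degC spacing)."""
    grid = THERMAL_GRID_DEFAULT if grid is None else np.asarray(grid, dtype=float)
    y = thermal_signal(grid, thermo, baselines)
    amp = abs(float(baselines.intermediate(thermo.Tm1) - baselines.native(thermo.Tm1)))
    y = y + noise.draw(len(grid), amp)
    return DenaturationCurve(grid, y, mode="thermal",
                             meta=_truth_meta(thermo=thermo, baselines=baselines,
                                              noise=noise))


def simulate_dsc(transitions: Sequence[DSCTransition],
                 drift: tuple = (0.0, 0.0),
                 noise: NoiseModel = NoiseModel(),
                 grid: Optional[np.ndarray] = None) -> DSCThermogram:
    """Molar excess-heat-capacity thermogram: sum of van't Hoff peaks plus a
    linear drift ``drift[0] + drift[1]*(T - Tmin)`` and noise scaled to the
    tallest peak. Returned flagged as baseline-subtracted and normalized."""
    grid = DSC_GRID_DEFAULT if grid is None else np.asarray(grid, dtype=float)
    cp = np.full_like(grid, drift[0]) + drift[1] * (grid - grid[0])
    peak = 0.0
    for tr in transitions:
        term = vanthoff_excess_cp(grid, tr)
        peak = max(peak, float(term.max()))
        cp = cp + term
    cp = cp + noise.draw(len(grid), peak if transitions else 1.0)
    return DSCThermogram(grid, cp, normalized=True, baseline_subtracted=True,
                         meta=_truth_meta(transitions=tuple(transitions),
                                          drift=drift, noise=noise))


def _lognormal_band(wl: np.ndarray, center: float, fwhm: float,
                    amplitude: float, asym: float = 1.3) -> np.ndarray:
    """Siano-Metzler log-normal lineshape peaking at ``center`` with the
    given FWHM and asymmetry ratio (>1 skews to the red, as Trp emission)."""
    arg = 1.0 + (wl - center) * (asym ** 2 - 1.0) / (fwhm * asym)
    out = np.zeros_like(wl)
    ok = arg > 0
    out[ok] = amplitude * np.exp(-np.log(2.0) / np.log(asym) ** 2 * np.log(arg[ok]) ** 2)
    return out


def simulate_spectrum(center: float, fwhm: float = 55.0, amplitude: float = 100.0,
                      noise: NoiseModel = NoiseModel(),
                      grid: Optional[np.ndarray] = None) -> EmissionSpectrum:
    """Single-band emission spectrum on a wavelength grid (default 300-460 nm
    at 1 nm). Intensities are clipped at zero after adding noise."""
    grid = SPECTRUM_GRID_DEFAULT if grid is None else np.asarray(grid, dtype=float)
    inten = _lognormal_band(grid, center, fwhm, amplitude)
    inten = np.clip(inten + noise.draw(len(grid), amplitude), 0.0, None)
    return EmissionSpectrum(grid, inten,
                            meta=_truth_meta(center=center, fwhm=fwhm,
                                             amplitude=amplitude, noise=noise))


def simulate_cs(peaks: Sequence[tuple],
                noise: NoiseModel = NoiseModel(),
                grid: Optional[np.ndarray] = None) -> CsDistribution:
    """Gaussian-mixture c(s) distribution from ``(s, width, weight)`` peaks.

    Weights are renormalized to sum to 1; each peak integrates (over s) to
    its normalized weight. Signal is clipped at zero after adding noise."""
    grid = CS_GRID_DEFAULT if grid is None else np.asarray(grid, dtype=float)
    peaks = [tuple(p) for p in peaks]
    wsum = sum(w for _, _, w in peaks)
    if wsum <= 0:
        raise InvalidInputError("peak weights must sum to a positive value")
    signal = np.zeros_like(grid)
    for s0, width, w in peaks:
        signal += (w / wsum) * np.exp(-0.5 * ((grid - s0) / width) ** 2) \
            / (width * np.sqrt(2.0 * np.pi))
    signal = np.clip(signal + noise.draw(len(grid), float(signal.max())), 0.0, None)
    return CsDistribution(grid, signal,
                          meta=_truth_meta(peaks=tuple((s, w_, w / wsum)
                                                       for (s, w_, w) in peaks),
                                           noise=noise))


def simulate_preset(name: str, seed: int = 0, sigma: Optional[float] = None):
    """Simulate a named scenario with its default grid and noise level.

    Returns the family's native object (DenaturationCurve, DSCThermogram,
    EmissionSpectrum or CsDistribution)."""
    preset = get_preset(name)
    noise = NoiseModel(sigma=preset.default_sigma if sigma is None else sigma,
                       relative=True, seed=seed)
    if preset.family == "chemical":
        thermo, baselines = preset.params
        return simulate_chem_curve(thermo, baselines, noise=noise)
    if preset.family == "thermal":
        thermo, baselines = preset.params
        return simulate_thermal_curve(thermo, baselines, noise=noise)
    if preset.family == "dsc":
        return simulate_dsc(list(preset.params), noise=noise)
    if preset.family == "spectrum":
        center, fwhm, amplitude = preset.params
        return simulate_spectrum(center, fwhm, amplitude, noise=noise)
    if preset.family == "cs":
        return simulate_cs(preset.params, noise=noise)
    raise InvalidInputError(f"unknown preset family {preset.family!r}")
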