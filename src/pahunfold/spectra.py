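"""Tryptophan fluorescence emission-spectrum descriptors.

The position of the tryptophan emission maximum reports on solvent exposure
(~330 nm buried, ~355 nm fully exposed); spectral shifts between conditions
and simple intensity ratios (I355/I337 by default) are the standard scalar
summaries of a denaturation series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["EmissionSpectrum", "PeakEstimate", "emission_maximum",
           "spectral_shift", "intensity_ratio"]

MIN_POINTS = 20
MIN_SPAN_NM = 60.0


@dataclass
class EmissionSpectrum:
    """Wavelength (nm, strictly increasing) vs. intensity (a.u., >= 0)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.ndim != 1 or self.wavelength.shape != self.intensity.shape:
            raise InvalidInputError("wavelength and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if np.any(self.intensity < 0):
            raise InvalidInputError("intensities must be non-negative")


@dataclass(frozen=True)
class PeakEstimate:
    """An emission-maximum estimate; ``at_edge`` flags a maximum found at the
    boundary of the scanned range (position then unreliable)."""

    wavelength: float
    at_edge: bool = False

    def __float__(self):
        return float(self.wavelength)


def emission_maximum(spectrum: EmissionSpectrum, smooth_window: float = 5.0) -> PeakEstimate:
    """Wavelength of the emission maximum, nm.

    The spectrum is smoothed with a centered moving average of width
    ``smooth_window`` nm before locating the discrete maximum, which is then
    refined by a quadratic through the three surrounding points. A maximum
    at the first or last grid point is returned flagged instead of refined.
    """
    wl, inten = spectrum.wavelength, spectrum.intensity
    if len(wl) < MIN_POINTS or (wl[-1] - wl[0]) < MIN_SPAN_NM:
        raise InvalidInputError(
            f"need >= {MIN_POINTS} points spanning >= {MIN_SPAN_NM:g} nm")
    step = float(np.median(np.diff(wl)))
    npts = max(3, int(round(smooth_window / step)) | 1)
    pad = npts // 2
    sm = np.convolve(np.pad(inten, pad, mode="edge"), np.ones(npts) / npts, mode="valid")
    i = int(np.argmax(sm))
    if i == 0 or i == len(sm) - 1:
        return PeakEstimate(float(wl[i]), at_edge=True)
    # quadratic vertex through the three points around the discrete maximum
    x0, x1, x2 = wl[i - 1:i + 2]
    y0, y1, y2 = sm[i - 1:i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # flat or inverted triple: keep the grid point
        return PeakEstimate(float(wl[i]), at_edge=False)
    return PeakEstimate(float(-b / (2 * a)), at_edge=False)


def spectral_shift(a: EmissionSpectrum, b: EmissionSpectrum,
                   smooth_window: float = 5.0) -> PeakEstimate:
    """Signed shift of b's emission maximum relative to a's (positive =
    red-shift of b); edge flags propagate."""
    pa = emission_maximum(a, smooth_window)
    pb = emission_maximum(b, smooth_window)
    return PeakEstimate(pb.wavelength - pa.wavelength,
                        at_edge=pa.at_edge or pb.at_edge)


def intensity_ratio(spectrum: EmissionSpectrum,
                    num_nm: float = 355.0, den_nm: float = 337.0) -> float:
    """Linear-interpolated intensity ratio I(num_nm)/I(den_nm)."""
    wl = spectrum.wavelength
    for nm in (num_nm, den_nm):
        if not (wl[0] <= nm <= wl[-1]):
            raise InvalidInputError(f"{nm} nm outside the scanned range [{wl[0]}, {wl[-1]}]")
    num = float(np.interp(num_nm, wl, spectrum.intensity))
    den = float(np.interp(den_nm, wl, spectrum.intensity))
    if den <= 0:
        raise InvalidInputError(f"denominator intensity at {den_nm} nm is not positive")
    return num / den
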