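"""DSC thermogram processing and two-transition van't Hoff deconvolution.

Pipeline order is enforced by provenance flags on the thermogram: buffer
baseline subtraction, molar normalization, transition-temperature location
from the smoothed first derivative, and finally a least-squares
deconvolution into two independent two-state van't Hoff peaks plus a linear
residual baseline. Each transition's excess heat capacity is

    Cp_exc(T) = dHvH^2 * f * (1 - f) / (R * T^2),
    f = K / (1 + K),   K = exp(-dHvH * (1 - T/Tm) / (R * T)),

whose maximum sits marginally below Tm (by < 0.1 K for dHvH >= 80
kcal mol-1) and whose integral over temperature equals dHvH.

High-temperature data are often distorted by irreversible aggregation; the
deconvolution therefore clips its fitting window where the signal has
fallen to a configurable fraction of the second peak's height on the
high-temperature side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import lmfit
import numpy as np
from scipy.signal import peak_prominences

from .constants import R_KCAL, celsius_to_kelvin, kelvin_to_celsius
from .errors import InvalidInputError, ProcessingOrderError

__all__ = [
    "DSCThermogram",
    "DSCTransition",
    "subtract_baseline",
    "normalize",
    "find_tm_first_derivative",
    "vanthoff_excess_cp",
    "deconvolve_two_transitions",
]


@dataclass
class DSCThermogram:
    """Temperature vs. heat capacity, with processing provenance flags.

    ``T`` is in Kelvin internally (I/O is Celsius). ``cp`` is in raw
    instrument units until :func:`normalize` converts it to molar excess
    heat capacity (kcal mol-1 K-1).
    """

    T: np.ndarray
    cp: np.ndarray
    normalized: bool = False
    baseline_subtracted: bool = False
    scan_rate: float = 1.0  # K min-1
    conc: Optional[float] = None   # subunit concentration, uM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.T.ndim != 1 or self.T.shape != self.cp.shape:
            raise InvalidInputError("T and cp must be 1-D arrays of equal length")
        if np.any(np.diff(self.T) <= 0):
            raise InvalidInputError("temperatures must be strictly increasing")

    @property
    def T_celsius(self):
        return kelvin_to_celsius(self.T)


@dataclass(frozen=True)
class DSCTransition:
    """One two-state transition of the deconvolution: mid-temperature Tm (K),
    van't Hoff enthalpy dHvH (kcal mol-1) and a dimensionless amplitude
    scale (1 = ideal two-state calorimetric/van't Hoff agreement)."""

    Tm: float
    dHvH: float
    scale: float = 1.0

    def __post_init__(self):
        if self.dHvH <= 0:
            raise InvalidInputError("van't Hoff enthalpy must be positive")
        if self.Tm <= 0:
            raise InvalidInputError("Tm must be a positive absolute temperature")

    @property
    def Tm_celsius(self):
        return kelvin_to_celsius(self.Tm)


def subtract_baseline(sample: DSCThermogram, buffer: DSCThermogram) -> DSCThermogram:
    """Subtract a buffer-buffer scan from a protein scan.

    The buffer scan is interpolated linearly onto the sample grid; the
    result keeps the sample grid restricted to the overlapping range.
    """
    if sample.baseline_subtracted:
        raise ProcessingOrderError("baseline already subtracted")
    lo = max(sample.T[0], buffer.T[0])
    hi = min(sample.T[-1], buffer.T[-1])
    if lo >= hi:
        raise InvalidInputError("sample and buffer temperature ranges do not overlap")
    keep = (sample.T >= lo) & (sample.T <= hi)
    T = sample.T[keep]
    cp = sample.cp[keep] - np.interp(T, buffer.T, buffer.cp)
    return replace(sample, T=T, cp=cp, baseline_subtracted=True,
                   meta=dict(sample.meta))


def normalize(thermogram: DSCThermogram, conc: float, cell_volume: float) -> DSCThermogram:
    """Normalize a baseline-subtracted thermogram to moles of subunit.

    conc : subunit concentration in uM; cell_volume : calorimeter cell
    volume in mL. Divides cp by conc*volume*1e-9 mol, giving molar heat
    capacity in kcal mol-1 K-1 (assuming cp entered in kcal K-1).
    """
    if not thermogram.baseline_subtracted:
        raise ProcessingOrderError("normalize requires a baseline-subtracted thermogram")
    if thermogram.normalized:
        raise ProcessingOrderError("thermogram already normalized")
    if conc <= 0 or cell_volume <= 0:
        raise InvalidInputError("concentration and cell volume must be positive")
    moles = conc * 1e-6 * cell_volume * 1e-3
    return replace(thermogram, cp=thermogram.cp / moles, normalized=True,
                   conc=conc, meta=dict(thermogram.meta))


def _moving_average(y: np.ndarray, npts: int) -> np.ndarray:
    npts = max(3, int(npts) | 1)
    pad = npts // 2
    return np.convolve(np.pad(y, pad, mode="edge"), np.ones(npts) / npts, mode="valid")


def find_tm_first_derivative(thermogram: DSCThermogram,
                             smooth_window: float = 1.5,
                             prominence_frac: float = 0.05) -> list:
    """Transition temperatures from the first derivative of the thermogram.

    The heat capacity is smoothed with a centered moving average of width
    ``smooth_window`` (K), and local maxima are located where the smoothed
    first derivative crosses zero from + to -, with sub-grid refinement by
    linear interpolation of the derivative. Maxima whose prominence is below
    ``prominence_frac`` of the global peak height are suppressed. Returns
    Celsius values in ascending order (empty list if nothing qualifies).
    """
    if not thermogram.normalized:
        raise ProcessingOrderError("find_tm_first_derivative requires a normalized thermogram")
    T, cp = thermogram.T, thermogram.cp
    step = float(np.median(np.diff(T)))
    cps = _moving_average(cp, round(smooth_window / step))
    d = np.gradient(cps, T)

    found = []  # (Tm_kelvin, peak height)
    crossings = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
    threshold = prominence_frac * cps.max()
    for i in crossings:
        # sub-grid zero of the derivative
        t0 = T[i] + d[i] * (T[i + 1] - T[i]) / (d[i] - d[i + 1])
        # prominence is evaluated at the discrete local maximum flanking the crossing
        idx = i if cps[i] >= cps[i + 1] else i + 1
        if 0 < idx < len(cps) - 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero prominence just fails the filter
                prom = peak_prominences(cps, [idx])[0][0]
        else:
            prom = 0.0
        if prom >= threshold:
            found.append((t0, cps[idx]))
    # merge detections closer than the smoothing window (noise jitter on one peak)
    found.sort()
    tms = []
    for t0, height in found:
        if tms and abs(t0 - tms[-1][0]) < smooth_window:
            if height > tms[-1][1]:
                tms[-1] = (t0, height)
        else:
            tms.append((t0, height))
    return [kelvin_to_celsius(t) for t, _ in tms]


def vanthoff_excess_cp(T, tr: DSCTransition):
    """Excess heat capacity of one two-state van't Hoff transition.

    Non-negative, single-peaked; integrates to ``scale * dHvH`` over
    temperature; the unfolded fraction equals 1/2 exactly at Tm.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise InvalidInputError("absolute temperature must be positive")
    rt = R_KCAL * T
    lnK = -tr.dHvH * (1.0 - T / tr.Tm) / rt
    # f*(1-f) = K/(1+K)^2, computed stably from |lnK|
    f1mf = np.exp(-np.abs(lnK)) / (1.0 + np.exp(-np.abs(lnK))) ** 2
    return tr.scale * tr.dHvH ** 2 * f1mf / (rt * T)


def _two_peak_model(params, T):
    v = params.valuesdict()
    out = v["b0"] + v["b1"] * (T - T.mean())
    for i in (1, 2):
        tr = DSCTransition(Tm=v[f"Tm{i}"], dHvH=v[f"dH{i}"], scale=v[f"s{i}"])
        out = out + vanthoff_excess_cp(T, tr)
    return out


def deconvolve_two_transitions(thermogram: DSCThermogram,
                               clip_fraction: float = 0.25,
                               degenerate_scale: float = 0.05):
    """Least-squares deconvolution into two van't Hoff peaks + linear baseline.

    Initialized from :func:`find_tm_first_derivative`. The fitting window is
    clipped above the temperature where cp falls below ``clip_fraction`` of
    the second peak's height on the high-temperature side (aggregation
    distortion). Returns ``(transitions, fit_info)`` where ``transitions``
    is a pair of :class:`DSCTransition` in ascending Tm and ``fit_info``
    holds residuals, rss, convergence flag and a ``degenerate`` flag set
    when the fit does not support two genuine transitions (one amplitude
    scale below ``degenerate_scale``, or the two fitted Tm within 1 K).
    """
    if not thermogram.normalized:
        raise ProcessingOrderError("deconvolution requires a normalized thermogram")
    tms_c = find_tm_first_derivative(thermogram)
    if not tms_c:
        raise InvalidInputError("no detectable maximum to initialize the deconvolution")
    T, cp = thermogram.T, thermogram.cp

    if len(tms_c) == 1:
        guess = [tms_c[0], tms_c[0] + 8.0]
    else:
        guess = [tms_c[0], tms_c[-1]]
    tm2_k = celsius_to_kelvin(guess[1])

    # clip the aggregation-distorted high-T tail
    peak2 = float(np.interp(tm2_k, T, cp))
    above = T > tm2_k
    low = above & (cp < clip_fraction * peak2)
    hi_cut = T[low][0] if low.any() else T[-1]
    win = T <= hi_cut
    Tw, cpw = T[win], cp[win]

    params = lmfit.Parameters()
    span = T[-1] - T[0]
    for i, tm_c in enumerate(guess, start=1):
        tm_k = celsius_to_kelvin(tm_c)
        params.add(f"Tm{i}", value=tm_k, min=T[0] - 0.1 * span, max=T[-1] + 0.1 * span)
        params.add(f"dH{i}", value=100.0, min=10.0, max=500.0)
        params.add(f"s{i}", value=1.0, min=0.0, max=5.0)
    params.add("_gap", value=max(celsius_to_kelvin(guess[1]) - celsius_to_kelvin(guess[0]), 0.5),
               min=1e-3, max=span)
    params["Tm2"].set(expr="Tm1 + _gap")
    params.add("b0", value=float(np.percentile(cpw, 5)))
    params.add("b1", value=0.0)

    out = lmfit.minimize(lambda p: _two_peak_model(p, Tw) - cpw, params,
                         method="leastsq", nan_policy="raise")
    v = out.params.valuesdict()
    transitions = sorted(
        (DSCTransition(Tm=v[f"Tm{i}"], dHvH=v[f"dH{i}"], scale=v[f"s{i}"]) for i in (1, 2)),
        key=lambda tr: tr.Tm)
    fit_info = {
        "residuals": np.asarray(out.residual),
        "rss": float(np.sum(out.residual ** 2)),
        "converged": bool(out.success),
        # one real transition can masquerade as two: either the second
        # amplitude collapses or the two fitted Tm coincide
        "degenerate": bool(min(v["s1"], v["s2"]) < degenerate_scale
                           or abs(v["Tm2"] - v["Tm1"]) < 1.0),
        "window": (float(Tw[0]), float(Tw[-1])),
        "stderr": {k: (float(out.params[k].stderr) if out.params[k].stderr is not None else np.nan)
                   for k in ("Tm1", "Tm2", "dH1", "dH2")},
        "message": str(out.message),
    }
    return transitions, fit_info
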