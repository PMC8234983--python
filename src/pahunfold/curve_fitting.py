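"""Individual and global nonlinear least-squares fitting of unfolding curves.

A global fit pools two or more replicate denaturation curves and minimizes a
single residual vector in which the thermodynamic parameters (midpoints and
m-values, or Tm and dH) are shared across curves while the three linear
signal baselines remain free per curve. This is the standard way to report
one apparent parameter set per construction/concentration from replicate
fluorescence curves; fitting a single curve is the special case n_curves=1.

Optimization uses Levenberg-Marquardt (via lmfit) restarted from several
randomized perturbations of a data-driven initial guess, because two-
transition models have local minima when the transitions overlap. Standard
errors come from the scaled inverse of the Gauss-Newton normal matrix at the
optimum (lmfit's covariance estimate); an optional residual bootstrap is
provided for when the curvature-based errors are in doubt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy.signal import find_peaks

from .constants import R_KCAL, T_CHEM_DEFAULT
from .equilibrium_models import (
    ChemThermoParams,
    SignalBaselines,
    ThermalThermoParams,
    chem_free_energies,
    species_fractions,
    thermal_free_energy,
)
from .errors import FitNotConvergedError, InvalidInputError

__all__ = [
    "DenaturationCurve",
    "FitConfig",
    "FitResult",
    "initial_guess",
    "fit_individual",
    "fit_global",
    "population_curve",
    "bootstrap_stderr",
]

THERMO_NAMES = {
    "chemical": ("Um1", "m1", "Um2", "m2"),
    "thermal": ("Tm1", "dH1", "Tm2", "dH2", "dCp1", "dCp2"),
}
BASELINE_NAMES = ("FN0", "mN", "FI0", "mI", "FU0", "mU")

MIN_POINTS = 12


@dataclass
class DenaturationCurve:
    """One unfolding curve: signal vs. denaturant concentration or temperature.

    ``x`` is urea concentration in M (mode="chemical") or absolute
    temperature in K (mode="thermal"), strictly increasing, at least 12
    points. ``meta`` carries provenance (construction, subunit concentration
    in uM, wavelengths, generator truth for synthetic curves).
    """

    x: np.ndarray
    y: np.ndarray
    mode: str = "chemical"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.mode not in ("chemical", "thermal"):
            raise InvalidInputError(f"mode must be 'chemical' or 'thermal', got {self.mode!r}")
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise InvalidInputError("x and y must be 1-D arrays of equal length")
        if len(self.x) < MIN_POINTS:
            raise InvalidInputError(
                f"curve has {len(self.x)} points; at least {MIN_POINTS} are required")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise InvalidInputError("curve contains non-finite values")
        if np.any(np.diff(self.x) <= 0):
            raise InvalidInputError("x must be strictly increasing")

    def __len__(self):
        return len(self.x)


@dataclass
class FitConfig:
    """Options controlling a fit.

    shared : names of thermodynamic parameters shared across curves in a
        global fit (None = all of them; baselines are always per-curve).
    fixed : parameter name -> value held constant (thermal fits fix
        dCp1 = dCp2 = 0 by default unless overridden).
    bounds : parameter name -> (low, high), overriding the defaults.
    multistart : number of randomized restarts around the initial guess.
    """

    shared: Optional[set] = None
    fixed: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    multistart: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.multistart < 1:
            raise InvalidInputError("multistart must be >= 1")
        for name, value in self.fixed.items():
            if name in self.bounds:
                lo, hi = self.bounds[name]
                if not (lo <= value <= hi):
                    raise InvalidInputError(
                        f"fixed value {name}={value} outside its bounds ({lo}, {hi})")


@dataclass
class FitResult:
    """Outcome of an individual or global fit."""

    thermo: object                     # ChemThermoParams | ThermalThermoParams
    baselines: list                    # one SignalBaselines per curve
    params: dict                       # flat name -> fitted value
    stderr: dict                       # flat name -> standard error (nan if unavailable)
    residuals: np.ndarray
    rss: float
    converged: bool
    n_curves: int
    mode: str
    guess_fallback: bool = False
    message: str = ""

    def require_converged(self):
        if not self.converged:
            raise FitNotConvergedError(self.message or "fit did not converge")
        return self


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    window = max(3, int(window) | 1)  # odd, >= 3
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def initial_guess(curve: DenaturationCurve) -> dict:
    """Data-driven starting values for all parameters of one curve.

    Transition midpoints come from the two largest-magnitude extrema of a
    smoothed first derivative of y(x); native/unfolded baselines from linear
    fits to the first and last 15% of points; the intermediate baseline from
    the plateau between the estimated midpoints; m / dH from the derivative
    peak width via the two-state relation (the 10-90% width of a transition
    spans ~4.4 RT of free energy). If fewer than two derivative extrema are
    found, midpoints fall back to the 33rd/66th percentiles of the x-range
    and the returned dict carries ``"_fallback": True``.
    """
    x, y = curve.x, curve.y
    n = len(x)
    ys = _smooth(y, max(5, n // 10))
    dy = np.gradient(ys, x)
    mag = np.abs(dy)

    # candidate transition centres: local maxima of |dy/dx|; a genuine
    # transition stands well above the typical derivative magnitude, which
    # filters out flat/featureless data where |dy| is near-constant
    peaks, props = find_peaks(mag, prominence=0.05 * (mag.max() - mag.min() + 1e-300))
    significant = mag.max() > 3.0 * np.median(mag) + 1e-12
    fallback = not significant or len(peaks) < 2
    if not fallback:
        best = peaks[np.argsort(mag[peaks])[-2:]]
        i1, i2 = sorted(best)
        xm1, xm2 = x[i1], x[i2]
        if xm2 - xm1 < 0.05 * (x[-1] - x[0]):
            fallback = True
    if fallback:
        xm1 = x[0] + (x[-1] - x[0]) / 3.0
        xm2 = x[0] + 2.0 * (x[-1] - x[0]) / 3.0
        i1 = int(np.searchsorted(x, xm1))
        i2 = int(np.searchsorted(x, xm2))

    # steepness from the half-height width of each derivative peak
    def peak_width(i):
        half = mag[i] / 2.0
        lo = i
        while lo > 0 and mag[lo] > half:
            lo -= 1
        hi = i
        while hi < n - 1 and mag[hi] > half:
            hi += 1
        return max(x[hi] - x[lo], 2.0 * np.mean(np.diff(x)))

    w1, w2 = peak_width(i1), peak_width(i2)

    # edge baselines from the outer 15% of points
    k = max(2, int(round(0.15 * n)))
    mN, FN0 = np.polyfit(x[:k], y[:k], 1)
    mU, FU0 = np.polyfit(x[-k:], y[-k:], 1)

    # intermediate baseline from the plateau between the midpoints
    mid = (x >= xm1 + 0.25 * (xm2 - xm1)) & (x <= xm2 - 0.25 * (xm2 - xm1))
    if mid.sum() >= 3:
        mI, FI0 = np.polyfit(x[mid], y[mid], 1)
    else:
        xc = 0.5 * (xm1 + xm2)
        mI, FI0 = 0.0, float(np.interp(xc, x, ys))

    guess = {
        "FN0": FN0, "mN": mN, "FI0": FI0, "mI": mI, "FU0": FU0, "mU": mU,
        "_fallback": fallback,
    }
    if curve.mode == "chemical":
        rt = R_KCAL * T_CHEM_DEFAULT
        guess.update(
            Um1=xm1, Um2=xm2,
            m1=float(np.clip(4.39 * rt / w1, 0.3, 15.0)),
            m2=float(np.clip(4.39 * rt / w2, 0.3, 15.0)),
        )
    else:
        guess.update(
            Tm1=xm1, Tm2=xm2,
            dH1=float(np.clip(4.39 * R_KCAL * xm1 ** 2 / w1, 20.0, 400.0)),
            dH2=float(np.clip(4.39 * R_KCAL * xm2 ** 2 / w2, 20.0, 400.0)),
            dCp1=0.0, dCp2=0.0,
        )
    return guess


def _default_bounds(mode: str, x: np.ndarray) -> dict:
    lo, hi = float(x.min()), float(x.max())
    pad = 0.1 * (hi - lo)
    bounds = {}
    if mode == "chemical":
        for name in ("Um1", "Um2"):
            bounds[name] = (max(1e-3, lo - pad), hi + pad)
        for name in ("m1", "m2"):
            bounds[name] = (1e-3, 20.0)
    else:
        for name in ("Tm1", "Tm2"):
            bounds[name] = (lo - pad, hi + pad)
        for name in ("dH1", "dH2"):
            bounds[name] = (1.0, 500.0)
        for name in ("dCp1", "dCp2"):
            bounds[name] = (0.0, 10.0)
    return bounds


def _raw_eval(mode, tv, bv, x):
    """Model surface without dataclass validation (optimizer may probe
    parameter sets that violate the physical invariants, e.g. Um2 < Um1)."""
    if mode == "chemical":
        dG1 = tv["m1"] * (tv["Um1"] - x)
        dG2 = tv["m2"] * (tv["Um2"] - x)
        T = T_CHEM_DEFAULT
    else:
        dG1 = thermal_free_energy(x, max(tv["Tm1"], 1e-3), tv["dH1"], tv["dCp1"])
        dG2 = thermal_free_energy(x, max(tv["Tm2"], 1e-3), tv["dH2"], tv["dCp2"])
        T = x
    fN, fI, fU = species_fractions(dG1, dG2, T)
    FN0, mN, FI0, mI, FU0, mU = bv
    return fN * (FN0 + mN * x) + fI * (FI0 + mI * x) + fU * (FU0 + mU * x)


def _build_params(mode, guesses, curves, config: FitConfig) -> lmfit.Parameters:
    thermo_names = THERMO_NAMES[mode]
    bounds = _default_bounds(mode, np.concatenate([c.x for c in curves]))
    bounds.update(config.bounds)
    params = lmfit.Parameters()

    # shared thermodynamic parameters, initialized from the mean of the
    # per-curve guesses (permutation-invariant)
    fixed = dict(config.fixed)
    if mode == "thermal":
        fixed.setdefault("dCp1", 0.0)
        fixed.setdefault("dCp2", 0.0)
    for name in thermo_names:
        value = float(np.mean([g[name] for g in guesses]))
        lo, hi = bounds.get(name, (-np.inf, np.inf))
        if name in fixed:
            params.add(name, value=fixed[name], vary=False)
        else:
            params.add(name, value=float(np.clip(value, lo, hi)), min=lo, max=hi)
    # keep the two transitions ordered: midpoint 2 = midpoint 1 + positive gap
    first, second = thermo_names[0], thermo_names[2]
    if params[second].vary and params[first].vary:
        gap0 = max(params[second].value - params[first].value, 1e-3)
        params.add(f"_gap_{second}", value=gap0, min=1e-6,
                   max=params[second].max - params[first].min)
        params[second].set(expr=f"{first} + _gap_{second}")

    for ci, g in enumerate(guesses):
        for name in BASELINE_NAMES:
            params.add(f"{name}_c{ci}", value=float(g[name]))
    return params


def _residual(params: lmfit.Parameters, mode, curves):
    vals = params.valuesdict()
    thermo_names = THERMO_NAMES[mode]
    tv = {k: vals[k] for k in thermo_names}
    if mode == "chemical":
        tv.setdefault("dCp1", 0.0)
    res = []
    for ci, c in enumerate(curves):
        bv = [vals[f"{name}_c{ci}"] for name in BASELINE_NAMES]
        res.append(_raw_eval(mode, tv, bv, c.x) - c.y)
    return np.concatenate(res)


def fit_global(curves: Sequence[DenaturationCurve],
               config: Optional[FitConfig] = None) -> FitResult:
    """Global fit of one or more curves with shared thermodynamics.

    The thermodynamic parameter vector is shared across all curves (unless
    restricted via ``config.shared``); baselines are always per-curve. With a
    single curve this reduces exactly to an individual fit. The best of
    ``config.multistart`` seeded restarts (the first unperturbed, the others
    perturbed by +-20%) is returned.
    """
    config = config or FitConfig()
    curves = list(curves)
    if not curves:
        raise InvalidInputError("at least one curve is required")
    modes = {c.mode for c in curves}
    if len(modes) > 1:
        raise InvalidInputError(f"curves of mixed mode cannot be fitted jointly: {modes}")
    mode = curves[0].mode

    guesses = [initial_guess(c) for c in curves]
    fallback = any(g["_fallback"] for g in guesses)
    base_params = _build_params(mode, guesses, curves, config)

    if config.shared is not None:
        unshared = set(THERMO_NAMES[mode]) - set(config.shared)
        if unshared:
            raise InvalidInputError(
                "per-curve (unshared) thermodynamic parameters are not supported; "
                f"cannot unshare {sorted(unshared)}")

    rng = np.random.default_rng(config.seed)
    best = None
    for start in range(config.multistart):
        params = base_params.copy()
        if start > 0:
            for p in params.values():
                if not p.vary or p.expr:
                    continue
                scale = abs(p.value) if p.value != 0 else 1.0
                val = p.value + rng.uniform(-0.2, 0.2) * scale
                if np.isfinite(p.min):
                    val = max(val, p.min + 1e-9 * max(abs(p.min), 1.0))
                if np.isfinite(p.max):
                    val = min(val, p.max - 1e-9 * max(abs(p.max), 1.0))
                p.set(value=val)
        try:
            out = lmfit.minimize(_residual, params, args=(mode, curves),
                                 method="leastsq", nan_policy="raise")
        except Exception:
            continue
        rss = float(np.sum(out.residual ** 2))
        if best is None or (out.success and rss < best[1]):
            if best is None or out.success:
                best = (out, rss)

    if best is None:
        return FitResult(thermo=None, baselines=[], params={}, stderr={},
                         residuals=np.array([]), rss=np.inf, converged=False,
                         n_curves=len(curves), mode=mode, guess_fallback=fallback,
                         message="all restarts failed")

    out, rss = best
    vals = out.params.valuesdict()
    thermo_names = THERMO_NAMES[mode]
    stderr = {}
    for name in thermo_names:
        p = out.params[name]
        stderr[name] = float(p.stderr) if (p.stderr is not None) else np.nan
    flat = {name: float(vals[name]) for name in thermo_names}

    baselines = []
    for ci in range(len(curves)):
        bvals = {}
        for name in BASELINE_NAMES:
            key = f"{name}_c{ci}"
            flat[key] = float(vals[key])
            p = out.params[key]
            stderr[key] = float(p.stderr) if (p.stderr is not None) else np.nan
            bvals[name] = float(vals[key])
        baselines.append(SignalBaselines(x_kind=mode, **bvals))

    if mode == "chemical":
        thermo = ChemThermoParams(Um1=flat["Um1"], m1=flat["m1"],
                                  Um2=flat["Um2"], m2=flat["m2"])
    else:
        thermo = ThermalThermoParams(Tm1=flat["Tm1"], dH1=flat["dH1"],
                                     Tm2=flat["Tm2"], dH2=flat["dH2"],
                                     dCp1=flat["dCp1"], dCp2=flat["dCp2"])
    return FitResult(thermo=thermo, baselines=baselines, params=flat,
                     stderr=stderr, residuals=np.asarray(out.residual),
                     rss=rss, converged=bool(out.success),
                     n_curves=len(curves), mode=mode,
                     guess_fallback=fallback, message=str(out.message))


def fit_individual(curve: DenaturationCurve,
                   config: Optional[FitConfig] = None) -> FitResult:
    """Fit a single curve; equivalent to a one-curve global fit."""
    return fit_global([curve], config)


def population_curve(result: FitResult, grid) -> np.ndarray:
    """Species fractions (fN, fI, fU) of a converged fit over a grid of x.

    Returns an array of shape (len(grid), 3); each row sums to 1.
    """
    result.require_converged()
    grid = np.asarray(grid, dtype=float)
    if result.mode == "chemical":
        dG1, dG2 = chem_free_energies(grid, result.thermo)
        fN, fI, fU = species_fractions(dG1, dG2, T_CHEM_DEFAULT)
    else:
        t = result.thermo
        dG1 = thermal_free_energy(grid, t.Tm1, t.dH1, t.dCp1)
        dG2 = thermal_free_energy(grid, t.Tm2, t.dH2, t.dCp2)
        fN, fI, fU = species_fractions(dG1, dG2, grid)
    return np.column_stack([fN, fI, fU])


def bootstrap_stderr(curves: Sequence[DenaturationCurve], result: FitResult,
                     config: Optional[FitConfig] = None,
                     n_boot: int = 200, seed: int = 0) -> dict:
    """Residual-bootstrap standard errors of the shared parameters.

    Refits ``n_boot`` resampled datasets built from the fitted surface plus
    residuals resampled with replacement. Slower but free of the local-
    curvature approximation.
    """
    result.require_converged()
    config = config or FitConfig(multistart=1)
    rng = np.random.default_rng(seed)
    names = THERMO_NAMES[result.mode]
    draws = {n: [] for n in names}
    res = result.residuals
    offsets = np.cumsum([0] + [len(c) for c in curves])
    for _ in range(n_boot):
        boot = []
        for ci, c in enumerate(curves):
            r = res[offsets[ci]:offsets[ci + 1]]
            yhat = c.y - r
            ynew = yhat + rng.choice(res, size=len(c), replace=True)
            boot.append(DenaturationCurve(c.x, ynew, mode=c.mode, meta=dict(c.meta)))
        fr = fit_global(boot, config)
        if fr.converged:
            for n in names:
                draws[n].append(fr.params[n])
    return {n: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
            for n, v in draws.items()}
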