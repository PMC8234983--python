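"""CSV readers/writers and run-directory bookkeeping.

All files are plain CSV with a header. The x-axis unit of an unfolding
curve is part of the file contract (column named ``urea_M`` or
``temperature_C``); ambiguous files are rejected, never guessed.
Temperatures are converted to Kelvin on load and back to Celsius on write.
Every run directory gets a YAML config snapshot, a log, machine-readable
results and the SHA-256 hashes of its inputs, so a run can be reproduced
bit-identically given its seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .curve_fitting import DenaturationCurve, FitResult
from .dsc import DSCThermogram
from .errors import CurveLoadError
from .hydrodynamics import CsDistribution
from .spectra import EmissionSpectrum

__all__ = [
    "CurveFileDialect", "RunConfig",
    "read_curve", "write_curve",
    "read_thermogram", "write_thermogram",
    "read_spectrum", "write_spectrum",
    "read_cs", "write_cs",
    "sha256_file", "write_run_snapshot", "write_report",
]

X_COLUMNS = {"urea_M": "chemical", "temperature_C": "thermal"}


@dataclass(frozen=True)
class CurveFileDialect:
    """Column contract for unfolding-curve CSVs. ``x_col`` must end with the
    unit tag (``_M`` or ``_C``); the default columns are ``urea_M`` /
    ``temperature_C`` and ``signal``."""

    x_col: Optional[str] = None     # None: accept either canonical x column
    y_col: str = "signal"


@dataclass
class RunConfig:
    """Serializable snapshot of one CLI run."""

    command: str
    options: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"command": self.command, "options": self.options,
                "inputs": self.inputs, "seed": self.seed}


def _load_csv(path, required: list) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CurveLoadError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CurveLoadError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CurveLoadError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def read_curve(path, dialect: CurveFileDialect = CurveFileDialect()) -> DenaturationCurve:
    """Load a denaturation curve, inferring the mode from the x-column name.

    Temperature files (``temperature_C``) are converted to Kelvin. The
    file's path and SHA-256 hash are retained in ``meta``.
    """
    df = _load_csv(path, [dialect.y_col])
    if dialect.x_col is not None:
        candidates = [dialect.x_col]
    else:
        candidates = [c for c in df.columns if c in X_COLUMNS]
    if len(candidates) != 1:
        raise CurveLoadError(
            f"{path}: expected exactly one x column of {sorted(X_COLUMNS)}, "
            f"found {candidates or list(df.columns)}")
    x_col = candidates[0]
    if x_col not in df.columns:
        raise CurveLoadError(f"{path}: missing column(s) ['{x_col}']")
    if x_col.endswith("_M"):
        mode = "chemical"
    elif x_col.endswith("_C"):
        mode = "thermal"
    else:
        raise CurveLoadError(f"{path}: x column {x_col!r} lacks a unit tag (_M or _C)")

    x = df[x_col].to_numpy(dtype=float)
    y = df[dialect.y_col].to_numpy(dtype=float)
    bad = ~(np.isfinite(x) & np.isfinite(y))
    if bad.any():
        rows = np.nonzero(bad)[0][:5] + 2  # 1-based + header
        raise CurveLoadError(f"{path}: non-finite values near row(s) {rows.tolist()}")
    if len(x) < 12:
        raise CurveLoadError(
            f"{path}: {len(x)} data rows; a curve needs at least 12 points")
    if np.any(np.diff(x) <= 0):
        i = int(np.nonzero(np.diff(x) <= 0)[0][0]) + 2
        raise CurveLoadError(f"{path}: x not strictly increasing at row {i}")
    if mode == "thermal":
        x = celsius_to_kelvin(x)
    meta = {"path": str(path), "sha256": sha256_file(path)}
    meta.update(_read_meta_sidecar(Path(path)))
    return DenaturationCurve(x, y, mode=mode, meta=meta)


def write_curve(curve: DenaturationCurve, path) -> Path:
    path = Path(path)
    if curve.mode == "thermal":
        df = pd.DataFrame({"temperature_C": kelvin_to_celsius(curve.x),
                           "signal": curve.y})
    else:
        df = pd.DataFrame({"urea_M": curve.x, "signal": curve.y})
    df.to_csv(path, index=False)
    _write_meta_sidecar(curve.meta, path)
    return path


def read_thermogram(path, normalized: bool = False,
                    baseline_subtracted: bool = False) -> DSCThermogram:
    """Load a DSC thermogram (columns ``temperature_C``, ``cp``); the caller
    states what processing the file has already seen."""
    df = _load_csv(path, ["temperature_C", "cp"])
    return DSCThermogram(celsius_to_kelvin(df["temperature_C"].to_numpy(dtype=float)),
                         df["cp"].to_numpy(dtype=float),
                         normalized=normalized,
                         baseline_subtracted=baseline_subtracted,
                         meta={"path": str(path), "sha256": sha256_file(path),
                               **_read_meta_sidecar(Path(path))})


def write_thermogram(tg: DSCThermogram, path) -> Path:
    path = Path(path)
    pd.DataFrame({"temperature_C": tg.T_celsius, "cp": tg.cp}).to_csv(path, index=False)
    _write_meta_sidecar(tg.meta, path)
    return path


def read_spectrum(path) -> EmissionSpectrum:
    df = _load_csv(path, ["wavelength_nm", "intensity"])
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(dtype=float),
                            df["intensity"].to_numpy(dtype=float),
                            meta={"path": str(path), "sha256": sha256_file(path),
                                  **_read_meta_sidecar(Path(path))})


def write_spectrum(sp: EmissionSpectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame({"wavelength_nm": sp.wavelength,
                  "intensity": sp.intensity}).to_csv(path, index=False)
    _write_meta_sidecar(sp.meta, path)
    return path


def read_cs(path) -> CsDistribution:
    df = _load_csv(path, ["s_svedberg", "signal"])
    return CsDistribution(df["s_svedberg"].to_numpy(dtype=float),
                          df["signal"].to_numpy(dtype=float),
                          meta={"path": str(path), "sha256": sha256_file(path),
                                **_read_meta_sidecar(Path(path))})


def write_cs(dist: CsDistribution, path) -> Path:
    path = Path(path)
    pd.DataFrame({"s_svedberg": dist.s, "signal": dist.signal}).to_csv(path, index=False)
    _write_meta_sidecar(dist.meta, path)
    return path


def _meta_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_meta_sidecar(meta: dict, path: Path) -> None:
    """Persist non-tabular metadata (e.g. generator truth) next to a CSV.

    Dataclasses are flattened to plain dicts; the sidecar is optional and
    merged back into ``meta`` on load when present."""
    if meta:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1, default=_meta_default))


def _read_meta_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_snapshot(outdir, config: RunConfig, log_lines: list) -> None:
    """Write config.yaml, run.log and input_hashes.json into a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    hashes = {p: sha256_file(p) for p in config.inputs if Path(p).exists()}
    (outdir / "input_hashes.json").write_text(json.dumps(hashes, indent=1))


def write_report(outdir, name: str, payload: dict) -> Path:
    """Write a flat machine-readable result file (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.json"
    path.write_text(json.dumps(payload, indent=1, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def fit_report(result: FitResult) -> dict:
    """Flat parameter/value/stderr report of a fit, temperatures in Celsius."""
    out = {"converged": result.converged, "n_curves": result.n_curves,
           "mode": result.mode, "rss": result.rss, "params": {}}
    for name, value in result.params.items():
        err = result.stderr.get(name)
        unit = _param_unit(name, result.mode)
        if result.mode == "thermal" and name.startswith("Tm"):
            value = kelvin_to_celsius(value)
        out["params"][name] = {"value": value,
                               "stderr": None if err is None or not np.isfinite(err) else err,
                               "unit": unit}
    return out


def _param_unit(name: str, mode: str) -> str:
    if name.startswith("Um"):
        return "M"
    if name.startswith("Tm"):
        return "degC"
    if name.startswith("dH"):
        return "kcal/mol"
    if name.startswith("dCp"):
        return "kcal/mol/K"
    if name.startswith("m") and "_" not in name:
        return "kcal/mol/M"
    return "a.u."
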