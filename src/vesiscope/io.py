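"""CSV readers and writers for instrument-style two-column exports.

All files are plain CSV with `# key=value` metadata headers followed by
a column-name row.  Temperatures are degrees Celsius at every file
boundary.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .dls import CorrelogramTrace
from .dsc import DSCTrace
from .fls import DecayHistogram
from .rheology import ViscosityCurve
from .saxs import SAXSProfile
from .units import celsius_to_kelvin

__all__ = [
    "read_correlogram",
    "write_correlogram",
    "read_saxs",
    "write_saxs",
    "read_dsc",
    "write_dsc",
    "read_viscosity",
    "write_viscosity",
    "read_decay",
    "write_decay",
    "read_calibration_pairs",
    "write_calibration_pairs",
]


class ReaderError(ValueError):
    """Malformed input file; message names the file and offending line."""


def _read_with_header(path) -> tuple[dict, pd.DataFrame]:
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if s.startswith("#"):
                if "=" in s:
                    key, _, val = s.lstrip("#").strip().partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if s:
                body_lines.append(line)
    if not body_lines:
        raise ReaderError(f"{path}: no data rows")
    try:
        df = pd.read_csv(_io.StringIO("".join(body_lines)))
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ReaderError(f"{path}: {exc}") from exc
    return meta, df


def _require(meta: dict, key: str, path) -> str:
    if key not in meta:
        raise ReaderError(f"{path}: missing required header '# {key}='")
    return meta[key]


def _header_block(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


# ---------------------------------------------------------------- DLS

def read_correlogram(path, baseline: str = "none") -> CorrelogramTrace:
    """Read `delay_s,g2_minus_1` (or `g2` with ``baseline='subtract'``)."""
    meta, df = _read_with_header(path)
    q = float(_require(meta, "q", path).split()[0])
    t_C = float(_require(meta, "temperature_C", path))
    if "g2_minus_1" in df.columns:
        y = df["g2_minus_1"].to_numpy(float)
    elif "g2" in df.columns and baseline == "subtract":
        g2 = df["g2"].to_numpy(float)
        plateau = float(np.mean(g2[-max(3, len(g2) // 20):]))
        y = g2 - plateau
    else:
        raise ReaderError(f"{path}: expected column g2_minus_1 (or g2 with baseline subtraction)")
    return CorrelogramTrace(
        df["delay_s"].to_numpy(float), y, q=q,
        temperature=celsius_to_kelvin(t_C), label=meta.get("label", Path(path).stem),
    )


def write_correlogram(path, trace: CorrelogramTrace) -> None:
    meta = {
        "q": f"{trace.q:.6e} 1/m",
        "temperature_C": f"{trace.temperature - 273.15:.4f}",
        "label": trace.label,
    }
    df = pd.DataFrame({"delay_s": trace.delays, "g2_minus_1": trace.g2_minus_1})
    with open(path, "w") as fh:
        fh.write(_header_block(meta))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------- SAXS

def read_saxs(path) -> SAXSProfile:
    meta, df = _read_with_header(path)
    sigma = df["sigma"].to_numpy(float) if "sigma" in df.columns else None
    temp = float(meta["temperature_C"]) if "temperature_C" in meta else None
    return SAXSProfile(
        df["q_invnm"].to_numpy(float), df["intensity"].to_numpy(float),
        sigma=sigma, temperature=temp, label=meta.get("label", Path(path).stem),
    )


def write_saxs(path, profile: SAXSProfile) -> None:
    meta = {"label": profile.label}
    if profile.temperature is not None:
        meta["temperature_C"] = f"{profile.temperature:.4f}"
    cols = {"q_invnm": profile.q, "intensity": profile.intensity}
    if profile.sigma is not None:
        cols["sigma"] = profile.sigma
    with open(path, "w") as fh:
        fh.write(_header_block(meta))
        pd.DataFrame(cols).to_csv(fh, index=False)


# ---------------------------------------------------------------- DSC

def read_dsc(path) -> DSCTrace:
    meta, df = _read_with_header(path)
    rate = float(_require(meta, "scan_rate_C_per_min", path))
    direction = meta.get("direction", "cooling")
    exo_sign = float(meta.get("exo_sign", "1"))
    return DSCTrace(
        df["temperature_C"].to_numpy(float),
        exo_sign * df["heat_flow_W_per_g"].to_numpy(float),
        scan_rate=rate, direction=direction,  # type: ignore[arg-type]
        label=meta.get("label", Path(path).stem),
    )


def write_dsc(path, trace: DSCTrace) -> None:
    meta = {
        "scan_rate_C_per_min": f"{trace.scan_rate:g}",
        "direction": trace.direction,
        "exo_sign": "1",
        "label": trace.label,
    }
    df = pd.DataFrame(
        {"temperature_C": trace.temperature, "heat_flow_W_per_g": trace.heat_flow}
    )
    with open(path, "w") as fh:
        fh.write(_header_block(meta))
        df.to_csv(fh, index=False)


# ------------------------------------------------------------ rheology

def read_viscosity(path) -> ViscosityCurve:
    meta, df = _read_with_header(path)
    shear = float(meta["shear_rate_per_s"]) if "shear_rate_per_s" in meta else None
    return ViscosityCurve(
        df["temperature_C"].to_numpy(float), df["eta_mPas"].to_numpy(float),
        shear_rate=shear, label=meta.get("label", Path(path).stem),
    )


def write_viscosity(path, curve: ViscosityCurve) -> None:
    meta = {"label": curve.label}
    if curve.shear_rate is not None:
        meta["shear_rate_per_s"] = f"{curve.shear_rate:g}"
    df = pd.DataFrame({"temperature_C": curve.temperature, "eta_mPas": curve.eta})
    with open(path, "w") as fh:
        fh.write(_header_block(meta))
        df.to_csv(fh, index=False)


# ----------------------------------------------------------------- FLS

def read_decay(path) -> DecayHistogram:
    meta, df = _read_with_header(path)
    irf = df["irf_counts"].to_numpy(float) if "irf_counts" in df.columns else None
    temp = float(meta["temperature_C"]) if "temperature_C" in meta else None
    return DecayHistogram(
        df["time_ns"].to_numpy(float), df["counts"].to_numpy(np.int64),
        irf=irf, temperature=temp, label=meta.get("label", Path(path).stem),
    )


def write_decay(path, hist: DecayHistogram) -> None:
    meta = {"label": hist.label}
    if hist.temperature is not None:
        meta["temperature_C"] = f"{hist.temperature:.4f}"
    cols = {"time_ns": hist.time, "counts": hist.counts.astype(np.int64)}
    if hist.irf is not None:
        cols["irf_counts"] = hist.irf
    with open(path, "w") as fh:
        fh.write(_header_block(meta))
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_calibration_pairs(path) -> list[tuple[float, float]]:
    """Read `tau_ns,eta_cP` calibration anchors."""
    _, df = _read_with_header(path)
    return [(float(t), float(e)) for t, e in zip(df["tau_ns"], df["eta_cP"])]


def write_calibration_pairs(path, pairs, meta: dict | None = None) -> None:
    df = pd.DataFrame(pairs, columns=["tau_ns", "eta_cP"])
    with open(path, "w") as fh:
        fh.write(_header_block(meta or {}))
        df.to_csv(fh, index=False)
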