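"""Study orchestration: run every analysis stage from a config file.

The config is a YAML mapping that names the per-condition instrument
files and the physical parameters (vesicle geometry, transition
temperature, analysis windows).  ``run_study`` executes

    DLS -> SAXS -> DSC -> rheology -> FLS

per condition and assembles the derived quantities (hydrodynamic
diameters, adsorbed-layer thicknesses and their molar-mass scaling,
Bragg spacings and lamellarity, transition temperatures and enthalpies,
relative-viscosity step metrics, suspension-model comparison, mean
lifetimes and bilayer microviscosities) into a JSON report plus two CSV
summary tables.  Missing stage inputs mark the stage absent with a
logged reason; they are never zero-filled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .dls import BoundLayerSeries, bound_layer_thickness, fit_correlogram, fit_layer_scaling
from .dsc import detect_transition, integrate_enthalpy, relative_enthalpy_change
from .fls import fit_biexponential, fit_forster_hoffman, microviscosity_from_lifetime
from .rheology import (
    VesicleGeometry,
    compare_models,
    face_to_face_distance,
    relative_viscosity,
    thickening_metrics,
    vesicle_volume_fraction,
)
from .saxs import detect_lamellar_peaks

log = logging.getLogger("vesiscope")

__all__ = ["run_study", "load_config"]

_REQUIRED_KEYS = {"conditions", "reference_condition"}


def load_config(config_path) -> dict:
    """Parse and validate the study config."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{config_path}: config must be a mapping")
    missing = _REQUIRED_KEYS - cfg.keys()
    if missing:
        raise ValueError(f"{config_path}: missing required keys {sorted(missing)}")
    if cfg["reference_condition"] not in cfg["conditions"]:
        raise ValueError(
            f"{config_path}: reference_condition "
            f"{cfg['reference_condition']!r} not among conditions"
        )
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_study(config_path, data_dir, out_dir=None) -> dict:
    """Execute the full analysis described by ``config_path``.

    Returns the report dict; when ``out_dir`` is given, also writes
    ``report.json``, ``table_sizes.csv`` (per-condition sizes, thermal
    and diffusion quantities) and ``table_lifetimes.csv`` (lifetimes and
    microviscosities), plus ``provenance.json``.
    """
    cfg = load_config(config_path)
    data = Path(data_dir)
    ref_name = cfg["reference_condition"]
    temps = [float(t) for t in cfg.get("temperatures_C", [35.0, 15.0])]
    provenance: list[dict] = []
    report: dict = {"conditions": {}, "derived": {}, "config_hash": _sha256(Path(config_path))}

    def record(op: str, fname: str | None, **extra) -> None:
        entry = {"operation": op, "file": fname}
        entry.update(extra)
        provenance.append(entry)

    def stage_file(name) -> Path | None:
        if name is None:
            return None
        p = data / name
        if not p.exists():
            return None
        return p

    # ------------------------------------------------------------ SAXS
    saxs_cfg = cfg.get("saxs", {})
    window = tuple(saxs_cfg.get("window", (0.5, 3.0)))
    saxs_results = {}
    for fname in saxs_cfg.get("profiles", []):
        p = stage_file(fname)
        if p is None:
            log.warning("SAXS profile %s missing; skipped", fname)
            record("detect_lamellar_peaks", fname, status="absent")
            continue
        profile = vio.read_saxs(p)
        res = detect_lamellar_peaks(profile, window)
        saxs_results[profile.label or fname] = {
            "peaks_invnm": res.peak_positions,
            "d_spacing_nm": res.d_spacing,
            "lamellarity": res.lamellarity,
        }
        record("detect_lamellar_peaks", fname, sha=_sha256(p))
    report["saxs"] = saxs_results

    # ------------------------------------------------- per-condition loop
    for cond, spec in cfg["conditions"].items():
        rec: dict = {"molar_mass_g_per_mol": spec.get("molar_mass_g_per_mol")}

        # DLS
        dls_out: dict = {}
        for fname in spec.get("dls", []) or []:
            p = stage_file(fname)
            if p is None:
                record("fit_correlogram", fname, status="absent")
                continue
            trace = vio.read_correlogram(p)
            fit = fit_correlogram(trace)
            T_C = trace.temperature - 273.15
            dls_out[f"{T_C:g}"] = {
                "D_T_m2_per_s": fit.D_T,
                "diameter_nm": 2.0 * fit.R_h * 1e9 if fit.converged else None,
                "gamma_per_s": fit.gamma,
                "converged": fit.converged,
            }
            record("fit_correlogram", fname, sha=_sha256(p), converged=fit.converged)
        if dls_out:
            rec["dls"] = dls_out
        else:
            rec["dls"] = None
            log.info("condition %s: DLS stage absent", cond)

        # DSC
        p = stage_file(spec.get("dsc"))
        if p is None:
            rec["dsc"] = None
            record("detect_transition", spec.get("dsc"), status="absent")
        else:
            trace = vio.read_dsc(p)
            tr = detect_transition(trace)
            if tr.T_c is None:
                rec["dsc"] = {"T_c_C": None, "note": "no transition detected"}
            else:
                w = 4.0 * (tr.fwhm or 1.0)
                T_asc = trace.ascending()[0]
                window_T = (
                    max(tr.T_c - w, float(T_asc[0])),
                    min(tr.T_c + w, float(T_asc[-1])),
                )
                dH, warn = integrate_enthalpy(trace, window_T)
                rec["dsc"] = {
                    "T_c_C": tr.T_c,
                    "fwhm_C": tr.fwhm,
                    "enthalpy_J_per_g": dH,
                    "window_warning": warn,
                }
            record("detect_transition", spec.get("dsc"), sha=_sha256(p))

        # rheology: relative viscosity + thickening metrics
        p = stage_file(spec.get("viscosity"))
        ref_p = stage_file(cfg.get("viscosity_reference"))
        if p is None or ref_p is None:
            rec["rheology"] = None
            record("thickening_metrics", spec.get("viscosity"), status="absent")
        else:
            sample = vio.read_viscosity(p)
            reference = vio.read_viscosity(ref_p)
            eta_r = relative_viscosity(sample, reference)
            T_m = float(cfg.get("transition_T_m_C", 23.5))
            pw = tuple(cfg.get("plateau_window", (2.0, 6.0)))
            try:
                metrics = thickening_metrics(eta_r, T_m, plateau_window=pw)
            except ValueError as exc:
                metrics = {"error": str(exc)}
            rec["rheology"] = metrics
            record("thickening_metrics", spec.get("viscosity"), sha=_sha256(p))

        # FLS: lifetimes and microviscosity at each temperature
        fls_out: dict = {}
        for fname in spec.get("decay", []) or []:
            p = stage_file(fname)
            if p is None:
                record("fit_biexponential", fname, status="absent")
                continue
            hist = vio.read_decay(p)
            fit = fit_biexponential(hist)
            key = f"{hist.temperature:g}" if hist.temperature is not None else fname
            fls_out[key] = {
                "tau_avg_ns": fit.tau_avg,
                "lifetimes_ns": list(fit.lifetimes),
                "amplitudes": list(fit.amplitudes),
                "chi2_reduced": fit.chi2_reduced,
                "collapsed_single": fit.collapsed_single,
            }
            record("fit_biexponential", fname, sha=_sha256(p))
        rec["fls"] = fls_out or None

        report["conditions"][cond] = rec

    # --------------------------------------------- cross-condition steps
    ref = report["conditions"].get(ref_name, {})
    ref_dls = ref.get("dls") or {}
    T_hot = f"{temps[0]:g}"
    d_neat = (ref_dls.get(T_hot) or {}).get("diameter_nm")

    # adsorbed-layer thickness and scaling
    if d_neat:
        masses, deltas = [], []
        for cond, rec in report["conditions"].items():
            mw = rec.get("molar_mass_g_per_mol")
            d_mix = ((rec.get("dls") or {}).get(T_hot) or {}).get("diameter_nm")
            if cond == ref_name or mw is None or d_mix is None:
                continue
            delta = bound_layer_thickness(d_mix, d_neat)
            rec["delta_nm"] = delta
            masses.append(mw)
            deltas.append(delta)
        if len(masses) >= 2 and sum(d > 0 for d in deltas) >= 2:
            series = BoundLayerSeries(
                np.array(masses), np.array(deltas), baseline_diameter=d_neat
            )
            slope, logc = fit_layer_scaling(series)
            report["derived"]["layer_scaling"] = {
                "slope": slope,
                "log10_prefactor": logc,
            }
            record("fit_layer_scaling", None, n_pairs=len(masses))

    # enthalpy decrease relative to the bare vesicles
    dH_neat = (ref.get("dsc") or {}).get("enthalpy_J_per_g")
    if dH_neat:
        for cond, rec in report["conditions"].items():
            dH = (rec.get("dsc") or {}).get("enthalpy_J_per_g")
            if cond != ref_name and dH is not None:
                rec["enthalpy_decrease_percent"] = relative_enthalpy_change(
                    dH_neat, dH
                )

    # geometry-based volume fraction and interparticle distances
    if "geometry" in cfg:
        geom = VesicleGeometry(**cfg["geometry"])
        phi, n_lipid, n_density = vesicle_volume_fraction(geom)
        L, contact = face_to_face_distance(phi, geom.outer_diameter)
        report["derived"]["suspension"] = {
            "phi": phi,
            "lipids_per_vesicle": n_lipid,
            "vesicle_number_density_per_L": n_density,
            "face_to_face_distance_nm": L,
            "contact": contact,
        }
        record("vesicle_volume_fraction", None, phi=phi)

    # suspension-model comparison when observations are configured
    if "model_observations" in cfg:
        obs = cfg["model_observations"]
        cmp_res = compare_models(
            np.array(obs["phi"], dtype=float), np.array(obs["eta_r"], dtype=float)
        )
        report["derived"]["model_comparison"] = {
            "einstein_rms": cmp_res["einstein_rms"],
            "kd_rms": cmp_res["kd_rms"],
            "excluded_phi": cmp_res["excluded"],
        }
        record("compare_models", None)

    # Forster-Hoffmann calibration and microviscosities
    calib_files = cfg.get("calibration", {})
    calibrations = {}
    for T_key, fname in calib_files.items():
        p = stage_file(fname)
        if p is None:
            record("fit_forster_hoffman", fname, status="absent")
            continue
        pairs = vio.read_calibration_pairs(p)
        cal = fit_forster_hoffman(pairs, temperature=float(T_key))
        calibrations[f"{float(T_key):g}"] = cal
        record("fit_forster_hoffman", fname, sha=_sha256(p), A=cal.intercept_A, B=cal.slope_B)
    report["derived"]["calibrations"] = {
        k: {"A": c.intercept_A, "B": c.slope_B} for k, c in calibrations.items()
    }
    for cond, rec in report["conditions"].items():
        for T_key, fit in (rec.get("fls") or {}).items():
            cal = calibrations.get(T_key)
            if cal is not None:
                fit["microviscosity_cP"] = microviscosity_from_lifetime(
                    fit["tau_avg_ns"], cal
                )

    report["provenance"] = provenance
    if out_dir is not None:
        _write_outputs(report, temps, Path(out_dir))
    return report


def _write_outputs(report: dict, temps: list[float], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    with open(out / "provenance.json", "w") as fh:
        json.dump(report["provenance"], fh, indent=2)

    T_hot, T_cold = (f"{t:g}" for t in temps[:2])
    rows = []
    for cond, rec in report["conditions"].items():
        dls = rec.get("dls") or {}
        dsc = rec.get("dsc") or {}
        rows.append(
            {
                "condition": cond,
                "H_D_nm": (dls.get(T_hot) or {}).get("diameter_nm"),
                "T_c_C": dsc.get("T_c_C"),
                "enthalpy_J_per_g": dsc.get("enthalpy_J_per_g"),
                f"D_T_m2_per_s_{T_hot}C": (dls.get(T_hot) or {}).get("D_T_m2_per_s"),
                f"D_T_m2_per_s_{T_cold}C": (dls.get(T_cold) or {}).get("D_T_m2_per_s"),
                "delta_nm": rec.get("delta_nm"),
            }
        )
    pd.DataFrame(rows).to_csv(out / "table_sizes.csv", index=False)

    rows = []
    for cond, rec in report["conditions"].items():
        fls = rec.get("fls") or {}
        rows.append(
            {
                "condition": cond,
                f"tau_avg_ns_{T_hot}C": (fls.get(T_hot) or {}).get("tau_avg_ns"),
                f"microviscosity_cP_{T_hot}C": (fls.get(T_hot) or {}).get("microviscosity_cP"),
                f"tau_avg_ns_{T_cold}C": (fls.get(T_cold) or {}).get("tau_avg_ns"),
                f"microviscosity_cP_{T_cold}C": (fls.get(T_cold) or {}).get("microviscosity_cP"),
            }
        )
    pd.DataFrame(rows).to_csv(out / "table_lifetimes.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
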