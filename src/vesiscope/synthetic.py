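"""Forward models: instrument-like synthetic datasets with ground truth.

Each generator is the forward model of the corresponding analysis stage
(single-exponential correlograms, power-law SAXS profiles with optional
lamellar peaks, Gaussian DSC exotherms, logistic viscosity steps,
multi-exponential photon-count decays with Poisson noise).  Every
generator takes an explicit integer seed and uses one private
``numpy.random.Generator``; identical seeds give identical output.

``gen_study`` composes the generators into a full study bundle — one
bare-vesicle condition plus one condition per polymer molar mass,
measured at two temperatures — and writes a JSON manifest of the
generating ("ground truth") parameters next to the data files.

Default parameters emulate a suspension of ~120 nm extruded
phospholipid vesicles (gel-fluid transition near 23 degC) mixed with
poly(ethylene glycol) of 1.5-400 kg/mol, probed by DLS, SAXS, DSC,
steady-shear rheology and TCSPC lifetime measurements of a
membrane-embedded dye at 15 and 35 degC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .dls import CorrelogramTrace, compute_wave_vector, stokes_einstein
from .dsc import DSCTrace
from .fls import DecayHistogram
from .rheology import ViscosityCurve, VesicleGeometry
from .saxs import SAXSProfile
from .solvents import water_viscosity
from .units import celsius_to_kelvin

__all__ = [
    "StudyConfig",
    "gen_correlogram",
    "gen_saxs_profile",
    "gen_dsc_trace",
    "gen_viscosity_curve",
    "gen_decay_histogram",
    "gen_study",
]


def gen_correlogram(
    D: float,
    q: float,
    amplitude: float = 0.9,
    noise_sd: float = 0.01,
    n_points: int = 200,
    seed: int = 0,
    temperature_C: float = 35.0,
    label: str = "",
) -> CorrelogramTrace:
    """Single-exponential DLS correlogram, Gamma = D q^2.

    Delays are log-spaced over 0.01/Gamma .. 10/Gamma; noise is
    multiplicative Gaussian with fractional standard deviation
    ``noise_sd``.
    """
    if D <= 0 or q <= 0 or amplitude <= 0 or n_points < 20:
        raise ValueError("D, q, amplitude must be positive; n_points >= 20")
    rng = np.random.default_rng(seed)
    gamma = D * q * q
    delays = np.logspace(np.log10(0.01 / gamma), np.log10(10.0 / gamma), n_points)
    clean = amplitude * np.exp(-2.0 * gamma * delays)
    noisy = clean * (1.0 + noise_sd * rng.standard_normal(n_points))
    return CorrelogramTrace(
        delays, noisy, q=q, temperature=celsius_to_kelvin(temperature_C), label=label
    )


def gen_saxs_profile(
    d_spacing: float = 6.28,
    lamellar_weight: float = 0.0,
    powerlaw_exponent: float = 2.5,
    noise_fraction: float = 0.01,
    q_grid: np.ndarray | None = None,
    seed: int = 0,
    peak_width: float = 0.04,
    second_order_ratio: float = 0.4,
    prefactor: float = 1.0,
    temperature_C: float | None = None,
    label: str = "",
) -> SAXSProfile:
    """Power-law profile with optional lamellar peaks at 2pi/d and 4pi/d.

    I(q) = c q^-p + w [G(q; q*, width) + r G(q; 2q*, width)], with
    Gaussian peaks and noise proportional to sqrt(I).
    """
    if d_spacing <= 0:
        raise ValueError("d_spacing must be positive")
    rng = np.random.default_rng(seed)
    q = (
        np.linspace(0.2, 3.0, 400)
        if q_grid is None
        else np.asarray(q_grid, dtype=float)
    )
    q1 = 2.0 * np.pi / d_spacing
    I = prefactor * q ** (-powerlaw_exponent)
    if lamellar_weight > 0:
        for center, amp in ((q1, 1.0), (2.0 * q1, second_order_ratio)):
            I = I + lamellar_weight * amp * np.exp(
                -0.5 * ((q - center) / peak_width) ** 2
            )
    noisy = I + noise_fraction * np.sqrt(I) * rng.standard_normal(len(q))
    noisy = np.maximum(noisy, 1e-12 * np.max(I))
    return SAXSProfile(q, noisy, temperature=temperature_C, label=label)


def gen_dsc_trace(
    T_c: float = 22.84,
    fwhm: float = 1.2,
    enthalpy: float = 0.335,
    scan_rate: float = 2.0,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    T_range: tuple[float, float] = (5.0, 40.0),
    n_points: int = 701,
    direction: str = "cooling",
    label: str = "",
) -> DSCTrace:
    """Gaussian exotherm of given specific enthalpy on a linear baseline.

    The peak integrates to ``enthalpy * beta`` in heat-flow units
    (W/g over degC), with beta the scan rate in degC/s, so that
    integrating the trace back recovers ``enthalpy`` in J/g.
    """
    if enthalpy < 0:
        raise ValueError("enthalpy must be >= 0")
    rng = np.random.default_rng(seed)
    T = np.linspace(*T_range, n_points)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    beta = scan_rate / 60.0  # degC/s
    area = enthalpy * beta  # target integral of the peak over T
    peak = (
        area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * ((T - T_c) / sigma) ** 2)
        if enthalpy > 0
        else np.zeros_like(T)
    )
    a, b = baseline
    hf = peak + a + b * T + noise_sd * rng.standard_normal(n_points)
    if direction == "cooling":
        T, hf = T[::-1], hf[::-1]
    return DSCTrace(T, hf, scan_rate=scan_rate, direction=direction, label=label)


def gen_viscosity_curve(
    solvent_model: str = "water",
    eta_r_base: float = 1.2,
    jump_fraction: float = 0.1,
    T_m: float = 23.5,
    width: float = 2.0,
    T_range: tuple[float, float] = (10.0, 40.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 301,
    shear_rate: float = 30.0,
    label: str = "",
) -> ViscosityCurve:
    """Temperature-ramped viscosity with a logistic step at T_m.

    eta(T) = eta_solvent(T) * eta_r_base * (1 + jump * logistic((T-T_m)/(width/6)))
    with multiplicative Gaussian noise.  ``solvent_model='none'`` uses a
    unit solvent (the curve is then already a relative viscosity).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rng = np.random.default_rng(seed)
    T = np.linspace(*T_range, n_points)
    if solvent_model == "water":
        eta_s = water_viscosity(T + 273.15) * 1e3  # mPa s
    elif solvent_model == "none":
        eta_s = np.ones_like(T)
    else:
        raise ValueError(f"unknown solvent model {solvent_model!r}")
    step = 1.0 / (1.0 + np.exp(-(T - T_m) / (width / 6.0)))
    eta = eta_s * eta_r_base * (1.0 + jump_fraction * step)
    eta = eta * (1.0 + noise_sd * rng.standard_normal(n_points))
    return ViscosityCurve(T, eta, shear_rate=shear_rate, label=label)


def gen_decay_histogram(
    amplitudes,
    lifetimes,
    total_counts: float = 1e6,
    bin_width: float = 0.05,
    n_bins: int = 2000,
    irf_fwhm: float | None = None,
    seed: int = 0,
    background_fraction: float = 0.0,
    temperature_C: float | None = None,
    label: str = "",
) -> DecayHistogram:
    """Multi-exponential TCSPC histogram with Poisson counting noise.

    Expected per-bin counts follow sum(a_i exp(-t/tau_i)) (optionally
    convolved with a Gaussian IRF of the given FWHM), scaled so the
    expected total equals ``total_counts``; observed counts are Poisson
    draws (variance = mean).
    """
    a = np.asarray(amplitudes, dtype=float)
    taus = np.asarray(lifetimes, dtype=float)
    if total_counts < 1000:
        raise ValueError("need total_counts >= 1000")
    if np.any(a < 0) or np.any(taus <= 0):
        raise ValueError("amplitudes >= 0, lifetimes > 0 required")
    rng = np.random.default_rng(seed)
    t = np.arange(n_bins) * bin_width
    model = np.zeros(n_bins)
    for ai, ti in zip(a, taus):
        model += ai * np.exp(-t / ti)
    irf = None
    if irf_fwhm is not None:
        s = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        tk = np.arange(0, 6 * s + bin_width, bin_width)
        irf = np.exp(-0.5 * ((tk - 3 * s) / s) ** 2)
        model = np.convolve(model, irf / irf.sum(), mode="full")[:n_bins]
    expected = model / model.sum() * total_counts * (1.0 - background_fraction)
    expected = expected + background_fraction * total_counts / n_bins
    counts = rng.poisson(expected)
    irf_full = None
    if irf is not None:
        irf_full = np.zeros(n_bins)
        irf_full[: len(irf)] = irf
    return DecayHistogram(
        t, counts, irf=irf_full, temperature=temperature_C, label=label
    )


# ----------------------------------------------------------- full study


@dataclass
class StudyConfig:
    """Parameters of the emulated vesicle/polymer study.

    Defaults mirror the measured study conditions: a bare vesicle
    hydrodynamic diameter of 119.9 nm, polymer molar masses of 1.5, 20,
    100 and 400 kg/mol, adsorbed-layer scaling delta = c Mw^0.58
    anchored at delta(400 kg/mol) = 18.9 nm, a gel transition at
    22.84 degC with specific enthalpy 0.335 J/g (per gram of solution),
    and rotor lifetimes/calibrations that reproduce the measured
    lifetime tables at 15 and 35 degC.
    """

    seed: int = 0
    vesicle: VesicleGeometry = field(
        default_factory=lambda: VesicleGeometry(
            outer_diameter=119.9,
            bilayer_thickness=4.4,
            area_per_lipid=0.60,
            lipid_molar_mass=678.0,
            lipid_mass_concentration=17.0,
        )
    )
    polymer_molar_masses: tuple[float, ...] = (1.5e3, 2.0e4, 1.0e5, 4.0e5)
    # delta(Mw) = prefactor * Mw^exponent, nm with Mw in g/mol
    layer_scaling: tuple[float, float] = (0.010637, 0.58)
    # (T_m degC, transition width degC, relative-viscosity jump fraction)
    transition: tuple[float, float, float] = (22.84, 2.0, 0.10)
    dsc_enthalpy: float = 0.335  # J/g of solution
    dsc_fwhm: float = 1.2  # degC
    scan_rate: float = 2.0  # degC/min
    d_spacing: dict = field(default_factory=lambda: {"fluid": 6.28, "gel": 6.82})
    temperatures_C: tuple[float, float] = (35.0, 15.0)
    # measured mean rotor lifetimes (ns) per condition at (35, 15) degC
    lifetimes_ns: dict = field(
        default_factory=lambda: {
            "neat": (24.01, 28.91),
            "peg_1.5kDa": (20.61, 27.38),
            "peg_20kDa": (21.43, 27.59),
            "peg_100kDa": (22.72, 28.42),
            "peg_400kDa": (23.91, 28.74),
        }
    )
    # Forster-Hoffmann ln tau = A + B ln eta, per temperature
    calibration_truth: dict = field(
        default_factory=lambda: {
            35.0: (3.024881, 0.045729),
            15.0: (3.292219, 0.014501),
        }
    )
    # instrument noise (fractions unless noted)
    noise: dict = field(
        default_factory=lambda: {
            "dls": 0.01,
            "saxs": 0.01,
            "dsc_W_per_g": 2e-5,
            "viscosity": 0.003,
            "tcspc_counts": 1e6,
        }
    )
    # DLS optics
    wavelength_m: float = 633e-9
    scattering_angle_deg: float = 173.0
    refractive_index: float = 1.33

    def condition_names(self) -> list[str]:
        names = ["neat"]
        for mw in self.polymer_molar_masses:
            names.append(f"peg_{mw / 1e3:g}kDa")
        return names

    def delta_nm(self, molar_mass: float) -> float:
        c, nu = self.layer_scaling
        return c * molar_mass**nu

    def diameter_nm(self, condition: str) -> float:
        if condition == "neat":
            return self.vesicle.outer_diameter
        mw = float(condition.removeprefix("peg_").removesuffix("kDa")) * 1e3
        return self.vesicle.outer_diameter + 2.0 * self.delta_nm(mw)


def _subseed(seed: int, *tags: str) -> int:
    """Stable per-file child seed below 2^31."""
    h = np.uint64(seed)
    for tag in tags:
        for ch in tag.encode():
            h = np.uint64((int(h) * 1000003 + ch) % (2**31 - 1))
    return int(h)


def gen_study(config: StudyConfig, out_dir) -> dict:
    """Write a full synthetic study bundle plus a ground-truth manifest.

    One file per condition and instrument: DLS correlograms and TCSPC
    decays at both temperatures, one DSC cooling trace and one
    temperature-ramped viscosity curve per condition (plus the water
    reference), SAXS profiles for the unilamellar conditions and one
    multilamellar ("unextruded") reference, and the lifetime-viscosity
    calibration anchors per temperature.  Returns the manifest dict,
    also written to ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    q = compute_wave_vector(
        cfg.wavelength_m, cfg.refractive_index, cfg.scattering_angle_deg
    )
    T_m, trans_width, base_jump = cfg.transition
    manifest: dict = {
        "seed": cfg.seed,
        "q_1_per_m": q,
        "vesicle": asdict(cfg.vesicle),
        "layer_scaling": list(cfg.layer_scaling),
        "transition": list(cfg.transition),
        "d_spacing": dict(cfg.d_spacing),
        "calibration_truth": {str(k): list(v) for k, v in cfg.calibration_truth.items()},
        "conditions": {},
        "files": {},
    }

    # SAXS: multilamellar unextruded reference + one unilamellar profile
    saxs_ml = gen_saxs_profile(
        d_spacing=cfg.d_spacing["fluid"], lamellar_weight=0.5,
        noise_fraction=cfg.noise["saxs"], seed=_subseed(cfg.seed, "saxs", "ml"),
        label="unextruded",
    )
    vio.write_saxs(out / "saxs_unextruded.csv", saxs_ml)
    saxs_ul = gen_saxs_profile(
        d_spacing=cfg.d_spacing["fluid"], lamellar_weight=0.0,
        noise_fraction=cfg.noise["saxs"], seed=_subseed(cfg.seed, "saxs", "ul"),
        label="extruded_100nm",
    )
    vio.write_saxs(out / "saxs_extruded.csv", saxs_ul)
    manifest["files"]["saxs"] = ["saxs_unextruded.csv", "saxs_extruded.csv"]

    # calibration anchors per temperature: points on the true FH line
    eta_grid = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 150.0])
    for T_C, (A, B) in cfg.calibration_truth.items():
        taus = np.exp(A + B * np.log(eta_grid))
        fname = f"calibration_{T_C:g}C.csv"
        vio.write_calibration_pairs(
            out / fname, list(zip(taus, eta_grid)), meta={"temperature_C": f"{T_C:g}"}
        )
        manifest["files"].setdefault("calibration", []).append(fname)

    # water reference viscosity curve
    water = gen_viscosity_curve(
        solvent_model="water", eta_r_base=1.0, jump_fraction=0.0, T_m=T_m,
        width=trans_width, noise_sd=0.0, seed=_subseed(cfg.seed, "visc", "water"),
        label="water",
    )
    vio.write_viscosity(out / "viscosity_water.csv", water)
    manifest["files"]["viscosity_reference"] = "viscosity_water.csv"

    for cond in cfg.condition_names():
        diameter = cfg.diameter_nm(cond)
        rec: dict = {"diameter_nm": diameter}
        if cond != "neat":
            mw = float(cond.removeprefix("peg_").removesuffix("kDa")) * 1e3
            rec["molar_mass_g_per_mol"] = mw
            rec["delta_nm"] = cfg.delta_nm(mw)
        files: dict = {}

        # DLS at both temperatures
        rec["D_T_m2_per_s"] = {}
        for T_C in cfg.temperatures_C:
            T_K = celsius_to_kelvin(T_C)
            D = stokes_einstein(
                diameter / 2.0 * 1e-9, T_K, water_viscosity(T_K), direction="R->D"
            )
            rec["D_T_m2_per_s"][f"{T_C:g}"] = D
            trace = gen_correlogram(
                D, q, noise_sd=cfg.noise["dls"],
                seed=_subseed(cfg.seed, "dls", cond, f"{T_C:g}"),
                temperature_C=T_C, label=f"{cond}_{T_C:g}C",
            )
            fname = f"dls_{cond}_{T_C:g}C.csv"
            vio.write_correlogram(out / fname, trace)
            files.setdefault("dls", []).append(fname)

        # DSC cooling trace
        dsc = gen_dsc_trace(
            T_c=T_m, fwhm=cfg.dsc_fwhm, enthalpy=cfg.dsc_enthalpy,
            scan_rate=cfg.scan_rate, noise_sd=cfg.noise["dsc_W_per_g"],
            seed=_subseed(cfg.seed, "dsc", cond), label=cond,
        )
        fname = f"dsc_{cond}.csv"
        vio.write_dsc(out / fname, dsc)
        files["dsc"] = fname
        rec["T_c_C"] = T_m
        rec["enthalpy_J_per_g"] = cfg.dsc_enthalpy

        # viscosity ramp (larger adsorbed layers amplify the step)
        jump = base_jump * (diameter / cfg.vesicle.outer_diameter) ** 3
        visc = gen_viscosity_curve(
            solvent_model="water", eta_r_base=1.2, jump_fraction=jump, T_m=T_m,
            width=trans_width, noise_sd=cfg.noise["viscosity"],
            seed=_subseed(cfg.seed, "visc", cond), label=cond,
        )
        fname = f"viscosity_{cond}.csv"
        vio.write_viscosity(out / fname, visc)
        files["viscosity"] = fname
        rec["eta_r_jump_fraction"] = jump

        # TCSPC decays at both temperatures (single-component rotor decay)
        rec["tau_avg_ns"] = {}
        rec["microviscosity_cP"] = {}
        for T_C, tau in zip(cfg.temperatures_C, cfg.lifetimes_ns[cond]):
            hist = gen_decay_histogram(
                [1.0], [tau], total_counts=cfg.noise["tcspc_counts"],
                seed=_subseed(cfg.seed, "fls", cond, f"{T_C:g}"),
                temperature_C=T_C, label=f"{cond}_{T_C:g}C",
            )
            fname = f"decay_{cond}_{T_C:g}C.csv"
            vio.write_decay(out / fname, hist)
            files.setdefault("decay", []).append(fname)
            rec["tau_avg_ns"][f"{T_C:g}"] = tau
            A, B = cfg.calibration_truth[T_C]
            rec["microviscosity_cP"][f"{T_C:g}"] = float(
                np.exp((np.log(tau) - A) / B)
            )

        manifest["conditions"][cond] = rec
        manifest["files"][cond] = files

    # pipeline config describing the bundle, ready for run_study
    study_cfg = {
        "reference_condition": "neat",
        "temperatures_C": [float(t) for t in cfg.temperatures_C],
        "transition_T_m_C": float(T_m),
        "plateau_window": [2.0, 6.0],
        "geometry": asdict(cfg.vesicle),
        "viscosity_reference": "viscosity_water.csv",
        "saxs": {"window": [0.5, 3.0], "profiles": manifest["files"]["saxs"]},
        "calibration": {
            f"{T_C:g}": f"calibration_{T_C:g}C.csv" for T_C in cfg.calibration_truth
        },
        "conditions": {
            cond: {
                "molar_mass_g_per_mol": manifest["conditions"][cond].get(
                    "molar_mass_g_per_mol"
                ),
                "dls": manifest["files"][cond]["dls"],
                "dsc": manifest["files"][cond]["dsc"],
                "viscosity": manifest["files"][cond]["viscosity"],
                "decay": manifest["files"][cond]["decay"],
            }
            for cond in cfg.condition_names()
        },
    }
    with open(out / "study.yaml", "w") as fh:
        yaml.safe_dump(study_cfg, fh, sort_keys=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
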