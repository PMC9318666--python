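"""Suspension rheology of vesicle solutions.

Vesicles at volume fraction phi raise the solution viscosity over the
solvent.  Two parameter-free hard-sphere references are used:

* Einstein (dilute rigid spheres):      eta_r = 1 + 2.5 phi
* Krieger-Dougherty (concentrated):     eta_r = (1 - phi/phi_max)^(-A phi_max)
  with A = 2.7 and phi_max = 0.71 for submicron spheres.

The vesicle volume fraction (counting the enclosed water) follows from
bilayer geometry: the lipids in a shell of outer radius R_out and inner
radius R_in = R_out - t cover area 4 pi (R_out^2 + R_in^2) at a_L per
lipid, which fixes the lipids per vesicle, the vesicle number density at
a given lipid mass concentration, and hence phi.

Near the gel-fluid transition the relative viscosity of vesicle
suspensions shows a step ("thermal thickening"); ``thickening_metrics``
quantifies its magnitude and width from plateau medians on either side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import AVOGADRO

__all__ = [
    "ViscosityCurve",
    "VesicleGeometry",
    "SuspensionPrediction",
    "relative_viscosity",
    "einstein_model",
    "krieger_dougherty",
    "vesicle_volume_fraction",
    "face_to_face_distance",
    "bound_chain_gap",
    "thickening_metrics",
    "compare_models",
]

KD_A_DEFAULT = 2.7
KD_PHI_MAX_DEFAULT = 0.71


@dataclass
class ViscosityCurve:
    temperature: np.ndarray  # degC, monotone
    eta: np.ndarray  # mPa s (or dimensionless for relative curves)
    shear_rate: float | None = None  # 1/s
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.temperature.shape != self.eta.shape:
            raise ValueError("temperature and eta must be equal length")
        d = np.diff(self.temperature)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("temperatures must be monotone")
        if np.any(self.eta <= 0):
            raise ValueError("viscosities must be positive")


@dataclass
class VesicleGeometry:
    """Bilayer/vesicle geometry and composition for volume-fraction work.

    Lengths in nm, area per lipid in nm^2, molar mass in g/mol, lipid
    mass concentration in g/L.
    """

    outer_diameter: float
    bilayer_thickness: float
    area_per_lipid: float
    lipid_molar_mass: float
    lipid_mass_concentration: float

    def __post_init__(self) -> None:
        vals = (
            self.outer_diameter,
            self.bilayer_thickness,
            self.area_per_lipid,
            self.lipid_molar_mass,
            self.lipid_mass_concentration,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry fields must be positive")
        if self.outer_diameter <= 2 * self.bilayer_thickness:
            raise ValueError("outer diameter must exceed twice the bilayer thickness")


@dataclass
class SuspensionPrediction:
    phi: float
    eta_r_einstein: float
    eta_r_kd: float
    A_kd: float = KD_A_DEFAULT
    phi_max: float = KD_PHI_MAX_DEFAULT


def relative_viscosity(
    sample: ViscosityCurve, reference: ViscosityCurve
) -> ViscosityCurve:
    """Pointwise eta_sample / eta_reference on the sample's temperatures.

    The reference is linearly interpolated onto the sample grid;
    temperatures outside the overlap are dropped.
    """
    Ts, es = sample.temperature, sample.eta
    Tr, er = reference.temperature, reference.eta
    if Tr[0] > Tr[-1]:
        Tr, er = Tr[::-1], er[::-1]
    lo, hi = max(min(Ts), Tr[0]), min(max(Ts), Tr[-1])
    mask = (Ts >= lo) & (Ts <= hi)
    if mask.sum() == 0:
        raise ValueError("sample and reference temperature ranges do not overlap")
    ref_on_sample = np.interp(Ts[mask], Tr, er)
    return ViscosityCurve(
        Ts[mask], es[mask] / ref_on_sample, sample.shear_rate,
        label=f"{sample.label}/[{reference.label}]",
    )


def einstein_model(phi: float | np.ndarray) -> float | np.ndarray:
    """Dilute hard-sphere relative viscosity, 1 + 2.5 phi."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("phi must lie in [0, 1)")
    out = 1.0 + 2.5 * phi
    return float(out) if out.ndim == 0 else out


def krieger_dougherty(
    phi: float | np.ndarray,
    A: float = KD_A_DEFAULT,
    phi_max: float = KD_PHI_MAX_DEFAULT,
) -> float | np.ndarray:
    """Krieger-Dougherty relative viscosity (1 - phi/phi_max)^(-A phi_max)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= phi_max):
        raise ValueError(f"phi must lie in [0, phi_max={phi_max})")
    out = (1.0 - phi / phi_max) ** (-A * phi_max)
    return float(out) if out.ndim == 0 else out


def vesicle_volume_fraction(
    geometry: VesicleGeometry,
) -> tuple[float, float, float]:
    """Vesicle volume fraction (enclosed water included) from geometry.

    Returns ``(phi, lipids_per_vesicle, vesicle_number_density)`` with
    the number density in 1/L.
    """
    R_out = geometry.outer_diameter / 2.0  # nm
    R_in = R_out - geometry.bilayer_thickness
    if R_in <= 0:
        raise ValueError("inner radius must be positive")
    n_lipid = 4.0 * np.pi * (R_out**2 + R_in**2) / geometry.area_per_lipid
    mass_per_vesicle = n_lipid * geometry.lipid_molar_mass / AVOGADRO  # g
    number_density = geometry.lipid_mass_concentration / mass_per_vesicle  # 1/L
    v_vesicle_nm3 = (4.0 / 3.0) * np.pi * R_out**3
    # 1 L = 1e24 nm^3
    phi = number_density * v_vesicle_nm3 / 1e24
    return float(phi), float(n_lipid), float(number_density)


def face_to_face_distance(phi: float, diameter: float) -> tuple[float, bool]:
    """Mean face-to-face gap L = d [(2/(pi phi))^(1/3) - 1] for random spheres.

    Returns ``(L_nm, contact)``; at phi >= 2/pi the spheres touch on
    average and L is clamped to 0 with ``contact=True``.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if phi >= 2.0 / np.pi:
        return 0.0, True
    return float(diameter * ((2.0 / (np.pi * phi)) ** (1.0 / 3.0) - 1.0)), False


def bound_chain_gap(L: float, layer_extent_2Rg: float) -> tuple[float, bool]:
    """Solvent gap between bound polymer layers on neighboring vesicles.

    ``L`` is the face-to-face bilayer distance and ``layer_extent_2Rg``
    the extent of one bound layer (about 2 R_g for Gaussian coils).
    Returns ``(gap_nm, overlap)``; a negative gap means the layers
    interpenetrate.
    """
    if L < 0 or layer_extent_2Rg < 0:
        raise ValueError("distances must be non-negative")
    gap = L - 2.0 * layer_extent_2Rg
    return float(gap), bool(gap < 0)


def thickening_metrics(
    eta_r_curve: ViscosityCurve,
    T_m: float,
    plateau_window: tuple[float, float] = (2.0, 6.0),
) -> dict:
    """Quantify a viscosity step at the gel-fluid transition.

    Plateaus are medians of eta_r over ``[T_m + w0, T_m + w1]`` above and
    the mirror window below the transition.  The jump is the
    plateau-to-plateau change in percent of the lower plateau; the width
    is the temperature span over which the step rises from 5% to 95% of
    its height, read off a logistic fitted to the transition region
    (robust to point noise); plateau slopes come from least squares on
    each window.

    Returns a dict with keys ``jump_percent``, ``transition_width_C``
    (None for a flat curve), ``slope_below``, ``slope_above``, and
    ``peak_jump_percent`` (maximum excursion above the lower plateau,
    which can exceed the plateau jump when the transition overshoots).
    """
    T, er = eta_r_curve.temperature, eta_r_curve.eta
    if T[0] > T[-1]:
        T, er = T[::-1], er[::-1]
    w0, w1 = plateau_window
    if T[0] > T_m - w1 or T[-1] < T_m + w1:
        raise ValueError("curve must span the plateau windows around T_m")
    below = (T >= T_m - w1) & (T <= T_m - w0)
    above = (T >= T_m + w0) & (T <= T_m + w1)
    if below.sum() < 3 or above.sum() < 3:
        raise ValueError("plateau windows contain too few points")
    p_lo = float(np.median(er[below]))
    p_hi = float(np.median(er[above]))
    jump = 100.0 * (p_hi - p_lo) / p_lo
    peak_jump = 100.0 * (float(np.max(er[(T >= T_m - w1) & (T <= T_m + w1)])) - p_lo) / p_lo
    slope_below = float(np.polyfit(T[below], er[below], 1)[0])
    slope_above = float(np.polyfit(T[above], er[above], 1)[0])

    width = None
    if abs(p_hi - p_lo) > 1e-9 * max(abs(p_lo), 1.0):
        mid = (T >= T_m - w1) & (T <= T_m + w1)
        width = _logistic_width(T[mid], er[mid], p_lo, p_hi, T_m)
    return {
        "jump_percent": jump,
        "peak_jump_percent": peak_jump,
        "transition_width_C": width,
        "slope_below": slope_below,
        "slope_above": slope_above,
    }


def _logistic_width(
    T: np.ndarray, er: np.ndarray, p_lo: float, p_hi: float, T_m: float
) -> float | None:
    """5%-95% rise span of a logistic fitted to the transition region."""
    from scipy.optimize import curve_fit

    def model(t, lo, hi, t0, s):
        return lo + (hi - lo) / (1.0 + np.exp(-(t - t0) / s))

    span = float(T[-1] - T[0])
    try:
        popt, _ = curve_fit(
            model, T, er,
            p0=(p_lo, p_hi, T_m, max(span / 20.0, 1e-3)),
            maxfev=5000,
        )
    except RuntimeError:
        return None
    s = abs(float(popt[3]))
    width = 2.0 * np.log(19.0) * s  # 5%..95% of a logistic step
    if not np.isfinite(width) or width > 2.0 * span:
        return None
    return float(width)


def compare_models(
    phi_values: np.ndarray,
    eta_r_observed: np.ndarray,
    A: float = KD_A_DEFAULT,
    phi_max: float = KD_PHI_MAX_DEFAULT,
) -> dict:
    """Residuals of observed relative viscosities against both models.

    No fitting is involved: phi comes from geometry and both models are
    parameter-free.  Points with phi >= phi_max are excluded from the
    Krieger-Dougherty column and reported under ``excluded``.
    """
    phi = np.asarray(phi_values, dtype=float)
    obs = np.asarray(eta_r_observed, dtype=float)
    if phi.shape != obs.shape:
        raise ValueError("phi and observation lists must have equal length")
    ein = 1.0 + 2.5 * phi
    res_e = obs - ein
    valid = phi < phi_max
    kd = np.full_like(phi, np.nan)
    kd[valid] = (1.0 - phi[valid] / phi_max) ** (-A * phi_max)
    res_kd = obs - kd
    return {
        "phi": phi,
        "einstein_residuals": res_e,
        "kd_residuals": res_kd,
        "einstein_rms": float(np.sqrt(np.mean(res_e**2))),
        "kd_rms": float(np.sqrt(np.mean(res_kd[valid] ** 2))),
        "excluded": [float(p) for p in phi[~valid]],
    }
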