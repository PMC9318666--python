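"""Dynamic light scattering: correlogram fitting and hydrodynamic sizing.

A dilute suspension of monodisperse spheres produces an intensity
autocorrelation function that decays as a single exponential,

    g2(q, tau) - 1 = A exp(-2 Gamma tau),      Gamma = D_T q^2,

where ``Gamma`` is the relaxation rate of concentration fluctuations at
wave vector ``q`` and ``D_T`` the translational diffusion coefficient.
The hydrodynamic radius follows from the Stokes-Einstein relation
``D_T = k_B T / (6 pi eta R_h)``.  For vesicles decorated with an
adsorbed polymer layer, the layer's hydrodynamic thickness ``delta`` is
half the diameter increase over the bare vesicle, and its dependence on
polymer molar mass follows a power law whose exponent reflects solvent
quality (0.5 theta, ~0.588 good solvent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .solvents import water_viscosity
from .units import BOLTZMANN

__all__ = [
    "CorrelogramTrace",
    "DiffusionFit",
    "BoundLayerSeries",
    "compute_wave_vector",
    "fit_correlogram",
    "stokes_einstein",
    "bound_layer_thickness",
    "fit_layer_scaling",
]


@dataclass
class CorrelogramTrace:
    """Normalized intensity autocorrelation ``g2 - 1`` versus delay time.

    Attributes
    ----------
    delays : array, seconds, strictly increasing and positive
    g2_minus_1 : array, dimensionless, baseline-subtracted amplitude
    q : float, scattering wave vector in 1/m
    temperature : float, kelvin
    label : free-text sample description
    """

    delays: np.ndarray
    g2_minus_1: np.ndarray
    q: float
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.g2_minus_1 = np.asarray(self.g2_minus_1, dtype=float)
        if self.delays.ndim != 1 or self.delays.shape != self.g2_minus_1.shape:
            raise ValueError("delays and g2_minus_1 must be 1-D and equal length")
        if np.any(np.diff(self.delays) <= 0) or np.any(self.delays <= 0):
            raise ValueError("delays must be strictly increasing and positive")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not np.all(np.isfinite(self.g2_minus_1)):
            raise ValueError("g2_minus_1 must be finite")


@dataclass
class DiffusionFit:
    """Result of a single-exponential correlogram fit."""

    amplitude: float  # A, dimensionless
    gamma: float  # relaxation rate, 1/s
    D_T: float  # m^2/s
    R_h: float  # m
    residual_ss: float
    converged: bool


@dataclass
class BoundLayerSeries:
    """Adsorbed-layer thickness delta as a function of polymer molar mass."""

    molar_masses: np.ndarray  # g/mol
    deltas: np.ndarray  # nm
    baseline_diameter: float  # nm, bare-vesicle hydrodynamic diameter
    slope: float = field(default=np.nan)
    log_prefactor: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.molar_masses = np.asarray(self.molar_masses, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if len(self.molar_masses) != len(self.deltas) or len(self.deltas) < 2:
            raise ValueError("need >= 2 (molar mass, delta) pairs of equal length")
        if np.any(self.molar_masses <= 0):
            raise ValueError("molar masses must be strictly positive")


def compute_wave_vector(
    wavelength_vacuum: float, refractive_index: float, scattering_angle: float
) -> float:
    """Scattering wave vector ``q = 4 pi n sin(theta/2) / lambda`` in 1/m.

    ``wavelength_vacuum`` in meters, ``scattering_angle`` in degrees
    (0..180), ``refractive_index`` >= 1 for the suspending medium.
    """
    if wavelength_vacuum <= 0:
        raise ValueError("wavelength must be positive")
    if refractive_index < 1:
        raise ValueError("refractive index must be >= 1")
    if not 0 <= scattering_angle <= 180:
        raise ValueError("scattering angle must lie in [0, 180] degrees")
    theta = np.deg2rad(scattering_angle)
    return 4.0 * np.pi * refractive_index * np.sin(theta / 2.0) / wavelength_vacuum


def fit_correlogram(
    trace: CorrelogramTrace, solvent_viscosity: float | None = None
) -> DiffusionFit:
    """Fit ``A exp(-2 Gamma tau)`` to a correlogram and size the particles.

    The decay rate is taken positive, ``Gamma = D_T q^2``.  The
    hydrodynamic radius is computed from the fitted ``D_T`` via
    Stokes-Einstein at the trace temperature; ``solvent_viscosity``
    (Pa s) defaults to pure water at that temperature.

    A trace that does not decay (constant, increasing, or with a fitted
    ``Gamma <= 0``) is returned with ``converged=False`` and NaN derived
    quantities rather than raising.
    """
    tau = trace.delays
    y = trace.g2_minus_1
    if len(tau) < 8:
        raise ValueError("need at least 8 delay points")

    a0 = float(y[0])
    # initial Gamma: delay at which g2-1 falls to A/e
    target = a0 / np.e
    below = np.nonzero(y <= target)[0]
    if a0 <= 0 or len(below) == 0:
        return DiffusionFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    g0 = 1.0 / (2.0 * tau[below[0]])

    def model(t, A, G):
        return A * np.exp(-2.0 * G * t)

    try:
        popt, _ = curve_fit(
            model, tau, y, p0=(a0, g0), maxfev=1000, ftol=1e-10, xtol=1e-12
        )
    except RuntimeError:
        return DiffusionFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    A, gamma = float(popt[0]), float(popt[1])
    resid = y - model(tau, A, gamma)
    ss = float(np.dot(resid, resid))
    if gamma <= 0 or A <= 0:
        return DiffusionFit(A, gamma, np.nan, np.nan, ss, False)

    D_T = gamma / trace.q**2
    eta = (
        water_viscosity(trace.temperature)
        if solvent_viscosity is None
        else solvent_viscosity
    )
    R_h = stokes_einstein(D_T, trace.temperature, eta, direction="D->R")
    return DiffusionFit(A, gamma, D_T, R_h, ss, True)


def stokes_einstein(
    value: float, temperature: float, solvent_viscosity: float, direction: str = "D->R"
) -> float:
    """Convert between diffusion coefficient and hydrodynamic radius.

    ``D = k_B T / (6 pi eta R)``.  ``direction`` is ``"D->R"`` (value is
    D in m^2/s, returns R in m) or ``"R->D"``.  The relation is an
    involution, so both directions share one formula.
    """
    if temperature <= 0 or solvent_viscosity <= 0:
        raise ValueError("temperature and viscosity must be positive")
    if value <= 0:
        raise ValueError("input D or R must be positive")
    if direction not in ("D->R", "R->D"):
        raise ValueError("direction must be 'D->R' or 'R->D'")
    return BOLTZMANN * temperature / (6.0 * np.pi * solvent_viscosity * value)


def bound_layer_thickness(
    diameter_with_polymer: float, diameter_neat: float
) -> float:
    """Hydrodynamic thickness delta = (d_mix - d_neat)/2, in nm.

    May be negative (apparent shrinkage); callers decide how to flag it.
    """
    if diameter_with_polymer <= 0 or diameter_neat <= 0:
        raise ValueError("diameters must be positive")
    return (diameter_with_polymer - diameter_neat) / 2.0


def fit_layer_scaling(series: BoundLayerSeries) -> tuple[float, float]:
    """Power-law exponent of delta(Mw) by least squares in log10-log10.

    Pairs with delta <= 0 are excluded.  Returns ``(slope,
    log_prefactor)`` and stores them on ``series``.  The slope is
    invariant to the logarithm base; the prefactor is reported base 10.
    """
    mask = series.deltas > 0
    if mask.sum() < 2:
        raise ValueError("need >= 2 pairs with positive delta")
    x = np.log10(series.molar_masses[mask])
    y = np.log10(series.deltas[mask])
    slope, intercept = np.polyfit(x, y, 1)
    series.slope = float(slope)
    series.log_prefactor = float(intercept)
    return series.slope, series.log_prefactor
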