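"""Differential scanning calorimetry: transition detection and enthalpy.

Lipid bilayers crystallize (gel transition) on cooling with a sharp
exotherm near the main transition temperature.  The trace is specific
heat flow (W per gram of sample) versus temperature at a constant scan
rate.  The transition temperature T_c is the extremum of the
baseline-subtracted peak, the width its FWHM, and the specific enthalpy
the peak area divided by the scan rate,

    dH = | integral (heat_flow - baseline) dT | / beta,    beta in degC/s.

Exotherms are stored positive (readers apply the vendor "exo up/down"
sign); a linear baseline is drawn between the integration-window
endpoints, so adding any linear function of T to the trace leaves the
result unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "DSCTrace",
    "TransitionResult",
    "detect_transition",
    "integrate_enthalpy",
    "relative_enthalpy_change",
]


@dataclass
class DSCTrace:
    temperature: np.ndarray  # degC, monotone along scan direction
    heat_flow: np.ndarray  # W/g, exotherm positive
    scan_rate: float  # degC/min
    direction: Literal["cooling", "heating"] = "cooling"
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.temperature.shape != self.heat_flow.shape:
            raise ValueError("temperature and heat_flow must be equal length")
        dT = np.diff(self.temperature)
        if self.direction == "cooling" and np.any(dT >= 0):
            raise ValueError("cooling trace must have strictly decreasing T")
        if self.direction == "heating" and np.any(dT <= 0):
            raise ValueError("heating trace must have strictly increasing T")
        if self.scan_rate <= 0:
            raise ValueError("scan rate must be positive")

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """Temperature-ascending view of the trace."""
        if self.temperature[0] < self.temperature[-1]:
            return self.temperature, self.heat_flow
        return self.temperature[::-1], self.heat_flow[::-1]


@dataclass
class TransitionResult:
    T_c: float | None  # degC; None when no transition found
    fwhm: float | None  # degC
    enthalpy: float | None = None  # J/g
    baseline_model: str = "linear-endpoints"


def _linear_baseline(T: np.ndarray, hf: np.ndarray) -> np.ndarray:
    """Line anchored on the flank averages of the (sub)trace.

    Averaging the outer 10% of points on each side suppresses point noise
    at the anchors; for any exactly linear input the construction
    reproduces that line, so baseline invariance is preserved.
    """
    n = max(2, len(T) // 10)
    T0, y0 = float(np.mean(T[:n])), float(np.mean(hf[:n]))
    T1, y1 = float(np.mean(T[-n:])), float(np.mean(hf[-n:]))
    slope = (y1 - y0) / (T1 - T0)
    return y0 + slope * (T - T0)


def detect_transition(
    trace: DSCTrace, noise_sigmas: float = 5.0
) -> TransitionResult:
    """Locate the transition peak: (T_c, FWHM) of the baseline-subtracted trace.

    The peak must exceed ``noise_sigmas`` times a robust noise estimate
    (median absolute deviation of the second difference) or a
    no-transition result (``T_c is None``) is returned.
    """
    T, hf = trace.ascending()
    if len(T) < 50:
        raise ValueError("need at least 50 points")
    signal = hf - _linear_baseline(T, hf)

    # robust noise level from second differences (peak contributes little)
    d2 = np.diff(signal, 2)
    noise = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)
    peak_idx = int(np.argmax(signal))
    height = signal[peak_idx]
    if height <= max(noise_sigmas * noise, 1e-300):
        return TransitionResult(None, None)

    # sub-grid peak position: quadratic fit over the top of the peak
    # (a Gaussian cap is parabolic to second order); averaging over many
    # points suppresses point noise
    T_c = float(T[peak_idx])
    top = signal >= 0.8 * height
    lo = peak_idx
    while lo > 0 and top[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < len(T) - 1 and top[hi + 1]:
        hi += 1
    if hi - lo >= 4:
        c2, c1, _ = np.polyfit(T[lo: hi + 1], signal[lo: hi + 1], 2)
        if c2 < 0:
            vertex = -c1 / (2.0 * c2)
            if T[lo] <= vertex <= T[hi]:
                T_c = float(vertex)
    half = height / 2.0
    # FWHM by linear interpolation of the half-height crossings
    left = right = None
    for i in range(peak_idx, 0, -1):
        if signal[i - 1] <= half:
            f = (half - signal[i - 1]) / (signal[i] - signal[i - 1])
            left = T[i - 1] + f * (T[i] - T[i - 1])
            break
    for i in range(peak_idx, len(T) - 1):
        if signal[i + 1] <= half:
            f = (half - signal[i + 1]) / (signal[i] - signal[i + 1])
            right = T[i + 1] - f * (T[i + 1] - T[i])
            break
    if left is None or right is None:
        return TransitionResult(T_c, None)
    return TransitionResult(T_c, float(right - left))


def integrate_enthalpy(
    trace: DSCTrace,
    window: tuple[float, float],
    baseline_slope_tolerance: float = 0.5,
) -> tuple[float, bool]:
    """Specific transition enthalpy (J/g) from the peak area in ``window``.

    A linear baseline is drawn between the window endpoints and the
    baseline-subtracted heat flow integrated over temperature, then
    divided by the scan rate in degC/s.  Returns ``(dH, edge_warning)``;
    the warning flags a window edge that sits inside the peak, detected
    as flank curvature inconsistent between the two edges relative to
    the peak height (``baseline_slope_tolerance`` is that fraction).
    """
    T, hf = trace.ascending()
    lo, hi = min(window), max(window)
    mask = (T >= lo) & (T <= hi)
    if mask.sum() < 10:
        raise ValueError("integration window must contain >= 10 points")
    Tw, hw = T[mask], hf[mask]
    baseline = _linear_baseline(Tw, hw)
    signal = hw - baseline
    beta = trace.scan_rate / 60.0  # degC/s
    # signed integral (exotherms are stored positive); |total| keeps the
    # result convention-free without rectifying baseline noise into bias
    dH = float(abs(np.trapezoid(signal, Tw)) / beta)

    # edge-in-peak check: on a clean window the detrended flanks are flat;
    # an edge cutting the peak leaves a steep detrended slope there
    height = float(np.max(np.abs(signal)))
    n_edge = max(3, len(Tw) // 10)
    s_lo = float(np.polyfit(Tw[:n_edge], signal[:n_edge], 1)[0])
    s_hi = float(np.polyfit(Tw[-n_edge:], signal[-n_edge:], 1)[0])
    span = float(Tw[-1] - Tw[0])
    warn = bool(
        height > 0
        and max(abs(s_lo), abs(s_hi)) * span > baseline_slope_tolerance * height
    )
    return dH, warn


def relative_enthalpy_change(neat: float, mixed: float) -> float:
    """Percent decrease of the transition enthalpy relative to ``neat``."""
    if neat <= 0:
        raise ValueError("neat enthalpy must be positive")
    return 100.0 * (neat - mixed) / neat
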