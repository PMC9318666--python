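"""Time-resolved fluorescence: biexponential decays and microviscosity.

A TCSPC histogram of a membrane-embedded molecular rotor is fitted from
the peak bin onward with

    I(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2) + background,

using Poisson (Pearson) weights taken from the model, 1/sqrt(max(m, 1)),
which avoids the small-count bias of weighting by observed counts.  The
intensity-weighted mean lifetime is
tau_avg = sum(a_i tau_i^2) / sum(a_i tau_i).

Rotor lifetimes report the viscosity of the probe's immediate
surroundings through the Forster-Hoffmann relation, linear in log-log
form:

    ln(tau) = A + B ln(eta).

Calibrating A and B against solvents of known viscosity (here
methanol-glycerol mixtures, or printed lifetime/viscosity anchor pairs)
lets a measured lifetime be inverted to a bilayer microviscosity,
eta = exp((ln tau - A)/B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "DecayHistogram",
    "LifetimeFit",
    "FHCalibration",
    "fit_biexponential",
    "intensity_weighted_lifetime",
    "fit_forster_hoffman",
    "microviscosity_from_lifetime",
]


@dataclass
class DecayHistogram:
    time: np.ndarray  # ns, uniform bins
    counts: np.ndarray  # non-negative integers
    irf: np.ndarray | None = None  # instrument response, same binning
    temperature: float | None = None  # degC
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.time.shape != self.counts.shape:
            raise ValueError("time and counts must be equal length")
        dt = np.diff(self.time)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6) or dt[0] <= 0:
            raise ValueError("time bins must be uniform and increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class LifetimeFit:
    amplitudes: tuple[float, float]  # fractional, sum to 1
    lifetimes: tuple[float, float]  # ns, tau1 <= tau2
    tau_avg: float  # ns, intensity-weighted
    chi2_reduced: float
    background: float  # counts/bin
    scale: float  # total model amplitude at t=0, counts
    converged: bool = True
    collapsed_single: bool = False


@dataclass
class FHCalibration:
    """Forster-Hoffmann calibration ln(tau) = A + B ln(eta) at one temperature."""

    intercept_A: float
    slope_B: float
    temperature: float | None = None  # degC
    calibration_pairs: list[tuple[float, float]] = field(default_factory=list)


def intensity_weighted_lifetime(amplitudes, lifetimes) -> float:
    """Intensity-weighted mean lifetime sum(a tau^2)/sum(a tau) in ns."""
    a = np.asarray(amplitudes, dtype=float)
    t = np.asarray(lifetimes, dtype=float)
    if a.shape != t.shape:
        raise ValueError("amplitudes and lifetimes must have equal length")
    if np.any(a < 0) or not np.any(a > 0):
        raise ValueError("amplitudes must be >= 0 and not all zero")
    if np.any(t <= 0):
        raise ValueError("lifetimes must be positive")
    return float(np.sum(a * t**2) / np.sum(a * t))


def _biexp_model(t, a1, a2, tau1, tau2, bg, irf=None, bin_width=None):
    decay = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    if irf is not None:
        kernel = irf / irf.sum()
        decay = np.convolve(decay, kernel, mode="full")[: len(t)]
    return decay + bg


def fit_biexponential(
    hist: DecayHistogram,
    collapse_tolerance: float = 0.05,
    f_threshold: float = 10.0,
) -> LifetimeFit:
    """Fit a two-exponential decay to a TCSPC histogram (tail fit).

    Fitting starts at the peak bin.  Residuals carry Poisson weights
    evaluated from the model.  A single-exponential fit is always run as
    the null model; the second component is kept only when it improves
    the fit significantly (F statistic above ``f_threshold``), because a
    tail fit happily absorbs baseline noise into a spurious slow
    component that inflates the intensity-weighted mean.  The fit also
    collapses when the two lifetimes agree within ``collapse_tolerance``
    or one amplitude vanishes.  When ``hist.irf`` is present the model
    is convolved with the normalized instrument response.
    """
    total = int(np.sum(hist.counts))
    if total == 0:
        raise ValueError("histogram is empty")
    if total < 1e4:
        raise ValueError("need >= 1e4 total counts for a stable biexponential fit")
    peak = int(np.argmax(hist.counts))
    if len(hist.counts) - peak < 100:
        raise ValueError("need >= 100 bins past the peak")

    t = hist.time[peak:] - hist.time[peak]
    y = hist.counts[peak:].astype(float)
    irf = hist.irf[peak:] if hist.irf is not None else None

    def resid(p):
        m = _biexp_model(
            t, p["a1"].value, p["a2"].value, p["tau1"].value, p["tau2"].value,
            p["bg"].value, irf=irf,
        )
        return (y - m) / np.sqrt(np.maximum(m, 1.0))

    # moment-based lifetime guess (robust to background and truncation)
    tau_m = float(np.sum(t * y) / np.sum(y))
    scale0 = float(max(y[0], 1.0))
    bg_tail = max(float(np.median(y[-max(5, len(y) // 50):])), 0.0)

    # two starts: background-free and tail-level background; keep the
    # better chi^2 (the two parameters are strongly correlated on short
    # windows, so a bad background start can trap the optimizer)
    out = None
    for bg0 in (0.0, bg_tail):
        params = Parameters()
        params.add("a1", value=0.5 * scale0, min=0.0)
        params.add("a2", value=0.5 * scale0, min=0.0)
        params.add("tau1", value=max(tau_m / 3.0, 1e-3), min=1e-6)
        params.add("tau2", value=1.3 * tau_m, min=1e-6)
        params.add("bg", value=bg0, min=0.0)
        cand = minimize(resid, params, method="least_squares", max_nfev=20000, calc_covar=False)
        if out is None or cand.chisqr < out.chisqr:
            out = cand
    pv = out.params.valuesdict()
    a1, a2, tau1, tau2, bg = pv["a1"], pv["a2"], pv["tau1"], pv["tau2"], pv["bg"]

    # null model: single exponential from the same data
    p1 = Parameters()
    p1.add("a", value=scale0, min=0.0)
    p1.add("tau", value=tau_m, min=1e-6)
    p1.add("bg", value=0.0, min=0.0)

    def resid1(p):
        m = _biexp_model(
            t, p["a"].value, 0.0, p["tau"].value, 1.0, p["bg"].value, irf=irf
        )
        return (y - m) / np.sqrt(np.maximum(m, 1.0))

    out1 = minimize(resid1, p1, method="least_squares", max_nfev=5000, calc_covar=False)

    # F-test: is the second component worth its two extra parameters?
    dof2 = max(out.nfree, 1)
    f_stat = ((out1.chisqr - out.chisqr) / 2.0) / max(out.chisqr / dof2, 1e-300)
    degenerate = (
        abs(tau1 - tau2) <= collapse_tolerance * max(tau1, tau2)
        or min(a1, a2) == 0
    )
    collapsed = False
    if degenerate or f_stat < f_threshold:
        q = out1.params.valuesdict()
        a1, a2, tau1, tau2, bg = q["a"], 0.0, q["tau"], q["tau"], q["bg"]
        collapsed = True
        out = out1

    # deterministic ordering tau1 <= tau2
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    scale = a1 + a2
    frac = (a1 / scale, a2 / scale) if scale > 0 else (0.0, 0.0)
    if collapsed or a2 == 0:
        tau_avg = intensity_weighted_lifetime([1.0], [tau1])
    elif a1 == 0:
        tau_avg = intensity_weighted_lifetime([1.0], [tau2])
    else:
        tau_avg = intensity_weighted_lifetime([a1, a2], [tau1, tau2])
    nfree = max(out.nfree, 1)
    return LifetimeFit(
        amplitudes=frac,
        lifetimes=(float(tau1), float(tau2)),
        tau_avg=tau_avg,
        chi2_reduced=float(out.chisqr / nfree),
        background=float(bg),
        scale=float(scale),
        converged=bool(out.success),
        collapsed_single=collapsed,
    )


def fit_forster_hoffman(
    pairs, temperature: float | None = None
) -> FHCalibration:
    """Ordinary least squares of ln(tau) on ln(eta).

    ``pairs`` is a sequence of (tau_ns, eta_cP).  With exactly two pairs
    the result is the exact two-point line.
    """
    pairs = [(float(t), float(e)) for t, e in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration pairs")
    tau = np.array([p[0] for p in pairs])
    eta = np.array([p[1] for p in pairs])
    if np.any(tau <= 0) or np.any(eta <= 0):
        raise ValueError("lifetimes and viscosities must be positive")
    x, y = np.log(eta), np.log(tau)
    if len(pairs) == 2:
        if x[0] == x[1]:
            raise ValueError("two-point calibration is singular: duplicate viscosity")
        B = (y[1] - y[0]) / (x[1] - x[0])
        A = y[0] - B * x[0]
    else:
        B, A = np.polyfit(x, y, 1)
    return FHCalibration(float(A), float(B), temperature, pairs)


def microviscosity_from_lifetime(tau: float, calibration: FHCalibration) -> float:
    """Invert the calibration: eta = exp((ln tau - A)/B), in cP."""
    if tau <= 0:
        raise ValueError("lifetime must be positive")
    if calibration.slope_B == 0:
        raise ValueError("calibration slope is zero; relation is not invertible")
    return float(
        np.exp((np.log(tau) - calibration.intercept_A) / calibration.slope_B)
    )
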