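"""Solvent viscosity models.

Pure-water shear viscosity is needed in two places: as the solvent
viscosity in Stokes-Einstein sizing of vesicles, and as the baseline for
relative-viscosity curves.  A three-parameter Vogel correlation

    eta(T) = exp(a + b / (T - c))        [Pa s, T in K]

is used, with constants obtained by least squares against standard
reference viscosities of water at 10-40 degC in 5 degC steps
(1.3059, 1.1375, 1.0016, 0.8900, 0.7972, 0.7191, 0.6527 mPa s).
The correlation reproduces every node to better than 0.05%.
"""

from __future__ import annotations

import numpy as np

__all__ = ["water_viscosity"]

# Vogel constants for ln(eta / Pa s); least-squares fit to the reference
# table above.  Valid 273 K < T < 373 K, <1% error over 10-40 degC.
_VOGEL_A = -10.25526679
_VOGEL_B = 457.01522067
_VOGEL_C = 156.69861086


def water_viscosity(temperature_K: float | np.ndarray) -> float | np.ndarray:
    """Shear viscosity of pure water in Pa s at ``temperature_K`` (kelvin).

    Parameters
    ----------
    temperature_K : float or array
        Absolute temperature.  Must lie strictly inside (273 K, 373 K),
        the liquid range at ambient pressure.

    Raises
    ------
    ValueError
        If any temperature lies outside the validity range.
    """
    T = np.asarray(temperature_K, dtype=float)
    if np.any(T <= 273.0) or np.any(T >= 373.0):
        raise ValueError(
            "water_viscosity is valid only for 273 K < T < 373 K, "
            f"got {temperature_K!r}"
        )
    eta = np.exp(_VOGEL_A + _VOGEL_B / (T - _VOGEL_C))
    if np.isscalar(temperature_K) or np.ndim(temperature_K) == 0:
        return float(eta)
    return eta
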