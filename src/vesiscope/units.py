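"""Unit conventions and physical constants.

All I/O boundaries use degrees Celsius; computations use kelvin.
Lengths are reported in nanometers, viscosities in mPa s (= cP),
diffusion constants in m^2/s, lifetimes in ns.
"""

from __future__ import annotations

BOLTZMANN = 1.380649e-23  # J/K (exact, SI 2019)
AVOGADRO = 6.02214076e23  # 1/mol (exact)

ZERO_CELSIUS = 273.15  # K


def celsius_to_kelvin(t_C: float) -> float:
    return t_C + ZERO_CELSIUS


def kelvin_to_celsius(t_K: float) -> float:
    return t_K - ZERO_CELSIUS
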