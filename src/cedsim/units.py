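"""Unit conversions to SI.

All physics in this package is carried out in SI units (m, s, Pa, mol/m^3).
Image geometry follows the NIfTI convention (affines in mm); conversion to
metres happens once, at the solver boundary, through these helpers.
"""

from __future__ import annotations

MM_TO_M = 1.0e-3
UM_TO_M = 1.0e-6
CM2_PER_S_TO_M2_PER_S = 1.0e-4
UL_PER_MIN_TO_M3_PER_S = 1.0e-9 / 60.0
PER_MIN_TO_PER_S = 1.0 / 60.0
MOL_PER_L_TO_MOL_PER_M3 = 1.0e3


def ul_per_min(q: float) -> float:
    """Infusion rate in uL/min -> m^3/s (3 uL/min -> 5e-11 m^3/s)."""
    return q * UL_PER_MIN_TO_M3_PER_S


def per_min(rate: float) -> float:
    """First-order rate in 1/min -> 1/s (0.01 /min -> 1.6667e-4 /s)."""
    return rate * PER_MIN_TO_PER_S


def cm2_per_s(d: float) -> float:
    """Diffusivity in cm^2/s -> m^2/s (1.54e-6 cm^2/s -> 1.54e-10 m^2/s)."""
    return d * CM2_PER_S_TO_M2_PER_S


def mol_per_l(c: float) -> float:
    """Concentration in mol/L -> mol/m^3 (0.5 mol/L -> 500 mol/m^3)."""
    return c * MOL_PER_L_TO_MOL_PER_M3
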