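"""Tissue density to lipid-store proportion.

Approximate, species-extrapolated conversion: an affine map through two
published (density, lipid-fraction) pairs for a repeatedly sampled adult
male humpback, derived originally from elephant-seal isotope-dilution work.
Denser tissue means a smaller lipid fraction, so the slope is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


@dataclass(frozen=True)
class LipidCalibration:
    """Affine map P_lipid(rho) through two anchor (density, fraction) pairs."""

    anchor1: tuple = (1037.0, 0.363)
    anchor2: tuple = (1031.2, 0.390)
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self):
        (r1, p1), (r2, p2) = self.anchor1, self.anchor2
        if r1 == r2:
            raise ValueError("anchor densities must be distinct")
        slope = (p2 - p1) / (r2 - r1)
        if slope >= 0:
            raise ValueError("calibration slope must be negative (denser => leaner)")
        object.__setattr__(self, "slope", slope)
        object.__setattr__(self, "intercept", p1 - slope * r1)


DEFAULT_CALIBRATION = LipidCalibration()

#: Plausible humpback tissue-density range; outside it the affine
#: extrapolation is increasingly speculative.
PLAUSIBLE_RANGE = (1000.0, 1070.0)


def lipid_fraction(rho: float, calib: LipidCalibration = DEFAULT_CALIBRATION) -> float:
    """Approximate lipid-store proportion for tissue density ``rho`` (kg m^-3).

    Warns (but still computes) outside the plausible tissue-density range.
    """
    if not PLAUSIBLE_RANGE[0] <= rho <= PLAUSIBLE_RANGE[1]:
        warnings.warn(
            f"tissue density {rho} kg m^-3 outside plausible range "
            f"{PLAUSIBLE_RANGE}; lipid fraction is an extrapolation",
            stacklevel=2,
        )
    return calib.intercept + calib.slope * rho
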