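"""Length-standardized surface area index (LSSAI) from overhead outlines.

A whale outline from an aerial image is summarized as the total length
(rostrum tip to fluke notch, pixels) and the body width at each of 21
equally spaced section boundaries.  Each of the 20 sections is treated as a
trapezoid; its projected area, standardized by total length, is

    PA_i = (B/L + b/L) * (h/L) / 2

with B and b the widths at the section's two boundaries and h = L/20.
LSSAI is the sum of PA over sections 7-17 (30-85% of body length from the
rostrum), the mid-body region where whale-to-whale variation concentrates.
Because every dimension is divided by L, the index is invariant to image
scale, altitude and camera parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

N_SECTIONS = 20
N_BOUNDARIES = N_SECTIONS + 1
#: Inclusive section range summed by the index (mid-body).
LSSAI_SECTIONS = (7, 17)


@dataclass(frozen=True)
class FrameScore:
    """Quality score of one video frame: posture, brightness, submergence.

    Each criterion is ordinal 1 (poor), 2 (medium), 3 (good).
    """

    posture: int
    brightness: int
    submergence: int

    def __post_init__(self):
        for v in (self.posture, self.brightness, self.submergence):
            if v not in (1, 2, 3):
                raise ValueError(f"frame score criteria must be in {{1,2,3}}, got {v}")

    @property
    def mean(self) -> float:
        return (self.posture + self.brightness + self.submergence) / 3.0


@dataclass(frozen=True)
class WhaleOutline:
    """Outline measurements of one whale in one frame (pixel units)."""

    total_length: float
    boundary_widths: tuple
    score: FrameScore | None = None
    whale_id: str = ""
    frame_id: str = ""

    def __post_init__(self):
        if self.total_length <= 0:
            raise ValueError("total_length must be > 0")
        widths = tuple(float(w) for w in self.boundary_widths)
        if len(widths) != N_BOUNDARIES:
            raise ValueError(
                f"expected {N_BOUNDARIES} boundary widths, got {len(widths)}"
            )
        if any(np.isnan(widths[i]) for i in range(6, 18)):
            raise ValueError(
                "boundary widths w6..w17 (sections 7-17) must be present; "
                "no imputation is performed"
            )
        if any(w < 0 for w in widths if not np.isnan(w)):
            raise ValueError("boundary widths must be >= 0")
        object.__setattr__(self, "boundary_widths", widths)

    @property
    def section_height(self) -> float:
        return self.total_length / N_SECTIONS


def select_best_frame(frames: Sequence[WhaleOutline]) -> WhaleOutline:
    """Outline with the highest mean frame score; ties go to the earliest frame."""
    if not frames:
        raise ValueError("need at least one frame")
    best = frames[0]
    for f in frames[1:]:
        if f.score is None or best.score is None:
            raise ValueError("all frames must carry a FrameScore")
        if f.score.mean > best.score.mean:
            best = f
    return best


def projected_area(B: float, b: float, h: float, L: float) -> float:
    """Length-standardized trapezoid area of one body section.

    (B/L + b/L) * (h/L) / 2 with widths B, b, section height h and total
    length L, all in the same (pixel) units.
    """
    if L <= 0:
        raise ValueError("total length must be > 0")
    if min(B, b, h) < 0:
        raise ValueError("widths and height must be >= 0")
    return (B / L + b / L) * (h / L) / 2.0


def section_areas(outline: WhaleOutline) -> np.ndarray:
    """PA for each of the 20 sections (section i uses boundaries i-1 and i)."""
    w = np.asarray(outline.boundary_widths, dtype=float)
    L = outline.total_length
    h = outline.section_height
    return (w[:-1] / L + w[1:] / L) * (h / L) / 2.0


def lssai(outline: WhaleOutline) -> float:
    """Sum of PA over sections 7-17 inclusive (11 sections, 30-85% of length)."""
    lo, hi = LSSAI_SECTIONS
    pa = section_areas(outline)
    return float(np.sum(pa[lo - 1 : hi]))


def pixel_mask_oracle(outline: WhaleOutline, resolution: int = 4000) -> float:
    """Independent rasterized estimate of LSSAI.

    Renders the outline as a filled polygon (piecewise-linear half-width
    profile about the midline) on a grid with ``resolution`` pixels along the
    body, counts mask pixels with centres between 30% and 85% of body length,
    and divides by the squared rendered length.  Converges to :func:`lssai`
    as resolution grows because the trapezoid rule is exact for the linear
    width interpolation.
    """
    if resolution < 2000:
        raise ValueError("resolution must be >= 2000 px body length")
    L = float(resolution)
    # outline half-width at fractional position along body, linearly interpolated
    frac_nodes = np.linspace(0.0, 1.0, N_BOUNDARIES)
    w_nodes = np.asarray(outline.boundary_widths, dtype=float) / outline.total_length
    lo, hi = LSSAI_SECTIONS
    x_lo, x_hi = (lo - 1) / N_SECTIONS, hi / N_SECTIONS  # 0.30, 0.85

    # pixel-centre columns within the section range
    cols = np.arange(int(np.floor(L))) + 0.5
    frac = cols / L
    in_range = (frac >= x_lo) & (frac < x_hi)
    half_w = 0.5 * np.interp(frac[in_range], frac_nodes, w_nodes) * L
    # row centres sit at |y| = 0.5, 1.5, ... about the midline; a column of
    # half-width hw therefore contains 2*floor(hw + 0.5) pixel centres
    n_rows = 2.0 * np.floor(half_w + 0.5)
    count = float(np.sum(n_rows))
    return count / L**2
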