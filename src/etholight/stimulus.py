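"""Moving-dot protocol: visual-angle conversion and block trial plans.

The standard trial is 7 blocks of 6 dots each, one unique dot size per block,
presented in size-ascending or seeded pseudo-random block order, with a 19 s
stimulus-free gap between consecutive blocks and dots traveling at 13.5 mm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_DOT_SPEED_MM_S = 13.5
DEFAULT_REPS_PER_BLOCK = 6
DEFAULT_GAP_S = 19.0


def pixels_to_degrees(
    diameter_px: float, pixel_pitch_mm: float, viewing_distance_mm: float
) -> float:
    """Dot diameter on screen converted to degrees of the subject's visual
    field: 2*arctan(s / 2D) with s the physical diameter and D the viewing
    distance."""
    if diameter_px <= 0 and diameter_px != 0:
        raise ValueError("diameter must be non-negative")
    if pixel_pitch_mm <= 0 or viewing_distance_mm <= 0:
        raise ValueError("pixel pitch and viewing distance must be positive")
    s = diameter_px * pixel_pitch_mm
    return math.degrees(2.0 * math.atan(s / (2.0 * viewing_distance_mm)))


def degrees_to_pixels(
    diameter_deg: float, pixel_pitch_mm: float, viewing_distance_mm: float
) -> float:
    """Inverse of :func:`pixels_to_degrees`."""
    if not 0 <= diameter_deg < 180:
        raise ValueError("visual angle must lie in [0, 180) degrees")
    if pixel_pitch_mm <= 0 or viewing_distance_mm <= 0:
        raise ValueError("pixel pitch and viewing distance must be positive")
    s = 2.0 * viewing_distance_mm * math.tan(math.radians(diameter_deg) / 2.0)
    return s / pixel_pitch_mm


@dataclass(frozen=True)
class DotStimulus:
    """One moving dot: screen size, visual angle, luminance, and speed."""

    diameter_px: float
    diameter_deg: float
    luminance: float = 0.0  # minimal screen black by default
    speed_mm_s: float = DEFAULT_DOT_SPEED_MM_S

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")
        if not 0 < self.diameter_deg < 180:
            raise ValueError("diameter_deg must lie in (0, 180)")
        if self.speed_mm_s <= 0:
            raise ValueError("speed must be positive")
        if self.luminance < 0:
            raise ValueError("luminance must be non-negative")


@dataclass(frozen=True)
class TrialPlan:
    """Ordered block plan of a dot trial.

    ``blocks`` is the presentation order: (size_deg, repetitions) per block.
    """

    blocks: tuple[tuple[float, int], ...]
    order_mode: str  # "ascending" | "pseudo_random"
    gap_s: float = DEFAULT_GAP_S
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.order_mode not in ("ascending", "pseudo_random"):
            raise ValueError(f"unknown order_mode {self.order_mode!r}")
        sizes = [s for s, _ in self.blocks]
        if len(set(sizes)) != len(sizes):
            raise ValueError("duplicate dot sizes across blocks")
        if any(r < 1 for _, r in self.blocks):
            raise ValueError("each block needs >= 1 repetition")
        if self.order_mode == "ascending" and sizes != sorted(sizes):
            raise ValueError("ascending plan must have strictly increasing sizes")

    @property
    def sizes_deg(self) -> tuple[float, ...]:
        return tuple(s for s, _ in self.blocks)

    @property
    def n_presentations(self) -> int:
        return sum(r for _, r in self.blocks)

    @property
    def n_gaps(self) -> int:
        return len(self.blocks) - 1

    def presentations(self) -> list[tuple[int, int, float]]:
        """Flat presentation list: (block_index, presentation_index, size_deg).

        ``presentation_index`` is 1-based within the block.
        """
        out = []
        for b, (size, reps) in enumerate(self.blocks):
            for k in range(1, reps + 1):
                out.append((b, k, size))
        return out


def make_trial_plan(
    sizes_deg,
    order_mode: str = "ascending",
    seed: int | None = None,
    reps: int = DEFAULT_REPS_PER_BLOCK,
    gap_s: float = DEFAULT_GAP_S,
) -> TrialPlan:
    """Build a block trial plan from the set of dot sizes.

    ``pseudo_random`` applies a uniform seeded shuffle of the block order;
    the same seed always yields the same order.
    """
    sizes = [float(s) for s in sizes_deg]
    if len(set(sizes)) != len(sizes):
        raise ValueError("dot sizes must be distinct")
    if any(not 0 < s < 180 for s in sizes):
        raise ValueError("dot sizes must lie in (0, 180) degrees")
    ordered = sorted(sizes)
    if order_mode == "pseudo_random":
        rng = np.random.default_rng(seed)
        ordered = list(rng.permutation(ordered))
    elif order_mode != "ascending":
        raise ValueError(f"unknown order_mode {order_mode!r}")
    blocks = tuple((float(s), reps) for s in ordered)
    return TrialPlan(blocks=blocks, order_mode=order_mode, gap_s=gap_s, seed=seed)
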