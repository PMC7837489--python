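"""Light stimuli: spectra, photon flux, contrast, and light/dark schedules.

Spectra are tabulated spectral irradiance E(lambda) in W m^-2 nm^-1 on a
wavelength grid in nm. Photon flux integrates E(lambda) * lambda / (h*c) by the
trapezoid rule over the sampled grid. Schedules are ordered, contiguous,
half-open [start, end) intervals, each labeled with a light condition and an
optional relative intensity; acclimation intervals are flagged and excluded
from analysis aggregates by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Planck constant times speed of light, J*m.
HC = 1.98645e-25

#: Recognized light-condition labels. "dark" is special-cased by transition
#: finders; every other label counts as a lit condition.
CONDITIONS = ("dark", "white", "blue", "green", "red")


class ScheduleError(ValueError):
    """Raised for overlapping, gapped, or zero-length schedule intervals."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled emission spectrum.

    Parameters
    ----------
    wavelength_nm : array-like
        Strictly increasing wavelengths, nm.
    irradiance : array-like
        Spectral irradiance at each wavelength, W m^-2 nm^-1, all >= 0.
    label : str
        Free-text description (e.g. "screen white 100%").
    """

    wavelength_nm: np.ndarray
    irradiance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        ir = np.asarray(self.irradiance, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("spectrum needs at least one sample")
        if wl.size != ir.size:
            raise ValueError("wavelength and irradiance lengths differ")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(ir)):
            raise ValueError("spectrum values must be finite")
        if np.any(ir < 0):
            raise ValueError("spectral irradiance must be non-negative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "irradiance", ir)

    @property
    def n_samples(self) -> int:
        return int(self.wavelength_nm.size)


def photon_flux(spectrum: Spectrum, bandwidth_nm: float | None = None) -> float:
    """Total photon flux of a spectrum, photons m^-2 s^-1.

    Computes trapezoid(E(lambda) * lambda / (h*c)) over the sampled grid,
    with lambda converted to meters. A single-sample spectrum cannot be
    integrated; pass ``bandwidth_nm`` to treat it as a rectangular band.
    """
    wl = spectrum.wavelength_nm
    ir = spectrum.irradiance
    photons_per_joule = (wl * 1e-9) / HC  # 1/lambda-photon energy
    if spectrum.n_samples == 1:
        if bandwidth_nm is None:
            raise ValueError(
                "cannot integrate a single-sample spectrum; "
                "supply an explicit bandwidth_nm"
            )
        if bandwidth_nm <= 0:
            raise ValueError("bandwidth_nm must be positive")
        return float(ir[0] * photons_per_joule[0] * bandwidth_nm)
    return float(np.trapezoid(ir * photons_per_joule, wl))


def scale_intensity(flux: float, factor: float) -> float:
    """Scale a photon flux by a relative intensity factor in [0, 1]."""
    if not 0.0 <= factor <= 1.0:
        raise ValueError(f"intensity factor {factor!r} outside [0, 1]")
    if flux < 0:
        raise ValueError("photon flux must be non-negative")
    return flux * factor


@dataclass(frozen=True)
class ContrastPair:
    """Maximum and minimum luminance of a stimulus/background pair.

    Units are arbitrary but must be linear and shared between the two.
    """

    l_max: float
    l_min: float

    def __post_init__(self) -> None:
        if self.l_min < 0 or self.l_max < self.l_min:
            raise ValueError("require l_max >= l_min >= 0")


def michelson_contrast(pair: ContrastPair) -> float:
    """(l_max - l_min) / (l_max + l_min); scale-invariant, in [0, 1]."""
    if pair.l_max == 0.0:
        raise ValueError("undefined contrast: both luminances are zero")
    return (pair.l_max - pair.l_min) / (pair.l_max + pair.l_min)


@dataclass(frozen=True)
class LightInterval:
    """One half-open [start_s, end_s) schedule interval."""

    start_s: float
    end_s: float
    condition: str
    intensity: float = 1.0
    acclimation: bool = False

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ScheduleError(
                f"interval [{self.start_s}, {self.end_s}) has non-positive length"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity factor must lie in [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_dark(self) -> bool:
        return self.condition == "dark"

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class LightSchedule:
    """An ordered, contiguous, non-overlapping sequence of light intervals."""

    intervals: tuple[LightInterval, ...]
    origin_zt: float = 0.0

    def __post_init__(self) -> None:
        ivs = tuple(self.intervals)
        if not ivs:
            raise ScheduleError("schedule must contain at least one interval")
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s != a.end_s:
                raise ScheduleError(
                    f"intervals not contiguous at t={a.end_s} -> {b.start_s}"
                )
        object.__setattr__(self, "intervals", ivs)

    @property
    def start_s(self) -> float:
        return self.intervals[0].start_s

    @property
    def end_s(self) -> float:
        return self.intervals[-1].end_s

    @property
    def total_duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def analysis_intervals(self) -> tuple[LightInterval, ...]:
        """Intervals that enter aggregate analyses (acclimation excluded)."""
        return tuple(iv for iv in self.intervals if not iv.acclimation)

    @property
    def analysis_duration_s(self) -> float:
        return float(sum(iv.duration_s for iv in self.analysis_intervals))

    def interval_at(self, t: float) -> LightInterval:
        for iv in self.intervals:
            if iv.contains(t):
                return iv
        raise KeyError(f"t={t} outside schedule [{self.start_s}, {self.end_s})")

    def condition_at(self, t: float) -> str:
        return self.interval_at(t).condition

    def transitions(self) -> list[tuple[float, LightInterval, LightInterval]]:
        """All boundaries where the condition changes: (t, before, after)."""
        out = []
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.condition != b.condition or a.intensity != b.intensity:
                out.append((a.end_s, a, b))
        return out

    def light_to_dark_transitions(self) -> list[float]:
        """Times where a lit interval ends and a dark interval begins."""
        return [
            t for t, a, b in self.transitions() if not a.is_dark and b.is_dark
        ]

    def dark_to_light_transitions(self) -> list[float]:
        """Times where a dark interval ends and a lit interval begins."""
        return [
            t for t, a, b in self.transitions() if a.is_dark and not b.is_dark
        ]


def build_schedule(
    blocks: Sequence[tuple],
    repeats: int = 1,
    acclimation_s: float | None = None,
    acclimation_condition: str = "dark",
    origin_zt: float = 0.0,
) -> LightSchedule:
    """Build a contiguous schedule from a repeated block pattern.

    Parameters
    ----------
    blocks : sequence of (duration_s, condition[, intensity])
        One repetition of the pattern, in order.
    repeats : int
        How many times the block list repeats.
    acclimation_s : float, optional
        Length of a leading acclimation interval; it is flagged and
        excluded from ``analysis_intervals``.
    acclimation_condition : str
        Condition during acclimation (default dark).
    origin_zt : float
        Zeitgeber hours at the start of the trial (acclimation included).
    """
    if repeats < 1:
        raise ScheduleError("repeats must be >= 1")
    if not blocks:
        raise ScheduleError("block list must not be empty")
    intervals: list[LightInterval] = []
    t = 0.0
    if acclimation_s is not None:
        if acclimation_s <= 0:
            raise ScheduleError("acclimation duration must be positive")
        intervals.append(
            LightInterval(0.0, acclimation_s, acclimation_condition,
                          acclimation=True)
        )
        t = acclimation_s
    for _ in range(repeats):
        for block in blocks:
            if len(block) == 2:
                duration, condition = block
                intensity = 1.0
            else:
                duration, condition, intensity = block
            if duration <= 0:
                raise ScheduleError("block durations must be positive")
            intervals.append(
                LightInterval(t, t + duration, condition, intensity=intensity)
            )
            t += duration
    return LightSchedule(tuple(intervals), origin_zt=origin_zt)


def photokinesis_schedule(
    light_condition: str = "white",
    block_s: float = 30 * 60.0,
    repeats: int = 3,
    acclimation_s: float = 5 * 60.0,
    origin_zt: float = 3.0,
) -> LightSchedule:
    """The alternating light/dark paradigm: 5-min dark acclimation, then
    ``repeats`` x (30 min light + 30 min dark), 3 h of analysis time."""
    return build_schedule(
        [(block_s, light_condition), (block_s, "dark")],
        repeats=repeats,
        acclimation_s=acclimation_s,
        origin_zt=origin_zt,
    )


def diel_schedule(
    light_condition: str = "blue",
    light_h: float = 16.0,
    dark_h: float = 8.0,
    days: int = 2,
    origin_zt: float = 16.0,
    dark_first: bool = True,
) -> LightSchedule:
    """A multi-day photoperiod schedule; trials start at the light-to-dark
    transition, so each day is dark_h of darkness then light_h of light."""
    if dark_first:
        blocks = [(dark_h * 3600.0, "dark"), (light_h * 3600.0, light_condition)]
    else:
        blocks = [(light_h * 3600.0, light_condition), (dark_h * 3600.0, "dark")]
    return build_schedule(blocks, repeats=days, origin_zt=origin_zt)
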