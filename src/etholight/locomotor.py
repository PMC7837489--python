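"""Locomotor activity: binned distance series and interval AUC metrics.

Raw trajectories (time-stamped positions of one subject) are reduced to a
distance-moved-per-bin series (10 s bins for the alternating light/dark
paradigm, 60 s bins for multi-day photoperiod trials). The activity summary of
a schedule interval is its AUC, i.e. the sum of bin distances in the interval
(the series already holds distance per bin, so the sum IS the area; a
trapezoid rule is available as an option). Two derived readouts:

* normalized fast dark-photokinesis response: mean per-bin distance during the
  first 2 min after light cessation, divided by the mean per-bin distance of
  the 5 min of darkness preceding that light interval;
* lights-on windows: AUC of the first 30 and 90 min after each dark-to-light
  transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from etholight.lightfield import LightInterval, LightSchedule

DEFAULT_GAP_TOLERANCE_S = 1.0
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """Per-frame positions of one subject in one arena."""

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    subject_id: str = ""
    genotype: str = ""
    arena_id: str = ""
    frame_rate_hz: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        x = np.asarray(self.x_mm, dtype=float)
        y = np.asarray(self.y_mm, dtype=float)
        if not (t.size == x.size == y.size):
            raise ValueError("t, x, y must have equal lengths")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        # missing samples are NaN coordinates; time must always be finite
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("timestamps must be finite")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "x_mm", x)
        object.__setattr__(self, "y_mm", y)

    @property
    def n_frames(self) -> int:
        return int(self.t_s.size)


@dataclass(frozen=True)
class ActivitySeries:
    """Distance moved per time bin, aligned to the schedule origin."""

    bin_width_s: float
    origin_s: float
    distance_mm: np.ndarray  # one value per bin
    flagged: np.ndarray  # bool per bin: tracking gap > tolerance inside bin
    subject_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_mm, dtype=float)
        f = np.asarray(self.flagged, dtype=bool)
        if d.size != f.size:
            raise ValueError("distance and flag arrays differ in length")
        if np.any(d < 0):
            raise ValueError("bin distances must be non-negative")
        object.__setattr__(self, "distance_mm", d)
        object.__setattr__(self, "flagged", f)

    @property
    def n_bins(self) -> int:
        return int(self.distance_mm.size)

    @property
    def bin_starts_s(self) -> np.ndarray:
        return self.origin_s + self.bin_width_s * np.arange(self.n_bins)

    @property
    def end_s(self) -> float:
        return self.origin_s + self.bin_width_s * self.n_bins


@dataclass(frozen=True)
class IntervalMetric:
    """AUC of one schedule interval or named window for one subject."""

    label: str
    start_s: float
    end_s: float
    auc_mm: float
    n_bins: int
    n_flagged: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.auc_mm < 0:
            raise ValueError("AUC must be non-negative")


@dataclass(frozen=True)
class DarkResponse:
    """Normalized fast dark-photokinesis response at one transition."""

    value: float
    defined: bool
    transition_s: float
    response_mean_mm: float
    baseline_mean_mm: float


def distance_series(
    traj: Trajectory,
    bin_width_s: float,
    origin_s: float = 0.0,
    end_s: float | None = None,
    gap_tolerance_s: float = DEFAULT_GAP_TOLERANCE_S,
) -> ActivitySeries:
    """Bin a trajectory into distance moved per ``bin_width_s`` seconds.

    Each step between consecutive tracked frames contributes its Euclidean
    length to the bin containing the step's midpoint. Frames with missing
    (NaN) coordinates are skipped; a resulting time gap no longer than
    ``gap_tolerance_s`` is bridged by the straight-line step across it
    (linear interpolation), while longer gaps contribute nothing and flag
    every bin they touch.
    """
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    ok = np.isfinite(traj.x_mm) & np.isfinite(traj.y_mm)
    if ok.sum() < 2:
        raise ValueError("trajectory has fewer than two tracked frames")
    t = traj.t_s[ok]
    x = traj.x_mm[ok]
    y = traj.y_mm[ok]

    if end_s is None:
        end_s = float(t[-1])
    n_bins = int(math.ceil((end_s - origin_s) / bin_width_s - _EDGE_EPS))
    if n_bins < 1:
        raise ValueError("series extent is empty")

    dt = np.diff(t)
    steps = np.hypot(np.diff(x), np.diff(y))
    mid = 0.5 * (t[:-1] + t[1:])
    good = dt <= gap_tolerance_s + _EDGE_EPS

    idx = np.floor((mid - origin_s) / bin_width_s).astype(int)
    in_range = (idx >= 0) & (idx < n_bins)

    distance = np.zeros(n_bins)
    np.add.at(distance, idx[good & in_range], steps[good & in_range])

    flagged = np.zeros(n_bins, dtype=bool)
    for i in np.nonzero(~good)[0]:
        lo = int(np.floor((t[i] - origin_s) / bin_width_s))
        hi = int(np.floor((t[i + 1] - origin_s) / bin_width_s))
        lo = max(lo, 0)
        hi = min(hi, n_bins - 1)
        if hi >= lo:
            flagged[lo : hi + 1] = True

    return ActivitySeries(
        bin_width_s=float(bin_width_s),
        origin_s=float(origin_s),
        distance_mm=distance,
        flagged=flagged,
        subject_id=traj.subject_id,
        genotype=traj.genotype,
    )


def _bin_slice(series: ActivitySeries, start_s: float, end_s: float) -> slice:
    """Bin-index slice for [start_s, end_s); boundaries must sit on bin edges."""
    w = series.bin_width_s
    for name, edge in (("start", start_s), ("end", end_s)):
        k = (edge - series.origin_s) / w
        if abs(k - round(k)) > 1e-6:
            raise ValueError(
                f"interval {name} {edge} s is not aligned to {w} s bin edges "
                f"(origin {series.origin_s} s); no silent partial bins"
            )
    i0 = int(round((start_s - series.origin_s) / w))
    i1 = int(round((end_s - series.origin_s) / w))
    if i0 < 0 or i1 > series.n_bins or i1 <= i0:
        raise ValueError("interval outside the series extent")
    return slice(i0, i1)


def interval_auc(
    series: ActivitySeries,
    interval: LightInterval | tuple[float, float],
    label: str | None = None,
    rule: str = "sum",
) -> IntervalMetric:
    """Activity AUC over one interval: sum of bin distances with bin start in
    [start, end). ``rule='trapezoid'`` integrates the per-bin curve instead.

    Flagged (gap) bins contribute 0 and are counted in ``n_flagged``.
    """
    if isinstance(interval, LightInterval):
        start_s, end_s = interval.start_s, interval.end_s
        if label is None:
            label = interval.condition
    else:
        start_s, end_s = interval
        if label is None:
            label = f"[{start_s},{end_s})"
    sl = _bin_slice(series, start_s, end_s)
    vals = series.distance_mm[sl]
    if rule == "sum":
        auc = float(vals.sum())
    elif rule == "trapezoid":
        auc = float(np.trapezoid(vals)) if vals.size > 1 else float(vals.sum())
    else:
        raise ValueError(f"unknown AUC rule {rule!r}")
    return IntervalMetric(
        label=label,
        start_s=start_s,
        end_s=end_s,
        auc_mm=auc,
        n_bins=int(vals.size),
        n_flagged=int(series.flagged[sl].sum()),
        subject_id=series.subject_id,
    )


def condition_aggregate(
    series: ActivitySeries,
    schedule: LightSchedule,
    include_acclimation: bool = False,
    rule: str = "sum",
) -> dict[str, IntervalMetric]:
    """Total AUC per light condition, pooled over all intervals sharing the
    condition label. Acclimation intervals are excluded unless requested."""
    intervals = (
        schedule.intervals if include_acclimation else schedule.analysis_intervals
    )
    if not intervals:
        raise ValueError("schedule has no analysis intervals")
    totals: dict[str, list[IntervalMetric]] = {}
    for iv in intervals:
        m = interval_auc(series, iv, rule=rule)
        totals.setdefault(iv.condition, []).append(m)
    out: dict[str, IntervalMetric] = {}
    for cond, ms in totals.items():
        out[cond] = IntervalMetric(
            label=cond,
            start_s=min(m.start_s for m in ms),
            end_s=max(m.end_s for m in ms),
            auc_mm=float(sum(m.auc_mm for m in ms)),
            n_bins=int(sum(m.n_bins for m in ms)),
            n_flagged=int(sum(m.n_flagged for m in ms)),
            subject_id=series.subject_id,
        )
    return out


def normalized_dark_response(
    series: ActivitySeries,
    schedule: LightSchedule,
    response_window_s: float = 120.0,
    baseline_window_s: float = 300.0,
    transition_index: int = 0,
) -> DarkResponse:
    """Fast dark-photokinesis response normalized to preceding darkness.

    For the selected light-to-dark transition, returns

        mean per-bin distance in the first ``response_window_s`` after light
        cessation / mean per-bin distance during the last
        ``baseline_window_s`` of the dark interval preceding that light
        interval.

    The baseline darkness may be the flagged acclimation interval. A zero
    baseline yields ``defined=False`` with a NaN value rather than an
    exception. The ratio is invariant under rescaling all distances.
    """
    transitions = schedule.light_to_dark_transitions()
    if not transitions:
        raise ValueError("schedule has no light-to-dark transition")
    t_off = transitions[transition_index]

    # the lit interval that ends at t_off, and the darkness preceding it
    lit = next(iv for iv in schedule.intervals if iv.end_s == t_off)
    preceding_dark = [
        iv for iv in schedule.intervals if iv.is_dark and iv.end_s <= lit.start_s
    ]
    if not preceding_dark:
        raise ValueError("no preceding darkness before the analyzed transition")
    base_iv = preceding_dark[-1]
    if base_iv.duration_s + 1e-9 < baseline_window_s:
        raise ValueError(
            f"preceding darkness ({base_iv.duration_s} s) shorter than the "
            f"{baseline_window_s} s baseline window"
        )

    resp = series.distance_mm[_bin_slice(series, t_off, t_off + response_window_s)]
    base = series.distance_mm[
        _bin_slice(series, base_iv.end_s - baseline_window_s, base_iv.end_s)
    ]
    resp_mean = float(resp.mean())
    base_mean = float(base.mean())
    if base_mean == 0.0:
        return DarkResponse(
            value=float("nan"),
            defined=False,
            transition_s=t_off,
            response_mean_mm=resp_mean,
            baseline_mean_mm=base_mean,
        )
    return DarkResponse(
        value=resp_mean / base_mean,
        defined=True,
        transition_s=t_off,
        response_mean_mm=resp_mean,
        baseline_mean_mm=base_mean,
    )


def lights_on_windows(
    series: ActivitySeries,
    schedule: LightSchedule,
    windows_s: Sequence[float] = (30 * 60.0, 90 * 60.0),
    rule: str = "sum",
) -> list[IntervalMetric]:
    """AUC of the first N minutes after every dark-to-light transition.

    For the default windows this yields, per transition (one per day in a
    photoperiod schedule), the 30-min and 90-min lights-on activity. Windows
    must fit inside the lit interval they open.
    """
    transitions = schedule.dark_to_light_transitions()
    if not transitions:
        raise ValueError("schedule has no dark-to-light transition")
    out: list[IntervalMetric] = []
    for day, t_on in enumerate(transitions, start=1):
        lit = next(iv for iv in schedule.intervals if iv.start_s == t_on)
        for w in windows_s:
            if t_on + w > lit.end_s + 1e-9:
                raise ValueError(
                    f"{w} s window exceeds the lit interval starting at {t_on} s"
                )
            m = interval_auc(
                series,
                (t_on, t_on + w),
                label=f"lights_on_{int(round(w / 60))}min_day{day}",
                rule=rule,
            )
            out.append(m)
    return out
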