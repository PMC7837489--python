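"""Avoidance-index scoring of dot-interaction events.

Each dot presentation is scored approach / avoidance / neutral. The avoidance
index for one subject at one dot size is

    AI = (n_avoidance - n_approach) / n_total

with neutrals counted in the denominator, so AI lies in [-1, 1]. Cohort
curves average per-subject AIs (mean +/- SEM) per size; "total avoidance" is
the trapezoidal area of the AI-versus-size curve over the measured size range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

OUTCOMES = ("approach", "avoidance", "neutral")

#: canonical event-table columns
EVENT_COLUMNS = ["subject_id", "genotype", "size_deg", "presentation_index", "outcome"]


@dataclass(frozen=True)
class InteractionEvent:
    """One dot presentation's scored outcome."""

    subject_id: str
    genotype: str
    size_deg: float
    presentation_index: int
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(
                f"outcome {self.outcome!r} not one of {OUTCOMES}"
            )
        if not 0 < self.size_deg < 180:
            raise ValueError("size_deg must lie in (0, 180)")


@dataclass(frozen=True)
class AvoidanceCurve:
    """Per-size cohort summary of avoidance indices."""

    points: pd.DataFrame  # columns: size_deg, mean_ai, sem, n

    def __post_init__(self) -> None:
        pts = self.points
        required = {"size_deg", "mean_ai", "sem", "n"}
        if not required.issubset(pts.columns):
            raise ValueError(f"curve needs columns {sorted(required)}")
        if not pts["size_deg"].is_monotonic_increasing:
            raise ValueError("sizes must be increasing")
        if ((pts["mean_ai"] < -1) | (pts["mean_ai"] > 1)).any():
            raise ValueError("mean AI out of [-1, 1]")

    @property
    def sizes_deg(self) -> np.ndarray:
        return self.points["size_deg"].to_numpy()

    @property
    def mean_ai(self) -> np.ndarray:
        return self.points["mean_ai"].to_numpy()


def avoidance_index(outcomes: Iterable[str]) -> float:
    """AI of one subject at one size from its scored outcomes."""
    outs = list(outcomes)
    if not outs:
        raise ValueError("avoidance index undefined for an empty event list")
    bad = set(outs) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcomes: {sorted(bad)}")
    n_avoid = sum(o == "avoidance" for o in outs)
    n_approach = sum(o == "approach" for o in outs)
    return (n_avoid - n_approach) / len(outs)


def events_to_frame(events: Iterable[InteractionEvent]) -> pd.DataFrame:
    """Materialize events as the canonical long-format table."""
    rows = [
        (e.subject_id, e.genotype, e.size_deg, e.presentation_index, e.outcome)
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def subject_ai_table(events: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-size AI table (columns subject_id, size_deg, ai).

    Genotype is carried through when present.
    """
    if events.empty:
        raise ValueError("no events")
    keys = ["subject_id", "size_deg"]
    if "genotype" in events.columns:
        keys = ["subject_id", "genotype", "size_deg"]
    out = (
        events.groupby(keys, sort=True)["outcome"]
        .apply(avoidance_index)
        .rename("ai")
        .reset_index()
    )
    return out


def tuning_curve(events: pd.DataFrame) -> AvoidanceCurve:
    """Cohort size-tuning curve: mean per-subject AI per size, with SEM.

    SEM = sample sd / sqrt(n); with a single subject at a size the SEM is
    reported as 0 and n = 1 marks the point as degenerate. Subjects with no
    events at a size simply do not contribute to that point's n.
    """
    per_subject = subject_ai_table(events)
    g = per_subject.groupby("size_deg")["ai"]
    pts = g.agg(mean_ai="mean", n="count").reset_index()
    sd = g.std(ddof=1).reset_index(drop=True)
    pts["sem"] = (sd / np.sqrt(pts["n"])).fillna(0.0)
    pts = pts[["size_deg", "mean_ai", "sem", "n"]].sort_values("size_deg")
    return AvoidanceCurve(points=pts.reset_index(drop=True))


def total_avoidance(sizes_deg: Sequence[float], ai: Sequence[float]) -> float:
    """Area under an AI-versus-size curve (trapezoid rule, degree*AI units)."""
    sizes = np.asarray(sizes_deg, dtype=float)
    vals = np.asarray(ai, dtype=float)
    if sizes.size != vals.size:
        raise ValueError("sizes and AI values have different lengths")
    if sizes.size < 2:
        raise ValueError("area undefined: need at least two dot sizes")
    if not np.all(np.diff(sizes) > 0):
        raise ValueError("sizes must be strictly increasing")
    return float(np.trapezoid(vals, sizes))


def subject_total_avoidance(events: pd.DataFrame) -> pd.DataFrame:
    """Per-subject total avoidance (area of each subject's own AI curve).

    Returns columns (subject_id[, genotype], total_avoidance). Subjects seen
    at fewer than two sizes are dropped (their area is undefined).
    """
    per_subject = subject_ai_table(events)
    keys = ["subject_id"]
    if "genotype" in per_subject.columns:
        keys = ["subject_id", "genotype"]
    rows = []
    for key, grp in per_subject.groupby(keys):
        grp = grp.sort_values("size_deg")
        if len(grp) < 2:
            continue
        area = total_avoidance(grp["size_deg"].to_numpy(), grp["ai"].to_numpy())
        rows.append((*key, area) if isinstance(key, tuple) else (key, area))
    return pd.DataFrame(rows, columns=[*keys, "total_avoidance"])
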