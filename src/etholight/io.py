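"""Readers and writers for the plain-text interchange formats.

All tables are UTF-8 CSV with a single header row and '.' decimal separator;
nested structures (schedules, trial plans, run provenance) are JSON. Every
reader validates the invariants of the type it builds and raises
``FormatError`` naming the file and the violated constraint.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from etholight.avoidance import EVENT_COLUMNS, OUTCOMES
from etholight.expression import WELL_COLUMNS
from etholight.lightfield import LightInterval, LightSchedule, Spectrum
from etholight.locomotor import ActivitySeries, IntervalMetric, Trajectory
from etholight.stimulus import TrialPlan


class FormatError(ValueError):
    """A file does not satisfy its format contract."""

    def __init__(self, path, message: str):
        super().__init__(f"{path}: {message}")
        self.path = str(path)


def _read_csv(path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(path, f"unreadable CSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(path, f"missing columns {sorted(missing)}")
    return df


# -- spectra ---------------------------------------------------------------

def read_spectrum(path, label: str | None = None) -> Spectrum:
    df = _read_csv(path, ["wavelength_nm", "irradiance_W_m2_nm"])
    try:
        return Spectrum(
            wavelength_nm=df["wavelength_nm"].to_numpy(float),
            irradiance=df["irradiance_W_m2_nm"].to_numpy(float),
            label=label if label is not None else Path(path).stem,
        )
    except ValueError as exc:
        raise FormatError(path, str(exc)) from exc


def write_spectrum(path, spectrum: Spectrum) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelength_nm,
            "irradiance_W_m2_nm": spectrum.irradiance,
        }
    ).to_csv(path, index=False)


# -- schedules -------------------------------------------------------------

def read_schedule(path) -> LightSchedule:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(path, f"invalid JSON at line {exc.lineno}") from exc
    try:
        intervals = tuple(
            LightInterval(
                start_s=float(iv["start_s"]),
                end_s=float(iv["end_s"]),
                condition=iv["condition"],
                intensity=float(iv.get("intensity", 1.0)),
                acclimation=bool(iv.get("acclimation", False)),
            )
            for iv in payload["intervals"]
        )
        return LightSchedule(intervals, origin_zt=float(payload.get("origin_zt", 0.0)))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(path, f"invalid schedule ({exc})") from exc


def write_schedule(path, schedule: LightSchedule) -> None:
    payload = {
        "origin_zt": schedule.origin_zt,
        "intervals": [
            {
                "start_s": iv.start_s,
                "end_s": iv.end_s,
                "condition": iv.condition,
                "intensity": iv.intensity,
                "acclimation": iv.acclimation,
            }
            for iv in schedule.intervals
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# -- trial plans -----------------------------------------------------------

def read_trial_plan(path) -> TrialPlan:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        return TrialPlan(
            blocks=tuple((float(s), int(r)) for s, r in payload["blocks"]),
            order_mode=payload["order_mode"],
            gap_s=float(payload.get("gap_s", 19.0)),
            seed=payload.get("seed"),
        )
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(path, f"invalid trial plan ({exc})") from exc


def write_trial_plan(path, plan: TrialPlan) -> None:
    payload = {
        "blocks": [[s, r] for s, r in plan.blocks],
        "order_mode": plan.order_mode,
        "gap_s": plan.gap_s,
        "seed": plan.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# -- interaction events ----------------------------------------------------

def read_events(path) -> pd.DataFrame:
    df = _read_csv(path, EVENT_COLUMNS)
    bad = set(df["outcome"].unique()) - set(OUTCOMES)
    if bad:
        raise FormatError(path, f"unknown outcomes {sorted(bad)}")
    return df[EVENT_COLUMNS]


def write_events(path, events: pd.DataFrame) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


# -- trajectories ----------------------------------------------------------

TRAJECTORY_COLUMNS = ["subject_id", "genotype", "t_s", "x_mm", "y_mm"]


def read_trajectories(path) -> list[Trajectory]:
    """Read a multi-subject trajectory table into one Trajectory per subject.

    Missing coordinates may be blank (NaN); timestamps must be present and
    strictly increasing within a subject.
    """
    df = _read_csv(path, ["subject_id", "t_s", "x_mm", "y_mm"])
    if df.empty:
        raise FormatError(path, "trajectory file contains no frames")
    if "genotype" not in df.columns:
        df["genotype"] = ""
    out = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        try:
            out.append(
                Trajectory(
                    t_s=grp["t_s"].to_numpy(float),
                    x_mm=grp["x_mm"].to_numpy(float),
                    y_mm=grp["y_mm"].to_numpy(float),
                    subject_id=str(subject_id),
                    genotype=str(grp["genotype"].iloc[0]),
                )
            )
        except ValueError as exc:
            raise FormatError(path, f"subject {subject_id}: {exc}") from exc
    return out


def write_trajectories(path, trajectories: Iterable[Trajectory]) -> None:
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": traj.subject_id,
                    "genotype": traj.genotype,
                    "t_s": traj.t_s,
                    "x_mm": traj.x_mm,
                    "y_mm": traj.y_mm,
                }
            )
        )
    pd.concat(frames, ignore_index=True)[TRAJECTORY_COLUMNS].to_csv(
        path, index=False, float_format="%.6f"
    )


# -- activity series and metrics -------------------------------------------

def write_activity(path, series_list: Iterable[ActivitySeries]) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "bin_start_s": s.bin_starts_s,
                    "distance_mm": s.distance_mm,
                    "flagged": s.flagged.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def metrics_frame(metrics: Iterable[IntervalMetric]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "label": m.label,
                "start_s": m.start_s,
                "end_s": m.end_s,
                "auc_mm": m.auc_mm,
                "n_bins": m.n_bins,
                "n_flagged": m.n_flagged,
            }
            for m in metrics
        ]
    )


def write_metrics(path, metrics: Iterable[IntervalMetric]) -> None:
    metrics_frame(metrics).to_csv(path, index=False)


# -- qPCR ------------------------------------------------------------------

def read_qpcr(path) -> pd.DataFrame:
    df = _read_csv(path, WELL_COLUMNS)
    ct = df["ct"].astype(float)
    if ((ct <= 0) | (ct >= 45)).any():
        raise FormatError(path, "Ct values must lie in (0, 45)")
    return df[WELL_COLUMNS]


def write_qpcr(path, wells: pd.DataFrame) -> None:
    wells[WELL_COLUMNS].to_csv(path, index=False)


# -- grouped samples for the stats CLI -------------------------------------

def read_sample_table(path) -> pd.DataFrame:
    df = _read_csv(path, ["subject_id", "group", "value"])
    if df["group"].nunique() != 2:
        raise FormatError(path, "stats input must contain exactly two groups")
    if not np.all(np.isfinite(df["value"].astype(float))):
        raise FormatError(path, "non-finite values in 'value' column")
    return df
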