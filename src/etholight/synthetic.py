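"""Synthetic cohorts with the statistical structure the analyses assume.

Swimming is a two-state (rest/move) continuous-time Markov chain whose
rest-to-move rate depends on the current light condition; genotype effects
multiply those condition-specific rates. In the move state the fish advances
at a per-bout log-normal speed along a persistent-turning heading inside a
rectangular arena (positions are folded back at the walls). Dot-trial
outcomes follow a log-size logistic avoidance probability with multiplicative
habituation; qPCR plates follow Ct = base_ct - log2(expression) + noise.

All generators draw from ``numpy.random.default_rng`` seeded with
``(seed, *stream, subject_index)`` so cohorts are order-independent and
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from etholight.avoidance import EVENT_COLUMNS
from etholight.expression import DEFAULT_REFERENCE_GENE
from etholight.lightfield import LightSchedule
from etholight.locomotor import Trajectory, condition_aggregate, distance_series
from etholight.stats_engine import compare_groups
from etholight.stimulus import TrialPlan


@dataclass(frozen=True)
class SwimModel:
    """Two-state swim kinetics and move-state speed distribution."""

    rate_rest_to_move: dict  # condition -> s^-1 (>= 0)
    rate_move_to_rest: float = 0.5  # s^-1 (>= 0)
    speed_log_mu: float = 1.0  # log of median speed, mm/s
    speed_log_sigma: float = 0.4
    turn_sd_rad: float = 0.35  # per-frame heading diffusion

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rate_rest_to_move.values()):
            raise ValueError("rest-to-move rates must be >= 0")
        if self.rate_move_to_rest < 0:
            raise ValueError("move-to-rest rate must be >= 0")
        if self.speed_log_sigma < 0:
            raise ValueError("speed sigma must be >= 0")

    def mean_speed(self) -> float:
        """E[speed] of the log-normal bout speed, mm/s."""
        return math.exp(self.speed_log_mu + self.speed_log_sigma**2 / 2.0)


@dataclass(frozen=True)
class GenotypeEffect:
    """How a genotype perturbs the simulators."""

    #: condition -> multiplier on the rest-to-move rate
    activity_multiplier: dict = field(default_factory=dict)
    #: additive shift of log(theta0) in the avoidance model
    log_theta0_shift: float = 0.0
    #: multiplier on the maximal avoidance probability
    avoid_max_scale: float = 1.0

    def rate_factor(self, condition: str) -> float:
        return float(self.activity_multiplier.get(condition, 1.0))


@dataclass(frozen=True)
class AvoidanceModel:
    """Size-tuned categorical outcome model for dot presentations.

    P(avoid) = avoid_max * sigmoid(slope * (ln theta - ln theta0)) * h**k
    P(approach) = approach_max * sigmoid(-slope * (ln theta - ln theta0))

    where k counts prior presentations of dots at least as large as
    ``habituation_threshold_deg`` (theta0 when unset) and h in (0, 1] is the
    habituation factor.
    """

    theta0_deg: float = 25.0
    slope: float = 3.0
    avoid_max: float = 0.8
    approach_max: float = 0.35
    habituation: float = 1.0
    habituation_threshold_deg: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.habituation <= 1:
            raise ValueError("habituation factor must lie in (0, 1]")
        if not (0 <= self.avoid_max <= 1 and 0 <= self.approach_max <= 1):
            raise ValueError("probability caps must lie in [0, 1]")
        if self.theta0_deg <= 0:
            raise ValueError("theta0 must be positive")


@dataclass(frozen=True)
class QpcrModel:
    """Ct generation: base_ct - log2(expression) + N(0, noise_sd)."""

    base_ct: float = 22.0
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _default_swim() -> SwimModel:
    return SwimModel(
        rate_rest_to_move={"dark": 0.05, "white": 0.03, "blue": 0.03,
                           "green": 0.03, "red": 0.03},
        rate_move_to_rest=1.0,
        speed_log_mu=1.0,
        speed_log_sigma=0.4,
    )


@dataclass(frozen=True)
class SimConfig:
    """Everything the generators need, plus the master seed."""

    seed: int
    n_subjects: int = 12
    frame_rate_hz: float = 60.0
    arena_mm: tuple[float, float] = (35.0, 35.0)
    swim: SwimModel = field(default_factory=_default_swim)
    avoidance: AvoidanceModel = field(default_factory=AvoidanceModel)
    qpcr: QpcrModel = field(default_factory=QpcrModel)
    genotype_effects: dict = field(
        default_factory=lambda: {"wt": GenotypeEffect()}
    )

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    def effect(self, genotype: str) -> GenotypeEffect:
        return self.genotype_effects.get(genotype, GenotypeEffect())


def _rng(config: SimConfig, stream: tuple[int, ...], subject_index: int):
    return np.random.default_rng((int(config.seed), *map(int, stream),
                                  int(subject_index)))


def _fold(p: np.ndarray, width: float) -> np.ndarray:
    """Reflect coordinates into [0, width] (triangle-wave folding)."""
    q = np.mod(p, 2.0 * width)
    return np.where(q <= width, q, 2.0 * width - q)


def _simulate_bouts(config, schedule, effect, rng):
    """Event-driven rest/move segments: (start_times, states) arrays.

    Exponential dwell times are truncated at schedule-interval boundaries and
    redrawn (valid by memorylessness), so condition-dependent rates switch
    exactly at the boundaries.
    """
    swim = config.swim
    t0, t1 = schedule.start_s, schedule.end_s
    starts = [t0]
    states = [0]  # 0 = rest, 1 = move
    t, state = t0, 0
    while t < t1 - 1e-12:
        iv = schedule.interval_at(t)
        if state == 0:
            cond = iv.condition
            rate = swim.rate_rest_to_move.get(cond, 0.0) * effect.rate_factor(cond)
        else:
            rate = swim.rate_move_to_rest
        dwell = math.inf if rate <= 0 else rng.exponential(1.0 / rate)
        boundary = iv.end_s
        if t + dwell >= boundary:
            if boundary >= t1:
                break
            t = boundary  # same state continues into the next interval
        else:
            t = t + dwell
            state = 1 - state
            starts.append(t)
            states.append(state)
    return np.asarray(starts), np.asarray(states)


def simulate_trajectory(
    config: SimConfig,
    schedule: LightSchedule,
    subject_index: int = 0,
    genotype: str = "wt",
    stream: tuple[int, ...] = (),
) -> Trajectory:
    """One subject's frame-level trajectory over the whole schedule."""
    effect = config.effect(genotype)
    rng = _rng(config, (0, *stream), subject_index)
    starts, states = _simulate_bouts(config, schedule, effect, rng)

    fps = config.frame_rate_hz
    t0 = schedule.start_s
    n_frames = int(round(schedule.total_duration_s * fps)) + 1
    ft = t0 + np.arange(n_frames) / fps

    seg = np.searchsorted(starts, ft, side="right") - 1
    bout_speed = np.where(
        states == 1,
        rng.lognormal(config.swim.speed_log_mu, config.swim.speed_log_sigma,
                      states.size),
        0.0,
    )
    frame_speed = bout_speed[seg]

    heading = rng.uniform(0, 2 * np.pi) + np.cumsum(
        rng.normal(0.0, config.swim.turn_sd_rad, n_frames)
    )
    step = frame_speed / fps
    dx = step * np.cos(heading)
    dy = step * np.sin(heading)
    w, h = config.arena_mm
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    x[0] = rng.uniform(0, w)
    y[0] = rng.uniform(0, h)
    # frame i's step is taken between frame i and i+1
    x[1:] = x[0] + np.cumsum(dx[:-1])
    y[1:] = y[0] + np.cumsum(dy[:-1])
    x = _fold(x, w)
    y = _fold(y, h)

    return Trajectory(
        t_s=ft,
        x_mm=x,
        y_mm=y,
        subject_id=f"{genotype}_{subject_index:03d}",
        genotype=genotype,
        arena_id=f"arena_{subject_index % 6}",
        frame_rate_hz=fps,
    )


def simulate_cohort(
    config: SimConfig,
    schedule: LightSchedule,
    genotype: str = "wt",
    n_subjects: int | None = None,
    stream: tuple[int, ...] = (),
) -> list[Trajectory]:
    """Independent trajectories for one genotype cohort."""
    n = config.n_subjects if n_subjects is None else n_subjects
    return [
        simulate_trajectory(config, schedule, i, genotype, stream=stream)
        for i in range(n)
    ]


def move_occupancy(config: SimConfig, condition: str,
                   genotype: str = "wt") -> float:
    """Long-run probability of the move state under one condition:
    r_on / (r_on + r_off)."""
    effect = config.effect(genotype)
    r_on = config.swim.rate_rest_to_move.get(condition, 0.0)
    r_on *= effect.rate_factor(condition)
    r_off = config.swim.rate_move_to_rest
    if r_on == 0:
        return 0.0
    if r_off == 0:
        return 1.0
    return r_on / (r_on + r_off)


def expected_distance(config: SimConfig, schedule: LightSchedule,
                      condition: str, genotype: str = "wt") -> float:
    """Closed-form expected distance in one condition over the analysis
    intervals: occupancy x mean bout speed x condition duration."""
    dur = sum(
        iv.duration_s for iv in schedule.analysis_intervals
        if iv.condition == condition
    )
    return move_occupancy(config, condition, genotype) * config.swim.mean_speed() * dur


def _presentation_probs(config: SimConfig, plan: TrialPlan,
                        genotype: str) -> pd.DataFrame:
    """Per-presentation avoid/approach probabilities (the simulator's own
    closed form, also used as the oracle for convergence checks)."""
    model = config.avoidance
    effect = config.effect(genotype)
    theta0 = model.theta0_deg * math.exp(effect.log_theta0_shift)
    avoid_max = min(1.0, model.avoid_max * effect.avoid_max_scale)
    threshold = (model.habituation_threshold_deg
                 if model.habituation_threshold_deg is not None else theta0)
    rows = []
    k = 0
    for block, pres, size in plan.presentations():
        z = model.slope * (math.log(size) - math.log(theta0))
        p_avoid = avoid_max * float(expit(z)) * model.habituation**k
        p_approach = model.approach_max * float(expit(-z))
        rows.append((block, pres, size, p_avoid, p_approach))
        if size >= threshold:
            k += 1
    return pd.DataFrame(
        rows, columns=["block", "presentation_index", "size_deg",
                       "p_avoid", "p_approach"]
    )


def expected_ai_by_size(config: SimConfig, plan: TrialPlan,
                        genotype: str = "wt") -> pd.DataFrame:
    """E[AI] per dot size implied by the outcome model for this plan."""
    probs = _presentation_probs(config, plan, genotype)
    probs["e_ai"] = probs["p_avoid"] - probs["p_approach"]
    return (
        probs.groupby("size_deg")["e_ai"].mean().reset_index()
        .sort_values("size_deg").reset_index(drop=True)
    )


def simulate_avoidance_trial(
    config: SimConfig,
    plan: TrialPlan,
    subject_index: int = 0,
    genotype: str = "wt",
    stream: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Scored dot-interaction events of one subject for one trial plan."""
    rng = _rng(config, (1, *stream), subject_index)
    probs = _presentation_probs(config, plan, genotype)
    u = rng.random(len(probs))
    outcome = np.where(
        u < probs["p_avoid"],
        "avoidance",
        np.where(u < probs["p_avoid"] + probs["p_approach"],
                 "approach", "neutral"),
    )
    return pd.DataFrame(
        {
            "subject_id": f"{genotype}_{subject_index:03d}",
            "genotype": genotype,
            "size_deg": probs["size_deg"],
            "presentation_index": probs["presentation_index"],
            "outcome": outcome,
        }
    )[EVENT_COLUMNS]


def simulate_avoidance_cohort(
    config: SimConfig,
    plan: TrialPlan,
    genotype: str = "wt",
    n_subjects: int | None = None,
    stream: tuple[int, ...] = (),
) -> pd.DataFrame:
    n = config.n_subjects if n_subjects is None else n_subjects
    frames = [
        simulate_avoidance_trial(config, plan, i, genotype, stream=stream)
        for i in range(n)
    ]
    return pd.concat(frames, ignore_index=True)


def simulate_qpcr(
    config: SimConfig,
    expression_by_group: dict,
    n_samples: int = 4,
    replicates: int = 2,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    stream: tuple[int, ...] = (),
) -> pd.DataFrame:
    """A qPCR well table for a group design.

    ``expression_by_group`` maps group label -> {gene: relative expression};
    the reference gene is added at expression 1.0 when absent. Technical
    replicates share one biological expression value and differ only by
    measurement noise.
    """
    rows = []
    for gi, (group, genes) in enumerate(sorted(expression_by_group.items())):
        genes = dict(genes)
        genes.setdefault(reference_gene, 1.0)
        rng = _rng(config, (2, *stream), gi)
        for s in range(n_samples):
            sample_id = f"{group}_{s:02d}"
            for gene, expr in sorted(genes.items()):
                if expr <= 0:
                    raise ValueError("expression must be positive")
                true_ct = config.qpcr.base_ct - math.log2(expr)
                for rep in range(1, replicates + 1):
                    ct = true_ct + rng.normal(0.0, config.qpcr.noise_sd)
                    rows.append((sample_id, group, gene, rep, ct))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene", "replicate", "ct"]
    )


def dark_auc_per_subject(
    config: SimConfig,
    schedule: LightSchedule,
    genotype: str,
    n_subjects: int,
    stream: tuple[int, ...],
    bin_width_s: float = 10.0,
) -> np.ndarray:
    """Full pipeline per subject: simulate -> bin -> per-condition AUC,
    returning each subject's total dark-interval AUC."""
    out = np.empty(n_subjects)
    for i in range(n_subjects):
        traj = simulate_trajectory(config, schedule, i, genotype, stream=stream)
        series = distance_series(
            traj, bin_width_s, origin_s=schedule.start_s, end_s=schedule.end_s
        )
        totals = condition_aggregate(series, schedule)
        out[i] = totals["dark"].auc_mm if "dark" in totals else 0.0
    return out


def implied_dark_ratio(config: SimConfig, mutant: str, wildtype: str = "wt") -> float:
    """Closed-form mutant/wildtype expected dark-activity ratio
    (occupancy ratio; bout speeds are genotype-independent)."""
    occ_m = move_occupancy(config, "dark", mutant)
    occ_w = move_occupancy(config, "dark", wildtype)
    if occ_w == 0:
        raise ValueError("wild-type dark occupancy is zero")
    return occ_m / occ_w


def recovery_experiment(
    config: SimConfig,
    schedule: LightSchedule,
    mutant: str = "mut",
    wildtype: str = "wt",
    n_per_group: int | None = None,
    n_replicates: int = 50,
    alpha: float = 0.05,
    bin_width_s: float = 10.0,
) -> dict:
    """Parameter-recovery report over replicate simulated cohorts.

    Each replicate simulates a wild-type and a mutant cohort, runs the
    locomotor pipeline to per-subject dark AUCs, estimates the mutant/wild-type
    dark-activity ratio, and applies the gated two-sample comparison. Returns
    the mean estimated ratio, the closed-form ratio implied by the configured
    rates, and the empirical power (fraction of replicates with p <= alpha).
    """
    n = config.n_subjects if n_per_group is None else n_per_group
    ratios = np.empty(n_replicates)
    rejected = 0
    for r in range(n_replicates):
        wt = dark_auc_per_subject(config, schedule, wildtype, n,
                                  stream=(r, 0), bin_width_s=bin_width_s)
        mu = dark_auc_per_subject(config, schedule, mutant, n,
                                  stream=(r, 1), bin_width_s=bin_width_s)
        ratios[r] = mu.mean() / wt.mean()
        report = compare_groups(mu, wt)
        if report.p_two_tailed <= alpha:
            rejected += 1
    return {
        "n_per_group": n,
        "n_replicates": n_replicates,
        "ratio_estimate": float(ratios.mean()),
        "ratio_se": float(ratios.std(ddof=1) / math.sqrt(n_replicates)),
        "implied_ratio": implied_dark_ratio(config, mutant, wildtype),
        "power": rejected / n_replicates,
        "alpha": alpha,
    }
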