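import numpy as np
import pytest

from etholight.lightfield import diel_schedule, photokinesis_schedule
from etholight.locomotor import ActivitySeries
from etholight.stimulus import make_trial_plan
from etholight.synthetic import GenotypeEffect, SimConfig


@pytest.fixture
def photok_schedule():
    """5 min dark acclimation + 3 x (30 min white + 30 min dark)."""
    return photokinesis_schedule()


@pytest.fixture
def two_day_schedule():
    """2 days of 8 h dark + 16 h blue light, starting at lights-off."""
    return diel_schedule()


@pytest.fixture
def standard_plan():
    return make_trial_plan([5, 10, 20, 30, 40, 60, 80], "ascending")


@pytest.fixture
def sim_config():
    return SimConfig(
        seed=11,
        n_subjects=6,
        frame_rate_hz=5.0,
        genotype_effects={
            "wt": GenotypeEffect(),
            "mut": GenotypeEffect(activity_multiplier={"dark": 1.5}),
        },
    )


def constant_series(schedule, bin_width_s, per_bin_mm, subject_id="s1"):
    """An ActivitySeries with the same distance in every bin of a schedule."""
    n = int(round(schedule.total_duration_s / bin_width_s))
    return ActivitySeries(
        bin_width_s=bin_width_s,
        origin_s=schedule.start_s,
        distance_mm=np.full(n, float(per_bin_mm)),
        flagged=np.zeros(n, dtype=bool),
        subject_id=subject_id,
    )


@pytest.fixture
def make_constant_series():
    return constant_series
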