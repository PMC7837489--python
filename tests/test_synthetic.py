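import numpy as np
import pandas as pd
import pytest

from etholight.avoidance import tuning_curve
from etholight.expression import fold_change, relative_expression
from etholight.lightfield import build_schedule
from etholight.locomotor import distance_series
from etholight.stimulus import make_trial_plan
from etholight.synthetic import (
    AvoidanceModel,
    GenotypeEffect,
    QpcrModel,
    SimConfig,
    SwimModel,
    expected_ai_by_size,
    expected_distance,
    implied_dark_ratio,
    move_occupancy,
    recovery_experiment,
    simulate_avoidance_cohort,
    simulate_avoidance_trial,
    simulate_qpcr,
    simulate_trajectory,
)


def config_with(swim, **kwargs):
    return SimConfig(seed=kwargs.pop("seed", 1), swim=swim, **kwargs)


class TestTrajectorySimulator:
    def test_zero_onset_rate_means_zero_distance(self):
        swim = SwimModel(rate_rest_to_move={"dark": 0.0, "white": 0.0})
        cfg = config_with(swim, frame_rate_hz=10.0)
        sched = build_schedule([(120.0, "white"), (120.0, "dark")])
        traj = simulate_trajectory(cfg, sched)
        assert np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm)).sum() == 0.0

    def test_seed_reproducibility(self, sim_config, photok_schedule):
        a = simulate_trajectory(sim_config, photok_schedule, 3, "wt")
        b = simulate_trajectory(sim_config, photok_schedule, 3, "wt")
        np.testing.assert_array_equal(a.x_mm, b.x_mm)
        np.testing.assert_array_equal(a.y_mm, b.y_mm)

    def test_subjects_are_independent_streams(self, sim_config, photok_schedule):
        a = simulate_trajectory(sim_config, photok_schedule, 0, "wt")
        b = simulate_trajectory(sim_config, photok_schedule, 1, "wt")
        assert not np.array_equal(a.x_mm, b.x_mm)

    def test_pure_move_total_distance_matches_mean_speed(self):
        # near-certain move occupancy, many bouts, huge arena so the walls
        # never shorten steps: total distance ~ E[speed] * T
        swim = SwimModel(
            rate_rest_to_move={"white": 1e5},
            rate_move_to_rest=1.0,
            speed_log_mu=1.0,
            speed_log_sigma=0.3,
        )
        cfg = SimConfig(seed=2, frame_rate_hz=10.0, arena_mm=(1e6, 1e6), swim=swim)
        sched = build_schedule([(600.0, "white")])
        totals = []
        for i in range(12):
            traj = simulate_trajectory(cfg, sched, i)
            totals.append(np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm)).sum())
        totals = np.asarray(totals)
        expected = swim.mean_speed() * 600.0
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - expected) < 3 * se

    def test_move_occupancy_converges(self):
        swim = SwimModel(rate_rest_to_move={"white": 0.2}, rate_move_to_rest=0.6)
        cfg = SimConfig(seed=3, frame_rate_hz=10.0, swim=swim)
        sched = build_schedule([(3000.0, "white")])
        occs = []
        for i in range(10):
            traj = simulate_trajectory(cfg, sched, i)
            steps = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))
            occs.append((steps > 0).mean())
        occs = np.asarray(occs)
        expected = move_occupancy(cfg, "white")
        assert expected == pytest.approx(0.25)
        se = occs.std(ddof=1) / np.sqrt(occs.size)
        assert abs(occs.mean() - expected) < 3 * se

    def test_condition_modulates_activity(self, sim_config, photok_schedule):
        # dark onset rate > light onset rate in the default model: pipeline
        # distance should follow the closed form occupancy * speed * time
        dists = {"white": [], "dark": []}
        from etholight.locomotor import condition_aggregate

        for i in range(8):
            traj = simulate_trajectory(sim_config, photok_schedule, i, "wt")
            s = distance_series(traj, 10.0, origin_s=0.0, end_s=photok_schedule.end_s)
            totals = condition_aggregate(s, photok_schedule)
            for c in dists:
                dists[c].append(totals[c].auc_mm)
        for cond in dists:
            vals = np.asarray(dists[cond])
            expected = expected_distance(sim_config, photok_schedule, cond)
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - expected) < 4 * se

    def test_positions_stay_in_arena(self, sim_config, photok_schedule):
        traj = simulate_trajectory(sim_config, photok_schedule, 0, "wt")
        w, h = sim_config.arena_mm
        assert traj.x_mm.min() >= 0 and traj.x_mm.max() <= w
        assert traj.y_mm.min() >= 0 and traj.y_mm.max() <= h


class TestAvoidanceSimulator:
    def test_seed_reproducibility(self, sim_config, standard_plan):
        a = simulate_avoidance_trial(sim_config, standard_plan, 2, "wt")
        b = simulate_avoidance_trial(sim_config, standard_plan, 2, "wt")
        pd.testing.assert_frame_equal(a, b)

    def test_cohort_converges_to_closed_form(self, standard_plan):
        cfg = SimConfig(seed=7)
        events = simulate_avoidance_cohort(cfg, standard_plan, "wt", n_subjects=60)
        curve = tuning_curve(events).points
        expected = expected_ai_by_size(cfg, standard_plan)
        merged = curve.merge(expected, on="size_deg")
        sem = merged["sem"].clip(lower=1e-6)
        z = (merged["mean_ai"] - merged["e_ai"]).abs() / sem
        assert (z < 3.0).all(), merged

    def test_no_habituation_makes_order_irrelevant(self):
        cfg = SimConfig(seed=5, avoidance=AvoidanceModel(habituation=1.0))
        sizes = [5, 10, 20, 30, 40, 60, 80]
        asc = expected_ai_by_size(cfg, make_trial_plan(sizes, "ascending"))
        rnd = expected_ai_by_size(
            cfg, make_trial_plan(sizes, "pseudo_random", seed=9)
        )
        pd.testing.assert_frame_equal(asc, rnd)

    def test_habituation_lowers_late_expected_avoidance(self):
        cfg = SimConfig(seed=5, avoidance=AvoidanceModel(habituation=0.9))
        sizes = [5, 10, 20, 30, 40, 60, 80]
        plan = make_trial_plan(sizes, "ascending")
        with_hab = expected_ai_by_size(cfg, plan)
        cfg0 = SimConfig(seed=5, avoidance=AvoidanceModel(habituation=1.0))
        without = expected_ai_by_size(cfg0, plan)
        # the largest (last-presented) dots lose the most expected avoidance
        assert with_hab["e_ai"].iloc[-1] < without["e_ai"].iloc[-1]

    def test_steep_slope_gives_step_tuning(self):
        model = AvoidanceModel(
            theta0_deg=25.0, slope=1e6, avoid_max=0.8, approach_max=0.3,
            habituation=1.0,
        )
        cfg = SimConfig(seed=5, avoidance=model)
        plan = make_trial_plan([5, 10, 20, 30, 40, 60, 80], "ascending")
        e = expected_ai_by_size(cfg, plan).set_index("size_deg")["e_ai"]
        assert e.loc[5.0] == pytest.approx(-0.3, abs=1e-6)
        assert e.loc[80.0] == pytest.approx(0.8, abs=1e-6)

    def test_genotype_shift_raises_mid_size_avoidance(self, standard_plan):
        cfg = SimConfig(
            seed=6,
            genotype_effects={
                "wt": GenotypeEffect(),
                "mut": GenotypeEffect(log_theta0_shift=-0.5),
            },
        )
        wt = expected_ai_by_size(cfg, standard_plan, "wt").set_index("size_deg")
        mut = expected_ai_by_size(cfg, standard_plan, "mut").set_index("size_deg")
        assert mut.loc[20.0, "e_ai"] > wt.loc[20.0, "e_ai"]


class TestQpcrSimulator:
    def test_zero_noise_gives_exact_ct(self):
        cfg = SimConfig(seed=1, qpcr=QpcrModel(base_ct=22.0, noise_sd=0.0))
        wells = simulate_qpcr(cfg, {"wt": {"tg": 1.0}}, n_samples=2)
        tg = wells[wells["gene"] == "tg"]["ct"]
        ref = wells[wells["gene"] == "beta-actin"]["ct"]
        assert np.allclose(tg, 22.0)
        assert np.allclose(ref, 22.0)

    def test_half_expression_shifts_delta_ct_by_one(self):
        cfg = SimConfig(seed=1, qpcr=QpcrModel(noise_sd=0.0))
        wells = simulate_qpcr(cfg, {"wt": {"tg": 1.0}, "mut": {"tg": 0.5}})
        rel = relative_expression(wells)
        dct = rel.groupby("group")["delta_ct"].mean()
        assert dct["mut"] - dct["wt"] == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        cfg = SimConfig(seed=44)
        design = {"wt": {"tg": 1.0}}
        pd.testing.assert_frame_equal(
            simulate_qpcr(cfg, design), simulate_qpcr(cfg, design)
        )

    def test_fold_recovery_unbiased_over_plates(self):
        # recovered mutant fold over many simulated plates is unbiased
        cfg = SimConfig(seed=21, qpcr=QpcrModel(base_ct=22.0, noise_sd=0.15))
        folds = []
        for plate in range(300):
            wells = simulate_qpcr(
                cfg, {"wt": {"tg": 1.0}, "mut": {"tg": 0.5}},
                n_samples=4, stream=(plate,),
            )
            f = fold_change(relative_expression(wells), "wt")
            folds.append(f[f["group"] == "mut"]["fold_change"].mean())
        folds = np.asarray(folds)
        se = folds.std(ddof=1) / np.sqrt(folds.size)
        assert abs(folds.mean() - 0.5) < 3 * se


class TestRecovery:
    def _fast_config(self, multiplier):
        return SimConfig(
            seed=9,
            frame_rate_hz=5.0,
            genotype_effects={
                "wt": GenotypeEffect(),
                "mut": GenotypeEffect(activity_multiplier={"dark": multiplier}),
            },
        )

    def _short_schedule(self):
        return build_schedule(
            [(300.0, "white"), (300.0, "dark")], repeats=3, acclimation_s=300.0
        )

    def test_null_multiplier_rejects_near_alpha(self):
        cfg = self._fast_config(1.0)
        report = recovery_experiment(
            cfg, self._short_schedule(), n_per_group=12, n_replicates=40
        )
        assert report["power"] <= 0.2
        assert report["implied_ratio"] == 1.0

    def test_implied_ratio_closed_form(self):
        cfg = self._fast_config(1.5)
        r1 = cfg.swim.rate_rest_to_move["dark"]
        r2 = cfg.swim.rate_move_to_rest
        manual = (1.5 * r1 / (1.5 * r1 + r2)) / (r1 / (r1 + r2))
        assert implied_dark_ratio(cfg, "mut") == pytest.approx(manual)

    def test_power_nondecreasing_in_n(self):
        cfg = self._fast_config(1.5)
        sched = self._short_schedule()
        powers = [
            recovery_experiment(cfg, sched, n_per_group=n, n_replicates=25)["power"]
            for n in (6, 24)
        ]
        # monotone within Monte-Carlo error
        assert powers[1] + 0.15 >= powers[0]
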