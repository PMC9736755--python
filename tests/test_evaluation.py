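from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

from walktrigger import (
    CountFixtureSpec,
    EmissionProfile,
    ParticipantDay,
    PromptEvent,
    PromptKind,
    RouteConfig,
    TriggerConfig,
    compliance_report,
    day_validity,
    filter_valid_days,
    make_count_fixture,
    match_routes,
    pre_prompt_activity,
    reconstruct_routes,
    run_trigger,
    simulate_cohort,
    simulate_responses,
    specificity_report,
    time_based_comparator,
)
from walktrigger.evaluation import pct, pre_prompt_table
from walktrigger.types import AccelEpoch, GpsFix

from _reference import reference_match

T0 = datetime(2020, 9, 7, 10, 0)


def make_routes(n, start=T0, minutes=10, spacing_min=30):
    from walktrigger.fixtures import make_count_fixture as mcf

    fx = mcf(CountFixtureSpec(n_routes=n))
    return fx.routes


class TestMatchRoutes:
    def test_grace_boundary_inclusive_at_120s(self):
        (route,) = make_routes(1)
        inside = PromptEvent("P001", route.end + timedelta(seconds=120), PromptKind.main)
        outside = PromptEvent("P001", route.end + timedelta(seconds=121), PromptKind.main)
        assert match_routes([route], [inside])[0] == [True]
        assert match_routes([route], [outside])[0] == [False]

    def test_start_boundary_inclusive(self):
        (route,) = make_routes(1)
        at_start = PromptEvent("P001", route.start, PromptKind.repeated)
        before = PromptEvent("P001", route.start - timedelta(seconds=1), PromptKind.main)
        assert match_routes([route], [at_start])[0] == [True]
        assert match_routes([route], [before])[0] == [False]

    def test_random_prompts_do_not_count(self):
        (route,) = make_routes(1)
        rnd = PromptEvent("P001", route.start, PromptKind.random)
        flags, rep = match_routes([route], [rnd])
        assert flags == [False] and rep.sensitivity_pct == 0.0

    def test_zero_prompts_zero_pct(self):
        routes = make_routes(5)
        _, rep = match_routes(routes, [])
        assert (rep.n_matched, rep.sensitivity_pct) == (0, 0.0)

    def test_empty_routes_flagged_undefined(self):
        _, rep = match_routes([], [])
        assert rep.n_routes == 0 and rep.sensitivity_pct is None

    def test_equals_brute_force_double_loop(self):
        rng = np.random.default_rng(42)
        routes = make_routes(40)
        t0 = routes[0].start
        for _ in range(25):
            times = sorted(
                t0 + timedelta(seconds=float(s))
                for s in rng.uniform(0, 40 * 1800, size=rng.integers(0, 30))
            )
            prompts = [PromptEvent("P001", t, PromptKind.main) for t in times]
            flags, _ = match_routes(routes, prompts)
            assert flags == reference_match(routes, times)


class TestComparator:
    def test_fixture_random_matching(self):
        fx = make_count_fixture(CountFixtureSpec(n_routes=842, n_random_matched=29, n_random=29))
        n, p = time_based_comparator(fx.routes, fx.random_times)
        assert (n, p) == (29, 3.4)

    def test_night_prompts_match_nothing(self):
        routes = make_routes(10)
        night = [datetime.combine(routes[0].start.date(), time(3, 0))]
        assert time_based_comparator(routes, night) == (0, 0.0)

    def test_matched_fraction_agrees_with_occupancy_model(self):
        """With k independent uniform prompt times in a window of which a route
        occupies fraction f, P(route hit) = 1 - (1-f)^k; Monte Carlo over
        seeded days agrees within 3 binomial SEs."""
        rng = np.random.default_rng(7)
        n_days = 3000
        window_s = 12 * 3600
        route_s = 1800 + 120  # route duration + grace
        k = 3
        f = route_s / window_s
        hits = 0
        day0 = datetime(2020, 9, 7, 10, 0)
        fx = make_count_fixture(CountFixtureSpec(n_routes=1))
        (route,) = fx.routes
        # route occupies [0, 1800+120) within the window, relocated per day by symmetry
        for _ in range(n_days):
            times = rng.uniform(0, window_s, size=k)
            if (times < route_s).any():
                hits += 1
        p_hat = hits / n_days
        p_true = 1 - (1 - f) ** k
        se = (p_true * (1 - p_true) / n_days) ** 0.5
        assert abs(p_hat - p_true) <= 3 * se


class TestPrePromptActivity:
    def _prompt(self, t=T0):
        return PromptEvent("P001", t, PromptKind.main, answered=True, self_report_walking=True)

    def test_zero_steps_no_flags(self):
        epochs = [
            AccelEpoch(T0 - timedelta(seconds=120), 0.0, 0),
            AccelEpoch(T0 - timedelta(seconds=60), 0.0, 0),
        ]
        act = pre_prompt_activity(self._prompt(), epochs, [])
        assert (act.steps, act.above_low, act.above_high, act.gps_present) == (0, False, False, False)

    def test_active_window_both_flags(self):
        epochs = [
            AccelEpoch(T0 - timedelta(seconds=120), 0.25, 60),
            AccelEpoch(T0 - timedelta(seconds=60), 0.22, 55),
        ]
        act = pre_prompt_activity(self._prompt(), epochs, [])
        assert act.steps == 115
        assert act.above_low and act.above_high  # mean 0.235 > 0.1 and >= 0.2

    def test_threshold_boundaries(self):
        # strictly above 0.1, at-or-above 0.2
        epochs = [
            AccelEpoch(T0 - timedelta(seconds=120), 0.1, 0),
            AccelEpoch(T0 - timedelta(seconds=60), 0.1, 0),
        ]
        act = pre_prompt_activity(self._prompt(), epochs, [])
        assert not act.above_low
        epochs2 = [
            AccelEpoch(T0 - timedelta(seconds=120), 0.2, 0),
            AccelEpoch(T0 - timedelta(seconds=60), 0.2, 0),
        ]
        act2 = pre_prompt_activity(self._prompt(), epochs2, [])
        assert act2.above_low and act2.above_high

    def test_any_epoch_mode_differs_from_window_mean(self):
        epochs = [
            AccelEpoch(T0 - timedelta(seconds=120), 0.30, 0),
            AccelEpoch(T0 - timedelta(seconds=60), 0.05, 0),
        ]
        mean_mode = pre_prompt_activity(self._prompt(), epochs, [], mode="window_mean")
        any_mode = pre_prompt_activity(self._prompt(), epochs, [], mode="any_epoch")
        assert not mean_mode.above_high  # mean 0.175 < 0.2
        assert any_mode.above_high  # one epoch reaches 0.3

    def test_gps_presence(self):
        fix = GpsFix(T0 - timedelta(seconds=30), 48.0, 9.0, 5.0)
        act = pre_prompt_activity(self._prompt(), [], [fix])
        assert act.gps_present
        act2 = pre_prompt_activity(self._prompt(), [], [])
        assert not act2.gps_present


class TestSpecificityReport:
    def test_fixture_strata_sizes(self):
        fx = make_count_fixture(
            CountFixtureSpec(n_main=1840, n_main_answered=1206, n_self_walking=838)
        )
        rep = specificity_report(fx.prompts, fx.epochs, fx.fixes)
        assert rep.n_main == 1840 and rep.n_answered == 1206
        assert rep.pct_self_walking == 69.5
        assert {k: v.n for k, v in rep.strata.items()} == {
            "walking": 838,
            "not_walking": 368,
            "unanswered": 634,
        }

    def test_all_unanswered_gives_empty_answered_strata(self):
        fx = make_count_fixture(CountFixtureSpec(n_main=10))
        rep = specificity_report(fx.prompts, fx.epochs, fx.fixes)
        assert rep.strata["walking"].n == 0 and rep.strata["not_walking"].n == 0
        assert rep.strata["unanswered"].n == 10

    def test_simulated_walking_stratum_has_more_steps(self):
        """Across seeded simulated days, mean pre-prompt steps are strictly
        higher when ground-truth walking was self-reported than when denied."""
        cohort = simulate_cohort(5, 10, seed=21)
        cfg0 = TriggerConfig()
        frames = []
        for day in cohort.days:
            cfg = cfg0.model_copy(update={"home_point": cohort.homes[day.participant_id]})
            prompts = run_trigger(day.participant_id, day.date, day.epochs, day.fixes, cfg, seed=5)
            truth = cohort.truth[(day.participant_id, day.date)]
            answered = simulate_responses(prompts, truth, seed=6)
            frames.append(pre_prompt_table(answered, day.epochs, day.fixes))
        table = pd.concat(frames, ignore_index=True)
        walking = table[table.stratum == "walking"]["steps"]
        not_walking = table[table.stratum == "not_walking"]["steps"]
        assert len(walking) > 20 and len(not_walking) > 5
        assert walking.mean() > not_walking.mean()

    def test_percentages_recomputable_from_counts(self):
        fx = make_count_fixture(
            CountFixtureSpec(
                n_main=200, n_main_answered=150, n_self_walking=100,
                gps_present_walking=80, gps_present_not_walking=20, gps_present_unanswered=10,
            )
        )
        rep = specificity_report(fx.prompts, fx.epochs, fx.fixes)
        for name, s in rep.strata.items():
            assert s.share_pct == pct(s.n, rep.n_main)
        assert rep.strata["walking"].pct_with_gps == pct(80, 100)


class TestCompliance:
    def test_fixture_rates(self):
        fx = make_count_fixture(
            CountFixtureSpec(
                n_main=1840, n_main_answered=1206,
                n_repeated=1443, n_repeated_answered=1052,
            )
        )
        rep = compliance_report(fx.prompts)
        assert rep.by_kind["main"].rate_pct == 65.5
        assert rep.by_kind["repeated"].rate_pct == 72.9
        assert rep.triggered.prompted == 3283 and rep.triggered.answered == 2258
        assert rep.triggered.rate_pct == 68.8

    def test_all_answered_100_pct(self):
        fx = make_count_fixture(CountFixtureSpec(n_main=5, n_main_answered=5, n_self_walking=5))
        rep = compliance_report(fx.prompts)
        assert rep.by_kind["main"].rate_pct == 100.0
        assert rep.overall.rate_pct == 100.0

    def test_overall_is_sum_over_kinds(self):
        fx = make_count_fixture(
            CountFixtureSpec(
                n_main=10, n_main_answered=4, n_repeated=6, n_repeated_answered=3,
                n_random=8, n_random_answered=5,
            )
        )
        rep = compliance_report(fx.prompts)
        assert rep.overall.prompted == sum(k.prompted for k in rep.by_kind.values())
        assert rep.overall.answered == sum(k.answered for k in rep.by_kind.values())


class TestDayValidity:
    def _day(self, worn_minutes):
        t0 = datetime(2020, 9, 7, 6, 0)
        epochs = [
            AccelEpoch(t0 + timedelta(minutes=m), 0.02, 0, worn=m < worn_minutes)
            for m in range(960)
        ]
        return ParticipantDay("P001", date(2020, 9, 7), epochs, [])

    def test_boundary_7_9_hours_invalid(self):
        assert not day_validity(self._day(474))  # 7.9 h

    def test_8_hours_valid(self):
        assert day_validity(self._day(480))
        assert day_validity(self._day(720))  # 12 h

    def test_cohort_exclusion_count(self):
        days = [self._day(480)] * 13 + [self._day(300)] * 7
        valid, excluded = filter_valid_days(days)
        assert (len(valid), excluded) == (13, 7)


class TestDropoutDegradation:
    def test_bout_coverage_degrades_with_gps_dropout(self):
        """Fraction of >=10-min walking bouts receiving a prompt falls
        monotonically as walking GPS availability drops from 1 to 0."""
        fractions = []
        for avail in (1.0, 0.15, 0.0):
            emission = EmissionProfile().clean().with_walk_availability(avail)
            cohort = simulate_cohort(3, 5, seed=31, emission_profile=emission)
            hit = total = 0
            for day in cohort.days:
                cfg = TriggerConfig(home_point=cohort.homes[day.participant_id])
                prompts = run_trigger(
                    day.participant_id, day.date, day.epochs, day.fixes, cfg, seed=8
                )
                for b in cohort.schedules[(day.participant_id, day.date)]:
                    if b.is_walking and b.minutes >= 10:
                        total += 1
                        hit += any(b.start <= p.timestamp <= b.end for p in prompts)
            fractions.append(hit / total)
        assert fractions[0] == 1.0
        assert fractions[0] >= fractions[1] >= fractions[2]
        assert fractions[2] == 0.0
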