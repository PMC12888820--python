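"""Elementary model functions, trip schedules and the energy ledger."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import tripforage as tf
from tripforage import (
    EnvironmentBelief,
    ForagerParams,
    TripPlan,
    build_schedule,
    energy_trace,
    nearest_patch_pdf,
    patch_rate,
    prep_time,
    survival,
)
from conftest import random_setup


def belief_of(p=0.01, gamma=0.0, mu=10.0, D=1000.0):
    return EnvironmentBelief(p, gamma, mu, D)


class TestNearestPatchPdf:
    @pytest.mark.parametrize(
        "p, r, d, expected",
        [
            (0.01, 0.0, 0.0, 0.01),  # density at the origin equals p
            (0.01, 100.0, 150.0, 0.01 * math.exp(-0.5)),
            (0.01, 100.0, 50.0, 0.0),  # nothing below the explored range
        ],
    )
    def test_values(self, p, r, d, expected):
        assert nearest_patch_pdf(belief_of(p=p), r, d) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        b = belief_of()
        with pytest.raises(ValueError):
            nearest_patch_pdf(b, -1.0, 10.0)
        with pytest.raises(ValueError):
            nearest_patch_pdf(b, 0.0, -5.0)
        with pytest.raises(ValueError):
            nearest_patch_pdf(b, b.D + 1.0, 10.0)

    @pytest.mark.parametrize("p, r", [(0.01, 0.0), (0.003, 250.0), (0.2, 900.0)])
    def test_mass_matches_survival(self, p, r):
        """The density integrates over (r, D] to 1 - e^{-p(D-r)}."""
        b = belief_of(p=p)
        mass, _ = quad(lambda d: nearest_patch_pdf(b, r, d), r, b.D, epsabs=1e-13)
        assert mass == pytest.approx(1.0 - survival(b, r, b.D), abs=1e-10)
        assert survival(b, r, b.D) == pytest.approx(math.exp(-p * (b.D - r)), rel=1e-12)


class TestRatesAndPrepTime:
    def test_patch_rate_values(self):
        b = belief_of(gamma=0.001)
        assert patch_rate(b, 0.0) == pytest.approx(10.0)
        assert patch_rate(b, 1000.0) == pytest.approx(0.0)

    def test_patch_rate_relative_profile(self, circuit_demo_setup):
        # steep relative profile: R(d)/R0 = 40 (1 - 0.0004 d), so 32 at d=500
        belief, params = circuit_demo_setup
        assert patch_rate(belief, 500.0) / params.R0 == pytest.approx(32.0, rel=1e-12)

    def test_patch_rate_domain(self):
        with pytest.raises(ValueError):
            patch_rate(belief_of(), 1000.1)

    @pytest.mark.parametrize(
        "R0, RD, d, expected",
        [(0.25, -0.25, 100.0, 200.0), (0.1, -0.1, 0.0, 0.0), (0.1, -0.1, 200.0, 400.0)],
    )
    def test_prep_time_values(self, R0, RD, d, expected):
        assert prep_time(ForagerParams(R0, RD, 1000.0), d) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        R0=st.floats(0.01, 10.0),
        RD=st.floats(-10.0, -0.01),
        d=st.floats(0.0, 1e4),
    )
    def test_prep_time_funds_round_trip(self, R0, RD, d):
        """Harvesting for Omega(d) yields exactly the round-trip energy 2 d |RDelta|."""
        params = ForagerParams(R0, RD, 1.0)
        assert prep_time(params, d) * R0 == pytest.approx(2.0 * d * abs(RD), rel=1e-12)


class TestValidation:
    def test_params_sign_constraints(self):
        for bad in [dict(R0=-1.0, RDelta=-1.0, T=1.0), dict(R0=1.0, RDelta=1.0, T=1.0),
                    dict(R0=1.0, RDelta=-1.0, T=-1.0), dict(R0=1.0, RDelta=-1.0, T=1.0, v=2.0)]:
            with pytest.raises(ValueError):
                ForagerParams(**bad)

    def test_quality_decay_warning(self):
        with pytest.warns(UserWarning, match="gamma"):
            EnvironmentBelief(0.01, 0.002, 10.0, 1000.0)

    def test_mu_must_beat_home_rate(self):
        b = belief_of(mu=0.05)
        with pytest.raises(ValueError, match="mu"):
            b.require_profitable(ForagerParams(0.1, -0.1, 100.0))

    def test_plan_ordering_enforced(self):
        with pytest.raises(ValueError):
            TripPlan([100.0, 100.0])
        with pytest.raises(ValueError):
            TripPlan([100.0], origin_r=150.0)


class TestSchedule:
    def test_single_trip(self):
        params = ForagerParams(0.25, -0.25, 1e4)  # rtilde = 1
        s = build_schedule(TripPlan([100.0]), params)
        assert s.leave_time[0] == pytest.approx(200.0)
        assert s.return_time[0] == pytest.approx(400.0)

    def test_empty_plan(self):
        s = build_schedule(TripPlan([]), ForagerParams(0.1, -0.1, 100.0))
        assert len(s) == 0 and s.fits

    def test_two_trip_chain(self):
        # hand-chained recurrence, cross-checked against the step simulator below
        params = ForagerParams(0.25, -0.25, 1e4)
        s = build_schedule(TripPlan([100.0, 300.0]), params)
        assert s.feed_start[1] == pytest.approx(400.0)
        assert s.leave_time[1] == pytest.approx(1000.0)
        assert s.return_time[1] == pytest.approx(1600.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1.0, 500.0), min_size=1, max_size=5, unique=True))
    def test_recurrences(self, raw):
        params = ForagerParams(0.2, -0.3, 1e9)
        plan = TripPlan(sorted(raw))
        s = build_schedule(plan, params)
        d = np.asarray(plan.distances)
        np.testing.assert_allclose(s.leave_time, s.feed_start + prep_time(params, d), rtol=1e-12)
        np.testing.assert_allclose(s.return_time, s.leave_time + 2 * d, rtol=1e-12)
        np.testing.assert_allclose(s.feed_start[1:], s.return_time[:-1], rtol=1e-12)
        assert s.feed_start[0] == 0.0

    def test_overflow_flagging(self):
        params = ForagerParams(0.25, -0.25, 300.0)
        s = build_schedule(TripPlan([100.0]), params)  # returns at 400 > 300
        assert not s.fits and s.overflows[0]


def _independent_rate(t, plan, params, belief, found_at):
    """Instantaneous energy rate at time t, rebuilt from first principles."""
    tau = 0.0
    prev_cov = plan.origin_r
    for d in plan.distances:
        omega = prep_time(params, d)
        if t < tau + omega:
            return params.R0
        tau += omega
        if found_at is not None and prev_cov < found_at <= d:
            if t < tau + found_at:
                return params.RDelta
            return patch_rate(belief, found_at)
        if t < tau + 2 * d:
            return params.RDelta
        tau += 2 * d
        prev_cov = d
    return params.R0


class TestEnergyTrace:
    def setup_method(self):
        self.params = ForagerParams(0.1, -0.1, 8000.0)
        self.belief = belief_of(p=0.01, gamma=0.0, mu=10.0)

    def test_stay_forever(self):
        led = energy_trace(TripPlan([]), self.params, self.belief)
        assert led.final_energy == pytest.approx(0.1 * 8000.0)

    def test_no_find_loss(self):
        # every skipped trip costs 2 d (R0 - RDelta) off the stay-put energy
        led = energy_trace(TripPlan([100.0, 250.0]), self.params, self.belief)
        expected = 0.1 * 8000.0 - 2 * (100.0 + 250.0) * (0.1 - (-0.1))
        assert led.final_energy == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(led.return_reserves, 0.0, atol=1e-9)

    def test_found_episode_hand_ledger(self):
        # feed 200 (gain 20), travel 50 outbound (lose 5), harvest 10/time for 7750
        led = energy_trace(TripPlan([100.0]), self.params, self.belief, found_at=50.0)
        assert led.found and led.find_time == pytest.approx(250.0)
        assert led.final_energy == pytest.approx(20.0 - 5.0 + 7750.0 * 10.0, rel=1e-12)

    def test_found_outside_coverage_rejected(self):
        with pytest.raises(ValueError):
            energy_trace(TripPlan([100.0]), self.params, self.belief, found_at=150.0)
        with pytest.raises(ValueError):
            energy_trace(TripPlan([100.0], origin_r=50.0), self.params, self.belief, found_at=30.0)

    def test_reserve_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            belief, params = random_setup(rng)
            c = params.trip_time_factor
            hi = min(belief.D, 0.9 * params.T / c / 3)
            d = np.sort(rng.uniform(1.0, hi, size=rng.integers(1, 4)))
            d = np.unique(d)
            plan = TripPlan(d)
            found = float(rng.uniform(0, d[-1])) if rng.random() < 0.5 else None
            if found is not None and found <= 0:
                found = None
            led = energy_trace(plan, params, belief, found_at=found)
            assert led.min_reserve() >= -1e-9
            np.testing.assert_allclose(led.return_reserves, 0.0, atol=1e-8)
            sched = build_schedule(plan, params)
            for i, t_leave in enumerate(sched.leave_time):
                if t_leave > params.T or (led.find_time is not None and t_leave > led.find_time):
                    break
                # reserve at departure is exactly the stocked round-trip energy
                assert led.reserve_at(t_leave) == pytest.approx(
                    2 * plan.distances[i] * (-params.RDelta), rel=1e-9, abs=1e-9
                )

    @pytest.mark.parametrize("found_at", [None, 50.0, 180.0])
    def test_matches_step_simulator(self, found_at):
        """Ledger equals a small-step time-marching integration of the rate."""
        params = ForagerParams(0.1, -0.1, 2500.0)  # short horizon keeps the march cheap
        plan = TripPlan([100.0, 250.0])
        dt = 1e-3
        tt = np.arange(0.0, params.T, dt) + dt / 2
        rates = np.fromiter(
            (_independent_rate(t, plan, params, self.belief, found_at) for t in tt),
            dtype=float,
            count=len(tt),
        )
        led = energy_trace(plan, params, self.belief, found_at=found_at)
        max_rate = max(abs(params.RDelta), self.belief.mu, params.R0)
        assert led.final_energy == pytest.approx(float(np.sum(rates) * dt), abs=10 * dt * max_rate)

    def test_truncation_at_horizon(self):
        short = ForagerParams(0.1, -0.1, 300.0)
        led = energy_trace(TripPlan([100.0]), short, self.belief)  # return would be at 400
        assert led.times[-1] == pytest.approx(300.0)
        # fed 200 time units (gain 20), travelled 100 (lose 10)
        assert led.final_energy == pytest.approx(20.0 - 10.0, rel=1e-12)
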