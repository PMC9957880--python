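"""QALY/cost accrual, discounting, ICER and CEAC tests."""

import numpy as np
import pytest

from chondrosim.economics import (
    CostLedger,
    UtilitySchedule,
    accrue,
    compute_ceac,
    compute_icer,
    discount,
    dominant_fraction,
)
from chondrosim.engine import (
    BEFORE_REPAIR,
    MACI,
    REPAIR_ACI,
    WITH_MACI,
    Event,
    Segment,
    Trajectory,
)
from chondrosim.population import ConfigurationError, PatientProfile


def make_traj(segments, events, death_age=40.0):
    profile = PatientProfile(0, "male", 36.0, 4.0)
    return Trajectory(
        profile=profile,
        scenario=WITH_MACI,
        events=events,
        segments=segments,
        death_age=death_age,
    )


@pytest.fixture
def ledger():
    return CostLedger(
        procedure_costs={
            "maci": 11000.0,
            "microfracture": 1500.0,
            "mbms": 3500.0,
            "pkr": 6000.0,
            "tkr": 9000.0,
            "tkr_revision": 15000.0,
        }
    )


class TestDiscount:
    def test_t_zero_identity(self):
        assert discount(1000.0, 0.0, 0.02) == pytest.approx(1000.0)

    def test_closed_form_ten_years(self):
        assert float(discount(1000.0, 10.0, 0.02)) == pytest.approx(820.35, abs=0.01)

    def test_zero_rate_identity(self):
        for t in (0.0, 3.7, 50.0):
            assert discount(123.4, t, 0.0) == pytest.approx(123.4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount(100.0, -1.0, 0.02)


class TestAccrue:
    def test_one_year_before_repair(self, ledger):
        traj = make_traj(
            [Segment(0.0, 1.0, BEFORE_REPAIR)], [Event(1.0, "death")], death_age=37.0
        )
        res = accrue(traj, UtilitySchedule(), ledger, rate=0.0)
        assert res.qaly == pytest.approx(0.65)
        assert res.cost == pytest.approx(800.0)  # conservative therapy

    def test_aci_then_death_at_three_years(self, ledger):
        """First post-implantation year at 0.76, steady state 0.82."""
        traj = make_traj(
            [Segment(0.0, 3.0, REPAIR_ACI)],
            [Event(0.0, "intervention", MACI, 4.0), Event(3.0, "death")],
            death_age=39.0,
        )
        res = accrue(traj, UtilitySchedule(), ledger, rate=0.0)
        assert res.qaly == pytest.approx(0.76 + 2 * 0.82)
        assert res.cost == pytest.approx(11000.0)

    def test_death_at_entry_costs_only(self, ledger):
        traj = make_traj(
            [], [Event(0.0, "intervention", MACI, 4.0), Event(0.0, "death")],
            death_age=36.0,
        )
        res = accrue(traj, UtilitySchedule(), ledger, rate=0.02)
        assert res.qaly == 0.0
        assert res.cost == pytest.approx(11000.0)
        assert res.cost_discounted == pytest.approx(11000.0)

    def test_all_weights_one_gives_survival_time(self, params, small_cohort, ledger):
        """Conservation: unit utility weights turn QALYs into lifetime."""
        from chondrosim.engine import run_scenarios

        schedule = UtilitySchedule()
        for state in schedule.bands:
            schedule.bands[state] = [(float("inf"), 1.0)]
        trajs = run_scenarios(small_cohort[:100], params, seed=1)[WITH_MACI]
        for traj in trajs:
            res = accrue(traj, schedule, ledger, rate=0.0)
            horizon = traj.death_age - traj.profile.entry_age
            assert res.qaly == pytest.approx(horizon, abs=1e-6)

    def test_discounted_below_undiscounted(self, params, small_cohort, ledger):
        from chondrosim.engine import run_scenarios

        trajs = run_scenarios(small_cohort[:100], params, seed=1)[WITH_MACI]
        for traj in trajs:
            res = accrue(traj, UtilitySchedule(), ledger, rate=0.02)
            assert res.qaly_discounted <= res.qaly + 1e-9
            assert res.cost_discounted <= res.cost + 1e-9

    def test_event_ledger_oracle(self, params, small_cohort, ledger):
        """Undiscounted totals equal an independently computed event-by-event
        sum over procedure costs and symptomatic stream durations."""
        from chondrosim.engine import SYMPTOMATIC_STATES, run_scenarios

        schedule = UtilitySchedule()
        paired = run_scenarios(small_cohort[:200], params, seed=8)
        for trajs in paired.values():
            for traj in trajs:
                res = accrue(traj, schedule, ledger, rate=0.02)
                oracle_cost = sum(
                    ledger.cost_of(e.treatment)
                    for e in traj.events
                    if e.kind == "intervention"
                ) + 800.0 * sum(
                    s.end - s.start
                    for s in traj.segments
                    if s.state in SYMPTOMATIC_STATES
                )
                # QALY oracle: midpoint quadrature over each segment's
                # banded step function
                step = 1.0 / 256
                grid_q = 0.0
                for s in traj.segments:
                    ys = np.arange(step / 2, s.end - s.start, step)
                    if len(ys):
                        bands = schedule.bands[s.state]
                        ends = np.array([e for e, _ in bands])
                        ws = np.array([w for _, w in bands])
                        grid_q += float(
                            np.sum(ws[np.searchsorted(ends, ys, side="right")]) * step
                        )
                assert res.cost == pytest.approx(oracle_cost, rel=1e-9)
                assert res.qaly == pytest.approx(grid_q, abs=0.05)

    def test_unmapped_state_reported(self, ledger):
        traj = make_traj([Segment(0.0, 1.0, "mystery")], [Event(1.0, "death")])
        with pytest.raises(ConfigurationError, match="mystery"):
            accrue(traj, UtilitySchedule(), ledger, rate=0.0)


class TestIcer:
    def test_printed_component_means(self):
        """The worked-example identity: printed incremental cost and QALY
        reproduce the printed ICER to rounding."""
        res = compute_icer(4455.0, 1.32)
        assert res.icer == pytest.approx(3376.0, rel=5e-4)

    def test_identical_scenarios_undefined(self):
        res = compute_icer(0.0, 0.0)
        assert res.icer is None

    def test_dominance_quadrant(self):
        res = compute_icer(-100.0, 0.1)
        assert res.dominant and not res.dominated
        res2 = compute_icer(100.0, -0.1)
        assert res2.dominated and not res2.dominant


class TestCeac:
    def test_zero_wtp_equals_cost_saving_fraction(self):
        rng = np.random.default_rng(0)
        dc, dq = rng.normal(1000, 3000, 500), rng.normal(1, 1, 500)
        [(_, p0)] = compute_ceac(dc, dq, [0.0])
        assert p0 == pytest.approx(np.mean(dc <= 0))

    def test_large_wtp_limit(self):
        rng = np.random.default_rng(1)
        dc, dq = rng.normal(1000, 3000, 500), rng.normal(1, 1, 500)
        [(_, p)] = compute_ceac(dc, dq, [1e12])
        assert p == pytest.approx(np.mean(dq >= 0), abs=2e-3)

    def test_brute_force_oracle(self):
        """CEAC equals the fraction-by-threshold obtained by sorting the
        per-patient break-even WTP values."""
        rng = np.random.default_rng(2)
        dc = rng.normal(4000, 6000, 400)
        dq = rng.normal(1.3, 1.5, 400)
        grid = [0, 5000, 20000, 50000]
        got = dict(compute_ceac(dc, dq, grid))
        for lam in grid:
            oracle = np.mean([lam * q - c >= 0 for c, q in zip(dc, dq)])
            assert got[lam] == pytest.approx(oracle)

    def test_monotone_when_all_gain(self):
        rng = np.random.default_rng(3)
        dc = rng.normal(4000, 6000, 400)
        dq = np.abs(rng.normal(1.3, 1.0, 400))  # all QALY gains >= 0
        probs = [p for _, p in compute_ceac(dc, dq, np.linspace(0, 1e5, 30))]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_ceac(np.array([1.0]), np.array([1.0]), [])

    def test_dominant_fraction_definition(self):
        dc = np.array([-1.0, 1.0, -1.0, 0.0])
        dq = np.array([0.5, 0.5, -0.5, 0.5])
        assert dominant_fraction(dc, dq) == pytest.approx(0.25)
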