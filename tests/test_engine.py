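"""Event-loop, policy and trajectory-invariant tests."""

import copy

import numpy as np
import pytest

from chondrosim import default_config
from chondrosim.config import build_params
from chondrosim.engine import (
    MACI,
    MBMS,
    MF,
    PKR,
    TKR,
    WITH_MACI,
    WITHOUT_MACI,
    PatientState,
    action_distribution,
    ever_received,
    run_scenarios,
    second_surgery_fraction,
    simulate_patient,
)
from chondrosim.population import PatientProfile
from chondrosim.streams import substream


def dist(params, scenario, **state_kwargs):
    return action_distribution(PatientState(**state_kwargs), scenario, params)


class TestTreatmentSelection:
    def test_small_defect_gets_microfracture_not_maci(self, params):
        d = dist(params, WITHOUT_MACI, defect=1.5, age=30)
        assert d == {MF: 1.0}

    def test_large_defect_young_patient_gets_pkr_not_tkr(self, params):
        d = dist(params, WITHOUT_MACI, defect=12.0, age=40)
        assert TKR not in d
        assert d[PKR] == pytest.approx(1.0)

    def test_maci_scenario_primary_is_always_maci(self, params):
        d = dist(params, WITH_MACI, defect=4.0, age=36)
        assert d == {MACI: 1.0}

    def test_midsize_defect_without_maci_split(self, params):
        d = dist(params, WITHOUT_MACI, defect=7.0, age=36)
        p = params.policy.midband_pkr_prob[WITHOUT_MACI]
        assert d[PKR] == pytest.approx(p)
        assert d[MBMS] == pytest.approx(1 - p)

    def test_tkr_only_inside_age_window(self, params):
        young = dist(params, WITHOUT_MACI, defect=4.0, age=50, n_interventions=1)
        old = dist(params, WITHOUT_MACI, defect=4.0, age=60, n_interventions=1)
        assert TKR not in young
        assert old.get(TKR, 0.0) > 0

    def test_probabilities_sum_to_one(self, params):
        states = [
            dict(defect=d, age=a, n_interventions=k, n_kr=nk, repair_exhausted=ex)
            for d in (1.0, 3.0, 7.0, 12.0)
            for a in (30, 50, 60, 82)
            for k in (0, 1, 3)
            for nk, ex in ((0, False), (0, True), (1, False))
        ]
        for scen in (WITH_MACI, WITHOUT_MACI):
            for s in states:
                d = dist(params, scen, **s)
                assert sum(d.values()) == pytest.approx(1.0), (scen, s)


class TestSimulatePatient:
    def run_one(self, params, scenario="with_maci", seed=0, **profile_kwargs):
        profile = PatientProfile(
            patient_id=0,
            sex=profile_kwargs.pop("sex", "male"),
            entry_age=profile_kwargs.pop("entry_age", 36.0),
            defect_size=profile_kwargs.pop("defect_size", 4.0),
        )
        return simulate_patient(
            profile,
            scenario,
            params,
            death_age=profile_kwargs.pop("death_age", 84.0),
            failure_rng=substream(seed, 0, 1),
            select_rng=substream(seed, 0, 2),
            periop_rng=substream(seed, 0, 3),
        )

    def test_first_event_is_immediate_primary_maci(self, params):
        traj = self.run_one(params)
        first = traj.events[0]
        assert first.kind == "intervention"
        assert first.treatment == MACI
        assert first.time == pytest.approx(0.0)

    def test_no_failure_limit_single_intervention(self, cfg):
        never = copy.deepcopy(cfg)
        for block in never["failure"].values():
            block["anchors"] = [{"t": 1000.0, "s": 0.999}]
            block["two_year"] = 1e-9
        params = build_params(never)
        traj = self.run_one(params)
        kinds = [e.kind for e in traj.events]
        assert kinds == ["intervention", "death"]

    def test_event_times_increasing_single_death_last(self, params, small_cohort):
        paired = run_scenarios(small_cohort, params, seed=3)
        for trajs in paired.values():
            for traj in trajs:
                times = [e.time for e in traj.events]
                assert all(b > a for a, b in zip(times, times[1:]))
                death_kinds = [
                    e.kind for e in traj.events if e.kind.endswith("death")
                ]
                assert len(death_kinds) == 1
                assert traj.events[-1].kind.endswith("death")

    def test_segments_tile_the_lifetime(self, params, small_cohort):
        """Health-state segments are contiguous, non-overlapping, and end at
        death."""
        paired = run_scenarios(small_cohort, params, seed=3)
        for trajs in paired.values():
            for traj in trajs:
                segs = traj.segments
                assert all(s.end > s.start for s in segs)
                for a, b in zip(segs, segs[1:]):
                    assert b.start == pytest.approx(a.end)
                horizon = traj.death_age - traj.profile.entry_age
                if segs:
                    assert segs[-1].end == pytest.approx(horizon, abs=1e-9)

    def test_zero_perioperative_mortality_all_life_table_deaths(self, cfg, small_cohort):
        c = copy.deepcopy(cfg)
        c["treatments"][TKR]["perioperative_mortality"] = [0.0, 0.0]
        params = build_params(c)
        paired = run_scenarios(small_cohort, params, seed=5)
        for trajs in paired.values():
            assert len(trajs) == len(small_cohort)
            assert all(t.events[-1].kind == "death" for t in trajs)


class TestRunScenarios:
    def test_same_seed_bit_identical(self, params, small_cohort):
        a = run_scenarios(small_cohort, params, seed=9)
        b = run_scenarios(small_cohort, params, seed=9)
        for scen in a:
            for ta, tb in zip(a[scen], b[scen]):
                assert ta.events == tb.events
                assert ta.segments == tb.segments

    def test_death_age_shared_between_scenarios(self, params, small_cohort):
        paired = run_scenarios(small_cohort, params, seed=4)
        for ta, tb in zip(paired[WITH_MACI], paired[WITHOUT_MACI]):
            periop = {ta.events[-1].kind, tb.events[-1].kind}
            if periop == {"death"}:
                assert ta.death_age == pytest.approx(tb.death_age)

    def test_tkr_incidence_dominance_across_seeds(self, params):
        """With paired runs, TKR incidence with M-ACI never exceeds the
        incidence without it, for every seed."""
        from chondrosim.population import sample_cohort

        for seed in range(6):
            cohort = sample_cohort(400, seed=seed)
            paired = run_scenarios(cohort, params, seed=seed)
            assert ever_received(paired[WITH_MACI], TKR) <= ever_received(
                paired[WITHOUT_MACI], TKR
            )

    def test_unbounded_tkr_age_weakly_increases_incidence(self, cfg, small_cohort):
        base = build_params(cfg)
        wide_cfg = copy.deepcopy(cfg)
        wide_cfg["treatments"][TKR]["age_min"] = 0.0
        wide_cfg["treatments"][TKR]["age_max"] = 200.0
        wide = build_params(wide_cfg)
        for seed in (0, 1):
            got_base = ever_received(
                run_scenarios(small_cohort, base, seed=seed)[WITHOUT_MACI], TKR
            )
            got_wide = ever_received(
                run_scenarios(small_cohort, wide, seed=seed)[WITHOUT_MACI], TKR
            )
            assert got_wide >= got_base - 1e-12

    def test_second_surgery_fraction_estimator(self, params):
        """The cumulative second-surgery estimator is 0 before any failure
        horizon and approaches the ever-fraction for long horizons."""
        from chondrosim.population import sample_cohort

        cohort = sample_cohort(500, seed=2)
        trajs = run_scenarios(cohort, params, seed=2)[WITH_MACI]
        assert second_surgery_fraction(trajs, 0.1) == pytest.approx(0.0, abs=0.01)
        frac25 = second_surgery_fraction(trajs, 25.0)
        frac60 = second_surgery_fraction(trajs, 60.0)
        assert 0.0 < frac25 < frac60 <= 1.0
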