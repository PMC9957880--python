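"""Per-patient discrete-event simulation of cartilage-repair pathways.

Each patient is followed in continuous time from model entry (symptomatic
defect) to death under two healthcare scenarios: one in which matrix-
associated autologous chondrocyte implantation (M-ACI) is available and used
as primary repair in all patients, and a counter-factual one without M-ACI.
The loop alternates treatment selection, implant survival (a draw from the
treatment's Weibull-mixture failure model), and symptomatic relapse, until
all-cause death from the life table (or perioperative death at knee
replacement).  Paired runs share death ages and the primary repair's
failure quantile between scenarios (common random numbers).

Pathway rules
-------------
* Repairs (M-ACI, microfracture, mBMS) follow defect-size eligibility bands.
* A failed repair marks the knee as degeneration-prone: knee replacement
  (KR) enters the option set at re-interventions, with TKR restricted to the
  configured age window and PKR to large defects; the per-presentation KR
  probabilities are scenario-specific calibration inputs.
* Once a KR has failed the patient stays on the arthroplasty pathway:
  failed PKR -> TKR; failed TKR -> at most the configured number of
  revisions; afterwards a terminal "no further KR" state.
* When no surgical option is (or will become) available the patient remains
  in conservative care, re-evaluated annually while circumstances can still
  change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .failure import FailureModel, sample_time_to_failure
from .population import (
    CohortStrata,
    ConfigurationError,
    LifeTable,
    PatientProfile,
    sample_death_age,
)
from . import streams
from .streams import substream

WITH_MACI = "with_maci"
WITHOUT_MACI = "without_maci"
SCENARIOS = (WITH_MACI, WITHOUT_MACI)

# treatment names
MACI = "maci"
MF = "microfracture"
MBMS = "mbms"
PKR = "pkr"
TKR = "tkr"
TKR_REVISION = "tkr_revision"
CONSERVATIVE = "conservative"

# health-state keys (utility schedule)
BEFORE_REPAIR = "before_repair"
REPAIR_ACI = "repair_aci"
REPAIR_MF = "repair_mf"
NO_FURTHER_REPAIR = "no_further_repair"
BEFORE_FIRST_KR = "before_first_kr"
BEFORE_SECOND_KR = "before_second_kr"
POST_KR = "post_kr"
NO_FURTHER_KR = "no_further_kr"

#: states in which the patient is symptomatic and accrues conservative care
SYMPTOMATIC_STATES = frozenset(
    {BEFORE_REPAIR, NO_FURTHER_REPAIR, BEFORE_FIRST_KR, BEFORE_SECOND_KR, NO_FURTHER_KR}
)

RELAPSE_STREAM = 5


class PairedFailureStream:
    """Failure-quantile source for paired runs: the primary intervention's
    draws are shared between scenarios (common random numbers on the
    decades-scale primary durability), later draws are scenario-specific."""

    def __init__(self, shared: np.random.Generator, own: np.random.Generator,
                 shared_draws: int = 2):
        self._shared = shared
        self._own = own
        self._left = shared_draws

    def random(self) -> float:
        if self._left > 0:
            self._left -= 1
            return float(self._shared.random())
        return float(self._own.random())


@dataclass(frozen=True)
class TreatmentSpec:
    """Eligibility window, cost and failure model of one intervention."""

    name: str
    cost: float
    defect_min: float = 0.0
    defect_max: float = math.inf
    age_min: float = -math.inf
    age_max: float = math.inf
    failure_model: FailureModel | None = None
    utility_key: str = REPAIR_ACI
    # (probability at age_min, probability at age_max), linear in between
    perioperative_mortality: tuple[float, float] | None = None

    def eligible(self, defect: float, age: float) -> bool:
        return (
            self.defect_min < defect <= self.defect_max
            and self.age_min <= age <= self.age_max
        )

    def periop_risk(self, age: float) -> float:
        if self.perioperative_mortality is None:
            return 0.0
        lo, hi = self.perioperative_mortality
        if not math.isfinite(self.age_min) or self.age_max == self.age_min:
            return lo
        a0, a1 = self.age_min, self.age_max
        w = min(max((age - a0) / (a1 - a0), 0.0), 1.0)
        return lo + w * (hi - lo)


@dataclass
class PolicyParams:
    """Assignment-policy knobs (scenario-specific calibration inputs)."""

    symptomatic_delay: float = 0.25
    repair_age_max: float = 80.0
    max_tkr_revisions: int = 1
    revision_age_max: float = 85.0
    # outside the published band, mid-size defects (5-10 cm²) have no
    # published repair option; they are split between extended-indication
    # mBMS and PKR
    mbms_extended_max: float = 10.0
    midband_pkr_prob: dict = field(
        default_factory=lambda: {WITH_MACI: 0.10, WITHOUT_MACI: 0.65}
    )
    relapse_size: str = "original"  # original | resample
    # per-presentation probability of choosing TKR at a re-intervention when
    # the age window allows it
    reint_tkr_prob: dict = field(
        default_factory=lambda: {WITH_MACI: 0.012, WITHOUT_MACI: 0.06}
    )
    # per-presentation probability of PKR at a re-intervention: repeatedly
    # operated knees are treated as degeneration-prone, so PKR is offered
    # there independent of the primary defect-size band
    reint_pkr_prob: dict = field(
        default_factory=lambda: {WITH_MACI: 0.05, WITHOUT_MACI: 0.28}
    )
    # probability that a re-intervention in the M-ACI scenario renews M-ACI
    reint_maci_renew: float = 0.10
    # probability that a failed PKR is converted to TKR when the age window
    # allows; otherwise the patient keeps conservative care (no further KR)
    pkr_to_tkr_prob: float = 0.4
    # per-presentation probability (3rd intervention onward) that the patient
    # declines / is not offered further repair and stays conservative
    reint_stop_prob: dict = field(
        default_factory=lambda: {WITH_MACI: 0.40, WITHOUT_MACI: 0.10}
    )
    # annual probability that a repair-exhausted patient inside the TKR age
    # window proceeds to TKR while waiting in the pre-arthroplasty state
    wait_tkr_prob: dict = field(
        default_factory=lambda: {WITH_MACI: 0.004, WITHOUT_MACI: 0.12}
    )
    primary_maci_all: bool = True

    def validate(self) -> None:
        if self.symptomatic_delay <= 0:
            raise ConfigurationError("symptomatic_delay must be > 0")
        for name in ("reint_tkr_prob", "reint_pkr_prob"):
            for scen in SCENARIOS:
                p = getattr(self, name).get(scen)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"{name}[{scen}] must be in [0,1], got {p!r}"
                    )
        if not 0.0 <= self.reint_maci_renew <= 1.0:
            raise ConfigurationError("reint_maci_renew must be in [0,1]")
        if not 0.0 <= self.pkr_to_tkr_prob <= 1.0:
            raise ConfigurationError("pkr_to_tkr_prob must be in [0,1]")
        for scen in SCENARIOS:
            p = self.reint_stop_prob.get(scen)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"reint_stop_prob[{scen}] must be in [0,1], got {p!r}"
                )
        for scen in SCENARIOS:
            p = self.wait_tkr_prob.get(scen)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"wait_tkr_prob[{scen}] must be in [0,1], got {p!r}"
                )
        for scen in SCENARIOS:
            p = self.midband_pkr_prob.get(scen)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"midband_pkr_prob[{scen}] must be in [0,1], got {p!r}"
                )
        if self.relapse_size not in ("original", "resample"):
            raise ConfigurationError(
                f"relapse_size must be 'original' or 'resample', got {self.relapse_size!r}"
            )


@dataclass
class ModelParams:
    """Everything the event loop needs for one run."""

    treatments: dict[str, TreatmentSpec]
    policy: PolicyParams
    life_table: LifeTable
    strata: CohortStrata | None = None

    def validate(self) -> None:
        self.policy.validate()
        for name in (MACI, MF, MBMS, PKR, TKR, TKR_REVISION):
            if name not in self.treatments:
                raise ConfigurationError(f"missing treatment spec {name!r}")
            spec = self.treatments[name]
            if spec.cost < 0:
                raise ConfigurationError(f"{name}: negative cost")
            if spec.failure_model is None:
                raise ConfigurationError(f"{name}: no failure model calibrated")


@dataclass(frozen=True)
class PatientState:
    """Decision-relevant state at a treatment-selection point."""

    defect: float
    age: float
    n_interventions: int = 0
    n_kr: int = 0
    n_tkr: int = 0
    n_revisions: int = 0
    repair_exhausted: bool = False


@dataclass(frozen=True)
class Event:
    time: float
    kind: str  # intervention | implant_failure | death | perioperative_death
    treatment: str | None = None
    defect_size: float = 0.0


@dataclass(frozen=True)
class Segment:
    """Maximal interval in one health state; utility bands run from start."""

    start: float
    end: float
    state: str


@dataclass
class Trajectory:
    profile: PatientProfile
    scenario: str
    events: list[Event]
    segments: list[Segment]
    death_age: float

    @property
    def intervention_times(self) -> list[float]:
        return [e.time for e in self.events if e.kind == "intervention"]

    def count(self, treatment: str) -> int:
        return sum(
            1
            for e in self.events
            if e.kind == "intervention" and e.treatment == treatment
        )


# ---------------------------------------------------------------------------
# Treatment selection
# ---------------------------------------------------------------------------

#: sentinel actions beyond actual treatments
WAIT = "wait"  # conservative care, re-evaluated annually
STOP_REPAIR = "stop_repair"  # repair options exhausted; moves to the KR track
STOP_KR = "stop_kr"  # terminal: no further knee replacement
TERMINAL = "terminal"  # terminal: no further repair (too old for any option)


def action_distribution(
    state: PatientState, scenario: str, params: ModelParams
) -> dict[str, float]:
    """Probability vector over actions for one presentation.

    Deterministic function of the state; `select_treatment` samples from it.
    Probabilities are only ever placed on treatments whose eligibility
    window (possibly policy-extended for mBMS) covers the state.
    """
    pol = params.policy
    tr = params.treatments
    d, age = state.defect, state.age

    # --- arthroplasty pathway: a KR has already failed -------------------
    if state.n_kr > 0:
        if state.n_tkr > 0:
            if (
                state.n_revisions < pol.max_tkr_revisions
                and age <= pol.revision_age_max
            ):
                return {TKR_REVISION: 1.0}
            return {STOP_KR: 1.0}
        # failed PKR: TKR when the age window allows, wait below it
        if tr[TKR].age_min <= age <= tr[TKR].age_max:
            p = pol.pkr_to_tkr_prob
            return {TKR: p, STOP_KR: 1.0 - p} if p < 1.0 else {TKR: 1.0}
        if age < tr[TKR].age_min:
            return {WAIT: 1.0}
        return {STOP_KR: 1.0}

    # --- repair options exhausted: waiting for arthroplasty ---------------
    if state.repair_exhausted:
        if age > tr[TKR].age_max:
            return {TERMINAL: 1.0}
        if age >= tr[TKR].age_min:
            p = pol.wait_tkr_prob[scenario]
            return {TKR: p, WAIT: 1.0 - p} if p < 1.0 else {TKR: 1.0}
        return {WAIT: 1.0}

    # --- repair pathway ---------------------------------------------------
    def band_repair() -> dict[str, float] | None:
        """Distribution over defect-size-matched repair options."""
        if tr[MF].eligible(d, age):
            return {MF: 1.0}
        if tr[MBMS].eligible(d, age):
            return {MBMS: 1.0}
        if d <= pol.mbms_extended_max:
            # mid-size band: no published option; extended mBMS or PKR
            p = pol.midband_pkr_prob[scenario]
            return {MBMS: 1.0 - p, PKR: p} if p > 0 else {MBMS: 1.0}
        if tr[PKR].eligible(d, age):
            return {PKR: 1.0}
        return None

    if state.n_interventions == 0:
        if scenario == WITH_MACI and pol.primary_maci_all:
            return {MACI: 1.0}
        repair = band_repair()
        if repair is not None:
            return repair
        if tr[TKR].eligible(d, age):
            return {TKR: 1.0}
        if age < tr[TKR].age_min and d > pol.mbms_extended_max:
            return {WAIT: 1.0}  # large defect, too young for TKR
        return {STOP_REPAIR: 1.0}

    # re-intervention after a failed repair
    if age > pol.repair_age_max:
        # too old for further cartilage repair; TKR only if window still open
        if tr[TKR].age_min <= age <= tr[TKR].age_max:
            return {TKR: 1.0}
        return {STOP_REPAIR: 1.0}

    dist: dict[str, float] = {}
    p_tkr = 0.0
    if tr[TKR].age_min <= age <= tr[TKR].age_max:
        p_tkr = pol.reint_tkr_prob[scenario]
        dist[TKR] = p_tkr
    rest = 1.0 - p_tkr
    p_pkr = pol.reint_pkr_prob[scenario]
    if p_pkr > 0 and rest > 0:
        dist[PKR] = dist.get(PKR, 0.0) + rest * p_pkr
        rest *= 1.0 - p_pkr
    if state.n_interventions >= 2 and rest > 0:
        stop = rest * pol.reint_stop_prob[scenario]
        if stop > 0:
            dist[STOP_REPAIR] = stop
            rest -= stop
    if rest > 0:
        repair = band_repair()
        if scenario == WITH_MACI and tr[MACI].eligible(d, age):
            renew = rest * pol.reint_maci_renew
            dist[MACI] = dist.get(MACI, 0.0) + renew
            rest -= renew
        if repair is not None:
            for name, p in repair.items():
                dist[name] = dist.get(name, 0.0) + rest * p
        elif tr[TKR].age_min <= age <= tr[TKR].age_max:
            dist[TKR] += rest
        else:
            dist[WAIT] = dist.get(WAIT, 0.0) + rest
    return dist


def select_treatment(
    state: PatientState,
    scenario: str,
    params: ModelParams,
    rng: np.random.Generator,
) -> str:
    """Sample one action from the policy distribution (one uniform)."""
    dist = action_distribution(state, scenario, params)
    actions = sorted(dist)
    probs = np.array([dist[a] for a in actions])
    total = probs.sum()
    if not np.isclose(total, 1.0):
        raise ConfigurationError(
            f"policy probabilities sum to {total} for state {state}"
        )
    u = rng.random()
    idx = int(np.searchsorted(np.cumsum(probs / total), u, side="right"))
    return actions[min(idx, len(actions) - 1)]


# ---------------------------------------------------------------------------
# Event loop
# ---------------------------------------------------------------------------


def _post_state(treatment: str) -> str:
    if treatment in (PKR, TKR, TKR_REVISION):
        return POST_KR
    if treatment == MF:
        return REPAIR_MF
    return REPAIR_ACI


def _symptomatic_state(n_kr: int, defect: float, mbms_max: float) -> str:
    if n_kr > 0:
        return BEFORE_SECOND_KR
    if defect > mbms_max:
        return BEFORE_FIRST_KR
    return BEFORE_REPAIR


def simulate_patient(
    profile: PatientProfile,
    scenario: str,
    params: ModelParams,
    death_age: float,
    failure_rng: np.random.Generator,
    select_rng: np.random.Generator,
    periop_rng: np.random.Generator,
    relapse_rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run one patient through one scenario until death."""
    pol = params.policy
    tr = params.treatments
    entry = profile.entry_age
    horizon = death_age - entry
    t = 0.0
    defect = profile.defect_size
    n_int = n_kr = n_tkr = n_rev = 0
    exhausted = False
    events: list[Event] = []
    segments: list[Segment] = []
    death_kind = "death"
    final_death_age = death_age

    def seg(a: float, b: float, state_key: str) -> None:
        if b > a:
            segments.append(Segment(a, b, state_key))

    while t < horizon:
        state = PatientState(
            defect=defect,
            age=entry + t,
            n_interventions=n_int,
            n_kr=n_kr,
            n_tkr=n_tkr,
            n_revisions=n_rev,
            repair_exhausted=exhausted,
        )
        action = select_treatment(state, scenario, params, select_rng)

        if action == WAIT:
            t_next = min(t + 1.0, horizon)
            if exhausted and n_kr == 0:
                wait_state = BEFORE_FIRST_KR
            else:
                wait_state = _symptomatic_state(n_kr, defect, pol.mbms_extended_max)
            seg(t, t_next, wait_state)
            t = t_next
            continue
        if action == STOP_REPAIR:
            # no further cartilage repair: degenerated knee awaits arthroplasty
            exhausted = True
            continue
        if action == TERMINAL:
            seg(t, horizon, NO_FURTHER_REPAIR)
            t = horizon
            break
        if action == STOP_KR:
            seg(t, horizon, NO_FURTHER_KR)
            t = horizon
            break

        spec = tr[action]
        events.append(
            Event(time=t, kind="intervention", treatment=action, defect_size=defect)
        )
        n_int += 1
        if action in (PKR, TKR):
            n_kr += 1
        if action == TKR:
            n_tkr += 1
        if action == TKR_REVISION:
            n_rev += 1

        if action in (TKR, TKR_REVISION):
            risk = tr[TKR].periop_risk(entry + t)
            if periop_rng.random() < risk:
                death_kind = "perioperative_death"
                final_death_age = entry + t
                horizon = t
                break

        ttf = sample_time_to_failure(spec.failure_model, failure_rng)
        fail_t = t + ttf
        post = spec.utility_key or _post_state(action)
        if fail_t >= horizon:
            seg(t, horizon, post)
            t = horizon
            break
        seg(t, fail_t, post)
        if pol.relapse_size == "resample" and relapse_rng is not None and n_kr == 0:
            from .population import BASELINE_STRATA, _sample_stratified

            strata = (params.strata or BASELINE_STRATA).defect_strata[profile.sex]
            defect = float(_sample_stratified(relapse_rng, strata, 1)[0][0])
        else:
            defect = profile.defect_size
        events.append(
            Event(time=fail_t, kind="implant_failure", treatment=action, defect_size=defect)
        )
        delay_end = min(fail_t + pol.symptomatic_delay, horizon)
        seg(fail_t, delay_end, _symptomatic_state(n_kr, defect, pol.mbms_extended_max))
        t = fail_t + pol.symptomatic_delay
    t = min(t, horizon)

    events.append(Event(time=horizon, kind=death_kind))
    return Trajectory(
        profile=profile,
        scenario=scenario,
        events=events,
        segments=segments,
        death_age=final_death_age,
    )


def run_scenarios(
    cohort: list[PatientProfile],
    params: ModelParams,
    seed: int,
    scenarios: tuple[str, ...] = SCENARIOS,
) -> dict[str, list[Trajectory]]:
    """Simulate every patient in both scenarios with common random numbers.

    Death age and the failure-quantile stream are identical across scenarios
    for each patient (common random numbers), so scenario contrasts are
    paired at the patient level; treatment-selection and perioperative draws
    are scenario-specific because the decision sequences differ.
    """
    if not cohort:
        raise ConfigurationError("cohort is empty")
    params.validate()
    out: dict[str, list[Trajectory]] = {s: [] for s in scenarios}
    for profile in cohort:
        pid = profile.patient_id
        death_age = sample_death_age(
            profile, params.life_table, substream(seed, pid, streams.DEATH)
        )
        for scen in scenarios:
            sel = streams.SELECTION if scen == WITH_MACI else streams.SELECTION_ALT
            per = streams.PERIOP if scen == WITH_MACI else streams.PERIOP_ALT
            fail_alt = streams.FAILURE if scen == WITH_MACI else streams.FAILURE_ALT
            failure_rng = PairedFailureStream(
                substream(seed, pid, streams.FAILURE_SHARED),
                substream(seed, pid, fail_alt),
            )
            traj = simulate_patient(
                profile,
                scen,
                params,
                death_age,
                failure_rng=failure_rng,
                select_rng=substream(seed, pid, sel),
                periop_rng=substream(seed, pid, per),
                relapse_rng=substream(seed, pid, RELAPSE_STREAM),
            )
            out[scen].append(traj)
    return out


# ---------------------------------------------------------------------------
# Trajectory summary statistics
# ---------------------------------------------------------------------------


def ever_received(trajs: list[Trajectory], treatment: str) -> float:
    """Fraction of patients with at least one event of the given treatment."""
    return float(np.mean([traj.count(treatment) > 0 for traj in trajs]))


def mean_surgeries(trajs: list[Trajectory]) -> float:
    return float(np.mean([len(traj.intervention_times) for traj in trajs]))


def mean_age_at(trajs: list[Trajectory], treatment: str) -> float:
    ages = []
    for traj in trajs:
        for e in traj.events:
            if e.kind == "intervention" and e.treatment == treatment:
                ages.append(traj.profile.entry_age + e.time)
                break
    return float(np.mean(ages)) if ages else math.nan


def second_surgery_fraction(trajs: list[Trajectory], by_time: float) -> float:
    """Kaplan-Meier estimate of the cumulative fraction of patients with a
    second surgical intervention by `by_time` years after entry, treating
    death before the second intervention as censoring."""
    times, observed = [], []
    for traj in trajs:
        ints = traj.intervention_times
        if len(ints) >= 2:
            times.append(ints[1])
            observed.append(True)
        else:
            times.append(traj.death_age - traj.profile.entry_age)
            observed.append(False)
    order = np.argsort(times)
    t_sorted = np.asarray(times)[order]
    obs_sorted = np.asarray(observed)[order]
    at_risk = len(times)
    surv = 1.0
    for t_i, is_event in zip(t_sorted, obs_sorted):
        if t_i > by_time:
            break
        if is_event:
            surv *= 1.0 - 1.0 / at_risk
        at_risk -= 1
    return 1.0 - surv
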