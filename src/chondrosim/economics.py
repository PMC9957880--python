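"""QALY and cost accrual along trajectories, discounting, ICER and CEAC.

Utilities are annual weights per health state, with within-state year bands
(e.g. first post-implantation year lower than steady state, microfracture
benefit decaying back to the symptomatic weight from year five).  Costs are
per-procedure amounts at event times plus a conservative-therapy rate per
year while symptomatic.  Point amounts are discounted continuously,
(1+r)**(-t); continuous streams are discounted in annual slices at their
slice-start factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import (
    BEFORE_FIRST_KR,
    BEFORE_REPAIR,
    BEFORE_SECOND_KR,
    NO_FURTHER_KR,
    NO_FURTHER_REPAIR,
    POST_KR,
    REPAIR_ACI,
    REPAIR_MF,
    SYMPTOMATIC_STATES,
    Trajectory,
)
from .population import ConfigurationError

#: utility bands: state -> list of (band end in years since state entry, weight)
DEFAULT_UTILITIES: dict[str, list[tuple[float, float]]] = {
    BEFORE_REPAIR: [(math.inf, 0.65)],
    REPAIR_ACI: [(1.0, 0.76), (math.inf, 0.82)],
    REPAIR_MF: [(1.0, 0.76), (4.0, 0.82), (math.inf, 0.65)],
    NO_FURTHER_REPAIR: [(math.inf, 0.69)],
    BEFORE_FIRST_KR: [(math.inf, 0.62)],
    POST_KR: [(math.inf, 0.78)],
    BEFORE_SECOND_KR: [(math.inf, 0.56)],
    NO_FURTHER_KR: [(math.inf, 0.69)],
}


@dataclass
class UtilitySchedule:
    """Annual utility weights per health state with year-within-state bands."""

    bands: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_UTILITIES.items()}
    )

    def validate(self) -> None:
        problems = []
        for state, b in self.bands.items():
            if not b or b[-1][0] != math.inf:
                problems.append(f"{state}: last band must be open-ended")
            for end, w in b:
                if not 0.0 <= w <= 1.0:
                    problems.append(f"{state}: weight {w} outside [0,1]")
            ends = [e for e, _ in b]
            if sorted(ends) != ends:
                problems.append(f"{state}: band ends not increasing")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def weight(self, state: str, years_in_state: float) -> float:
        try:
            bands = self.bands[state]
        except KeyError:
            raise ConfigurationError(f"no utility mapped for state {state!r}")
        for end, w in bands:
            if years_in_state < end:
                return w
        return bands[-1][1]

    def scaled(self, factor: float) -> "UtilitySchedule":
        """All weights multiplied by factor, capped at 1 (sensitivity knob)."""
        return UtilitySchedule(
            bands={
                s: [(e, min(w * factor, 1.0)) for e, w in b]
                for s, b in self.bands.items()
            }
        )


@dataclass
class CostLedger:
    """Per-procedure costs (EUR) and the conservative-therapy rate (EUR/yr)."""

    procedure_costs: dict[str, float]
    conservative_per_year: float = 800.0

    def validate(self) -> None:
        bad = [k for k, v in self.procedure_costs.items() if v < 0]
        if bad or self.conservative_per_year < 0:
            raise ConfigurationError(f"negative costs: {bad}")

    def cost_of(self, treatment: str) -> float:
        try:
            return self.procedure_costs[treatment]
        except KeyError:
            raise ConfigurationError(f"no cost mapped for treatment {treatment!r}")

    def scaled(self, treatment: str, factor: float) -> "CostLedger":
        costs = dict(self.procedure_costs)
        costs[treatment] = costs[treatment] * factor
        return CostLedger(costs, self.conservative_per_year)


def discount(amount: float, t: float, rate: float):
    """Present value of a point amount at time t (years): amount*(1+r)**-t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return amount * (1.0 + rate) ** (-t)


_CURVE_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}
_CURVE_YEARS = 256  # beyond any attainable lifetime


def _discount_curve(rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice factors D[k] = (1+r)^-k and their prefix sums."""
    try:
        return _CURVE_CACHE[rate]
    except KeyError:
        d = (1.0 + rate) ** (-np.arange(_CURVE_YEARS, dtype=float))
        prefix = np.concatenate([[0.0], np.cumsum(d)])
        _CURVE_CACHE[rate] = (d, prefix)
        return d, prefix


def _stream_value(a: float, b: float, per_year: float, rate: float) -> tuple[float, float]:
    """(undiscounted, discounted) value of a constant stream over [a, b).

    Discounted in annual slices [k, k+1) at the slice-start factor: the
    discounted year-equivalent of [0, t) is F(t) = sum_{j<k} D[j] +
    (t - k) D[k] with k = floor(t), so a segment contributes
    per_year * (F(b) - F(a)).
    """
    if b <= a:
        return 0.0, 0.0
    undisc = per_year * (b - a)
    if rate == 0.0:
        return undisc, undisc
    d, prefix = _discount_curve(rate)

    def F(t: float) -> float:
        k = int(t)
        return prefix[k] + (t - k) * d[k]

    return undisc, per_year * (F(b) - F(a))


@dataclass
class PatientEconomics:
    patient_id: int
    scenario: str
    cost: float
    cost_discounted: float
    qaly: float
    qaly_discounted: float


def accrue(
    trajectory: Trajectory,
    schedule: UtilitySchedule,
    ledger: CostLedger,
    rate: float = 0.02,
) -> PatientEconomics:
    """Accrue QALYs and costs along one trajectory.

    Between consecutive events the patient occupies exactly one health
    state; QALYs are weight x duration per band, costs are procedure costs
    at event times plus conservative therapy while symptomatic.
    """
    qaly = qaly_d = cost = cost_d = 0.0
    for seg in trajectory.segments:
        # split the segment at its utility band boundaries
        pos = seg.start
        for end, w in schedule.bands.get(seg.state) or _missing(seg):
            band_end = min(seg.start + end, seg.end)
            if band_end > pos:
                u, d = _stream_value(pos, band_end, w, rate)
                qaly += u
                qaly_d += d
                pos = band_end
            if pos >= seg.end:
                break
        if seg.state in SYMPTOMATIC_STATES:
            u, d = _stream_value(seg.start, seg.end, ledger.conservative_per_year, rate)
            cost += u
            cost_d += d
    for ev in trajectory.events:
        if ev.kind == "intervention":
            c = ledger.cost_of(ev.treatment)
            cost += c
            cost_d += float(discount(c, ev.time, rate))
    return PatientEconomics(
        patient_id=trajectory.profile.patient_id,
        scenario=trajectory.scenario,
        cost=cost,
        cost_discounted=cost_d,
        qaly=qaly,
        qaly_discounted=qaly_d,
    )


def _missing(seg):
    raise ConfigurationError(
        f"no utility mapped for state {seg.state!r} at t={seg.start:.2f}"
    )


# ---------------------------------------------------------------------------
# Cohort-level results
# ---------------------------------------------------------------------------


@dataclass
class IcerResult:
    incremental_cost: float
    incremental_qaly: float
    icer: float | None  # EUR per QALY; None when the QALY difference is 0
    dominant: bool  # lower cost, higher QALYs
    dominated: bool  # higher cost, lower QALYs


def compute_icer(incremental_cost: float, incremental_qaly: float) -> IcerResult:
    """ICER from incremental discounted means; flags dominance quadrants."""
    if incremental_qaly == 0.0:
        icer = None
    else:
        icer = incremental_cost / incremental_qaly
    return IcerResult(
        incremental_cost=incremental_cost,
        incremental_qaly=incremental_qaly,
        icer=icer,
        dominant=incremental_cost < 0 and incremental_qaly > 0,
        dominated=incremental_cost > 0 and incremental_qaly < 0,
    )


def compute_ceac(
    delta_costs: np.ndarray, delta_qalys: np.ndarray, wtp_grid
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability: for each willingness-to-pay level,
    the fraction of patients whose incremental net monetary benefit
    wtp * dQALY - dCost is >= 0."""
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise ConfigurationError("WTP grid is empty")
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    return [(float(l), float(np.mean(l * dq - dc >= 0.0))) for l in wtp_grid]


def dominant_fraction(delta_costs, delta_qalys) -> float:
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    return float(np.mean((dc < 0) & (dq > 0)))


@dataclass
class EconomicResult:
    """Per-patient and cohort-level economics of one paired run."""

    per_patient: dict  # scenario -> list[PatientEconomics]
    means: dict  # scenario -> dict of mean cost/qaly (both discount states)
    icer: IcerResult
    delta_costs_discounted: np.ndarray
    delta_qalys_discounted: np.ndarray

    @property
    def dominant_fraction(self) -> float:
        return dominant_fraction(
            self.delta_costs_discounted, self.delta_qalys_discounted
        )


def evaluate(
    paired: dict, schedule: UtilitySchedule, ledger: CostLedger, rate: float = 0.02
) -> EconomicResult:
    """Accrue both scenarios of a paired run and summarise."""
    schedule.validate()
    ledger.validate()
    per_patient = {
        scen: [accrue(traj, schedule, ledger, rate) for traj in trajs]
        for scen, trajs in paired.items()
    }
    means = {}
    for scen, econs in per_patient.items():
        means[scen] = {
            "cost": float(np.mean([e.cost for e in econs])),
            "cost_discounted": float(np.mean([e.cost_discounted for e in econs])),
            "qaly": float(np.mean([e.qaly for e in econs])),
            "qaly_discounted": float(np.mean([e.qaly_discounted for e in econs])),
        }
    from .engine import WITH_MACI, WITHOUT_MACI

    w, wo = per_patient[WITH_MACI], per_patient[WITHOUT_MACI]
    dc = np.array([a.cost_discounted - b.cost_discounted for a, b in zip(w, wo)])
    dq = np.array([a.qaly_discounted - b.qaly_discounted for a, b in zip(w, wo)])
    icer = compute_icer(float(np.mean(dc)), float(np.mean(dq)))
    return EconomicResult(
        per_patient=per_patient,
        means=means,
        icer=icer,
        delta_costs_discounted=dc,
        delta_qalys_discounted=dq,
    )
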