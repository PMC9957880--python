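"""Synthetic cohort generation and all-cause mortality.

The study population is a cohort of patients presenting with a symptomatic
articular cartilage defect of the knee.  Only marginal distributions of the
source population are public (sex split, age strata, defect-size strata, and
per-sex means), so the generator samples stratified marginals treating age
and defect size as independent given sex, then applies a per-sex affine
(shift-only) correction so the sample means match the published targets.

All-cause mortality comes from a life table: per-sex annual death
probabilities q(sex, age).  The packaged default is a Gompertz–Makeham
parametrisation per sex calibrated so the baseline cohort has a median death
age of about 84 years (median modelled horizon about 48 years); an arbitrary
life table can be loaded from CSV (columns ``sex,age,qx``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .streams import COHORT, DEATH, substream

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

AGE_MIN, AGE_MAX = 15.0, 70.0
DEFECT_MIN, DEFECT_MAX = 0.0, 20.0


class ConfigurationError(ValueError):
    """Invalid strata, life table, or other configuration input."""


@dataclass(frozen=True)
class PatientProfile:
    """Fixed attributes of one simulated individual."""

    patient_id: int
    sex: str
    entry_age: float
    defect_size: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if not (AGE_MIN <= self.entry_age <= AGE_MAX):
            raise ConfigurationError(
                f"entry_age {self.entry_age} outside [{AGE_MIN}, {AGE_MAX}]"
            )
        if not (DEFECT_MIN < self.defect_size <= DEFECT_MAX):
            raise ConfigurationError(
                f"defect_size {self.defect_size} outside ({DEFECT_MIN}, {DEFECT_MAX}]"
            )


@dataclass(frozen=True)
class Stratum:
    lower: float
    upper: float
    proportion: float


def _check_strata(name: str, strata: Sequence[Stratum]) -> None:
    total = sum(s.proportion for s in strata)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"{name}: stratum proportions sum to {total!r}, expected 1"
        )
    for i, s in enumerate(strata):
        if s.lower > s.upper:
            raise ConfigurationError(f"{name}[{i}]: lower {s.lower} > upper {s.upper}")
        if s.proportion < 0:
            raise ConfigurationError(f"{name}[{i}]: negative proportion")
        if i > 0 and s.lower < strata[i - 1].upper:
            raise ConfigurationError(
                f"{name}[{i}]: overlaps previous stratum "
                f"({s.lower} < {strata[i - 1].upper})"
            )


@dataclass(frozen=True)
class CohortStrata:
    """Marginal strata per sex, with optional mean targets."""

    sex_probabilities: dict  # sex -> proportion
    age_strata: dict  # sex -> list of Stratum
    defect_strata: dict  # sex -> list of Stratum
    age_mean: dict = field(default_factory=dict)  # sex -> target mean or None
    defect_mean: dict = field(default_factory=dict)

    def validate(self) -> None:
        total = sum(self.sex_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"sex probabilities sum to {total!r}")
        for sex in self.sex_probabilities:
            if sex not in SEXES:
                raise ConfigurationError(f"unknown sex {sex!r}")
            _check_strata(f"age[{sex}]", self.age_strata[sex])
            _check_strata(f"defect[{sex}]", self.defect_strata[sex])


def _stratum(lower, upper, proportion):
    return Stratum(float(lower), float(upper), float(proportion))


#: Default strata reproducing the published baseline cohort.  Open-ended
#: strata are closed at 70 yr (age) and 15 cm² (defect size); lowest defect
#: stratum starts at 0.5 cm² (smaller lesions are rarely surgical candidates).
BASELINE_STRATA = CohortStrata(
    sex_probabilities={MALE: 0.6069, FEMALE: 0.3931},
    age_strata={
        MALE: [
            _stratum(15, 35, 0.467),
            _stratum(35, 45, 0.300),
            _stratum(45, 55, 0.207),
            _stratum(55, 70, 0.026),
        ],
        FEMALE: [
            _stratum(15, 35, 0.432),
            _stratum(35, 45, 0.288),
            _stratum(45, 55, 0.251),
            _stratum(55, 70, 0.029),
        ],
    },
    defect_strata={
        MALE: [
            _stratum(0.5, 2, 0.123),
            _stratum(2, 4, 0.334),
            _stratum(4, 6, 0.272),
            _stratum(6, 8, 0.123),
            _stratum(8, 10, 0.106),
            _stratum(10, 15, 0.042),
        ],
        FEMALE: [
            _stratum(0.5, 2, 0.156),
            _stratum(2, 4, 0.368),
            _stratum(4, 6, 0.252),
            _stratum(6, 8, 0.106),
            _stratum(8, 10, 0.086),
            _stratum(10, 15, 0.032),
        ],
    },
    age_mean={MALE: 35.9, FEMALE: 36.6},
    defect_mean={MALE: 4.5, FEMALE: 4.1},
)


def _sample_stratified(
    rng: np.random.Generator, strata: Sequence[Stratum], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n values: pick a stratum by proportion, then uniform within it."""
    props = np.array([s.proportion for s in strata])
    idx = rng.choice(len(strata), size=n, p=props / props.sum())
    lo = np.array([s.lower for s in strata])[idx]
    hi = np.array([s.upper for s in strata])[idx]
    return lo + (hi - lo) * rng.random(n), idx


def _mean_match(values: np.ndarray, lo: np.ndarray, hi: np.ndarray, target: float) -> np.ndarray:
    """Shift values so the clipped mean hits target; clip to stratum bounds.

    mean(clip(v + d, lo, hi)) is continuous and non-decreasing in d, so the
    shift is found by bracketing root search.  Values are clipped just below
    the upper bound so half-open stratum membership [lower, upper) is
    preserved; degenerate strata (lo == hi) pass through unchanged.
    """
    hi = np.where(hi > lo, np.nextafter(hi, -np.inf), hi)

    def shifted_mean(d: float) -> float:
        return float(np.mean(np.clip(values + d, lo, hi)))

    base = shifted_mean(0.0)
    if abs(base - target) < 1e-12:
        return values
    span = float(np.max(hi) - np.min(lo)) + 1.0
    f_lo, f_hi = shifted_mean(-span) - target, shifted_mean(span) - target
    if f_lo > 0 or f_hi < 0:
        # target unreachable inside the strata support; clip as far as possible
        d = -span if f_lo > 0 else span
    else:
        d = brentq(lambda x: shifted_mean(x) - target, -span, span, xtol=1e-10)
    return np.clip(values + d, lo, hi)


def sample_cohort(n: int, strata: CohortStrata | None = None, seed: int = 0) -> list[PatientProfile]:
    """Generate a synthetic cohort of n patients.

    Sex is drawn from the configured split; age and defect size are drawn by
    stratified-uniform sampling per sex, then mean-matched (shift-only, values
    clipped to their stratum bounds) to the per-sex targets when targets are
    configured.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    strata = BASELINE_STRATA if strata is None else strata
    strata.validate()

    rng = substream(seed, 0, COHORT)
    sexes = list(strata.sex_probabilities)
    probs = np.array([strata.sex_probabilities[s] for s in sexes])
    sex_idx = rng.choice(len(sexes), size=n, p=probs / probs.sum())

    ages = np.empty(n)
    defects = np.empty(n)
    for si, sex in enumerate(sexes):
        mask = sex_idx == si
        m = int(mask.sum())
        if m == 0:
            continue
        for dim, store, target in (
            ("age", ages, strata.age_mean.get(sex)),
            ("defect", defects, strata.defect_mean.get(sex)),
        ):
            sdef = strata.age_strata[sex] if dim == "age" else strata.defect_strata[sex]
            vals, idx = _sample_stratified(rng, sdef, m)
            if target is not None:
                lo = np.array([s.lower for s in sdef])[idx]
                hi = np.array([s.upper for s in sdef])[idx]
                vals = _mean_match(vals, lo, hi, float(target))
            store[mask] = vals

    return [
        PatientProfile(
            patient_id=i,
            sex=sexes[sex_idx[i]],
            entry_age=float(ages[i]),
            defect_size=float(max(defects[i], 1e-6)),
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: Iterable[PatientProfile]):
    """Cohort as a pandas DataFrame (export schema)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "entry_age": p.entry_age,
                "defect_size_cm2": p.defect_size,
            }
            for p in cohort
        ]
    )


# ---------------------------------------------------------------------------
# Life tables
# ---------------------------------------------------------------------------


@dataclass
class LifeTable:
    """Per-sex annual death probabilities for integer ages 0..max_age."""

    qx: dict  # sex -> np.ndarray of length max_age + 1
    max_age: int

    def validate(self) -> None:
        problems = []
        for sex in SEXES:
            if sex not in self.qx:
                problems.append(f"missing sex {sex!r}")
                continue
            q = self.qx[sex]
            if len(q) != self.max_age + 1:
                problems.append(
                    f"{sex}: {len(q)} rows, expected ages 0..{self.max_age}"
                )
                continue
            bad = np.flatnonzero((q < 0) | (q > 1))
            if bad.size:
                problems.append(f"{sex}: qx outside [0,1] at ages {bad.tolist()[:5]}")
            if q[self.max_age] != 1.0:
                problems.append(f"{sex}: qx at max_age {self.max_age} must be 1")
            tail = q[60:]
            if np.any(np.diff(tail) < -1e-12):
                problems.append(f"{sex}: qx not non-decreasing beyond age 60")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def q(self, sex: str, age: int) -> float:
        return float(self.qx[sex][min(int(age), self.max_age)])

    def _knots(self, sex: str, entry_age: float) -> tuple[np.ndarray, np.ndarray]:
        """Age knots and survival-from-entry at each knot (piecewise linear
        CDF: death is uniform within its year)."""
        q = self.qx[sex]
        first = int(np.floor(entry_age))
        frac = first + 1 - entry_age
        ages = [entry_age]
        surv = [1.0]
        s = (1.0 - q[min(first, self.max_age)]) ** frac
        ages.append(first + 1)
        surv.append(s)
        a = first + 1
        while s > 0 and a <= self.max_age:
            s *= 1.0 - q[a]
            a += 1
            ages.append(a)
            surv.append(s)
        return np.asarray(ages, dtype=float), np.asarray(surv)

    def survival_from(self, sex: str, entry_age: float, ages: np.ndarray) -> np.ndarray:
        """Analytic survival-from-entry evaluated at arbitrary ages."""
        knots, surv = self._knots(sex, entry_age)
        return np.interp(np.asarray(ages, dtype=float), knots, surv)

    def median_death_age(self, sex: str, entry_age: float) -> float:
        knots, surv = self._knots(sex, entry_age)
        # survival decreasing: find where it crosses 0.5
        idx = int(np.searchsorted(-surv, -0.5))
        idx = min(max(idx, 1), len(knots) - 1)
        s0, s1 = surv[idx - 1], surv[idx]
        if s0 == s1:
            return float(knots[idx])
        w = (s0 - 0.5) / (s0 - s1)
        return float(knots[idx - 1] + w * (knots[idx] - knots[idx - 1]))


def sample_death_age(
    profile: PatientProfile, table: LifeTable, rng: np.random.Generator
) -> float:
    """Draw a death age for one patient by inverting the piecewise-linear
    lifetime CDF implied by annual death probabilities with uniform placement
    of death within its year.  Uses exactly one uniform from rng."""
    if profile.entry_age >= table.max_age:
        raise ValueError(
            f"entry_age {profile.entry_age} >= life-table max_age {table.max_age}"
        )
    knots, surv = table._knots(profile.sex, profile.entry_age)
    u = rng.random()
    target = 1.0 - u  # survival level at death
    idx = int(np.searchsorted(-surv, -target))
    idx = min(max(idx, 1), len(knots) - 1)
    s0, s1 = surv[idx - 1], surv[idx]
    w = 0.5 if s0 == s1 else (s0 - target) / (s0 - s1)
    death = knots[idx - 1] + w * (knots[idx] - knots[idx - 1])
    return float(min(death, table.max_age))


def death_age_for(profile: PatientProfile, table: LifeTable, seed: int) -> float:
    """Death age from the patient's dedicated death stream (shared by both
    scenarios of a paired run)."""
    return sample_death_age(profile, table, substream(seed, profile.patient_id, DEATH))


#: Gompertz–Makeham hazard h(x) = a + b * exp(g * x), per sex.  Calibrated so
#: the baseline cohort reaches a median death age of ~84 yr with the female
#: median life expectancy above the male one.
DEFAULT_GOMPERTZ_MAKEHAM = {
    MALE: {"a": 3.0e-4, "b": 6.8e-6, "g": 0.112},
    FEMALE: {"a": 2.0e-4, "b": 3.2e-6, "g": 0.117},
    "max_age": 110,
}


def life_table_from_parametric(spec: dict | None = None) -> LifeTable:
    """Expand a Gompertz–Makeham spec to an integer-age life table.

    q(x) = 1 - exp(-integral of the hazard over [x, x+1)); q(max_age) = 1.
    """
    spec = DEFAULT_GOMPERTZ_MAKEHAM if spec is None else spec
    max_age = int(spec.get("max_age", 110))
    qx = {}
    for sex in SEXES:
        p = spec[sex]
        a, b, g = float(p["a"]), float(p["b"]), float(p["g"])
        x = np.arange(max_age + 1, dtype=float)
        if g == 0:
            cumhaz = np.full_like(x, a + b)
        else:
            cumhaz = a + (b / g) * (np.exp(g * (x + 1)) - np.exp(g * x))
        q = 1.0 - np.exp(-cumhaz)
        q = np.clip(q, 0.0, 1.0)
        q[60:] = np.maximum.accumulate(q[60:])  # monotone tail (Gompertz already is)
        q[max_age] = 1.0
        qx[sex] = q
    table = LifeTable(qx=qx, max_age=max_age)
    table.validate()
    return table


def default_life_table() -> LifeTable:
    return life_table_from_parametric(DEFAULT_GOMPERTZ_MAKEHAM)


def load_life_table(source) -> LifeTable:
    """Load a life table from a CSV path (columns sex,age,qx) or expand a
    parametric spec dict."""
    if isinstance(source, dict):
        return life_table_from_parametric(source)
    rows: dict[str, dict[int, float]] = {s: {} for s in SEXES}
    problems = []
    with open(source, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"sex", "age", "qx"} <= set(reader.fieldnames):
            raise ConfigurationError("life-table CSV must have header sex,age,qx")
        for lineno, row in enumerate(reader, start=2):
            sex = row["sex"].strip().lower()
            if sex not in SEXES:
                problems.append(f"row {lineno}: unknown sex {row['sex']!r}")
                continue
            try:
                age = int(row["age"])
                q = float(row["qx"])
            except ValueError:
                problems.append(f"row {lineno}: non-numeric age/qx")
                continue
            if not 0 <= q <= 1:
                problems.append(f"row {lineno}: qx {q} outside [0,1]")
            rows[sex][age] = q
    if problems:
        raise ConfigurationError("; ".join(problems))
    if not rows[MALE] or not rows[FEMALE]:
        raise ConfigurationError("life-table CSV missing one or both sexes")
    max_age = min(max(rows[s]) for s in SEXES)
    qx = {}
    for sex in SEXES:
        missing = [a for a in range(max_age + 1) if a not in rows[sex]]
        if missing:
            raise ConfigurationError(
                f"{sex}: missing ages {missing[:10]} (coverage must be 0..{max_age})"
            )
        qx[sex] = np.array([rows[sex][a] for a in range(max_age + 1)])
        qx[sex][max_age] = 1.0
    table = LifeTable(qx=qx, max_age=max_age)
    table.validate()
    return table
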