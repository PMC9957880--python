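"""Two-component Weibull failure-time models for repairs and implants.

Each intervention's durability is described by a mixture of two Weibull
components: a short-term component capturing early failure (graft
non-integration, early symptomatic relapse) and a long-term wear-out
component.  The mixture survival is

    S(t) = w * exp(-(t/lam_s)**k_s) + (1 - w) * exp(-(t/lam_l)**k_l)

Calibration is anchored on survivorship points: the long-term component is
fitted through published/configured long-term survivorship anchors (closed
form through two points, least squares on the log-log linearised survival
for more, fixed shape for a single anchor), and the short-term scale is then
solved so the *mixture* reproduces the 2-year failure probability exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log
from typing import Sequence

import numpy as np
from scipy.optimize import brentq


class CalibrationError(ValueError):
    """Anchors inconsistent or calibration infeasible."""


@dataclass(frozen=True)
class SurvivorshipAnchor:
    """One survivorship point: S(time) = survival."""

    time: float
    survival: float

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise CalibrationError(f"anchor time {self.time} must be > 0")
        if not 0.0 < self.survival < 1.0:
            raise CalibrationError(
                f"anchor survival {self.survival} must be in (0, 1)"
            )


@dataclass(frozen=True)
class WeibullComponent:
    """Single Weibull with shape k and scale lam (years)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise CalibrationError(
                f"shape and scale must be > 0 (got k={self.shape}, lam={self.scale})"
            )

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-((t / self.scale) ** self.shape))

    def quantile(self, u):
        """Inverse CDF: time by which a fraction u has failed."""
        u = np.asarray(u, dtype=float)
        return self.scale * (-np.log1p(-u)) ** (1.0 / self.shape)


def fit_weibull_two_point(
    anchor_a: SurvivorshipAnchor, anchor_b: SurvivorshipAnchor
) -> WeibullComponent:
    """Closed-form Weibull through two survivorship points.

    k = ln(ln S(t1) / ln S(t2)) / ln(t1 / t2), lam from the first anchor.
    """
    a, b = sorted((anchor_a, anchor_b), key=lambda x: x.time)
    if a.time == b.time:
        raise CalibrationError("anchors must have distinct times")
    if b.survival >= a.survival:
        raise CalibrationError(
            f"survival must be strictly decreasing in time "
            f"(S({a.time})={a.survival}, S({b.time})={b.survival})"
        )
    k = log(log(a.survival) / log(b.survival)) / log(a.time / b.time)
    lam = a.time / (-log(a.survival)) ** (1.0 / k)
    return WeibullComponent(shape=k, scale=lam)


def fit_weibull_anchors(
    anchors: Sequence[SurvivorshipAnchor], fixed_shape: float | None = None
) -> WeibullComponent:
    """Fit one Weibull through >= 1 anchors.

    Two anchors: exact closed form.  More: least squares on the linearised
    form ln(-ln S) = k ln t - k ln lam.  A single anchor needs a fixed shape.
    """
    anchors = sorted(anchors, key=lambda a: a.time)
    for prev, cur in zip(anchors, anchors[1:]):
        if cur.survival > prev.survival:
            raise CalibrationError(
                f"anchors not non-increasing at t={cur.time}"
            )
    if len(anchors) == 1:
        if fixed_shape is None:
            raise CalibrationError("a single anchor requires a fixed shape")
        a = anchors[0]
        lam = a.time / (-log(a.survival)) ** (1.0 / fixed_shape)
        return WeibullComponent(shape=fixed_shape, scale=lam)
    if len(anchors) == 2:
        return fit_weibull_two_point(anchors[0], anchors[1])
    x = np.log([a.time for a in anchors])
    y = np.log([-log(a.survival) for a in anchors])
    k, intercept = np.polyfit(x, y, 1)
    if k <= 0:
        raise CalibrationError("least-squares shape not positive; check anchors")
    lam = exp(-intercept / k)
    return WeibullComponent(shape=float(k), scale=float(lam))


@dataclass(frozen=True)
class FailureModel:
    """Two-component Weibull mixture; weight w on the short-term component."""

    short_term: WeibullComponent
    long_term: WeibullComponent
    mixture_weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise CalibrationError(
                f"mixture weight {self.mixture_weight} outside [0, 1]"
            )

    def survival(self, t):
        w = self.mixture_weight
        return w * self.short_term.survival(t) + (1 - w) * self.long_term.survival(t)

    def cdf(self, t):
        return 1.0 - self.survival(t)

    def quantile(self, u: float) -> float:
        """Numeric inverse of the mixture CDF."""
        if not 0.0 <= u < 1.0:
            raise ValueError("u must be in [0, 1)")
        if u == 0.0:
            return 0.0
        hi = max(self.short_term.scale, self.long_term.scale)
        while self.cdf(hi) < u:
            hi *= 2.0
        return float(brentq(lambda t: self.cdf(t) - u, 0.0, hi, xtol=1e-10))

    def median(self) -> float:
        return self.quantile(0.5)


def calibrate_failure_model(
    two_year_failure: float,
    long_term_anchors: Sequence[SurvivorshipAnchor | dict],
    mixture_weight: float = 0.5,
    short_shape: float = 1.0,
    long_shape: float | None = 2.5,
) -> FailureModel:
    """Calibrate a mixture so S(2) = 1 - two_year_failure exactly.

    The long-term component is fitted through the long-term anchors alone;
    the short-term scale is then solved (at the configured short shape) so
    the mixture passes through the 2-year point.
    """
    if not 0.0 < two_year_failure < 1.0:
        raise CalibrationError(
            f"two_year_failure {two_year_failure} must be in (0, 1)"
        )
    anchors = [
        a if isinstance(a, SurvivorshipAnchor) else SurvivorshipAnchor(a["t"], a["s"])
        for a in long_term_anchors
    ]
    if not anchors or min(a.time for a in anchors) <= 2.0:
        raise CalibrationError("need at least one long-term anchor with t > 2 yr")
    long_term = fit_weibull_anchors(anchors, fixed_shape=long_shape)

    s2_target = 1.0 - two_year_failure
    w = mixture_weight
    if w == 0.0:
        # degenerate: no short-term component; keep a placeholder with no mass
        if abs(float(long_term.survival(2.0)) - s2_target) > 1e-6:
            raise CalibrationError(
                "mixture_weight 0 leaves the 2-year point to the long-term "
                "component, which does not pass through it"
            )
        return FailureModel(WeibullComponent(1.0, 1.0), long_term, 0.0)
    s2_short = (s2_target - (1 - w) * float(long_term.survival(2.0))) / w
    if not 0.0 < s2_short < 1.0:
        raise CalibrationError(
            f"infeasible calibration: implied short-term S(2) = {s2_short:.4f} "
            "(long-term component already fails more than the 2-year target)"
        )
    lam_s = 2.0 / (-log(s2_short)) ** (1.0 / short_shape)
    short_term = WeibullComponent(shape=short_shape, scale=lam_s)
    return FailureModel(short_term, long_term, w)


def sample_time_to_failure(model: FailureModel, rng: np.random.Generator) -> float:
    """Inverse-CDF draw: pick a component by the mixture weight, then
    t = lam * (-ln U)**(1/k).  Consumes exactly two uniforms, so paired
    scenario runs stay in lockstep."""
    u_comp = rng.random()
    u_time = rng.random()
    comp = model.short_term if u_comp < model.mixture_weight else model.long_term
    return float(comp.quantile(u_time))
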