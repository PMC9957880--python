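"""One-way tornado analysis and named scenario analyses.

The tornado perturbs each scalar input by a fixed ±20% around its baseline,
reruns the full paired simulation with the same seed and cohort (all other
randomness unchanged), and records the ICER at both ends.  Scenario
analyses apply absolute overrides (e.g. a 4.5% discount rate, or
microfracture eligibility up to 5 cm²) and rerun the paired study.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from . import config as cfgm
from . import economics as econ
from .population import ConfigurationError


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    value_low: float
    value_high: float
    icer_low: float | None
    icer_high: float | None
    icer_baseline: float | None

    @property
    def swing(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return 0.0
        return abs(self.icer_high - self.icer_low)


def default_tornado_parameters() -> list[str]:
    """All published scalar inputs: procedure costs, 2-year failure rates,
    the conservative-therapy rate, and a global utility multiplier."""
    params = [f"treatments.{name}.cost" for name in
              ("maci", "microfracture", "mbms", "pkr", "tkr", "tkr_revision")]
    params += [f"failure.{name}.two_year" for name in
               ("maci", "microfracture", "mbms", "pkr", "tkr")]
    params += ["economics.conservative_cost_per_year", "economics.utility_multiplier"]
    return params


def _icer_for(cfg: dict, n: int, seed: int) -> float | None:
    _, _, result = cfgm.run_paired(cfg, n=n, seed=seed)
    return result.icer.icer


def tornado(
    cfg: dict,
    parameters: list[str] | None = None,
    seed: int | None = None,
    n: int | None = None,
    spread: float = 0.20,
) -> list[TornadoEntry]:
    """±20% one-way analysis; entries sorted by ICER swing, descending.

    The input config is never mutated; every arm reruns both scenarios with
    the identical seed so parameter effects are isolated from Monte-Carlo
    noise.
    """
    cfgm.validate_config(cfg)
    if parameters is None:
        parameters = default_tornado_parameters()
    seed = cfg["seed"] if seed is None else seed
    n = cfg["n"] if n is None else n
    if not parameters:
        return []
    baseline = _icer_for(copy.deepcopy(cfg), n, seed)
    entries = []
    for param in parameters:
        base_val = cfgm.get_path(cfg, param)
        if not isinstance(base_val, (int, float)):
            raise ConfigurationError(f"tornado parameter {param!r} is not scalar")
        arms = {}
        for tag, factor in (("low", 1.0 - spread), ("high", 1.0 + spread)):
            arm_cfg = copy.deepcopy(cfg)
            cfgm.set_path(arm_cfg, param, base_val * factor)
            arms[tag] = _icer_for(arm_cfg, n, seed)
        entries.append(
            TornadoEntry(
                parameter=param,
                value_low=base_val * (1.0 - spread),
                value_high=base_val * (1.0 + spread),
                icer_low=arms["low"],
                icer_high=arms["high"],
                icer_baseline=baseline,
            )
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


#: the named scenario analyses reported alongside the base case
NAMED_SCENARIOS: dict[str, dict] = {
    "discount_4_5": {"economics.discount_rate": 0.045},
    "mf_up_to_5cm2": {"treatments.microfracture.defect_max": 5.0},
}


def run_scenario_analysis(
    overrides: dict | str,
    cfg: dict,
    seed: int | None = None,
    n: int | None = None,
) -> tuple[econ.EconomicResult, dict]:
    """Full paired run under absolute overrides (dotted path -> value).

    `overrides` may be a named scenario.  Returns the economic result and a
    summary dict; the baseline config is left untouched.
    """
    if isinstance(overrides, str):
        try:
            overrides = NAMED_SCENARIOS[overrides]
        except KeyError:
            raise ConfigurationError(
                f"unknown scenario {overrides!r}; known: {sorted(NAMED_SCENARIOS)}"
            )
    arm_cfg = copy.deepcopy(cfg)
    for path, value in overrides.items():
        cfgm.set_path(arm_cfg, path, value)
    cfgm.validate_config(arm_cfg)
    seed = arm_cfg["seed"] if seed is None else seed
    n = arm_cfg["n"] if n is None else n
    _, paired, result = cfgm.run_paired(arm_cfg, n=n, seed=seed)
    summary = cfgm.summarize(arm_cfg, paired, result)
    return result, summary
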