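"""Policy-scenario machinery: timed transference-rate overrides and
baseline-vs-scenario comparison.

A scenario is a list of overrides, each raising one rate (tau1..tau4) to a
floor value for a set of age groups over a calendar window -- e.g. school
food-and-activity programmes lifting the recovery rates tau3 (obese ->
overweight) and tau4 (overweight -> not overweight) to 0.02/year for ages
5-14 from 2011 to 2030.  Overrides are *floors*: the effective rate is
``max(baseline, value)`` inside the window ("raise the rate to 0.02"), the
untouched baseline outside it.  Overrides leave births, deaths and aging
untouched, so scenario runs conserve population exactly as the baseline
does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import AGE_GROUP_LABELS, N_AGE_GROUPS, TransferenceRateTable
from .simulate import ProjectionResult

__all__ = [
    "Override",
    "ScenarioSpec",
    "apply_scenario",
    "scenario_rates",
    "compare",
    "school_age_recovery_scenario",
    "youth_recovery_scenario",
]


@dataclass(frozen=True)
class Override:
    """One timed rate override.

    ``age_groups`` are group indices (0 = ages 0-4, ..., 11 = 55-59);
    ``tau_index`` is 1..4; ``value`` is the floor (fraction/year) applied
    while ``start <= t <= end``; ``mode`` is ``"floor"`` (default,
    max(baseline, value)) or ``"replace"``.
    """

    age_groups: tuple[int, ...]
    tau_index: int
    value: float
    start: float
    end: float
    mode: str = "floor"

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_groups", tuple(int(g) for g in self.age_groups))
        for g in self.age_groups:
            if not 0 <= g < N_AGE_GROUPS:
                raise ValueError(f"age group {g} out of range 0..{N_AGE_GROUPS - 1}")
        if self.tau_index not in (1, 2, 3, 4):
            raise ValueError("tau_index must be 1..4")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("override value must lie in [0, 1]")
        if self.start > self.end:
            raise ValueError("override start must not exceed end")
        if self.mode not in ("floor", "replace"):
            raise ValueError(f"unknown override mode {self.mode!r}")

    def active(self, t: float) -> bool:
        return self.start <= t <= self.end


@dataclass(frozen=True)
class ScenarioSpec:
    """A labelled collection of overrides; empty list = baseline."""

    label: str = "scenario"
    overrides: tuple[Override, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "overrides", tuple(self.overrides))


def apply_scenario(
    rates: TransferenceRateTable, spec: ScenarioSpec, t: float
) -> TransferenceRateTable:
    """Effective TR table at time ``t`` under ``spec``.

    Inactive overrides leave the baseline untouched; the overridden table is
    re-validated, so an infeasible combination (tau2 + tau4 > 1) raises.
    """
    active = [o for o in spec.overrides if o.active(t)]
    if not active:
        return rates
    tau = rates.tau.copy()
    for o in active:
        col = o.tau_index - 1
        for g in o.age_groups:
            if o.mode == "floor":
                tau[g, col] = max(tau[g, col], o.value)
            else:
                tau[g, col] = o.value
    return rates.replace(tau)


def scenario_rates(
    rates: TransferenceRateTable, spec: ScenarioSpec
) -> Callable[[float], TransferenceRateTable]:
    """Time-varying rates callable for :func:`~nutristage.simulate.run_projection`.

    Tables are cached per activation pattern, so the per-step cost is a
    dictionary lookup.
    """
    cache: dict[tuple[bool, ...], TransferenceRateTable] = {}

    def at(t: float) -> TransferenceRateTable:
        key = tuple(o.active(t) for o in spec.overrides)
        if key not in cache:
            if not any(key):
                cache[key] = rates
            else:
                sub = ScenarioSpec(
                    spec.label, tuple(o for o, a in zip(spec.overrides, key) if a)
                )
                cache[key] = apply_scenario(rates, sub, t)
        return cache[key]

    return at


def compare(
    baseline: ProjectionResult,
    scenario: ProjectionResult,
    age_groups: Sequence[int] | range,
    year: int,
    categories: Sequence[str] = ("overweight", "obese"),
) -> pd.DataFrame:
    """Prevalence differences between a scenario and its baseline.

    For each category, reports the aggregate prevalence over ``age_groups``
    in ``year`` under both runs, the percentage-point difference
    (scenario - baseline) and the percent relative change
    ``(scenario - baseline) / baseline * 100``.  The relative change is the
    headline metric; both are emitted.
    """
    if baseline.years != scenario.years:
        raise ValueError("baseline and scenario are on different calendars")
    if int(year) not in baseline.years:
        raise ValueError(f"year {year} not in the run calendar")
    idx = list(age_groups)
    rows = []
    for cat in categories:
        b = baseline.prevalence(year, cat, idx)
        s = scenario.prevalence(year, cat, idx)
        rows.append(
            {
                "category": cat,
                "baseline": b,
                "scenario": s,
                "diff_points": s - b,
                "relative_change_pct": 0.0 if b == 0 else (s - b) / b * 100.0,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def school_age_recovery_scenario(
    value: float = 0.02, start: float = 2011.0, end: float = 2030.0
) -> ScenarioSpec:
    """Recovery-rate floor (tau3, tau4 -> ``value``) for ages 5-14:
    school-based healthy-food and physical-activity programmes."""
    groups = (1, 2)
    return ScenarioSpec(
        "school_age_recovery",
        (
            Override(groups, 3, value, start, end),
            Override(groups, 4, value, start, end),
        ),
    )


def youth_recovery_scenario(
    value: float = 0.02, start: float = 2011.0, end: float = 2030.0
) -> ScenarioSpec:
    """Same recovery-rate floor applied to ages 15-24, the ages where the
    rates towards overweight rise steeply."""
    groups = (3, 4)
    return ScenarioSpec(
        "youth_recovery",
        (
            Override(groups, 3, value, start, end),
            Override(groups, 4, value, start, end),
        ),
    )
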