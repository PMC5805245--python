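"""Parallel simulation of socioeconomic strata and between-strata summaries.

The three SES strata (lower = wealth-index quintiles 1-2, middle = quintile
3, higher = quintiles 4-5) run as independent copies of the aging chain on a
shared calendar -- individuals never move between strata.  This module adds
the obesity prevalence ratio (adult lower-SES obesity prevalence over the
higher-SES one) and the per-stratum mean-TR summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    N_AGE_GROUPS,
    DemographicParams,
    PopulationState,
    SESGroup,
    TransferenceRateTable,
)
from .simulate import IntegrationConfig, ProjectionResult, RatesLike, run_projection

__all__ = [
    "StratifiedRun",
    "run_stratified",
    "prevalence_ratio",
    "prevalence_ratio_series",
    "pooled_prevalence",
    "mean_tr",
    "ADULT_GROUPS",
]

#: Age groups 20-24 .. 55-59, the adult range used by the prevalence ratio.
ADULT_GROUPS = range(4, N_AGE_GROUPS)


@dataclass
class StratifiedRun:
    """Per-stratum projections on a shared calendar."""

    runs: dict[SESGroup, ProjectionResult]

    def __post_init__(self) -> None:
        years = None
        for ses, run in self.runs.items():
            if years is None:
                years = run.years
            elif run.years != years:
                raise ValueError(f"stratum {ses.value} is on a different calendar")

    @property
    def years(self) -> list[int]:
        return next(iter(self.runs.values())).years

    def frame(self) -> pd.DataFrame:
        return pd.concat([r.frame for r in self.runs.values()], ignore_index=True)


def run_stratified(
    initials: Mapping[SESGroup | str, PopulationState],
    tr_tables: Mapping[SESGroup | str, RatesLike],
    demos: Mapping[SESGroup | str, DemographicParams] | DemographicParams,
    cfg: IntegrationConfig | None = None,
) -> StratifiedRun:
    """Run one projection per stratum.

    ``demos`` may be a single shared demography (the fallback when
    stratum-specific mortality/fertility are unknown) or a mapping per
    stratum.  Raises if a stratum lacks an initial state or TR table.
    """
    def _lookup(mapping, ses):
        for k in (ses, ses.value):
            if k in mapping:
                return mapping[k]
        raise KeyError(ses.value)

    runs: dict[SESGroup, ProjectionResult] = {}
    for key, initial in initials.items():
        ses = SESGroup(key)
        try:
            rates = _lookup(tr_tables, ses)
        except KeyError:
            raise KeyError(f"no TR table for stratum {ses.value}") from None
        demo = _lookup(demos, ses) if isinstance(demos, Mapping) else demos
        if initial.ses != ses:
            initial = PopulationState(t=initial.t, stocks=initial.stocks, ses=ses)
        runs[ses] = run_projection(initial, rates, demo, cfg)
    if not runs:
        raise ValueError("no strata supplied")
    return StratifiedRun(runs)


def _adult_obesity_prevalence(run: ProjectionResult, year: int) -> float:
    return run.prevalence(year, "obese", ADULT_GROUPS)


def prevalence_ratio(
    run: StratifiedRun,
    year: int,
    *,
    low: SESGroup | str = SESGroup.LOWER,
    high: SESGroup | str = SESGroup.HIGHER,
) -> float:
    """Obesity prevalence ratio for adults aged 20-59.

    PR = (lower-SES adult obesity prevalence) / (higher-SES adult obesity
    prevalence); PR > 1 places the obesity burden on the lower stratum.
    Invariant to uniform scaling of either stratum's population.
    """
    p_low = _adult_obesity_prevalence(run.runs[SESGroup(low)], year)
    p_high = _adult_obesity_prevalence(run.runs[SESGroup(high)], year)
    if p_high <= 0.0:
        raise ZeroDivisionError(
            f"higher-SES adult obesity prevalence is zero in {year}; PR undefined"
        )
    return p_low / p_high


def prevalence_ratio_series(run: StratifiedRun, **kw) -> pd.Series:
    """PR for every report year, as a year-indexed series."""
    return pd.Series(
        {year: prevalence_ratio(run, year, **kw) for year in run.years},
        name="obesity_prevalence_ratio",
    )


def pooled_prevalence(
    run: StratifiedRun,
    year: int,
    category: str,
    age_groups=None,
) -> float:
    """Whole-population prevalence: the population-weighted mean over
    strata (equivalently, pooled counts over pooled totals)."""
    idx = list(age_groups) if age_groups is not None else list(range(N_AGE_GROUPS))
    from .core import CATEGORY_LABELS

    c = CATEGORY_LABELS.index(category)
    num = den = 0.0
    for r in run.runs.values():
        stocks = r.stocks_at(year)
        num += stocks[idx, c].sum()
        den += stocks[idx, :].sum()
    if den <= 0:
        raise ZeroDivisionError("no pooled population")
    return num / den


def mean_tr(
    table: TransferenceRateTable | Mapping[SESGroup | str, TransferenceRateTable],
    which: int,
    ses: SESGroup | str | None = None,
) -> float:
    """Unweighted arithmetic mean of tau<which> over the 12 age groups.

    ``table`` is either a single stratum table or a mapping keyed by SES (in
    which case ``ses`` selects the stratum).  This is the aggregation behind
    the headline per-SES mean TRs, conventionally reported at 4 decimals.
    """
    if which not in (1, 2, 3, 4):
        raise ValueError("which must be one of 1..4 (tau index)")
    if isinstance(table, Mapping):
        if ses is None:
            raise ValueError("ses required when a mapping of tables is given")
        table = table[SESGroup(ses)]
    col = table.tau[:, which - 1]
    if col.shape != (N_AGE_GROUPS,):
        raise ValueError("incomplete TR table")
    return float(np.mean(col))
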