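"""Packaged inputs: published transference-rate tables for urban Colombia
(2005-2010) and a synthetic reconstruction of the 2005 starting conditions.

``load_urban_rates`` / ``load_ses_rates`` return the published estimates of
the annual BMI-category transference rates for the whole urban population
and per SES stratum.

``synthetic_colombia_2005`` builds a *synthetic* stand-in for the 2005
starting conditions of the Colombian urban projection: the group-level
prevalences that are publicly reported for 2005 are used as-is; the
remaining groups are filled with field-typical values, and the 40-59 groups
are shifted by a constant so the adult (20-59) aggregates reproduce the
observed 2005 values of 34.2% overweight and 15.7% obese exactly.
Demography (population pyramid, mortality, fertility path, birth-category
fractions) is a plausible urban-Colombia reconstruction at DANE scale, not
the official series.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    N_AGE_GROUPS,
    DemographicParams,
    PopulationState,
    SESGroup,
    TransferenceRateTable,
)

__all__ = [
    "load_urban_rates",
    "load_ses_rates",
    "synthetic_colombia_2005",
    "ColombiaInputs",
]

ADULT_GROUPS = list(range(4, 12))


def _data_path(name: str):
    return resources.files("nutristage.data").joinpath(name)


def load_urban_rates() -> TransferenceRateTable:
    """Published annual transference rates for the entire urban population
    (2005-2010), by 5-year age group."""
    df = pd.read_csv(_data_path("transference_rates_urban.csv"))
    return TransferenceRateTable.from_frame(df, ses=SESGroup.ALL)


def load_ses_rates() -> dict[SESGroup, TransferenceRateTable]:
    """Published annual transference rates per SES stratum (2005-2010)."""
    df = pd.read_csv(_data_path("transference_rates_ses.csv"))
    return {
        ses: TransferenceRateTable.from_frame(df, ses=ses)
        for ses in (SESGroup.LOWER, SESGroup.MIDDLE, SESGroup.HIGHER)
    }


# 2005 group-level prevalences (percent).  Groups 3-7 carry the publicly
# reported values (overweight 12.6/18.9/27.9/35.5/38.2; obese 2.8/-/9.2/
# 13.71/17.0); childhood and the 40-59 groups are synthetic fills, the
# latter adjusted below to match the reported adult aggregates.
_OVERWEIGHT_2005 = np.array(
    [16.0, 15.0, 14.5, 12.6, 18.9, 27.9, 35.5, 38.2, 41.5, 42.5, 42.5, 41.0]
)
_OBESE_2005 = np.array(
    [5.0, 4.5, 4.0, 2.8, 6.0, 9.2, 13.71, 17.0, 20.5, 23.0, 25.0, 24.6]
)
_ADULT_AGG_2005 = {"overweight": 34.2, "obese": 15.7}

#: Urban population by 5-year group, thousands (DANE-scale reconstruction).
_POPULATION_2005 = np.array(
    [3330.0, 3310.0, 3290.0, 3140.0, 2930.0, 2590.0,
     2250.0, 2180.0, 2030.0, 1730.0, 1430.0, 1130.0]
)

#: Per-year mortality rate by group (synthetic, Colombia-2005 scale).
_MORTALITY = np.array(
    [0.004, 0.0004, 0.0004, 0.001, 0.0015, 0.0015,
     0.0016, 0.002, 0.003, 0.004, 0.006, 0.009]
)

#: Birth-category fractions (prevalence at ages 0-2 months; synthetic).
_THETA = np.array([0.85, 0.11, 0.04])

#: 2005 adult (20-59) prevalences per SES stratum (percent, reported).
_SES_ADULT_2005 = {
    SESGroup.LOWER: {"overweight": 30.7, "obese": 13.0},
    SESGroup.MIDDLE: {"overweight": 34.3, "obese": 16.3},
    SESGroup.HIGHER: {"overweight": 36.4, "obese": 17.2},
}
#: Urban population shares of the wealth-index strata (synthetic).
_SES_POP_SHARE = {SESGroup.LOWER: 0.40, SESGroup.MIDDLE: 0.20, SESGroup.HIGHER: 0.40}


def _fertility_series() -> dict[int, float]:
    """Urban total fertility rate: observed decline 2005-2015, flat
    projection afterwards (children per woman; synthetic path)."""
    out = {}
    for year in range(2005, 2016):
        out[year] = 2.1 - 0.025 * (year - 2005)
    for year in range(2016, 2036):
        out[year] = out[2015]
    return out


def _calibrated_prevalence() -> np.ndarray:
    """(12, 3) category shares with the 40-59 fills shifted so the
    population-weighted adult aggregates match the observed 2005 values."""
    ow = _OVERWEIGHT_2005.copy()
    ob = _OBESE_2005.copy()
    pop = _POPULATION_2005
    adult_pop = pop[ADULT_GROUPS].sum()
    fill = ADULT_GROUPS[4:]  # groups 40-44 .. 55-59
    for arr, target in ((ow, _ADULT_AGG_2005["overweight"]),
                        (ob, _ADULT_AGG_2005["obese"])):
        agg = (arr[ADULT_GROUPS] * pop[ADULT_GROUPS]).sum() / adult_pop
        arr[fill] += (target - agg) * adult_pop / pop[fill].sum()
    shares = np.column_stack([100.0 - ow - ob, ow, ob]) / 100.0
    if np.any(shares < 0):
        raise AssertionError("calibrated prevalence left the simplex")
    return shares


@dataclass(frozen=True)
class ColombiaInputs:
    """Synthetic 2005 starting conditions for the urban projection."""

    initial: PopulationState
    initial_by_ses: dict[SESGroup, PopulationState]
    demography: DemographicParams
    populations: np.ndarray


def synthetic_colombia_2005() -> ColombiaInputs:
    """Build the synthetic stand-in inputs for the 2005-2030 projection."""
    shares = _calibrated_prevalence()
    stocks = _POPULATION_2005[:, None] * shares
    initial = PopulationState(t=2005.0, stocks=stocks, ses=SESGroup.ALL)
    demo = DemographicParams(
        mortality=_MORTALITY,
        fertility=_fertility_series(),
        mu=0.523,
        theta=_THETA,
    )
    by_ses = {}
    urban = _ADULT_AGG_2005
    for ses, targets in _SES_ADULT_2005.items():
        f_ow = targets["overweight"] / urban["overweight"]
        f_ob = targets["obese"] / urban["obese"]
        ow = shares[:, 1] * f_ow
        ob = shares[:, 2] * f_ob
        s = np.column_stack([1.0 - ow - ob, ow, ob])
        pop = _POPULATION_2005 * _SES_POP_SHARE[ses]
        by_ses[ses] = PopulationState(t=2005.0, stocks=pop[:, None] * s, ses=ses)
    return ColombiaInputs(
        initial=initial,
        initial_by_ses=by_ses,
        demography=demo,
        populations=_POPULATION_2005.copy(),
    )
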