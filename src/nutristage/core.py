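"""Core domain types for the nutritional-stage (BMI-category) population model.

The population aged 0-59 is carved into twelve 5-year age groups, each split
into three BMI categories (*not overweight*, *overweight*, *obese*).  People
enter the first group through births, move between categories at annual
transference rates (TRs), age through the chain with a 5-year mean residence
time, die at age-specific rates, and exit the system at age 60.  This module
holds the shared containers -- population stocks, TR tables, demographic
parameters, survey prevalence tables -- and the two demographic primitives
every later stage needs: the survival fraction over a group residence and the
initialisation of stocks from observed prevalence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BMICategory",
    "SESGroup",
    "CATEGORIES",
    "N_CATEGORIES",
    "N_AGE_GROUPS",
    "AGE_GROUP_LABELS",
    "AGE_GROUP_LABELS_EXTENDED",
    "MAX_SURVEY_AGE",
    "TransferenceRateTable",
    "DemographicParams",
    "PopulationState",
    "SurveyPrevalence",
    "survival_fraction",
    "stocks_from_prevalence",
    "age_group_label",
]


class BMICategory(str, enum.Enum):
    """The three nutritional stages, in the fixed order used by every vector
    and matrix in the package (index 0, 1, 2)."""

    NOT_OVERWEIGHT = "not_overweight"
    OVERWEIGHT = "overweight"
    OBESE = "obese"

    @property
    def index(self) -> int:
        return CATEGORIES.index(self)


class SESGroup(str, enum.Enum):
    """Socioeconomic strata from wealth-index quintiles (lower = Q1-2,
    middle = Q3, higher = Q4-5); ``ALL`` marks an unstratified run."""

    LOWER = "lower"
    MIDDLE = "middle"
    HIGHER = "higher"
    ALL = "all"


CATEGORIES: tuple[BMICategory, ...] = (
    BMICategory.NOT_OVERWEIGHT,
    BMICategory.OVERWEIGHT,
    BMICategory.OBESE,
)
CATEGORY_LABELS: tuple[str, ...] = tuple(c.value for c in CATEGORIES)
N_CATEGORIES = 3

#: Number of simulated 5-year age groups (0-4 ... 55-59); people exit at 60.
N_AGE_GROUPS = 12
AGE_GROUP_LABELS: tuple[str, ...] = tuple(
    f"{5 * i}-{5 * i + 4}" for i in range(N_AGE_GROUPS)
)
#: Estimation targets extend one group further (60-64) because the cohort
#: observed at ages 55-59 in wave 1 is re-observed at 60-64 in wave 2.
AGE_GROUP_LABELS_EXTENDED: tuple[str, ...] = AGE_GROUP_LABELS + ("60-64",)
#: Highest single year of age a survey table must cover.
MAX_SURVEY_AGE = 64

_SIMPLEX_ATOL = 1e-6


def age_group_label(i: int) -> str:
    return AGE_GROUP_LABELS_EXTENDED[i]


def _as_float_array(x, shape, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


@dataclass(frozen=True)
class TransferenceRateTable:
    """Annual transference rates between BMI categories per age group.

    ``tau`` has shape (12, 4) with columns

    ==== =================================
    tau1 not overweight -> overweight
    tau2 overweight -> obese
    tau3 obese -> overweight
    tau4 overweight -> not overweight
    ==== =================================

    all expressed as fraction of the source category per year.  The retention
    rates follow from the simplex constraints: ``alpha1 = 1 - tau1``,
    ``alpha2 = 1 - tau2 - tau4``, ``alpha3 = 1 - tau3``; feasibility requires
    every tau in [0, 1] and ``tau2 + tau4 <= 1``.
    """

    tau: np.ndarray
    ses: SESGroup = SESGroup.ALL

    def __post_init__(self) -> None:
        tau = _as_float_array(self.tau, (N_AGE_GROUPS, 4), "tau")
        object.__setattr__(self, "tau", tau)
        if np.any(tau < 0.0) or np.any(tau > 1.0):
            raise ValueError("transference rates must lie in [0, 1]")
        if np.any(tau[:, 1] + tau[:, 3] > 1.0 + 1e-12):
            raise ValueError("infeasible rates: tau2 + tau4 > 1 in some age group")
        if not isinstance(self.ses, SESGroup):
            object.__setattr__(self, "ses", SESGroup(self.ses))

    @property
    def tau1(self) -> np.ndarray:
        return self.tau[:, 0]

    @property
    def tau2(self) -> np.ndarray:
        return self.tau[:, 1]

    @property
    def tau3(self) -> np.ndarray:
        return self.tau[:, 2]

    @property
    def tau4(self) -> np.ndarray:
        return self.tau[:, 3]

    @property
    def alpha1(self) -> np.ndarray:
        return 1.0 - self.tau1

    @property
    def alpha2(self) -> np.ndarray:
        return 1.0 - self.tau2 - self.tau4

    @property
    def alpha3(self) -> np.ndarray:
        return 1.0 - self.tau3

    @classmethod
    def zeros(cls, ses: SESGroup | str = SESGroup.ALL) -> "TransferenceRateTable":
        return cls(np.zeros((N_AGE_GROUPS, 4)), ses=SESGroup(ses))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ses: SESGroup | str = SESGroup.ALL):
        """Build a table from a frame with columns age_group, tau1..tau4."""
        ses = SESGroup(ses)
        if "ses" in df.columns:
            df = df[df["ses"] == ses.value]
        df = df.set_index("age_group").reindex(list(AGE_GROUP_LABELS))
        if df[["tau1", "tau2", "tau3", "tau4"]].isna().any().any():
            raise ValueError("TR table is missing age-group rows")
        return cls(df[["tau1", "tau2", "tau3", "tau4"]].to_numpy(), ses=ses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ses": self.ses.value,
                "age_group": list(AGE_GROUP_LABELS),
                "tau1": self.tau[:, 0],
                "tau2": self.tau[:, 1],
                "tau3": self.tau[:, 2],
                "tau4": self.tau[:, 3],
            }
        )

    def replace(self, tau: np.ndarray) -> "TransferenceRateTable":
        return TransferenceRateTable(tau, ses=self.ses)


def survival_fraction(R_i, Y: float = 5.0):
    """Fraction surviving a residence of ``Y`` years at per-year mortality
    rate ``R_i``: ``exp(-R_i * Y)``.

    Decreasing in both arguments; equals 1 at zero mortality.  Accepts
    scalars or arrays.
    """
    R = np.asarray(R_i, dtype=float)
    if np.any(R < 0.0):
        raise ValueError("mortality rate must be non-negative")
    if Y <= 0.0:
        raise ValueError("residence time Y must be positive")
    out = np.exp(-R * Y)
    return float(out) if np.isscalar(R_i) or out.ndim == 0 else out


@dataclass(frozen=True)
class DemographicParams:
    """Demography for one population stratum.

    Parameters
    ----------
    mortality : (12,) array
        Per-year mortality rate ``R_i`` by age group (same for all BMI
        categories within a group).
    fertility : mapping year -> float
        Total fertility rate (children per woman), looked up
        piecewise-constant by calendar year; no implicit extrapolation.
    mu : float
        Fraction of the population aged 15-49 that is female.
    theta : (3,) array
        Birth fractions by BMI category (prevalence at ages 0-2 months);
        must sum to 1.
    Y : float
        Mean residence time in an age group, 5 years.
    childbearing : (first, last) ages, inclusive; defaults (15, 49), so
        births are spread over ``last - first + 1 = 35`` woman-years.
    """

    mortality: np.ndarray
    fertility: Mapping[int, float]
    mu: float = 0.523
    theta: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    Y: float = 5.0
    childbearing: tuple[int, int] = (15, 49)

    def __post_init__(self) -> None:
        R = _as_float_array(self.mortality, (N_AGE_GROUPS,), "mortality")
        object.__setattr__(self, "mortality", R)
        if np.any(R < 0.0):
            raise ValueError("mortality rates must be non-negative")
        th = _as_float_array(self.theta, (N_CATEGORIES,), "theta")
        object.__setattr__(self, "theta", th)
        if abs(th.sum() - 1.0) > 1e-9 or np.any(th < 0.0):
            raise ValueError("birth fractions theta must be non-negative and sum to 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.Y <= 0.0:
            raise ValueError("Y must be positive")
        fert = {int(k): float(v) for k, v in dict(self.fertility).items()}
        if any(v < 0.0 for v in fert.values()):
            raise ValueError("fertility rates must be non-negative")
        object.__setattr__(self, "fertility", fert)

    @property
    def survival(self) -> np.ndarray:
        """Survival fraction S_i per 5-year residence, by age group."""
        return survival_fraction(self.mortality, self.Y)

    @property
    def childbearing_groups(self) -> range:
        """Indices of the 5-year groups covering the childbearing ages."""
        first, last = self.childbearing
        return range(first // 5, last // 5 + 1)

    @property
    def childbearing_span(self) -> int:
        first, last = self.childbearing
        return last - first + 1

    def fertility_at(self, t: float) -> float:
        year = int(np.floor(t))
        try:
            return self.fertility[year]
        except KeyError:
            raise KeyError(
                f"fertility rate undefined for year {year}; series covers "
                f"{min(self.fertility)}-{max(self.fertility)}"
            ) from None


@dataclass
class PopulationState:
    """Population stocks (people) at one instant: shape (12 age groups,
    3 categories), plus the calendar time ``t``."""

    t: float
    stocks: np.ndarray
    ses: SESGroup = SESGroup.ALL

    def __post_init__(self) -> None:
        self.stocks = _as_float_array(
            self.stocks, (N_AGE_GROUPS, N_CATEGORIES), "stocks"
        )
        if np.any(self.stocks < 0.0):
            raise ValueError("population stocks must be non-negative")
        if not isinstance(self.ses, SESGroup):
            self.ses = SESGroup(self.ses)

    @property
    def total(self) -> float:
        return float(self.stocks.sum())

    def group_totals(self) -> np.ndarray:
        return self.stocks.sum(axis=1)

    def prevalence(self) -> np.ndarray:
        """Per-group category shares; rows of empty groups are zero."""
        totals = self.group_totals()
        out = np.zeros_like(self.stocks)
        nz = totals > 0
        out[nz] = self.stocks[nz] / totals[nz, None]
        return out


@dataclass(frozen=True)
class SurveyPrevalence:
    """Cross-sectional prevalence by BMI category and single year of age.

    ``P`` has shape (3 categories, 65 ages) covering ages 0..64; every age
    column lies on the probability simplex.  Columns are validated to within
    1e-6 and renormalised to machine precision on construction.
    """

    wave: int
    P: np.ndarray
    ses: SESGroup = SESGroup.ALL

    def __post_init__(self) -> None:
        P = _as_float_array(self.P, (N_CATEGORIES, MAX_SURVEY_AGE + 1), "P")
        if np.any(P < -1e-12):
            raise ValueError("prevalences must be non-negative")
        sums = P.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > _SIMPLEX_ATOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"prevalences at age {bad} sum to {sums[bad]:.6f}, not 1"
            )
        object.__setattr__(self, "P", np.clip(P, 0.0, None) / sums)
        if not isinstance(self.ses, SESGroup):
            object.__setattr__(self, "ses", SESGroup(self.ses))

    @property
    def ages(self) -> np.ndarray:
        return np.arange(MAX_SURVEY_AGE + 1)

    def group_columns(self, i: int) -> np.ndarray:
        """The (3, 5) prevalence columns for the single ages of group ``i``."""
        if not 0 <= i <= MAX_SURVEY_AGE // 5:
            raise IndexError(f"age group {i} out of range")
        return self.P[:, 5 * i : 5 * i + 5]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        wave: int | None = None,
        ses: SESGroup | str = SESGroup.ALL,
    ) -> "SurveyPrevalence":
        """Build from the long prevalence schema
        ``wave,ses,age_years,category,prevalence``."""
        ses = SESGroup(ses)
        sub = df
        if "wave" in sub.columns and wave is not None:
            sub = sub[sub["wave"] == wave]
        if "ses" in sub.columns:
            sub = sub[sub["ses"] == ses.value]
        if sub.empty:
            raise ValueError(f"no prevalence rows for wave={wave}, ses={ses.value}")
        if wave is None:
            waves = sub["wave"].unique()
            if len(waves) != 1:
                raise ValueError("wave must be given when the frame mixes waves")
            wave = int(waves[0])
        wide = sub.pivot_table(
            index="category", columns="age_years", values="prevalence"
        )
        try:
            wide = wide.loc[list(CATEGORY_LABELS), list(range(MAX_SURVEY_AGE + 1))]
        except KeyError as exc:
            raise ValueError(f"prevalence table incomplete: {exc}") from None
        if wide.isna().any().any():
            raise ValueError("prevalence table has missing category/age cells")
        return cls(wave=int(wave), P=wide.to_numpy(), ses=ses)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, cat in enumerate(CATEGORY_LABELS):
            for a in range(MAX_SURVEY_AGE + 1):
                rows.append((self.wave, self.ses.value, a, cat, self.P[c, a]))
        return pd.DataFrame(
            rows, columns=["wave", "ses", "age_years", "category", "prevalence"]
        )


def stocks_from_prevalence(
    prev: SurveyPrevalence,
    pop_by_group: Sequence[float],
    *,
    age_weights: Sequence[float] | None = None,
    t: float | None = None,
) -> PopulationState:
    """Initialise population stocks from survey prevalence and group sizes.

    The category split of group ``i`` is the mean of its five single-year
    prevalence columns -- unweighted by default, or weighted by the single-age
    population ``age_weights`` (length 65) when those are known.  Per-group
    stocks sum exactly to ``pop_by_group[i]``.
    """
    pop = _as_float_array(pop_by_group, (N_AGE_GROUPS,), "pop_by_group")
    if np.any(pop < 0.0):
        raise ValueError("populations must be non-negative")
    if age_weights is not None:
        w = np.asarray(age_weights, dtype=float)
        if w.shape != (MAX_SURVEY_AGE + 1,) or np.any(w < 0.0):
            raise ValueError("age_weights must be 65 non-negative values")
    stocks = np.empty((N_AGE_GROUPS, N_CATEGORIES))
    for i in range(N_AGE_GROUPS):
        cols = prev.group_columns(i)
        if age_weights is None:
            share = cols.mean(axis=1)
        else:
            wi = w[5 * i : 5 * i + 5]
            if wi.sum() <= 0.0:
                share = cols.mean(axis=1)
            else:
                share = cols @ (wi / wi.sum())
        stocks[i] = pop[i] * share / share.sum()
    return PopulationState(
        t=float(prev.wave if t is None else t), stocks=stocks, ses=prev.ses
    )
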