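"""Stock-and-flow engine for the BMI-category aging chain.

Twelve 5-year age-group stocks per BMI category are advanced in time with:

* births entering the 0-4 group, split by the birth fractions ``theta`` and
  driven by ``mu * f(t) / 35`` applied to the population of childbearing age
  (15-49);
* annual transfers between categories within each group at the transference
  rates tau1..tau4;
* exit flows ``E_i = stock_i / Y`` (mean residence ``Y = 5`` years), of which
  a fraction ``S_i = exp(-R_i Y)`` matures into group ``i+1`` and ``1 - S_i``
  dies; the survivors of group 11 (55-59) leave the system at age 60.

The exit flow has a second, literal formulation in which exits are the net
inflow divided by ``Y``; it is degenerate (a stock with no inflow never
drains) and is retained only for fidelity experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
import pandas as pd

from .core import (
    AGE_GROUP_LABELS,
    CATEGORY_LABELS,
    N_AGE_GROUPS,
    N_CATEGORIES,
    DemographicParams,
    PopulationState,
    SESGroup,
    TransferenceRateTable,
)

__all__ = [
    "IntegrationConfig",
    "FlowSet",
    "ProjectionResult",
    "births",
    "transfer_flows",
    "exit_rates",
    "net_derivative",
    "run_projection",
]

logger = logging.getLogger(__name__)

EXIT_FORMULATIONS = ("stock_outflow", "literal_paper")

RatesLike = Union[TransferenceRateTable, Callable[[float], TransferenceRateTable]]


@dataclass(frozen=True)
class IntegrationConfig:
    """Fixed-step integration settings.

    dt defaults to a quarter year, mirroring common system-dynamics practice;
    results are reported at integer calendar years, so ``1 / dt`` must be an
    integer number of steps per year.
    """

    t0: float = 2005.0
    t1: float = 2030.0
    dt: float = 0.25
    method: str = "euler"
    exit_formulation: str = "stock_outflow"

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.t1 <= self.t0:
            raise ValueError("t1 must exceed t0")
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.exit_formulation not in EXIT_FORMULATIONS:
            raise ValueError(
                f"unknown exit formulation {self.exit_formulation!r}; "
                f"choose from {EXIT_FORMULATIONS}"
            )
        steps = 1.0 / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("1/dt must be an integer (yearly report points)")


@dataclass(frozen=True)
class FlowSet:
    """All instantaneous flows (people/year) at one state evaluation."""

    births: np.ndarray  # (3,) B_N, B_W, B_O
    exits: np.ndarray  # (12, 3) E_i^c
    transfers: np.ndarray  # (12, 3) net within-group category transfers


def births(
    stocks: np.ndarray, demo: DemographicParams, t: float
) -> np.ndarray:
    """Births per year by BMI category.

    ``B_c = mu * theta_c * f(t) / (YF - YI + 1) * sum_{i in 15-49 groups}
    (N_i + W_i + O_i)``.
    """
    cb = list(demo.childbearing_groups)
    pool = float(stocks[cb, :].sum())
    rate = demo.mu * demo.fertility_at(t) / demo.childbearing_span
    return demo.theta * rate * pool


def transfer_flows(stocks: np.ndarray, rates: TransferenceRateTable) -> np.ndarray:
    """Net within-group category transfer rates (people/year), shape (12, 3).

    Not overweight loses tau1*N and gains tau4*W; overweight gains tau1*N +
    tau3*O and loses (tau2 + tau4)*W; obese gains tau2*W and loses tau3*O.
    Rows sum to zero: transfers conserve each group's population.
    """
    N, W, O = stocks[:, 0], stocks[:, 1], stocks[:, 2]
    t1, t2, t3, t4 = rates.tau1, rates.tau2, rates.tau3, rates.tau4
    out = np.empty_like(stocks)
    out[:, 0] = t4 * W - t1 * N
    out[:, 1] = t1 * N + t3 * O - (t2 + t4) * W
    out[:, 2] = t2 * W - t3 * O
    return out


def exit_rates(
    stocks: np.ndarray,
    rates: TransferenceRateTable,
    demo: DemographicParams,
    birth_flows: np.ndarray,
    formulation: str = "stock_outflow",
) -> np.ndarray:
    """Exit flows E_i^c (people/year) for every age group and category.

    ``stock_outflow`` (default): ``E_i^c = stock_i^c / Y``, the first-order
    aging chain.  ``literal_paper``: exits equal the *net inflow* of the
    stock divided by Y, computed recursively down the chain; provided for
    fidelity experiments only (a stock with no inflows then never drains).
    """
    if formulation == "stock_outflow":
        return stocks / demo.Y
    if formulation != "literal_paper":
        raise ValueError(f"unknown exit formulation {formulation!r}")
    S = demo.survival
    tf = transfer_flows(stocks, rates)
    E = np.empty_like(stocks)
    E[0] = (birth_flows + tf[0]) / demo.Y
    for i in range(1, N_AGE_GROUPS):
        E[i] = (E[i - 1] * S[i - 1] + tf[i]) / demo.Y
    return E


def net_derivative(
    state: PopulationState,
    rates: TransferenceRateTable,
    demo: DemographicParams,
    t: float | None = None,
    formulation: str = "stock_outflow",
) -> np.ndarray:
    """d(stocks)/dt, shape (12, 3).

    Group 0 receives births; groups 1..11 receive the surviving share
    ``E_{i-1} S_{i-1}`` of the upstream exits.  Every group loses its full
    exit flow (deaths ``E_i (1 - S_i)`` plus maturation ``E_i S_i``).
    """
    flows = evaluate_flows(state.stocks, rates, demo, t, formulation)
    return _derivative_from_flows(state.stocks, flows, demo)


def evaluate_flows(
    stocks: np.ndarray,
    rates: TransferenceRateTable,
    demo: DemographicParams,
    t: float | None,
    formulation: str,
) -> FlowSet:
    if np.any(stocks < 0.0):
        raise ValueError("negative stock passed to flow evaluation")
    B = births(stocks, demo, t if t is not None else min(demo.fertility))
    return FlowSet(
        births=B,
        exits=exit_rates(stocks, rates, demo, B, formulation),
        transfers=transfer_flows(stocks, rates),
    )


def _derivative_from_flows(
    stocks: np.ndarray, flows: FlowSet, demo: DemographicParams
) -> np.ndarray:
    S = demo.survival
    d = flows.transfers - flows.exits
    d[0] += flows.births
    d[1:] += flows.exits[:-1] * S[:-1, None]
    return d


@dataclass
class ProjectionResult:
    """Yearly trajectory of stocks and prevalences for one stratum.

    ``states`` maps integer report years to (12, 3) stock arrays; ``frame``
    is the long-format table with columns
    ``year, ses, age_group, category, count, prevalence``.
    """

    ses: SESGroup
    states: dict[int, np.ndarray]
    config: IntegrationConfig
    clamp_events: int = 0
    frame: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for year in sorted(self.states):
            stocks = self.states[year]
            totals = stocks.sum(axis=1)
            for i in range(N_AGE_GROUPS):
                prev = stocks[i] / totals[i] if totals[i] > 0 else np.zeros(3)
                for c in range(N_CATEGORIES):
                    rows.append(
                        (
                            year,
                            self.ses.value,
                            AGE_GROUP_LABELS[i],
                            CATEGORY_LABELS[c],
                            stocks[i, c],
                            prev[c],
                        )
                    )
        self.frame = pd.DataFrame(
            rows,
            columns=["year", "ses", "age_group", "category", "count", "prevalence"],
        )

    @property
    def years(self) -> list[int]:
        return sorted(self.states)

    def stocks_at(self, year: int) -> np.ndarray:
        return self.states[int(year)]

    def prevalence(
        self,
        year: int,
        category: str,
        age_groups: range | list[int] | None = None,
    ) -> float:
        """Aggregate prevalence of ``category`` over ``age_groups`` (all 12
        by default) in the given year: category count over total count."""
        stocks = self.stocks_at(year)
        idx = list(age_groups) if age_groups is not None else list(range(N_AGE_GROUPS))
        c = CATEGORY_LABELS.index(category)
        total = stocks[idx, :].sum()
        if total <= 0:
            raise ZeroDivisionError(f"no population in groups {idx} in {year}")
        return float(stocks[idx, c].sum() / total)

    def group_prevalence(self, year: int, group: int, category: str) -> float:
        return self.prevalence(year, category, [group])

    def total_population(self, year: int) -> float:
        return float(self.stocks_at(year).sum())


def _resolve_rates(rates: RatesLike, t: float) -> TransferenceRateTable:
    return rates(t) if callable(rates) else rates


def run_projection(
    initial: PopulationState,
    rates: RatesLike,
    demo: DemographicParams,
    cfg: IntegrationConfig | None = None,
) -> ProjectionResult:
    """Integrate the aging chain from ``cfg.t0`` to ``cfg.t1``.

    ``rates`` may be a fixed table or a callable ``t -> table`` (used by the
    policy-scenario machinery).  Fixed-step Euler (default) or classic RK4;
    stocks are clamped at zero after each step (clamp events are counted and
    logged).  Deterministic given inputs and configuration.
    """
    cfg = cfg or IntegrationConfig()
    stocks = initial.stocks.copy()
    t = cfg.t0
    states: dict[int, np.ndarray] = {}
    clamps = 0

    def deriv(s: np.ndarray, tt: float) -> np.ndarray:
        flows = evaluate_flows(
            np.clip(s, 0.0, None), _resolve_rates(rates, tt), demo, tt,
            cfg.exit_formulation,
        )
        return _derivative_from_flows(np.clip(s, 0.0, None), flows, demo)

    def record(tt: float, s: np.ndarray) -> None:
        year = round(tt)
        if abs(tt - year) < 1e-9:
            states[int(year)] = s.copy()

    record(t, stocks)
    n_steps = round((cfg.t1 - cfg.t0) / cfg.dt)
    if abs(n_steps * cfg.dt - (cfg.t1 - cfg.t0)) > 1e-9:
        n_steps = int(np.ceil((cfg.t1 - cfg.t0) / cfg.dt))
    for k in range(n_steps):
        if cfg.method == "euler":
            stocks = stocks + cfg.dt * deriv(stocks, t)
        else:  # rk4
            h = cfg.dt
            k1 = deriv(stocks, t)
            k2 = deriv(stocks + 0.5 * h * k1, t + 0.5 * h)
            k3 = deriv(stocks + 0.5 * h * k2, t + 0.5 * h)
            k4 = deriv(stocks + h * k3, t + h)
            stocks = stocks + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(stocks)):
            raise FloatingPointError(
                f"non-finite state at t={t + cfg.dt:.3f}; reduce dt or check inputs"
            )
        neg = stocks < 0.0
        if np.any(neg):
            clamps += int(neg.sum())
            stocks = np.clip(stocks, 0.0, None)
        t = cfg.t0 + (k + 1) * cfg.dt
        record(t, stocks)
    if clamps:
        logger.info("negative-stock guard triggered %d times", clamps)
    return ProjectionResult(
        ses=initial.ses, states=states, config=cfg, clamp_events=clamps
    )
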