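"""Economic evaluation: discounting, cost/QALY accumulation, ICERs.

Turns a cohort trace plus per-state costs and utilities into discounted
totals, and compares strategies by incremental cost-effectiveness ratio
(ICER), dominance, and a GDP-based willingness-to-pay classification.

Costs are carried in Vietnamese dong (VND) throughout; conversion to
USD happens only at reporting time.  All arithmetic is double
precision; rounding to whole VND / cents is a serialization concern.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import CohortTrace

logger = logging.getLogger("markovcea")

# willingness-to-pay classes
HIGHLY_COST_EFFECTIVE = "highly_cost_effective"
COST_EFFECTIVE = "cost_effective"
NOT_COST_EFFECTIVE = "not_cost_effective"
NOT_APPLICABLE = "not_applicable"

# comparison labels
LABEL_ICER = "icer"
LABEL_DOMINANT = "dominant"
LABEL_DOMINATED = "dominated"
LABEL_UNDEFINED = "undefined"


@dataclass(frozen=True)
class CostComponents:
    """Per-cycle cost of occupying a state, split by payer-perspective class.

    direct_medical: drugs, procedures, consultations (VND/cycle).
    direct_nonmedical: food, transport to facilities (VND/cycle).
    indirect: productivity loss / absenteeism (VND/cycle).
    """

    direct_medical: float = 0.0
    direct_nonmedical: float = 0.0
    indirect: float = 0.0

    def __post_init__(self) -> None:
        for name in ("direct_medical", "direct_nonmedical", "indirect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.direct_medical + self.direct_nonmedical + self.indirect


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied to both costs and outcomes."""

    annual_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("discount rate must be >= 0")


def discount_factor(spec: DiscountSpec, cycle_index: int, cycle_length: float) -> float:
    """Discount factor (1 + r)^(-t) at t = cycle_index * cycle_length years."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    return (1.0 + spec.annual_rate) ** (-(cycle_index * cycle_length))


@dataclass(frozen=True)
class EconomyParams:
    """Macro-economic context: GDP per capita, exchange rate, CPI.

    ``gdp_per_capita_vnd`` defaults to the exact product of the USD
    figure and the exchange rate (2021 Vietnam: 3756 USD x 23,486
    VND/USD = 88,213,416 VND).
    """

    gdp_per_capita_usd: float = 3756.0
    exchange_rate: float = 23486.0
    gdp_per_capita_vnd: float | None = None
    cpi_series: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.exchange_rate <= 0:
            raise ValueError("exchange_rate must be positive")
        if self.gdp_per_capita_vnd is None:
            object.__setattr__(
                self, "gdp_per_capita_vnd", self.gdp_per_capita_usd * self.exchange_rate
            )

    @property
    def monthly_gdp_vnd(self) -> float:
        return self.gdp_per_capita_vnd / 12.0


@dataclass
class CEAResult:
    """Discounted totals for one strategy, with a per-cycle breakdown."""

    strategy_id: str
    total_cost: float
    total_qalys: float
    breakdown: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.total_cost < 0 or self.total_qalys < 0:
            raise ValueError("totals must be non-negative")


def accumulate(
    trace: CohortTrace,
    per_state_costs: Mapping[str, CostComponents],
    per_state_utility: Mapping[str, float],
    discount: DiscountSpec,
    half_cycle: bool = False,
    strategy_id: str = "",
) -> CEAResult:
    """Accumulate discounted costs and QALYs over a cohort trace.

    Per cycle t (1..T):

    * cost_t  = sum_s occupancy[t, s] * total_cost(s)      * d(t)
    * qaly_t  = sum_s occupancy[t, s] * utility(s) * cycle * d(t)

    where d(t) = (1+r)^(-t*cycle).  With ``half_cycle`` the occupancy
    row is replaced by the average of rows t-1 and t (trapezoid).

    Every non-death state must appear in both maps with utility in
    [0, 1]; the death state is implicitly zero-cost, zero-utility.
    """
    n = len(trace.states)
    costs = np.zeros(n)
    utils = np.zeros(n)
    for i, s in enumerate(trace.states):
        if s.kind == "death":
            cc = per_state_costs.get(s.id)
            if cc is not None and cc.total != 0:
                raise ValueError("death state must have zero cost")
            u = per_state_utility.get(s.id, 0.0)
            if u != 0.0:
                raise ValueError("death state must have zero utility")
            continue
        if s.id not in per_state_costs:
            raise KeyError(f"no cost entry for state {s.id!r}")
        if s.id not in per_state_utility:
            raise KeyError(f"no utility entry for state {s.id!r}")
        u = per_state_utility[s.id]
        if not (0.0 <= u <= 1.0):
            raise ValueError(f"utility for {s.id!r} is {u}, outside [0, 1]")
        costs[i] = per_state_costs[s.id].total
        utils[i] = u

    T = trace.n_cycles
    cycles = np.arange(1, T + 1)
    disc = (1.0 + discount.annual_rate) ** (-(cycles * trace.cycle_length))
    occ = trace.occupancy[1:]
    if half_cycle:
        occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])

    cost_per_cycle = (occ @ costs) * disc
    qaly_per_cycle = (occ @ utils) * trace.cycle_length * disc

    breakdown = pd.DataFrame(
        {
            "cycle": cycles,
            "discount_factor": disc,
            "cost": cost_per_cycle,
            "qalys": qaly_per_cycle,
        }
    )
    return CEAResult(
        strategy_id=strategy_id,
        total_cost=float(cost_per_cycle.sum()),
        total_qalys=float(qaly_per_cycle.sum()),
        breakdown=breakdown,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental comparison of strategy a against comparator b.

    ``icer`` is numeric only when the deltas support a meaningful ratio
    (more costly and more effective, or — flagged — cheaper and less
    effective, i.e. savings per QALY forgone); the other quadrants
    resolve to dominance labels with the raw deltas always reported.
    """

    strategy_a: str
    strategy_b: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str
    savings_per_qaly_forgone: bool = False


def compare_strategies(a: CEAResult, b: CEAResult) -> ComparisonResult:
    """Incremental cost-effectiveness of a vs b: ICER = dCost / dQALY."""
    dc = a.total_cost - b.total_cost
    dq = a.total_qalys - b.total_qalys
    icer: float | None = None
    flag = False
    if dq == 0.0:
        label = LABEL_UNDEFINED
    elif dq > 0 and dc <= 0:
        label = LABEL_DOMINANT  # cheaper (or equal) and more effective
    elif dq > 0:
        label = LABEL_ICER
        icer = dc / dq
    elif dc >= 0:
        label = LABEL_DOMINATED  # costlier (or equal) and less effective
    else:  # dc < 0 and dq < 0: savings per QALY forgone
        label = LABEL_ICER
        icer = dc / dq
        flag = True
    return ComparisonResult(
        strategy_a=a.strategy_id,
        strategy_b=b.strategy_id,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        label=label,
        savings_per_qaly_forgone=flag,
    )


def wtp_classify(comparison: ComparisonResult, economy: EconomyParams) -> str:
    """Classify a comparison against GDP-per-capita WTP thresholds.

    ICER below 1x GDP per capita: highly cost-effective; between 1x and
    3x (boundaries included): cost-effective; above 3x: not
    cost-effective.  A dominant strategy is highly cost-effective by
    construction; dominated/undefined comparisons and the
    savings-per-QALY-forgone quadrant get ``not_applicable``.
    """
    if comparison.label == LABEL_DOMINANT:
        return HIGHLY_COST_EFFECTIVE
    if comparison.icer is None or comparison.savings_per_qaly_forgone:
        return NOT_APPLICABLE
    gdp = economy.gdp_per_capita_vnd
    if comparison.icer < gdp:
        return HIGHLY_COST_EFFECTIVE
    if comparison.icer <= 3.0 * gdp:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE


def usd_to_vnd(amount_usd: float, rate: float) -> float:
    """Convert USD to VND at ``rate`` VND per USD (no rounding)."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return amount_usd * rate


def vnd_to_usd(amount_vnd: float, rate: float) -> float:
    """Convert VND to USD at ``rate`` VND per USD (no rounding)."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return amount_vnd / rate


def cpi_adjust(amount: float, from_year: int, to_year: int, cpi_series: Mapping[int, float]) -> float:
    """Inflate/deflate a monetary amount by the CPI ratio between two years."""
    for year in (from_year, to_year):
        if year not in cpi_series:
            raise KeyError(f"year {year} missing from CPI series; no extrapolation")
    return amount * cpi_series[to_year] / cpi_series[from_year]


def indirect_cost(absent_months: float, economy: EconomyParams) -> float:
    """Absenteeism cost: months off work times monthly GDP per capita."""
    if absent_months < 0:
        raise ValueError("absent_months must be >= 0")
    return absent_months * economy.monthly_gdp_vnd
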