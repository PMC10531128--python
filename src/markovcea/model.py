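"""Model/Results facade over the cohort pipeline.

``CostUtilityModel`` bundles a set of treatment-sequence strategies
with cohort, economy and discount settings; ``run()`` (alias ``fit()``)
evaluates every strategy and returns a ``CostUtilityResults`` object
carrying the CEA table, pairwise comparisons, a text summary, and the
tornado sensitivity analysis.
"""
from __future__ import annotations

import logging
from dataclasses import replace

import pandas as pd

from . import sensitivity as _sensitivity
from .econ import CEAResult, ComparisonResult, compare_strategies, vnd_to_usd, wtp_classify
from .engine import CohortTrace, run_cohort
from .pipeline import evaluate_strategy, resolve_sequence
from .regimens import (
    REGIMEN_CODES,
    ModelInputs,
    RegimenSequence,
    to_transition_matrix,
    vietnam_fixture,
)

logger = logging.getLogger("markovcea")

#: add-on vs standard comparisons evaluated by default on the bundled regimens
DEFAULT_COMPARISONS = (
    ("PGD", "PD"),
    ("PDG", "PD"),
    ("PGD", "PDG"),
    ("PDE", "PD"),
    ("PGDE", "PDE"),
    ("PDEG", "PDE"),
    ("PGDE", "PDEG"),
)

#: the four glucosamine add-on scenarios analysed in the tornado by default
DEFAULT_TORNADO_COMPARISONS = (
    ("PGD", "PD"),
    ("PDG", "PD"),
    ("PGDE", "PDE"),
    ("PDEG", "PDE"),
)


class CostUtilityModel:
    """Markov cohort cost-utility model over a set of strategies.

    Parameters
    ----------
    inputs : ModelInputs
        Treatment catalogue, cohort, economy and discount settings.
    strategies : sequence of str or RegimenSequence
        Regimen codes resolved against the catalogue, or explicit
        sequences.
    half_cycle : bool
        Apply the trapezoidal half-cycle correction when accruing
        costs and QALYs (default off: membership counted at cycle end).
    """

    def __init__(self, inputs: ModelInputs, strategies=REGIMEN_CODES, half_cycle: bool = False):
        self.inputs = inputs
        self.strategies = list(strategies)
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        self.half_cycle = half_cycle

    @classmethod
    def from_fixture(cls, strategies=REGIMEN_CODES, half_cycle: bool = False, **fixture_options):
        """Model on the bundled Vietnamese knee-osteoarthritis inputs."""
        return cls(vietnam_fixture(**fixture_options), strategies, half_cycle)

    def _key(self, strategy) -> str:
        return strategy if isinstance(strategy, str) else strategy.code

    def run(self) -> "CostUtilityResults":
        """Evaluate every strategy; returns the results object."""
        logger.info(
            "run: discount=%.4g/yr, cycle=%.3g y, horizon=%d cycles, half_cycle=%s",
            self.inputs.discount.annual_rate,
            self.inputs.cohort.cycle_length,
            self.inputs.cohort.horizon_cycles,
            self.half_cycle,
        )
        results: dict[str, CEAResult] = {}
        traces: dict[str, CohortTrace] = {}
        for strategy in self.strategies:
            seq = resolve_sequence(self.inputs, strategy)
            matrix = to_transition_matrix(seq)
            cohort = replace(self.inputs.cohort, initial_state=seq.steps[0].name)
            traces[seq.code] = run_cohort(matrix, cohort)
            results[seq.code] = evaluate_strategy(self.inputs, strategy, half_cycle=self.half_cycle)
        return CostUtilityResults(self, results, traces)

    # statsmodels-style alias; the model is simulated, not estimated
    fit = run


class CostUtilityResults:
    """Discounted totals, comparisons and sensitivity for a fitted model."""

    def __init__(self, model: CostUtilityModel, results: dict[str, CEAResult], traces):
        self.model = model
        self.results = results
        self.traces = traces

    @property
    def strategy_ids(self) -> list[str]:
        return list(self.results)

    def cea_table(self) -> pd.DataFrame:
        """One row per strategy: discounted cost (VND and USD) and QALYs."""
        rate = self.model.inputs.economy.exchange_rate
        rows = [
            {
                "strategy": r.strategy_id,
                "cost_vnd": r.total_cost,
                "cost_usd": vnd_to_usd(r.total_cost, rate),
                "qalys": r.total_qalys,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows)

    def compare(self, a: str, b: str) -> ComparisonResult:
        """Incremental comparison (a vs comparator b)."""
        return compare_strategies(self.results[a], self.results[b])

    def _default_pairs(self) -> list[tuple[str, str]]:
        ids = set(self.strategy_ids)
        pairs = [p for p in DEFAULT_COMPARISONS if set(p) <= ids]
        if pairs:
            return pairs
        order = self.strategy_ids
        return [(order[i + 1], order[i]) for i in range(len(order) - 1)]

    def comparison_table(self, pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
        """Pairwise deltas, ICER/dominance label and WTP class."""
        economy = self.model.inputs.economy
        rows = []
        for a, b in pairs if pairs is not None else self._default_pairs():
            c = self.compare(a, b)
            rows.append(
                {
                    "strategy": a,
                    "comparator": b,
                    "delta_cost_vnd": c.delta_cost,
                    "delta_qalys": c.delta_qaly,
                    "icer_vnd_per_qaly": c.icer,
                    "icer_usd_per_qaly": (
                        vnd_to_usd(c.icer, economy.exchange_rate) if c.icer is not None else None
                    ),
                    "label": c.label,
                    "wtp_class": wtp_classify(c, economy),
                }
            )
        return pd.DataFrame(rows)

    def tornado(
        self,
        comparison: tuple[str, str],
        parameters=None,
        fraction: float = 0.20,
    ) -> pd.DataFrame:
        """One-way sensitivity of the pairwise ICER; see
        :func:`markovcea.sensitivity.tornado`."""
        entries = _sensitivity.tornado(
            self.model.inputs,
            comparison,
            parameters=parameters,
            fraction=fraction,
            half_cycle=self.model.half_cycle,
        )
        return _sensitivity.tornado_table(entries)

    def plot_tornado(self, comparison: tuple[str, str], path=None, fraction: float = 0.20):
        """Tornado bar plot for one comparison; saves to ``path`` if given."""
        entries = _sensitivity.tornado(
            self.model.inputs, comparison, fraction=fraction, half_cycle=self.model.half_cycle
        )
        base = self.compare(*comparison)
        return _sensitivity.plot_tornado(
            entries, base.icer, path=path, title=f"{comparison[0]} vs {comparison[1]}"
        )

    def summary(self) -> str:
        """Plain-text summary: settings, CEA table, comparison table."""
        inputs = self.model.inputs
        lines = [
            "Markov cohort cost-utility analysis",
            "===================================",
            f"strategies:     {', '.join(self.strategy_ids)}",
            f"cohort:         age {inputs.cohort.start_age:g} to {inputs.cohort.life_expectancy:g} y, "
            f"{inputs.cohort.horizon_cycles} cycles of {inputs.cohort.cycle_length:g} y",
            f"discount:       {inputs.discount.annual_rate:.1%}/year (costs and outcomes)",
            f"half-cycle:     {'on' if self.model.half_cycle else 'off'}",
            f"WTP thresholds: {inputs.economy.gdp_per_capita_vnd:,.0f} / "
            f"{3 * inputs.economy.gdp_per_capita_vnd:,.0f} VND per QALY (1x / 3x GDP per capita)",
            "",
            "Discounted totals",
            "-----------------",
            self.cea_table().round({"cost_vnd": 0, "cost_usd": 2, "qalys": 4}).to_string(index=False),
            "",
            "Incremental comparisons",
            "-----------------------",
            self.comparison_table()
            .round({"delta_cost_vnd": 0, "delta_qalys": 4, "icer_vnd_per_qaly": 0, "icer_usd_per_qaly": 2})
            .to_string(index=False),
        ]
        return "\n".join(lines)
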