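"""End-to-end evaluation helpers: regimen -> trace -> discounted totals.

Shared by the model facade, the sensitivity analysis and the CLI so
that every caller runs the identical pipeline.
"""
from __future__ import annotations

from dataclasses import replace

from .econ import CEAResult, ComparisonResult, accumulate, compare_strategies
from .engine import run_cohort
from .regimens import ModelInputs, RegimenSequence, TreatmentSpec, build_regimen, to_transition_matrix


def resolve_sequence(
    inputs: ModelInputs,
    strategy: str | RegimenSequence,
    treatments: dict[str, TreatmentSpec] | None = None,
) -> RegimenSequence:
    """Turn a regimen code (or pass through a sequence) using the given
    treatment catalogue (default: the one in ``inputs``)."""
    if isinstance(strategy, RegimenSequence):
        if treatments is None:
            return strategy
        return RegimenSequence(strategy.code, [treatments[s.name] for s in strategy.steps])
    return build_regimen(strategy, treatments if treatments is not None else inputs.treatments)


def evaluate_strategy(
    inputs: ModelInputs,
    strategy: str | RegimenSequence,
    *,
    half_cycle: bool = False,
    treatments: dict[str, TreatmentSpec] | None = None,
) -> CEAResult:
    """Run one strategy through the full pipeline and return its
    discounted cost/QALY totals."""
    seq = resolve_sequence(inputs, strategy, treatments)
    matrix = to_transition_matrix(seq)
    cohort = replace(inputs.cohort, initial_state=seq.steps[0].name)
    trace = run_cohort(matrix, cohort)
    return accumulate(
        trace,
        seq.per_state_costs(),
        seq.per_state_utilities(),
        inputs.discount,
        half_cycle=half_cycle,
        strategy_id=seq.code,
    )


def evaluate_pair(
    inputs: ModelInputs,
    strategy_a: str | RegimenSequence,
    strategy_b: str | RegimenSequence,
    *,
    half_cycle: bool = False,
    treatments: dict[str, TreatmentSpec] | None = None,
) -> ComparisonResult:
    """Incremental comparison of two strategies under identical settings."""
    a = evaluate_strategy(inputs, strategy_a, half_cycle=half_cycle, treatments=treatments)
    b = evaluate_strategy(inputs, strategy_b, half_cycle=half_cycle, treatments=treatments)
    return compare_strategies(a, b)
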