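"""Synthetic scenario generator for property testing.

Emulates the statistical structure of the sequential-treatment model —
row-stochastic matrices over an ordered no-backtracking state sequence
with one absorbing death state, utilities in (0, 1], non-negative
costs in three classes — without any claim of clinical realism.  One
integer seed drives one explicit ``numpy`` Generator; no global state.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .econ import DiscountSpec, EconomyParams
from .engine import CohortSpec, TransitionMatrix
from .regimens import ModelInputs, RegimenSequence, TreatmentSpec, to_transition_matrix


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic generator; the seed fully determines output.

    ``n_treatment_states`` counts the pre-death states (drug lines plus
    the final surgical state), between 2 and 8.
    """

    seed: int
    n_treatment_states: int = 4
    escalation_prob_range: tuple[float, float] = (0.05, 0.95)
    utility_range: tuple[float, float] = (0.30, 0.95)
    cost_scale: float = 1e6
    horizon_cycles: int = 40
    discount_rate: float = 0.03
    cycle_length: float = 0.5
    start_age: float = 40.0

    def __post_init__(self) -> None:
        if not (2 <= self.n_treatment_states <= 8):
            raise ValueError("n_treatment_states must be in [2, 8]")
        for name, (lo, hi), dom in (
            ("escalation_prob_range", self.escalation_prob_range, (0.0, 1.0)),
            ("utility_range", self.utility_range, (0.0, 1.0)),
        ):
            if not (dom[0] <= lo <= hi <= dom[1]):
                raise ValueError(f"{name} must be well-ordered within {dom}")
        if self.cost_scale <= 0:
            raise ValueError("cost_scale must be positive")
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if not (0.0 < self.cycle_length <= 1.0):
            raise ValueError("cycle_length must be in (0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")


@dataclass
class SyntheticScenario:
    """One generated instance: a regimen plus cohort/economy settings."""

    regimen: RegimenSequence
    cohort: CohortSpec
    discount: DiscountSpec
    economy: EconomyParams

    @property
    def matrix(self) -> TransitionMatrix:
        return to_transition_matrix(self.regimen)

    @property
    def inputs(self) -> ModelInputs:
        return ModelInputs(
            treatments={s.name: s for s in self.regimen.steps},
            cohort=self.cohort,
            economy=self.economy,
            discount=self.discount,
        )


def _draw_step(rng: np.random.Generator, config: ScenarioConfig, name: str, kind: str) -> TreatmentSpec:
    p_lo, p_hi = config.escalation_prob_range
    u_lo, u_hi = config.utility_range
    log_scale = np.log10(config.cost_scale)
    # log-uniform costs one decade around the configured magnitude
    drug = 10.0 ** rng.uniform(log_scale - 1.0, log_scale + 1.0)
    nonmed = 10.0 ** rng.uniform(log_scale - 2.0, log_scale)
    indirect = 10.0 ** rng.uniform(log_scale - 2.0, log_scale) if kind == "surgery" else 0.0
    return TreatmentSpec(
        name=name,
        escalation_prob=float(rng.uniform(p_lo, p_hi)),
        drug_cost=float(drug),
        nonmedical_cost=float(nonmed),
        indirect_cost=float(indirect),
        utility=float(rng.uniform(u_lo, u_hi)),
        kind=kind,
    )


def random_model(config: ScenarioConfig) -> SyntheticScenario:
    """Generate one reproducible synthetic instance.

    The sequence has ``n_treatment_states - 1`` drug lines followed by
    one surgical state and the absorbing death state; every instance
    passes the full matrix and regimen validation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_treatment_states
    steps = [_draw_step(rng, config, f"t{i}", "treatment") for i in range(n - 1)]
    steps.append(_draw_step(rng, config, "surgery", "surgery"))
    regimen = RegimenSequence(code=f"SYN{config.seed}", steps=steps)
    cohort = CohortSpec(
        start_age=config.start_age,
        life_expectancy=config.start_age + config.horizon_cycles * config.cycle_length,
        initial_state=steps[0].name,
        cycle_length=config.cycle_length,
    )
    return SyntheticScenario(
        regimen=regimen,
        cohort=cohort,
        discount=DiscountSpec(annual_rate=config.discount_rate),
        economy=EconomyParams(),
    )


def paired_variant(
    base: SyntheticScenario,
    insert_position: int,
    new_spec: TreatmentSpec | None = None,
) -> SyntheticScenario:
    """Insert one extra treatment state at ``insert_position`` (0-based,
    at most just before the surgical state), leaving every other step
    untouched — mirrors adding an adjunct drug before/after a given
    line of an existing sequence.
    """
    steps = list(base.regimen.steps)
    if not (0 <= insert_position <= len(steps) - 1):
        raise ValueError(
            f"insert_position must be in [0, {len(steps) - 1}] (before the surgical state)"
        )
    if new_spec is None:
        neighbour = steps[insert_position]
        new_spec = replace(neighbour, name=f"{neighbour.name}_ins", kind="treatment")
    if new_spec.kind != "treatment":
        raise ValueError("inserted state must be a treatment state")
    steps.insert(insert_position, new_spec)
    regimen = RegimenSequence(code=f"{base.regimen.code}+ins{insert_position}", steps=steps)
    cohort = replace(base.cohort, initial_state=steps[0].name)
    return SyntheticScenario(regimen, cohort, base.discount, base.economy)


def remove_variant(base: SyntheticScenario, position: int) -> SyntheticScenario:
    """Remove the treatment state at ``position`` (inverse of
    :func:`paired_variant` at the same position)."""
    steps = list(base.regimen.steps)
    if not (0 <= position < len(steps)) or steps[position].kind != "treatment":
        raise ValueError("position must address a treatment state")
    steps.pop(position)
    regimen = RegimenSequence(code=f"{base.regimen.code}-del{position}", steps=steps)
    cohort = replace(base.cohort, initial_state=steps[0].name)
    return SyntheticScenario(regimen, cohort, base.discount, base.economy)
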