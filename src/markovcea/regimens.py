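"""Treatment-sequence strategies for knee osteoarthritis in Vietnam.

Six regimens built from a catalogue of treatment lines: two standard
sequences and four variants that insert crystalline glucosamine sulfate
before or after the NSAID step.

Codes (P = pain reliever, D = Diclofenac+PPI, E = Etoricoxib,
G = glucosamine; every sequence ends Triamcinolone -> TKA -> death):

* ``PD``    acetaminophen -> diclofenac+PPI -> triamcinolone -> TKA
* ``PDE``   acetaminophen -> diclofenac+PPI -> etoricoxib -> triamcinolone -> TKA
* ``PGD``   glucosamine inserted before diclofenac+PPI in PD
* ``PDG``   glucosamine inserted after diclofenac+PPI in PD
* ``PGDE``  glucosamine inserted before diclofenac+PPI in PDE
* ``PDEG``  glucosamine inserted after etoricoxib in PDE

All numeric inputs are literature-derived Vietnamese values (drug
tariffs from the national drug administration, GDP and exchange rate
for 2021/2023) and are frozen constants here, never recomputed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .econ import CEAResult, CostComponents, DiscountSpec, EconomyParams
from .engine import DEATH_STATE_ID, CohortSpec, HealthState, TransitionMatrix

logger = logging.getLogger("markovcea")

REGIMEN_CODES = ("PD", "PDE", "PGD", "PDG", "PGDE", "PDEG")

_SEQUENCES: dict[str, tuple[str, ...]] = {
    "PD": ("acetaminophen", "diclofenac_ppi", "triamcinolone", "tka"),
    "PDE": ("acetaminophen", "diclofenac_ppi", "etoricoxib", "triamcinolone", "tka"),
    "PGD": ("acetaminophen", "glucosamine", "diclofenac_ppi", "triamcinolone", "tka"),
    "PDG": ("acetaminophen", "diclofenac_ppi", "glucosamine", "triamcinolone", "tka"),
    "PGDE": ("acetaminophen", "glucosamine", "diclofenac_ppi", "etoricoxib", "triamcinolone", "tka"),
    "PDEG": ("acetaminophen", "diclofenac_ppi", "etoricoxib", "glucosamine", "triamcinolone", "tka"),
}


@dataclass(frozen=True)
class TreatmentSpec:
    """One line of treatment: escalation probability, per-cycle costs, utility.

    ``escalation_prob`` is the per-cycle probability of moving to the
    next state in the sequence (non-response); ``companion_costs``
    covers co-prescribed drugs (the PPI alongside Diclofenac);
    ``indirect_cost`` is nonzero only where absenteeism attaches
    (post-surgery recovery).
    """

    name: str
    escalation_prob: float
    drug_cost: float
    companion_costs: float = 0.0
    nonmedical_cost: float = 0.0
    indirect_cost: float = 0.0
    utility: float = 0.0
    kind: str = "treatment"

    def __post_init__(self) -> None:
        if not (0.0 <= self.escalation_prob <= 1.0):
            raise ValueError(f"{self.name}: escalation_prob outside [0, 1]")
        if not (0.0 <= self.utility <= 1.0):
            raise ValueError(f"{self.name}: utility outside [0, 1]")
        for f in ("drug_cost", "companion_costs", "nonmedical_cost", "indirect_cost"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be >= 0")
        if self.kind not in ("treatment", "surgery"):
            raise ValueError(f"{self.name}: kind must be treatment or surgery")

    @property
    def cost_components(self) -> CostComponents:
        return CostComponents(
            direct_medical=self.drug_cost + self.companion_costs,
            direct_nonmedical=self.nonmedical_cost,
            indirect=self.indirect_cost,
        )


@dataclass
class RegimenSequence:
    """Ordered treatment lines ending in surgery; death appended automatically."""

    code: str
    steps: list[TreatmentSpec]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a regimen needs at least one step")
        if self.steps[-1].kind != "surgery":
            raise ValueError("the final step of a regimen must be the surgical state")
        names = [s.name for s in self.steps]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate step names in regimen {self.code}: {names}")

    @property
    def states(self) -> list[HealthState]:
        out = [HealthState(s.name, s.kind, i) for i, s in enumerate(self.steps)]
        out.append(HealthState(DEATH_STATE_ID, "death", len(self.steps)))
        return out

    def per_state_costs(self) -> dict[str, CostComponents]:
        d = {s.name: s.cost_components for s in self.steps}
        d[DEATH_STATE_ID] = CostComponents()
        return d

    def per_state_utilities(self) -> dict[str, float]:
        d = {s.name: s.utility for s in self.steps}
        d[DEATH_STATE_ID] = 0.0
        return d


def default_treatments(
    *,
    triamcinolone_per_administration: bool = False,
    drug_cost_multiplier: float = 1.0,
    recovery_months: float = 1.0,
) -> dict[str, TreatmentSpec]:
    """The frozen treatment catalogue behind the six bundled regimens.

    Costs are VND per 6-month cycle as tariffed; utilities are
    state-specific quality-of-life weights from published instruments.
    ``triamcinolone_per_administration`` doubles the injection cost (40
    mg every 3 months means two administrations per 6-month cycle);
    ``recovery_months`` scales the food/transport and absenteeism costs
    attached to the post-surgery recovery period (default one month).
    """
    m = drug_cost_multiplier
    tri_cost = 19_400.0 * (2.0 if triamcinolone_per_administration else 1.0)
    return {
        "acetaminophen": TreatmentSpec(
            "acetaminophen", escalation_prob=0.3380, drug_cost=588_600.0 * m, utility=0.7010
        ),
        "glucosamine": TreatmentSpec(
            "glucosamine", escalation_prob=0.3857, drug_cost=186_300.0 * m, utility=0.6760
        ),
        "diclofenac_ppi": TreatmentSpec(
            "diclofenac_ppi",
            escalation_prob=0.8647,
            drug_cost=60_210.0 * m,
            companion_costs=344_700.0 * m,  # omeprazole co-prescription
            utility=0.7230,
        ),
        "etoricoxib": TreatmentSpec(
            "etoricoxib", escalation_prob=0.5657, drug_cost=785_700.0 * m, utility=0.7230
        ),
        "triamcinolone": TreatmentSpec(
            "triamcinolone", escalation_prob=0.0392, drug_cost=tri_cost * m, utility=0.6400
        ),
        "tka": TreatmentSpec(
            "tka",
            escalation_prob=0.5122,
            drug_cost=88_712_500.0,
            nonmedical_cost=(2_700_000.0 + 2_953_620.0) * recovery_months,
            indirect_cost=7_342_373.0 * recovery_months,
            utility=0.7600,
            kind="surgery",
        ),
    }


def build_regimen(code: str, treatments: dict[str, TreatmentSpec] | None = None) -> RegimenSequence:
    """Build one of the six named regimens from a treatment catalogue."""
    if code not in _SEQUENCES:
        raise KeyError(f"unknown regimen code {code!r}; expected one of {REGIMEN_CODES}")
    catalogue = treatments if treatments is not None else default_treatments()
    return RegimenSequence(code=code, steps=[catalogue[name] for name in _SEQUENCES[code]])


def to_transition_matrix(regimen: RegimenSequence) -> TransitionMatrix:
    """Bidiagonal chain matrix: each state keeps 1 - p on itself and
    sends p to the next ordinal state; the surgical state escalates to
    death the same way; death is absorbing."""
    states = regimen.states
    n = len(states)
    probs = np.zeros((n, n))
    for i, step in enumerate(regimen.steps):
        probs[i, i] = 1.0 - step.escalation_prob
        probs[i, i + 1] = step.escalation_prob
    probs[n - 1, n - 1] = 1.0
    return TransitionMatrix(states, probs)


def efficacy_to_transition(response_prob: float, trial_duration: float, cycle_length: float) -> float:
    """Convert a trial response probability to a per-cycle transition
    probability via a constant hazard: rate = -ln(1-p)/duration,
    per-cycle p = 1 - exp(-rate * cycle_length).

    Equals ``response_prob`` when the trial duration matches the cycle
    length.  A response probability of exactly 1 maps to 1 (logged) —
    the implied hazard is infinite.
    """
    if not (0.0 <= response_prob <= 1.0):
        raise ValueError("response_prob must be in [0, 1]")
    if trial_duration <= 0 or cycle_length <= 0:
        raise ValueError("durations must be positive")
    if response_prob == 1.0:
        logger.info("response probability 1 with finite duration: per-cycle probability 1")
        return 1.0
    rate = -math.log1p(-response_prob) / trial_duration
    return 1.0 - math.exp(-rate * cycle_length)


@dataclass
class ModelInputs:
    """Full input bundle: treatment catalogue + cohort + economy + discount."""

    treatments: dict[str, TreatmentSpec]
    cohort: CohortSpec
    economy: EconomyParams = field(default_factory=EconomyParams)
    discount: DiscountSpec = field(default_factory=DiscountSpec)


def vietnam_fixture(
    *,
    start_age: float = 40.0,
    life_expectancy: float = 73.6,
    cycle_length: float = 0.5,
    **treatment_options,
) -> ModelInputs:
    """The bundled Vietnamese knee-osteoarthritis input set.

    Cohort enters at age 40 on acetaminophen and is followed to the
    national average life expectancy (73.6 years, 2021) in 6-month
    cycles; 3% annual discount on costs and outcomes; 2021 GDP per
    capita of USD 3756 at 23,486 VND/USD.
    """
    return ModelInputs(
        treatments=default_treatments(**treatment_options),
        cohort=CohortSpec(
            start_age=start_age,
            life_expectancy=life_expectancy,
            initial_state="acetaminophen",
            cycle_length=cycle_length,
        ),
        economy=EconomyParams(gdp_per_capita_usd=3756.0, exchange_rate=23486.0),
        discount=DiscountSpec(annual_rate=0.03),
    )


def published_base_case() -> dict[str, CEAResult]:
    """Reference base-case totals (discounted cost in VND, QALYs) for
    the six regimens, as reported in the source literature for this
    input set.  Used as inputs to incremental analysis: feeding these
    pairs to ``compare_strategies`` reproduces the published ICERs.
    """
    published = {
        "PD": (314_758_471.0, 56.9374),
        "PGD": (348_133_295.0, 100.7445),
        "PDG": (339_027_398.0, 92.7119),
        "PDE": (367_478_671.0, 129.8038),
        "PGDE": (443_969_715.0, 230.6720),
        "PDEG": (425_013_733.0, 211.3288),
    }
    return {
        code: CEAResult(strategy_id=code, total_cost=cost, total_qalys=qalys)
        for code, (cost, qalys) in published.items()
    }
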