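"""Schema-validated run configuration (YAML) for the CLI.

A single human-readable YAML file describes strategies, cohort,
economy, discounting and the sensitivity block; unknown keys are
rejected so typos fail loudly.
"""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .econ import DiscountSpec, EconomyParams
from .engine import CohortSpec
from .model import DEFAULT_TORNADO_COMPARISONS, CostUtilityModel
from .regimens import REGIMEN_CODES, ModelInputs, RegimenSequence, TreatmentSpec, default_treatments


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Strict):
    start_age: float = 40.0
    life_expectancy: float = 73.6
    cycle_length: float = 0.5
    cohort_mass: float = 1.0


class EconomyConfig(_Strict):
    gdp_per_capita_usd: float = 3756.0
    exchange_rate: float = 23486.0
    cpi_series: dict[int, float] | None = None


class StepConfig(_Strict):
    name: str
    escalation_prob: float
    drug_cost: float
    companion_costs: float = 0.0
    nonmedical_cost: float = 0.0
    indirect_cost: float = 0.0
    utility: float
    kind: str = "treatment"


class SensitivityBlock(_Strict):
    fraction: float = 0.20
    comparisons: list[tuple[str, str]] | None = None
    parameters: list[str] | None = None  # dotted paths; None = costs+utilities of compared states


class RunConfig(_Strict):
    """Top-level run configuration; see the bundled example in the docs."""

    strategies: list[str] = Field(default_factory=lambda: list(REGIMEN_CODES))
    custom_strategies: dict[str, list[StepConfig]] = Field(default_factory=dict)
    treatment_overrides: dict[str, dict[str, float]] = Field(default_factory=dict)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    economy: EconomyConfig = Field(default_factory=EconomyConfig)
    discount_rate: float = 0.03
    half_cycle: bool = False
    sensitivity: SensitivityBlock = Field(default_factory=SensitivityBlock)
    output_dir: str = "results"
    seed: int | None = None

    def build_inputs(self) -> ModelInputs:
        treatments = default_treatments()
        for name, overrides in self.treatment_overrides.items():
            if name not in treatments:
                raise KeyError(f"treatment_overrides refers to unknown treatment {name!r}")
            from dataclasses import replace

            treatments[name] = replace(treatments[name], **overrides)
        for cname, steps in self.custom_strategies.items():
            for sc in steps:
                treatments.setdefault(sc.name, TreatmentSpec(**sc.model_dump()))
        cohort = CohortSpec(
            start_age=self.cohort.start_age,
            life_expectancy=self.cohort.life_expectancy,
            initial_state="acetaminophen",
            cycle_length=self.cohort.cycle_length,
            cohort_mass=self.cohort.cohort_mass,
        )
        economy = EconomyParams(
            gdp_per_capita_usd=self.economy.gdp_per_capita_usd,
            exchange_rate=self.economy.exchange_rate,
            cpi_series=self.economy.cpi_series,
        )
        return ModelInputs(
            treatments=treatments,
            cohort=cohort,
            economy=economy,
            discount=DiscountSpec(annual_rate=self.discount_rate),
        )

    def build_strategies(self) -> list:
        out: list = []
        for code in self.strategies:
            if code in self.custom_strategies:
                steps = [TreatmentSpec(**sc.model_dump()) for sc in self.custom_strategies[code]]
                out.append(RegimenSequence(code=code, steps=steps))
            else:
                out.append(code)
        return out

    def build_model(self) -> CostUtilityModel:
        return CostUtilityModel(self.build_inputs(), self.build_strategies(), self.half_cycle)

    def tornado_comparisons(self) -> list[tuple[str, str]]:
        if self.sensitivity.comparisons is not None:
            return [tuple(p) for p in self.sensitivity.comparisons]
        ids = set(self.strategies)
        return [p for p in DEFAULT_TORNADO_COMPARISONS if set(p) <= ids]


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(exclude_none=True), fh, sort_keys=False)
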