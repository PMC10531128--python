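"""One-way deterministic sensitivity analysis (tornado diagrams).

Each scalar input is perturbed to a low and a high value while all
other inputs stay at base case, the full pipeline is re-run, and the
resulting ICER excursions are ranked by spread.  Parameters are
addressed by dotted path into the treatment catalogue, e.g.
``"tka.drug_cost"`` or ``"acetaminophen.utility"``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .econ import LABEL_ICER
from .pipeline import evaluate_pair, resolve_sequence
from .regimens import ModelInputs, RegimenSequence, TreatmentSpec

logger = logging.getLogger("markovcea")

#: fields perturbed for every state in the default tornado set
DEFAULT_FIELDS = ("drug_cost", "utility")

_UNIT_INTERVAL_FIELDS = ("utility", "escalation_prob")


@dataclass(frozen=True)
class ParameterRef:
    """One scalar input with its base value and perturbation bounds."""

    path: str  # "<treatment>.<field>"
    base_value: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base_value <= self.high):
            raise ValueError(f"{self.path}: need low <= base <= high")

    @property
    def treatment(self) -> str:
        return self.path.split(".", 1)[0]

    @property
    def field(self) -> str:
        return self.path.split(".", 1)[1]


@dataclass
class TornadoEntry:
    """ICER excursion of one parameter; a dominance label replaces a
    numeric ICER where the perturbation flips the comparison quadrant."""

    parameter: ParameterRef
    icer_low: float | None
    icer_high: float | None
    label_low: str
    label_high: str
    spread: float
    rank: int = 0
    flagged: bool = False  # spread computed from a single numeric excursion


def default_range(path: str, base_value: float, fraction: float = 0.20) -> tuple[float, float]:
    """Symmetric +/- ``fraction`` range around the base value, clamped to
    the parameter's domain (probabilities and utilities to [0, 1],
    costs to >= 0); clamping is logged."""
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    low = base_value * (1.0 - fraction)
    high = base_value * (1.0 + fraction)
    field = path.split(".", 1)[1]
    lo_bound, hi_bound = (0.0, 1.0) if field in _UNIT_INTERVAL_FIELDS else (0.0, float("inf"))
    if low < lo_bound:
        logger.info("clamping %s low %.6g -> %.6g", path, low, lo_bound)
        low = lo_bound
    if high > hi_bound:
        logger.info("clamping %s high %.6g -> %.6g", path, high, hi_bound)
        high = hi_bound
    return low, high


def default_parameters(
    inputs: ModelInputs,
    comparison: tuple[str | RegimenSequence, str | RegimenSequence],
    fraction: float = 0.20,
    fields: tuple[str, ...] = DEFAULT_FIELDS,
) -> list[ParameterRef]:
    """Cost and utility of every state appearing in either compared
    regimen, each with a symmetric +/- ``fraction`` range."""
    names: list[str] = []
    for strategy in comparison:
        seq = resolve_sequence(inputs, strategy)
        for step in seq.steps:
            if step.name not in names:
                names.append(step.name)
    params = []
    for name in sorted(names):
        for f in fields:
            base = getattr(inputs.treatments[name], f)
            low, high = default_range(f"{name}.{f}", base, fraction)
            params.append(ParameterRef(f"{name}.{f}", base, low, high))
    return params


def _perturbed_catalogue(
    treatments: dict[str, TreatmentSpec], path: str, value: float
) -> dict[str, TreatmentSpec]:
    name, f = path.split(".", 1)
    if name not in treatments:
        raise KeyError(f"unknown treatment {name!r} in parameter path {path!r}")
    out = dict(treatments)
    out[name] = replace(treatments[name], **{f: value})
    return out


def tornado(
    inputs: ModelInputs,
    comparison: tuple[str | RegimenSequence, str | RegimenSequence],
    parameters: list[ParameterRef] | None = None,
    fraction: float = 0.20,
    half_cycle: bool = False,
) -> list[TornadoEntry]:
    """One-way sensitivity of the pairwise ICER to each parameter.

    The base-case comparison must yield a numeric ICER.  For each
    parameter the pipeline is re-run at its low and high value (all
    other inputs at base; no leakage between parameters).  Entries are
    ranked by spread = |icer_high - icer_low|, ties broken by parameter
    path; where one excursion lands in a dominance quadrant its label
    is recorded and the spread falls back to the distance between the
    remaining numeric excursion and the base ICER (flagged).
    """
    base = evaluate_pair(inputs, *comparison, half_cycle=half_cycle)
    if base.label != LABEL_ICER:
        raise ValueError(
            f"base-case comparison is {base.label!r}, not a numeric ICER; tornado undefined"
        )
    if parameters is None:
        parameters = default_parameters(inputs, comparison, fraction)

    entries: list[TornadoEntry] = []
    for p in parameters:
        excursions: dict[str, tuple[float | None, str]] = {}
        for side, value in (("low", p.low), ("high", p.high)):
            cat = _perturbed_catalogue(inputs.treatments, p.path, value)
            cmp_ = evaluate_pair(inputs, *comparison, half_cycle=half_cycle, treatments=cat)
            excursions[side] = (cmp_.icer if cmp_.label == LABEL_ICER else None, cmp_.label)
        icer_low, label_low = excursions["low"]
        icer_high, label_high = excursions["high"]
        flagged = False
        if icer_low is not None and icer_high is not None:
            spread = abs(icer_high - icer_low)
        elif icer_low is not None:
            spread, flagged = abs(icer_low - base.icer), True
        elif icer_high is not None:
            spread, flagged = abs(icer_high - base.icer), True
        else:
            spread, flagged = 0.0, True
        entries.append(
            TornadoEntry(p, icer_low, icer_high, label_low, label_high, spread, flagged=flagged)
        )

    entries.sort(key=lambda e: (-e.spread, e.parameter.path))
    for i, e in enumerate(entries, start=1):
        e.rank = i
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Ranked tornado entries as a flat table (CSV-ready)."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter.path for e in entries],
            "base_value": [e.parameter.base_value for e in entries],
            "low": [e.parameter.low for e in entries],
            "high": [e.parameter.high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "label_low": [e.label_low for e in entries],
            "label_high": [e.label_high for e in entries],
            "spread": [e.spread for e in entries],
            "rank": [e.rank for e in entries],
            "flagged": [e.flagged for e in entries],
        }
    )


def plot_tornado(entries: list[TornadoEntry], base_icer: float, path: str | None = None, title: str = ""):
    """Horizontal-bar tornado plot; saves to ``path`` if given.

    Entries without a numeric excursion on one side draw a one-sided bar.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = sorted(entries, key=lambda e: e.spread)  # widest on top
    labels = [e.parameter.path for e in entries]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    for y, e in enumerate(entries):
        lo = e.icer_low if e.icer_low is not None else base_icer
        hi = e.icer_high if e.icer_high is not None else base_icer
        left, right = min(lo, hi), max(lo, hi)
        ax.barh(y, right - left, left=left, color="#4878d0", edgecolor="black", height=0.6)
    ax.axvline(base_icer, color="black", lw=1, ls="--")
    ax.set_yticks(range(len(entries)), labels)
    ax.set_xlabel("ICER (VND/QALY)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
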