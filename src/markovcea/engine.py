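"""Forward simulation of a closed cohort over a finite-state Markov chain.

The chains modelled here describe ordered treatment pathways: a closed
cohort moves through a sequence of health states (drug lines, then a
surgical state) and ends in a single absorbing death state.  Disease
progression is one-way — once a patient has escalated to a later line of
treatment they cannot return — so a valid transition matrix is upper
triangular when states are listed in pathway order.

The engine is deliberately generic: it knows nothing about costs,
utilities or discounting (see :mod:`markovcea.econ`), only about
redistributing cohort mass cycle by cycle.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("markovcea")

STATE_KINDS = ("treatment", "surgery", "death")
DEATH_STATE_ID = "death"

#: tolerance within which a row must sum to 1 to count as stochastic
ROW_SUM_TOL = 1e-12
#: rows within this distance of 1 are renormalised (with a warning) on input
ROW_RENORMALIZE_TOL = 1e-8


@dataclass(frozen=True)
class HealthState:
    """One mutually exclusive health state of the cohort model.

    Parameters
    ----------
    id : str
        Unique short label, e.g. ``"acetaminophen"`` or ``"death"``.
    kind : {"treatment", "surgery", "death"}
        Role of the state in the pathway.
    ordinal : int
        Position in the treatment sequence; death is always last.
    """

    id: str
    kind: str
    ordinal: int

    def __post_init__(self) -> None:
        if self.kind not in STATE_KINDS:
            raise ValueError(f"unknown state kind {self.kind!r}")
        if self.ordinal < 0:
            raise ValueError("state ordinal must be >= 0")


class TransitionMatrix:
    """Per-cycle transition probabilities over an ordered state list.

    Rows are indexed by source state, columns by target state, in the
    order of ``states``.  Construction checks dimensions only (a
    mismatch is a structural error); semantic invariants are reported by
    :func:`validate_matrix`.

    Parameters
    ----------
    states : sequence of HealthState
    probs : (n, n) array-like
    renormalize : bool
        If True, rows whose sums are within ``ROW_RENORMALIZE_TOL`` of 1
        are rescaled to sum exactly to 1 (logged); rows further off
        raise ``ValueError``.
    """

    def __init__(self, states, probs, *, renormalize: bool = False):
        self.states: list[HealthState] = list(states)
        probs = np.array(probs, dtype=float)
        n = len(self.states)
        if probs.ndim != 2 or probs.shape != (n, n):
            raise ValueError(
                f"probs has shape {probs.shape}, expected ({n}, {n}) "
                f"to match the {n} states"
            )
        if renormalize:
            sums = probs.sum(axis=1)
            far = np.abs(sums - 1.0) > ROW_RENORMALIZE_TOL
            if far.any():
                rows = [self.states[i].id for i in np.flatnonzero(far)]
                raise ValueError(f"rows {rows} are not stochastic (sum off by > {ROW_RENORMALIZE_TOL})")
            off = np.abs(sums - 1.0) > ROW_SUM_TOL
            if off.any():
                rows = [self.states[i].id for i in np.flatnonzero(off)]
                logger.warning("renormalizing near-stochastic rows: %s", rows)
                probs = probs / sums[:, None]
        self.probs: np.ndarray = probs
        self._index = {s.id: i for i, s in enumerate(self.states)}
        if len(self._index) != n:
            # duplicate ids also surface via validate_matrix; keep lookup safe
            logger.warning("duplicate state ids in transition matrix")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self, state_id: str) -> int:
        try:
            return self._index[state_id]
        except KeyError:
            raise KeyError(f"unknown state id {state_id!r}") from None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ids = [s.id for s in self.states]
        return f"TransitionMatrix(states={ids})"


def validate_matrix(matrix: TransitionMatrix) -> list[str]:
    """Check all chain invariants; return a list of violation messages.

    An empty list means the matrix is a valid one-way pathway chain:
    entries in [0, 1], rows stochastic, no backward transitions (target
    ordinal below source ordinal), exactly one absorbing death state
    with the highest ordinal, unique state ids.
    """
    violations: list[str] = []
    states, probs = matrix.states, matrix.probs

    seen: set[str] = set()
    for s in states:
        if s.id in seen:
            violations.append(f"duplicate state id {s.id!r}")
        seen.add(s.id)

    deaths = [s for s in states if s.kind == "death"]
    if len(deaths) != 1:
        violations.append(f"expected exactly one death state, found {len(deaths)}")
    else:
        death = deaths[0]
        if any(s.ordinal >= death.ordinal for s in states if s is not death):
            violations.append("death state must have the highest ordinal")
        i = states.index(death)
        row = np.zeros(matrix.n_states)
        row[i] = 1.0
        if not np.array_equal(probs[i], row):
            violations.append(f"death row {death.id!r} is not absorbing")

    for i, s in enumerate(states):
        for j, t in enumerate(states):
            p = probs[i, j]
            if not (0.0 <= p <= 1.0):
                violations.append(f"entry [{s.id!r} -> {t.id!r}] = {p} outside [0, 1]")
            if t.ordinal < s.ordinal and p != 0.0:
                violations.append(
                    f"backward transition [{s.id!r} -> {t.id!r}] = {p} (no backtracking allowed)"
                )

    sums = probs.sum(axis=1)
    for i, s in enumerate(states):
        if abs(sums[i] - 1.0) > ROW_SUM_TOL:
            violations.append(f"row {s.id!r} sums to {sums[i]!r}, not 1")

    return violations


@dataclass(frozen=True)
class CohortSpec:
    """Closed-cohort simulation settings.

    The horizon runs from ``start_age`` to ``life_expectancy`` in cycles
    of ``cycle_length`` years; a fractional final cycle is rounded up to
    a whole cycle.

    Parameters
    ----------
    start_age : float
        Age (years) at model entry.
    life_expectancy : float
        Age (years) at which the horizon ends (population average life
        expectancy for a lifetime model).
    initial_state : str
        State id holding the whole cohort at cycle 0.
    cycle_length : float
        Cycle length in years, in (0, 1].
    cohort_mass : float
        Total cohort mass (1.0 models per-person expectations).
    """

    start_age: float
    life_expectancy: float
    initial_state: str
    cycle_length: float = 0.5
    cohort_mass: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.cycle_length <= 1.0):
            raise ValueError("cycle_length must be in (0, 1] years")
        if not self.life_expectancy > self.start_age:
            raise ValueError("life_expectancy must exceed start_age")
        if self.cohort_mass <= 0:
            raise ValueError("cohort_mass must be positive")
        if self.horizon_cycles < 1:
            raise ValueError("horizon must cover at least one cycle")

    @property
    def horizon_cycles(self) -> int:
        span = self.life_expectancy - self.start_age
        # guard against float fuzz making e.g. 67.2 cycles ceil to 68 vs 67.2000000001
        return math.ceil(round(span / self.cycle_length, 9))


@dataclass
class CohortTrace:
    """State-occupancy history of a closed cohort.

    ``occupancy`` has one row per cycle boundary (row 0 is the initial
    distribution) and one column per state, in the order of ``states``.
    """

    occupancy: np.ndarray
    cycle_length: float
    states: list[HealthState]
    cohort_mass: float = 1.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def index_of(self, state_id: str) -> int:
        for i, s in enumerate(self.states):
            if s.id == state_id:
                return i
        raise KeyError(f"unknown state id {state_id!r}")

    def check(self) -> list[str]:
        """Return invariant violations (mass conservation, positivity,
        monotone death occupancy); empty for a healthy trace."""
        out: list[str] = []
        sums = self.occupancy.sum(axis=1)
        if np.max(np.abs(sums - self.cohort_mass)) > 1e-9:
            out.append("row mass not conserved")
        if (self.occupancy < -1e-15).any():
            out.append("negative occupancy")
        deaths = [i for i, s in enumerate(self.states) if s.kind == "death"]
        for i in deaths:
            col = self.occupancy[:, i]
            if np.any(np.diff(col) < -1e-12):
                out.append(f"death occupancy decreases ({self.states[i].id})")
        return out

    def to_dataframe(self, start_age: float | None = None) -> pd.DataFrame:
        """Trace as a tidy table: cycle, (age,) one column per state."""
        df = pd.DataFrame(self.occupancy, columns=[s.id for s in self.states])
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        if start_age is not None:
            df.insert(1, "age", start_age + df["cycle"] * self.cycle_length)
        return df


def run_cohort(matrix: TransitionMatrix, spec: CohortSpec) -> CohortTrace:
    """Simulate the cohort forward: row t+1 = row t @ probs.

    The matrix must pass :func:`validate_matrix`; the full violation
    list is included in the error if it does not.
    """
    violations = validate_matrix(matrix)
    if violations:
        raise ValueError("invalid transition matrix: " + "; ".join(violations))
    i0 = matrix.index_of(spec.initial_state)
    T = spec.horizon_cycles
    occ = np.zeros((T + 1, matrix.n_states))
    occ[0, i0] = spec.cohort_mass
    for t in range(T):
        occ[t + 1] = occ[t] @ matrix.probs
    return CohortTrace(occ, spec.cycle_length, list(matrix.states), spec.cohort_mass)


def time_in_state(trace: CohortTrace, state_id: str, half_cycle: bool = False) -> float:
    """Person-years spent in one state over the trace.

    Without half-cycle correction membership is counted at cycle end
    (rows 1..T); with it, consecutive rows are averaged (trapezoid),
    approximating mid-cycle transitions.
    """
    j = trace.index_of(state_id)
    col = trace.occupancy[:, j]
    occ = 0.5 * (col[:-1] + col[1:]) if half_cycle else col[1:]
    return float(occ.sum() * trace.cycle_length)
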