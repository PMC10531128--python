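"""Discounting, accumulation, ICER/dominance, WTP and currency arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    COST_EFFECTIVE,
    HIGHLY_COST_EFFECTIVE,
    NOT_APPLICABLE,
    NOT_COST_EFFECTIVE,
    CEAResult,
    ComparisonResult,
    CostComponents,
    DiscountSpec,
    EconomyParams,
    TransitionMatrix,
    accumulate,
    compare_strategies,
    cpi_adjust,
    discount_factor,
    indirect_cost,
    run_cohort,
    usd_to_vnd,
    vnd_to_usd,
    wtp_classify,
)

from conftest import make_states, random_chain_matrix, simple_cohort


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,cycle,length,expected",
        [
            (0.03, 0, 0.5, 1.0),
            (0.0, 17, 0.5, 1.0),
            (0.03, 2, 0.5, 1 / 1.03),
        ],
    )
    def test_closed_form(self, rate, cycle, length, expected):
        assert discount_factor(DiscountSpec(rate), cycle, length) == pytest.approx(expected)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(DiscountSpec(0.03), -1, 0.5)

    def test_monotone_nonincreasing(self):
        spec = DiscountSpec(0.05)
        factors = [discount_factor(spec, t, 0.5) for t in range(50)]
        assert all(a >= b for a, b in zip(factors, factors[1:]))
        assert all(0 < f <= 1 for f in factors)


def _single_state_trace(n_cycles=20, utility=1.0):
    states = make_states(2)
    trace = run_cohort(TransitionMatrix(states, np.eye(2)), simple_cohort(horizon_cycles=n_cycles))
    costs = {"s0": CostComponents(), "death": CostComponents()}
    utils = {"s0": utility, "death": 0.0}
    return trace, costs, utils


class TestAccumulate:
    def test_person_time_identity(self):
        trace, costs, utils = _single_state_trace(utility=1.0)
        res = accumulate(trace, costs, utils, DiscountSpec(0.0))
        assert res.total_qalys == pytest.approx(10.0)
        assert res.total_cost == 0.0

    def test_utility_scales_linearly(self):
        trace, costs, utils = _single_state_trace(utility=0.5)
        res = accumulate(trace, costs, utils, DiscountSpec(0.0))
        assert res.total_qalys == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        m = random_chain_matrix(rng, 4)
        trace = run_cohort(m, simple_cohort(horizon_cycles=25))
        costs = {
            s.id: CostComponents(*rng.uniform(0, 1e6, size=3)) if s.kind != "death" else CostComponents()
            for s in trace.states
        }
        utils = {
            s.id: float(rng.uniform(0.2, 1.0)) if s.kind != "death" else 0.0 for s in trace.states
        }
        disc = DiscountSpec(0.03)
        res = accumulate(trace, costs, utils, disc)
        # independent double loop over cycles and states
        exp_cost = exp_qaly = 0.0
        for t in range(1, trace.n_cycles + 1):
            d = 1.03 ** (-(t * trace.cycle_length))
            for j, s in enumerate(trace.states):
                occ = trace.occupancy[t, j]
                exp_cost += occ * costs[s.id].total * d
                exp_qaly += occ * utils[s.id] * trace.cycle_length * d
        assert res.total_cost == pytest.approx(exp_cost, rel=1e-9)
        assert res.total_qalys == pytest.approx(exp_qaly, rel=1e-9)

    def test_breakdown_sums_to_totals(self, rng):
        m = random_chain_matrix(rng, 3)
        trace = run_cohort(m, simple_cohort(horizon_cycles=12))
        costs = {s.id: CostComponents(direct_medical=1e5) if s.kind != "death" else CostComponents() for s in trace.states}
        utils = {s.id: 0.7 if s.kind != "death" else 0.0 for s in trace.states}
        res = accumulate(trace, costs, utils, DiscountSpec(0.03), half_cycle=True)
        assert res.breakdown["cost"].sum() == pytest.approx(res.total_cost, rel=1e-6)
        assert res.breakdown["qalys"].sum() == pytest.approx(res.total_qalys, rel=1e-6)

    def test_discounting_never_increases_totals(self, rng):
        m = random_chain_matrix(rng, 3)
        trace = run_cohort(m, simple_cohort(horizon_cycles=12))
        costs = {s.id: CostComponents(direct_medical=1e5) if s.kind != "death" else CostComponents() for s in trace.states}
        utils = {s.id: 0.7 if s.kind != "death" else 0.0 for s in trace.states}
        flat = accumulate(trace, costs, utils, DiscountSpec(0.0))
        disc = accumulate(trace, costs, utils, DiscountSpec(0.03))
        assert disc.total_cost < flat.total_cost
        assert disc.total_qalys < flat.total_qalys

    def test_missing_state_and_bad_utility_rejected(self, rng):
        trace = run_cohort(random_chain_matrix(rng, 3), simple_cohort(horizon_cycles=3))
        with pytest.raises(KeyError):
            accumulate(trace, {}, {}, DiscountSpec())
        costs = {s.id: CostComponents() for s in trace.states}
        utils = {s.id: 1.5 for s in trace.states}
        utils["death"] = 0.0
        with pytest.raises(ValueError, match="outside"):
            accumulate(trace, costs, utils, DiscountSpec())


class TestCompareStrategies:
    def test_dominance_and_quadrants(self):
        a = CEAResult("a", 100.0, 10.0)
        cheaper_better = CEAResult("b", 50.0, 12.0)
        c = compare_strategies(cheaper_better, a)
        assert c.label == "dominant" and c.icer is None
        assert compare_strategies(a, cheaper_better).label == "dominated"
        same = compare_strategies(a, CEAResult("c", 90.0, 10.0))
        assert same.label == "undefined" and same.icer is None
        savings = compare_strategies(CEAResult("d", 50.0, 8.0), a)
        assert savings.icer == pytest.approx(25.0) and savings.savings_per_qaly_forgone

    def test_antisymmetric_deltas(self):
        a = CEAResult("a", 120.0, 9.0)
        b = CEAResult("b", 100.0, 7.0)
        ab, ba = compare_strategies(a, b), compare_strategies(b, a)
        assert ab.delta_cost == -ba.delta_cost
        assert ab.delta_qaly == -ba.delta_qaly
        # both deltas flip sign; the savings-quadrant ICER matches numerically
        assert ba.icer == pytest.approx(ab.icer)


class TestWTPClassify:
    GDP = 88_213_416.0

    def _cmp(self, icer):
        return ComparisonResult("a", "b", icer * 1.0, 1.0, icer, "icer")

    @pytest.mark.parametrize(
        "icer,expected",
        [
            (761_858.0, HIGHLY_COST_EFFECTIVE),
            (2 * GDP, COST_EFFECTIVE),
            (GDP, COST_EFFECTIVE),  # boundary -> middle band
            (3 * GDP, COST_EFFECTIVE),
            (4 * GDP, NOT_COST_EFFECTIVE),
        ],
    )
    def test_threshold_bands(self, icer, expected):
        assert wtp_classify(self._cmp(icer), EconomyParams()) == expected

    def test_dominant_and_non_numeric(self):
        economy = EconomyParams()
        dom = ComparisonResult("a", "b", -1.0, 1.0, None, "dominant")
        assert wtp_classify(dom, economy) == HIGHLY_COST_EFFECTIVE
        und = ComparisonResult("a", "b", 1.0, 0.0, None, "undefined")
        assert wtp_classify(und, economy) == NOT_APPLICABLE

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(lo=st.floats(0, 5e8), delta=st.floats(0, 5e8))
    def test_monotone_in_icer(self, lo, delta):
        """Raising the ICER never makes the class more favourable."""
        order = [HIGHLY_COST_EFFECTIVE, COST_EFFECTIVE, NOT_COST_EFFECTIVE]
        economy = EconomyParams()
        a = order.index(wtp_classify(self._cmp(lo), economy))
        b = order.index(wtp_classify(self._cmp(lo + delta), economy))
        assert a <= b


class TestCurrencyAndCPI:
    def test_gdp_conversion_exact(self):
        assert usd_to_vnd(3756, 23486) == 88_213_416
        assert usd_to_vnd(0, 23486) == 0

    def test_inverse_conversion(self):
        assert vnd_to_usd(186_300, 23486) == pytest.approx(7.93, abs=0.005)
        with pytest.raises(ValueError):
            vnd_to_usd(1.0, 0.0)

    def test_cpi_ratio(self):
        series = {2019: 100.0, 2021: 107.0}
        assert cpi_adjust(1_000_000, 2019, 2021, series) == pytest.approx(1_070_000)
        assert cpi_adjust(42.0, 2019, 2019, series) == 42.0
        assert cpi_adjust(10.0, 2019, 2021, {2019: 50.0, 2021: 100.0}) == 20.0
        with pytest.raises(KeyError, match="2020"):
            cpi_adjust(1.0, 2019, 2020, series)

    def test_indirect_cost_monthly_gdp(self):
        economy = EconomyParams()
        assert indirect_cost(0, economy) == 0.0
        one = indirect_cost(1, economy)
        assert one == pytest.approx(88_213_416 / 12)
        assert indirect_cost(2, economy) == pytest.approx(2 * one)
        with pytest.raises(ValueError):
            indirect_cost(-0.5, economy)


def test_negative_cost_component_rejected():
    with pytest.raises(ValueError):
        CostComponents(direct_medical=-1.0)
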