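"""Engine tests, including the straight-line brute-force oracle."""

import dataclasses
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pancreg import cohort as C
from pancreg.parameters import CenterRates, default_parameters, with_value


def brute_force_totals(n_resected, f_hvc, d_hvc, c_hvc, d_lvc, c_lvc, cost):
    """Independent straight-line recomputation of run_state totals."""
    n_hvc = math.floor(n_resected * f_hvc + 0.5)
    n_lvc = n_resected - n_hvc
    deaths = math.floor(n_lvc * d_lvc + 0.5) + math.floor(n_hvc * d_hvc + 0.5)
    compl = math.floor(n_lvc * c_lvc + 0.5) + math.floor(n_hvc * c_hvc + 0.5)
    cost_total = (math.floor(n_lvc * c_lvc + 0.5)
                  + math.floor(n_hvc * c_hvc + 0.5)) * cost
    return deaths, compl, cost_total


def cohort_of_size(n):
    """Parameter set whose operated cohort is exactly n patients."""
    p = default_parameters()
    p = with_value(p, "annual_incidence", n)
    p = with_value(p, "p_resectable", 1.0)
    return with_value(p, "p_resection", 1.0)


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0), (0.5, 1), (1.49, 1), (2.5, 3), (4.66, 5),
         (-0.5, -1), (-2.5, -3), (455.282, 455), (17.586, 18)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert C.round_half_up(x) == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="rounding"):
            C.derive_cohort(10, 0.5, 0.5, rounding="banker")


class TestDeriveCohort:
    def test_statewide_funnel(self):
        counts = C.derive_cohort(5958, 0.41, 0.40)
        assert (counts.n_incident, counts.n_resectable, counts.n_resected) \
            == (5958, 2443, 977)

    def test_empty_cohort(self):
        assert C.derive_cohort(0, 0.41, 0.40) == C.CohortCounts(0, 0, 0)

    def test_exact_halves(self):
        assert C.derive_cohort(1000, 0.5, 0.5) == C.CohortCounts(1000, 500, 250)

    def test_monotone_funnel_enforced(self):
        with pytest.raises(ValueError, match="monotone"):
            C.CohortCounts(10, 20, 5)


class TestAllocate:
    @pytest.mark.parametrize(
        "n, f, expected",
        [(977, 0.466, (455, 522)), (977, 1.0, (977, 0)), (10, 0.466, (5, 5)),
         (0, 0.5, (0, 0))],
    )
    def test_known_splits(self, n, f, expected):
        assert C.allocate(n, f) == expected

    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.0, max_value=1.0))
    def test_conservation(self, n, f):
        for rounding in C.ROUNDING_MODES:
            n_hvc, n_lvc = C.allocate(n, f, rounding)
            assert n_hvc + n_lvc == n
            assert n_hvc >= 0 and n_lvc >= 0

    def test_fraction_out_of_bounds(self):
        with pytest.raises(ValueError, match="p_hvc"):
            C.allocate(10, 1.5)


class TestCenterOutcomes:
    def test_low_volume_row(self):
        out = C.center_outcomes(C.LVC, 522, CenterRates(0.052, 0.398), 16815)
        assert (out.n_deaths, out.n_complications, out.complication_cost) \
            == (27, 208, 3_497_520)

    def test_high_volume_row(self):
        out = C.center_outcomes(C.HVC, 455, CenterRates(0.018, 0.343), 16815)
        assert (out.n_deaths, out.n_complications, out.complication_cost) \
            == (8, 156, 2_623_140)

    def test_empty_center_is_all_zero(self):
        out = C.center_outcomes(C.HVC, 0, CenterRates(0.9, 0.9), 99999)
        assert (out.n_deaths, out.n_complications, out.complication_cost) == (0, 0, 0)

    @given(st.integers(min_value=0, max_value=5000),
           st.floats(min_value=0.0, max_value=1.0),
           st.integers(min_value=0, max_value=100_000))
    def test_cost_is_exact_integer_product(self, n, rate, unit_cost):
        out = C.center_outcomes(C.HVC, n, CenterRates(0.0, rate), unit_cost)
        assert isinstance(out.complication_cost, int)
        assert out.complication_cost == out.n_complications * unit_cost
        assert out.n_complications <= n


class TestRunState:
    @pytest.mark.parametrize("f_hvc", [0.0, 0.25, 0.466, 0.75, 1.0])
    @pytest.mark.parametrize(
        "rates",
        [(0.018, 0.343, 0.052, 0.398), (0.02, 0.3, 0.06, 0.45),
         (0.0, 0.0, 1.0, 1.0)],
    )
    def test_oracle_equivalence_small_cohorts(self, f_hvc, rates):
        """run_state matches the straight-line oracle for n = 0..200."""
        d_hvc, c_hvc, d_lvc, c_lvc = rates
        base = cohort_of_size(0)
        base = dataclasses.replace(
            base,
            hvc_rates=CenterRates(d_hvc, c_hvc),
            lvc_rates=CenterRates(d_lvc, c_lvc),
        )
        for n in range(201):
            params = with_value(base, "annual_incidence", n)
            state = C.run_state(params, f_hvc)
            expected = brute_force_totals(
                n, f_hvc, d_hvc, c_hvc, d_lvc, c_lvc, 16815)
            assert (state.total_deaths, state.total_complications,
                    state.total_cost) == expected
            assert state.total_surgeries == n

    def test_totals_equal_sum_of_outcomes(self, defaults):
        state = C.run_state(defaults, 0.466)
        assert state.total_deaths == sum(o.n_deaths for o in state.outcomes)
        assert state.total_cost == sum(o.complication_cost for o in state.outcomes)

    def test_allocation_irrelevant_when_rates_equal(self, defaults):
        same = dataclasses.replace(defaults, lvc_rates=defaults.hvc_rates)
        lo = C.run_state(same, 0.0)
        hi = C.run_state(same, 1.0)
        assert (lo.total_deaths, lo.total_complications, lo.total_cost) \
            == (hi.total_deaths, hi.total_complications, hi.total_cost)

    def test_monotone_in_hvc_fraction_without_rounding(self, defaults):
        """With better HVC rates, outcomes improve as allocation shifts."""
        fractions = [i / 20 for i in range(21)]
        states = [C.run_state(defaults, f, rounding="off") for f in fractions]
        deaths = [s.total_deaths for s in states]
        compl = [s.total_complications for s in states]
        assert deaths == sorted(deaths, reverse=True)
        assert compl == sorted(compl, reverse=True)

    def test_invalid_params_propagate(self, defaults):
        from pancreg.parameters import ParameterError
        bad = with_value(defaults, "p_hvc", 1.5)
        with pytest.raises(ParameterError):
            C.run_state(bad, 0.5)


class TestCompareStates:
    def test_self_comparison_is_zero(self, defaults):
        s = C.run_state(defaults, 0.466)
        assert C.compare_states(s, s) == C.Differential(0, 0, 0)

    def test_mismatched_cohorts_rejected(self, defaults):
        s1 = C.run_state(defaults, 0.466)
        smaller = with_value(defaults, "annual_incidence", 100)
        s2 = C.run_state(smaller, 0.466)
        with pytest.raises(ValueError, match="not comparable"):
            C.compare_states(s1, s2)

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_zero_differential_when_rates_and_costs_equal(self, f1, f2):
        params = default_parameters()
        params = dataclasses.replace(params, lvc_rates=params.hvc_rates)
        for rounding in C.ROUNDING_MODES:
            cur = C.run_state(params, f1, rounding=rounding)
            fut = C.run_state(params, f2, rounding=rounding)
            diff = C.compare_states(cur, fut)
            assert diff.delta_deaths == pytest.approx(0, abs=1)  # +-1 rounding
            if rounding == "off":
                assert diff.delta_deaths == pytest.approx(0, abs=1e-9)
                assert diff.delta_complications == pytest.approx(0, abs=1e-9)
                assert diff.delta_cost == pytest.approx(0, abs=1e-6)

    def test_equal_complications_different_costs(self, defaults):
        cheap = C.run_state(defaults, 0.466)
        expensive_params = with_value(
            with_value(defaults, "cost_per_complication_hvc", 20000),
            "cost_per_complication_lvc", 20000)
        expensive = C.run_state(expensive_params, 0.466)
        diff = C.compare_states(expensive, cheap)
        assert diff.delta_complications == 0
        assert diff.delta_cost == 364 * (20000 - 16815)
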