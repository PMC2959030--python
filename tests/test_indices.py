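"""Index values, the cost ratio, and the kappa(1-P) = J identity."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cutcost import (
    CostSpec,
    Rates,
    cost_ratio,
    expected_cost,
    implicit_cost_ratio_of_j,
    log_odds_ratio,
    rates_of,
    rescaled_expected_cost,
    table_from_counts,
    weighted_kappa,
    youden_j,
)
from cutcost.exceptions import (
    CutcostError,
    DegeneratePopulationError,
    IndifferentCostsError,
    UndefinedLogOddsError,
)

cells = st.integers(min_value=0, max_value=500)
valid_table = (
    st.tuples(cells, cells, cells, cells)
    .filter(lambda c: c[0] + c[3] > 0 and c[1] + c[2] > 0)
    .map(lambda c: table_from_counts(*c))
)
interior_r = st.floats(0.01, 0.99)


class TestYoudenJ:
    @pytest.mark.parametrize(
        "se, sp, expected",
        [(0.8, 0.4, 0.2), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0)],
    )
    def test_values(self, se, sp, expected):
        r = Rates(se=se, sp=sp, q=0.5, p=0.5)
        assert youden_j(r).value == pytest.approx(expected)

    def test_identical_across_prevalences(self, low_prev_table, high_prev_table):
        """Two populations sharing (SE, SP) share J regardless of P."""
        j1 = youden_j(rates_of(low_prev_table)).value
        j2 = youden_j(rates_of(high_prev_table)).value
        assert j1 == pytest.approx(j2) == pytest.approx(0.2)


class TestCostRatio:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (CostSpec(b_tp=1, c_fn=1, b_tn=1, c_fp=1), 0.5),
            (CostSpec(b_tp=3, c_fn=3, b_tn=1, c_fp=1), 0.75),
            (CostSpec(b_tp=0, c_fn=0, b_tn=1, c_fp=1), 0.0),
        ],
    )
    def test_values(self, spec, expected):
        assert cost_ratio(spec) == pytest.approx(expected)

    def test_all_zero_costs_rejected(self):
        with pytest.raises(IndifferentCostsError):
            CostSpec(b_tp=0, b_tn=0, c_fp=0, c_fn=0)


class TestExpectedCost:
    def test_unit_error_costs_give_misclassification_rate(self, low_prev_table):
        spec = CostSpec(c_fp=1, c_fn=1)
        assert expected_cost(low_prev_table, spec).value == pytest.approx(0.5)

    def test_perfect_table_costs_nothing(self):
        t = table_from_counts(10, 0, 10, 0)
        assert expected_cost(t, CostSpec(c_fp=1, c_fn=1)).value == 0.0


class TestRescaledExpectedCost:
    def test_worked_example(self, low_prev_table):
        r = rates_of(low_prev_table)
        assert rescaled_expected_cost(r, 0.5).value == pytest.approx(0.25)

    def test_perfect_test(self):
        r = Rates(se=1, sp=1, q=0.3, p=0.3)
        assert rescaled_expected_cost(r, 0.7).value == pytest.approx(
            0.3 * 0.7 + 0.7 * 0.3
        )

    def test_useless_test_scores_zero(self):
        r = Rates(se=0, sp=0, q=0.7, p=0.3)
        assert rescaled_expected_cost(r, 0.4).value == 0.0

    def test_r_outside_unit_interval_rejected(self):
        with pytest.raises(CutcostError):
            rescaled_expected_cost(Rates(0.5, 0.5, 0.5, 0.5), 1.2)

    @settings(max_examples=300, deadline=None)
    @given(valid_table, st.floats(0, 1))
    def test_rate_form_equals_cell_form(self, table, r):
        """P*SE*r + (1-P)*SP*(1-r) == TP*r + TN*(1-r) on proportions."""
        rt = rates_of(table)
        prop = table.as_proportions()
        assert rescaled_expected_cost(rt, r).value == pytest.approx(
            prop.tp * r + prop.tn * (1 - r), abs=1e-12
        )


class TestWeightedKappa:
    def test_low_prevalence_worked_example(self, low_prev_table):
        assert weighted_kappa(low_prev_table, 0.5).value == pytest.approx(
            0.0375 / 0.2875
        )

    def test_high_prevalence_worked_example(self, high_prev_table):
        assert weighted_kappa(high_prev_table, 0.5).value == pytest.approx(0.2)

    def test_kappa_depends_on_prevalence_at_fixed_r(
        self, low_prev_table, high_prev_table
    ):
        """Same (SE, SP), same r, different prevalence -> different kappa."""
        k1 = weighted_kappa(low_prev_table, 0.5).value
        k2 = weighted_kappa(high_prev_table, 0.5).value
        assert abs(k1 - k2) > 0.05

    @settings(max_examples=500, deadline=None)
    @given(valid_table)
    def test_reduces_to_youden_at_implicit_ratio(self, table):
        """kappa(1 - P) equals J for every table."""
        rt = rates_of(table)
        if not 0 < rt.p < 1:
            return
        k = weighted_kappa(table, 1 - rt.p).value
        assert k == pytest.approx(youden_j(rt).value, abs=1e-10)

    @settings(max_examples=500, deadline=None)
    @given(valid_table, interior_r)
    def test_matches_rewritten_rate_form(self, table, r):
        """Eq-of-cells form agrees with the SE/SP/Q rewriting
        P(1-P)(SE+SP-1) / (r*P + Q*(1-r-P))."""
        rt = rates_of(table)
        denom = r * rt.p + rt.q * (1 - r - rt.p)
        if abs(denom) < 1e-9:
            return
        rewritten = rt.p * (1 - rt.p) * (rt.se + rt.sp - 1) / denom
        assert weighted_kappa(table, r).value == pytest.approx(
            rewritten, abs=1e-12
        )

    @settings(max_examples=500, deadline=None)
    @given(valid_table, interior_r)
    def test_unit_range_for_informative_tables(self, table, r):
        """kappa(r) lies in [0, 1] whenever J >= 0."""
        rt = rates_of(table)
        if youden_j(rt).value < 0:
            return
        k = weighted_kappa(table, r).value
        assert -1e-12 <= k <= 1 + 1e-12


class TestImplicitCostRatio:
    @pytest.mark.parametrize("p, expected", [(0.25, 0.75), (0.75, 0.25), (0.5, 0.5)])
    def test_one_minus_prevalence(self, p, expected):
        assert implicit_cost_ratio_of_j(p) == expected

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_degenerate_population_rejected(self, p):
        with pytest.raises(DegeneratePopulationError):
            implicit_cost_ratio_of_j(p)


class TestLogOddsRatio:
    def test_worked_example(self, low_prev_table):
        assert log_odds_ratio(low_prev_table).value == pytest.approx(
            math.log(864 / 324), abs=1e-9
        )

    def test_prevalence_free(self, low_prev_table, high_prev_table):
        """Tables sharing (SE, SP) share the log OR despite different
        prevalence — exactly why it cannot encode costs."""
        assert log_odds_ratio(low_prev_table).value == pytest.approx(
            log_odds_ratio(high_prev_table).value, abs=1e-12
        )

    def test_no_association_is_zero(self):
        assert log_odds_ratio(table_from_counts(7, 7, 7, 7)).value == 0.0

    def test_counts_and_proportions_agree(self, low_prev_table):
        assert log_odds_ratio(low_prev_table).value == pytest.approx(
            log_odds_ratio(low_prev_table.as_proportions()).value, abs=1e-12
        )

    def test_zero_cell_rejected(self):
        with pytest.raises(UndefinedLogOddsError):
            log_odds_ratio(table_from_counts(5, 0, 5, 5))
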