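"""Closed-form cost model: line items, protocol totals, diversion, scaling."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvccost import (
    DiversionConvention,
    cost_protocol_A,
    cost_protocol_B,
    diversion_probability,
    incremental_result,
    line_cost,
    scale_to_population,
    set_parameter,
)
from cvccost.reporting import round_cents, whole_percent

from conftest import make_params

SEQ = DiversionConvention.SEQUENTIAL
ADD = DiversionConvention.ADDITIVE


@pytest.mark.parametrize(
    "minutes, wage, expected",
    [
        (15, 0.51, 7.65),  # technician acquiring the radiograph
        (0, 1.72, 0.0),
        (3, 1.89, 5.67),  # radiologist interpretation
    ],
)
def test_line_cost_examples(minutes, wage, expected):
    assert line_cost(minutes, wage) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "minutes, wage, field",
    [(-1, 0.51, "minutes"), (3, 0.0, "wage"), (3, -0.5, "wage")],
)
def test_line_cost_rejects_bad_inputs(minutes, wage, field):
    with pytest.raises(ValueError, match=field):
        line_cost(minutes, wage)


class TestProtocolA:
    def test_central_total(self, params):
        a = cost_protocol_A(params)
        assert len(a.lines) == 3
        assert a.diversion_malposition == 0.0
        assert a.diversion_pneumothorax == 0.0
        assert round_cents(a.total) == 18.48
        # total is the exact sum of the line items, not of rounded cells
        assert a.total == sum(l.cost for l in a.lines)

    def test_linear_in_wages(self, params):
        doubled = make_params(
            wages={
                "bedside-physician": 3.44,
                "radiologist": 3.78,
                "registered-nurse": 1.28,
                "radiology-technician": 1.02,
            }
        )
        assert cost_protocol_A(doubled).total == pytest.approx(2 * 18.48, abs=1e-9)

    def test_low_technician_time(self):
        p = make_params(times={"techTimeA": 10.0})
        # 10 x 0.51 + 3 x 1.72 + 3 x 1.89
        assert cost_protocol_A(p).total == pytest.approx(15.93, abs=1e-9)

    def test_independent_of_ultrasound_parameters(self, params):
        base = cost_protocol_A(params).total
        for label, value in [("mdTimeB", 8.1), ("rnTimeB", 3.1), ("pMalposition", 0.3), ("pPneumothorax", 0.2)]:
            assert cost_protocol_A(set_parameter(params, label, value)).total == base


class TestProtocolB:
    def test_central_total_sequential(self, params):
        b = cost_protocol_B(params, SEQ)
        assert len(b.lines) == 2
        assert round_cents(b.total) == 14.66

    def test_zero_complications_is_base_cost(self):
        p = make_params(p_mal=0.0, p_ptx=0.0)
        for conv in (SEQ, ADD):
            b = cost_protocol_B(p, conv)
            assert b.total == pytest.approx(5.6 * 1.72 + 5.6 * 0.64, abs=1e-12)
            assert b.diversion_malposition == 0.0
            assert b.diversion_pneumothorax == 0.0

    def test_diversion_terms_match_printed_formulas(self, params):
        b = cost_protocol_B(params, SEQ)
        a_total = cost_protocol_A(params).total
        assert b.diversion_malposition == pytest.approx(0.068 * a_total, abs=1e-12)
        assert b.diversion_pneumothorax == pytest.approx((1 - 0.068) * 0.011 * a_total, abs=1e-12)
        assert round_cents(b.diversion_malposition) == 1.26
        assert round_cents(b.diversion_pneumothorax) == 0.19

    def test_sequential_diversion_never_exceeds_additive(self, params):
        # equality only when one probability vanishes
        b_seq = cost_protocol_B(params, SEQ)
        b_add = cost_protocol_B(params, ADD)
        assert b_seq.total < b_add.total
        p0 = make_params(p_mal=0.0, p_ptx=0.2)
        assert cost_protocol_B(p0, SEQ).total == cost_protocol_B(p0, ADD).total

    def test_totals_come_from_exact_products_not_display_cells(self, params):
        """The published cost table prints $9.65 and $3.57 for the two
        ultrasound line items, but the exact products are 5.6 x 1.72 =
        9.632 and 5.6 x 0.64 = 3.584; only the exact products reconcile
        the $14.66 total (the printed cells sum to $14.67)."""
        b = cost_protocol_B(params, SEQ)
        assert b.lines[0].cost == pytest.approx(9.632, abs=1e-12)
        assert b.lines[1].cost == pytest.approx(3.584, abs=1e-12)
        assert round_cents(b.total) == 14.66
        printed_cells = 9.65 + 3.57 + 1.26 + 0.19
        assert round_cents(printed_cells) == 14.67


class TestIncrementalResult:
    def test_base_case_savings(self, params):
        inc = incremental_result(params, SEQ)
        assert round_cents(inc.absolute_savings) == 3.82
        assert whole_percent(inc.relative_savings) == 21

    def test_equal_cost_protocols_have_zero_savings(self):
        # choose the ultrasound physician time so B costs exactly A
        rn_cost = 5.6 * 0.64
        a_total = 18.48
        t = (a_total - rn_cost) / 1.72
        p = make_params(times={"mdTimeB": t}, p_mal=0.0, p_ptx=0.0)
        inc = incremental_result(p, SEQ)
        assert inc.absolute_savings == pytest.approx(0.0, abs=1e-9)

    def test_upper_extreme_physician_time_flips_sign(self, params):
        p = set_parameter(params, "mdTimeB", 8.1)
        inc = incremental_result(p, SEQ)
        assert inc.absolute_savings < 0
        excess_pct = whole_percent(-inc.absolute_savings / inc.cost_a)
        assert excess_pct == 3


@pytest.mark.parametrize(
    "p_mal, p_ptx, convention, expected",
    [
        (0.068, 0.011, ADD, 0.079),
        (0.068, 0.011, SEQ, 0.078252),
        (0.0, 0.0, ADD, 0.0),
        (0.0, 0.0, SEQ, 0.0),
    ],
)
def test_diversion_probability(p_mal, p_ptx, convention, expected):
    probs = make_params(p_mal=p_mal, p_ptx=p_ptx).probabilities
    assert diversion_probability(probs, convention) == pytest.approx(expected, abs=1e-12)


class TestPopulationScaling:
    def test_hospital_year(self, params):
        a = cost_protocol_A(params).total
        b = cost_protocol_B(params, SEQ).total
        assert round(scale_to_population(a, 2045)) == 37792
        assert round(scale_to_population(b, 2045)) == 29984

    def test_zero_population(self):
        assert scale_to_population(123.45, 0) == 0.0

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            scale_to_population(10.0, -1)

    def test_displayed_per_patient_value_does_not_reproduce_totals(self, params):
        """The hospital totals require the unrounded per-patient cost."""
        b = cost_protocol_B(params, SEQ).total
        assert round(scale_to_population(round_cents(b), 2045)) != 29984


# ---- invariants ----------------------------------------------------------

_scale = st.floats(min_value=0.1, max_value=10.0, allow_nan=False)


@settings(max_examples=50, deadline=None)
@given(factor=_scale)
def test_uniform_wage_rescaling(factor):
    """Scaling every wage scales both totals and the absolute savings;
    relative savings is invariant."""
    base = make_params()
    scaled = make_params(
        wages={
            "bedside-physician": 1.72 * factor,
            "radiologist": 1.89 * factor,
            "registered-nurse": 0.64 * factor,
            "radiology-technician": 0.51 * factor,
        }
    )
    inc0, inc1 = incremental_result(base, SEQ), incremental_result(scaled, SEQ)
    assert inc1.cost_a == pytest.approx(factor * inc0.cost_a, rel=1e-12)
    assert inc1.cost_b == pytest.approx(factor * inc0.cost_b, rel=1e-12)
    assert inc1.absolute_savings == pytest.approx(factor * inc0.absolute_savings, rel=1e-9)
    assert inc1.relative_savings == pytest.approx(inc0.relative_savings, rel=1e-9)


@pytest.mark.parametrize(
    "label, low, high",
    [
        ("mdTimeA", 2.0, 4.0),
        ("mdTimeB", 3.1, 8.1),
        ("radiologistRead", 2.0, 4.0),
        ("rnTimeB", 3.1, 8.1),
        ("techTimeA", 10.0, 20.0),
        ("mdWage", 1.41, 1.99),
        ("radiologistWage", 1.66, 2.06),
        ("rnWage", 0.52, 0.79),
        ("techWage", 0.42, 0.63),
        ("pMalposition", 0.026, 0.176),
        ("pPneumothorax", 0.011, 0.032),
    ],
)
def test_cost_b_monotone_in_each_parameter(params, label, high, low):
    """Expected ultrasound-protocol cost never decreases as any wage,
    time or probability increases."""
    for conv in (SEQ, ADD):
        lo = cost_protocol_B(set_parameter(params, label, low), conv).total
        mid = cost_protocol_B(params, conv).total
        hi = cost_protocol_B(set_parameter(params, label, high), conv).total
        assert lo <= mid <= hi
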