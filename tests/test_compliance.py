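"""Direction-aware compliance checks and plotting-position probabilities."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquacpi.compliance import (
    P_CEILING,
    P_FLOOR,
    build_p_table,
    is_violation,
    nonexceedance_probability,
    summarize_compliance,
)
from aquacpi.types import BoundType, CensorFlag, ObjectiveSpec, ScenarioStandards

from conftest import CHEM, MICRO, make_series


@pytest.mark.parametrize(
    "value,objective,censored,expected",
    [
        # boundary equality is compliant
        (10, ObjectiveSpec(bound_type="upper", high=10), CensorFlag.none, False),
        (11, ObjectiveSpec(bound_type="upper", high=10), CensorFlag.none, True),
        (5, ObjectiveSpec(bound_type="lower", low=5), CensorFlag.none, False),
        (4.9, ObjectiveSpec(bound_type="lower", low=5), CensorFlag.none, True),
        # pH outside its window fails on either side
        (5, ObjectiveSpec(bound_type="range", low=6, high=8.4), CensorFlag.none, True),
        (9, ObjectiveSpec(bound_type="range", low=6, high=8.4), CensorFlag.none, True),
        (7, ObjectiveSpec(bound_type="range", low=6, high=8.4), CensorFlag.none, False),
        # coliform non-detect complies with an absence target; presence fails
        (1, ObjectiveSpec(bound_type="absent"), CensorFlag.below_detection, False),
        (3, ObjectiveSpec(bound_type="absent"), CensorFlag.none, True),
        (0, ObjectiveSpec(bound_type="absent"), CensorFlag.none, False),
    ],
)
def test_is_violation(value, objective, censored, expected):
    assert is_violation(value, objective, censored) is expected


def test_summarize_retains_failed_values(ph_range):
    summary = summarize_compliance(make_series([7, 7, 9, 5]), ph_range)
    assert summary.n_tests == 4
    assert summary.n_failed == 2
    assert summary.failed_values == [9, 5]


class TestNonExceedance:
    def test_clean_series_gets_rank_one(self, upper10):
        # m = 1, Pe = 100/5 = 20
        assert nonexceedance_probability(make_series([1, 2, 3, 4]), upper10) == 80.0

    def test_always_failing_hits_floor(self):
        objective = ObjectiveSpec(bound_type="upper", high=5)
        assert nonexceedance_probability(make_series([10, 20]), objective) == P_FLOOR

    def test_all_censored_absence_short_circuits(self, absent):
        series = make_series([1] * 52, parameter=MICRO, censored=range(52))
        assert nonexceedance_probability(series, absent) == P_CEILING

    def test_absence_with_quantified_presence_uses_rank(self, absent):
        series = make_series([1, 1, 2], parameter=MICRO, censored=[0, 1])
        # one violation: m = 2, Pe = 200/4 = 50
        assert nonexceedance_probability(series, absent) == 50.0

    def test_fully_compliant_year_matches_closed_form(self, upper10):
        series = make_series([1.0] * 399)
        assert nonexceedance_probability(series, upper10) == pytest.approx(99.75)


@given(
    values=st.lists(st.floats(-100, 100), min_size=1, max_size=60),
    bound_type=st.sampled_from(["upper", "lower", "range"]),
    a=st.floats(-50, 49),
    width=st.floats(0.5, 60),
)
@settings(max_examples=200, deadline=None)
def test_violation_count_matches_brute_force(values, bound_type, a, width):
    """n_failed equals an explicit loop over the direction logic."""
    if bound_type == "upper":
        objective = ObjectiveSpec(bound_type="upper", high=a)
        brute = sum(1 for v in values if v > a)
    elif bound_type == "lower":
        objective = ObjectiveSpec(bound_type="lower", low=a)
        brute = sum(1 for v in values if v < a)
    else:
        objective = ObjectiveSpec(bound_type="range", low=a, high=a + width)
        brute = sum(1 for v in values if v < a or v > a + width)
    summary = summarize_compliance(make_series(values), objective)
    assert summary.n_failed == brute


@given(
    values=st.lists(st.floats(0, 20), min_size=1, max_size=40),
    high=st.floats(1, 19),
)
@settings(max_examples=200, deadline=None)
def test_monotonicity_and_clamp(values, high):
    """Adding a violation never raises P; adding a compliant value never lowers it;
    every P lies in the clamp band."""
    objective = ObjectiveSpec(bound_type="upper", high=high)
    p = nonexceedance_probability(make_series(values), objective)
    assert P_FLOOR <= p <= P_CEILING
    p_worse = nonexceedance_probability(make_series(values + [high + 1]), objective)
    p_better = nonexceedance_probability(make_series(values + [high - 0.5]), objective)
    assert p_worse <= p + 1e-12
    assert p_better >= p - 1e-12


def test_p_plus_pe_is_100_before_clamping(upper10):
    table = build_p_table(
        [make_series([1, 2, 3, 4])],
        ScenarioStandards(scenario_id="S1", objectives={"X": upper10}),
    )
    entry = table.entries[("F1", "X")]
    assert entry.p + entry.pe == pytest.approx(100.0)
    assert entry.m == 1 and entry.n == 4


def test_build_p_table_requires_objectives(upper10):
    standards = ScenarioStandards(scenario_id="S3", objectives={"Y": upper10})
    with pytest.raises(KeyError, match="X"):
        build_p_table([make_series([1.0, 2.0])], standards)


def test_build_p_table_one_entry(upper10):
    standards = ScenarioStandards(scenario_id="S1", objectives={"X": upper10})
    table = build_p_table([make_series([1.0, 2.0])], standards)
    assert list(table.entries) == [("F1", "X")]
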