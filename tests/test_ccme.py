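"""Modified CCME index: factors, excursions, sub-indices, categorization."""

import math

import pytest

from aquacpi.ccme import (
    amplitude,
    categorize,
    cwqi_pc,
    modified_cwqi,
    scope_frequency,
    wqi_mb,
)
from aquacpi.compliance import ComplianceSummary, summarize_compliance
from aquacpi.types import ObjectiveSpec

from conftest import make_series


def summary(n_tests, failed_values, objective):
    return ComplianceSummary(
        parameter_code="X",
        n_tests=n_tests,
        n_failed=len(failed_values),
        failed_values=list(failed_values),
        objective=objective,
    )


UPPER5 = ObjectiveSpec(bound_type="upper", high=5)
CL2_RANGE = ObjectiveSpec(bound_type="range", low=0.2, high=0.5)


class TestScopeFrequency:
    def test_fraction_of_failing_variables(self):
        summaries = [summary(40, [6], UPPER5) for _ in range(3)] + [
            summary(40, [], UPPER5) for _ in range(8)
        ]
        f1, f2 = scope_frequency(summaries)
        assert f1 == pytest.approx(100 * 3 / 11)  # 27.27
        assert f2 == pytest.approx(100 * 3 / 440)

    def test_ten_failed_of_400_tests(self):
        summaries = [summary(200, [6] * 10, UPPER5), summary(200, [], UPPER5)]
        assert scope_frequency(summaries)[1] == pytest.approx(2.5)

    def test_no_failures(self):
        f1, f2 = scope_frequency([summary(10, [], UPPER5)])
        assert (f1, f2) == (0.0, 0.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            scope_frequency([])


class TestAmplitude:
    def test_upper_side_excursion_identity(self):
        excursions, _, _ = amplitude([summary(4, [10], UPPER5)])
        assert excursions == [pytest.approx(1.0)]

    def test_lower_side_excursion_for_chlorine(self):
        excursions, _, _ = amplitude([summary(4, [0.1], CL2_RANGE)])
        assert excursions == [pytest.approx(1.0)]  # 0.2/0.1 - 1

    def test_range_dispatches_per_violated_side(self):
        excursions, _, _ = amplitude([summary(4, [1.0, 0.1], CL2_RANGE)])
        assert excursions == [pytest.approx(1.0), pytest.approx(1.0)]

    def test_nse_and_f3_hand_value(self):
        # excursions sum to 2 over 4 tests: nse = 0.5, F3 = 0.5/0.015
        _, nse, f3 = amplitude([summary(4, [10, 10], UPPER5)])
        assert nse == pytest.approx(0.5)
        assert f3 == pytest.approx(33.33, abs=0.01)

    def test_zero_failed_value_is_capped(self):
        excursions, _, _ = amplitude([summary(4, [0.0], CL2_RANGE)])
        assert excursions == [100.0]

    def test_excursions_vanish_exactly_at_the_limit(self):
        excursions, _, _ = amplitude([summary(2, [5.0], UPPER5)])
        assert excursions == [pytest.approx(0.0)]

    def test_absent_objective_is_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            amplitude([summary(2, [3.0], ObjectiveSpec(bound_type="absent"))])


class TestCwqiPc:
    def test_no_failures_scores_100(self):
        assert cwqi_pc(0, 0, 0) == 100.0

    def test_factor_vector_maximum_is_floored_to_zero(self):
        # sqrt(3)·100 / 1.732 slightly exceeds 100; the residue floors at 0
        assert cwqi_pc(100, 100, 100) == 0.0

    def test_worked_example(self):
        assert cwqi_pc(27.27, 2.5, 33.33) == pytest.approx(75.09, abs=0.01)

    def test_nonincreasing_in_each_factor(self):
        base = cwqi_pc(20, 10, 30)
        assert cwqi_pc(25, 10, 30) < base
        assert cwqi_pc(20, 15, 30) < base
        assert cwqi_pc(20, 10, 35) < base


def test_f3_is_increasing_with_asymptote_100():
    f3 = lambda nse: nse / (0.01 * nse + 0.01)
    assert f3(1.0) == pytest.approx(50.0)
    values = [f3(x) for x in (0.1, 1, 10, 100, 10_000)]
    assert values == sorted(values)
    assert values[-1] < 100.0
    assert f3(1e9) == pytest.approx(100.0, abs=1e-5)


class TestWqiMb:
    def test_pass_rates(self):
        clean = summary(52, [], UPPER5)
        assert wqi_mb([clean]) == 100.0
        failed = summary(52, [9] * 13, UPPER5)
        assert wqi_mb([failed]) == 75.0
        all_failed = summary(4, [9] * 4, UPPER5)
        assert wqi_mb([all_failed]) == 0.0

    def test_no_tests_is_an_error(self):
        with pytest.raises(ValueError):
            wqi_mb([])


class TestModifiedCwqi:
    def test_scenario3_blend(self):
        result = modified_cwqi(80.0, 100.0, "S3")
        assert result.modified_cwqi == pytest.approx(86.0)
        assert (result.w1, result.w2) == (0.7, 0.3)

    def test_perfect_sub_indices(self):
        assert modified_cwqi(100.0, 100.0, "S1").modified_cwqi == 100.0

    def test_scenario2_weighting(self):
        result = modified_cwqi(50.0, 100.0, "S2")
        assert (result.w1, result.w2) == (0.8, 0.2)
        assert result.modified_cwqi == pytest.approx(60.0)

    def test_unknown_scenario_without_weights(self):
        with pytest.raises(KeyError):
            modified_cwqi(80.0, 100.0, "S9")
        result = modified_cwqi(80.0, 100.0, "S9", weights={"S9": (0.5, 0.5)})
        assert result.modified_cwqi == pytest.approx(90.0)


@pytest.mark.parametrize(
    "index,expected",
    [
        (100.0, "Excellent"),
        (96.0, "Excellent"),
        (95.0, "Excellent"),
        (94.9, "Very Good"),
        (89.0, "Very Good"),
        (88.5, "Good"),
        (80.0, "Good"),
        (79.9, "Fair"),
        (65.0, "Fair"),
        (45.0, "Marginal"),
        (44.0, "Poor"),
        (0.0, "Poor"),
    ],
)
def test_categorize_bands(index, expected):
    assert categorize(index) == expected


def test_categorize_rejects_out_of_range():
    with pytest.raises(ValueError):
        categorize(101.0)
    with pytest.raises(ValueError):
        categorize(-0.1)


def test_zero_failures_give_100_for_every_weighting():
    series = make_series([1, 2, 3])
    pc = summarize_compliance(series, UPPER5)
    f1, f2 = scope_frequency([pc])
    _, _, f3 = amplitude([pc])
    for sid in ("S1", "S2", "S3", "S4"):
        result = modified_cwqi(cwqi_pc(f1, f2, f3), 100.0, sid)
        assert result.modified_cwqi == 100.0
        assert result.category == "Excellent"
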