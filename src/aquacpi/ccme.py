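"""Modified CCME water quality index for treated effluent.

The physico-chemical sub-index CWQI_PC aggregates three factors:

    F1 (scope)     = 100 · failed variables / total variables
    F2 (frequency) = 100 · failed tests / total tests
    F3 (amplitude) = nse / (0.01·nse + 0.01)

where an excursion measures how far a failed test lies beyond its
objective (value/objective − 1 for an exceeded maximum,
objective/value − 1 for an undershot minimum) and nse is the excursion
sum normalized by the total number of tests.  The three factors combine
as

    CWQI_PC = 100 − sqrt(F1² + F2² + F3²) / 1.732,

the 1.732 (= sqrt 3) divisor rescaling the maximal factor vector
(100, 100, 100) back to the 0–100 range; small negative rounding
residues are floored at 0.

Microbiological parameters, whose target may be complete absence, cannot
enter this formulation and get their own pass-rate sub-index
WQI_MB = 100·(1 − failed/total).  The modified index blends the two with
scenario-specific weights:  W1·CWQI_PC + W2·WQI_MB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .compliance import ComplianceSummary
from .types import BoundType

__all__ = [
    "SUBINDEX_WEIGHTS",
    "CATEGORY_BANDS",
    "CcmeFactors",
    "CcmeResult",
    "scope_frequency",
    "amplitude",
    "cwqi_pc",
    "wqi_mb",
    "modified_cwqi",
    "categorize",
]

#: (W1 physico-chemical, W2 microbiological) per reuse scenario
SUBINDEX_WEIGHTS: dict[str, tuple[float, float]] = {
    "S1": (0.9, 0.1),
    "S2": (0.8, 0.2),
    "S3": (0.7, 0.3),
    "S4": (0.7, 0.3),
}

#: half-open bands [low, high) except the closed top band, lowest first
CATEGORY_BANDS: list[tuple[float, float, str]] = [
    (0.0, 45.0, "Poor"),
    (45.0, 65.0, "Marginal"),
    (65.0, 80.0, "Fair"),
    (80.0, 89.0, "Good"),
    (89.0, 95.0, "Very Good"),
    (95.0, 100.0, "Excellent"),
]

#: cap on a single lower-side excursion, guarding objective/value blow-up
#: when a failed value sits at or near zero
DEFAULT_EXCURSION_CAP = 100.0


@dataclass(frozen=True)
class CcmeFactors:
    f1: float
    f2: float
    f3: float
    nse: float
    excursions: tuple[float, ...]


@dataclass(frozen=True)
class CcmeResult:
    scenario_id: str
    cwqi_pc: float
    wqi_mb: float
    w1: float
    w2: float
    modified_cwqi: float
    category: str
    factors: CcmeFactors | None = None


def scope_frequency(summaries: Sequence[ComplianceSummary]) -> tuple[float, float]:
    """F1 (percent of variables failing at least once) and F2 (percent of failed tests)."""
    if not summaries:
        raise ValueError("no compliance summaries given")
    n_vars = len(summaries)
    n_failed_vars = sum(1 for s in summaries if s.n_failed > 0)
    total_tests = sum(s.n_tests for s in summaries)
    failed_tests = sum(s.n_failed for s in summaries)
    f1 = 100.0 * n_failed_vars / n_vars
    f2 = 100.0 * failed_tests / total_tests
    return f1, f2


def _excursion(value: float, summary: ComplianceSummary, cap: float) -> float:
    obj = summary.objective
    bt = obj.bound_type
    if bt is BoundType.absent:
        raise ValueError(
            f"parameter {summary.parameter_code!r}: an 'absent' objective has no "
            "finite side; handle microbiology through wqi_mb"
        )
    if bt is BoundType.upper or (bt is BoundType.range and value > obj.high):
        return value / obj.high - 1.0
    # lower limit undershot (dedicated lower bound, or the low side of a range)
    if value <= 0:
        return cap
    return min(obj.low / value - 1.0, cap)


def amplitude(
    summaries: Sequence[ComplianceSummary],
    excursion_cap: float = DEFAULT_EXCURSION_CAP,
) -> tuple[list[float], float, float]:
    """Excursions, nse and the amplitude factor F3.

    nse divides the excursion sum by the *total* number of tests, failed
    or not, so rare mild failures stay small.
    """
    if not summaries:
        raise ValueError("no compliance summaries given")
    excursions = [
        _excursion(v, s, excursion_cap) for s in summaries for v in s.failed_values
    ]
    total_tests = sum(s.n_tests for s in summaries)
    nse = sum(excursions) / total_tests
    f3 = nse / (0.01 * nse + 0.01)
    return excursions, nse, f3


def cwqi_pc(f1: float, f2: float, f3: float) -> float:
    """Aggregate the three factors; floored at 0."""
    index = 100.0 - math.sqrt(f1 * f1 + f2 * f2 + f3 * f3) / 1.732
    return max(index, 0.0)


def wqi_mb(micro_summaries: Sequence[ComplianceSummary]) -> float:
    """Microbiological sub-index: percent of coliform tests passing."""
    total = sum(s.n_tests for s in micro_summaries)
    if total == 0:
        raise ValueError("no microbiological tests")
    failed = sum(s.n_failed for s in micro_summaries)
    return 100.0 * (1.0 - failed / total)


def modified_cwqi(
    cwqi_pc_value: float,
    wqi_mb_value: float,
    scenario_id: str,
    weights: dict[str, tuple[float, float]] | None = None,
    factors: CcmeFactors | None = None,
) -> CcmeResult:
    """Blend the physico-chemical and microbiological sub-indices."""
    table = weights if weights is not None else SUBINDEX_WEIGHTS
    if scenario_id not in table:
        raise KeyError(f"no sub-index weights for scenario {scenario_id!r}")
    w1, w2 = table[scenario_id]
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError(f"sub-index weights must sum to 1, got {w1}+{w2}")
    value = w1 * cwqi_pc_value + w2 * wqi_mb_value
    return CcmeResult(
        scenario_id=scenario_id,
        cwqi_pc=cwqi_pc_value,
        wqi_mb=wqi_mb_value,
        w1=w1,
        w2=w2,
        modified_cwqi=value,
        category=categorize(value),
        factors=factors,
    )


def categorize(
    index: float, bands: Sequence[tuple[float, float, str]] | None = None
) -> str:
    """Map an index value in [0, 100] to its performance category."""
    bands = bands if bands is not None else CATEGORY_BANDS
    low0 = bands[0][0]
    _, top, top_label = bands[-1]
    if not low0 <= index <= top:
        raise ValueError(f"index {index} outside [{low0}, {top}]")
    if index == top:
        return top_label
    for low, high, label in bands:
        if low <= index < high:
            return label
    raise AssertionError("bands do not cover the index range")  # pragma: no cover
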