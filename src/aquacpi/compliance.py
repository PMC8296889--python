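"""Compliance evaluation and rank-based non-exceedance probabilities.

Each measurement is checked against its scenario objective in a
direction-aware way (upper limit, lower limit, closed range, or complete
absence for microbiology).  The probability that a parameter meets its
objective is then estimated with the Weibull plotting position: the
objective is inserted into the severity-sorted sample at rank
m = 1 + (number of violations), the exceedance probability is
Pe = 100·m/(n+1) percent, and the non-exceedance probability is
P = 100 − Pe, clamped to the reporting band [0.01, 99.99].

A microbiological "absent" target met by an entirely non-detect series
short-circuits to P = 99.99 regardless of n: the laboratory never
quantified any presence, so the plotting position has nothing to rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .types import (
    BoundType,
    CensorFlag,
    MonitoringSeries,
    ObjectiveSpec,
    ScenarioStandards,
)

__all__ = [
    "P_FLOOR",
    "P_CEILING",
    "ComplianceSummary",
    "PEntry",
    "NonExceedanceTable",
    "is_violation",
    "summarize_compliance",
    "nonexceedance_probability",
    "build_p_table",
]

P_FLOOR = 0.01
P_CEILING = 99.99


def is_violation(
    value: float,
    objective: ObjectiveSpec,
    censored: CensorFlag = CensorFlag.none,
) -> bool:
    """True if a single test result fails its objective.

    Boundary equality is compliant: limits are read as inclusive.  For an
    "absent" target, a censored non-detect (or an exact quantified zero)
    complies; any quantified presence fails.
    """
    bt = objective.bound_type
    if bt is BoundType.absent:
        if censored is CensorFlag.below_detection:
            return False
        return value > 0
    if bt is BoundType.upper:
        return value > objective.high
    if bt is BoundType.lower:
        return value < objective.low
    # range
    return value < objective.low or value > objective.high


@dataclass
class ComplianceSummary:
    """Violation counts and the failed test values for one series."""

    parameter_code: str
    n_tests: int
    n_failed: int
    failed_values: list[float]
    objective: ObjectiveSpec

    def __post_init__(self) -> None:
        if not 0 <= self.n_failed <= self.n_tests:
            raise ValueError("need 0 <= n_failed <= n_tests")
        if len(self.failed_values) != self.n_failed:
            raise ValueError("failed_values length must equal n_failed")


def summarize_compliance(
    series: MonitoringSeries, objective: ObjectiveSpec
) -> ComplianceSummary:
    """Count violations in a series and retain the failing values."""
    failed = [
        m.value
        for m in series.measurements
        if is_violation(m.value, objective, m.censored)
    ]
    return ComplianceSummary(
        parameter_code=series.parameter.code,
        n_tests=series.n,
        n_failed=len(failed),
        failed_values=failed,
        objective=objective,
    )


def nonexceedance_probability(
    series: MonitoringSeries, objective: ObjectiveSpec
) -> float:
    """Percent probability P that the parameter meets its objective."""
    p, _ = _nonexceedance(series, objective)
    return p


def _nonexceedance(
    series: MonitoringSeries, objective: ObjectiveSpec
) -> tuple[float, "PEntry"]:
    n = series.n
    if objective.bound_type is BoundType.absent and all(
        m.censored is CensorFlag.below_detection for m in series.measurements
    ):
        # absence confirmed by every test: report the ceiling directly
        p = P_CEILING
        return p, PEntry(p=p, pe=100.0 - p, m=None, n=n)
    summary = summarize_compliance(series, objective)
    m = 1 + summary.n_failed
    pe = 100.0 * m / (n + 1)
    p = min(max(100.0 - pe, P_FLOOR), P_CEILING)
    return p, PEntry(p=p, pe=pe, m=m, n=n)


@dataclass(frozen=True)
class PEntry:
    """One cell of a non-exceedance table.

    ``m`` and ``n`` are None for entries loaded from a printed table, where
    only P is known.  ``pe`` is the pre-clamp exceedance percentage.
    """

    p: float
    pe: float
    m: Optional[int] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 100.0:
            raise ValueError(f"P must lie in (0, 100), got {self.p}")


@dataclass
class NonExceedanceTable:
    """Non-exceedance percentages per (facility, parameter) for one scenario."""

    scenario_id: str
    entries: dict[tuple[str, str], PEntry] = field(default_factory=dict)

    def facilities(self) -> list[str]:
        return sorted({f for f, _ in self.entries})

    def parameters(self) -> list[str]:
        return sorted({p for _, p in self.entries})

    def p(self, facility_id: str, parameter_code: str) -> float:
        return self.entries[(facility_id, parameter_code)].p

    def to_frame(self):
        """Facility × parameter grid of P values (pandas DataFrame)."""
        import pandas as pd

        frame = pd.DataFrame(index=self.facilities(), columns=self.parameters(), dtype=float)
        for (facility, code), entry in self.entries.items():
            frame.loc[facility, code] = entry.p
        return frame


def build_p_table(
    dataset: Iterable[MonitoringSeries], standards: ScenarioStandards
) -> NonExceedanceTable:
    """Assemble the non-exceedance table of a scenario from raw series."""
    table = NonExceedanceTable(scenario_id=standards.scenario_id)
    for series in dataset:
        code = series.parameter.code
        if code not in standards.objectives:
            raise KeyError(
                f"no objective for parameter {code!r} in scenario "
                f"{standards.scenario_id}"
            )
        _, entry = _nonexceedance(series, standards.objectives[code])
        table.entries[(series.facility_id, code)] = entry
    return table
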