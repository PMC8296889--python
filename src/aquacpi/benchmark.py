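"""Per-facility, per-scenario assessment, benchmarking and recommendations.

``assess`` orchestrates the full pipeline for each reuse scenario: build
the non-exceedance table and the grey index, build compliance summaries
and the modified CCME index, derive the cross-facility benchmark (the
unweighted mean index value) and each facility's performance gap, and
attach the scenario's improvement actions.

The benchmark follows the average-line reading of the CPI concept; a
"presumed" benchmark of 90 — the bottom of the very-good/excellent zone —
is carried as a reporting overlay only and never enters gap arithmetic.
Facilities below the benchmark are flagged for major improvement;
facilities above it either maintain performance (Excellent) or pursue
minor improvements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Mapping, Optional, Sequence

from .ccme import (
    CcmeFactors,
    CcmeResult,
    amplitude,
    categorize,
    cwqi_pc,
    modified_cwqi,
    scope_frequency,
    wqi_mb,
)
from .compliance import build_p_table, summarize_compliance
from .grey import GreyConfig, gwqi
from .types import MonitoringSeries, ParameterGroup, ScenarioStandards

__all__ = [
    "PRESUMED_BENCHMARK",
    "IndexResult",
    "ActionRule",
    "DEFAULT_ACTION_RULES",
    "ccme_for_facility",
    "assess",
    "recommend",
]

PRESUMED_BENCHMARK = 90.0


@dataclass
class IndexResult:
    """Both indices, benchmark context and actions for one facility × scenario."""

    facility_id: str
    scenario_id: str
    gwqi: Optional[float] = None
    ccme: Optional[CcmeResult] = None
    gwqi_benchmark: Optional[float] = None
    gwqi_gap: Optional[float] = None
    ccme_benchmark: Optional[float] = None
    ccme_gap: Optional[float] = None
    presumed_benchmark: float = PRESUMED_BENCHMARK
    actions: list[str] = field(default_factory=list)

    @property
    def primary_index(self) -> Optional[float]:
        """The stricter modified CWQI when available, else the GWQI."""
        if self.ccme is not None:
            return self.ccme.modified_cwqi
        return self.gwqi

    @property
    def benchmark(self) -> Optional[float]:
        return self.ccme_benchmark if self.ccme is not None else self.gwqi_benchmark

    @property
    def gap(self) -> Optional[float]:
        return self.ccme_gap if self.ccme is not None else self.gwqi_gap

    @property
    def category(self) -> Optional[str]:
        if self.ccme is not None:
            return self.ccme.category
        if self.gwqi is not None:
            return categorize(self.gwqi)
        return None


@dataclass
class ActionRule:
    """Scenario-level improvement actions plus per-category advice."""

    scenario_id: str
    actions: list[str]
    category_advice: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.actions:
            raise ValueError(f"scenario {self.scenario_id}: at least one action required")


_MONITORING_ACTION = "Careful monitoring and process control."
_CHLORINE_ACTION = "Attention is required for controlling residual chlorine."
_MBR_ACTION = (
    "Improve nutrients removal by integrating the existing system with "
    "membrane bioreactor (MBR) process."
)
_RO_ACTION = (
    "Upgrade tertiary treatment by adding reverse osmosis process for the "
    "removal of total dissolved solids (TDS) and dissolved organics."
)

_CATEGORY_ADVICE = {
    "Excellent": "Maintain performance.",
    "Very Good": (
        "Maintain performance with minor improvements, e.g. monitoring "
        "frequency and proactive maintenance practices."
    ),
}

DEFAULT_ACTION_RULES: list[ActionRule] = [
    ActionRule("S1", [_MONITORING_ACTION, _CHLORINE_ACTION], dict(_CATEGORY_ADVICE)),
    ActionRule("S2", [_MONITORING_ACTION, _CHLORINE_ACTION], dict(_CATEGORY_ADVICE)),
    ActionRule("S3", [_MONITORING_ACTION, _MBR_ACTION], dict(_CATEGORY_ADVICE)),
    ActionRule("S4", [_MONITORING_ACTION, _MBR_ACTION, _RO_ACTION], dict(_CATEGORY_ADVICE)),
]


def ccme_for_facility(
    dataset: Sequence[MonitoringSeries],
    standards: ScenarioStandards,
    subindex_weights: dict[str, tuple[float, float]] | None = None,
    excursion_cap: float = 100.0,
) -> CcmeResult:
    """Modified CWQI for one facility's series under one scenario.

    Physical and chemical parameters drive F1–F3; biological parameters
    are scored separately through the microbiological pass rate.
    """
    pc = [s for s in dataset if s.parameter.group is not ParameterGroup.biological]
    mb = [s for s in dataset if s.parameter.group is ParameterGroup.biological]
    if not pc:
        raise ValueError("no physico-chemical series for CWQI_PC")
    pc_summaries = [
        summarize_compliance(s, standards.objective_for(s.parameter.code)) for s in pc
    ]
    mb_summaries = [
        summarize_compliance(s, standards.objective_for(s.parameter.code)) for s in mb
    ]
    f1, f2 = scope_frequency(pc_summaries)
    excursions, nse, f3 = amplitude(pc_summaries, excursion_cap)
    pc_index = cwqi_pc(f1, f2, f3)
    mb_index = wqi_mb(mb_summaries)
    return modified_cwqi(
        pc_index,
        mb_index,
        standards.scenario_id,
        weights=subindex_weights,
        factors=CcmeFactors(f1, f2, f3, nse, tuple(excursions)),
    )


def _group_by_facility(
    dataset: Iterable[MonitoringSeries],
) -> dict[str, list[MonitoringSeries]]:
    grouped: dict[str, list[MonitoringSeries]] = {}
    for series in dataset:
        grouped.setdefault(series.facility_id, []).append(series)
    return grouped


def assess(
    dataset: Sequence[MonitoringSeries],
    standards: Sequence[ScenarioStandards],
    weights: Mapping[str, Mapping[str, float]] | None = None,
    *,
    indices: Sequence[str] = ("gwqi", "cwqi"),
    grey_config: GreyConfig | None = None,
    subindex_weights: dict[str, tuple[float, float]] | None = None,
    action_rules: Sequence[ActionRule] | None = None,
    presumed_benchmark: float = PRESUMED_BENCHMARK,
) -> list[IndexResult]:
    """Run the full assessment for every facility under every scenario.

    ``weights`` maps scenario id to a parameter→weight mapping and is
    required when the grey index is requested.  Results are deterministic
    given the inputs and ordered by (scenario, facility).
    """
    indices = tuple(indices)
    unknown = set(indices) - {"gwqi", "cwqi"}
    if unknown:
        raise ValueError(f"unknown indices {sorted(unknown)}")
    if "gwqi" in indices and weights is None:
        raise ValueError("the grey index requires per-scenario weights")
    rules = list(action_rules) if action_rules is not None else DEFAULT_ACTION_RULES
    by_facility = _group_by_facility(dataset)

    results: list[IndexResult] = []
    for scenario in standards:
        sid = scenario.scenario_id
        scenario_results: list[IndexResult] = []
        gwqi_values: dict[str, float] = {}
        if "gwqi" in indices:
            if sid not in weights:
                raise KeyError(f"no weights for scenario {sid}")
            try:
                p_table = build_p_table(dataset, scenario)
                gwqi_values = gwqi(p_table, weights[sid], grey_config).gwqi
            except (KeyError, ValueError) as err:
                raise type(err)(f"scenario {sid}: {err}") from err
        for facility in sorted(by_facility):
            result = IndexResult(
                facility_id=facility,
                scenario_id=sid,
                presumed_benchmark=presumed_benchmark,
            )
            if "gwqi" in indices:
                result.gwqi = gwqi_values[facility]
            if "cwqi" in indices:
                try:
                    result.ccme = ccme_for_facility(
                        by_facility[facility], scenario, subindex_weights
                    )
                except (KeyError, ValueError) as err:
                    raise type(err)(
                        f"facility {facility}, scenario {sid}: {err}"
                    ) from err
            scenario_results.append(result)

        if "gwqi" in indices:
            bench = mean(r.gwqi for r in scenario_results)
            for r in scenario_results:
                r.gwqi_benchmark = bench
                r.gwqi_gap = r.gwqi - bench
        if "cwqi" in indices:
            bench = mean(r.ccme.modified_cwqi for r in scenario_results)
            for r in scenario_results:
                r.ccme_benchmark = bench
                r.ccme_gap = r.ccme.modified_cwqi - bench
        for r in scenario_results:
            r.actions = recommend(r, rules)
        results.extend(scenario_results)
    return results


def recommend(result: IndexResult, rules: Sequence[ActionRule]) -> list[str]:
    """Improvement actions for one result: scenario actions plus gap advice."""
    rule = next((r for r in rules if r.scenario_id == result.scenario_id), None)
    if rule is None:
        raise KeyError(f"no action rule for scenario {result.scenario_id}")
    actions = list(rule.actions)
    gap = result.gap
    category = result.category
    if gap is not None and gap < 0:
        actions.append(
            "Performing below the benchmark: major improvement needed to match "
            "better-performing facilities and more stringent future standards."
        )
    elif category is not None:
        advice = rule.category_advice.get(category)
        if advice is not None:
            actions.append(advice)
        else:
            actions.append("Minor improvement: lift performance toward the benchmark.")
    return actions
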