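"""Domain types for effluent-quality assessment.

The objects here model the vocabulary of a reuse-oriented effluent
monitoring programme: water-quality parameters (physical, chemical,
biological), per-scenario objective limits, and dated measurement series
with left-censoring ("<1" style non-detects, common for coliform counts).
Validation is strict at construction time so downstream index arithmetic
can assume well-formed inputs.
"""

from __future__ import annotations

import datetime as dt
from enum import Enum
from typing import Optional

from pydantic import BaseModel, field_validator, model_validator

__all__ = [
    "ParameterGroup",
    "BoundType",
    "CensorFlag",
    "ParameterDef",
    "ObjectiveSpec",
    "ScenarioStandards",
    "Measurement",
    "MonitoringSeries",
]

#: unit substrings that mark a count-per-volume (microbiological) unit
_COUNT_UNIT_MARKERS = ("MPN", "CFU", "/100")


class ParameterGroup(str, Enum):
    physical = "physical"
    chemical = "chemical"
    biological = "biological"


class BoundType(str, Enum):
    """Direction of an objective limit.

    ``upper``  — compliance requires value <= high (e.g. BOD5 <= 40 mg/L)
    ``lower``  — compliance requires value >= low
    ``range``  — compliance requires low <= value <= high (pH, residual Cl2)
    ``absent`` — the target is complete absence (fecal coliforms under the
                 strictest reuse scenarios); only non-detects comply.
    """

    upper = "upper"
    lower = "lower"
    range = "range"
    absent = "absent"


class CensorFlag(str, Enum):
    none = "none"
    below_detection = "below_detection"


class ParameterDef(BaseModel):
    """A monitored water-quality parameter and its reporting unit."""

    code: str
    name: str = ""
    unit: str = ""
    group: ParameterGroup

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _biological_iff_count_unit(self) -> "ParameterDef":
        is_count = any(marker in self.unit for marker in _COUNT_UNIT_MARKERS)
        if (self.group is ParameterGroup.biological) != is_count:
            raise ValueError(
                f"parameter {self.code!r}: group={self.group.value} inconsistent "
                f"with unit {self.unit!r} (biological parameters must carry a "
                "count-per-volume unit and vice versa)"
            )
        return self


class ObjectiveSpec(BaseModel):
    """One parameter's objective limit under one reuse scenario."""

    bound_type: BoundType
    low: Optional[float] = None
    high: Optional[float] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_bounds(self) -> "ObjectiveSpec":
        bt = self.bound_type
        if bt is BoundType.upper:
            if self.high is None or self.low is not None:
                raise ValueError("upper bound requires high set and low null")
        elif bt is BoundType.lower:
            if self.low is None or self.high is not None:
                raise ValueError("lower bound requires low set and high null")
        elif bt is BoundType.range:
            if self.low is None or self.high is None:
                raise ValueError("range bound requires both low and high")
            if not self.low < self.high:
                raise ValueError(
                    f"range bound requires low < high (got {self.low} >= {self.high})"
                )
        elif bt is BoundType.absent:
            if self.low is not None or self.high is not None:
                raise ValueError("absent target carries no numeric limits")
        return self


class ScenarioStandards(BaseModel):
    """The full objective table for one reuse scenario (S1..S4 by default)."""

    scenario_id: str
    description: str = ""
    objectives: dict[str, ObjectiveSpec]

    def objective_for(self, code: str) -> ObjectiveSpec:
        try:
            return self.objectives[code]
        except KeyError:
            raise KeyError(
                f"scenario {self.scenario_id}: no objective for parameter {code!r}"
            ) from None


class Measurement(BaseModel):
    """A single dated test result, possibly left-censored.

    For a censored result the stored ``value`` equals the detection limit,
    mirroring how "<1" is reported in laboratory summaries.
    """

    date: dt.date
    value: float
    censored: CensorFlag = CensorFlag.none
    detection_limit: Optional[float] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _censor_consistency(self) -> "Measurement":
        if self.censored is CensorFlag.below_detection:
            if self.detection_limit is None:
                raise ValueError("censored measurement requires a detection_limit")
            if self.value != self.detection_limit:
                raise ValueError(
                    "censored measurement must store value = detection_limit"
                )
        return self


class MonitoringSeries(BaseModel):
    """All measurements of one parameter at one facility.

    Dates are metadata only: every index statistic downstream is order-free,
    so the series is required merely to be non-empty and date-sorted.
    """

    facility_id: str
    parameter: ParameterDef
    measurements: list[Measurement]

    @field_validator("measurements")
    @classmethod
    def _non_empty(cls, v: list[Measurement]) -> list[Measurement]:
        if not v:
            raise ValueError("measurements must be non-empty")
        return v

    @model_validator(mode="after")
    def _dates_sorted(self) -> "MonitoringSeries":
        dates = [m.date for m in self.measurements]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"series {self.facility_id}/{self.parameter.code}: "
                "dates must be non-decreasing"
            )
        return self

    @property
    def n(self) -> int:
        """Number of times the parameter was monitored."""
        return len(self.measurements)

    @property
    def values(self) -> list[float]:
        return [m.value for m in self.measurements]
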