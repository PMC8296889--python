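"""Shannon-entropy importance weights for water-quality parameters.

Experts score each parameter against n evaluation criteria (by default
C1 impact on the geoenvironment, C2 on plant growth, C3 on livestock
safety, C4 on possible human contact) on a 1–10 Likert scale.  A
parameter whose scores are spread evenly across criteria carries no
discriminating information (entropy E_j = 1, diversity d_j = 0); a
parameter scored very unevenly is highly discriminating and earns a
large entropy weight w_j = d_j / Σ d_j.  The entropy weight is then
blended with an a-priori subjective rating ŵ_j from the odd Likert
scale {1,3,5,7,9}:

    W_j = ŵ_j · w_j / Σ_k ŵ_k · w_k,      Σ_j W_j = 1.

If every parameter is scored uniformly (all d_j = 0) the blend is
undefined; the weights then fall back to the normalized a-priori
ratings alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CRITERIA",
    "LIKERT_PRIORI_SCALE",
    "ExpertScoreMatrix",
    "PrioriVector",
    "WeightVector",
    "entropy_vector",
    "final_weights",
    "read_expert_scores_csv",
    "read_priori_csv",
]

DEFAULT_CRITERIA = ("C1", "C2", "C3", "C4")
LIKERT_PRIORI_SCALE = (1, 3, 5, 7, 9)


@dataclass
class ExpertScoreMatrix:
    """A k-parameter × n-criterion grid of Likert scores (>= 1).

    Scores may be non-integer when several experts' matrices have been
    averaged element-wise.
    """

    parameters: list[str]
    criteria: list[str] = field(default_factory=lambda: list(DEFAULT_CRITERIA))
    scores: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        k, n = len(self.parameters), len(self.criteria)
        if self.scores.shape != (k, n):
            raise ValueError(
                f"scores shape {self.scores.shape} != ({k} parameters, {n} criteria)"
            )
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 1):
            raise ValueError("all scores must be finite and >= 1")


@dataclass
class PrioriVector:
    """A-priori subjective ratings ŵ_j on the {1,3,5,7,9} scale."""

    ratings: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.ratings.items() if v not in LIKERT_PRIORI_SCALE}
        if bad:
            raise ValueError(f"ratings outside the {LIKERT_PRIORI_SCALE} scale: {bad}")


@dataclass
class WeightVector:
    """Entropy quantities and final weights per parameter for one scenario."""

    scenario_id: str
    parameters: list[str]
    alpha: float
    entropy: np.ndarray       # E_j in [0, 1]
    diversity: np.ndarray     # d_j = 1 - E_j
    entropy_weights: np.ndarray  # w_j = d_j / sum d_j (or 0s under fallback)
    priori: np.ndarray        # ŵ_j
    weights: np.ndarray       # final W_j, sums to 1

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("final weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("final weights must be nonnegative")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.parameters, map(float, self.weights)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "E_j": self.entropy,
                "d_j": self.diversity,
                "w_j": self.entropy_weights,
                "priori": self.priori,
                "W_j": self.weights,
            },
            index=self.parameters,
        )


def _share_matrix(matrix: ExpertScoreMatrix, normalization: str) -> np.ndarray:
    """Per-parameter probability shares across criteria.

    ``within_parameter`` (default): each row is divided by its own sum, so a
    parameter's entropy measures how evenly it was scored across criteria.
    ``within_criterion``: scores are first divided by their criterion-column
    sum (the classical decision-matrix orientation) and the resulting rows
    renormalized to probability vectors.
    """
    scores = matrix.scores
    if normalization == "within_criterion":
        scores = scores / scores.sum(axis=0, keepdims=True)
    elif normalization != "within_parameter":
        raise ValueError(f"unknown normalization {normalization!r}")
    return scores / scores.sum(axis=1, keepdims=True)


def entropy_vector(
    matrix: ExpertScoreMatrix, normalization: str = "within_parameter"
) -> tuple[np.ndarray, np.ndarray]:
    """Entropy E_j and diversity d_j = 1 - E_j for every parameter.

    E_j = -α Σ_i P_ij ln P_ij with α = 1/ln(n criteria); a zero share
    contributes 0 via the x·ln x → 0 limit.
    """
    n = len(matrix.criteria)
    if n < 2:
        raise ValueError("entropy requires at least 2 criteria (alpha = 1/ln n)")
    shares = _share_matrix(matrix, normalization)
    alpha = 1.0 / np.log(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(shares > 0, shares * np.log(shares), 0.0)
    e = -alpha * plogp.sum(axis=1)
    e = np.clip(e, 0.0, 1.0)  # guard rounding at the uniform extreme
    return e, 1.0 - e


def final_weights(
    matrix: ExpertScoreMatrix,
    priori: PrioriVector,
    scenario_id: str = "",
    normalization: str = "within_parameter",
) -> WeightVector:
    """Blend entropy weights with a-priori ratings into final weights W_j."""
    missing = [p for p in matrix.parameters if p not in priori.ratings]
    if missing:
        raise ValueError(f"priori ratings missing for parameters: {missing}")
    e, d = entropy_vector(matrix, normalization)
    priori_arr = np.array([priori.ratings[p] for p in matrix.parameters], float)
    d_sum = float(d.sum())
    if d_sum <= 1e-12:
        # fully uniform scoring: no entropy information, use priori alone
        w = np.zeros_like(d)
        final = priori_arr / priori_arr.sum()
    else:
        w = d / d_sum
        blended = priori_arr * w
        final = blended / blended.sum()
    return WeightVector(
        scenario_id=scenario_id,
        parameters=list(matrix.parameters),
        alpha=1.0 / np.log(len(matrix.criteria)),
        entropy=e,
        diversity=d,
        entropy_weights=w,
        priori=priori_arr,
        weights=final,
    )


def read_expert_scores_csv(path: str | Path) -> ExpertScoreMatrix:
    """Read ``parameter,criterion,score[,expert_id]`` rows into a score matrix.

    Multiple experts' scores for the same cell are combined by arithmetic
    mean before the entropy computation.
    """
    frame = pd.read_csv(path)
    required = {"parameter", "criterion", "score"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    grid = (
        frame.groupby(["parameter", "criterion"], sort=False)["score"]
        .mean()
        .unstack("criterion")
    )
    if grid.isna().any().any():
        raise ValueError(f"{path}: incomplete score grid")
    return ExpertScoreMatrix(
        parameters=list(grid.index),
        criteria=list(grid.columns),
        scores=grid.to_numpy(),
    )


def read_priori_csv(path: str | Path) -> PrioriVector:
    """Read ``parameter,rating`` rows into a priori vector."""
    frame = pd.read_csv(path)
    if not {"parameter", "rating"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns parameter,rating")
    return PrioriVector(
        ratings=dict(zip(frame["parameter"], frame["rating"].astype(float)))
    )
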