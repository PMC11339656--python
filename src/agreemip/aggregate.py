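"""Weighted aggregation of the 12 criterion scores into the overall score.

overall = sum(w_i * s_i) / sum(w_i)

Weights express the relative importance of the criteria on a four-point
integer scale (1-4).  The default vector reflects expert judgment: the
solvent-heavy criteria (5, porogen; 10, elution solvent) weigh most, the
once-per-batch inhibitor removal (1), the small-mass template (3) and
particle size (9) weigh least.  Users may override the weights but are
expected to justify the change; the justification travels with the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .criteria import CriterionScore, round_score

__all__ = ["DEFAULT_WEIGHTS", "WeightScheme", "AssessmentResult", "validate_weights", "overall_score"]

DEFAULT_WEIGHTS: tuple[int, ...] = (1, 2, 1, 3, 4, 3, 2, 3, 1, 4, 3, 3)

_N_CRITERIA = 12


@dataclass(frozen=True)
class WeightScheme:
    weights: tuple[int, ...]
    provenance: str = "default"  # "default" or "user"
    justification: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(self.weights))
        problems = []
        if len(self.weights) != _N_CRITERIA:
            raise ValueError(
                f"weight vector must have {_N_CRITERIA} entries, got {len(self.weights)}"
            )
        for i, w in enumerate(self.weights, start=1):
            if isinstance(w, bool) or not isinstance(w, int):
                problems.append(f"criterion {i}: weight {w!r} is not an integer")
            elif not 1 <= w <= 4:
                problems.append(f"criterion {i}: weight {w} outside the 1-4 scale")
        if problems:
            raise ValueError("invalid weights: " + "; ".join(problems))

    @property
    def total(self) -> int:
        return sum(self.weights)


def validate_weights(
    weights: Sequence[int] | None, justification: str | None = None
) -> WeightScheme:
    """Validate a candidate 12-tuple of 1-4 integer weights.

    ``None`` or the default vector yields provenance "default"; anything else
    is "user" and carries the optional justification into reports.
    """
    if weights is None:
        return WeightScheme(DEFAULT_WEIGHTS, "default")
    scheme_weights = tuple(weights)
    if scheme_weights == DEFAULT_WEIGHTS and justification is None:
        return WeightScheme(DEFAULT_WEIGHTS, "default")
    return WeightScheme(scheme_weights, "user", justification)


@dataclass(frozen=True)
class AssessmentResult:
    """The 12 criterion scores, the weights, and the weighted overall score."""

    scores: tuple[CriterionScore, ...]
    weights: WeightScheme
    overall: float  # full precision; round only for display

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(self.scores))
        if len(self.scores) != _N_CRITERIA:
            raise ValueError(f"expected {_N_CRITERIA} scores, got {len(self.scores)}")
        ids = [s.criterion_id for s in self.scores]
        if ids != list(range(1, _N_CRITERIA + 1)):
            raise ValueError(f"scores must cover criteria 1-12 in order, got ids {ids}")
        if not 0.0 <= self.overall <= 1.0:
            raise ValueError(f"overall score out of [0, 1]: {self.overall}")

    @property
    def display_overall(self) -> float:
        return round_score(self.overall)

    def score_values(self) -> tuple[float, ...]:
        return tuple(s.score for s in self.scores)


def overall_score(
    scores: Sequence[CriterionScore],
    weights: WeightScheme | Sequence[int] | None = None,
) -> AssessmentResult:
    """Weighted mean of the 12 criterion scores.

    Kept at full floating precision internally; two-decimal rounding is
    display-only so that comparing procedures never suffers double rounding.
    """
    if not isinstance(weights, WeightScheme):
        weights = validate_weights(weights)
    scores = tuple(scores)
    if len(scores) != _N_CRITERIA:
        raise ValueError(f"expected {_N_CRITERIA} criterion scores, got {len(scores)}")
    num = sum(w * s.score for w, s in zip(weights.weights, scores))
    overall = num / weights.total
    return AssessmentResult(scores=scores, weights=weights, overall=overall)
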