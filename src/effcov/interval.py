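"""Interval estimates shared by all three confidence-interval methods."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class IntervalStatus(str, enum.Enum):
    """Classification of a confidence interval.

    ``valid``          both bounds inside [0, 1].
    ``invalid_bounds`` a Wald bound crosses 0 or 1 (possible for the exact
                       method only; bounds are reported unclipped so that
                       invalid intervals can be counted).
    ``degenerate``     zero-width interval because the point estimate is
                       exactly 0 or 1.
    ``undefined``      the interval cannot be formed (delta method with an
                       empty or full count cell, whose logit is infinite).
    """

    VALID = "valid"
    INVALID_BOUNDS = "invalid_bounds"
    DEGENERATE = "degenerate"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with method-tagged variance and CI bounds.

    Bounds are never clipped to [0, 1]; use :meth:`clipped` for display.
    """

    point: float
    variance: float
    lower: float
    upper: float
    method: str  # "exact" | "delta" | "bootstrap"
    status: IntervalStatus
    level: str = "stratum"  # "stratum" | "region" | "national"
    region_id: str | None = None
    facility_type: str | None = None

    def __post_init__(self) -> None:
        if self.status is not IntervalStatus.UNDEFINED and self.lower > self.upper:
            raise ValueError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    def clipped(self) -> tuple[float, float]:
        """Bounds clipped to [0, 1] for presentation only (never for
        invalidity accounting)."""
        return (max(self.lower, 0.0), min(self.upper, 1.0))

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def classify_wald(point: float, lower: float, upper: float) -> IntervalStatus:
    """Status of an unclipped Wald interval for a proportion.

    Degeneracy is assigned from the point estimate (0 or 1), not from zero
    variance, matching the simulation removal rule.
    """
    if point in (0.0, 1.0):
        return IntervalStatus.DEGENERATE
    if lower < 0.0 or upper > 1.0:
        return IntervalStatus.INVALID_BOUNDS
    return IntervalStatus.VALID
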