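"""Effective-coverage point estimates at stratum, region and national level.

A *stratum* is one (region, facility-type) cell.  Crude coverage p_x is the
sample proportion of individuals in need who use facilities of that type in
that region; readiness p_y is the sample proportion of such facilities meeting
a quality criterion (binary) or the sample mean of a bounded readiness score
(continuous).  Effective coverage for the stratum is the product p_x * p_y;
regional effective coverage sums the stratum products over facility types;
the national figure is a weighted average of regional values with weights
proportional to each region's denominator population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "StratumSummary",
    "AggregationSpec",
    "effective_coverage_stratum",
    "effective_coverage_region",
    "effective_coverage_national",
]

#: tolerance on the per-region constraint sum_f p_x <= 1
PARTITION_TOL = 1e-9


@dataclass(frozen=True)
class StratumSummary:
    """Observed counts/statistics for one (region, facility-type) cell.

    Proportions are always derived from counts (never accepted pre-rounded)
    so the logit intercepts of the delta method, which need the raw success
    and failure counts, are always computable.

    Parameters
    ----------
    region_id, facility_type
        Identifiers for the stratum.
    x_successes, n_x
        Individuals using this facility type, out of the (effective)
        individual sample size.
    readiness_kind
        ``"binary"`` (readiness from y_successes / n_y) or ``"continuous"``
        (readiness from a bounded score with mean ``y_mean`` and sample
        variance ``y_var``).
    y_successes, n_y
        Facilities meeting the readiness criterion, out of the (effective)
        facility sample size.  ``y_successes`` applies to binary readiness.
    y_mean, y_var
        Mean and sample variance of the continuous readiness score in [0, 1].
    s_bx, s_by
        Optional design-based logit-scale standard errors overriding the
        simple-random-sampling closed form; for complex-survey use.
    """

    region_id: str
    facility_type: str
    x_successes: int
    n_x: int
    readiness_kind: str = "binary"
    y_successes: int | None = None
    n_y: int = 1
    y_mean: float | None = None
    y_var: float | None = None
    s_bx: float | None = None
    s_by: float | None = None

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("sample sizes n_x and n_y must be >= 1")
        if not 0 <= self.x_successes <= self.n_x:
            raise ValueError(
                f"x_successes={self.x_successes} outside [0, n_x={self.n_x}]"
            )
        if self.readiness_kind == "binary":
            if self.y_successes is None:
                raise ValueError("binary readiness requires y_successes")
            if not 0 <= self.y_successes <= self.n_y:
                raise ValueError(
                    f"y_successes={self.y_successes} outside [0, n_y={self.n_y}]"
                )
        elif self.readiness_kind == "continuous":
            if self.y_mean is None or self.y_var is None:
                raise ValueError("continuous readiness requires y_mean and y_var")
            if not 0.0 <= self.y_mean <= 1.0:
                raise ValueError(f"y_mean={self.y_mean} outside [0, 1]")
            if self.y_var < 0:
                raise ValueError(f"y_var={self.y_var} must be >= 0")
            if self.n_y >= 2:
                # a [0,1]-supported score cannot exceed the Bernoulli bound
                bound = self.y_mean * (1 - self.y_mean) * self.n_y / (self.n_y - 1)
                if self.y_var > bound + 1e-12:
                    raise ValueError(
                        f"y_var={self.y_var} exceeds the maximum sample variance "
                        f"{bound:.6g} of a [0,1] score with mean {self.y_mean}"
                    )
        else:
            raise ValueError(f"unknown readiness_kind {self.readiness_kind!r}")

    @property
    def p_x(self) -> float:
        """Crude-coverage sample proportion."""
        return self.x_successes / self.n_x

    @property
    def p_y(self) -> float:
        """Readiness proportion (binary) or score mean (continuous)."""
        if self.readiness_kind == "binary":
            return self.y_successes / self.n_y
        return float(self.y_mean)

    @property
    def p_product(self) -> float:
        """Stratum effective coverage p_x * p_y."""
        return self.p_x * self.p_y


@dataclass
class AggregationSpec:
    """Region weights and the stratum -> region -> national structure.

    Weights are accepted unnormalized (they need only be proportional to each
    region's denominator population) and are normalized on construction.
    """

    region_weights: dict[str, float]
    strata: list[StratumSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.region_weights.values()):
            raise ValueError("region weights must be nonnegative")
        total = sum(self.region_weights.values())
        if total <= 0:
            raise ValueError("region weights must not all be zero")
        self.region_weights = {r: w / total for r, w in self.region_weights.items()}
        missing = {s.region_id for s in self.strata} - set(self.region_weights)
        if missing:
            raise ValueError(f"strata reference regions without weights: {sorted(missing)}")

    def by_region(self) -> dict[str, list[StratumSummary]]:
        """Strata grouped by region, in input order within region."""
        groups: dict[str, list[StratumSummary]] = {}
        for s in self.strata:
            groups.setdefault(s.region_id, []).append(s)
        return groups


def _check_proportion(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")


def effective_coverage_stratum(p_x: float, p_y: float) -> float:
    """Stratum effective coverage: the product p_x * p_y."""
    _check_proportion(p_x, "p_x")
    _check_proportion(p_y, "p_y")
    return p_x * p_y


def effective_coverage_region(strata: list[StratumSummary]) -> float:
    """Regional effective coverage: sum of stratum products over facility types.

    The crude-coverage proportions across facility types partition (at most)
    the population in need, so their sum may not exceed 1.
    """
    if not strata:
        raise ValueError("region must contain at least one stratum")
    regions = {s.region_id for s in strata}
    if len(regions) != 1:
        raise ValueError(f"strata span multiple regions: {sorted(regions)}")
    total_px = sum(s.p_x for s in strata)
    if total_px > 1.0 + PARTITION_TOL:
        raise ValueError(
            f"sum of crude-coverage proportions {total_px:.6g} exceeds 1: "
            "facility-type users cannot exceed the population in need"
        )
    return sum(s.p_x * s.p_y for s in strata)


def effective_coverage_national(spec: AggregationSpec) -> float:
    """National effective coverage: weighted average of regional values."""
    groups = spec.by_region()
    if not groups:
        raise ValueError("aggregation spec contains no strata")
    return sum(
        spec.region_weights[r] * effective_coverage_region(strata)
        for r, strata in groups.items()
    )
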