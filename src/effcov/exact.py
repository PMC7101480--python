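"""Goodman exact variance of a product of independent proportions, with
Wald-type confidence intervals.

For independent Z and M, Var(ZM) = (Var Z + (EZ)^2)(Var M + (EM)^2) - (EZ EM)^2
is an identity, not an approximation.  Plugging in the binomial variance
p(1-p)/n and the observed proportions gives the estimated variance of the
stratum effective coverage p_x * p_y.  The interval is the symmetric Wald
interval p +/- z * s, reported unclipped: near the 0/1 boundary the bounds can
leave [0, 1], and those invalid intervals are counted rather than hidden.

Under the independence-across-strata assumption the regional variance is the
sum of stratum variances and the national variance weights each regional
variance by the squared (normalized) region weight.
"""

from __future__ import annotations

import math

import numpy as np

from .estimands import AggregationSpec, StratumSummary
from .interval import IntervalEstimate, IntervalStatus, classify_wald

__all__ = [
    "Z_95",
    "exact_variance_stratum",
    "exact_variance_continuous",
    "exact_variance_region",
    "exact_variance_national",
    "exact_ci",
    "exact_estimate_stratum",
]

#: the fixed 95% normal quantile used throughout (not recomputed from scipy,
#: so intervals are bit-compatible with the conventional 1.96)
Z_95 = 1.96


def exact_variance_stratum(p_x, n_x, p_y, n_y):
    """Plug-in Goodman variance of the product of two sample proportions.

    Accepts scalars or broadcasting numpy arrays.  Never negative: each
    bracketed factor is at least the corresponding squared mean.
    """
    p_x, p_y = np.asarray(p_x, float), np.asarray(p_y, float)
    if np.any(p_x < 0) or np.any(p_x > 1) or np.any(p_y < 0) or np.any(p_y > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if np.any(np.asarray(n_x) < 1) or np.any(np.asarray(n_y) < 1):
        raise ValueError("sample sizes must be >= 1")
    bx = p_x * (1.0 - p_x) / n_x + p_x**2
    by = p_y * (1.0 - p_y) / n_y + p_y**2
    out = bx * by - (p_x * p_y) ** 2
    # clamp tiny negative round-off; the identity guarantees >= 0
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def exact_variance_continuous(p_x, n_x, y_mean, y_var, n_y):
    """Goodman variance with a continuous readiness score.

    The readiness factor contributes Var(ybar) = y_var / n_y and mean y_mean
    in place of the binomial variance and proportion.
    """
    p_x, y_mean = np.asarray(p_x, float), np.asarray(y_mean, float)
    y_var = np.asarray(y_var, float)
    if np.any(y_var < 0):
        raise ValueError("y_var must be >= 0")
    if np.any(p_x < 0) or np.any(p_x > 1) or np.any(y_mean < 0) or np.any(y_mean > 1):
        raise ValueError("p_x and y_mean must lie in [0, 1]")
    bx = p_x * (1.0 - p_x) / n_x + p_x**2
    by = y_var / n_y + y_mean**2
    out = np.maximum(bx * by - (p_x * y_mean) ** 2, 0.0)
    return out if out.ndim else float(out)


def _stratum_variance(s: StratumSummary) -> float:
    if s.readiness_kind == "binary":
        return exact_variance_stratum(s.p_x, s.n_x, s.p_y, s.n_y)
    return exact_variance_continuous(s.p_x, s.n_x, s.y_mean, s.y_var, s.n_y)


def exact_variance_region(strata: list[StratumSummary]) -> float:
    """Regional variance: sum of stratum variances (independence assumed)."""
    if not strata:
        raise ValueError("region must contain at least one stratum")
    return float(sum(_stratum_variance(s) for s in strata))


def exact_variance_national(spec: AggregationSpec) -> float:
    """National variance: sum over regions of w_r^2 times the regional variance."""
    groups = spec.by_region()
    if not groups:
        raise ValueError("aggregation spec contains no strata")
    return float(
        sum(
            spec.region_weights[r] ** 2 * exact_variance_region(strata)
            for r, strata in groups.items()
        )
    )


def exact_ci(
    point: float,
    variance: float,
    z: float = Z_95,
    level: str = "stratum",
    region_id: str | None = None,
    facility_type: str | None = None,
) -> IntervalEstimate:
    """Symmetric Wald interval point +/- z*sqrt(variance), unclipped.

    Status is ``degenerate`` when the point estimate is exactly 0 or 1,
    ``invalid_bounds`` when a bound leaves [0, 1], ``valid`` otherwise.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    half = z * math.sqrt(variance)
    lower, upper = point - half, point + half
    return IntervalEstimate(
        point=point,
        variance=variance,
        lower=lower,
        upper=upper,
        method="exact",
        status=classify_wald(point, lower, upper),
        level=level,
        region_id=region_id,
        facility_type=facility_type,
    )


def exact_estimate_stratum(s: StratumSummary, z: float = Z_95) -> IntervalEstimate:
    """Convenience: point, Goodman variance and Wald CI for one stratum."""
    return exact_ci(
        s.p_product,
        _stratum_variance(s),
        z=z,
        level="stratum",
        region_id=s.region_id,
        facility_type=s.facility_type,
    )
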