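"""Delta-method (logit-scale) variance and asymmetric confidence intervals.

The effective-coverage estimate is mapped to the logit scale,
F = logit(p), where a normal sampling distribution is a better approximation
than on the proportion scale and where back-transformed bounds can never
leave (0, 1).  Because logit(p_x * p_y) does not factor, Var(F) is obtained
by a first-order (delta-method) expansion in the logit intercepts of the two
samples:

    Var(F) ~= sum over strata of  g_x^2 s_bx^2 + g_y^2 s_by^2

where b = log(n1/n0) is the intercept of an empty logit regression,
s_b = sqrt(1/n0 + 1/n1) its standard error, and the gradients g follow from
the chain rule through antilogit and logit.  At the stratum level

    g_x = p_x (1 - p_x) p_y / (p (1 - p)) = (1 - p_x) / (1 - p),

with p = p_x p_y; regional and national gradients replace p by the regional
or national point estimate and, nationally, carry the region weight w_r in
the numerator.  All analytic gradients are validated against central finite
differences in the test suite.

The interval is F -/+ z * sqrt(Var F) back-transformed by the antilogit; it
is asymmetric about the point estimate and always strictly inside (0, 1).
The method is undefined when any required logit is infinite: an empty or
full count cell (p = 0, or p_x or p_y equal to 1), detected from the counts
rather than from floating-point equality.

For a continuous readiness score the readiness factor enters the expansion
on the natural (mean) scale, contributing (p_x / (p(1-p)))^2 * y_var / n_y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimands import (
    AggregationSpec,
    StratumSummary,
    effective_coverage_national,
    effective_coverage_region,
)
from .exact import Z_95
from .interval import IntervalEstimate, IntervalStatus

__all__ = [
    "LogitStat",
    "DeltaGradient",
    "UndefinedLogitError",
    "logit_stat",
    "antilogit",
    "delta_gradient_stratum",
    "delta_gradients",
    "delta_variance",
    "delta_variance_continuous",
    "delta_ci",
    "delta_estimate",
]


class UndefinedLogitError(ValueError):
    """A required logit intercept is infinite (empty or full count cell)."""


def antilogit(x: float) -> float:
    """Inverse logit, exp(x)/(1+exp(x)), computed stably for large |x|."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class LogitStat:
    """Intercept and standard error of an empty logit regression.

    b = log(n1/n0); s_b = sqrt(1/n0 + 1/n1).  antilogit(b) recovers the
    sample proportion n1/(n0+n1).
    """

    b: float
    s_b: float
    n1: int
    n0: int


def logit_stat(successes: int, trials: int) -> LogitStat:
    """Logit intercept and SE from a binomial count.

    Raises :class:`UndefinedLogitError` when successes is 0 or trials (the
    intercept is infinite and the delta interval cannot be formed).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes={successes} outside [0, {trials}]")
    n1, n0 = successes, trials - successes
    if n1 == 0 or n0 == 0:
        raise UndefinedLogitError(
            f"logit undefined for {n1} successes out of {trials} trials"
        )
    return LogitStat(
        b=math.log(n1 / n0), s_b=math.sqrt(1.0 / n0 + 1.0 / n1), n1=n1, n0=n0
    )


@dataclass(frozen=True)
class DeltaGradient:
    """Per-stratum partial derivatives (g_x, g_y) of the logit-scale target.

    For a continuous-readiness stratum g_y is the derivative with respect to
    the score mean on the natural scale.
    """

    pairs: list[tuple[float, float]]


def delta_gradient_stratum(p_x: float, p_y: float) -> DeltaGradient:
    """Gradient of logit(p_x * p_y) with respect to the two logit intercepts.

    g_x = (1 - p_x) / (1 - p_x p_y) and symmetrically for g_y.
    """
    p = p_x * p_y
    if not 0.0 < p < 1.0:
        raise UndefinedLogitError(f"product {p} on the boundary of (0, 1)")
    g_x = (1.0 - p_x) / (1.0 - p)
    g_y = (1.0 - p_y) / (1.0 - p)
    return DeltaGradient(pairs=[(g_x, g_y)])


def _level_point(level, strata, spec: AggregationSpec | None) -> float:
    if level == "stratum":
        (s,) = strata
        return s.p_product
    if level == "region":
        return effective_coverage_region(strata)
    if level == "national":
        return effective_coverage_national(spec)
    raise ValueError(f"unknown level {level!r}")


def _stratum_gradient(s: StratumSummary, p: float, w: float) -> tuple[float, float]:
    """(g_x, g_y) for one stratum of a level with point estimate p.

    g_x is the derivative of logit(level estimate) with respect to the
    stratum's coverage logit intercept b_x; g_y with respect to the readiness
    intercept b_y (binary) or the score mean on the natural scale
    (continuous).  w is the region weight (1 below national level).
    """
    denom = p * (1.0 - p)
    if s.readiness_kind == "binary":
        g_x = w * s.p_x * (1.0 - s.p_x) * s.p_y / denom
        g_y = w * s.p_x * s.p_y * (1.0 - s.p_y) / denom
        return g_x, g_y
    if not 0.0 < s.y_mean < 1.0:
        raise UndefinedLogitError(f"score mean {s.y_mean} on the boundary")
    g_x = w * s.p_x * (1.0 - s.p_x) * s.y_mean / denom
    g_y = w * s.p_x / denom
    return g_x, g_y


def delta_gradients(
    level: str,
    strata: list[StratumSummary] | None = None,
    spec: AggregationSpec | None = None,
) -> DeltaGradient:
    """Per-stratum analytic gradients of the level's logit-scale target.

    Stratum order matches the input (national: region groups in input
    order).  Region weights are folded into the national gradients.
    """
    if level == "national":
        if spec is None:
            raise ValueError("national level requires an AggregationSpec")
        p = _level_point(level, None, spec)
        if not 0.0 < p < 1.0:
            raise UndefinedLogitError(f"national estimate {p} on the boundary")
        pairs = [
            _stratum_gradient(s, p, spec.region_weights[r])
            for r, group in spec.by_region().items()
            for s in group
        ]
        return DeltaGradient(pairs=pairs)
    if not strata:
        raise ValueError("no strata supplied")
    p = _level_point(level, strata, None)
    if not 0.0 < p < 1.0:
        raise UndefinedLogitError(f"{level} estimate {p} on the boundary")
    return DeltaGradient(pairs=[_stratum_gradient(s, p, 1.0) for s in strata])


def _stratum_terms(s: StratumSummary, p: float, w: float) -> float:
    """One stratum's contribution g_x^2 s_bx^2 + g_y^2 s_by^2 to Var(F)."""
    g_x, g_y = _stratum_gradient(s, p, w)
    lx = logit_stat(s.x_successes, s.n_x)
    s_bx = s.s_bx if s.s_bx is not None else lx.s_b
    if s.readiness_kind == "binary":
        ly = logit_stat(s.y_successes, s.n_y)
        s_by = s.s_by if s.s_by is not None else ly.s_b
        return g_x**2 * s_bx**2 + g_y**2 * s_by**2
    return g_x**2 * s_bx**2 + g_y**2 * (s.y_var / s.n_y)


def delta_variance(
    level: str,
    strata: list[StratumSummary] | None = None,
    spec: AggregationSpec | None = None,
) -> float:
    """Delta-method Var(F) at the requested aggregation level.

    ``strata`` is the single stratum (stratum level), one region's strata
    (region level) or ignored in favour of ``spec`` (national level).
    Raises :class:`UndefinedLogitError` if any contributing stratum has an
    empty or full count cell or the level point estimate is 0 or 1.
    """
    if level == "national":
        if spec is None:
            raise ValueError("national level requires an AggregationSpec")
        p = _level_point(level, None, spec)
        if not 0.0 < p < 1.0:
            raise UndefinedLogitError(f"national estimate {p} on the boundary")
        return float(
            sum(
                _stratum_terms(s, p, spec.region_weights[r])
                for r, group in spec.by_region().items()
                for s in group
            )
        )
    if not strata:
        raise ValueError("no strata supplied")
    p = _level_point(level, strata, None)
    if not 0.0 < p < 1.0:
        raise UndefinedLogitError(f"{level} estimate {p} on the boundary")
    return float(sum(_stratum_terms(s, p, 1.0) for s in strata))


def delta_variance_continuous(
    x_successes: int, n_x: int, y_mean: float, y_var: float, n_y: int
) -> float:
    """Stratum-level Var(F) with a continuous readiness score.

    Var(F) = ((1-p_x)/(1-p))^2 s_bx^2 + (p_x/(p(1-p)))^2 y_var/n_y with
    p = p_x * y_mean.
    """
    s = StratumSummary(
        region_id="_", facility_type="_", x_successes=x_successes, n_x=n_x,
        readiness_kind="continuous", y_mean=y_mean, y_var=y_var, n_y=n_y,
    )
    return delta_variance("stratum", [s])


def delta_ci(
    F: float,
    varF: float,
    z: float = Z_95,
    level: str = "stratum",
    region_id: str | None = None,
    facility_type: str | None = None,
) -> IntervalEstimate:
    """Back-transformed interval antilogit(F -/+ z*sqrt(varF)).

    Always strictly inside (0, 1); asymmetric about the point estimate.
    """
    if varF < 0:
        raise ValueError("varF must be >= 0")
    half = z * math.sqrt(varF)
    return IntervalEstimate(
        point=antilogit(F),
        variance=varF,
        lower=antilogit(F - half),
        upper=antilogit(F + half),
        method="delta",
        status=IntervalStatus.VALID,
        level=level,
        region_id=region_id,
        facility_type=facility_type,
    )


def delta_estimate(
    level: str,
    strata: list[StratumSummary] | None = None,
    spec: AggregationSpec | None = None,
    z: float = Z_95,
    region_id: str | None = None,
    facility_type: str | None = None,
) -> IntervalEstimate:
    """Point estimate plus delta-method CI at the requested level.

    Returns an ``undefined`` interval (NaN bounds) instead of raising when a
    logit cell is empty or full, so callers can account for undefined cases
    the way the simulation study does.
    """
    if level == "national":
        point = effective_coverage_national(spec)
    elif level == "region":
        point = effective_coverage_region(strata)
    else:
        (s,) = strata
        point = s.p_product
        region_id = region_id or s.region_id
        facility_type = facility_type or s.facility_type
    try:
        varF = delta_variance(level, strata, spec)
    except UndefinedLogitError:
        return IntervalEstimate(
            point=point, variance=float("nan"), lower=float("nan"),
            upper=float("nan"), method="delta",
            status=IntervalStatus.UNDEFINED, level=level,
            region_id=region_id, facility_type=facility_type,
        )
    F = math.log(point / (1.0 - point))
    return delta_ci(F, varF, z=z, level=level,
                    region_id=region_id, facility_type=facility_type)
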