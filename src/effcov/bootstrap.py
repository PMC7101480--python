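"""Parametric bootstrap percentile intervals for stratum effective coverage.

Replicate coverage proportions are drawn as Binomial(n_x, p_x)/n_x and
readiness proportions as Binomial(n_y, p_y)/n_y (or as means of n_y Beta
draws moment-matched to the observed score mean and variance, for a
continuous readiness measure).  The interval is the (2.5, 97.5) percentile
pair of the B elementwise products.  Percentile bounds can never leave
[0, 1]; the interval is degenerate exactly when the observed product is 0
or 1, in which case every replicate product is that same constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interval import IntervalEstimate, IntervalStatus

__all__ = [
    "BootstrapConfig",
    "parametric_bootstrap_ci",
    "parametric_bootstrap_ci_continuous",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the parametric bootstrap.

    quantile_rule is the numpy quantile method name; the default linear
    interpolation between order statistics (Hyndman-Fan type 7) perturbs
    endpoints by < 1e-3 at B = 10000 relative to other conventions.
    """

    B: int = 10_000
    seed: int | None = None
    percentiles: tuple[float, float] = (2.5, 97.5)
    quantile_rule: str = "linear"

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("B must be >= 100")
        lo, hi = self.percentiles
        if not 0.0 < lo < hi < 100.0:
            raise ValueError("percentiles must satisfy 0 < lower < upper < 100")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _percentile_interval(
    products: np.ndarray, point: float, cfg: BootstrapConfig,
    region_id: str | None, facility_type: str | None,
) -> IntervalEstimate:
    lo, hi = np.quantile(
        products, [p / 100.0 for p in cfg.percentiles], method=cfg.quantile_rule
    )
    status = (
        IntervalStatus.DEGENERATE if point in (0.0, 1.0) else IntervalStatus.VALID
    )
    return IntervalEstimate(
        point=point,
        variance=float(np.var(products, ddof=1)),
        lower=float(lo),
        upper=float(hi),
        method="bootstrap",
        status=status,
        level="stratum",
        region_id=region_id,
        facility_type=facility_type,
    )


def parametric_bootstrap_ci(
    p_x: float,
    n_x: int,
    p_y: float,
    n_y: int,
    cfg: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
    region_id: str | None = None,
    facility_type: str | None = None,
) -> IntervalEstimate:
    """Percentile bootstrap CI for p_x * p_y from binomial resampling.

    Deterministic for a fixed cfg.seed; an explicit ``rng`` overrides the
    config seed (used by the simulation harness to manage substreams).
    """
    if not (0.0 <= p_x <= 1.0 and 0.0 <= p_y <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    cfg = cfg or BootstrapConfig()
    gen = rng if rng is not None else cfg.rng()
    bx = gen.binomial(n_x, p_x, size=cfg.B) / n_x
    by = gen.binomial(n_y, p_y, size=cfg.B) / n_y
    return _percentile_interval(bx * by, p_x * p_y, cfg, region_id, facility_type)


def parametric_bootstrap_ci_continuous(
    p_x: float,
    n_x: int,
    y_mean: float,
    y_var: float,
    n_y: int,
    cfg: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
    region_id: str | None = None,
    facility_type: str | None = None,
) -> IntervalEstimate:
    """Percentile bootstrap CI with continuous readiness scores.

    Readiness replicates are means of n_y Beta(alpha, beta) draws with
    alpha, beta matched to (y_mean, y_var); requires
    y_var < y_mean * (1 - y_mean) for a valid Beta law (y_var = 0 gives a
    constant score).
    """
    if not (0.0 <= p_x <= 1.0 and 0.0 <= y_mean <= 1.0):
        raise ValueError("p_x and y_mean must lie in [0, 1]")
    if y_var < 0:
        raise ValueError("y_var must be >= 0")
    cfg = cfg or BootstrapConfig()
    gen = rng if rng is not None else cfg.rng()
    bx = gen.binomial(n_x, p_x, size=cfg.B) / n_x
    if y_var == 0.0 or y_mean in (0.0, 1.0):
        by = np.full(cfg.B, y_mean)
    else:
        bound = y_mean * (1.0 - y_mean)
        if y_var >= bound:
            raise ValueError(
                f"y_var={y_var} >= y_mean*(1-y_mean)={bound:.6g}: no Beta "
                "distribution has these moments"
            )
        nu = bound / y_var - 1.0
        alpha, beta = y_mean * nu, (1.0 - y_mean) * nu
        by = gen.beta(alpha, beta, size=(cfg.B, n_y)).mean(axis=1)
    return _percentile_interval(
        bx * by, p_x * y_mean, cfg, region_id, facility_type
    )
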