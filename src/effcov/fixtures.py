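"""Synthetic stratum-table generator with known truths.

Emulates the shape of a national effective-coverage analysis built from two
survey sources: a handful of regions, several facility types per region,
per-stratum crude-coverage and readiness truths, and region population
weights.  Because the truths are recorded alongside the generated counts,
the generator supports end-to-end parameter-recovery tests without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimands import AggregationSpec, StratumSummary

__all__ = ["TruthConfig", "FixtureTruth", "generate_fixture"]


@dataclass(frozen=True)
class TruthConfig:
    """Ranges the true parameters are drawn from.

    Per region, total crude coverage is drawn uniformly from
    ``region_coverage_range`` and split across facility types by a flat
    Dirichlet, so the partition constraint sum_f P_x <= 1 holds by
    construction.  Readiness truths are uniform on ``readiness_range``.
    """

    n_x: int = 1000
    n_y: int = 100
    readiness_kind: str = "binary"
    region_coverage_range: tuple[float, float] = (0.3, 0.9)
    readiness_range: tuple[float, float] = (0.2, 0.95)
    y_dispersion: float = 0.5  # continuous scores: fraction of Bernoulli variance


@dataclass(frozen=True)
class FixtureTruth:
    """The generating parameters behind a synthetic stratum table."""

    region_weights: dict[str, float]
    P_x: dict[tuple[str, str], float]
    P_y: dict[tuple[str, str], float]

    def stratum(self, region_id: str, facility_type: str) -> float:
        key = (region_id, facility_type)
        return self.P_x[key] * self.P_y[key]

    def region(self, region_id: str) -> float:
        return sum(
            self.P_x[k] * self.P_y[k] for k in self.P_x if k[0] == region_id
        )

    @property
    def national(self) -> float:
        return sum(w * self.region(r) for r, w in self.region_weights.items())


def generate_fixture(
    n_regions: int,
    n_facility_types: int,
    seed: int,
    truth_config: TruthConfig | None = None,
) -> tuple[AggregationSpec, FixtureTruth]:
    """Draw a synthetic stratum table and the truth record behind it."""
    if n_regions < 1 or n_facility_types < 1:
        raise ValueError("need at least one region and one facility type")
    cfg = truth_config or TruthConfig()
    rng = np.random.default_rng(seed)

    regions = [f"R{i + 1:02d}" for i in range(n_regions)]
    ftypes = [f"F{j + 1}" for j in range(n_facility_types)]
    raw_w = rng.uniform(0.5, 2.0, size=n_regions)
    weights = {r: float(w / raw_w.sum()) for r, w in zip(regions, raw_w)}

    P_x: dict[tuple[str, str], float] = {}
    P_y: dict[tuple[str, str], float] = {}
    strata: list[StratumSummary] = []
    lo_c, hi_c = cfg.region_coverage_range
    lo_r, hi_r = cfg.readiness_range
    for r in regions:
        total = rng.uniform(lo_c, hi_c)
        shares = rng.dirichlet(np.ones(n_facility_types))
        for f, share in zip(ftypes, shares):
            px = float(total * share)
            py = float(rng.uniform(lo_r, hi_r))
            P_x[(r, f)], P_y[(r, f)] = px, py
            x_succ = int(rng.binomial(cfg.n_x, px))
            if cfg.readiness_kind == "binary":
                strata.append(
                    StratumSummary(
                        region_id=r, facility_type=f,
                        x_successes=x_succ, n_x=cfg.n_x,
                        readiness_kind="binary",
                        y_successes=int(rng.binomial(cfg.n_y, py)), n_y=cfg.n_y,
                    )
                )
            else:
                var = cfg.y_dispersion * py * (1.0 - py)
                nu = py * (1.0 - py) / var - 1.0
                scores = rng.beta(py * nu, (1.0 - py) * nu, size=cfg.n_y)
                strata.append(
                    StratumSummary(
                        region_id=r, facility_type=f,
                        x_successes=x_succ, n_x=cfg.n_x,
                        readiness_kind="continuous",
                        y_mean=float(scores.mean()),
                        y_var=float(scores.var(ddof=1)) if cfg.n_y > 1 else 0.0,
                        n_y=cfg.n_y,
                    )
                )

    spec = AggregationSpec(region_weights=weights, strata=strata)
    return spec, FixtureTruth(region_weights=weights, P_x=P_x, P_y=P_y)
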