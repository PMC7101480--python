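"""Monte-Carlo study of confidence-interval coverage for effective coverage.

For each setting (true crude coverage P_x, true readiness P_y, sample sizes
n_x and n_y) the engine simulates simple random samples, forms the stratum
product estimate and a nominally 95% interval with each requested method,
and estimates the coverage probability: the fraction of intervals containing
the true product P_x * P_y.

Accounting follows per-method removal rules.  The exact and bootstrap
methods remove iterations with a *degenerate* interval (product estimate
exactly 0 or 1); the delta method removes *undefined* iterations (product 0,
or either observed proportion equal to 1 — any empty or full count cell).
Exact intervals with a bound outside [0, 1] are counted as *invalid* among
the non-degenerate iterations but still contribute to coverage when they
contain the truth.

Reproducibility: every setting derives its own RNG substream from the master
seed and the setting parameters, so any subset of the grid reproduces the
corresponding cells of a full run.  The inner bootstrap is vectorized by
deduplicating repeated observed count pairs — the percentile interval is a
pure function of the observed counts, so each distinct pair is resampled
once per setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exact import Z_95, exact_variance_continuous, exact_variance_stratum

__all__ = [
    "TABLE1_P_GRID",
    "TABLE1_SIZE_PAIRS",
    "SimulationSetting",
    "SimulationConfig",
    "MethodResult",
    "SettingResult",
    "simulate_dataset",
    "run_setting",
    "run_grid",
    "grid_summary",
    "table1_settings",
]

#: the standard grid of true proportions for coverage-probability studies
TABLE1_P_GRID: tuple[float, ...] = (
    0.02, 0.04, 0.06, 0.08, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45,
    0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.92, 0.94, 0.96,
    0.98,
)

#: the standard (n_x, n_y) sample-size pairs
TABLE1_SIZE_PAIRS: tuple[tuple[int, int], ...] = (
    (50, 50), (100, 100), (200, 200), (300, 300), (400, 400), (500, 500),
    (100, 50), (200, 50), (300, 50), (400, 50), (500, 50),
)

ALL_METHODS = ("exact", "delta", "bootstrap")


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of the simulation grid.

    For continuous readiness the facility scores are Beta distributed with
    mean P_y and variance ``y_dispersion * P_y * (1 - P_y)`` (a fraction of
    the Bernoulli variance; 0 < y_dispersion < 1).
    """

    P_x: float
    P_y: float
    n_x: int
    n_y: int
    readiness_kind: str = "binary"
    reps: int = 10_000
    y_dispersion: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.P_x <= 1.0 and 0.0 <= self.P_y <= 1.0):
            raise ValueError("true proportions must lie in [0, 1]")
        if self.n_x < 1 or self.n_y < 1 or self.reps < 1:
            raise ValueError("n_x, n_y and reps must be >= 1")
        if self.readiness_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown readiness_kind {self.readiness_kind!r}")
        if self.readiness_kind == "continuous" and not 0.0 < self.y_dispersion < 1.0:
            raise ValueError("y_dispersion must lie in (0, 1)")

    @property
    def truth(self) -> float:
        return self.P_x * self.P_y


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level options shared across settings."""

    seed: int = 0
    inner_B: int = 10_000  # bootstrap resamples per iteration
    z: float = Z_95
    quantile_rule: str = "linear"


@dataclass(frozen=True)
class MethodResult:
    """Coverage accounting for one method in one setting."""

    method: str
    coverage_probability: float  # NaN when nothing contributes
    n_total: int
    n_removed: int  # degenerate (exact/bootstrap) or undefined (delta)
    n_invalid: int  # exact only: bounds outside [0,1] among non-degenerate
    mean_interval_width: float

    @property
    def n_contributing(self) -> int:
        return self.n_total - self.n_removed


@dataclass(frozen=True)
class SettingResult:
    setting: SimulationSetting
    methods: dict[str, MethodResult]

    @property
    def no_information(self) -> bool:
        """True when every method removed every iteration."""
        return all(m.n_contributing == 0 for m in self.methods.values())


def _setting_seed(cfg: SimulationConfig, s: SimulationSetting) -> np.random.SeedSequence:
    # keyed on the setting parameters, not the grid position, so subsets of
    # a grid reproduce the matching cells of a full run
    kind = 0 if s.readiness_kind == "binary" else 1
    return np.random.SeedSequence(
        [
            int(cfg.seed),
            int(round(s.P_x * 10_000)),
            int(round(s.P_y * 10_000)),
            int(s.n_x),
            int(s.n_y),
            int(s.reps),
            kind,
        ]
    )


def _beta_params(mean: float, var: float) -> tuple[float, float]:
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _draw_counts(setting: SimulationSetting, rng: np.random.Generator, reps: int):
    """Vectorized draws: k_x and either k_y (binary) or score means/vars."""
    k_x = rng.binomial(setting.n_x, setting.P_x, size=reps)
    if setting.readiness_kind == "binary":
        k_y = rng.binomial(setting.n_y, setting.P_y, size=reps)
        return k_x, k_y, None, None
    if setting.P_y in (0.0, 1.0):
        scores = np.full((reps, setting.n_y), setting.P_y)
    else:
        a, b = _beta_params(
            setting.P_y, setting.y_dispersion * setting.P_y * (1.0 - setting.P_y)
        )
        scores = rng.beta(a, b, size=(reps, setting.n_y))
    y_mean = scores.mean(axis=1)
    y_var = scores.var(axis=1, ddof=1) if setting.n_y > 1 else np.zeros(reps)
    return k_x, None, y_mean, y_var


def simulate_dataset(
    setting: SimulationSetting, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one simulated dataset; returns the observed (p_x_hat, p_y_hat)."""
    k_x, k_y, y_mean, _ = _draw_counts(setting, rng, reps=1)
    p_x_hat = float(k_x[0]) / setting.n_x
    if setting.readiness_kind == "binary":
        return p_x_hat, float(k_y[0]) / setting.n_y
    return p_x_hat, float(y_mean[0])


def _exact_bounds(setting, p_x, p_y_or_mean, y_var, z):
    if setting.readiness_kind == "binary":
        var = exact_variance_stratum(p_x, setting.n_x, p_y_or_mean, setting.n_y)
    else:
        var = exact_variance_continuous(
            p_x, setting.n_x, p_y_or_mean, y_var, setting.n_y
        )
    half = z * np.sqrt(var)
    prod = p_x * p_y_or_mean
    return prod - half, prod + half


def _tally(
    method: str,
    reps: int,
    removed: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    truth: float,
    count_invalid: bool,
) -> MethodResult:
    keep = ~removed
    n_keep = int(keep.sum())
    if n_keep == 0:
        return MethodResult(method, float("nan"), reps, reps, 0, float("nan"))
    lo, hi = lower[keep], upper[keep]
    covered = (lo <= truth) & (truth <= hi)
    invalid = int(((lo < 0.0) | (hi > 1.0)).sum()) if count_invalid else 0
    return MethodResult(
        method=method,
        coverage_probability=float(covered.mean()),
        n_total=reps,
        n_removed=reps - n_keep,
        n_invalid=invalid,
        mean_interval_width=float((hi - lo).mean()),
    )


# cap on elements per inner-bootstrap chunk (memory control)
_BOOT_CHUNK_ELEMS = 16_777_216


def _bootstrap_bounds_binary(
    setting: SimulationSetting,
    k_x: np.ndarray,
    k_y: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bounds per iteration, deduplicating repeated (k_x, k_y).

    The bootstrap CI depends only on the observed counts, so each distinct
    pair is resampled once; draws for the unique pairs come from a single
    per-setting substream in sorted-pair order, which keeps the run
    deterministic for a given master seed.
    """
    n_x, n_y, B = setting.n_x, setting.n_y, cfg.inner_B
    codes = k_x.astype(np.int64) * (n_y + 1) + k_y
    uniq, inverse = np.unique(codes, return_inverse=True)
    u_kx, u_ky = uniq // (n_y + 1), uniq % (n_y + 1)
    q = [p / 100.0 for p in (2.5, 97.5)]
    lo_u = np.empty(uniq.size)
    hi_u = np.empty(uniq.size)
    chunk = max(1, _BOOT_CHUNK_ELEMS // B)
    for start in range(0, uniq.size, chunk):
        sl = slice(start, min(start + chunk, uniq.size))
        px = (u_kx[sl] / n_x)[:, None]
        py = (u_ky[sl] / n_y)[:, None]
        m = px.shape[0]
        bx = rng.binomial(n_x, px, size=(m, B)) / n_x
        by = rng.binomial(n_y, py, size=(m, B)) / n_y
        qs = np.quantile(bx * by, q, axis=1, method=cfg.quantile_rule)
        lo_u[sl], hi_u[sl] = qs[0], qs[1]
    return lo_u[inverse], hi_u[inverse]


def _bootstrap_bounds_continuous(
    setting: SimulationSetting,
    k_x: np.ndarray,
    y_mean: np.ndarray,
    y_var: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-iteration percentile bounds with Beta-resampled readiness means."""
    n_x, n_y, B = setting.n_x, setting.n_y, cfg.inner_B
    reps = k_x.size
    q = [p / 100.0 for p in (2.5, 97.5)]
    lower = np.empty(reps)
    upper = np.empty(reps)
    for i in range(reps):
        bx = rng.binomial(n_x, k_x[i] / n_x, size=B) / n_x
        m, v = y_mean[i], y_var[i]
        if v <= 0.0 or m <= 0.0 or m >= 1.0 or v >= m * (1.0 - m):
            by = np.full(B, m)
        else:
            a, b = _beta_params(m, v)
            by = rng.beta(a, b, size=(B, n_y)).mean(axis=1)
        lower[i], upper[i] = np.quantile(bx * by, q, method=cfg.quantile_rule)
    return lower, upper


def run_setting(
    setting: SimulationSetting,
    methods: tuple[str, ...] = ALL_METHODS,
    cfg: SimulationConfig | None = None,
) -> SettingResult:
    """Run one simulation setting and tally per-method coverage.

    An iteration can contribute to one method while being removed for
    another; removal rules are method-specific (see module docstring).
    """
    cfg = cfg or SimulationConfig()
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ss = _setting_seed(cfg, setting)
    child = ss.spawn(2)
    rng = np.random.default_rng(child[0])
    boot_rng = np.random.default_rng(child[1])
    reps, truth = setting.reps, setting.truth
    n_x, n_y = setting.n_x, setting.n_y
    binary = setting.readiness_kind == "binary"

    k_x, k_y, y_mean, y_var = _draw_counts(setting, rng, reps)
    p_x = k_x / n_x
    if binary:
        p_y = k_y / n_y
        prod_zero = (k_x == 0) | (k_y == 0)
        prod_one = (k_x == n_x) & (k_y == n_y)
        undefined = (k_x == 0) | (k_x == n_x) | (k_y == 0) | (k_y == n_y)
    else:
        p_y = y_mean
        prod_zero = (k_x == 0) | (y_mean == 0.0)
        prod_one = (k_x == n_x) & (y_mean == 1.0)
        undefined = (k_x == 0) | (k_x == n_x) | (y_mean == 0.0) | (y_mean == 1.0)
    degenerate = prod_zero | prod_one

    results: dict[str, MethodResult] = {}

    if "exact" in methods:
        lo, hi = _exact_bounds(setting, p_x, p_y, y_var, cfg.z)
        results["exact"] = _tally(
            "exact", reps, degenerate, lo, hi, truth, count_invalid=True
        )

    if "delta" in methods:
        lo = np.full(reps, np.nan)
        hi = np.full(reps, np.nan)
        d = ~undefined
        if d.any():
            px, py = p_x[d], p_y[d]
            p = px * py
            with np.errstate(divide="ignore"):
                s2_bx = 1.0 / k_x[d] + 1.0 / (n_x - k_x[d])
            gx = (1.0 - px) / (1.0 - p)
            if binary:
                s2_by = 1.0 / k_y[d] + 1.0 / (n_y - k_y[d])
                gy = (1.0 - py) / (1.0 - p)
                varF = gx**2 * s2_bx + gy**2 * s2_by
            else:
                gy = px / (p * (1.0 - p))
                varF = gx**2 * s2_bx + gy**2 * (y_var[d] / n_y)
            F = np.log(p / (1.0 - p))
            half = cfg.z * np.sqrt(varF)
            lo[d] = 1.0 / (1.0 + np.exp(-(F - half)))
            hi[d] = 1.0 / (1.0 + np.exp(-(F + half)))
        results["delta"] = _tally(
            "delta", reps, undefined, lo, hi, truth, count_invalid=False
        )

    if "bootstrap" in methods:
        if binary:
            lo, hi = _bootstrap_bounds_binary(setting, k_x, k_y, cfg, boot_rng)
        else:
            lo, hi = _bootstrap_bounds_continuous(
                setting, k_x, y_mean, y_var, cfg, boot_rng
            )
        results["bootstrap"] = _tally(
            "bootstrap", reps, degenerate, lo, hi, truth, count_invalid=False
        )

    return SettingResult(setting=setting, methods=results)


def table1_settings(
    size_pairs: tuple[tuple[int, int], ...] = TABLE1_SIZE_PAIRS,
    p_grid: tuple[float, ...] = TABLE1_P_GRID,
    reps: int = 10_000,
    readiness_kind: str = "binary",
) -> list[SimulationSetting]:
    """The full cross of the true-proportion grid with the sample-size pairs."""
    return [
        SimulationSetting(P_x=px, P_y=py, n_x=nx, n_y=ny,
                          readiness_kind=readiness_kind, reps=reps)
        for (nx, ny) in size_pairs
        for px in p_grid
        for py in p_grid
    ]


def run_grid(
    grid: list[SimulationSetting],
    methods: tuple[str, ...] = ALL_METHODS,
    cfg: SimulationConfig | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every setting; one row per (setting, method).

    Deterministic given the master seed regardless of grid order.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    cfg = cfg or SimulationConfig()
    rows = []
    for i, setting in enumerate(grid):
        res = run_setting(setting, methods, cfg)
        for m, mr in res.methods.items():
            rows.append(
                {
                    "P_x": setting.P_x,
                    "P_y": setting.P_y,
                    "n_x": setting.n_x,
                    "n_y": setting.n_y,
                    "reps": setting.reps,
                    "readiness_kind": setting.readiness_kind,
                    "method": m,
                    "coverage_probability": mr.coverage_probability,
                    "n_total": mr.n_total,
                    "n_removed": mr.n_removed,
                    "n_contributing": mr.n_contributing,
                    "n_invalid": mr.n_invalid,
                    "invalid_fraction": (
                        mr.n_invalid / mr.n_contributing
                        if mr.n_contributing else float("nan")
                    ),
                    "mean_interval_width": mr.mean_interval_width,
                    "no_information": res.no_information,
                }
            )
        if progress and (i + 1) % 25 == 0:
            print(f"  {i + 1}/{len(grid)} settings done", flush=True)
    return pd.DataFrame(rows)


def grid_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-method extrema over a grid: coverage range and worst invalid rate."""
    out = []
    for m, g in df.groupby("method"):
        cov = g["coverage_probability"].dropna()
        out.append(
            {
                "method": m,
                "min_coverage": cov.min() if len(cov) else float("nan"),
                "max_coverage": cov.max() if len(cov) else float("nan"),
                "max_invalid_fraction": g["invalid_fraction"].max()
                if m == "exact"
                else 0.0,
                "total_removed": int(g["n_removed"].sum()),
            }
        )
    return pd.DataFrame(out)
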