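import numpy as np
import pytest

from effcov.estimands import AggregationSpec, StratumSummary


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def single_stratum():
    return StratumSummary(
        region_id="R1", facility_type="F1",
        x_successes=50, n_x=100, readiness_kind="binary",
        y_successes=50, n_y=100,
    )


@pytest.fixture
def two_region_spec():
    """Two regions x two facility types with interior counts."""
    strata = [
        StratumSummary("R1", "F1", 30, 100, "binary", 40, 80),
        StratumSummary("R1", "F2", 20, 100, "binary", 60, 80),
        StratumSummary("R2", "F1", 45, 120, "binary", 30, 50),
        StratumSummary("R2", "F2", 15, 120, "binary", 45, 50),
    ]
    return AggregationSpec(region_weights={"R1": 3.0, "R2": 1.0}, strata=strata)


def random_interior_stratum(rng, kind="binary"):
    """A stratum whose count cells are strictly interior (logits defined)."""
    n_x = int(rng.integers(20, 200))
    k_x = int(rng.integers(1, n_x))
    if kind == "binary":
        n_y = int(rng.integers(20, 200))
        k_y = int(rng.integers(1, n_y))
        return StratumSummary("R1", "F1", k_x, n_x, "binary", k_y, n_y)
    n_y = int(rng.integers(10, 100))
    mean = float(rng.uniform(0.1, 0.9))
    var = float(rng.uniform(0.1, 0.8)) * mean * (1 - mean)
    return StratumSummary(
        "R1", "F1", k_x, n_x, "continuous", None, n_y, y_mean=mean, y_var=var
    )
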