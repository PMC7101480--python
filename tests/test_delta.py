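import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effcov.delta import (
    UndefinedLogitError,
    antilogit,
    delta_ci,
    delta_estimate,
    delta_gradient_stratum,
    delta_gradients,
    delta_variance,
    delta_variance_continuous,
    logit_stat,
)
from effcov.estimands import AggregationSpec, StratumSummary
from effcov.exact import exact_ci, exact_variance_stratum
from effcov.interval import IntervalStatus

from conftest import random_interior_stratum


def _logit(p):
    return math.log(p / (1.0 - p))


def finite_difference(f, x, step=1e-6):
    """Central finite-difference gradient of f at x."""
    x = np.asarray(x, float)
    g = np.empty_like(x)
    for i in range(x.size):
        hi, lo = x.copy(), x.copy()
        hi[i] += step
        lo[i] -= step
        g[i] = (f(hi) - f(lo)) / (2 * step)
    return g


def level_logit_function(strata, weights):
    """The map from per-stratum free parameters to the level's logit.

    Binary strata contribute (b_x, b_y); continuous strata (b_x, y_mean),
    the score mean entering on the natural scale.
    """
    def params():
        out = []
        for s in strata:
            out.append(_logit(s.p_x))
            out.append(_logit(s.p_y) if s.readiness_kind == "binary" else s.y_mean)
        return np.array(out)

    def f(theta):
        total = 0.0
        for j, s in enumerate(strata):
            px = antilogit(theta[2 * j])
            py = (
                antilogit(theta[2 * j + 1])
                if s.readiness_kind == "binary"
                else theta[2 * j + 1]
            )
            total += weights[j] * px * py
        return _logit(total)

    return f, params()


class TestLogitStat:
    def test_balanced_cell(self):
        ls = logit_stat(50, 100)
        assert ls.b == 0.0
        assert ls.s_b == pytest.approx(0.2)

    def test_minimal_symmetric_cell(self):
        ls = logit_stat(1, 2)
        assert ls.b == 0.0
        assert ls.s_b == pytest.approx(math.sqrt(2))

    @pytest.mark.parametrize("successes,trials", [(0, 50), (50, 50)])
    def test_empty_or_full_cell_undefined(self, successes, trials):
        with pytest.raises(UndefinedLogitError):
            logit_stat(successes, trials)

    def test_antilogit_recovers_proportion(self):
        ls = logit_stat(17, 60)
        assert antilogit(ls.b) == pytest.approx(17 / 60)


class TestStratumGradient:
    def test_symmetric_midpoint(self):
        g = delta_gradient_stratum(0.5, 0.5)
        (gx, gy), = g.pairs
        assert gx == pytest.approx(2 / 3)
        assert gy == pytest.approx(2 / 3)

    def test_perfect_readiness_limit(self):
        (gx, _), = delta_gradient_stratum(0.37, 1.0 - 1e-12).pairs
        assert gx == pytest.approx(1.0, rel=1e-6)

    def test_swap_symmetry(self):
        (gx, gy), = delta_gradient_stratum(0.2, 0.7).pairs
        (gx2, gy2), = delta_gradient_stratum(0.7, 0.2).pairs
        assert (gx, gy) == pytest.approx((gy2, gx2))

    def test_boundary_product_undefined(self):
        with pytest.raises(UndefinedLogitError):
            delta_gradient_stratum(1.0, 1.0)

    def test_matches_finite_differences(self, rng):
        for _ in range(25):
            px, py = rng.uniform(0.05, 0.95, 2)
            (gx, gy), = delta_gradient_stratum(px, py).pairs
            f = lambda t: _logit(antilogit(t[0]) * antilogit(t[1]))
            fd = finite_difference(f, [_logit(px), _logit(py)])
            assert gx == pytest.approx(fd[0], rel=1e-5)
            assert gy == pytest.approx(fd[1], rel=1e-5)


class TestDeltaVariance:
    def test_single_stratum_composition(self, single_stratum):
        # g_x = g_y = 2/3, s_b^2 = 0.04 on each side
        assert delta_variance("stratum", [single_stratum]) == pytest.approx(
            2 * (2 / 3) ** 2 * 0.04
        )

    def test_full_cell_undefined(self):
        s = StratumSummary("R1", "F1", 100, 100, "binary", 10, 50)
        with pytest.raises(UndefinedLogitError):
            delta_variance("stratum", [s])

    def test_national_single_region_equals_region(self, single_stratum):
        spec = AggregationSpec({"R1": 1.0}, [single_stratum])
        assert delta_variance("national", spec=spec) == pytest.approx(
            delta_variance("region", [single_stratum])
        )

    def test_continuous_arithmetic_example(self):
        got = delta_variance_continuous(50, 100, 0.5, 0.01, 25)
        assert got == pytest.approx((2 / 3) ** 2 * 0.04 + (8 / 3) ** 2 * 0.0004)

    def test_continuous_zero_score_variance(self):
        got = delta_variance_continuous(50, 100, 0.5, 0.0, 25)
        assert got == pytest.approx((2 / 3) ** 2 * 0.04)

    def test_design_based_se_override(self, single_stratum):
        import dataclasses

        s = dataclasses.replace(single_stratum, s_bx=0.5, s_by=0.5)
        assert delta_variance("stratum", [s]) == pytest.approx(
            2 * (2 / 3) ** 2 * 0.25
        )


class TestGradientOracles:
    """Analytic gradients vs central finite differences (step 1e-6)."""

    def test_region_level(self, rng):
        for _ in range(20):
            strata = [
                StratumSummary("R1", f"F{j}", int(rng.integers(1, 40)), 200,
                               "binary", int(rng.integers(1, 99)), 100)
                for j in range(3)
            ]
            grads = delta_gradients("region", strata).pairs
            f, theta = level_logit_function(strata, [1.0] * 3)
            fd = finite_difference(f, theta)
            for j, (gx, gy) in enumerate(grads):
                assert gx == pytest.approx(fd[2 * j], rel=1e-5)
                assert gy == pytest.approx(fd[2 * j + 1], rel=1e-5)

    def test_national_level(self, two_region_spec):
        grads = delta_gradients("national", spec=two_region_spec).pairs
        groups = two_region_spec.by_region()
        strata = [s for g in groups.values() for s in g]
        w = [two_region_spec.region_weights[s.region_id] for s in strata]
        f, theta = level_logit_function(strata, w)
        fd = finite_difference(f, theta)
        for j, (gx, gy) in enumerate(grads):
            assert gx == pytest.approx(fd[2 * j], rel=1e-5)
            assert gy == pytest.approx(fd[2 * j + 1], rel=1e-5)

    def test_continuous_stratum(self, rng):
        for _ in range(20):
            s = random_interior_stratum(rng, kind="continuous")
            grads = delta_gradients("stratum", [s]).pairs
            f, theta = level_logit_function([s], [1.0])
            fd = finite_difference(f, theta)
            (gx, gy), = grads
            assert gx == pytest.approx(fd[0], rel=1e-5)
            assert gy == pytest.approx(fd[1], rel=1e-5)


class TestDeltaInterval:
    def test_zero_variance_collapses_to_point(self):
        ci = delta_ci(0.8, 0.0)
        assert ci.lower == ci.upper == pytest.approx(antilogit(0.8))

    def test_symmetric_logit_example(self):
        ci = delta_ci(0.0, 0.04)
        assert ci.lower == pytest.approx(antilogit(-0.392), abs=1e-6)
        assert ci.upper == pytest.approx(antilogit(0.392), abs=1e-6)

    # |F| is bounded by log(n^2) for counts, so +/-20 covers any real table;
    # beyond ~37 the antilogit saturates to 1.0 in double precision
    @given(F=st.floats(-20, 20), varF=st.floats(0, 25))
    @settings(max_examples=200, deadline=None)
    def test_always_strictly_inside_unit_interval(self, F, varF):
        ci = delta_ci(F, varF)
        assert 0.0 < ci.lower <= ci.upper < 1.0

    def test_undefined_estimate_flagged_not_raised(self):
        s = StratumSummary("R1", "F1", 0, 100, "binary", 10, 50)
        est = delta_estimate("stratum", [s])
        assert est.status is IntervalStatus.UNDEFINED
        assert math.isnan(est.lower)

    def test_large_n_agreement_with_exact_method(self):
        """Both are first-order intervals: endpoints agree at n = 1e5."""
        n = 100_000
        for px, py in [(0.3, 0.6), (0.5, 0.5), (0.7, 0.2)]:
            kx, ky = int(px * n), int(py * n)
            s = StratumSummary("R1", "F1", kx, n, "binary", ky, n)
            d = delta_estimate("stratum", [s])
            e = exact_ci(px * py, exact_variance_stratum(px, n, py, n))
            assert d.lower == pytest.approx(e.lower, abs=1e-3)
            assert d.upper == pytest.approx(e.upper, abs=1e-3)
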