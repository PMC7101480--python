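import numpy as np
import pandas as pd
import pytest

from effcov.simulation import (
    TABLE1_P_GRID,
    TABLE1_SIZE_PAIRS,
    SimulationConfig,
    SimulationSetting,
    grid_summary,
    run_grid,
    run_setting,
    simulate_dataset,
    table1_settings,
)

FAST = SimulationConfig(seed=123, inner_B=500)


class TestDataGeneration:
    def test_zero_truth_always_zero(self, rng):
        setting = SimulationSetting(0.0, 0.5, 50, 50)
        for _ in range(10):
            p_x_hat, _ = simulate_dataset(setting, rng)
            assert p_x_hat == 0.0

    def test_mean_recovery_clt_bound(self):
        """Mean of simulated proportions matches the truth within 3 sigma."""
        setting = SimulationSetting(0.3, 0.6, 100, 50)
        rng = np.random.default_rng(7)
        draws = np.array([simulate_dataset(setting, rng) for _ in range(2000)])
        se_x = np.sqrt(0.3 * 0.7 / (100 * 2000))
        se_y = np.sqrt(0.6 * 0.4 / (50 * 2000))
        assert abs(draws[:, 0].mean() - 0.3) < 3 * se_x
        assert abs(draws[:, 1].mean() - 0.6) < 3 * se_y

    def test_seeded_reproducibility(self):
        setting = SimulationSetting(0.3, 0.6, 100, 50)
        a = simulate_dataset(setting, np.random.default_rng(5))
        b = simulate_dataset(setting, np.random.default_rng(5))
        assert a == b

    def test_continuous_scores_have_requested_mean(self):
        setting = SimulationSetting(
            0.5, 0.6, 100, 200, readiness_kind="continuous", reps=1
        )
        rng = np.random.default_rng(3)
        means = [simulate_dataset(setting, rng)[1] for _ in range(500)]
        assert np.mean(means) == pytest.approx(0.6, abs=0.01)


class TestRunSetting:
    def test_accounting_identity(self):
        res = run_setting(
            SimulationSetting(0.1, 0.1, 50, 50, reps=2000), cfg=FAST
        )
        for mr in res.methods.values():
            assert mr.n_removed + mr.n_contributing == mr.n_total == 2000

    def test_method_specific_removal_rules(self):
        # at (0.02, 0.02, 50, 50) many iterations have an empty cell: the
        # delta method removes every boundary cell while exact/bootstrap
        # remove only zero products, so delta removes at least as many
        res = run_setting(
            SimulationSetting(0.02, 0.02, 50, 50, reps=2000),
            ("exact", "delta"), FAST,
        )
        assert res.methods["delta"].n_removed >= res.methods["exact"].n_removed

    def test_central_nominal_coverage_exact_delta(self):
        res = run_setting(
            SimulationSetting(0.5, 0.5, 500, 500, reps=10_000),
            ("exact", "delta"), FAST,
        )
        for m in ("exact", "delta"):
            assert 0.94 <= res.methods[m].coverage_probability <= 0.96

    def test_central_nominal_coverage_bootstrap(self):
        res = run_setting(
            SimulationSetting(0.5, 0.5, 500, 500, reps=2000),
            ("bootstrap",), SimulationConfig(seed=123, inner_B=1000),
        )
        assert 0.93 <= res.methods["bootstrap"].coverage_probability <= 0.97

    def test_delta_never_invalid_bootstrap_never_undefined(self):
        res = run_setting(
            SimulationSetting(0.04, 0.04, 50, 50, reps=1000), cfg=FAST
        )
        assert res.methods["delta"].n_invalid == 0
        assert res.methods["bootstrap"].n_invalid == 0
        # exact removals are degenerate products only; delta removals are
        # all boundary cells
        assert res.methods["bootstrap"].n_removed == res.methods["exact"].n_removed

    def test_continuous_readiness_runs_all_methods(self):
        res = run_setting(
            SimulationSetting(0.5, 0.5, 100, 25, readiness_kind="continuous",
                              reps=200),
            cfg=SimulationConfig(seed=9, inner_B=200),
        )
        for m, mr in res.methods.items():
            assert 0.8 <= mr.coverage_probability <= 1.0, m

    def test_no_information_flag(self):
        res = run_setting(
            SimulationSetting(0.0, 0.5, 50, 50, reps=50), ("exact", "delta"), FAST
        )
        assert res.no_information


class TestRunGrid:
    def test_single_setting_grid_matches_run_setting(self):
        setting = SimulationSetting(0.2, 0.3, 100, 50, reps=2000)
        df = run_grid([setting], ("exact", "delta"), FAST)
        res = run_setting(setting, ("exact", "delta"), FAST)
        for m in ("exact", "delta"):
            row = df[df.method == m].iloc[0]
            assert row.coverage_probability == res.methods[m].coverage_probability
            assert row.n_removed == res.methods[m].n_removed

    def test_master_seed_determinism_and_subset_reproduction(self):
        settings = [
            SimulationSetting(0.2, 0.3, 100, 50, reps=500),
            SimulationSetting(0.8, 0.9, 100, 50, reps=500),
        ]
        full = run_grid(settings, ("exact", "bootstrap"), FAST)
        again = run_grid(settings, ("exact", "bootstrap"), FAST)
        pd.testing.assert_frame_equal(full, again)
        # a one-setting run reproduces the matching cells of the full run
        sub = run_grid(settings[1:], ("exact", "bootstrap"), FAST)
        cols = ["coverage_probability", "n_removed", "n_invalid"]
        pd.testing.assert_frame_equal(
            full[full.P_x == 0.8][cols].reset_index(drop=True), sub[cols]
        )

    def test_standard_grid_size(self):
        grid = table1_settings(reps=10)
        assert len(grid) == len(TABLE1_P_GRID) ** 2 * len(TABLE1_SIZE_PAIRS)
        assert len(grid) == 6875

    def test_grid_summary_extrema(self):
        settings = [
            SimulationSetting(0.02, 0.02, 50, 50, reps=500),
            SimulationSetting(0.5, 0.5, 50, 50, reps=500),
        ]
        df = run_grid(settings, ("exact",), FAST)
        summ = grid_summary(df)
        row = summ[summ.method == "exact"].iloc[0]
        assert row.max_coverage >= row.min_coverage
        assert row.max_invalid_fraction > 0.9  # the extreme cell is ~all invalid

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_grid([], ("exact",), FAST)
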