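"""Sweep orchestration: determinism, seed scheme, read-outs, persistence, CLI."""

import math

import numpy as np
import pandas as pd
import pytest

from flyolf import (
    ExperimentConfig,
    ParameterError,
    SweepResult,
    argmax_connectivity,
    argmax_threshold,
    draw_odor_panel,
    encode_state,
    kc_response,
    mean_over_thresholds,
    mi_from_codes,
    read_results,
    render_heatmap,
    run_fly,
    sample_connectome,
    sweep,
    write_results,
)
from flyolf.circuit import ALState
from flyolf.experiments import _panel_entropy


def small_config(**over):
    base = dict(
        n_odors=3, n_trials=20, n_flies=3, theta=(1, 2, 3), r=0.3,
        concentration=0.5, alpha=None, seed=42,
    )
    base.update(over)
    return ExperimentConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_trials", 50),  # not divisible by 4
            ("n_trials", 4),  # too few for the quarter partitions
            ("theta", (0, 5)),
            ("r", (0.0,)),
            ("concentration", 1.5),
            ("alpha", -0.1),
            ("inhibition_activity", "mean"),
            ("log_base", 1.0),
        ],
    )
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ParameterError):
            small_config(**{field: value})

    def test_scalars_normalized_to_grids(self):
        cfg = small_config()
        assert cfg.r == (0.3,) and cfg.alpha == (None,)
        assert cfg.theta == (1, 2, 3)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(alpha=(None, 0.9), concentration=(0.15, 0.75))
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert ExperimentConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError):
            ExperimentConfig.from_dict({"n_odours": 5})


class TestRunFly:
    def test_same_seed_same_panel_same_mi(self):
        cfg = small_config(theta=2)
        panel = draw_odor_panel(3, 0.5, rng=np.random.default_rng(0))
        assert run_fly(cfg, panel, 7) == run_fly(cfg, panel, 7)

    def test_unreachable_threshold_gives_zero_mi(self):
        cfg = small_config(theta=60)  # above n_glomeruli: no KC can ever fire
        panel = draw_odor_panel(3, 0.5, rng=np.random.default_rng(0))
        assert run_fly(cfg, panel, 7) == 0.0

    def test_grid_config_rejected(self):
        cfg = small_config(theta=(1, 2))
        panel = draw_odor_panel(3, 0.5, rng=np.random.default_rng(0))
        with pytest.raises(ParameterError):
            run_fly(cfg, panel, 7)

    def test_deterministic_regime_matches_enumeration(self):
        """With c=1 and saturating gain every reachable OPN fires every
        trial, so the fly's MI equals the entropy of the deterministic
        odor->KC-state map, computable by direct enumeration."""
        cfg = small_config(n_odors=4, concentration=1.0, beta=1e3, theta=4,
                           n_trials=16)
        panel = draw_odor_panel(4, 1.0, rng=np.random.default_rng(1))
        fly_seed = 99
        conn = sample_connectome(
            cfg.n_kc, cfg.n_glomeruli, 0.3,
            np.random.default_rng(np.random.SeedSequence([fly_seed], spawn_key=(1,))),
        )
        codes = []
        for odor in panel:
            al = np.zeros(cfg.n_glomeruli, dtype=np.uint8)
            al[list(odor.reachable_opns)] = 1
            codes.append(encode_state(kc_response(conn, ALState(active=al), 4)))
        expected = mi_from_codes([[c] * cfg.n_trials for c in codes])
        assert run_fly(cfg, panel, fly_seed) == pytest.approx(expected, abs=1e-12)


class TestSweep:
    def test_end_to_end_deterministic(self):
        cfg = small_config(alpha=(None, 0.9))
        a, b = sweep(cfg), sweep(cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_worker_count_invariance(self):
        cfg = small_config()
        serial = sweep(cfg, jobs=1)
        parallel = sweep(cfg, jobs=2)
        pd.testing.assert_frame_equal(serial.table, parallel.table)

    def test_single_point_grid_reduces_to_run_fly_mean(self):
        cfg = small_config(theta=2)
        per_fly = []
        for f in range(cfg.n_flies):
            panel = draw_odor_panel(
                cfg.n_odors, cfg.concentration[0],
                rng=np.random.default_rng(
                    np.random.SeedSequence(_panel_entropy(cfg, 0, f))
                ),
            )
            per_fly.append(
                run_fly(cfg, panel, np.random.SeedSequence([cfg.seed, 0, 0, f]))
            )
        result = sweep(cfg)
        assert len(result.table) == 1
        assert result.table["mi_mean"].iloc[0] == pytest.approx(
            np.mean(per_fly), abs=1e-12
        )

    def test_row_count_is_grid_product(self):
        cfg = small_config(theta=(1, 2), r=(0.2, 0.4),
                           concentration=(0.3, 0.6), alpha=(None, 0.9))
        result = sweep(cfg)
        assert len(result.table) == 2 * 2 * 2 * 2
        assert result.table["mi_mean"].between(0, math.log2(cfg.n_odors)).all()

    def test_shared_panel_switch(self):
        shared = sweep(small_config(shared_panel=True))
        per_fly = sweep(small_config(shared_panel=False))
        assert not shared.table.equals(per_fly.table)


def synthetic_result(mi_by_theta, r=0.3):
    cfg = small_config(theta=tuple(range(1, len(mi_by_theta) + 1)))
    rows = [
        dict(n_kc=10, r=r, concentration=0.5, theta=t + 1, alpha=np.nan,
             mi_mean=mi, mi_sd=0.0, n_flies=3)
        for t, mi in enumerate(mi_by_theta)
    ]
    return SweepResult(table=pd.DataFrame(rows), config=cfg)


class TestReadouts:
    def test_single_theta_grid(self):
        assert argmax_threshold(synthetic_result([0.7])) == 1

    def test_monotone_decreasing_curve(self):
        assert argmax_threshold(synthetic_result([0.9, 0.5, 0.2, 0.1])) == 1

    def test_tie_broken_toward_smaller_theta(self):
        assert argmax_threshold(synthetic_result([0.1, 0.8, 0.8, 0.2])) == 2

    def test_filter_errors(self):
        result = synthetic_result([0.1, 0.2])
        with pytest.raises(ParameterError):
            argmax_threshold(result, fixed={"r": 0.9})  # no such rows
        two_r = SweepResult(
            table=pd.concat(
                [result.table, synthetic_result([0.3, 0.4], r=0.6).table],
                ignore_index=True,
            ),
            config=result.config,
        )
        with pytest.raises(ParameterError):
            argmax_threshold(two_r)  # ambiguous without fixing r

    def test_argmax_connectivity_dual_readout(self):
        result = synthetic_result([0.1, 0.2])
        two_r = SweepResult(
            table=pd.concat(
                [result.table, synthetic_result([0.3, 0.4], r=0.6).table],
                ignore_index=True,
            ),
            config=result.config,
        )
        assert argmax_connectivity(two_r, fixed={"theta": 2}) == 0.6

    def test_mean_over_thresholds_keeps_no_inhibition_rows(self):
        cfg = small_config(theta=(1, 2), alpha=(None, 0.9))
        out = mean_over_thresholds(sweep(cfg))
        assert len(out) == 2  # one aggregate row per alpha, incl. alpha=None
        assert out["alpha"].isna().sum() == 1


class TestPersistence:
    def test_csv_round_trip_exact(self, tmp_path):
        result = sweep(small_config(alpha=(None, 0.9)))
        path = tmp_path / "sweep.csv"
        write_results(result, path)
        back = read_results(path)
        pd.testing.assert_frame_equal(back.table, result.table)
        assert back.config == result.config

    def test_header_provenance(self, tmp_path):
        result = sweep(small_config())
        path = tmp_path / "sweep.csv"
        write_results(result, path)
        head = path.read_text().splitlines()[:3]
        assert head[0].startswith("# flyolf_version:")
        assert head[1] == "# seed: 42"
        assert head[2].startswith("# config:")

    def test_heatmap_written(self, tmp_path):
        result = sweep(small_config(theta=(1, 2, 3), r=(0.2, 0.5)))
        path = tmp_path / "surface.png"
        render_heatmap(result, path, fixed={"alpha": None})
        assert path.exists() and path.stat().st_size > 0


class TestCLI:
    def test_panel_command(self, tmp_path):
        from click.testing import CliRunner
        from flyolf.cli import main

        out = tmp_path / "panel.csv"
        res = CliRunner().invoke(
            main, ["panel", "--n-odors", "4", "--seed", "3", "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        from flyolf import OdorPanel

        assert len(OdorPanel.from_csv(out)) == 4

    def test_selftest_command(self):
        from click.testing import CliRunner
        from flyolf.cli import main

        res = CliRunner().invoke(main, ["selftest"])
        assert res.exit_code == 0, res.output

    def test_sweep_command_writes_results(self, tmp_path):
        from click.testing import CliRunner
        from flyolf.cli import main

        res = CliRunner().invoke(
            main,
            ["sweep", "--seed", "1", "--out-dir", str(tmp_path),
             "--n-flies", "2", "--n-trials", "20", "--n-odors", "3",
             "--theta", "1", "--theta", "2", "--r", "0.3",
             "--concentration", "0.5", "--alpha", "none"],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "sweep.csv").exists()
        assert len(read_results(tmp_path / "sweep.csv").table) == 2
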