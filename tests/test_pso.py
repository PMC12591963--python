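"""Swarm optimizer: update arithmetic, determinism, convergence, and the
multi-run harness."""

import numpy as np
import pytest

from rsmpso.pso import (
    EXPERIMENTAL_BOUNDS,
    REPRODUCTION_BOUNDS,
    ParticleState,
    SwarmConfig,
    export_contour_grid,
    export_trace_csv,
    inertia_at,
    multi_run,
    pso_maximize,
    run_seed_sequence,
    update_particle,
)
from rsmpso.registry import printed_model, registry_surfaces
from rsmpso.rsm import bounded_optimum


class TestSwarmConfig:
    def test_defaults_match_stated_hyperparameters(self):
        cfg = SwarmConfig()
        assert cfg.swarm_size == 10
        assert cfg.iterations == 40
        assert cfg.c1 == cfg.c2 == 0.10
        assert (cfg.w_start, cfg.w_end) == (0.90, 0.30)
        assert cfg.n_runs == 30
        assert cfg.bounds == REPRODUCTION_BOUNDS

    def test_validation_collects_all_problems(self):
        with pytest.raises(ValueError) as err:
            SwarmConfig(swarm_size=1, iterations=0, w_start=0.1, w_end=0.9)
        msg = str(err.value)
        assert "swarm_size" in msg and "iterations" in msg and "w_start" in msg


class TestInertia:
    def test_first_iteration(self):
        assert inertia_at(0, SwarmConfig()) == pytest.approx(0.90)

    def test_last_iteration(self):
        assert inertia_at(39, SwarmConfig()) == pytest.approx(0.30)

    def test_midpoint_of_odd_schedule(self):
        cfg = SwarmConfig(iterations=41)
        assert inertia_at(20, cfg) == pytest.approx(0.60)

    def test_linearity(self):
        cfg = SwarmConfig()
        ws = [inertia_at(t, cfg) for t in range(40)]
        diffs = np.diff(ws)
        np.testing.assert_allclose(diffs, diffs[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="iteration"):
            inertia_at(40, SwarmConfig())
        with pytest.raises(ValueError, match="iteration"):
            inertia_at(-1, SwarmConfig())


WIDE = ((0.0, 1000.0), (0.0, 1000.0))


class TestUpdateParticle:
    def test_pure_inertia_update(self):
        state = ParticleState(
            position=np.array([1.0, 2.0]),
            velocity=np.array([0.5, -0.5]),
            best_position=np.array([9.0, 9.0]),
            best_score=0.0,
        )
        new = update_particle(state, np.array([3.0, 3.0]),
                              w=1.0, c1=0.0, c2=0.0, r1=1.0, r2=1.0, bounds=WIDE)
        np.testing.assert_allclose(new.velocity, [0.5, -0.5])
        np.testing.assert_allclose(new.position, [1.5, 1.5])

    def test_attraction_vanishes_at_consensus(self):
        x = np.array([5.0, 5.0])
        state = ParticleState(position=x, velocity=np.array([1.0, -2.0]),
                              best_position=x.copy(), best_score=0.0)
        new = update_particle(state, x.copy(), w=0.7, c1=0.1, c2=0.1,
                              r1=0.3, r2=0.8, bounds=WIDE)
        np.testing.assert_allclose(new.velocity, [0.7, -1.4])

    def test_hand_worked_update(self):
        # v' = 0.9*1 + 0.1*1*(145-140) + 0.1*1*(150-140) = 2.4
        state = ParticleState(
            position=np.array([140.0, 400.0]),
            velocity=np.array([1.0, 0.0]),
            best_position=np.array([145.0, 400.0]),
            best_score=0.0,
        )
        new = update_particle(state, np.array([150.0, 400.0]),
                              w=0.9, c1=0.1, c2=0.1, r1=1.0, r2=1.0,
                              bounds=EXPERIMENTAL_BOUNDS)
        np.testing.assert_allclose(new.velocity, [2.4, 0.0])
        np.testing.assert_allclose(new.position, [142.4, 400.0])

    def test_position_clamped_velocity_untouched(self):
        state = ParticleState(
            position=np.array([149.0, 400.0]),
            velocity=np.array([5.0, 0.0]),
            best_position=np.array([149.0, 400.0]),
            best_score=0.0,
        )
        new = update_particle(state, np.array([149.0, 400.0]),
                              w=1.0, c1=0.0, c2=0.0, r1=0.5, r2=0.5,
                              bounds=REPRODUCTION_BOUNDS)
        assert new.position[0] == 150.0  # clamped to the upper bound
        assert new.velocity[0] == 5.0  # velocity left as-is

    def test_personal_best_refreshed_from_objective(self):
        surface = printed_model("firik", "taste")
        state = ParticleState(
            position=np.array([138.0, 390.0]),
            velocity=np.array([1.0, 3.0]),
            best_position=np.array([138.0, 390.0]),
            best_score=float(surface.evaluate(138.0, 390.0)),
        )
        new = update_particle(state, np.array([140.0, 396.5]),
                              w=0.9, c1=0.1, c2=0.1, r1=0.5, r2=0.5,
                              bounds=REPRODUCTION_BOUNDS, objective=surface)
        assert new.best_score >= state.best_score

    def test_rejects_r_outside_unit_interval(self):
        state = ParticleState(np.zeros(2), np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValueError, match="r1 and r2"):
            update_particle(state, np.zeros(2), 1, 0.1, 0.1, 1.5, 0.5, WIDE)


class TestPsoMaximize:
    def test_constant_objective_never_improves(self):
        trace = pso_maximize(lambda x1, x2: np.full_like(np.asarray(x1), 4.2),
                             SwarmConfig(seed=1))
        np.testing.assert_allclose(trace.best_scores, 4.2)

    def test_same_seed_identical_trace(self):
        surface = printed_model("siyez", "color")
        cfg = SwarmConfig(seed=11)
        a = pso_maximize(surface, cfg, run_index=3)
        b = pso_maximize(surface, cfg, run_index=3)
        np.testing.assert_array_equal(a.best_scores, b.best_scores)
        np.testing.assert_array_equal(a.best_positions, b.best_positions)

    def test_different_run_index_different_trace(self):
        surface = printed_model("siyez", "color")
        cfg = SwarmConfig(seed=11)
        a = pso_maximize(surface, cfg, run_index=0)
        b = pso_maximize(surface, cfg, run_index=1)
        assert not np.array_equal(a.best_positions, b.best_positions)

    def test_firik_taste_reaches_published_optimum(self):
        surface = printed_model("firik", "taste")
        summary = multi_run(surface, SwarmConfig(seed=0))
        assert summary.best_overall_score == pytest.approx(7.514, abs=0.005)
        assert summary.best_overall_position[0] == pytest.approx(140.0, abs=0.5)
        assert summary.best_overall_position[1] == pytest.approx(396.5, abs=3.0)

    def test_trace_length_and_monotonicity(self):
        trace = pso_maximize(printed_model("firik", "smell"), SwarmConfig(seed=5))
        assert len(trace.best_scores) == 41  # init + 40 iterations
        assert np.all(np.diff(trace.best_scores) >= 0)

    def test_positions_inside_bounds(self, all_surfaces):
        cfg = SwarmConfig(seed=2, n_runs=3)
        (lo1, hi1), (lo2, hi2) = cfg.bounds
        for surface in all_surfaces.values():
            summary = multi_run(surface, cfg)
            for trace in summary.traces:
                assert np.all(trace.best_positions[:, 0] >= lo1)
                assert np.all(trace.best_positions[:, 0] <= hi1)
                assert np.all(trace.best_positions[:, 1] >= lo2)
                assert np.all(trace.best_positions[:, 1] <= hi2)

    def test_non_finite_objective_reports_position(self):
        def bad(x1, x2):
            return np.where(np.asarray(x1) > 140.0, np.nan, 1.0)

        with pytest.raises(ValueError, match="non-finite"):
            pso_maximize(bad, SwarmConfig(seed=0))

    def test_velocity_clamp_honoured(self):
        surface = printed_model("siyez", "taste")
        cfg = SwarmConfig(seed=3, velocity_clamp=0.05)
        trace = pso_maximize(surface, cfg)
        assert np.all(np.diff(trace.best_scores) >= 0)


class TestMultiRun:
    def test_summary_invariants(self, all_surfaces):
        cfg = SwarmConfig(seed=7, n_runs=5)
        for surface in all_surfaces.values():
            s = multi_run(surface, cfg)
            assert s.mean_best <= s.best_overall_score + 1e-12
            assert s.sd_best >= 0
            assert len(s.traces) == 5

    def test_single_run_flagged(self):
        s = multi_run(printed_model("firik", "color"), SwarmConfig(seed=1, n_runs=1))
        assert s.single_run is True
        assert s.sd_best == 0.0

    def test_seed_determinism_byte_identical_serialization(self):
        surface = printed_model("karakilcik", "color")
        cfg = SwarmConfig(seed=123)
        assert multi_run(surface, cfg).to_json() == multi_run(surface, cfg).to_json()

    def test_firik_taste_thirty_run_spread(self):
        s = multi_run(printed_model("firik", "taste"), SwarmConfig(seed=0))
        assert s.best_overall_score == pytest.approx(7.514, abs=0.005)
        assert s.sd_best <= 0.01

    def test_karakilcik_smell_within_oracle(self):
        surface = printed_model("karakilcik", "smell")
        s = multi_run(surface, SwarmConfig(seed=0))
        _, _, oracle = bounded_optimum(surface, REPRODUCTION_BOUNDS)
        assert abs(s.best_overall_score - oracle) <= 0.01

    def test_oracle_equivalence_all_surfaces(self, all_surfaces):
        cfg = SwarmConfig(seed=0)
        for key, surface in all_surfaces.items():
            s = multi_run(surface, cfg)
            _, _, oracle = bounded_optimum(surface, cfg.bounds)
            assert abs(s.best_overall_score - oracle) <= 0.02, key

    def test_run_seed_sequence_is_stable(self):
        a = run_seed_sequence(5, 2).generate_state(4)
        b = run_seed_sequence(5, 2).generate_state(4)
        c = run_seed_sequence(5, 3).generate_state(4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestExports:
    def test_trace_csv_schema(self, tmp_path):
        trace = pso_maximize(printed_model("firik", "taste"), SwarmConfig(seed=1))
        path = tmp_path / "trace.csv"
        export_trace_csv(trace, path)
        header = path.read_text().splitlines()[0]
        assert header == "iteration,best_x1,best_x2,best_score"

    def test_contour_grid_shape_and_values(self, tmp_path):
        surface = printed_model("siyez", "taste")
        df = export_contour_grid(surface, REPRODUCTION_BOUNDS, resolution=11,
                                 path=tmp_path / "grid.csv")
        assert list(df.columns) == ["x1", "x2", "predicted"]
        assert len(df) == 121
        row = df.iloc[0]
        assert row["predicted"] == pytest.approx(
            surface.evaluate(row["x1"], row["x2"])
        )
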