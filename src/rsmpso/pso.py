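"""Global-best particle swarm maximizer with linear inertia decay.

Velocity and position updates follow the classic formulation

    v(t+1) = w(t) v(t) + c1 r1 (p_i - x) + c2 r2 (p_g - x)
    x(t+1) = x(t) + v(t+1)

with r1, r2 drawn uniformly in [0, 1] per particle per iteration and the
inertia weight decayed linearly from ``w_start`` at the first iteration to
``w_end`` at the last.  Positions are clamped to the search rectangle
component-wise (velocities are left untouched on clamp), which is what lets
boundary optima be attained exactly.  Maximization is native — no sign flip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "Bounds",
    "REPRODUCTION_BOUNDS",
    "EXPERIMENTAL_BOUNDS",
    "SwarmConfig",
    "ParticleState",
    "RunTrace",
    "MultiRunSummary",
    "inertia_at",
    "update_particle",
    "pso_maximize",
    "multi_run",
    "run_seed_sequence",
    "export_trace_csv",
    "export_contour_grid",
]

Bounds = tuple[tuple[float, float], tuple[float, float]]

#: rectangle on which every published optimum lies exactly on or inside
REPRODUCTION_BOUNDS: Bounds = ((135.0, 150.0), (375.0, 425.0))
#: full experimental factor region
EXPERIMENTAL_BOUNDS: Bounds = ((130.0, 150.0), (350.0, 450.0))


@dataclass(frozen=True)
class SwarmConfig:
    """Hyperparameters of the swarm and of the multi-run harness."""

    swarm_size: int = 10
    iterations: int = 40
    c1: float = 0.10
    c2: float = 0.10
    w_start: float = 0.90
    w_end: float = 0.30
    bounds: Bounds = REPRODUCTION_BOUNDS
    n_runs: int = 30
    seed: int = 0
    velocity_init_fraction: float = 0.10
    velocity_clamp: float | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.swarm_size < 2:
            problems.append(f"swarm_size must be >= 2 (got {self.swarm_size})")
        if self.iterations < 1:
            problems.append(f"iterations must be >= 1 (got {self.iterations})")
        if self.w_start < self.w_end:
            problems.append(
                f"w_start ({self.w_start}) must be >= w_end ({self.w_end})"
            )
        (lo1, hi1), (lo2, hi2) = self.bounds
        if not (lo1 < hi1 and lo2 < hi2):
            problems.append(f"bounds rectangle is empty: {self.bounds}")
        if self.n_runs < 1:
            problems.append(f"n_runs must be >= 1 (got {self.n_runs})")
        if problems:
            raise ValueError("; ".join(problems))

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[0][0], self.bounds[1][0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[0][1], self.bounds[1][1]])


@dataclass
class ParticleState:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_score: float


@dataclass
class RunTrace:
    """Per-iteration global-best history of one run.

    Index 0 is the post-initialization state; indices 1..iterations follow
    each update sweep.
    """

    best_positions: np.ndarray  # (iterations + 1, 2)
    best_scores: np.ndarray  # (iterations + 1,)
    seed: int

    @property
    def final_position(self) -> np.ndarray:
        return self.best_positions[-1]

    @property
    def final_score(self) -> float:
        return float(self.best_scores[-1])

    def plateau_iteration(self, tol: float = 0.01) -> int:
        """First iteration whose best-so-far is within ``tol`` of the final
        score."""
        hits = np.nonzero(self.best_scores >= self.final_score - tol)[0]
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.best_scores)),
                "best_x1": self.best_positions[:, 0],
                "best_x2": self.best_positions[:, 1],
                "best_score": self.best_scores,
            }
        )


@dataclass
class MultiRunSummary:
    traces: list[RunTrace]
    best_overall_score: float
    best_overall_position: np.ndarray
    mean_best: float
    sd_best: float
    master_seed: int
    single_run: bool = False

    @property
    def per_run_bests(self) -> np.ndarray:
        return np.array([t.final_score for t in self.traces])

    @property
    def best_trace(self) -> RunTrace:
        return self.traces[int(np.argmax(self.per_run_bests))]

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "n_runs": len(self.traces),
            "single_run": self.single_run,
            "best_overall_score": self.best_overall_score,
            "best_overall_position": [float(v) for v in self.best_overall_position],
            "mean_best": self.mean_best,
            "sd_best": self.sd_best,
            "per_run_bests": [float(v) for v in self.per_run_bests],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def inertia_at(t: int, config: SwarmConfig) -> float:
    """Linearly decayed inertia weight at (0-based) iteration ``t``."""
    if not 0 <= t < config.iterations:
        raise ValueError(
            f"iteration {t} outside schedule [0, {config.iterations})"
        )
    if config.iterations == 1:
        return config.w_start
    frac = t / (config.iterations - 1)
    return config.w_start + (config.w_end - config.w_start) * frac


def _as_objective(objective) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    evaluate = getattr(objective, "evaluate", None)
    return evaluate if callable(evaluate) else objective


def update_particle(
    state: ParticleState,
    global_best: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    r1: float,
    r2: float,
    bounds: Bounds,
    objective=None,
) -> ParticleState:
    """One velocity/position update for a single particle.

    ``r1``/``r2`` are the realized uniform draws (scalars) so that the
    update itself is deterministic and unit-testable.  If ``objective`` is
    given, the personal best is refreshed from the new position.
    """
    if not (0.0 <= r1 <= 1.0 and 0.0 <= r2 <= 1.0):
        raise ValueError("r1 and r2 must lie in [0, 1]")
    x = np.asarray(state.position, dtype=float)
    v = np.asarray(state.velocity, dtype=float)
    pbest = np.asarray(state.best_position, dtype=float)
    gbest = np.asarray(global_best, dtype=float)

    v_new = w * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
    lo = np.array([bounds[0][0], bounds[1][0]])
    hi = np.array([bounds[0][1], bounds[1][1]])
    x_new = np.clip(x + v_new, lo, hi)

    best_position, best_score = pbest, state.best_score
    if objective is not None:
        f = _as_objective(objective)
        score = float(f(x_new[0], x_new[1]))
        if score > best_score:
            best_position, best_score = x_new.copy(), score
    return ParticleState(
        position=x_new,
        velocity=v_new,
        best_position=best_position,
        best_score=best_score,
    )


def run_seed_sequence(master_seed: int, run_index: int) -> np.random.SeedSequence:
    """Deterministic per-run seed: the master seed and the run index are
    combined into one seed-sequence key (a splittable-generator contract —
    runs are independent streams, reproducible individually)."""
    return np.random.SeedSequence((master_seed, run_index))


def pso_maximize(objective, config: SwarmConfig, run_index: int = 0) -> RunTrace:
    """One swarm run.  ``objective`` is a response surface (anything with an
    ``evaluate(x1, x2)`` method) or a vectorized callable ``f(x1, x2)``."""
    f = _as_objective(objective)
    rng = np.random.default_rng(run_seed_sequence(config.seed, run_index))
    lo, hi = config.lower, config.upper
    span = hi - lo
    n = config.swarm_size

    X = rng.uniform(lo, hi, size=(n, 2))
    vmax0 = config.velocity_init_fraction * span
    V = rng.uniform(-vmax0, vmax0, size=(n, 2))

    scores = np.asarray(f(X[:, 0], X[:, 1]), dtype=float)
    _require_finite(scores, X)
    P = X.copy()
    P_scores = scores.copy()
    g = int(np.argmax(P_scores))
    g_pos, g_score = P[g].copy(), float(P_scores[g])

    best_positions = [g_pos.copy()]
    best_scores = [g_score]

    for t in range(config.iterations):
        w = inertia_at(t, config)
        r1 = rng.random((n, 1))
        r2 = rng.random((n, 1))
        V = w * V + config.c1 * r1 * (P - X) + config.c2 * r2 * (g_pos - X)
        if config.velocity_clamp is not None:
            vmax = config.velocity_clamp * span
            V = np.clip(V, -vmax, vmax)
        X = np.clip(X + V, lo, hi)
        scores = np.asarray(f(X[:, 0], X[:, 1]), dtype=float)
        _require_finite(scores, X)
        improved = scores > P_scores
        P[improved] = X[improved]
        P_scores[improved] = scores[improved]
        g = int(np.argmax(P_scores))
        if P_scores[g] > g_score:
            g_pos, g_score = P[g].copy(), float(P_scores[g])
        best_positions.append(g_pos.copy())
        best_scores.append(g_score)

    return RunTrace(
        best_positions=np.array(best_positions),
        best_scores=np.array(best_scores),
        seed=run_index,
    )


def _require_finite(scores: np.ndarray, X: np.ndarray) -> None:
    bad = ~np.isfinite(scores)
    if bad.any():
        where = X[bad][0]
        raise ValueError(
            f"objective returned a non-finite value at position "
            f"({where[0]:.6g}, {where[1]:.6g})"
        )


def multi_run(objective, config: SwarmConfig) -> MultiRunSummary:
    """Independent repeated runs with per-run seeds split from the master
    seed; summary statistics are over the per-run final bests (sample SD)."""
    traces = [
        pso_maximize(objective, config, run_index=i) for i in range(config.n_runs)
    ]
    bests = np.array([t.final_score for t in traces])
    i_best = int(np.argmax(bests))
    single = config.n_runs == 1
    sd = 0.0 if single else float(np.std(bests, ddof=1))
    return MultiRunSummary(
        traces=traces,
        best_overall_score=float(bests[i_best]),
        best_overall_position=traces[i_best].final_position.copy(),
        mean_best=float(bests.mean()),
        sd_best=sd,
        master_seed=config.seed,
        single_run=single,
    )


# ---------------------------------------------------------------------------
# data exports (convergence traces, contour grids)


def export_trace_csv(trace: RunTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def export_contour_grid(
    objective,
    bounds: Bounds,
    resolution: int = 101,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Long-format ``x1, x2, predicted`` grid for contour overlays."""
    f = _as_objective(objective)
    (lo1, hi1), (lo2, hi2) = bounds
    g1 = np.linspace(lo1, hi1, resolution)
    g2 = np.linspace(lo2, hi2, resolution)
    X1, X2 = np.meshgrid(g1, g2, indexing="ij")
    Z = f(X1, X2)
    df = pd.DataFrame(
        {"x1": X1.ravel(), "x2": X2.ravel(), "predicted": np.asarray(Z).ravel()}
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
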