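"""Synthetic sensory-panel generator.

Produces panel datasets with the statistical structure the analysis
assumes: a known quadratic truth surface sampled over a central composite
design, i.i.d. Gaussian score noise per panelist x run, optional clipping
to the 9-point hedonic range, and replicated centre points.  Used for
end-to-end testing and parameter-recovery studies in place of raw panel
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignTable
from .rsm import (
    PolynomialSurface,
    bounded_optimum,
    fit_quadratic,
    stationary_point,
)

__all__ = [
    "TruthSpec",
    "PanelTable",
    "HedonicClipWarning",
    "simulate_panel",
    "recovery_experiment",
    "RecoveryReport",
]

HEDONIC_RANGE = (1.0, 9.0)


class HedonicClipWarning(UserWarning):
    """Clipping moved a majority of scores: the truth surface and the
    hedonic scale are mismatched."""


@dataclass(frozen=True)
class TruthSpec:
    """Generating model for a synthetic panel."""

    surface: PolynomialSurface
    noise_sd: float = 0.0
    n_panelists: int = 50
    hedonic_clip: bool = True
    round_scores: bool = False
    panelist_sd: float = 0.0  # optional additive panelist random effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_panelists < 1:
            raise ValueError("n_panelists must be >= 1")
        if self.panelist_sd < 0:
            raise ValueError("panelist_sd must be >= 0")


@dataclass
class PanelTable:
    """Simulated panel in the published layout: per-run mean and SD, plus
    the long-format raw scores behind them."""

    summary: pd.DataFrame  # run, x1, x2, mean, sd
    raw: pd.DataFrame  # run, panelist, score

    def write_csv(self, summary_path: str | Path, raw_path: str | Path | None = None):
        self.summary.to_csv(summary_path, index=False)
        if raw_path is not None:
            self.raw.to_csv(raw_path, index=False)


def simulate_panel(truth: TruthSpec, design: DesignTable) -> PanelTable:
    """Draw one synthetic panel: ``score_ij = surface(x_i) + e_ij`` with
    ``e_ij ~ N(0, noise_sd^2)``, optionally clipped (and/or rounded) to the
    hedonic range."""
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    nat = design.natural_array
    n_runs = nat.shape[0]
    truth_vals = np.asarray(
        truth.surface.evaluate(nat[:, 0], nat[:, 1]), dtype=float
    )

    noise = rng.normal(0.0, truth.noise_sd, size=(n_runs, truth.n_panelists))
    scores = truth_vals[:, None] + noise
    if truth.panelist_sd > 0:
        scores = scores + rng.normal(0.0, truth.panelist_sd, size=truth.n_panelists)

    if truth.round_scores:
        scores = np.rint(scores)
    if truth.hedonic_clip:
        clipped = (scores < HEDONIC_RANGE[0]) | (scores > HEDONIC_RANGE[1])
        frac = float(clipped.mean())
        if frac > 0.5:
            warnings.warn(
                f"clipping moved {100 * frac:.0f}% of scores to the hedonic "
                "range; the truth surface does not live on this scale",
                HedonicClipWarning,
                stacklevel=2,
            )
        scores = np.clip(scores, *HEDONIC_RANGE)

    runs = [r.run for r in design.rows]
    summary = pd.DataFrame(
        {
            "run": runs,
            "x1": nat[:, 0],
            "x2": nat[:, 1],
            "mean": scores.mean(axis=1),
            "sd": scores.std(axis=1, ddof=1) if truth.n_panelists > 1 else 0.0,
        }
    )
    raw = pd.DataFrame(
        {
            "run": np.repeat(runs, truth.n_panelists),
            "panelist": np.tile(np.arange(1, truth.n_panelists + 1), n_runs),
            "score": scores.ravel(),
        }
    )
    return PanelTable(summary=summary, raw=raw)


@dataclass
class RecoveryReport:
    coefficient_bias: dict[str, float]
    coefficient_rmse: dict[str, float]
    argmax_error_mean: float
    argmax_error_rmse: float
    recovered_optima: np.ndarray  # (n_replicates, 2)
    n_replicates: int


def recovery_experiment(
    truth: TruthSpec,
    design: DesignTable,
    n_replicates: int,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> RecoveryReport:
    """Repeat simulate -> fit -> locate-optimum and report coefficient
    bias/RMSE and the distance between recovered and true optimum.

    The true optimum is the stationary point when it is an interior
    maximum, otherwise the grid-search optimum over ``bounds`` (defaulting
    to the design's factor bounds).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if bounds is None:
        bounds = tuple(
            (f.low_bound, f.high_bound) for f in design.factors
        )  # type: ignore[assignment]

    true_coefs = truth.surface.coefficients()
    sp = stationary_point(truth.surface)
    if sp.classification == "maximum" and _inside(sp, bounds):
        true_opt = np.array([sp.x1, sp.x2])
    else:
        x1o, x2o, _ = bounded_optimum(truth.surface, bounds)
        true_opt = np.array([x1o, x2o])

    names = list(true_coefs)
    errors = {k: [] for k in names}
    opt_errors = []
    optima = []
    for rep in range(n_replicates):
        rep_truth = TruthSpec(
            surface=truth.surface,
            noise_sd=truth.noise_sd,
            n_panelists=truth.n_panelists,
            hedonic_clip=truth.hedonic_clip,
            round_scores=truth.round_scores,
            panelist_sd=truth.panelist_sd,
            seed=int(np.random.SeedSequence((truth.seed, rep)).generate_state(1)[0]),
        )
        panel = simulate_panel(rep_truth, design)
        fit = fit_quadratic(design, panel.summary["mean"].to_numpy())
        fitted_coefs = fit.surface.coefficients()
        for k in names:
            errors[k].append(fitted_coefs[k] - true_coefs[k])
        spf = stationary_point(fit.surface)
        if spf.classification == "maximum" and _inside(spf, bounds):
            opt = np.array([spf.x1, spf.x2])
        else:
            x1o, x2o, _ = bounded_optimum(fit.surface, bounds)
            opt = np.array([x1o, x2o])
        optima.append(opt)
        opt_errors.append(float(np.linalg.norm(opt - true_opt)))

    opt_errors = np.array(opt_errors)
    return RecoveryReport(
        coefficient_bias={k: float(np.mean(errors[k])) for k in names},
        coefficient_rmse={
            k: float(np.sqrt(np.mean(np.square(errors[k])))) for k in names
        },
        argmax_error_mean=float(opt_errors.mean()),
        argmax_error_rmse=float(np.sqrt(np.mean(opt_errors**2))),
        recovered_optima=np.array(optima),
        n_replicates=n_replicates,
    )


def _inside(sp, bounds) -> bool:
    (lo1, hi1), (lo2, hi2) = bounds
    return lo1 <= sp.x1 <= hi1 and lo2 <= sp.x2 <= hi2
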