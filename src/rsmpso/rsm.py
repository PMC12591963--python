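"""Second-order response surfaces: representation, fitting, diagnostics,
and analytic / brute-force optimization.

Surfaces are stored as explicit monomial term lists rather than coefficient
vectors so that a source that prints the same monomial twice can be kept
verbatim; evaluation sums duplicates and :meth:`PolynomialSurface.merged`
produces the canonical six-coefficient view.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .design import DesignTable

__all__ = [
    "PolynomialSurface",
    "AnovaRow",
    "FitSummary",
    "RankDeficientDesignError",
    "evaluate_surface",
    "fit_quadratic",
    "anova_decompose",
    "stationary_point",
    "StationaryPoint",
    "bounded_optimum",
    "percent_difference",
]

Provenance = Literal["printed", "fitted", "synthetic"]

#: monomial order of the canonical quadratic: 1, X1, X2, X1^2, X2^2, X1*X2
CANONICAL_EXPONENTS: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 0), (0, 1), (2, 0), (0, 2), (1, 1),
)
_COEF_NAMES = ("b0", "b1", "b2", "b11", "b22", "b12")


@dataclass(frozen=True)
class PolynomialSurface:
    """A bivariate polynomial of total degree <= 2 as a term list.

    ``terms`` holds ``(coefficient, p, q)`` triples meaning
    ``coefficient * X1**p * X2**q``.  Duplicate monomials are allowed and
    contribute additively.
    """

    terms: tuple[tuple[float, int, int], ...]
    label: str = ""
    provenance: Provenance = "fitted"

    def __post_init__(self) -> None:
        for coef, p, q in self.terms:
            if p < 0 or q < 0 or p + q > 2:
                raise ValueError(f"term X1^{p} X2^{q} exceeds total degree 2")

    def evaluate(self, x1, x2):
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        out = np.zeros(np.broadcast_shapes(x1.shape, x2.shape))
        for coef, p, q in self.terms:
            out = out + coef * x1**p * x2**q
        return out if out.ndim else float(out)

    __call__ = evaluate

    def merged(self) -> "PolynomialSurface":
        """Canonical form with duplicate monomials summed."""
        acc: dict[tuple[int, int], float] = {}
        for coef, p, q in self.terms:
            acc[(p, q)] = acc.get((p, q), 0.0) + coef
        terms = tuple(
            (acc[e], *e) for e in CANONICAL_EXPONENTS if e in acc
        )
        return replace(self, terms=terms)

    def coefficients(self) -> dict[str, float]:
        """The canonical ``b0, b1, b2, b11, b22, b12`` view."""
        merged = {(p, q): c for c, p, q in self.merged().terms}
        return {
            name: merged.get(expo, 0.0)
            for name, expo in zip(_COEF_NAMES, CANONICAL_EXPONENTS)
        }

    @classmethod
    def from_coefficients(
        cls,
        b0: float = 0.0,
        b1: float = 0.0,
        b2: float = 0.0,
        b11: float = 0.0,
        b22: float = 0.0,
        b12: float = 0.0,
        label: str = "",
        provenance: Provenance = "fitted",
    ) -> "PolynomialSurface":
        vals = (b0, b1, b2, b11, b22, b12)
        terms = tuple(
            (v, *e) for v, e in zip(vals, CANONICAL_EXPONENTS) if v != 0.0
        ) or ((0.0, 0, 0),)
        return cls(terms=terms, label=label, provenance=provenance)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "provenance": self.provenance,
            "terms": [[c, p, q] for c, p, q in self.terms],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialSurface":
        return cls(
            terms=tuple((float(c), int(p), int(q)) for c, p, q in d["terms"]),
            label=d.get("label", ""),
            provenance=d.get("provenance", "fitted"),
        )


def evaluate_surface(surface: PolynomialSurface, x1, x2):
    """Functional alias for :meth:`PolynomialSurface.evaluate`."""
    return surface.evaluate(x1, x2)


# ---------------------------------------------------------------------------
# fitting


class RankDeficientDesignError(ValueError):
    """Raised when the quadratic design matrix is rank-deficient; carries the
    names of the dependent monomial columns."""

    def __init__(self, dependent: Sequence[str]):
        self.dependent = list(dependent)
        super().__init__(
            "design matrix is rank-deficient; dependent monomial columns: "
            + ", ".join(self.dependent)
        )


@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    f: float | None
    p: float | None


@dataclass
class FitSummary:
    """OLS fit of the full quadratic, with ``r2`` and ``adj_r2`` reported
    as percentages (the scale the source tables use)."""

    surface: PolynomialSurface
    r2: float
    adj_r2: float
    residuals: np.ndarray
    fitted: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    response: np.ndarray
    anova: list[AnovaRow] = field(default_factory=list)
    lack_of_fit_defined: bool | None = None

    def predict(self, x1, x2):
        return self.surface.evaluate(x1, x2)


_MONOMIAL_NAMES = ("1", "X1", "X2", "X1^2", "X2^2", "X1*X2")


def _model_matrix(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [x1**p * x2**q for p, q in CANONICAL_EXPONENTS]
    )


def _design_xy(design: "DesignTable | np.ndarray") -> tuple[np.ndarray, np.ndarray]:
    if isinstance(design, DesignTable):
        nat = design.natural_array
        return nat[:, 0], nat[:, 1]
    arr = np.asarray(design, dtype=float)
    return arr[:, 0], arr[:, 1]


def fit_quadratic(
    design: "DesignTable | np.ndarray",
    responses: Sequence[float],
    label: str = "",
) -> FitSummary:
    """Ordinary least squares fit of the full second-order model in natural
    units.  ``design`` is a :class:`DesignTable` or an (n, 2) array of
    natural (X1, X2) settings."""
    x1, x2 = _design_xy(design)
    y = np.asarray(responses, dtype=float)
    if y.shape[0] != x1.shape[0]:
        raise ValueError(
            f"{y.shape[0]} responses for {x1.shape[0]} design rows"
        )
    n_distinct = len({(a, b) for a, b in zip(x1, x2)})
    if n_distinct < 6:
        raise ValueError(
            f"need >= 6 distinct design points to fit a quadratic, "
            f"got {n_distinct}"
        )
    X = _model_matrix(x1, x2)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns that do not increase the rank when appended
        dependent = []
        cols: list[np.ndarray] = []
        for j, name in enumerate(_MONOMIAL_NAMES):
            trial = np.column_stack(cols + [X[:, j]]) if cols else X[:, [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                dependent.append(name)
            else:
                cols.append(X[:, j])
        raise RankDeficientDesignError(dependent)

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    n, p = X.shape
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")
    surface = PolynomialSurface.from_coefficients(
        *coef, label=label or "fitted quadratic", provenance="fitted"
    )
    return FitSummary(
        surface=surface,
        r2=100.0 * r2,
        adj_r2=100.0 * adj,
        residuals=resid,
        fitted=fitted,
        x1=x1,
        x2=x2,
        response=y,
    )


def _f_pvalue(f: float, df1: int, df2: int) -> float:
    from scipy.stats import f as f_dist

    return float(f_dist.sf(f, df1, df2))


def anova_decompose(fit: FitSummary, design: "DesignTable | None" = None) -> FitSummary:
    """Partition the response sum of squares by model source.

    Per-term rows use adjusted (partial) sums of squares — the SSE increase
    when that single monomial is dropped from the full model — mirroring
    standard DoE-software output.  The residual is split into lack-of-fit
    and pure error using replicated design points; when the replicates are
    identical the pure-error SS is zero and the lack-of-fit F is flagged
    undefined rather than fabricated.
    """
    x1, x2, y = fit.x1, fit.x2, fit.response
    n = y.shape[0]
    X = _model_matrix(x1, x2)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse_full = float(((y - X @ coef) ** 2).sum())
    df_resid = n - X.shape[1]
    ms_resid = sse_full / df_resid if df_resid > 0 else float("nan")

    sources = {
        "linear X1": 1,
        "linear X2": 2,
        "square X1": 3,
        "square X2": 4,
        "interaction": 5,
    }
    rows: list[AnovaRow] = []
    for name, j in sources.items():
        keep = [k for k in range(X.shape[1]) if k != j]
        c_red, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
        sse_red = float(((y - X[:, keep] @ c_red) ** 2).sum())
        ss = sse_red - sse_full
        if df_resid > 0 and ms_resid > 0:
            f_stat = ss / ms_resid
            rows.append(AnovaRow(name, ss, 1, f_stat, _f_pvalue(f_stat, 1, df_resid)))
        else:
            rows.append(AnovaRow(name, ss, 1, None, None))

    # pure error from replicate groups
    groups: dict[tuple[float, float], list[float]] = {}
    for a, b, v in zip(x1, x2, y):
        groups.setdefault((a, b), []).append(v)
    ss_pe = sum(
        float(((np.array(vals) - np.mean(vals)) ** 2).sum())
        for vals in groups.values()
    )
    # identical replicates give SS that is zero up to round-off
    if ss_pe <= 1e-12 * max(1.0, float(y @ y)):
        ss_pe = 0.0
    df_pe = n - len(groups)
    ss_lof = sse_full - ss_pe
    df_lof = df_resid - df_pe

    lof_defined = ss_pe > 0 and df_pe > 0 and df_lof > 0
    if lof_defined:
        f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        rows.append(AnovaRow("lack-of-fit", ss_lof, df_lof,
                             f_lof, _f_pvalue(f_lof, df_lof, df_pe)))
    else:
        rows.append(AnovaRow("lack-of-fit", ss_lof, df_lof, None, None))
    rows.append(AnovaRow("pure error", ss_pe, df_pe, None, None))

    fit.anova = rows
    fit.lack_of_fit_defined = lof_defined
    return fit


# ---------------------------------------------------------------------------
# optimization


@dataclass(frozen=True)
class StationaryPoint:
    x1: float
    x2: float
    classification: Literal["maximum", "minimum", "saddle", "degenerate"]


def stationary_point(surface: PolynomialSurface) -> StationaryPoint:
    """Solve the 2x2 gradient system of the (merged) quadratic and classify
    the critical point from Hessian definiteness."""
    c = surface.coefficients()
    H = np.array([[2 * c["b11"], c["b12"]], [c["b12"], 2 * c["b22"]]])
    g = np.array([c["b1"], c["b2"]])
    det = float(np.linalg.det(H))
    if abs(det) < 1e-300 or not math.isfinite(det) or det == 0.0:
        return StationaryPoint(float("nan"), float("nan"), "degenerate")
    x = np.linalg.solve(H, -g)
    if det < 0:
        kind = "saddle"
    elif H[0, 0] < 0:
        kind = "maximum"
    else:
        kind = "minimum"
    return StationaryPoint(float(x[0]), float(x[1]), kind)


def bounded_optimum(
    surface: PolynomialSurface,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    grid_step: float = 0.001,
    coarse_points: int = 301,
) -> tuple[float, float, float]:
    """Maximize over a rectangle by exhaustive grid search, refined once
    around the best coarse cell at ``grid_step`` resolution.

    Serves as the independent brute-force oracle for the swarm optimizer.
    """
    (lo1, hi1), (lo2, hi2) = bounds
    if not (lo1 < hi1 and lo2 < hi2):
        raise ValueError(f"empty search rectangle {bounds}")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")

    g1 = np.linspace(lo1, hi1, coarse_points)
    g2 = np.linspace(lo2, hi2, coarse_points)
    X1, X2 = np.meshgrid(g1, g2, indexing="ij")
    V = surface.evaluate(X1, X2)
    i, j = np.unravel_index(np.argmax(V), V.shape)

    c1 = (hi1 - lo1) / (coarse_points - 1)
    c2 = (hi2 - lo2) / (coarse_points - 1)
    f1 = _refined_axis(g1[i], c1, lo1, hi1, grid_step)
    f2 = _refined_axis(g2[j], c2, lo2, hi2, grid_step)
    F1, F2 = np.meshgrid(f1, f2, indexing="ij")
    W = surface.evaluate(F1, F2)
    k = np.unravel_index(np.argmax(W), W.shape)
    return float(F1[k]), float(F2[k]), float(W[k])


def _refined_axis(
    center: float, cell: float, lo: float, hi: float, step: float
) -> np.ndarray:
    a = max(lo, center - cell)
    b = min(hi, center + cell)
    n = max(2, int(round((b - a) / step)) + 1)
    return np.linspace(a, b, n)


def percent_difference(
    predicted: float,
    experimental: float,
    denominator: Literal["experimental", "predicted"] = "experimental",
) -> float:
    """``100 * |predicted - experimental| / denominator``.

    The published tables are consistent with an experimental-value
    denominator in 11 of 12 cells (the remaining one with a predicted
    denominator), so both conventions are available.
    """
    denom = experimental if denominator == "experimental" else predicted
    if denom == 0:
        raise ZeroDivisionError("percent difference denominator is zero")
    return 100.0 * abs(predicted - experimental) / abs(denom)
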