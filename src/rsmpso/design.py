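"""Two-factor central composite designs with coded/natural level conversion.

A five-level CCD consists of a 2**k factorial block (coded levels ±1),
2*k axial points (±alpha) and a block of replicated centre points (0).
Factors map coded levels to natural units either through an explicit
``level_map`` (which may deliberately disagree with linear scaling, as
happens when axial settings are rounded to convenient amounts) or through
the linear rule ``center + level * step``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignRow",
    "DesignTable",
    "build_ccd",
    "code_to_natural",
    "natural_to_code",
    "reference_factors",
    "reference_design",
    "DESIGN_ALPHA",
]

#: axial distance used throughout, kept at two decimals rather than sqrt(2)
DESIGN_ALPHA = 1.41

_LEVEL_TOL = 1e-9


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor and its coded-to-natural mapping."""

    name: str
    center: float
    step: float
    level_map: Mapping[float, float] | None = None
    low_bound: float | None = None
    high_bound: float | None = None

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be positive")
        if self.level_map is not None:
            keys = sorted(self.level_map)
            vals = [self.level_map[k] for k in keys]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"factor {self.name!r}: level_map must be strictly increasing "
                    f"in the coded level, got {dict(zip(keys, vals))}"
                )
            if 0.0 in self.level_map and self.level_map[0.0] != self.center:
                raise ValueError(
                    f"factor {self.name!r}: level_map[0] = {self.level_map[0.0]} "
                    f"disagrees with center = {self.center}"
                )
        if (
            self.low_bound is not None
            and self.high_bound is not None
            and not self.low_bound < self.high_bound
        ):
            raise ValueError(f"factor {self.name!r}: low_bound must be < high_bound")

    def _lookup(self, level: float) -> float | None:
        if self.level_map is None:
            return None
        for k, v in self.level_map.items():
            if abs(k - level) <= _LEVEL_TOL:
                return v
        return None


def code_to_natural(level: float, factor: FactorSpec) -> float:
    """Convert a coded level to natural units.

    Design levels present in the factor's ``level_map`` are looked up
    verbatim; anything else falls back to ``center + level * step``.
    Levels outside the hull of the map's keys are rejected.
    """
    hit = factor._lookup(level)
    if hit is not None:
        return hit
    if factor.level_map is not None:
        lo, hi = min(factor.level_map), max(factor.level_map)
        if not lo - _LEVEL_TOL <= level <= hi + _LEVEL_TOL:
            raise ValueError(
                f"coded level {level} outside the hull [{lo}, {hi}] of "
                f"factor {factor.name!r}"
            )
    return factor.center + level * factor.step


def natural_to_code(value: float, factor: FactorSpec) -> float:
    """Inverse of :func:`code_to_natural` (exact on design levels)."""
    if factor.level_map is not None:
        for k, v in factor.level_map.items():
            if abs(v - value) <= _LEVEL_TOL:
                return k
    return (value - factor.center) / factor.step


@dataclass(frozen=True)
class DesignRow:
    run: int
    coded: tuple[float, ...]
    natural: tuple[float, ...]


@dataclass
class DesignTable:
    """An ordered list of design runs plus the fixed recipe constants."""

    factors: Sequence[FactorSpec]
    rows: Sequence[DesignRow]
    n_center: int
    alpha: float = DESIGN_ALPHA
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_zero = sum(1 for r in self.rows if all(c == 0 for c in r.coded))
        if n_zero != self.n_center:
            raise ValueError(
                f"{n_zero} all-zero rows but n_center = {self.n_center}"
            )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def coded_array(self) -> np.ndarray:
        return np.array([r.coded for r in self.rows], dtype=float)

    @property
    def natural_array(self) -> np.ndarray:
        return np.array([r.natural for r in self.rows], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rec = {"run": [r.run for r in self.rows]}
        for j, f in enumerate(self.factors):
            rec[f"x{j + 1}_coded"] = [r.coded[j] for r in self.rows]
        for j, f in enumerate(self.factors):
            rec[f"x{j + 1}_natural"] = [r.natural[j] for r in self.rows]
        return pd.DataFrame(rec)

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if self.constants:
            sidecar = path.with_suffix(".constants.json")
            sidecar.write_text(json.dumps(dict(self.constants), sort_keys=True))

    @classmethod
    def read_csv(cls, path: str | Path, factors: Sequence[FactorSpec]) -> "DesignTable":
        path = Path(path)
        df = pd.read_csv(path)
        k = len(factors)
        rows = [
            DesignRow(
                run=int(rec["run"]),
                coded=tuple(float(rec[f"x{j + 1}_coded"]) for j in range(k)),
                natural=tuple(float(rec[f"x{j + 1}_natural"]) for j in range(k)),
            )
            for rec in df.to_dict("records")
        ]
        constants: dict[str, float] = {}
        sidecar = path.with_suffix(".constants.json")
        if sidecar.exists():
            constants = json.loads(sidecar.read_text())
        n_center = sum(1 for r in rows if all(c == 0 for c in r.coded))
        return cls(factors=list(factors), rows=rows, n_center=n_center,
                   constants=constants)


def build_ccd(
    factors: Sequence[FactorSpec],
    n_center: int,
    alpha: float = DESIGN_ALPHA,
    constants: Mapping[str, float] | None = None,
    permutation_seed: int | None = None,
) -> DesignTable:
    """Build a central composite design: factorial, axial, then centre runs.

    Run order is deterministic (factorial block, axial block, centre block)
    unless ``permutation_seed`` is given, in which case the rows are
    shuffled reproducibly and run ids follow the shuffled order.
    """
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    if alpha <= 1:
        raise ValueError(f"alpha must exceed 1, got {alpha}")
    k = len(factors)
    if k < 2:
        raise ValueError("a CCD needs at least two factors")

    coded_rows: list[tuple[float, ...]] = []
    coded_rows.extend(itertools.product((-1.0, 1.0), repeat=k))
    for j in range(k):
        for a in (-alpha, alpha):
            point = [0.0] * k
            point[j] = a
            coded_rows.append(tuple(point))
    coded_rows.extend([(0.0,) * k] * n_center)

    if permutation_seed is not None:
        rng = np.random.default_rng(permutation_seed)
        order = rng.permutation(len(coded_rows))
        coded_rows = [coded_rows[i] for i in order]

    rows = [
        DesignRow(
            run=i + 1,
            coded=coded,
            natural=tuple(code_to_natural(c, f) for c, f in zip(coded, factors)),
        )
        for i, coded in enumerate(coded_rows)
    ]
    return DesignTable(
        factors=list(factors),
        rows=rows,
        n_center=n_center,
        alpha=alpha,
        constants=dict(constants or {}),
    )


def reference_factors() -> tuple[FactorSpec, FactorSpec]:
    """The bulgur (g) and water (mL) factors of the published experiment.

    The axial naturals (130/150 g, 350/450 mL) were rounded by the
    original experimenters and are inconsistent with linear +/-1.41
    scaling, hence the explicit level maps.
    """
    x1 = FactorSpec(
        name="bulgur_g",
        center=140.0,
        step=5.0,
        level_map={-1.41: 130.0, -1.0: 135.0, 0.0: 140.0, 1.0: 145.0, 1.41: 150.0},
        low_bound=130.0,
        high_bound=150.0,
    )
    x2 = FactorSpec(
        name="water_ml",
        center=400.0,
        step=25.0,
        level_map={-1.41: 350.0, -1.0: 375.0, 0.0: 400.0, 1.0: 425.0, 1.41: 450.0},
        low_bound=350.0,
        high_bound=450.0,
    )
    return x1, x2


# run order of the published 13-run listing (coded levels)
_REFERENCE_ORDER: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (1.41, 0.0),
    (0.0, 0.0),
    (0.0, 0.0),
    (-1.0, 1.0),
    (1.0, 1.0),
    (1.0, -1.0),
    (0.0, -1.41),
    (0.0, 1.41),
    (0.0, 0.0),
    (-1.0, -1.0),
    (0.0, 0.0),
    (-1.41, 0.0),
)


def reference_design() -> DesignTable:
    """The published 13-run design in its printed run order."""
    factors = reference_factors()
    rows = [
        DesignRow(
            run=i + 1,
            coded=coded,
            natural=tuple(code_to_natural(c, f) for c, f in zip(coded, factors)),
        )
        for i, coded in enumerate(_REFERENCE_ORDER)
    ]
    return DesignTable(
        factors=list(factors),
        rows=rows,
        n_center=5,
        alpha=DESIGN_ALPHA,
        constants={"butter_g": 14.0, "salt_g": 2.0},
    )
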