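"""Closed-form quality metrics: radical-scavenging percent inhibition and
CIELAB-derived chroma, hue angle and total color difference."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ColorPoint",
    "AbsorbancePair",
    "dpph_inhibition",
    "chroma",
    "hue_angle",
    "delta_e",
    "read_color_table",
    "color_metrics_table",
]


@dataclass(frozen=True)
class ColorPoint:
    """CIELAB coordinates: L (lightness), a (green-red), b (blue-yellow)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.L, self.a, self.b)):
            raise ValueError("color coordinates must be finite")


@dataclass(frozen=True)
class AbsorbancePair:
    """Control and sample absorbances of a radical-scavenging assay."""

    A0: float
    A1: float

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError(f"control absorbance A0 must be positive, got {self.A0}")
        if self.A1 < 0:
            raise ValueError(f"sample absorbance A1 must be >= 0, got {self.A1}")


def dpph_inhibition(pair: AbsorbancePair) -> float:
    """Percent inhibition ``(A0 - A1) / A0 * 100``."""
    return (pair.A0 - pair.A1) / pair.A0 * 100.0


def chroma(color: ColorPoint) -> float:
    """Color intensity ``sqrt(a^2 + b^2)``."""
    return math.hypot(color.a, color.b)


def hue_angle(color: ColorPoint) -> float:
    """Hue in degrees in [0, 360), via the quadrant-correct two-argument
    arctangent (a bare ``atan(b/a)`` flips sign silently for a < 0)."""
    if color.a == 0 and color.b == 0:
        raise ValueError("hue undefined at a = b = 0")
    deg = math.degrees(math.atan2(color.b, color.a))
    return deg % 360.0


def delta_e(c1: ColorPoint, c2: ColorPoint) -> float:
    """Euclidean color difference in (L, a, b).  The reference color is
    caller-supplied; no default is assumed."""
    return math.sqrt(
        (c1.L - c2.L) ** 2 + (c1.a - c2.a) ** 2 + (c1.b - c2.b) ** 2
    )


def read_color_table(path: str | Path) -> dict[str, ColorPoint]:
    """Read a ``sample,L,a,b`` CSV into named color points."""
    df = pd.read_csv(path)
    missing = {"sample", "L", "a", "b"} - set(df.columns)
    if missing:
        raise ValueError(f"color table missing columns: {sorted(missing)}")
    return {
        str(r["sample"]): ColorPoint(float(r["L"]), float(r["a"]), float(r["b"]))
        for r in df.to_dict("records")
    }


def color_metrics_table(
    colors: dict[str, ColorPoint], path: str | Path | None = None
) -> pd.DataFrame:
    """Chroma and hue per sample, written as ``sample,C,h`` when ``path``
    is given."""
    df = pd.DataFrame(
        {
            "sample": list(colors),
            "C": [chroma(c) for c in colors.values()],
            "h": [hue_angle(c) for c in colors.values()],
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
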