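"""Registry of the twelve published response polynomials and the published
run-level response tables.

Coefficients are transcribed verbatim from the source equations, anomalies
included: the Siyez general-acceptance model prints the X1*X2 monomial
twice (with coefficients -0.004444 and +0.002299) and carries no X1^2
term.  The verbatim form is what reproduces the published optimization
results; :func:`corrected_model` offers the plausible reading of the first
cross term as X1^2, clearly flagged and never used for validation.
"""

from __future__ import annotations

from importlib import resources
from typing import Literal

import pandas as pd

from .rsm import PolynomialSurface

__all__ = [
    "VARIETIES",
    "RESPONSES",
    "printed_model",
    "corrected_model",
    "registry_surfaces",
    "load_response_table",
    "load_validation_row",
    "PRINTED_R2",
]

Variety = Literal["siyez", "firik", "karakilcik"]
Response = Literal["taste", "color", "smell", "general_acceptance"]

VARIETIES: tuple[str, ...] = ("siyez", "firik", "karakilcik")
RESPONSES: tuple[str, ...] = ("taste", "color", "smell", "general_acceptance")

# term lists: (coefficient, exponent of X1, exponent of X2)
_PRINTED: dict[tuple[str, str], tuple[tuple[float, int, int], ...]] = {
    ("siyez", "taste"): (
        (-171.9, 0, 0), (2.298, 1, 0), (-0.1073, 0, 1),
        (-0.004678, 2, 0), (-0.000283, 0, 2), (0.002420, 1, 1),
    ),
    ("siyez", "color"): (
        (28.3, 0, 0), (-0.977, 1, 0), (0.2183, 0, 1),
        (0.005856, 2, 0), (0.000014, 0, 2), (-0.001593, 1, 1),
    ),
    ("siyez", "smell"): (
        (153.8, 0, 0), (-1.744, 1, 0), (-0.1675, 0, 1),
        (0.008797, 2, 0), (0.000472, 0, 2), (-0.001520, 1, 1),
    ),
    # as printed: two X1*X2 terms, no X1^2 term
    ("siyez", "general_acceptance"): (
        (-0.6, 0, 0), (0.354, 1, 0), (-0.1019, 0, 1),
        (-0.004444, 1, 1), (-0.000269, 0, 2), (0.002299, 1, 1),
    ),
    ("firik", "taste"): (
        (-171.9, 0, 0), (2.298, 1, 0), (0.0935, 0, 1),
        (-0.009795, 2, 0), (-0.000316, 0, 2), (0.001122, 1, 1),
    ),
    ("firik", "color"): (
        (159.0, 0, 0), (-2.200, 1, 0), (-0.0015, 0, 1),
        (0.006303, 2, 0), (-0.000171, 0, 2), (0.001075, 1, 1),
    ),
    ("firik", "smell"): (
        (397.6, 0, 0), (-3.481, 1, 0), (-0.8012, 0, 1),
        (0.008632, 2, 0), (0.000504, 0, 2), (0.002964, 1, 1),
    ),
    ("firik", "general_acceptance"): (
        (519.4, 0, 0), (-3.620, 1, 0), (-1.3146, 0, 1),
        (0.001766, 2, 0), (0.000293, 0, 2), (0.007817, 1, 1),
    ),
    ("karakilcik", "taste"): (
        (-73.69, 0, 0), (1.5937, 1, 0), (-0.16647, 0, 1),
        (-0.007803, 2, 0), (-0.000033, 0, 2), (0.001464, 1, 1),
    ),
    ("karakilcik", "color"): (
        (-193.2, 0, 0), (2.476, 1, 0), (0.1047, 0, 1),
        (-0.009512, 2, 0), (-0.000214, 0, 2), (0.000580, 1, 1),
    ),
    ("karakilcik", "smell"): (
        (145.54, 0, 0), (-0.5278, 1, 0), (-0.5358, 0, 1),
        (-0.004189, 2, 0), (-0.000073, 0, 2), (0.004343, 1, 1),
    ),
    ("karakilcik", "general_acceptance"): (
        (-259.5, 0, 0), (3.727, 1, 0), (-0.0068, 0, 1),
        (-0.014254, 2, 0), (-0.000108, 0, 2), (0.000789, 1, 1),
    ),
}

#: published coefficient-of-determination values (%), per variety/response
PRINTED_R2: dict[tuple[str, str], float] = {
    ("siyez", "taste"): 96.90,
    ("siyez", "color"): 97.77,
    ("siyez", "smell"): 99.10,
    ("siyez", "general_acceptance"): 99.10,
    ("firik", "taste"): 99.05,
    ("firik", "color"): 98.40,
    ("firik", "smell"): 99.17,
    ("firik", "general_acceptance"): 98.86,
    ("karakilcik", "taste"): 99.93,
    ("karakilcik", "color"): 99.32,
    ("karakilcik", "smell"): 99.86,
    ("karakilcik", "general_acceptance"): 99.72,
}


def _check_key(variety: str, response: str) -> tuple[str, str]:
    key = (variety.lower(), response.lower())
    if key not in _PRINTED:
        raise KeyError(
            f"unknown model {variety!r}/{response!r}; varieties are "
            f"{VARIETIES} and responses are {RESPONSES}"
        )
    return key


def printed_model(
    variety: str, response: str, merged: bool = False
) -> PolynomialSurface:
    """The published polynomial for a variety/response pair, verbatim.

    With ``merged=True`` duplicate monomials are summed into the canonical
    six-coefficient form (identical evaluations, tidier term list).
    """
    key = _check_key(variety, response)
    surface = PolynomialSurface(
        terms=_PRINTED[key],
        label=f"{key[0]}:{key[1]} (printed)",
        provenance="printed",
    )
    return surface.merged() if merged else surface


def corrected_model(variety: str, response: str) -> PolynomialSurface:
    """Variant registry reading the Siyez general-acceptance model's first
    cross term as X1^2 (a plausible typo fix).  All other models are
    identical to :func:`printed_model`.  Not used for validation."""
    key = _check_key(variety, response)
    if key != ("siyez", "general_acceptance"):
        return printed_model(*key)
    terms = tuple(
        (-0.004444, 2, 0) if (c, p, q) == (-0.004444, 1, 1) else (c, p, q)
        for c, p, q in _PRINTED[key]
    )
    return PolynomialSurface(
        terms=terms, label=f"{key[0]}:{key[1]} (corrected)", provenance="printed"
    )


def registry_surfaces(merged: bool = False) -> dict[tuple[str, str], PolynomialSurface]:
    """All twelve printed surfaces keyed by (variety, response)."""
    return {
        key: printed_model(*key, merged=merged) for key in _PRINTED
    }


# ---------------------------------------------------------------------------
# published run-level tables


def _data_path(name: str):
    return resources.files("rsmpso.data").joinpath(name)


def load_response_table(variety: str, response: str) -> pd.DataFrame:
    """Published 13-run table for one variety/response, columns
    ``run, x1, x2, response_mean, response_sd, response_predicted``."""
    key = _check_key(variety, response)
    with resources.as_file(_data_path(f"{key[0]}_responses.csv")) as p:
        wide = pd.read_csv(p)
    short = {"taste": "taste", "color": "color", "smell": "smell",
             "general_acceptance": "accept"}[key[1]]
    df = wide[["run", "x1", "x2",
               f"{short}_mean", f"{short}_sd", f"{short}_pred"]].copy()
    df.columns = ["run", "x1", "x2",
                  "response_mean", "response_sd", "response_predicted"]
    return df


def load_validation_row(variety: str) -> dict:
    """The published optimum-formulation validation block for one variety:
    optimum (x1, x2), model-predicted and experimentally measured scores,
    and the published percent-difference row."""
    import json

    key = variety.lower()
    if key not in VARIETIES:
        raise KeyError(f"unknown variety {variety!r}")
    with resources.as_file(_data_path("validation_rows.json")) as p:
        return json.loads(p.read_text())[key]
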