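"""Published estimates for the worked selection-response example.

A large commercial study of ear and tail damage in six purebred pig lines
(about 33k scored animals) reported, for the seven damage trait
definitions, realized selection intensities at 5% selected (lower tail),
forward-validation (LR) EBV accuracies, and pedigree-based genetic
correlations. Feeding those three tables through
:func:`pigdamage.selection.response_table` reproduces the study's predicted
direct and correlated responses to selection -- the package's worked
example, and a useful end-to-end check of the response arithmetic.

Only the published point estimates are bundled here; the microdata behind
them are proprietary and are emulated by :mod:`pigdamage.simulate`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .selection import SelectionReport, response_table
from .traits import TRAITS

#: realized selection intensities at 5% selected against damage (SD units)
REALIZED_INTENSITIES = pd.Series(
    {"ED03": 2.237, "ED01": 2.071, "TD03": 1.904, "TD01": 1.788,
     "AD01": 2.036, "NBP": 1.963, "SD06": 2.137},
    name="intensity",
)

#: forward-validation (LR) EBV accuracies
LR_ACCURACIES = pd.Series(
    {"ED03": 0.350, "ED01": 0.318, "TD03": 0.281, "TD01": 0.273,
     "AD01": 0.305, "NBP": 0.317, "SD06": 0.357},
    name="accuracy",
)

#: genetic correlations between the trait definitions (across-line analysis)
_RG_UPPER = {
    ("ED03", "ED01"): 0.971, ("ED03", "TD03"): 0.444,
    ("ED03", "TD01"): 0.409, ("ED03", "AD01"): 0.835,
    ("ED03", "NBP"): 0.846, ("ED03", "SD06"): 0.893,
    ("ED01", "TD03"): 0.448, ("ED01", "TD01"): 0.418,
    ("ED01", "AD01"): 0.847, ("ED01", "NBP"): 0.876,
    ("ED01", "SD06"): 0.880,
    ("TD03", "TD01"): 0.849, ("TD03", "AD01"): 0.808,
    ("TD03", "NBP"): 0.779, ("TD03", "SD06"): 0.800,
    ("TD01", "AD01"): 0.824, ("TD01", "NBP"): 0.804,
    ("TD01", "SD06"): 0.730,
    ("AD01", "NBP"): 0.994, ("AD01", "SD06"): 0.960,
    ("NBP", "SD06"): 0.952,
}


def genetic_correlations() -> pd.DataFrame:
    """The 7x7 genetic-correlation matrix (symmetric, unit diagonal)."""
    rg = pd.DataFrame(np.eye(len(TRAITS)), index=TRAITS, columns=TRAITS)
    for (a, b), v in _RG_UPPER.items():
        rg.loc[a, b] = v
        rg.loc[b, a] = v
    return rg


def worked_example_response(proportion: float = 0.05) -> SelectionReport:
    """Predicted responses to selection from the published estimates.

    Returns the 7x7 table of responses (genetic-SD units per generation)
    when selecting the best 5% on each trait definition in turn.
    """
    return response_table(
        REALIZED_INTENSITIES, LR_ACCURACIES, genetic_correlations(),
        proportion=proportion, tail="lower",
    )
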