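"""Selection intensity and predicted response to selection.

Damage traits have few phenotype levels, so the distribution of EBVs can be
lumpy; truncating the lowest 5% of such a distribution need not give the
selection differential a normal distribution would. The realized selection
intensity is therefore computed from the actual EBV distribution:

    i = |mean(selected) - mean(all)| / sd(all)

with selection against damage acting on the lower tail, after removing the
genetic trend (EBVs adjusted for herd-year-season of scoring in a separate
least-squares model). The normal-theory benchmark is i = phi(z_{1-p}) / p,
the mean of a truncated standard normal (2.063 at p = 0.05).

Predicted responses per generation, in genetic standard deviation units:

    R_direct[s]        = i_s * r_s
    R_correlated[t, s] = R_direct[s] * r_g[t, s]

with r_s the EBV accuracy of the selection trait s (forward-validation
accuracies by convention) and r_g the genetic correlation. Assembling this
over the seven trait definitions gives a 7x7 response table whose diagonal
holds direct responses, so trait definitions can be compared both as
selection criteria and as breeding-goal traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Realized intensities, inputs and the response table."""

    response: pd.DataFrame          # rows: response trait, cols: selection
    intensities: pd.Series
    accuracies: pd.Series
    genetic_correlations: pd.DataFrame
    proportion: float
    tail: str
    best_selection_trait: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.best_selection_trait is None:
            self.best_selection_trait = self.response.idxmax(axis=1)


def detrend_ebv(ebv: pd.Series, hys: pd.Series) -> pd.Series:
    """Residuals of EBVs after a least-squares fit on herd-year-season.

    Removes the genetic trend absorbed by the herd-year-season-of-scoring
    grouping before intensities are computed. With an intercept in the fit
    the residuals are mean-zero; a one-factor fit makes them the deviations
    from the level means. Levels with a single animal get residual 0 (with
    a warning).
    """
    if not ebv.index.equals(hys.index):
        hys = hys.loc[ebv.index]
    if hys.isna().any():
        raise ValueError("every animal needs a herd-year-season level")
    counts = hys.value_counts()
    singles = counts[counts == 1]
    if len(singles):
        logger.warning("%d herd-year-season level(s) contain a single "
                       "animal; their residuals are 0", len(singles))
    means = ebv.groupby(hys).transform("mean")
    return ebv - means


def realized_intensity(ebv: pd.Series | np.ndarray, p: float,
                       tail: str = "lower") -> float:
    """Realized selection intensity of truncating a proportion p of EBVs.

    i = |mean(selected) - mean(all)| / sd(all), with round(p*n) animals
    selected from the requested tail. Ties are broken by a stable sort on
    the animal identifier, so the result is deterministic.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selected proportion must be in (0, 1)")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    s = pd.Series(ebv) if not isinstance(ebv, pd.Series) else ebv
    values = s.to_numpy(float)
    n = len(values)
    n_sel = int(round(p * n))
    if n_sel < 1:
        raise ValueError(f"selected count round(p*n) = {n_sel}; nothing "
                         "to select")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ValueError("EBV standard deviation is zero; intensity "
                         "undefined")
    order = s.sort_index(kind="stable").sort_values(kind="stable")
    chosen = order.iloc[:n_sel] if tail == "lower" else order.iloc[-n_sel:]
    return float(abs(chosen.mean() - values.mean()) / sd)


def normal_intensity(p: float) -> float:
    """Selection intensity of truncating a standard normal at proportion p.

    i = phi(z_{1-p}) / p, the mean of the selected tail.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selected proportion must be in (0, 1)")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def response_table(
    intensities: pd.Series,
    accuracies: pd.Series,
    rg: pd.DataFrame,
    proportion: float = 0.05,
    tail: str = "lower",
) -> SelectionReport:
    """Assemble the direct/correlated response table over trait definitions.

    ``intensities`` and ``accuracies`` are indexed by selection trait; ``rg``
    is the symmetric genetic-correlation matrix with unit diagonal. Cell
    [t, s] is the response in trait t when selecting on trait s, in genetic
    standard deviations per generation.
    """
    traits = list(rg.index)
    if list(rg.columns) != traits:
        raise ValueError("rg must be square with matching labels")
    R = rg.to_numpy(float)
    if np.abs(R).max() > 1.0 + 1e-12:
        raise ValueError("genetic correlations must be within [-1, 1]")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("rg must be symmetric")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("rg must have a unit diagonal")
    i = intensities.loc[traits].to_numpy(float)
    r = accuracies.loc[traits].to_numpy(float)
    direct = i * r
    table = pd.DataFrame(R * direct[None, :], index=traits, columns=traits)
    return SelectionReport(
        response=table,
        intensities=intensities.loc[traits],
        accuracies=accuracies.loc[traits],
        genetic_correlations=rg,
        proportion=proportion,
        tail=tail,
    )
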