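"""EBV validation: replicated k-fold cross-validation and LR forward method.

Three ways of judging how well the animal model predicts breeding values:

* model-derived accuracy per animal from the prediction error variance
  (in :mod:`.mixed_model`);
* replicated k-fold cross-validation against phenotypes adjusted for all
  non-animal effects, with fold grouping either random or constrained so
  that full-sibs (FS) or half-sibs (HS) never straddle folds;
* the LR (linear regression) forward-validation method, comparing EBVs of
  young animals predicted without their own records (partial dataset)
  against EBVs from the complete dataset.

In the CV, accuracy is corr(adjusted phenotype, EBV) / h and dispersion the
regression slope of the adjusted phenotypes on the EBVs; 1 means the EBVs
are correctly spread. The LR metrics are

    accuracy   = sqrt( cov(EBV_p, EBV_c) / ((1 - Fbar) sigma2_a) )
    bias       = mean(EBV_p) - mean(EBV_c)      (reported in sigma_a units)
    dispersion = cov(EBV_p, EBV_c) / var(EBV_p)

with Fbar the mean inbreeding of the validation animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed_model import (Design, ModelFit, ModelSpec, VarianceComponents,
                          build_design, heritability, reml_fit, solve_blup)
from .pedigree import Pedigree, mean_inbreeding

logger = logging.getLogger(__name__)


@dataclass
class CvScheme:
    """How records are allocated to cross-validation folds."""

    k: int = 5
    replicates: int = 1
    grouping: str = "random"        # random | full-sib | half-sib
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.grouping not in ("random", "full-sib", "half-sib"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class CvReport:
    """Replicate-fold means of CV accuracy and dispersion for one trait."""

    trait: str
    scheme: CvScheme
    accuracy: float
    accuracy_se: float
    dispersion: float
    dispersion_se: float
    fold_accuracies: list[float] = field(default_factory=list, repr=False)
    fold_dispersions: list[float] = field(default_factory=list, repr=False)

    def to_row(self) -> dict:
        return {
            "trait": self.trait, "scheme": self.scheme.grouping,
            "accuracy": self.accuracy, "accuracy_se": self.accuracy_se,
            "dispersion": self.dispersion, "dispersion_se": self.dispersion_se,
        }


@dataclass
class LrReport:
    """LR forward-validation metrics for one trait."""

    trait: str
    accuracy: float
    bias_sd_units: float
    dispersion: float
    fbar: float
    n_validation: int
    accuracy_valid: bool = True

    def to_row(self) -> dict:
        return {
            "trait": self.trait, "accuracy": self.accuracy,
            "bias_sd_units": self.bias_sd_units,
            "dispersion": self.dispersion,
        }


# ---------------------------------------------------------------------------
# adjusted phenotypes
# ---------------------------------------------------------------------------

def adjust_phenotypes(table: pd.DataFrame, fit: ModelFit) -> pd.Series:
    """Phenotypes minus all estimated effects except the animal effect.

    y_adj = y - X b - litter - pen - hys effects, using the estimates from
    the full-data fit (which itself included the animal effect); the animal
    effect and the residual stay in y_adj.
    """
    design = fit.design
    if len(table) != design.n:
        raise ValueError("table does not match the fitted design")
    y = np.asarray(design.y, dtype=float)
    adj = y - design.X @ fit.b.to_numpy()
    for term in design.Z:
        if term == "animal":
            continue
        u = fit.u[term]
        if u.isna().any():
            raise ValueError(f"missing effect estimates for term {term!r}")
        adj = adj - design.Z[term] @ u.to_numpy()
    return pd.Series(adj, index=table.index, name="y_adj")


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(table: pd.DataFrame, ped: Pedigree, scheme: CvScheme,
               animal_col: str = "animal") -> list[np.ndarray]:
    """Fold assignments per replicate.

    Returns one integer array (record -> fold) per replicate. ``random``
    allocates records uniformly; ``full-sib`` keeps every full-sib family
    (same sire and same dam) in one fold; ``half-sib`` keeps every group of
    animals connected through a shared sire or dam together (connected
    components of the sib graph), so no half-sib pair is ever split.
    Blocks are dealt to the currently smallest fold, largest block first.
    """
    rng = np.random.default_rng(scheme.seed)
    n = len(table)
    animals = table[animal_col].astype(str).to_list()
    if scheme.grouping == "random":
        blocks = [np.array([i]) for i in range(n)]
    else:
        idx = np.array([ped.index_of(a) for a in animals])
        sires, dams = ped.sire[idx], ped.dam[idx]
        if scheme.grouping == "full-sib":
            keys = {}
            for i, (s, d) in enumerate(zip(sires, dams)):
                keys.setdefault((s, d), []).append(i)
            blocks = [np.array(v) for v in keys.values()]
        else:
            blocks = _parent_components(sires, dams)
    out = []
    for _ in range(scheme.replicates):
        order = rng.permutation(len(blocks))
        ordered = sorted((blocks[j] for j in order), key=len, reverse=True)
        sizes = np.zeros(scheme.k, dtype=int)
        assign = np.empty(n, dtype=int)
        limit = n / scheme.k
        for block in ordered:
            if len(block) > limit:
                logger.warning(
                    "sib block of %d records exceeds the fold size %.0f; "
                    "placing it in the emptiest fold", len(block), limit)
            f = int(np.argmin(sizes))
            assign[block] = f
            sizes[f] += len(block)
        out.append(assign)
    return out


def _parent_components(sires: np.ndarray, dams: np.ndarray) -> list[np.ndarray]:
    """Connected components of records linked by a shared sire or dam."""
    n = len(sires)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    first_of: dict[int, int] = {}
    for i in range(n):
        for p in (sires[i], dams[i]):
            if p < 0:
                continue
            if p in first_of:
                union(i, first_of[p])
            else:
                first_of[p] = i
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [np.array(v) for v in comps.values()]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def run_cv(
    table: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    scheme: CvScheme,
    vc: VarianceComponents | None = None,
    full_fit: ModelFit | None = None,
) -> CvReport:
    """Replicated k-fold cross-validation for one trait.

    The full-data univariate REML fit supplies (a) the variance components,
    which are *not* re-estimated inside folds, (b) the heritability used to
    rescale correlations into accuracies, and (c) the effect estimates used
    to adjust the validation phenotypes. Each fold refit is a BLUP solve on
    the prediction records only; validation animals keep their pedigree
    links, so their EBVs come from relatives.
    """
    trait = spec.traits[0]
    if vc is None or full_fit is None:
        vc, full_fit = reml_fit(table, spec, ped)
    design = full_fit.design
    y_adj = adjust_phenotypes(table, full_fit).to_numpy()
    h2, _ = heritability(vc, include_hys=True)
    h = float(np.sqrt(h2))
    animals = design.row_animals
    ws_full = full_fit._workspace
    symbolic = ws_full._uni[0] if (ws_full is not None
                                   and ws_full._uni is not None) else None

    folds = make_folds(table, ped, scheme)
    accs, disps = [], []
    for assign in folds:
        for f in range(scheme.k):
            vmask = assign == f
            if vmask.sum() < 3:
                continue
            sub = design.subset_rows(~vmask)
            fit_f = solve_blup(sub, vc, symbolic=symbolic)
            ebv_v = fit_f.u["animal"].loc[
                [a for a, m in zip(animals, vmask) if m]].to_numpy()
            ya_v = y_adj[vmask]
            if np.std(ebv_v) < 1e-12:
                logger.warning("fold %d: no EBV variation; skipped", f)
                continue
            accs.append(float(np.corrcoef(ya_v, ebv_v)[0, 1]) / h)
            slope = float(np.polyfit(ebv_v, ya_v, 1)[0])
            disps.append(slope)
    accs, disps = np.array(accs), np.array(disps)
    m = len(accs)
    return CvReport(
        trait=trait, scheme=scheme,
        accuracy=float(accs.mean()),
        accuracy_se=float(accs.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
        dispersion=float(disps.mean()),
        dispersion_se=(float(disps.std(ddof=1) / np.sqrt(m))
                       if m > 1 else np.nan),
        fold_accuracies=accs.tolist(),
        fold_dispersions=disps.tolist(),
    )


# ---------------------------------------------------------------------------
# LR forward validation
# ---------------------------------------------------------------------------

def lr_split(table: pd.DataFrame, cutoff: str | pd.Timestamp,
             date_col: str = "birth_date") -> tuple[np.ndarray, np.ndarray]:
    """Partition records into training (born on/before cutoff) and validation.

    Returns boolean masks (training, validation); errors if either side is
    empty.
    """
    dates = pd.to_datetime(table[date_col])
    cutoff = pd.Timestamp(cutoff)
    vmask = (dates > cutoff).to_numpy()
    tmask = ~vmask
    if not tmask.any():
        raise ValueError("training set empty: cutoff before all birth dates")
    if not vmask.any():
        raise ValueError("validation set empty: cutoff after all birth dates")
    return tmask, vmask


def lr_metrics(ebv_p: pd.Series, ebv_c: pd.Series, vc: VarianceComponents,
               fbar: float, trait: str = "") -> LrReport:
    """LR accuracy, bias (genetic-SD units) and dispersion.

    ``ebv_p``: EBVs of the validation animals from the partial dataset
    (their phenotypes removed); ``ebv_c``: same animals, complete dataset.
    A negative covariance makes the accuracy undefined (NaN, flagged);
    bias and dispersion are still returned.
    """
    if not ebv_p.index.equals(ebv_c.index):
        ebv_c = ebv_c.loc[ebv_p.index]
    va = float(vc.components["animal"])
    if va <= 0:
        raise ValueError("additive variance must be positive")
    p = ebv_p.to_numpy(float)
    c = ebv_c.to_numpy(float)
    cov = float(np.cov(p, c)[0, 1])
    ok = cov >= 0
    if not ok:
        logger.warning("negative cov(EBV_p, EBV_c); LR accuracy undefined")
    acc = float(np.sqrt(cov / ((1.0 - fbar) * va))) if ok else float("nan")
    bias = float((p.mean() - c.mean()) / np.sqrt(va))
    disp = float(cov / np.var(p, ddof=1))
    return LrReport(trait=trait, accuracy=acc, bias_sd_units=bias,
                    dispersion=disp, fbar=fbar, n_validation=len(p),
                    accuracy_valid=ok)


def run_lr_validation(
    table: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    cutoff: str | pd.Timestamp,
    vc: VarianceComponents | None = None,
    full_fit: ModelFit | None = None,
) -> LrReport:
    """Complete LR forward validation for one trait.

    EBV_c come from the full-data fit; EBV_p from a BLUP solve on the
    training records only (components from the full-data REML), with the
    validation animals' pedigree links retained.
    """
    trait = spec.traits[0]
    if vc is None or full_fit is None:
        vc, full_fit = reml_fit(table, spec, ped)
    design = full_fit.design
    tmask, vmask = lr_split(table, cutoff)
    ws_full = full_fit._workspace
    symbolic = ws_full._uni[0] if (ws_full is not None
                                   and ws_full._uni is not None) else None
    fit_p = solve_blup(design.subset_rows(tmask), vc, symbolic=symbolic)
    vanimals = [a for a, m in zip(design.row_animals, vmask) if m]
    ebv_p = fit_p.u["animal"].loc[vanimals]
    ebv_c = full_fit.u["animal"].loc[vanimals]
    fbar = mean_inbreeding(ped, vanimals)
    return lr_metrics(ebv_p, ebv_c, vc, fbar, trait=trait)
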