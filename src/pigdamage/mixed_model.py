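"""Linear animal model: design, REML variance components, BLUP, accuracy.

The observation model is

    y = X b + Z_a a + Z_l l + Z_g g + Z_hys hys + e

with fixed effects b (sex, line, sex x line, scorer, and age at scoring as a
covariate), a random animal effect with covariance A sigma2_a (A the
pedigree relationship matrix), i.i.d. litter, pen-group and
herd-year-season-of-scoring effects, and an i.i.d. residual.

Variance components are estimated by REML. The restricted log-likelihood is
evaluated exactly through the mixed-model equations (MME): with
W = [X Z], M = W'W + blockdiag(0, A^-1/gamma_a, I/gamma_l, ...) and
gamma_k = sigma2_k / sigma2_e,

    -2 l_R = (n - p) log sigma2_e + sum_k q_k log gamma_k + log|A|
             + log|M| + y'Py + (n - p) log 2 pi,

where log|M| comes from a sparse LDL' factorisation and y'Py from the MME
solution. The likelihood is maximised by quasi-Newton iteration on the log
variance ratios (residual variance profiled out in the univariate case);
asymptotic standard errors come from the inverse average-information matrix
at the optimum, which needs only MME solves. Bivariate models use an
unstructured 2x2 covariance per random term, parameterised as
(log v1, log v2, atanh r) so every update is automatically positive
semi-definite; a term's correlation can be frozen (used to fix the litter
correlation at 0.99 for near-duplicate trait pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .pedigree import Pedigree, a_inverse
from .sparse_ldl import LDLFactor, SymbolicLDL, aligned_vector

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))

#: default model terms (term name -> phenotype-table column)
DEFAULT_RANDOM_TERMS = {
    "animal": "animal",
    "litter": "litter",
    "pen": "pen",
    "hys_scoring": "hys_scoring",
}


@dataclass
class ModelSpec:
    """Which columns enter the model and how."""

    traits: list[str]
    fixed_factors: list[str] = field(
        default_factory=lambda: ["sex", "line", "sex:line", "scorer"])
    covariates: list[str] = field(default_factory=lambda: ["age_days"])
    random_terms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RANDOM_TERMS))
    fix_correlation: dict[str, float] = field(default_factory=dict)
    var_floor: float = 1e-8     # relative to the phenotypic variance
    max_iter: int = 200

    def __post_init__(self) -> None:
        if isinstance(self.traits, str):
            self.traits = [self.traits]
        if "animal" not in self.random_terms:
            raise ValueError("the model requires an 'animal' random term")


@dataclass
class VarianceComponents:
    """Estimated (co)variance per random term plus the residual.

    Univariate: scalars per term. Bivariate: 2x2 arrays per term. ``se``
    carries the matching asymptotic standard errors (for 2x2 terms the SEs
    of (v1, cov, v2)).
    """

    components: dict[str, float | np.ndarray]
    se: dict[str, float | np.ndarray] | None = None
    param_cov: np.ndarray | None = None       # AI-inverse, estimation order
    param_names: list[str] | None = None

    @property
    def is_bivariate(self) -> bool:
        return np.ndim(self.components["animal"]) == 2

    def total_variance(self, include_hys: bool = True) -> float:
        tot = 0.0
        for term, v in self.components.items():
            if term == "hys_scoring" and not include_hys:
                continue
            tot += float(v) if np.ndim(v) == 0 else float(np.asarray(v)[0, 0])
        return tot

    def genetic_correlation(self) -> tuple[float, float]:
        """(r_g, SE) from the 2x2 additive-genetic block (bivariate only)."""
        S = np.asarray(self.components["animal"])
        rg = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        se = np.nan
        if self.param_cov is not None and self.param_names is not None:
            i1 = self.param_names.index("animal_v1")
            ic = self.param_names.index("animal_cov")
            i2 = self.param_names.index("animal_v2")
            g = np.zeros(len(self.param_names))
            g[i1] = -0.5 * rg / S[0, 0]
            g[i2] = -0.5 * rg / S[1, 1]
            g[ic] = 1.0 / np.sqrt(S[0, 0] * S[1, 1])
            se = float(np.sqrt(max(g @ self.param_cov @ g, 0.0)))
        return float(rg), se


@dataclass
class Design:
    """Design matrices for one trait (or a pair sharing the same design)."""

    y: np.ndarray                     # (n,) or (n, 2)
    X: np.ndarray                     # dense (n, p), full column rank
    x_names: list[str]
    Z: dict[str, sparse.csr_matrix]   # per random term, (n, q_term)
    levels: dict[str, list[str]]
    pedigree: Pedigree
    row_animals: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, mask: np.ndarray) -> "Design":
        """Row subset sharing the same columns (for CV fold refits)."""
        return Design(
            y=self.y[mask],
            X=self.X[mask],
            x_names=self.x_names,
            Z={k: Z[mask] for k, Z in self.Z.items()},
            levels=self.levels,
            pedigree=self.pedigree,
            row_animals=[a for a, m in zip(self.row_animals, mask) if m],
        )


@dataclass
class ModelFit:
    """MME solutions and bookkeeping for one fitted model."""

    spec: ModelSpec
    design: Design
    components: VarianceComponents
    b: pd.Series                      # fixed-effect solutions
    u: dict[str, pd.Series]           # random-effect solutions per term
    loglik: float                     # restricted log-likelihood
    converged: bool
    n_iter: int
    mme_residual: float
    _workspace: "MMEWorkspace | None" = field(default=None, repr=False)
    pev: pd.Series | None = None

    @property
    def ebv(self) -> pd.Series:
        """Estimated breeding values (univariate) over the whole pedigree."""
        return self.u["animal"]


class RankDeficientDesign(ValueError):
    pass


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(table: pd.DataFrame, spec: ModelSpec,
                 ped: Pedigree) -> Design:
    """Build fixed and random design matrices with treatment contrasts.

    The fixed design gets an intercept, drop-first dummies per factor,
    products of non-reference dummies for ':' interactions, and raw
    covariate columns; a QR rank check raises
    :class:`RankDeficientDesign` listing the confounded columns. The animal
    incidence matrix is indexed against the full pedigree so ancestors
    without records obtain EBVs through their relationships.
    """
    used = list(spec.covariates) + list(spec.traits) + [
        c for t in spec.fixed_factors for c in t.split(":")
    ] + [col for col in spec.random_terms.values()]
    for col in dict.fromkeys(used):
        if col not in table.columns:
            raise ValueError(f"phenotype table is missing column {col!r}")
        if table[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")

    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    def factor_dummies(fac: str) -> tuple[list[np.ndarray], list[str]]:
        values = table[fac].astype(str)
        levels = sorted(values.unique())
        dd, nn = [], []
        for lev in levels[1:]:
            dd.append((values == lev).to_numpy(float))
            nn.append(f"{fac}[{lev}]")
        return dd, nn

    for term in spec.fixed_factors:
        if ":" in term:
            f1, f2 = term.split(":")
            d1, n1 = factor_dummies(f1)
            d2, n2 = factor_dummies(f2)
            for a, na in zip(d1, n1):
                for b, nb in zip(d2, n2):
                    cols.append(a * b)
                    names.append(f"{na}:{nb}")
        else:
            dd, nn = factor_dummies(term)
            cols.extend(dd)
            names.extend(nn)
    for cov in spec.covariates:
        cols.append(pd.to_numeric(table[cov]).to_numpy(float))
        names.append(cov)

    X = np.column_stack(cols)
    # rank check: pivoted QR; true confounding (beyond the treatment-contrast
    # pruning already applied) is an error
    q, r, piv = _pivoted_qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-9 * np.abs(r[0, 0])))
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        raise RankDeficientDesign(
            "fixed design is rank deficient; confounded columns: "
            + ", ".join(dropped))

    Z: dict[str, sparse.csr_matrix] = {}
    levels: dict[str, list[str]] = {}
    rows = np.arange(n)
    for term, col in spec.random_terms.items():
        if term == "animal":
            levels[term] = list(ped.ids)
            cidx = np.array([ped.index_of(a) for a in table[col].astype(str)])
            q_ = len(ped)
        else:
            values = table[col].astype(str)
            levs = sorted(values.unique())
            levels[term] = levs
            lookup = {lv: i for i, lv in enumerate(levs)}
            cidx = values.map(lookup).to_numpy()
            q_ = len(levs)
        Z[term] = sparse.csr_matrix(
            (np.ones(n), (rows, cidx)), shape=(n, q_))

    y = table[spec.traits].to_numpy(float)
    if y.shape[1] == 1:
        y = y[:, 0]
    return Design(y=y, X=X, x_names=names, Z=Z, levels=levels, pedigree=ped,
                  row_animals=list(table[spec.random_terms["animal"]]
                                   .astype(str)))


def _pivoted_qr(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


# ---------------------------------------------------------------------------
# MME workspace
# ---------------------------------------------------------------------------

class MMEWorkspace:
    """Precomputed pieces of the mixed-model equations for one design.

    Holds W'W, W'y and the embedded penalty matrix per random term
    (A^-1 for the animal term, identity otherwise) so that the MME
    coefficient matrix for any components is two sparse additions away.
    """

    def __init__(self, design: Design,
                 symbolic: "SymbolicLDL | None" = None):
        self.design = design
        self._shared_sym = symbolic
        X = sparse.csr_matrix(design.X)
        parts = [X] + [design.Z[t] for t in design.Z]
        self.terms = list(design.Z)
        self.W = sparse.hstack(parts).tocsr()
        self.WtW = (self.W.T @ self.W).tocsc()
        y = design.y
        self.multi = y.ndim == 2
        self.Wty = self.W.T @ y
        self.yty = y.T @ y
        self.p = design.p
        self.n = design.n
        self.q = {t: design.Z[t].shape[1] for t in self.terms}
        offs = [self.p]
        for t in self.terms:
            offs.append(offs[-1] + self.q[t])
        self.slices = {t: slice(offs[i], offs[i + 1])
                       for i, t in enumerate(self.terms)}
        self.dim = offs[-1]
        ped = design.pedigree
        self.log_det_a = ped.log_det_a() if "animal" in self.terms else 0.0
        self.penalty: dict[str, sparse.csc_matrix] = {}
        for t in self.terms:
            base = (a_inverse(ped) if t == "animal"
                    else sparse.identity(self.q[t], format="csr")).tocoo()
            off = self.slices[t].start
            self.penalty[t] = sparse.coo_matrix(
                (base.data, (base.row + off, base.col + off)),
                shape=(self.dim, self.dim)).tocsc()
        self._uni: tuple | None = None   # symbolic LDL + aligned data vectors
        self._biv: tuple | None = None

    # -- factorisation backends ------------------------------------------

    def _setup_uni(self) -> None:
        if self._shared_sym is not None:
            sym = self._shared_sym    # pattern of a superset design
        else:
            pat = self.WtW.copy()
            for P in self.penalty.values():
                pat = pat + P
            sym = SymbolicLDL(pat)
        vec_wtw = aligned_vector(sym, self.WtW)
        vec_pen = {t: aligned_vector(sym, P)
                   for t, P in self.penalty.items()}
        self._uni = (sym, vec_wtw, vec_pen)

    def factor_uni(self, gamma: dict[str, float]) -> LDLFactor:
        """Factorise M = W'W + sum_k A_k^-1 / gamma_k."""
        if self._uni is None:
            self._setup_uni()
        sym, vec_wtw, vec_pen = self._uni
        data = vec_wtw.copy()
        for t in self.terms:
            data += vec_pen[t] * (1.0 / gamma[t])
        return sym.factor(data)

    def _setup_biv(self) -> None:
        pat = self.WtW.copy()
        for P in self.penalty.values():
            pat = pat + P
        sym = SymbolicLDL(sparse.kron(pat, np.ones((2, 2)), format="csc"))
        vecs: dict[tuple[str, int, int], np.ndarray] = {}
        mats = {"wtw": self.WtW, **self.penalty}
        for name, B in mats.items():
            for a in (0, 1):
                for b in (0, 1):
                    E = np.zeros((2, 2))
                    E[a, b] = 1.0
                    vecs[(name, a, b)] = aligned_vector(
                        sym, sparse.kron(B, E, format="coo"))
        self._biv = (sym, vecs)

    def factor_biv(self, sinv: dict[str, np.ndarray],
                   rinv: np.ndarray) -> "_BivariateSolver":
        """Factorise the two-trait MME (traits interleaved per equation)."""
        if self._biv is None:
            self._setup_biv()
        sym, vecs = self._biv
        data = np.zeros(sym.upper_nnz)
        for (name, a, b), v in vecs.items():
            c = rinv[a, b] if name == "wtw" else sinv[name][a, b]
            if c != 0.0:
                data += c * v
        return _BivariateSolver(sym.factor(data), self.dim)

    # -- univariate -------------------------------------------------------

    def coefficient_matrix(self, gamma: dict[str, float]) -> sparse.csc_matrix:
        M = self.WtW.copy()
        for t in self.terms:
            M = M + self.penalty[t] * (1.0 / gamma[t])
        return M.tocsc()

    def neg2_restricted_loglik(
        self, components: dict[str, float], resid: float,
        return_solution: bool = False,
    ):
        """Exact -2 log restricted likelihood at the given components."""
        gamma = {t: components[t] / resid for t in self.terms}
        lu = self.factor_uni(gamma)
        logdet = lu.logdet
        sol = lu.solve(self.Wty)
        quad = float(self.yty - sol @ self.Wty)
        npars = self.n - self.p
        val = (
            npars * np.log(resid)
            + sum(self.q[t] * np.log(gamma[t]) for t in self.terms)
            + self.log_det_a
            + logdet
            + quad / resid
            + npars * LOG2PI
        )
        if return_solution:
            return val, sol, lu, quad
        return val

    def profiled_neg2(self, gamma: dict[str, float]):
        """-2 l_R with sigma2_e at its conditional maximum."""
        lu = self.factor_uni(gamma)
        logdet = lu.logdet
        sol = lu.solve(self.Wty)
        quad = float(self.yty - sol @ self.Wty)
        npars = self.n - self.p
        sigma_e = quad / npars
        val = (
            npars * np.log(sigma_e)
            + sum(self.q[t] * np.log(gamma[t]) for t in self.terms)
            + self.log_det_a
            + logdet
            + npars
            + npars * LOG2PI
        )
        return val, sigma_e, sol, lu

    # -- shared -----------------------------------------------------------

    def solution_series(self, sol: np.ndarray) -> tuple[pd.Series, dict]:
        d = self.design
        b = pd.Series(sol[: self.p], index=d.x_names, name="fixed")
        u = {t: pd.Series(sol[self.slices[t]], index=d.levels[t], name=t)
             for t in self.terms}
        return b, u

    # -- bivariate --------------------------------------------------------

    def coefficient_matrix_biv(self, sinv: dict[str, np.ndarray],
                               rinv: np.ndarray) -> sparse.csc_matrix:
        """Two-trait MME coefficient matrix in blocked layout (tests only)."""
        def block(i: int, j: int) -> sparse.csc_matrix:
            B = self.WtW * rinv[i, j]
            for t in self.terms:
                B = B + self.penalty[t] * sinv[t][i, j]
            return B

        A00, A01, A11 = block(0, 0), block(0, 1), block(1, 1)
        return sparse.bmat([[A00, A01], [A01, A11]], format="csc")

    def neg2_restricted_loglik_biv(
        self, components: dict[str, np.ndarray],
        return_solution: bool = False,
    ):
        """-2 log restricted likelihood for the bivariate model."""
        R = np.asarray(components["residual"], dtype=float)
        rinv = _inv2(R)
        sinv = {t: _inv2(np.asarray(components[t], dtype=float))
                for t in self.terms}
        lu = self.factor_biv(sinv, rinv)
        logdet = lu.logdet
        rhs = np.concatenate([
            rinv[0, 0] * self.Wty[:, 0] + rinv[0, 1] * self.Wty[:, 1],
            rinv[1, 0] * self.Wty[:, 0] + rinv[1, 1] * self.Wty[:, 1],
        ])
        sol = lu.solve(rhs)
        yry = (rinv[0, 0] * self.yty[0, 0] + 2 * rinv[0, 1] * self.yty[0, 1]
               + rinv[1, 1] * self.yty[1, 1])
        quad = float(yry - sol @ rhs)
        val = (
            self.n * _logdet2(R)
            + sum(self.q[t] * _logdet2(np.asarray(components[t]))
                  for t in self.terms)
            + 2.0 * self.log_det_a
            + logdet
            + quad
            + (2 * self.n - 2 * self.p) * LOG2PI
        )
        if return_solution:
            return val, sol, lu
        return val


class _BivariateSolver:
    """Adapter exposing blocked-layout solves over the interleaved factor.

    The factorisation interleaves the two traits' equations (rows 2i, 2i+1)
    for locality; callers work with the blocked layout [trait-1 equations;
    trait-2 equations].
    """

    def __init__(self, factor: LDLFactor, dim: int):
        self._factor = factor
        self._dim = dim

    @property
    def logdet(self) -> float:
        return self._factor.logdet

    def solve(self, b: np.ndarray) -> np.ndarray:
        one_d = b.ndim == 1
        B = b[:, None] if one_d else b
        dim = self._dim
        Bi = np.empty_like(B, dtype=float)
        Bi[0::2] = B[:dim]
        Bi[1::2] = B[dim:]
        Xi = self._factor.solve(Bi)
        X = np.empty_like(Xi)
        X[:dim] = Xi[0::2]
        X[dim:] = Xi[1::2]
        return X[:, 0] if one_d else X


def _inv2(S: np.ndarray) -> np.ndarray:
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    if det <= 0:
        raise np.linalg.LinAlgError("singular 2x2 covariance block")
    return np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det


def _logdet2(S: np.ndarray) -> float:
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    if det <= 0:
        raise np.linalg.LinAlgError("singular 2x2 covariance block")
    return float(np.log(det))


# ---------------------------------------------------------------------------
# univariate REML
# ---------------------------------------------------------------------------

def reml_fit(
    table: pd.DataFrame,
    spec: ModelSpec,
    ped: Pedigree,
    start: VarianceComponents | None = None,
) -> tuple[VarianceComponents, ModelFit]:
    """Estimate variance components by REML and solve the MME (univariate).

    The profiled restricted likelihood (residual variance maximised out
    analytically) is maximised over the log variance ratios by L-BFGS-B with
    numerical gradients; every evaluation is exact through a sparse LU
    factorisation of the MME. Components are bounded below at
    ``spec.var_floor`` times the phenotypic variance. Non-convergence is
    reported through ``ModelFit.converged``, not an exception.
    """
    if len(spec.traits) != 1:
        raise ValueError("reml_fit is univariate; use reml_bivariate")
    design = build_design(table, spec, ped)
    ws = MMEWorkspace(design)
    terms = ws.terms
    vy = float(np.var(design.y))

    if start is not None:
        gamma0 = {t: max(float(start.components[t]), spec.var_floor * vy)
                  / float(start.components["residual"]) for t in terms}
    else:
        # equal split: each random term 10% of the phenotypic variance
        gamma0 = {t: 0.1 / (1.0 - 0.1 * len(terms)) for t in terms}

    lo = np.log(spec.var_floor)
    x0 = np.log([gamma0[t] for t in terms])
    nfev = 0

    def objective(x: np.ndarray) -> float:
        nonlocal nfev
        nfev += 1
        gamma = dict(zip(terms, np.exp(x)))
        try:
            val, _, _, _ = ws.profiled_neg2(gamma)
        except np.linalg.LinAlgError:
            return 1e12
        return val

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(lo, 16.0)] * len(terms),
        options={"maxiter": spec.max_iter, "ftol": 1e-11, "gtol": 1e-4,
                 "eps": 1e-5},
    )
    gamma = dict(zip(terms, np.exp(res.x)))
    neg2, sigma_e, sol, lu = ws.profiled_neg2(gamma)
    comps = {t: gamma[t] * sigma_e for t in terms}
    comps["residual"] = sigma_e

    se, param_cov, names = _ai_standard_errors_uni(ws, comps, sol, lu)
    vc = VarianceComponents(components=comps, se=se, param_cov=param_cov,
                            param_names=names)

    b, u = ws.solution_series(sol)
    M = ws.coefficient_matrix(gamma)
    resid_norm = float(
        np.linalg.norm(M @ sol - ws.Wty) / max(np.linalg.norm(ws.Wty), 1.0))
    fit = ModelFit(
        spec=spec, design=design, components=vc, b=b, u=u,
        loglik=-0.5 * neg2, converged=bool(res.success), n_iter=nfev,
        mme_residual=resid_norm, _workspace=ws,
    )
    ws.lu_opt = lu
    ws.sigma_e_opt = sigma_e
    if not res.success:
        logger.warning("REML did not converge: %s", res.message)
    return vc, fit


def _ai_standard_errors_uni(ws: MMEWorkspace, comps: dict[str, float],
                            sol: np.ndarray, lu):
    """SEs from the inverse average-information matrix.

    The AI matrix 0.5 y'P V_i P V_j P y needs only MME solves: the working
    vectors are V_k P y = Z_k u_k / sigma2_k per term and e / sigma2_e for
    the residual, and P f = (f - W M^-1 W'f) / sigma2_e.
    """
    d = ws.design
    terms = ws.terms
    sigma_e = comps["residual"]
    yhat = ws.W @ sol
    ehat = d.y - yhat
    F = np.empty((ws.n, len(terms) + 1))
    for j, t in enumerate(terms):
        F[:, j] = (d.Z[t] @ sol[ws.slices[t]]) / comps[t]
    F[:, -1] = ehat / sigma_e
    S = lu.solve(ws.W.T @ F)
    PF = (F - ws.W @ S) / sigma_e
    AI = 0.5 * (F.T @ PF)
    AI = 0.5 * (AI + AI.T)
    names = [f"{t}" for t in terms] + ["residual"]
    try:
        cov = np.linalg.inv(AI)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("AI matrix singular (component at bound?); "
                       "using pseudo-inverse for SEs")
        cov = np.linalg.pinv(AI)
    se = {nm: float(np.sqrt(max(cov[i, i], 0.0)))
          for i, nm in enumerate(names)}
    return se, cov, names


def heritability(vc: VarianceComponents,
                 include_hys: bool = True) -> tuple[float, float]:
    """h^2 = sigma2_a / phenotypic variance, with a delta-method SE.

    The phenotypic variance sums all estimated components; with
    ``include_hys=False`` the herd-year-season-of-scoring variance is left
    out of the denominator (the convention of studies that fit it fixed).
    """
    comps = vc.components
    tot = vc.total_variance(include_hys=include_hys)
    if tot <= 0:
        raise ZeroDivisionError("phenotypic variance is zero")
    va = float(comps["animal"])
    h2 = va / tot
    se = float("nan")
    if vc.param_cov is not None and vc.param_names is not None:
        g = np.zeros(len(vc.param_names))
        for i, nm in enumerate(vc.param_names):
            in_denom = include_hys or nm != "hys_scoring"
            dh = (1.0 / tot if nm == "animal" else 0.0)
            if in_denom:
                dh -= va / tot ** 2
            g[i] = dh
        se = float(np.sqrt(max(g @ vc.param_cov @ g, 0.0)))
    return h2, se


def compute_pev(fit: ModelFit, animals: list[str] | None = None,
                chunk: int = 512) -> pd.Series:
    """Prediction error variance of the EBVs from the inverse MME.

    PEV_i = sigma2_e * (M^-1)_{ii} over the animal block, obtained by
    unit-vector solves against the stored factorisation (chunked).
    """
    ws = fit._workspace
    if ws is None or not hasattr(ws, "lu_opt"):
        raise ValueError("fit carries no factorisation; re-run reml_fit")
    ped = fit.design.pedigree
    if animals is None:
        animals = list(fit.design.row_animals)
    animals = list(dict.fromkeys(animals))
    idx = np.array([ped.index_of(a) for a in animals])
    cols = ws.slices["animal"].start + idx
    pev = np.empty(len(cols))
    for s in range(0, len(cols), chunk):
        cc = cols[s:s + chunk]
        E = np.zeros((ws.dim, len(cc)))
        E[cc, np.arange(len(cc))] = 1.0
        sols = ws.lu_opt.solve(E)
        pev[s:s + len(cc)] = sols[cc, np.arange(len(cc))]
    pev *= ws.sigma_e_opt
    out = pd.Series(pev, index=animals, name="pev")
    fit.pev = out
    return out


def model_accuracy(fit: ModelFit, vc: VarianceComponents | None = None,
                   animals: list[str] | None = None) -> pd.Series:
    """Per-animal model-derived accuracy r_i = sqrt(1 - PEV_i / sigma2_a).

    PEV values outside [0, sigma2_a] are clamped before the square root and
    the clamping is logged.
    """
    if vc is None:
        vc = fit.components
    va = float(vc.components["animal"])
    if va <= 0:
        raise ValueError("additive variance must be positive for accuracy")
    pev = fit.pev
    if pev is None or (animals is not None
                       and not set(animals) <= set(pev.index)):
        pev = compute_pev(fit, animals)
    if animals is not None:
        pev = pev.loc[animals]
    clamped = int(((pev < 0) | (pev > va)).sum())
    if clamped:
        logger.warning("clamped %d PEV values into [0, sigma2_a]", clamped)
    r = np.sqrt(1.0 - np.clip(pev.to_numpy(), 0.0, va) / va)
    return pd.Series(r, index=pev.index, name="accuracy")


# ---------------------------------------------------------------------------
# BLUP at known components (CV fold refits, forward-validation refits)
# ---------------------------------------------------------------------------

def solve_blup(design: Design, vc: VarianceComponents,
               symbolic: "SymbolicLDL | None" = None) -> ModelFit:
    """Solve the MME at fixed variance components (no REML iteration).

    ``symbolic`` may reuse the symbolic analysis of a row-superset design
    (the sparsity pattern only shrinks when records are removed).
    """
    ws = MMEWorkspace(design, symbolic=symbolic)
    sigma_e = float(vc.components["residual"])
    gamma = {t: float(vc.components[t]) / sigma_e for t in ws.terms}
    M = ws.coefficient_matrix(gamma)
    lu = ws.factor_uni(gamma)
    sol = lu.solve(ws.Wty)
    b, u = ws.solution_series(sol)
    resid_norm = float(
        np.linalg.norm(M @ sol - ws.Wty) / max(np.linalg.norm(ws.Wty), 1.0))
    ws.lu_opt = lu
    ws.sigma_e_opt = sigma_e
    return ModelFit(
        spec=ModelSpec(traits=["<blup>"]), design=design, components=vc,
        b=b, u=u, loglik=float("nan"), converged=True, n_iter=0,
        mme_residual=resid_norm, _workspace=ws,
    )


# ---------------------------------------------------------------------------
# bivariate REML
# ---------------------------------------------------------------------------

def _pack_biv(comps: dict[str, np.ndarray], terms: list[str],
              fix: dict[str, float]) -> tuple[np.ndarray, list[str]]:
    x, names = [], []
    for t in terms + ["residual"]:
        S = np.asarray(comps[t], dtype=float)
        r = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        x += [np.log(S[0, 0]), np.log(S[1, 1])]
        names += [f"{t}_logv1", f"{t}_logv2"]
        if t not in fix:
            x.append(np.arctanh(np.clip(r, -0.99999, 0.99999)))
            names.append(f"{t}_z")
    return np.array(x), names


def _unpack_biv(x: np.ndarray, terms: list[str],
                fix: dict[str, float]) -> dict[str, np.ndarray]:
    comps = {}
    k = 0
    for t in terms + ["residual"]:
        v1, v2 = np.exp(x[k]), np.exp(x[k + 1])
        k += 2
        if t in fix:
            r = float(fix[t])
        else:
            r = float(np.tanh(x[k]))
            k += 1
        c = r * np.sqrt(v1 * v2)
        comps[t] = np.array([[v1, c], [c, v2]])
    return comps


def reml_bivariate(
    table: pd.DataFrame,
    spec: ModelSpec,
    ped: Pedigree,
    fix: dict[str, float] | None = None,
    start: tuple[VarianceComponents, VarianceComponents] | None = None,
) -> tuple[VarianceComponents, ModelFit]:
    """Bivariate REML with an unstructured 2x2 covariance per random term.

    Starting variances come from univariate fits of each trait (run
    internally when ``start`` is not supplied). ``fix`` freezes the named
    terms' correlations (e.g. ``{"litter": 0.99}``) while their variances
    keep updating; the (log v1, log v2, atanh r) parameterisation keeps
    every 2x2 block positive semi-definite by construction. Correlations
    are bounded at |r| <= 0.99999.
    """
    if len(spec.traits) != 2:
        raise ValueError("reml_bivariate needs exactly two traits")
    fix = dict(spec.fix_correlation, **(fix or {}))

    if start is None:
        from dataclasses import replace
        uni = []
        for tr in spec.traits:
            uspec = replace(spec, traits=[tr], fix_correlation={})
            vc_t, _ = reml_fit(table, uspec, ped)
            uni.append(vc_t)
        start = (uni[0], uni[1])
    vc1, vc2 = start

    design = build_design(table, spec, ped)
    ws = MMEWorkspace(design)
    terms = ws.terms
    vy = float(np.mean(np.var(design.y, axis=0)))
    floor = spec.var_floor * vy

    comps0: dict[str, np.ndarray] = {}
    for t in terms + ["residual"]:
        v1 = max(float(vc1.components[t]), floor)
        v2 = max(float(vc2.components[t]), floor)
        r0 = fix.get(t, 0.3)
        c = r0 * np.sqrt(v1 * v2)
        comps0[t] = np.array([[v1, c], [c, v2]])

    x0, pnames = _pack_biv(comps0, terms, fix)
    bounds = []
    for nm in pnames:
        if nm.endswith("_z"):
            bounds.append((-6.0, 6.0))
        else:
            bounds.append((np.log(floor), np.log(vy) + 10.0))
    nfev = 0

    def objective(x: np.ndarray) -> float:
        nonlocal nfev
        nfev += 1
        comps = _unpack_biv(x, terms, fix)
        try:
            return ws.neg2_restricted_loglik_biv(comps)
        except (np.linalg.LinAlgError, RuntimeError):
            return 1e12

    # stage 1: correlations only, variances held at their univariate REML
    # values (near-optimal marginally); stage 2: short full-parameter polish
    z_idx = np.array([i for i, nm in enumerate(pnames)
                      if nm.endswith("_z")], dtype=int)
    x_cur = x0.copy()
    if len(z_idx):
        def objective_z(xz: np.ndarray) -> float:
            xx = x_cur.copy()
            xx[z_idx] = xz
            return objective(xx)

        res_z = optimize.minimize(
            objective_z, x0[z_idx], method="L-BFGS-B",
            bounds=[bounds[i] for i in z_idx],
            options={"maxiter": spec.max_iter, "ftol": 1e-7, "gtol": 0.05,
                     "eps": 1e-4},
        )
        x_cur[z_idx] = res_z.x

    res = optimize.minimize(
        objective, x_cur, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 40, "ftol": 1e-7, "gtol": 0.05, "eps": 1e-4},
    )
    if res.fun > objective(x_cur):
        res.x, res.success = x_cur, True   # polish wandered; keep stage 1
    comps = _unpack_biv(res.x, terms, fix)
    neg2, sol, lu = ws.neg2_restricted_loglik_biv(comps, return_solution=True)

    se, param_cov, names = _ai_standard_errors_biv(ws, comps, sol, lu)
    vc = VarianceComponents(components=comps, se=se, param_cov=param_cov,
                            param_names=names)

    dim = ws.dim
    t1, t2 = spec.traits
    b = pd.Series(
        np.concatenate([sol[:ws.p], sol[dim:dim + ws.p]]),
        index=[f"{t1}:{nm}" for nm in design.x_names]
        + [f"{t2}:{nm}" for nm in design.x_names])
    u = {}
    for t in terms:
        sl = ws.slices[t]
        u[t] = pd.DataFrame(
            {t1: sol[sl], t2: sol[dim + sl.start:dim + sl.stop]},
            index=design.levels[t])
    fit = ModelFit(
        spec=spec, design=design, components=vc, b=b, u=u,
        loglik=-0.5 * neg2, converged=bool(res.success), n_iter=nfev,
        mme_residual=float("nan"), _workspace=ws,
    )
    if not res.success:
        logger.warning("bivariate REML did not converge: %s", res.message)
    return vc, fit


def _ai_standard_errors_biv(ws: MMEWorkspace, comps: dict[str, np.ndarray],
                            sol: np.ndarray, lu):
    """Average-information SEs for (v1, cov, v2) of every term + residual."""
    terms = ws.terms
    n, dim = ws.n, ws.dim
    rinv = _inv2(np.asarray(comps["residual"]))
    y = ws.design.y
    yhat = np.column_stack([ws.W @ sol[:dim], ws.W @ sol[dim:]])
    ehat = y - yhat

    E11 = np.array([[1.0, 0.0], [0.0, 0.0]])
    E12 = np.array([[0.0, 1.0], [1.0, 0.0]])
    E22 = np.array([[0.0, 0.0], [0.0, 1.0]])

    cols = []
    names = []
    for t in terms:
        sl = ws.slices[t]
        u_t = np.column_stack([sol[sl], sol[dim + sl.start:dim + sl.stop]])
        sinv = _inv2(np.asarray(comps[t]))
        Zt = ws.design.Z[t]
        for E, suffix in [(E11, "v1"), (E12, "cov"), (E22, "v2")]:
            g = u_t @ (E @ sinv).T
            cols.append(np.concatenate([Zt @ g[:, 0], Zt @ g[:, 1]]))
            names.append(f"{t}_{suffix}")
    for E, suffix in [(E11, "v1"), (E12, "cov"), (E22, "v2")]:
        g = ehat @ (E @ rinv).T
        cols.append(np.concatenate([g[:, 0], g[:, 1]]))
        names.append(f"residual_{suffix}")
    F = np.column_stack(cols)                       # (2n, n_par)

    def apply_rinv(v: np.ndarray) -> np.ndarray:
        a, b = v[:n], v[n:]
        return np.concatenate([rinv[0, 0] * a + rinv[0, 1] * b,
                               rinv[1, 0] * a + rinv[1, 1] * b])

    H = np.column_stack([apply_rinv(F[:, j]) for j in range(F.shape[1])])
    rhs = np.vstack([ws.W.T @ H[:n], ws.W.T @ H[n:]])
    theta = lu.solve(rhs)
    Wtheta = np.vstack([ws.W @ theta[:dim], ws.W @ theta[dim:]])
    PF = H - np.column_stack(
        [apply_rinv(Wtheta[:, j]) for j in range(F.shape[1])])
    AI = 0.5 * (F.T @ PF)
    AI = 0.5 * (AI + AI.T)
    try:
        cov = np.linalg.inv(AI)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("bivariate AI matrix singular; using pseudo-inverse")
        cov = np.linalg.pinv(AI)
    se = {}
    for t in terms + ["residual"]:
        ii = [names.index(f"{t}_v1"), names.index(f"{t}_cov"),
              names.index(f"{t}_v2")]
        se[t] = np.sqrt(np.clip(np.diag(cov)[ii], 0.0, None))
    return se, cov, names
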