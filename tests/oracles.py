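"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own computational paths:
gene dropping for additive relationships, a recursive kinship evaluator for
inbreeding, and dense whole-matrix GLS / restricted-likelihood evaluation.
"""

from __future__ import annotations

import numpy as np


def gene_drop_relationships(ped, n_drops: int = 100_000, seed: int = 0):
    """Estimate A by dropping biallelic founder alleles down the pedigree.

    Every founder gamete source gets a unique allele label; each drop
    segregates alleles independently. The additive relationship a_ij is
    twice the probability that random alleles from i and j are identical by
    descent. Returns (A_hat, SE_hat) with a per-entry Monte-Carlo SE.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    al = np.empty((n, 2, n_drops), dtype=np.int32)
    next_allele = 0
    for i in range(n):
        for gamete, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent < 0:
                al[i, gamete, :] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, n_drops)
                al[i, gamete, :] = np.where(
                    pick == 0, al[parent, 0, :], al[parent, 1, :])
    A = np.empty((n, n))
    SE = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                ibd = (al[i, 0] == al[i, 1]).astype(np.float64)
                per_drop = 1.0 + ibd
            else:
                per_drop = 0.5 * (
                    (al[i, 0] == al[j, 0]).astype(np.float64)
                    + (al[i, 0] == al[j, 1])
                    + (al[i, 1] == al[j, 0])
                    + (al[i, 1] == al[j, 1]))
            A[i, j] = A[j, i] = per_drop.mean()
            SE[i, j] = SE[j, i] = per_drop.std() / np.sqrt(n_drops)
    return A, SE


def recursive_kinship(sire: np.ndarray, dam: np.ndarray):
    """Kinship coefficients by the classic recursion (memoised).

    f(i, i) = 0.5 (1 + f(s_i, d_i)); for i < j (i not an ancestor of j is
    not required -- the ordered recursion handles it):
    f(i, j) = 0.5 (f(i, s_j) + f(i, d_j)) for j > i.
    Returns the function f(i, j); F_i = 2 f(i, i) - 1.
    """
    memo: dict[tuple[int, int], float] = {}

    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + f(sire[i], dam[i]))
        else:
            val = 0.5 * (f(i, sire[j]) + f(i, dam[j]))
        memo[key] = val
        return val

    return f


def dense_v_matrix(design, A: np.ndarray, comps: dict[str, float]):
    """Phenotypic covariance matrix V built densely from the components."""
    n = design.n
    V = comps["residual"] * np.eye(n)
    for term, Z in design.Z.items():
        Zd = Z.toarray()
        if term == "animal":
            V += comps[term] * Zd @ A @ Zd.T
        else:
            V += comps[term] * Zd @ Zd.T
    return V


def dense_gls(design, A: np.ndarray, comps: dict[str, float]):
    """Fixed effects and per-term BLUPs via the dense GLS formulas."""
    V = dense_v_matrix(design, A, comps)
    Vi = np.linalg.inv(V)
    X, y = design.X, design.y
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = Vi @ (y - X @ b)
    u = {}
    for term, Z in design.Z.items():
        Zd = Z.toarray()
        if term == "animal":
            u[term] = comps[term] * A @ Zd.T @ r
        else:
            u[term] = comps[term] * Zd.T @ r
    return b, u


def dense_neg2_restricted(design, A: np.ndarray, comps: dict[str, float]):
    """-2 log restricted likelihood from the dense V representation."""
    V = dense_v_matrix(design, A, comps)
    X, y = design.X, design.y
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    b = np.linalg.solve(XVX, X.T @ Vi @ y)
    quad = (y - X @ b) @ Vi @ y
    n, p = design.n, design.p
    return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1] + quad
            + (n - p) * np.log(2.0 * np.pi))
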