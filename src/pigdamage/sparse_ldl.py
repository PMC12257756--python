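"""Sparse LDL' factorisation for symmetric positive-definite MME systems.

REML iterates factorise the same sparsity pattern hundreds of times with
different numbers. This module therefore splits the work the way sparse
Cholesky codes do: a one-time symbolic analysis (fill-reducing ordering,
elimination tree, column counts) and a cheap numba-compiled numeric phase
(up-looking LDL', no pivoting -- the mixed-model coefficient matrix is
positive definite whenever the variance components are). The factor gives
log-determinants and triangular solves; both are exact, not approximate.

The ordering is taken from SuperLU's minimum-degree column permutation of
the pattern, computed once per pattern.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import splu


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):
    """Elimination tree and column counts of the upper-triangular pattern."""
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.empty(n, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i < k:
                while flag[i] != k:
                    if parent[i] == -1:
                        parent[i] = k
                    lnz[i] += 1
                    flag[i] = k
                    i = parent[i]
    return parent, lnz


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, Lp, parent, Li, Lx, D):
    """Up-looking numeric LDL'; returns 0 on success, k+1 on zero pivot."""
    Y = np.zeros(n)
    pattern = np.empty(n, dtype=np.int64)
    flag = np.empty(n, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i <= k:
                Y[i] += Ax[p]
                length = 0
                while flag[i] != k:
                    pattern[length] = i
                    length += 1
                    flag[i] = k
                    i = parent[i]
                while length > 0:
                    top -= 1
                    length -= 1
                    pattern[top] = pattern[length]
        D[k] = Y[k]
        Y[k] = 0.0
        for s in range(top, n):
            i = pattern[s]
            yi = Y[i]
            Y[i] = 0.0
            p2 = Lp[i] + lnz[i]
            for p in range(Lp[i], p2):
                Y[Li[p]] -= Lx[p] * yi
            lki = yi / D[i]
            D[k] -= lki * yi
            Li[p2] = k
            Lx[p2] = lki
            lnz[i] += 1
        if D[k] == 0.0:
            return k + 1
    return 0


@njit(cache=True)
def _locate_upper(Ap, Ai, pi, pj):
    """Binary-search positions of (pi, pj) entries in an upper CSC pattern."""
    out = np.empty(len(pi), dtype=np.int64)
    for k in range(len(pi)):
        lo, hi = Ap[pj[k]], Ap[pj[k] + 1]
        target = pi[k]
        while lo < hi:
            mid = (lo + hi) // 2
            if Ai[mid] < target:
                lo = mid + 1
            else:
                hi = mid
        out[k] = lo
    return out


@njit(cache=True)
def _ldl_solve(n, Lp, Li, Lx, D, B):
    """Solve L D L' X = B in place for each column of B."""
    for col in range(B.shape[1]):
        for j in range(n):
            bj = B[j, col]
            if bj != 0.0:
                for p in range(Lp[j], Lp[j + 1]):
                    B[Li[p], col] -= Lx[p] * bj
        for j in range(n):
            B[j, col] /= D[j]
        for j in range(n - 1, -1, -1):
            acc = B[j, col]
            for p in range(Lp[j], Lp[j + 1]):
                acc -= Lx[p] * B[Li[p], col]
            B[j, col] = acc


class SymbolicLDL:
    """Symbolic analysis of one SPD sparsity pattern, reused across factors.

    Parameters
    ----------
    pattern : scipy.sparse matrix
        Symmetric pattern (both triangles); values are ignored.
    """

    def __init__(self, pattern: sparse.spmatrix):
        S = sparse.csc_matrix(pattern)
        S.data = np.ones_like(S.data)
        n = S.shape[0]
        # fill-reducing ordering via SuperLU's minimum degree on the pattern
        lu = splu(S + sparse.identity(n, format="csc") * float(n),
                  permc_spec="MMD_AT_PLUS_A",
                  options={"SymmetricMode": True}, diag_pivot_thresh=0.0)
        # perm_c maps factor order -> original columns; invert it so that
        # S[perm][:, perm] eliminates in SuperLU's fill-reducing order
        self.perm = np.argsort(lu.perm_c).astype(np.int64)
        self.iperm = np.empty(n, dtype=np.int64)
        self.iperm[self.perm] = np.arange(n)

        P = S[self.perm][:, self.perm].tocsc()
        U = sparse.triu(P, format="csc")
        U.sort_indices()
        self.n = n
        self.Ap = U.indptr.astype(np.int64)
        self.Ai = U.indices.astype(np.int64)
        self.upper_nnz = U.nnz
        parent, lnz = _ldl_symbolic(n, self.Ap, self.Ai)
        self.parent = parent
        self.Lp = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(lnz, out=self.Lp[1:])
        self.lnz_total = int(self.Lp[-1])

    def data_map(self, mat: sparse.spmatrix) -> tuple[np.ndarray, np.ndarray]:
        """Map a matrix on (a subset of) the pattern into factor-input slots.

        Returns (slots, sign-preserving source index) such that
        ``upper_data[slots] += values[src]`` accumulates the permuted upper
        triangle of ``mat``.
        """
        C = sparse.coo_matrix(mat)
        C.sum_duplicates()
        pi = self.iperm[C.row]
        pj = self.iperm[C.col]
        keep = pi <= pj
        pi, pj = pi[keep], pj[keep]
        src = np.flatnonzero(keep)
        slots = _locate_upper(self.Ap, self.Ai, pi, pj)
        return slots, src

    def factor(self, upper_data: np.ndarray) -> "LDLFactor":
        """Numeric factorisation of the pattern filled with ``upper_data``."""
        Li = np.empty(self.lnz_total, dtype=np.int64)
        Lx = np.empty(self.lnz_total)
        D = np.empty(self.n)
        status = _ldl_numeric(self.n, self.Ap, self.Ai, upper_data,
                              self.Lp, self.parent, Li, Lx, D)
        if status != 0:
            raise np.linalg.LinAlgError(
                f"zero pivot at column {status - 1}: matrix not positive "
                "definite")
        return LDLFactor(self, Li, Lx, D)


class LDLFactor:
    """A numeric LDL' factor; solves and log-determinant."""

    def __init__(self, sym: SymbolicLDL, Li, Lx, D):
        self.sym = sym
        self.Li, self.Lx, self.D = Li, Lx, D

    @property
    def logdet(self) -> float:
        if np.any(self.D <= 0):
            raise np.linalg.LinAlgError("matrix not positive definite")
        return float(np.sum(np.log(self.D)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve M x = b for one or several right-hand sides."""
        sym = self.sym
        one_d = b.ndim == 1
        B = np.array(b, dtype=float, copy=True)
        if one_d:
            B = B[:, None]
        B = np.ascontiguousarray(B[sym.perm])
        _ldl_solve(sym.n, sym.Lp, self.Li, self.Lx, self.D, B)
        out = B[sym.iperm]
        return out[:, 0] if one_d else out


def aligned_vector(sym: SymbolicLDL, mat: sparse.spmatrix) -> np.ndarray:
    """Scatter a matrix on the pattern into a dense factor-input vector."""
    C = sparse.coo_matrix(mat)
    C.sum_duplicates()
    slots, src = sym.data_map(C)
    v = np.zeros(sym.upper_nnz)
    v[slots] = C.data[src]
    return v
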