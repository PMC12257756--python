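"""Pedigree handling: parsing, ordering, inbreeding and relationship matrices.

A pedigree is a list of (animal, sire, dam) triples. Internally animals are
indexed by topological order (parents before offspring), unknown parents are
coded as index -1, and inbreeding coefficients F are computed with the
Meuwissen & Luo path-tracing algorithm, which also yields the Mendelian
sampling variance coefficients d_i needed both for the sparse inverse of the
additive relationship matrix (Henderson's rules) and for simulating breeding
values consistent with the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: tokens accepted as "unknown parent" in pedigree files
DEFAULT_UNKNOWN_CODES = frozenset({"0", "", "NA", "na", "nan", ".", "unknown"})


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, ...)."""


@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    Attributes
    ----------
    ids : list of str
        Animal identifiers in topological order (every parent precedes its
        offspring).
    sire, dam : int arrays
        Parent indices into ``ids``; -1 codes an unknown parent.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _F: np.ndarray | None = field(default=None, repr=False)
    _d: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal: str) -> int:
        try:
            return self._index[animal]
        except KeyError:
            raise PedigreeError(f"unknown animal id: {animal!r}") from None

    @property
    def F(self) -> np.ndarray:
        """Inbreeding coefficient per animal (founders: 0)."""
        if self._F is None:
            self._compute_inbreeding()
        return self._F

    @property
    def mendelian_d(self) -> np.ndarray:
        """Mendelian sampling variance coefficients d_i.

        d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
        0.75 - 0.25 F_p with one parent known, and 1 for founders.
        These are the diagonal of D in A = T D T'.
        """
        if self._d is None:
            self._compute_inbreeding()
        return self._d

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build a pedigree from (animal, sire-or-None, dam-or-None) triples.

        Parents that never appear as animals are added as founders. Records
        are reordered topologically; cycles and duplicate ids raise
        :class:`PedigreeError`.
        """
        seen: dict[str, tuple[str | None, str | None]] = {}
        order_hint: list[str] = []
        for animal, s, d in records:
            if not animal:
                raise PedigreeError("empty animal id")
            if animal in seen:
                raise PedigreeError(f"duplicate animal id: {animal!r}")
            if s == animal or d == animal:
                raise PedigreeError(f"animal {animal!r} is its own parent")
            seen[animal] = (s, d)
            order_hint.append(animal)
        # auto-add parents that have no own record, as founders
        for animal in list(order_hint):
            for p in seen[animal]:
                if p is not None and p not in seen:
                    seen[p] = (None, None)
                    order_hint.append(p)

        order = _topological_order(seen, order_hint)
        index = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), -1, dtype=np.int64)
        dam = np.full(len(order), -1, dtype=np.int64)
        for a, (s, d) in seen.items():
            i = index[a]
            if s is not None:
                sire[i] = index[s]
            if d is not None:
                dam[i] = index[d]
        return cls(ids=order, sire=sire, dam=dam)

    def to_frame(self) -> pd.DataFrame:
        """Topologically sorted table with unknown parents coded '0'."""
        sire = ["0" if s < 0 else self.ids[s] for s in self.sire]
        dam = ["0" if d < 0 else self.ids[d] for d in self.dam]
        return pd.DataFrame({"animal": self.ids, "sire": sire, "dam": dam})

    def _compute_inbreeding(self) -> None:
        self._F, self._d = _meuwissen_luo(self.sire, self.dam)

    def log_det_a(self) -> float:
        """log-determinant of the additive relationship matrix A.

        With A = T D T' and T unit triangular, log|A| = sum(log d_i).
        """
        return float(np.sum(np.log(self.mendelian_d)))


def _topological_order(
    parents: dict[str, tuple[str | None, str | None]], order_hint: list[str]
) -> list[str]:
    """Kahn's algorithm, stable with respect to the input order.

    Raises :class:`PedigreeError` naming a member of a cycle if one exists.
    """
    children: dict[str, list[str]] = {a: [] for a in parents}
    n_parents: dict[str, int] = {}
    for a, (s, d) in parents.items():
        ps = {p for p in (s, d) if p is not None}
        n_parents[a] = len(ps)
        for p in ps:
            children[p].append(a)
    ready = [a for a in order_hint if n_parents[a] == 0]
    out: list[str] = []
    head = 0
    while head < len(ready):
        a = ready[head]
        head += 1
        out.append(a)
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                ready.append(c)
    if len(out) != len(parents):
        stuck = next(a for a in order_hint if a not in set(out))
        raise PedigreeError(
            f"pedigree contains a cycle (animal {stuck!r} is its own ancestor)"
        )
    return out


def _meuwissen_luo(
    sire: np.ndarray, dam: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding coefficients and Mendelian sampling coefficients.

    Path-tracing over the T matrix rows: a_ii = sum_j t_ij^2 d_j over the
    ancestors j of i, and F_i = a_ii - 1. The convention F = -1 for an
    unknown parent makes d_i = 0.5 - 0.25 (F_s + F_d) cover all three cases.
    """
    n = len(sire)
    F = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, t = sire[i], dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[t] if t >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or t < 0:
            continue  # F stays 0 with any unknown parent
        # trace the T-matrix row of the offspring; process ancestors in
        # decreasing index order so each coefficient is complete when used
        coeff: dict[int, float] = {}
        for p in (s, t):
            coeff[p] = coeff.get(p, 0.0) + 0.5
        a_off = 0.0
        todo = sorted(coeff, reverse=True)
        k = 0
        while k < len(todo):
            j = todo[k]
            k += 1
            c = coeff[j]
            a_off += c * c * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in coeff:
                        coeff[p] = 0.0
                        # insert keeping decreasing order
                        lo, hi = k, len(todo)
                        while lo < hi:
                            mid = (lo + hi) // 2
                            if todo[mid] > p:
                                lo = mid + 1
                            else:
                                hi = mid
                        todo.insert(lo, p)
                    coeff[p] += 0.5 * c
        # coeff started at the parents, so a_off = a_ii - d_i
        F[i] = a_off + d[i] - 1.0
    return F, d


def read_pedigree(path, unknown_codes=DEFAULT_UNKNOWN_CODES) -> Pedigree:
    """Read a pedigree CSV with columns animal,sire,dam.

    Unknown parents may be coded with any token in ``unknown_codes``
    (by default "0", empty, "NA" and a few common variants).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for c in ("animal", "sire", "dam"):
        if c not in cols:
            raise PedigreeError(f"pedigree file is missing column {c!r}")

    def norm(tok: str) -> str | None:
        tok = tok.strip()
        return None if tok in unknown_codes else tok

    records = [
        (a.strip(), norm(s), norm(d))
        for a, s, d in zip(df["animal"], df["sire"], df["dam"])
    ]
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a topologically sorted pedigree CSV (unknown parent = 0)."""
    ped.to_frame().to_csv(path, index=False)


def relationship_matrix(ped: Pedigree) -> pd.DataFrame:
    """Dense additive relationship matrix A by the tabular (recursive) method.

    a_ij = 0.5 (a_{i,s(j)} + a_{i,d(j)}) for i < j and
    a_jj = 1 + 0.5 a_{s(j),d(j)}; diagonal minus one reproduces F.
    Intended for pedigrees up to a few thousand animals; the mixed-model
    equations only ever need the sparse inverse from :func:`a_inverse`.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for j in range(n):
        s, d = sire[j], dam[j]
        if j > 0:
            row = np.zeros(j)
            if s >= 0:
                row += 0.5 * A[:j, s]
            if d >= 0:
                row += 0.5 * A[:j, d]
            A[:j, j] = row
            A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    # store F back into the pedigree (consistency with Meuwissen-Luo is a
    # property test)
    ped._F = np.diag(A) - 1.0
    return pd.DataFrame(A, index=ped.ids, columns=ped.ids)


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A via Henderson's rules with inbreeding.

    Uses alpha_i = 1/d_i with the Meuwissen-Luo Mendelian sampling
    coefficients, so fully accounts for inbred parents.
    """
    n = len(ped)
    alpha = 1.0 / ped.mendelian_d
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n)
    sire, dam = ped.sire, ped.dam

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=np.float64))

    add(idx, idx, alpha)
    for pcol in (sire, dam):
        m = pcol >= 0
        add(idx[m], pcol[m], -0.5 * alpha[m])
        add(pcol[m], idx[m], -0.5 * alpha[m])
        add(pcol[m], pcol[m], 0.25 * alpha[m])
    both = (sire >= 0) & (dam >= 0)
    add(sire[both], dam[both], 0.25 * alpha[both])
    add(dam[both], sire[both], 0.25 * alpha[both])
    Ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return Ainv.tocsr()


def mean_inbreeding(ped: Pedigree, subset: list[str]) -> float:
    """Mean inbreeding coefficient of a subset of animals.

    Equals the mean of the corresponding diagonal of A minus one.
    """
    if len(subset) == 0:
        raise PedigreeError("empty subset")
    idx = np.array([ped.index_of(a) for a in subset])
    return float(ped.F[idx].mean())


def prune_to_generations(
    ped: Pedigree, anchors: list[str], depth: int
) -> Pedigree:
    """Restrict a pedigree to anchors plus ancestors within `depth` meioses.

    Parents falling outside the cut become unknown. Relationships among
    retained animals whose full ancestry is retained are unchanged.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    keep: dict[int, int] = {}  # index -> remaining depth budget
    frontier = [(ped.index_of(a), depth) for a in anchors]
    while frontier:
        i, budget = frontier.pop()
        if i in keep and keep[i] >= budget:
            continue
        keep[i] = budget
        if budget > 0:
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    frontier.append((p, budget - 1))
    kept = sorted(keep)
    records = []
    kset = set(kept)
    for i in kept:
        s, d = ped.sire[i], ped.dam[i]
        records.append(
            (
                ped.ids[i],
                ped.ids[s] if s in kset else None,
                ped.ids[d] if d in kset else None,
            )
        )
    return Pedigree.from_records(records)
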