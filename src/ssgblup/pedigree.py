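"""Pedigree-based relationship machinery.

Numerator relationship matrices (A), their sparse inverses via
Henderson's rules with inbreeding, the genotyped-animal submatrix
A22, per-animal inbreeding coefficients, and the parent-average
accuracy baseline used to judge genomic candidates.

Animals with unknown parents are treated as unrelated, non-inbred
base individuals.  Input order is free: a topological sort is
computed internally and all public results are indexed by animal id.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve_triangular

__all__ = [
    "PedigreeError",
    "PedigreeTable",
    "compute_inbreeding",
    "build_A",
    "build_A_inverse",
    "extract_A22",
    "parent_average_accuracy",
]

UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, duplicate ids, ...)."""


@dataclass
class PedigreeTable:
    """Validated, topologically ordered pedigree.

    Attributes
    ----------
    ids : object ndarray of animal identifiers, parents before offspring.
    sire, dam : int ndarrays of positional parent indices (-1 = unknown).
    birth_year : int ndarray.
    breed : object ndarray of breed labels.
    sex : object ndarray ('M'/'F' or '' when unknown).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    breed: np.ndarray
    sex: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def indices_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"animal id not in pedigree: {exc.args[0]!r}") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PedigreeTable":
        """Build from a frame with columns animal, sire, dam, birth_year, breed, sex.

        Parent entries of 0, '0', '' or NaN mean unknown.  Rows may appear
        in any order; offspring listed before parents are handled by the
        topological sort.  Duplicate animal ids and pedigree cycles raise
        :class:`PedigreeError`.
        """
        required = {"animal", "sire", "dam"}
        missing = required - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree is missing columns: {sorted(missing)}")
        animals = df["animal"].to_numpy()
        if len(set(animals)) != len(animals):
            seen: set = set()
            dup = next(a for a in animals if a in seen or seen.add(a))
            raise PedigreeError(f"duplicate animal id in pedigree: {dup!r}")

        def norm(v):
            if pd.isna(v) or v == 0 or v == "0" or v == "":
                return None
            return v

        idx = {a: i for i, a in enumerate(animals)}
        n = len(animals)
        sire = np.full(n, UNKNOWN, dtype=np.int64)
        dam = np.full(n, UNKNOWN, dtype=np.int64)
        for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
            s, d = norm(s), norm(d)
            if s is not None:
                if s not in idx:
                    raise PedigreeError(f"sire {s!r} of {animals[i]!r} has no own record")
                sire[i] = idx[s]
            if d is not None:
                if d not in idx:
                    raise PedigreeError(f"dam {d!r} of {animals[i]!r} has no own record")
                dam[i] = idx[d]

        order = _toposort(sire, dam)
        inv = np.empty(n, dtype=np.int64)
        inv[order] = np.arange(n)

        def remap(parent):
            out = np.full(n, UNKNOWN, dtype=np.int64)
            old = parent[order]
            known = old != UNKNOWN
            out[known] = inv[old[known]]
            return out

        birth_year = (
            df["birth_year"].fillna(0).astype(int).to_numpy()
            if "birth_year" in df.columns
            else np.zeros(n, dtype=int)
        )
        breed = (
            df["breed"].astype(str).to_numpy()
            if "breed" in df.columns
            else np.full(n, "", dtype=object)
        )
        sex = (
            df["sex"].fillna("").astype(str).to_numpy()
            if "sex" in df.columns
            else np.full(n, "", dtype=object)
        )
        return cls(
            ids=np.asarray(animals, dtype=object)[order],
            sire=remap(sire),
            dam=remap(dam),
            birth_year=np.asarray(birth_year)[order],
            breed=np.asarray(breed, dtype=object)[order],
            sex=np.asarray(sex, dtype=object)[order],
        )

    def to_frame(self) -> pd.DataFrame:
        def back(parent):
            return [self.ids[p] if p != UNKNOWN else 0 for p in parent]

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": back(self.sire),
                "dam": back(self.dam),
                "birth_year": self.birth_year,
                "breed": self.breed,
                "sex": self.sex,
            }
        )


def _toposort(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Kahn topological order (parents first); raises on cycles."""
    n = len(sire)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                children[p].append(i)
                indeg[i] += 1
    from collections import deque

    queue = deque(i for i in range(n) if indeg[i] == 0)
    order = []
    while queue:
        i = queue.popleft()  # FIFO keeps the sort stable w.r.t. input order
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        raise PedigreeError("pedigree contains a cycle")
    return np.array(order, dtype=np.int64)


def compute_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Per-animal inbreeding coefficients F.

    F_i is half the kinship of the parents, computed by exact recursive
    kinship with memoization.  Animals with at least one unknown parent
    are non-inbred.
    """
    n = ped.n
    F = np.zeros(n)
    memo: dict[tuple[int, int], float] = {}
    sire, dam = ped.sire, ped.dam
    sys.setrecursionlimit(max(10000, 10 * n))

    def kin(a: int, b: int) -> float:
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if a == b:
            return 0.5 * (1.0 + F[a])
        if a < b:  # recurse on the later-born (larger topological index)
            a, b = b, a
        key = (a, b)
        hit = memo.get(key)
        if hit is not None:
            return hit
        val = 0.5 * (kin(sire[a], b) + kin(dam[a], b))
        memo[key] = val
        return val

    for i in range(n):  # topological order: parents already have F
        if sire[i] != UNKNOWN and dam[i] != UNKNOWN:
            F[i] = kin(sire[i], dam[i])
    return F


def mendelian_sampling_variance(ped: PedigreeTable, F: np.ndarray | None = None) -> np.ndarray:
    """Diagonal D of the A = T D T' decomposition.

    0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_known
    with one, and 1 for base animals.
    """
    if F is None:
        F = compute_inbreeding(ped)
    d = np.ones(ped.n)
    s_known = ped.sire != UNKNOWN
    d_known = ped.dam != UNKNOWN
    Fs = np.where(s_known, F[np.where(s_known, ped.sire, 0)], 0.0)
    Fd = np.where(d_known, F[np.where(d_known, ped.dam, 0)], 0.0)
    both = s_known & d_known
    one = s_known ^ d_known
    d[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    d[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    return d


def build_A(ped: PedigreeTable, ids=None) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    With ``ids`` the returned matrix is restricted to (and ordered by)
    those animals, but relationships are still propagated through all
    ancestors.  Materializes an n x n array; intended for desk-scale
    pedigrees and as the oracle for the sparse machinery.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    if ids is None:
        return A
    sel = ped.indices_of(ids)
    return A[np.ix_(sel, sel)]


def build_A_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 from Henderson's rules with inbreeding.

    Each animal contributes alpha_i = 1/d_i (Mendelian sampling
    variance d_i) to its own diagonal, -alpha/2 to animal x parent
    cells and alpha/4 among known parents.
    """
    if F is None:
        F = compute_inbreeding(ped)
    d = mendelian_sampling_variance(ped, F)
    alpha = 1.0 / d
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        a = alpha[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i)
        cols.append(i)
        vals.append(a)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-a / 2, -a / 2]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(a / 4)
    n = ped.n
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def relationship_columns(ped: PedigreeTable, ids, F: np.ndarray | None = None) -> np.ndarray:
    """Columns of A for the given animals without forming all of A.

    Uses A = T D T' with T = (I - P)^-1, P the parent-average matrix:
    two sparse triangular solves per block of right-hand sides
    (Colleau's indirect method), exact including inbreeding.
    """
    if F is None:
        F = compute_inbreeding(ped)
    n = ped.n
    sel = ped.indices_of(ids)
    d = mendelian_sampling_variance(ped, F)
    rows, cols, vals = [], [], []
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                rows.append(i)
                cols.append(p)
                vals.append(0.5)
    P = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    eye = sp.identity(n, format="csr")
    Z = np.zeros((n, len(sel)))
    Z[sel, np.arange(len(sel))] = 1.0
    # Y = T' Z  <=>  (I - P)' Y = Z   (upper triangular in topological order)
    Y = spsolve_triangular((eye - P).T.tocsr(), Z, lower=False)
    W = spsolve_triangular(eye - P, d[:, None] * Y, lower=True)
    return W  # n x k, column j = A[:, sel[j]]


def extract_A22(ped: PedigreeTable, genotyped_ids, F: np.ndarray | None = None) -> np.ndarray:
    """A restricted to the genotyped animals, in the order given.

    Exact (ancestors included) but never materializes the full A, so it
    scales to pedigrees where only the genotyped block is needed.
    """
    gid = list(genotyped_ids)
    if len(gid) != len(set(gid)):
        raise PedigreeError("duplicate ids in genotyped set")
    sel = ped.indices_of(gid)
    cols = relationship_columns(ped, gid, F=F)
    A22 = cols[sel, :]
    return 0.5 * (A22 + A22.T)  # symmetrize away solver round-off


def parent_average_accuracy(rel_sire: float, rel_dam: float):
    """Accuracy of the parent-average EBV: sqrt(rel_sire/4 + rel_dam/4).

    This is the pre-genomic baseline for a young candidate whose only
    information is its parents' reliabilities.  Accepts scalars or
    arrays; inputs must lie in [0, 1].
    """
    rs = np.asarray(rel_sire, dtype=float)
    rd = np.asarray(rel_dam, dtype=float)
    if np.any((rs < 0) | (rs > 1)) or np.any((rd < 0) | (rd > 1)):
        raise ValueError("parent reliabilities must lie in [0, 1]")
    out = np.sqrt(0.25 * rs + 0.25 * rd)
    return float(out) if out.ndim == 0 else out
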