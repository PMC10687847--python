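"""Pedigree container and additive (numerator) relationship machinery.

The additive relationship matrix A has a_ii = 1 + F_i (F_i the inbreeding
coefficient) and a_ij twice the kinship between i and j. Unknown parents are
treated as unrelated, non-inbred members of the base population; no genetic
groups are modelled.

Three routes to relatedness are provided:

* :meth:`Pedigree.relationship_matrix` — the dense tabular (recursive) method,
  the reference definition, intended for pedigrees up to a few thousand animals;
* :meth:`Pedigree.inbreeding` — Meuwissen & Luo style ancestor-tracing, linear
  memory, used wherever only the diagonal is needed;
* :meth:`Pedigree.a_inverse` — Henderson's rules with inbreeding, giving the
  sparse A^-1 the Gibbs samplers consume.
"""

from __future__ import annotations

import sys
from collections import deque
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

__all__ = ["Pedigree", "PedigreeError", "read_pedigree_csv"]

#: tokens accepted as "parent unknown" in input tables
UNKNOWN_TOKENS = {"", "0", "unknown", "UNKNOWN", "NA", "na", None}


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (cycles, duplicates, orphans)."""


def _is_unknown(tok) -> bool:
    if tok is None:
        return True
    if isinstance(tok, float) and np.isnan(tok):
        return True
    return str(tok).strip() in UNKNOWN_TOKENS


class Pedigree:
    """A topologically sorted pedigree.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``animal``, ``sire``, ``dam`` and optionally ``birth_year``.
        Unknown parents may be encoded as 0, empty, NA or "UNKNOWN".

    Raises
    ------
    PedigreeError
        On duplicate animal rows, a parent that never appears as an animal,
        an animal listed as its own ancestor, or any parent-relation cycle.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"animal", "sire", "dam"}
        missing = required - set(table.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns: {sorted(missing)}")

        animals = [str(a).strip() for a in table["animal"]]
        if len(set(animals)) != len(animals):
            dup = pd.Series(animals)
            dup = dup[dup.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal row: {dup!r}")

        pos = {a: k for k, a in enumerate(animals)}

        def parent_idx(tok, child):
            if _is_unknown(tok):
                return -1
            tok = str(tok).strip()
            if tok not in pos:
                raise PedigreeError(f"parent {tok!r} of {child!r} has no animal row")
            return pos[tok]

        n = len(animals)
        sire = np.empty(n, dtype=np.int64)
        dam = np.empty(n, dtype=np.int64)
        for k, (a, s, d) in enumerate(zip(animals, table["sire"], table["dam"])):
            sire[k] = parent_idx(s, a)
            dam[k] = parent_idx(d, a)
            if sire[k] == k or dam[k] == k:
                raise PedigreeError(f"animal {a!r} listed as its own parent")

        if "birth_year" in table.columns:
            by = pd.to_numeric(table["birth_year"], errors="coerce").to_numpy(float)
        else:
            by = np.full(n, np.nan)

        order = _topological_order(sire, dam, animals)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(n)

        remap = lambda idx: np.where(idx >= 0, rank[np.clip(idx, 0, None)], -1)
        self.ids: list[str] = [animals[k] for k in order]
        self.sire: np.ndarray = remap(sire)[order]
        self.dam: np.ndarray = remap(dam)[order]
        self.birth_year: np.ndarray = by[order]
        self._index = {a: k for k, a in enumerate(self.ids)}
        self._F: np.ndarray | None = None

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal) -> bool:
        return str(animal) in self._index

    def index_of(self, animals: Iterable) -> np.ndarray:
        """Row indices (in sorted order) of the given animal ids."""
        animals = list(animals)
        out = np.empty(len(animals), dtype=np.int64)
        for k, a in enumerate(animals):
            key = str(a).strip()
            if key not in self._index:
                raise PedigreeError(f"unknown animal id: {a!r}")
            out[k] = self._index[key]
        return out

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def to_frame(self) -> pd.DataFrame:
        """Sorted pedigree as a DataFrame (unknown parents encoded as '0')."""
        sire = ["0" if s < 0 else self.ids[s] for s in self.sire]
        dam = ["0" if d < 0 else self.ids[d] for d in self.dam]
        return pd.DataFrame(
            {"animal": self.ids, "sire": sire, "dam": dam, "birth_year": self.birth_year}
        )

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str}))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    # ------------------------------------------------------------- relatedness
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F (ancestor-tracing algorithm)."""
        if self._F is None:
            self._F = _inbreeding_ml(self.sire, self.dam)
        return self._F

    def relationship_matrix(self) -> np.ndarray:
        """Dense additive relationship matrix A in sorted-pedigree order."""
        return _tabular_a(self.sire, self.dam)

    def relationship_dataframe(self) -> pd.DataFrame:
        a = self.relationship_matrix()
        return pd.DataFrame(a, index=self.ids, columns=self.ids)

    def a_inverse(self) -> sparse.csr_matrix:
        """Sparse inverse of A (Henderson's rules with inbreeding)."""
        f = self.inbreeding()
        n = len(self)
        rows, cols, vals = _a_inverse_triplets(self.sire, self.dam, f)
        ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        ainv.sum_duplicates()
        return ainv

    def relatedness(self, i, j) -> float:
        """Additive relatedness a_ij for a single pair of animal ids."""
        a, b = self.index_of([i, j])
        memo: dict[tuple[int, int], float] = {}
        sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * len(self) + 100))
        return self._a_entry(max(a, b), min(a, b), memo)

    def _a_entry(self, i: int, j: int, memo) -> float:
        # i >= j in sorted order; recursion over ancestors only
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 1.0 + 0.5 * self._a_entry(self.sire[i], self.dam[i], memo)
        else:
            val = 0.5 * (
                self._a_entry(j, self.sire[i], memo) + self._a_entry(j, self.dam[i], memo)
            )
        memo[key] = val
        return val

    def mean_relatedness(self, pairs: Sequence[tuple]) -> float:
        """Arithmetic mean of a_ij over a list of (id, id) pairs."""
        if len(pairs) == 0:
            raise ValueError("no pairs given")
        memo: dict[tuple[int, int], float] = {}
        sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * len(self) + 100))
        total = 0.0
        for a, b in pairs:
            i, j = self.index_of([a, b])
            total += self._a_entry(max(i, j), min(i, j), memo)
        return total / len(pairs)


def read_pedigree_csv(path) -> Pedigree:
    """Read a header + comma-separated pedigree file (animal,sire,dam,birth_year)."""
    return Pedigree.from_csv(path)


# ---------------------------------------------------------------- topological
def _topological_order(sire: np.ndarray, dam: np.ndarray, names: list[str]) -> np.ndarray:
    """Kahn's algorithm, stable with respect to input order; names cycles."""
    n = len(sire)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for k in range(n):
        for p in (sire[k], dam[k]):
            if p >= 0:
                children[p].append(k)
                indeg[k] += 1
    queue = deque(k for k in range(n) if indeg[k] == 0)
    order = []
    while queue:
        k = queue.popleft()
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        stuck = next(k for k in range(n) if indeg[k] > 0)
        raise PedigreeError(
            f"pedigree contains a parent-relation cycle involving {names[stuck]!r}"
        )
    return np.asarray(order, dtype=np.int64)


# ------------------------------------------------------------------- kernels
@njit(cache=True)
def _tabular_a(sire, dam):  # pragma: no cover - exercised via wrapper
    n = sire.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        asd = a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * a[j, s]
            if d >= 0:
                v += 0.5 * a[j, d]
            a[i, j] = v
            a[j, i] = v
    return a


@njit(cache=True)
def _inbreeding_ml(sire, dam):  # pragma: no cover
    # a_ii = sum_j w_j^2 d_j over ancestors j, with w the L-row traced from i
    # and d_j the Mendelian-sampling variance ratio of j.
    n = sire.shape[0]
    f = np.zeros(n)
    d = np.zeros(n)
    w = np.zeros(n)
    touched = np.empty(n, dtype=np.int64)
    for i in range(n):
        s, dd = sire[i], dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[dd] if dd >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        ntouch = 0
        w[i] = 1.0
        touched[ntouch] = i
        ntouch += 1
        aii = 0.0
        for j in range(i, -1, -1):
            cj = w[j]
            if cj == 0.0:
                continue
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                if w[sj] == 0.0:
                    touched[ntouch] = sj
                    ntouch += 1
                w[sj] += 0.5 * cj
            if dj >= 0:
                if w[dj] == 0.0:
                    touched[ntouch] = dj
                    ntouch += 1
                w[dj] += 0.5 * cj
            aii += cj * cj * d[j]
        f[i] = aii - 1.0
        for t in range(ntouch):
            w[touched[t]] = 0.0
    return f


@njit(cache=True)
def _a_inverse_triplets(sire, dam, f):  # pragma: no cover
    n = sire.shape[0]
    cap = 9 * n
    rows = np.empty(cap, dtype=np.int64)
    cols = np.empty(cap, dtype=np.int64)
    vals = np.empty(cap)
    m = 0
    for i in range(n):
        s, d = sire[i], dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[d] if d >= 0 else -1.0
        alpha = 1.0 / (0.5 - 0.25 * (fs + fd))
        rows[m] = i; cols[m] = i; vals[m] = alpha; m += 1
        for p in (s, d):
            if p >= 0:
                rows[m] = i; cols[m] = p; vals[m] = -0.5 * alpha; m += 1
                rows[m] = p; cols[m] = i; vals[m] = -0.5 * alpha; m += 1
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    rows[m] = p; cols[m] = q; vals[m] = 0.25 * alpha; m += 1
    return rows[:m], cols[:m], vals[:m]
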