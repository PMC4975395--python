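"""Pedigree container and pedigree-based relationship matrices.

The numerator relationship matrix A holds expected additive genetic
relationships between animals implied by the pedigree.  Its inverse is
assembled directly and sparsely by Henderson's rules, with inbreeding
coefficients obtained by the Meuwissen–Luo recursion, so that no dense
inverse is ever formed for large pedigrees.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1


@dataclass
class Pedigree:
    """Ordered pedigree: parents always precede offspring.

    ids
        animal identifiers in record order.
    sire, dam
        integer positions of the parents in ``ids`` (``-1`` = unknown).
    generation
        optional generation label per animal (simulator fills this in).
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if len(self.ids) != len(self.sire) or len(self.ids) != len(self.dam):
            raise ValueError("ids, sire and dam must have equal length")
        if not self._pos:
            self._pos = {a: i for i, a in enumerate(self.ids)}
        if len(self._pos) != len(self.ids):
            raise ValueError("duplicate animal ids in pedigree")
        for i in range(self.n):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and not (0 <= p < i):
                    raise ValueError(
                        f"animal {self.ids[i]!r}: parent index {p} does not "
                        "precede the animal (pedigree must be sorted parents-first)"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id) -> int:
        try:
            return self._pos[animal_id]
        except KeyError:
            raise KeyError(f"animal id {animal_id!r} not in pedigree") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unknown=(0, "0", "", None)) -> "Pedigree":
        """Build from an (animal, sire, dam) table, re-sorting parents-first.

        Children listed before their parents are accepted and re-ordered;
        a parent id that never appears as an animal is an error.
        """
        animals = [a for a in df.iloc[:, 0]]
        sires = list(df.iloc[:, 1])
        dams = list(df.iloc[:, 2])
        unk = set(unknown)
        known = set(animals)
        parents = {}
        for a, s, d in zip(animals, sires, dams):
            s = None if (s in unk or (isinstance(s, float) and np.isnan(s))) else s
            d = None if (d in unk or (isinstance(d, float) and np.isnan(d))) else d
            for p in (s, d):
                if p is not None and p not in known:
                    raise ValueError(f"parent id {p!r} has no pedigree record")
            parents[a] = (s, d)
        # Kahn-style topological sort, stable in input order.
        order: list = []
        placed: set = set()
        pending = list(animals)
        while pending:
            progressed = False
            rest = []
            for a in pending:
                s, d = parents[a]
                if (s is None or s in placed) and (d is None or d in placed):
                    order.append(a)
                    placed.add(a)
                    progressed = True
                else:
                    rest.append(a)
            if not progressed:
                raise ValueError(f"pedigree contains a cycle involving {rest[:5]!r}")
            pending = rest
        pos = {a: i for i, a in enumerate(order)}
        sire_ix = np.array(
            [pos[parents[a][0]] if parents[a][0] is not None else UNKNOWN for a in order]
        )
        dam_ix = np.array(
            [pos[parents[a][1]] if parents[a][1] is not None else UNKNOWN for a in order]
        )
        return cls(order, sire_ix, dam_ix, _pos=pos)

    def to_frame(self) -> pd.DataFrame:
        sire_ids = [self.ids[s] if s != UNKNOWN else 0 for s in self.sire]
        dam_ids = [self.ids[d] if d != UNKNOWN else 0 for d in self.dam]
        return pd.DataFrame({"animal": self.ids, "sire": sire_ids, "dam": dam_ids})


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method, with inbreeding.

    a_ii = 1 + F_i where F_i = a(sire,dam)/2; off-diagonals follow the
    parent-average recursion.  O(n^2) time and memory — intended for
    pedigrees up to a few thousand animals.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    s, d = pedigree.sire, pedigree.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si != UNKNOWN and di != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        if i == 0:
            continue
        row = np.zeros(i)
        if si != UNKNOWN:
            row += 0.5 * A[si, :i]
        if di != UNKNOWN:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen–Luo recursion.

    For each animal the ancestor path coefficients L are accumulated from
    the animal down; A_ii = sum_j L_j^2 * D_j over ancestors j, where D_j
    is the Mendelian-sampling variance of j.  Runs in O(n * ancestors).
    """
    n = pedigree.n
    s, d = pedigree.sire, pedigree.dam
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian sampling variance, filled as we go
    for i in range(n):
        si, di = s[i], d[i]
        if si != UNKNOWN and di != UNKNOWN:
            D[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si != UNKNOWN or di != UNKNOWN:
            p = si if si != UNKNOWN else di
            D[i] = 0.75 - 0.25 * F[p]
        else:
            D[i] = 1.0
        if si == UNKNOWN or di == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate L over the ancestor closure of i, largest index first
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        seen = {i}
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            aii += lj * lj * D[j]
            for p in (s[j], d[j]):
                if p != UNKNOWN:
                    if p in L:
                        L[p] += 0.5 * lj
                    else:
                        L[p] = 0.5 * lj
                    if p not in seen:
                        seen.add(p)
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return F


def build_A_inverse(pedigree: Pedigree) -> sparse.csr_matrix:
    """Sparse A^{-1} by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of animal i is
    m_i = 0.5 - 0.25 (F_s + F_d) (both parents known),
    0.75 - 0.25 F_p (one known) or 1 (none); its reciprocal alpha_i is
    scattered over the (i, sire, dam) triple.
    """
    n = pedigree.n
    F = inbreeding_coefficients(pedigree)
    s, d = pedigree.sire, pedigree.dam
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        if si != UNKNOWN and di != UNKNOWN:
            m = 0.5 - 0.25 * (F[si] + F[di])
        elif si != UNKNOWN or di != UNKNOWN:
            p = si if si != UNKNOWN else di
            m = 0.75 - 0.25 * F[p]
        else:
            m = 1.0
        alpha = 1.0 / m
        add(i, i, alpha)
        for p in (si, di):
            if p != UNKNOWN:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (si, di):
            for q in (si, di):
                if p != UNKNOWN and q != UNKNOWN:
                    add(p, q, 0.25 * alpha)
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
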