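"""Pedigree and marker-based relationship matrices.

Three square matrices drive the rest of the pipeline:

* ``A`` — the pedigree numerator relationship matrix, built by the tabular
  (recursive) method: founders have ``a_ii = 1``; an animal with sire *s* and
  dam *d* has ``a_ii = 1 + 0.5 a_sd`` and ``a_ij = 0.5 (a_js + a_jd)`` for any
  older animal *j*; unknown parents contribute nothing.
* ``G`` — the VanRaden genomic relationship matrix
  ``G = W Wᵀ / (2 Σ p_i (1 − p_i))`` with ``W = M − 2P`` the allele-frequency
  centered dosage matrix.
* ``D`` — genetic dissimilarity ``d_ij = 1 − a_ij / √(a_ii a_jj)``, i.e. one
  minus Wright's coefficient of relationship, used to cluster animals into
  cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "build_A",
    "build_G",
    "build_D",
    "blend",
]

UNKNOWN = -1


@dataclass
class Pedigree:
    """Parent records for a set of animals.

    ``sire`` and ``dam`` are integer indices into ``ids`` (``-1`` = unknown).
    ``generation`` and ``sex`` (0 = male, 1 = female) are optional metadata
    used by the simulator.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(map(str, self.ids))) != n:
            raise ValueError("pedigree ids must be unique")
        for arr, name in ((self.sire, "sire"), (self.dam, "dam")):
            if arr.shape != (n,):
                raise ValueError(f"{name} array length != number of ids")
            if np.any((arr < UNKNOWN) | (arr >= n)):
                raise ValueError(f"{name} indices out of range")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], unknown: str = "0"
    ) -> "Pedigree":
        """Build from (animal, sire, dam) id triples; ``unknown`` marks a
        missing parent. Parents that never appear as animals are added as
        founders."""
        records = [tuple(map(str, r)) for r in records]
        ids: list[str] = []
        seen: set[str] = set()
        for a, s, d in records:
            for x in (s, d):
                if x != unknown and x not in seen:
                    seen.add(x)
                    ids.append(x)
            if a in seen:
                raise ValueError(f"duplicate or reordered animal id {a!r}")
            seen.add(a)
            ids.append(a)
        # parents-as-founders first is a convenience; re-derive parent arrays
        idx = {a: i for i, a in enumerate(ids)}
        recorded = {a: (s, d) for a, s, d in records}
        sire = np.full(len(ids), UNKNOWN, dtype=np.int64)
        dam = np.full(len(ids), UNKNOWN, dtype=np.int64)
        for a, (s, d) in recorded.items():
            if s != unknown:
                sire[idx[a]] = idx[s]
            if d != unknown:
                dam[idx[a]] = idx[d]
        ped = cls(ids=ids, sire=sire, dam=dam)
        ped.topological_order()  # validates acyclicity
        return ped

    def to_frame(self, unknown: str = "0") -> pd.DataFrame:
        def name(i: int) -> str:
            return unknown if i == UNKNOWN else str(self.ids[i])

        return pd.DataFrame(
            {
                "animal": [str(a) for a in self.ids],
                "sire": [name(i) for i in self.sire],
                "dam": [name(i) for i in self.dam],
            }
        )

    def topological_order(self) -> np.ndarray:
        """Order in which every parent precedes its offspring.

        Raises ``ValueError`` naming a cycle if the pedigree is cyclic
        (an animal its own ancestor).
        """
        n = self.n
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for j in range(n):
            for par in (self.sire[j], self.dam[j]):
                if par != UNKNOWN:
                    children[par].append(j)
                    indeg[j] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        order: list[int] = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) < n:
            cycle = self._find_cycle()
            names = " -> ".join(str(self.ids[i]) for i in cycle)
            raise ValueError(f"pedigree contains a cycle: {names}")
        return np.asarray(order, dtype=np.int64)

    def _find_cycle(self) -> list[int]:
        color = np.zeros(self.n, dtype=np.int8)  # 0 new, 1 active, 2 done
        stack: list[int] = []

        def dfs(i: int) -> list[int] | None:
            color[i] = 1
            stack.append(i)
            for par in (self.sire[i], self.dam[i]):
                if par == UNKNOWN:
                    continue
                if color[par] == 1:
                    k = stack.index(par)
                    return stack[k:] + [par]
                if color[par] == 0:
                    found = dfs(par)
                    if found:
                        return found
            color[i] = 2
            stack.pop()
            return None

        for i in range(self.n):
            if color[i] == 0:
                found = dfs(i)
                if found:
                    return found
        return []


@dataclass
class RelationshipMatrix:
    """A square symmetric relationship matrix keyed by animal ids."""

    kind: str  # "A", "G" or "D"
    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimension does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence) -> np.ndarray:
        lookup = {str(a): i for i, a in enumerate(self.ids)}
        try:
            return np.asarray([lookup[str(a)] for a in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"animal {exc.args[0]!r} not in matrix") from None

    def submatrix(self, ids: Sequence) -> "RelationshipMatrix":
        ix = self.index_of(ids)
        return RelationshipMatrix(
            kind=self.kind, ids=[self.ids[i] for i in ix],
            values=self.values[np.ix_(ix, ix)],
        )

    def to_frame(self) -> pd.DataFrame:
        names = [str(a) for a in self.ids]
        return pd.DataFrame(self.values, index=names, columns=names)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method."""
    order = ped.topological_order()
    n = ped.n
    A = np.zeros((n, n))
    for j in order:
        s, d = ped.sire[j], ped.dam[j]
        col = np.zeros(n)
        if s != UNKNOWN:
            col += 0.5 * A[:, s]
        if d != UNKNOWN:
            col += 0.5 * A[:, d]
        ajj = 1.0
        if s != UNKNOWN and d != UNKNOWN:
            ajj += 0.5 * A[s, d]
        A[:, j] = col
        A[j, :] = col
        A[j, j] = ajj
    return RelationshipMatrix(kind="A", ids=list(ped.ids), values=A)


def build_G(
    genotypes,
    freqs: np.ndarray | None = None,
    ids: Sequence | None = None,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    ``genotypes`` is an animals × SNPs dosage array (0/1/2, no missing) or a
    :class:`~gsel.qc.GenotypeMatrix`. ``freqs`` are counted-allele
    frequencies; by default they are recomputed from the given animals.
    """
    if hasattr(genotypes, "dosage"):
        M = np.asarray(genotypes.dosage, dtype=float)
        if ids is None:
            ids = list(genotypes.animal_ids)
    else:
        M = np.asarray(genotypes, dtype=float)
    if np.isnan(M).any():
        raise ValueError("dosage matrix contains missing values; impute first")
    if ids is None:
        ids = [str(i) for i in range(M.shape[0])]
    p = np.asarray(freqs, dtype=float) if freqs is not None else M.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    W = M - 2.0 * p
    G = (W @ W.T) / denom
    return RelationshipMatrix(kind="G", ids=list(ids), values=G)


def blend(rel: RelationshipMatrix | np.ndarray, weight: float = 0.01):
    """Shrink toward the identity, ``G* = (1−w) G + w I``, so the matrix is
    safely invertible in the mixed model equations."""
    if isinstance(rel, RelationshipMatrix):
        return RelationshipMatrix(
            kind=rel.kind, ids=list(rel.ids),
            values=blend(rel.values, weight),
        )
    V = np.asarray(rel, dtype=float)
    return (1.0 - weight) * V + weight * np.eye(V.shape[0])


def build_D(a: RelationshipMatrix) -> RelationshipMatrix:
    """Genetic dissimilarity ``d_ij = 1 − a_ij/√(a_ii a_jj)`` with an exactly
    zero diagonal."""
    diag = np.diag(a.values)
    if np.any(diag <= 0):
        bad = [str(a.ids[i]) for i in np.flatnonzero(diag <= 0)]
        raise ValueError(f"nonpositive diagonal for animals {bad}")
    scale = np.sqrt(np.outer(diag, diag))
    D = 1.0 - a.values / scale
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return RelationshipMatrix(kind="D", ids=list(a.ids), values=D)
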