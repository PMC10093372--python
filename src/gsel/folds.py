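"""Cross-validation fold design.

Two schemes: k-means clustering of animals on the rows of the genetic
dissimilarity matrix D (folds become families, minimizing relatedness
between training and validation sets) and balanced random splitting with
replicates. The k-means routine is Hartigan–Wong style: single-point
relocations accepted when they reduce the within-cluster sum of squares,
with the exact n/(n±1) transfer factors, restarted from ``n_starts`` random
initializations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "kmeans_folds",
    "random_folds",
    "relatedness_summary",
]


@dataclass
class FoldAssignment:
    """Animal → fold (1..k) mapping for one CV scheme."""

    scheme: str  # "kmeans" or "random"
    fold_of: pd.Series  # index: animal id (str), values: int fold
    replicate: int = 0
    wss: float | None = None  # k-means objective, when applicable

    @property
    def k(self) -> int:
        return int(self.fold_of.max())

    @property
    def fold_sizes(self) -> pd.Series:
        return self.fold_of.value_counts().sort_index()

    def fold_ids(self, fold: int) -> list[str]:
        return list(self.fold_of.index[self.fold_of == fold])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.fold_of.index,
                "scheme": self.scheme,
                "replicate": self.replicate,
                "fold": self.fold_of.to_numpy(),
            }
        )


def _hartigan_wong(
    X: np.ndarray, k: int, rng: np.random.Generator, max_sweeps: int = 100
) -> tuple[np.ndarray, float]:
    n = X.shape[0]
    centers_idx = rng.choice(n, size=k, replace=False)
    centers = X[centers_idx].astype(float).copy()
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    assign[centers_idx] = np.arange(k)  # guarantee non-empty clusters
    sizes = np.bincount(assign, minlength=k).astype(float)
    for c in range(k):
        centers[c] = X[assign == c].mean(axis=0)

    for _ in range(max_sweeps):
        moved = False
        for i in range(n):
            a = assign[i]
            if sizes[a] <= 1:
                continue  # never empty a cluster
            diff = centers - X[i]
            d2i = (diff * diff).sum(axis=1)
            remove_gain = sizes[a] / (sizes[a] - 1.0) * d2i[a]
            add_cost = sizes / (sizes + 1.0) * d2i
            add_cost[a] = np.inf
            b = int(add_cost.argmin())
            if add_cost[b] - remove_gain < -1e-12:
                centers[a] = (centers[a] * sizes[a] - X[i]) / (sizes[a] - 1.0)
                centers[b] = (centers[b] * sizes[b] + X[i]) / (sizes[b] + 1.0)
                sizes[a] -= 1.0
                sizes[b] += 1.0
                assign[i] = b
                moved = True
        if not moved:
            break
    wss = 0.0
    for c in range(k):
        diff = X[assign == c] - centers[c]
        wss += float((diff * diff).sum())
    return assign, wss


def _classical_mds(D: np.ndarray, n_components: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def kmeans_folds(
    d: RelationshipMatrix,
    k: int = 10,
    seed: int = 0,
    n_starts: int = 25,
    embed: str = "raw",
) -> FoldAssignment:
    """Cluster animals into k folds by k-means on the dissimilarity matrix.

    Each animal's feature vector is its row of D (``embed="raw"``, the
    default — equivalent to handing the D matrix to a k-means routine
    directly) or a classical-MDS embedding of D (``embed="mds"``). The best
    of ``n_starts`` restarts by within-cluster sum of squares is kept;
    cluster labels are renumbered 1..k in order of first appearance.
    """
    n = d.n
    if k > n:
        raise ValueError(f"k={k} exceeds the number of animals ({n})")
    if embed == "raw":
        X = d.values
    elif embed == "mds":
        X = _classical_mds(d.values, n_components=min(n - 1, 10))
    else:
        raise ValueError(f"unknown embedding {embed!r}")
    rng = np.random.default_rng(seed)
    best_assign, best_wss = None, np.inf
    for _ in range(n_starts):
        assign, wss = _hartigan_wong(X, k, rng)
        if wss < best_wss - 1e-12:
            best_assign, best_wss = assign, wss
    relabel: dict[int, int] = {}
    folds = np.empty(n, dtype=int)
    for i, c in enumerate(best_assign):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        folds[i] = relabel[c]
    fold_of = pd.Series(folds, index=[str(a) for a in d.ids], name="fold")
    sizes = fold_of.value_counts()
    logger.info(
        "kmeans folds: k=%d, WSS=%.4f, sizes %s",
        k, best_wss, sizes.sort_index().to_list(),
    )
    return FoldAssignment(scheme="kmeans", fold_of=fold_of, wss=best_wss)


def random_folds(
    ids, k: int = 10, n_replicates: int = 5, seed: int = 0
) -> list[FoldAssignment]:
    """Balanced random 10-fold partitions, one FoldAssignment per replicate;
    fold sizes differ by at most one."""
    ids = [str(a) for a in ids]
    n = len(ids)
    if n < k:
        raise ValueError(f"need at least k={k} animals, got {n}")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(1, n_replicates + 1):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, k), start=1):
            folds[chunk] = f
        out.append(
            FoldAssignment(
                scheme="random",
                replicate=rep,
                fold_of=pd.Series(folds, index=ids, name="fold"),
            )
        )
    return out


def relatedness_summary(
    a: RelationshipMatrix, assignment: FoldAssignment
) -> dict[str, float]:
    """Mean pairwise relationship within folds vs between folds — the
    quantity fold design by dissimilarity clustering is meant to separate."""
    ix = a.index_of(assignment.fold_of.index)
    V = a.values[np.ix_(ix, ix)]
    folds = assignment.fold_of.to_numpy()
    same = folds[:, None] == folds[None, :]
    off = ~np.eye(len(folds), dtype=bool)
    within = float(V[same & off].mean())
    between = float(V[~same].mean())
    return {"within": within, "between": between, "gap": within - between}
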