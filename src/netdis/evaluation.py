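"""Nearest-neighbour evaluation of distance matrices against clusters.

Classification quality of a network-comparison statistic is scored by how
well nearest neighbours under the distance agree with a ground-truth
clustering: the 1-NN score is the fraction of items whose single nearest
neighbour shares their cluster, and the k_C-NN score takes, for each item in
a cluster of size C, its C-1 nearest neighbours and averages the fraction
of them that share the cluster.  A random baseline is obtained by averaging
both scores over i.i.d. uniform random distance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("netdis")

__all__ = [
    "DistanceMatrix",
    "read_labels_tsv",
    "write_labels_tsv",
    "nn_score",
    "kc_nn_score",
    "random_baseline",
    "BaselineResult",
]


class UndefinedScoreError(ValueError):
    """Raised when a score has no eligible items (e.g. all singletons)."""


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal.

    Missing (degenerate) entries are NaN; items touched by a NaN are
    excluded from scoring and logged.
    """

    names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match names")
        both = ~np.isnan(self.values)
        if not np.array_equal(
            self.values[both & both.T], self.values.T[both & both.T]
        ):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.names, columns=self.names)
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(names=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=float))

    def complete_items(self) -> list:
        """Indices of items with no missing off-diagonal entries."""
        bad = np.isnan(self.values).any(axis=1)
        if bad.any():
            logger.warning(
                "excluding %d item(s) with missing distances: %s",
                bad.sum(),
                [self.names[i] for i in np.flatnonzero(bad)],
            )
        return [i for i in range(len(self.names)) if not bad[i]]


def read_labels_tsv(path: str | Path) -> dict:
    """Two-column TSV (name, cluster) -> label mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "cluster"],
                     dtype=str, comment="#")
    return dict(zip(df["name"], df["cluster"]))


def write_labels_tsv(labels: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(labels, key=str):
            fh.write(f"{name}\t{labels[name]}\n")


def _ranked_neighbours(D: DistanceMatrix, items, i):
    """Other items ordered by (distance, name): deterministic lexicographic
    tie-breaking."""
    others = [j for j in items if j != i]
    return sorted(others, key=lambda j: (D.values[i, j], str(D.names[j])))


def _check_labels(D: DistanceMatrix, labels: dict, items):
    missing = [D.names[i] for i in items if D.names[i] not in labels]
    if missing:
        raise KeyError(f"items without cluster labels: {missing}")


def nn_score(D: DistanceMatrix, labels: dict) -> float:
    """Fraction of items whose nearest neighbour shares their cluster."""
    items = D.complete_items()
    if len(items) < 2:
        raise ValueError("need at least 2 scorable items")
    _check_labels(D, labels, items)
    correct = 0
    for i in items:
        nearest = _ranked_neighbours(D, items, i)[0]
        correct += labels[D.names[i]] == labels[D.names[nearest]]
    return correct / len(items)


def kc_nn_score(D: DistanceMatrix, labels: dict) -> float:
    """Mean over items of the fraction of an item's C-1 nearest neighbours
    that share its cluster, where C is the item's cluster size.

    Items in singleton clusters are skipped (k would be 0); if every
    cluster is a singleton the score is undefined.
    """
    items = D.complete_items()
    if len(items) < 2:
        raise ValueError("need at least 2 scorable items")
    _check_labels(D, labels, items)
    sizes: dict = {}
    for i in items:
        lab = labels[D.names[i]]
        sizes[lab] = sizes.get(lab, 0) + 1
    contributions = []
    for i in items:
        lab = labels[D.names[i]]
        k = sizes[lab] - 1
        if k == 0:
            continue
        ranked = _ranked_neighbours(D, items, i)[:k]
        hits = sum(labels[D.names[j]] == lab for j in ranked)
        contributions.append(hits / k)
    if not contributions:
        raise UndefinedScoreError("all clusters are singletons")
    return float(np.mean(contributions))


@dataclass
class BaselineResult:
    """Nearest-neighbour scores of random distance matrices."""

    nn_scores: np.ndarray
    kc_scores: np.ndarray

    @property
    def mean_nn(self) -> float:
        return float(self.nn_scores.mean())

    @property
    def mean_kc(self) -> float:
        return float(self.kc_scores.mean())


def random_baseline(
    labels: dict, n_matrices: int = 50, seed: int = 0
) -> BaselineResult:
    """Average 1-NN and k_C-NN scores over random distance matrices whose
    upper-triangle entries are i.i.d. Uniform(0, 1)."""
    if n_matrices < 1:
        raise ValueError("n_matrices must be >= 1")
    names = sorted(labels, key=str)
    n = len(names)
    rng = np.random.default_rng(seed)
    nn_s, kc_s = [], []
    for _ in range(n_matrices):
        upper = rng.uniform(size=(n, n))
        values = np.triu(upper, 1)
        values = values + values.T
        D = DistanceMatrix(names=names, values=values)
        nn_s.append(nn_score(D, labels))
        kc_s.append(kc_nn_score(D, labels))
    return BaselineResult(
        nn_scores=np.array(nn_s), kc_scores=np.array(kc_s)
    )
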