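"""Neighbourhood-balance diagnostics for the sub-sampling scheme.

Sub-sampling ego-networks is theoretically justified when the dependency
neighbourhoods (two-step neighbourhoods) are of comparable size and do not
overlap too much on average.  These diagnostics are explicit *proxies* for
those conditions: the dispersion of the neighbourhood sizes gamma_i, an
estimate of the mean pairwise Jaccard overlap, the count of nodes whose
gamma_i falls outside a multiplicative band around the mean, and the
detection of groups of nodes with *identical* large neighbourhoods.  The
last signal targets the known failure mode where a network hides a small
region radically different from the rest -- e.g. a sparse random graph with
a disjoint 30-clique, whose clique ego-networks are all identical and
intersect completely: no scalar summary of gamma moves detectably there,
but the duplicate-neighbourhood group is unmistakable.

The report is advisory: it warns, it never blocks computation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graphs import adjacency_sets, two_step_ego_nodes

__all__ = [
    "NeighbourhoodStats",
    "RiskReport",
    "neighbourhood_stats",
    "flag_subsampling_risk",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_TAU = 3.0
DEFAULT_THRESHOLDS = {
    "cv_max": 1.0,              # coefficient of variation of gamma
    "overlap_max": 0.5,         # mean pairwise Jaccard overlap
    "coverage_max": 0.5,        # overlap only risky if neighbourhoods are
                                # small relative to the graph (mean closed
                                # neighbourhood <= this fraction of n)
    "dup_group_min": 3,         # nodes sharing an identical neighbourhood
    "dup_size_min_abs": 10,     # ... of at least this many nodes and
    "dup_size_min_rel": 2.0,    # ... at least this multiple of the mean
}


@dataclass
class NeighbourhoodStats:
    """Summary of dependency-neighbourhood sizes and overlaps.

    sizes
        gamma_i = |two-step neighbourhood of i, excluding i| per node.
    mean_pairwise_overlap
        Jaccard overlap of the neighbourhood sets, averaged over sampled
        node pairs (empty-vs-empty pairs count as overlap 0).
    n_unbalanced
        Nodes with gamma outside [mean/tau, tau*mean].
    max_duplicate_group / duplicate_group_size
        Size of the largest group of nodes sharing an identical *closed*
        two-step neighbourhood, and that shared neighbourhood's node count.
    """

    sizes: dict
    tau: float
    mean: float = field(init=False)
    cv: float = field(init=False)
    mean_pairwise_overlap: float = 0.0
    n_unbalanced: int = 0
    max_duplicate_group: int = 0
    duplicate_group_size: int = 0

    def __post_init__(self):
        gammas = np.array(list(self.sizes.values()), dtype=float)
        self.mean = float(gammas.mean()) if len(gammas) else 0.0
        self.cv = (
            float(gammas.std() / self.mean) if self.mean > 0 else 0.0
        )


def neighbourhood_stats(
    G: nx.Graph,
    tau: float = DEFAULT_TAU,
    pair_sample: int = 1000,
    seed: int = 0,
) -> NeighbourhoodStats:
    """Exact per-node gamma_i; overlap estimated over ``pair_sample``
    uniformly drawn node pairs; deterministic given ``seed``."""
    if tau <= 1:
        raise ValueError(f"tau must be > 1, got {tau}")
    if pair_sample < 1:
        raise ValueError("pair_sample must be >= 1")
    nodes = sorted(G, key=str)
    adj = adjacency_sets(G)
    closed = {v: frozenset(two_step_ego_nodes(adj, v)) for v in nodes}
    sizes = {v: len(closed[v]) - 1 for v in nodes}
    stats = NeighbourhoodStats(sizes=sizes, tau=tau)

    gammas = np.array([sizes[v] for v in nodes], dtype=float)
    if stats.mean > 0:
        lo, hi = stats.mean / tau, stats.mean * tau
        stats.n_unbalanced = int(((gammas < lo) | (gammas > hi)).sum())

    rng = np.random.default_rng(seed)
    n = len(nodes)
    overlaps = []
    if n >= 2:
        for _ in range(pair_sample):
            i, j = rng.choice(n, size=2, replace=False)
            a = closed[nodes[i]] - {nodes[i]}
            b = closed[nodes[j]] - {nodes[j]}
            union = len(a | b)
            overlaps.append(len(a & b) / union if union else 0.0)
    stats.mean_pairwise_overlap = float(np.mean(overlaps)) if overlaps else 0.0

    groups = defaultdict(list)
    for v in nodes:
        groups[closed[v]].append(v)
    best = max(groups.values(), key=len, default=[])
    if len(best) > 1:
        stats.max_duplicate_group = len(best)
        stats.duplicate_group_size = len(closed[best[0]])
    return stats


@dataclass
class RiskReport:
    """Advisory sub-sampling risk assessment."""

    flagged: bool
    reasons: list
    stats: NeighbourhoodStats

    def summary(self) -> str:
        head = (
            "sub-sampling risk: FLAGGED" if self.flagged
            else "sub-sampling risk: none detected"
        )
        lines = [head] + [f"  - {r}" for r in self.reasons]
        s = self.stats
        lines.append(
            f"  gamma mean={s.mean:.2f} cv={s.cv:.3f} "
            f"overlap={s.mean_pairwise_overlap:.4f} "
            f"unbalanced(tau={s.tau:g})={s.n_unbalanced}"
        )
        return "\n".join(lines)


def flag_subsampling_risk(
    stats: NeighbourhoodStats, thresholds: dict | None = None
) -> RiskReport:
    """Warn when neighbourhood sizes are too dispersed, overlaps too large,
    or a sizeable group of identical large neighbourhoods exists."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    reasons = []
    if stats.cv > th["cv_max"]:
        reasons.append(
            f"neighbourhood sizes highly dispersed (cv={stats.cv:.2f} "
            f"> {th['cv_max']:g})"
        )
    n = len(stats.sizes)
    small_neighbourhoods = (stats.mean + 1) <= th["coverage_max"] * max(n, 1)
    if stats.mean_pairwise_overlap > th["overlap_max"] and small_neighbourhoods:
        reasons.append(
            f"mean pairwise overlap {stats.mean_pairwise_overlap:.2f} "
            f"> {th['overlap_max']:g}"
        )
    dup_floor = max(
        th["dup_size_min_abs"], th["dup_size_min_rel"] * (stats.mean + 1)
    )
    if (
        stats.max_duplicate_group >= th["dup_group_min"]
        and stats.duplicate_group_size >= dup_floor
    ):
        reasons.append(
            f"{stats.max_duplicate_group} nodes share an identical "
            f"{stats.duplicate_group_size}-node neighbourhood (possible "
            "disconnected clique-like region)"
        )
    return RiskReport(flagged=bool(reasons), reasons=reasons, stats=stats)
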