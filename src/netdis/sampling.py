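"""Ego-network sub-sampling and the neighbourhood bootstrap.

Two sampling schemes are provided.  Plain uniform sub-sampling without
replacement (:func:`sample_ego_ids`) is what the distance pipeline uses: the
centered sums are computed over a random subset of ego-networks instead of
all of them.  The seed-plus-neighbourhood bootstrap
(:func:`bootstrap_sample`) draws seed nodes uniformly *with* replacement and
includes each seed's whole dependency neighbourhood (its two-step
ego-network); the result is summarised as an empirical measure whose point
masses are proportional to inclusion multiplicities and sum to 1.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphs import adjacency_sets, two_step_ego_nodes

__all__ = [
    "SampleSpec",
    "EmpiricalMeasure",
    "sample_ego_ids",
    "bootstrap_sample",
    "substream_seed",
]


class SampleTooLargeError(ValueError):
    """Raised when a count-mode sample exceeds the number of nodes."""


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-graph RNG substream seed derived from the run seed
    and the graph name, so adding a graph to a run does not perturb the
    samples drawn for the others."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SampleSpec:
    """How to sample ego-networks.

    mode
        ``"fraction"`` (sample ceil(value * |V|) egos) or ``"count"``
        (sample exactly ``value`` egos).
    value
        A fraction in (0, 1] or a positive integer count.
    seed
        RNG seed; the same spec always yields the same sample.
    replacement
        False for plain sub-sampling (the only mode accepted by
        :func:`sample_ego_ids`); bootstrap seeds use their own entry point.
    """

    mode: str
    value: float
    seed: int = 0
    replacement: bool = False

    def __post_init__(self):
        if self.mode not in ("fraction", "count"):
            raise ValueError(f"unknown sample mode {self.mode!r}")
        if self.mode == "fraction" and not 0 < self.value <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.value}")
        if self.mode == "count" and (
            self.value < 1 or int(self.value) != self.value
        ):
            raise ValueError(f"count must be a positive integer, got {self.value}")

    def size_for(self, n_nodes: int) -> int:
        if self.mode == "fraction":
            return min(n_nodes, math.ceil(self.value * n_nodes))
        return int(self.value)


def sample_ego_ids(G: nx.Graph, spec: SampleSpec) -> list:
    """Uniform sample of ego identifiers without replacement.

    Fraction mode rounds up so that any positive fraction samples at least
    one ego.  Output is sorted for stable downstream iteration.
    """
    if spec.replacement:
        raise ValueError("sample_ego_ids is a without-replacement sampler")
    nodes = sorted(G, key=str)
    n = len(nodes)
    size = spec.size_for(n)
    if size > n:
        raise SampleTooLargeError(f"requested {size} egos from {n} nodes")
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(n, size=size, replace=False)
    return sorted((nodes[i] for i in chosen), key=str)


@dataclass(frozen=True)
class EmpiricalMeasure:
    """Point masses on nodes, summing to 1; support is the bootstrap sample."""

    weights: dict

    def total_mass(self) -> float:
        return float(sum(self.weights.values()))


def bootstrap_sample(G: nx.Graph, kappa: int, seed: int = 0) -> EmpiricalMeasure:
    """Seed-and-neighbourhood bootstrap.

    Draws ``kappa`` seed nodes multinomially (uniform, with replacement);
    each drawn seed contributes its whole closed two-step neighbourhood to
    the sample.  A node's mass is proportional to the number of times it is
    included, normalized so all masses sum to 1.
    """
    if kappa < 1:
        raise ValueError(f"kappa must be >= 1, got {kappa}")
    if G.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(G, key=str)
    adj = adjacency_sets(G)
    rng = np.random.default_rng(seed)
    draws = Counter(rng.integers(0, len(nodes), size=kappa).tolist())
    inclusions: Counter = Counter()
    for i, mult in draws.items():
        for u in two_step_ego_nodes(adj, nodes[i]):
            inclusions[u] += mult
    total = sum(inclusions.values())
    return EmpiricalMeasure(
        weights={u: c / total for u, c in inclusions.items()}
    )
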