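"""Random-graph models for the synthetic benchmark suites.

Six models are supported, chosen to span very different local topologies at
a matched size and mean degree:

- ``erdos_renyi``: uniform graph with a fixed number of edges.
- ``configuration``: stub-matching with a prescribed degree sequence,
  simplified by erasing self-loops and parallel edges.
- ``geometric3d``: points uniform in the unit cube, linked within radius r.
- ``geometric_duplication``: geometric graph whose points are grown by
  duplicating a random existing point plus an isotropic Gaussian offset
  (clipped to the cube), then radius-linked -- a geometric caricature of
  gene duplication.
- ``chung_lu``: independent edges with probability min(1, w_i w_j / sum w).
- ``duplication_divergence``: growth from a single edge; each new node
  picks a uniform anchor, copies each anchor edge independently with
  retention probability p, and links to the anchor with probability q.

Degree matching (:func:`match_average_degree`) solves for each model's free
parameter so generated graphs hit a target mean degree, by closed form
where one exists and otherwise by bisection on a small Monte-Carlo average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MODELS",
    "ModelSpec",
    "generate",
    "match_average_degree",
    "benchmark_suite",
]

MODELS = (
    "erdos_renyi",
    "configuration",
    "geometric3d",
    "geometric_duplication",
    "chung_lu",
    "duplication_divergence",
)

DEFAULT_GEO_SIGMA = 0.1  # offset scale of the geometric-duplication model


class MatchingFailureError(RuntimeError):
    """Raised when no parameter in the search range brackets the target."""


@dataclass(frozen=True)
class ModelSpec:
    model: str
    n: int
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


def _radius_link(points: np.ndarray, r: float) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(len(points)))
    tree = cKDTree(points)
    G.add_edges_from(tree.query_pairs(r, output_type="ndarray").tolist())
    return G


def generate(spec: ModelSpec) -> nx.Graph:
    """Draw one simple undirected graph; deterministic given the spec."""
    n, params, seed = spec.n, spec.params, spec.seed
    rng = np.random.default_rng(seed)
    if spec.model == "erdos_renyi":
        m = int(params["m"])
        G = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    elif spec.model == "configuration":
        seq = [int(x) for x in params["degree_sequence"]]
        if len(seq) != n:
            raise ValueError("degree sequence length must equal n")
        if sum(seq) % 2:
            raise ValueError("degree sequence sum must be even")
        multi = nx.configuration_model(seq, seed=int(rng.integers(2**31)))
        G = nx.Graph(multi)  # erase parallel edges
        G.remove_edges_from(nx.selfloop_edges(G))
    elif spec.model == "geometric3d":
        pts = rng.uniform(size=(n, 3))
        G = _radius_link(pts, float(params["r"]))
    elif spec.model == "geometric_duplication":
        sigma = float(params.get("sigma", DEFAULT_GEO_SIGMA))
        n_init = min(n, int(params.get("n_init", 5)))
        pts = np.empty((n, 3))
        pts[:n_init] = rng.uniform(size=(n_init, 3))
        for i in range(n_init, n):
            parent = int(rng.integers(i))
            pts[i] = np.clip(pts[parent] + rng.normal(0, sigma, 3), 0.0, 1.0)
        G = _radius_link(pts, float(params["r"]))
    elif spec.model == "chung_lu":
        w = np.asarray(params["weights"], dtype=float)
        if len(w) != n:
            raise ValueError("weights length must equal n")
        G = nx.expected_degree_graph(
            w.tolist(), seed=int(rng.integers(2**31)), selfloops=False
        )
    elif spec.model == "duplication_divergence":
        p = float(params["p"])
        q = float(params.get("q", p))
        G = nx.Graph()
        G.add_edge(0, 1)
        for v in range(2, n):
            anchor = int(rng.integers(v))
            kept = [u for u in G[anchor] if rng.random() < p]
            G.add_node(v)
            G.add_edges_from((v, u) for u in kept)
            if rng.random() < q:
                G.add_edge(v, anchor)
    G.graph["name"] = f"{spec.model}_{seed}"
    return G


def _mean_degree(G: nx.Graph) -> float:
    return 2.0 * G.number_of_edges() / G.number_of_nodes()


def _mc_mean_degree(make_spec, x: float, seeds) -> float:
    return float(
        np.mean([_mean_degree(generate(replace(make_spec(x), seed=s)))
                 for s in seeds])
    )


def _bisect_parameter(make_spec, lo, hi, target, seeds, rtol=0.05,
                      max_iter=30):
    f_lo = _mc_mean_degree(make_spec, lo, seeds)
    f_hi = _mc_mean_degree(make_spec, hi, seeds)
    if not (f_lo <= target <= f_hi):
        raise MatchingFailureError(
            f"target degree {target} not bracketed by [{f_lo:.2f}, {f_hi:.2f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _mc_mean_degree(make_spec, mid, seeds)
        if abs(f_mid - target) <= rtol * target:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def match_average_degree(
    model: str,
    n: int,
    target: float,
    seed: int = 0,
    n_draws: int = 5,
    **fixed,
) -> ModelSpec:
    """Spec whose generated graphs have mean degree ~= ``target``.

    Closed form for Erdos-Renyi (m = n * target / 2); bisection on the free
    parameter with an ``n_draws``-draw Monte-Carlo average for the geometric
    and duplication models.  The configuration and Chung-Lu models take
    their degree sequence / weights from ``fixed`` (or from a companion
    duplication-divergence draw when absent), mirroring how the benchmark
    suite seeds them.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if target >= n - 1:
        raise ValueError(f"target degree {target} must be < n-1 = {n - 1}")
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(2**31, size=n_draws)]
    if model == "erdos_renyi":
        return ModelSpec(model, n, {"m": round(n * target / 2)}, seed=seed)
    if model in ("configuration", "chung_lu"):
        key = "degree_sequence" if model == "configuration" else "weights"
        if key in fixed:
            values = fixed[key]
        else:
            dd = match_average_degree(
                "duplication_divergence", n, target, seed=seed + 1,
                n_draws=n_draws,
            )
            values = sorted(
                (d for _, d in generate(dd).degree()), reverse=True
            )
        if model == "configuration" and sum(values) % 2:
            values = list(values)
            values[0] += 1
        return ModelSpec(model, n, {key: list(values)}, seed=seed)
    if model == "geometric3d":
        make = lambda r: ModelSpec(model, n, {"r": r})  # noqa: E731
        r = _bisect_parameter(make, 0.0, 3**0.5, target, seeds)
        return ModelSpec(model, n, {"r": r}, seed=seed)
    if model == "geometric_duplication":
        sigma = fixed.get("sigma", DEFAULT_GEO_SIGMA)
        make = lambda r: ModelSpec(  # noqa: E731
            model, n, {"r": r, "sigma": sigma}
        )
        r = _bisect_parameter(make, 0.0, 3**0.5, target, seeds)
        return ModelSpec(model, n, {"r": r, "sigma": sigma}, seed=seed)
    # duplication_divergence: bisection on the retention probability p,
    # with the anchor-link probability tied to it (q = p) by default.
    make = lambda p: ModelSpec(model, n, {"p": p, "q": p})  # noqa: E731
    p = _bisect_parameter(make, 0.01, 0.8, target, seeds)
    return ModelSpec(model, n, {"p": p, "q": p}, seed=seed)


def benchmark_suite(
    n: int,
    target: float,
    replicates: int,
    seed: int = 0,
    models=None,
):
    """Replicated labelled benchmark suite.

    Generates ``replicates`` graphs from each model (all six by default)
    matched to size ``n`` and mean degree ``target``, and returns
    ``(graphs, labels)`` where ``graphs`` maps a unique name to a graph and
    ``labels`` maps the same names to the generating model (the ground-truth
    clusters).  The configuration model's degree sequence and the Chung-Lu
    weights are the degree sequence of the suite's first
    duplication-divergence graph.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    models = list(models) if models is not None else list(MODELS)
    rng = np.random.default_rng(seed)
    rep_seeds = {
        m: [int(s) for s in rng.integers(2**31, size=replicates)]
        for m in MODELS
    }
    dd_spec = match_average_degree(
        "duplication_divergence", n, target, seed=int(rng.integers(2**31))
    )
    companion = generate(replace(dd_spec, seed=rep_seeds["duplication_divergence"][0]))
    dd_degrees = sorted((d for _, d in companion.degree()), reverse=True)
    graphs, labels = {}, {}
    for model in models:
        if model == "duplication_divergence":
            spec = dd_spec
        elif model in ("configuration", "chung_lu"):
            key = "degree_sequence" if model == "configuration" else "weights"
            spec = match_average_degree(
                model, n, target, seed=int(rng.integers(2**31)),
                **{key: dd_degrees},
            )
        else:
            spec = match_average_degree(
                model, n, target, seed=int(rng.integers(2**31))
            )
        for r, s in enumerate(rep_seeds[model]):
            G = generate(replace(spec, seed=s))
            name = f"{model}_{r}"
            G.graph["name"] = name
            graphs[name] = G
            labels[name] = model
    return graphs, labels
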