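"""The Netdis statistic: density-binned centering, netD2s, and distances.

Netdis compares two networks G and H through the counts of small connected
subgraphs in the two-step ego-network of every node.  Raw counts are
*centered* by subtracting the expected count among ego-networks of similar
edge density in a reference network, the centered counts are summed over
(all or sampled) ego-networks into per-type totals S_w, and the two total
vectors are combined into a correlation-like statistic

    netD2s(G, H) = sum_w s_w(G) s_w(H) /
                   sqrt( sum_w s_w(G)^2 * sum_w s_w(H)^2 ),

where s_w(X) = S_w(X) / sqrt(S_w(G)^2 + S_w(H)^2) rescales each subgraph
type by its magnitude across the pair.  By Cauchy-Schwarz netD2s lies in
[-1, 1], and

    Netdis(G, H) = (1 - netD2s(G, H)) / 2

is a dissimilarity in [0, 1] (0 for identical centered-count profiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .census import catalog, counts_from_edge_array
from .evaluation import DistanceMatrix
from .graphs import adjacency_sets, two_step_ego_nodes
from .sampling import SampleSpec, sample_ego_ids, substream_seed

logger = logging.getLogger("netdis")

__all__ = [
    "ExpectationTable",
    "CenteredSums",
    "NetdisResult",
    "ego_census",
    "build_expectation_table",
    "centered_sums",
    "centered_sums_from_census",
    "netd2s",
    "pairwise_netdis",
    "matrix_from_sums",
    "builtin_reference",
]

DEFAULT_K = 4
DEFAULT_BIN_WIDTH = 0.01


class DegenerateReferenceError(ValueError):
    """Raised when the reference graph has no edges."""


class DegenerateComparisonError(ValueError):
    """Raised when both centered-sum vectors are identically zero."""


class EmptySampleError(ValueError):
    """Raised when an empty list of ego identifiers is supplied."""


# ---------------------------------------------------------------------------
# Per-ego census


def ego_census(G: nx.Graph, ego_ids=None, k: int = DEFAULT_K) -> pd.DataFrame:
    """Subgraph census of the two-step ego-network of each requested node.

    Returns a DataFrame indexed by ego identifier with columns ``size``
    (node count of the ego-network), ``density`` and one count column per
    catalog type.  Ego-networks with fewer than k nodes naturally yield
    all-zero counts.
    """
    names = catalog(k)
    adj = adjacency_sets(G)
    if ego_ids is None:
        ego_ids = sorted(G, key=str)
    rows = []
    for v in ego_ids:
        nodes = two_step_ego_nodes(adj, v)
        s = len(nodes)
        idx = {u: i for i, u in enumerate(nodes)}
        edges = [
            (idx[u], idx[w])
            for u in nodes
            for w in adj[u] & nodes
            if idx[u] < idx[w]
        ]
        m = len(edges)
        dens = 2.0 * m / (s * (s - 1)) if s >= 2 else 0.0
        counts = counts_from_edge_array(
            s, np.array(edges, dtype=np.int64).reshape(-1, 2), k
        )
        rows.append((v, s, dens, *counts))
    return pd.DataFrame(
        rows, columns=["ego", "size", "density", *names]
    ).set_index("ego")


def write_ego_census_tsv(census: pd.DataFrame, path: str | Path) -> None:
    """Serialize a per-ego count matrix as TSV (ego id, size, density, one
    column per type name)."""
    census.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Expectation table (density-binned reference centering)


@dataclass
class ExpectationTable:
    """Expected per-type subgraph counts among reference ego-networks,
    binned by ego-network density into intervals of width ``bin_width``.

    ``bins`` maps a bin index i (density in [i*bin_width, (i+1)*bin_width))
    to the mean count vector of the reference egos falling in that bin.
    Queries fall back to the nearest non-empty bin, with ties resolved
    toward lower density.
    """

    k: int
    bin_width: float
    bins: dict
    bin_sizes: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        self._sorted_bins = np.array(sorted(self.bins), dtype=np.int64)

    def _bin_index(self, dens: float) -> int:
        return int(np.floor(dens / self.bin_width + 1e-12))

    def lookup_bin(self, dens: float) -> int:
        """Non-empty bin used for a query density (nearest; ties -> lower)."""
        i = self._bin_index(dens)
        if i in self.bins:
            return i
        b = self._sorted_bins
        j = int(np.argmin(np.abs(b - i)))  # argmin takes the first == lower
        return int(b[j])

    def expected(self, dens: float) -> np.ndarray:
        return self.bins[self.lookup_bin(dens)]

    def expected_many(self, densities) -> np.ndarray:
        return np.array([self.expected(d) for d in densities])

    def to_tsv(self, path: str | Path) -> None:
        names = catalog(self.k)
        rows = [
            (
                i,
                i * self.bin_width,
                self.bin_sizes.get(i, 0),
                *self.bins[i],
            )
            for i in sorted(self.bins)
        ]
        pd.DataFrame(
            rows, columns=["bin", "density_lower", "n_egos", *names]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, k: int, bin_width: float,
                 provenance: str = "") -> "ExpectationTable":
        df = pd.read_csv(path, sep="\t")
        names = list(catalog(k))
        bins = {
            int(r["bin"]): r[names].to_numpy(dtype=float)
            for _, r in df.iterrows()
        }
        sizes = {int(r["bin"]): int(r["n_egos"]) for _, r in df.iterrows()}
        return cls(k=k, bin_width=bin_width, bins=bins, bin_sizes=sizes,
                   provenance=provenance)


def build_expectation_table(
    ref: nx.Graph,
    k: int = DEFAULT_K,
    bin_width: float = DEFAULT_BIN_WIDTH,
    provenance: str | None = None,
) -> ExpectationTable:
    """Build the density-binned expectation table from every two-step
    ego-network of a reference graph.

    The expected count of type w in a bin is the arithmetic mean of the raw
    counts over the reference egos whose density falls in the bin.
    """
    if not 0 < bin_width <= 1:
        raise ValueError(f"bin_width must be in (0, 1], got {bin_width}")
    if ref.number_of_edges() == 0:
        raise DegenerateReferenceError(
            "reference graph has no edges; expectations would be degenerate"
        )
    census = ego_census(ref, k=k)
    names = list(catalog(k))
    idx = np.floor(
        census["density"].to_numpy() / bin_width + 1e-12
    ).astype(int)
    bins, sizes = {}, {}
    for i in np.unique(idx):
        sel = census.loc[idx == i, names]
        bins[int(i)] = sel.to_numpy(dtype=float).mean(axis=0)
        sizes[int(i)] = len(sel)
    return ExpectationTable(
        k=k,
        bin_width=bin_width,
        bins=bins,
        bin_sizes=sizes,
        provenance=provenance or ref.graph.get("name", "reference"),
    )


# ---------------------------------------------------------------------------
# Centered sums and the statistic


@dataclass
class CenteredSums:
    """Sum over (sampled) ego-networks of observed-minus-expected counts."""

    k: int
    S: np.ndarray
    n_egos_used: int
    name: str = ""


def centered_sums_from_census(
    census: pd.DataFrame,
    table: ExpectationTable,
    ego_subset=None,
    name: str = "",
) -> CenteredSums:
    """Centered sums from a precomputed per-ego census (fast path for
    repeated sub-sampling: sampling reduces to a row-subset sum)."""
    df = census if ego_subset is None else census.loc[list(ego_subset)]
    if len(df) == 0:
        raise EmptySampleError("no ego-networks selected")
    names = list(catalog(table.k))
    observed = df[names].to_numpy(dtype=float).sum(axis=0)
    expected = table.expected_many(df["density"].to_numpy()).sum(axis=0)
    return CenteredSums(
        k=table.k, S=observed - expected, n_egos_used=len(df), name=name
    )


def centered_sums(
    G: nx.Graph, ego_ids, table: ExpectationTable, name: str = ""
) -> CenteredSums:
    """S_w(G) = sum over the listed egos of (N_w(ego) - E_w(bin(density)))."""
    ego_ids = list(ego_ids)
    if not ego_ids:
        raise EmptySampleError("ego_ids is empty")
    census = ego_census(G, ego_ids, k=table.k)
    return centered_sums_from_census(census, table, name=name or
                                     G.graph.get("name", ""))


@dataclass
class NetdisResult:
    netd2s: float
    netdis: float
    per_type_terms: np.ndarray


def netd2s(SG: CenteredSums, SH: CenteredSums) -> NetdisResult:
    """The netD2s statistic and Netdis distance for a pair of networks.

    Types with S_w = 0 in both networks are excluded from every sum (they
    carry no signal); if *all* types are zero in both networks the
    comparison is degenerate and an error is raised rather than 0/0.  If
    exactly one of the two vectors is identically zero the statistic is
    defined as 0 (maximal non-informativeness, Netdis 1/2).
    """
    if SG.k != SH.k:
        raise ValueError(f"order mismatch: {SG.k} vs {SH.k}")
    g, h = np.asarray(SG.S, float), np.asarray(SH.S, float)
    norm2 = g**2 + h**2
    active = norm2 > 0
    if not active.any():
        raise DegenerateComparisonError(
            "both centered-sum vectors are identically zero"
        )
    terms = np.zeros_like(norm2)
    scale = np.sqrt(np.where(active, norm2, 1.0))
    sg = np.where(active, g / scale, 0.0)
    sh = np.where(active, h / scale, 0.0)
    den = np.sqrt((sg**2).sum() * (sh**2).sum())
    if den == 0:
        logger.warning(
            "one centered-sum vector is identically zero; netD2s set to 0"
        )
        value = 0.0
    else:
        terms = sg * sh / den
        value = float(np.clip(terms.sum(), -1.0, 1.0))
    return NetdisResult(
        netd2s=value, netdis=(1.0 - value) / 2.0, per_type_terms=terms
    )


def _unique_names(graphs) -> list:
    names, seen = [], {}
    for i, G in enumerate(graphs):
        base = str(G.graph.get("name", f"g{i}"))
        if base in seen:
            seen[base] += 1
            base = f"{base}.{seen[base]}"
        seen.setdefault(base, 0)
        names.append(base)
    return names


def pairwise_netdis(
    graphs,
    table: ExpectationTable,
    sampler: SampleSpec | None = None,
    names=None,
) -> DistanceMatrix:
    """Symmetric Netdis distance matrix over a list of graphs.

    Each graph's ego sample is drawn once (from a per-graph substream of
    the sampler's seed keyed by the graph name) and reused across all
    pairwise comparisons, so the matrix is internally consistent.
    Degenerate pairs are recorded as NaN and logged.
    """
    graphs = list(graphs)
    if len(graphs) < 2:
        raise ValueError("need at least 2 graphs")
    if names is None:
        names = _unique_names(graphs)
    sums = []
    for G, name in zip(graphs, names):
        if sampler is None:
            ids = sorted(G, key=str)
        else:
            from dataclasses import replace

            sub = replace(sampler, seed=substream_seed(sampler.seed, name))
            ids = sample_ego_ids(G, sub)
        sums.append(centered_sums(G, ids, table, name=name))
    return matrix_from_sums(sums, names)


def matrix_from_sums(sums, names=None) -> DistanceMatrix:
    """Netdis distance matrix from per-graph centered sums."""
    if names is None:
        names = [s.name or f"g{i}" for i, s in enumerate(sums)]
    n = len(sums)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = netd2s(sums[i], sums[j]).netdis
            except DegenerateComparisonError:
                logger.warning(
                    "degenerate comparison %s vs %s", names[i], names[j]
                )
                values[i, j] = values[j, i] = np.nan
    return DistanceMatrix(names=list(names), values=values)


def builtin_reference(seed: int = 0, n: int = 5000, m: int = 50000) -> nx.Graph:
    """The built-in centering reference: an Erdos-Renyi graph with 5,000
    nodes and 50,000 edges, usable with zero downloads.  A user-supplied
    reference network (e.g. a curated protein-interaction network)
    overrides it in the command-line tool."""
    G = nx.gnm_random_graph(n, m, seed=seed)
    G.graph["name"] = f"ER({n},{m})"
    return G
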