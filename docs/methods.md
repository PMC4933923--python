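# Methods

## The statistic

Netdis compares two undirected simple graphs G and H through the ensemble
of their two-step ego-networks. For a node p, the two-step ego-network is
the induced subgraph on all nodes at hop distance ≤ 2 from p (p included,
with every edge among those nodes). In each ego-network we count the
connected induced subgraphs on k nodes for every isomorphism class w ∈
A(k); A(3) = {path, triangle} and A(4) = {path, claw, cycle, paw, diamond,
complete}, in that fixed serialization order. k defaults to 4; k = 3 is
supported.

Counts are centered against a reference network: the reference's
ego-networks are binned by edge density (bin width 0.01), the expected
count E_w(bin) is the arithmetic mean of the raw counts in the bin, and a
query density uses its own bin when non-empty, otherwise the nearest
non-empty bin (ties toward lower density). Ego-networks with fewer than 2
nodes have density 0 and fall into the lowest bin; ego-networks with fewer
than k nodes contribute counts of zero (and therefore −E_w after
centering). The centered counts are summed over the selected ego-networks:

    S_w(G) = Σ_egos ( N_w(ego) − E_w(bin(ego density)) ).

With the rescaling s_w(X) = S_w(X)/√(S_w(G)² + S_w(H)²),

    netD2s = Σ_w s_w(G) s_w(H) / √( Σ_w s_w(G)² · Σ_w s_w(H)² ),
    Netdis = (1 − netD2s)/2.

netD2s ∈ [−1, 1] by Cauchy–Schwarz, so Netdis is a dissimilarity in
[0, 1]. Subgraph types with S_w = 0 in both networks carry no signal and
are excluded from all three sums; if *every* type is zero in both networks
the comparison is degenerate and raises an error (a pairwise matrix records
it as NA). If exactly one vector is all-zero the normalizer vanishes; we
define netD2s = 0 (Netdis 1/2, maximal non-informativeness) and warn.

Two readings of "expected number of counts … of similar density" are
possible: the per-bin mean of raw counts (implemented) and a
proportion-based rescaling by ego size within the bin. We implement the
mean-count reading; it makes the self-centering identity exact (a table
built from G zeroes S_w(G) over all egos, because within-bin deviations
from the bin mean cancel), which the test suite checks.

## Subgraph census

Induced counts are computed by closed-form combinatorics rather than
subgraph enumeration: degrees, the common-neighbour matrix A², per-edge and
per-node triangle counts give the *non-induced* (subgraph) counts of each
class; the vector is converted to induced counts by inverting the 6×6
inclusion matrix between classes (computed once by enumerating edge subsets
of the class prototypes, not hand-coded). K4s are counted at their vertex
of lowest degree rank as triangles among higher-ranked neighbours — the
degeneracy-ordering trick that keeps the per-node work small around hubs.
The cost is therefore polynomial in edges and insensitive to how many
4-subgraphs exist, which matters for ego-networks containing
duplication-divergence hubs where enumeration-based counting (e.g. ESU)
blows up. A brute-force enumerator (connectivity test plus classification
by sorted degree sequence and triangle count) serves as the oracle; the
suite verifies exact agreement on hundreds of random graphs and, as an
independent cross-check, against igraph's ESU motif counts.

## Sampling

Plain sub-sampling draws ego identifiers uniformly without replacement;
fraction f draws ⌈f·n⌉ so any positive fraction samples at least one ego.
Sampled centered sums are row-subset sums of the per-ego census, so
repeated re-sampling (as in the sweep experiment) costs almost nothing
beyond the one-time census. E[S_w over a fraction-f sample] = f·S_w(full),
checked by Monte-Carlo.

The bootstrap draws κ seed nodes uniformly *with* replacement and includes
each seed's closed two-step neighbourhood (the "dependency neighbourhood":
nodes whose ego-networks overlap with the seed's are exactly those within
two steps). Masses proportional to inclusion counts, normalized to 1.
Three- or four-step neighbourhoods are excluded: they tend to cover a large
share of the whole network and would erase the computational gain.

Per-graph RNG substreams are derived from (run seed, graph name) via a
SHA-256 hash, so adding a graph to a run does not perturb the samples drawn
for the others, and full reruns are byte-identical.

## Reference and defaults

- k = 4 (k = 3 available); bin width 0.01.
- Built-in reference: Erdős–Rényi with 5,000 nodes and 50,000 edges, so
  the tool works with zero downloads; any edge list (e.g. a curated yeast
  protein-interaction network) can replace it. Centering against a
  reference of similar density is what makes counts comparable across
  networks of different sizes.
- Edge lists are whitespace-delimited with `#` comments; self-loops are
  dropped (the census is defined on simple graphs) with a logged count;
  extra tokens (weights) are ignored with a one-time warning.

## Generators

The benchmark suite draws replicate graphs from six models matched to a
common size n and target mean degree d̄ (the study design: 6 models × 5
replicates; the large-network variant omits Chung–Lu, which converges to
the configuration model at scale):

- Erdős–Rényi G(n, m): m = n·d̄/2, closed form.
- configuration model: erased stub-matching on a prescribed degree
  sequence — taken from the suite's first duplication-divergence draw, so
  it shares that model's degree distribution but not its local structure.
- 3D geometric: n points uniform in the unit cube, linked within radius r
  (r found by bisection on a 5-draw Monte-Carlo mean degree, stopping
  within 5 % of target).
- geometric with duplication: points grown by copying a uniformly chosen
  existing point plus an isotropic Gaussian offset (σ = 0.1, clipped to
  the cube), radius-linked; r matched by the same bisection.
- Chung–Lu: independent edges with probability min(1, w_i w_j/Σw); weights
  default to the duplication-divergence degree sequence, mirroring the
  configuration model's seeding.
- duplication-divergence: growth from a single edge; each new node copies
  each edge of a uniform anchor with retention probability p and links to
  the anchor with probability q. We tie q = p and match p by bisection;
  the steady-state mean degree 2q/(1−2p) is very sensitive near the
  matching point, so individual replicates scatter around the target even
  though the 5-draw average is within tolerance. That scatter is a
  property of the model, not removed by calibration, and density-binned
  centering absorbs it.

Isolated nodes are kept so n is exact. Degree matching guarantees the
*Monte-Carlo average* within 10 % of target; single replicates of the
duplication models can deviate further.

## Evaluation

1−NN is the fraction of networks whose nearest neighbour under the
distance matrix shares their ground-truth cluster; k_C−NN averages, over
networks in clusters of size C, the fraction of the C−1 nearest neighbours
in-cluster. Distance ties are broken by lexicographic name — deterministic
and auditable; random tie-breaking was rejected for reproducibility.
Singleton clusters are skipped in k_C−NN (k would be 0). The chance
baseline averages both scores over 50 random matrices with i.i.d.
Uniform(0,1) upper triangles; its expected 1−NN is Σ_G (C_G−1)/(n−1)/n
(4/29 for 6 clusters of 5), which the tests verify by Monte-Carlo.

## Diagnostics

Sampling is theoretically safe when dependency neighbourhoods are of
comparable size and overlap little on average. We expose proxies, not the
formal error bound: per-node γᵢ (two-step neighbourhood size minus one),
its coefficient of variation, a sampled-pair mean Jaccard overlap, the
count of nodes with γᵢ outside [γ̄/τ, τ·γ̄] (τ = 3), and the largest group
of nodes sharing an *identical* closed two-step neighbourhood. The last
signal exists because the canonical failure case — a sparse random graph
with a disjoint 30-clique, whose ego-networks are all identical, size 30
versus a background average near 10 — moves neither the γ dispersion nor
the random-pair overlap detectably; a duplicate group of ≥ 3 nodes with a
shared neighbourhood at least twice the mean ego size (and ≥ 10 nodes)
flags it deterministically while never firing on a pure sparse random
graph, where identical neighbourhoods only occur in tiny components. The
overlap warning is suppressed when neighbourhoods cover most of the graph
(mean closed neighbourhood > half of n): fully overlapping neighbourhoods
of a vertex-transitive graph, e.g. a single clique, are not a sampling
hazard. The report is advisory and never blocks computation.

## Problem sizes in the shipped experiments

The sampling experiment in the test suite uses 5 models × 5 replicates at
n = 1,000 and mean degree ≈ 20, fractions {100 %, 10 %} with 20 sampling
repetitions, scored against a 50-matrix random baseline — a desk-scale
rendition of the published study design (which used up to 100,000-node
networks and 250 repetitions). The generator defaults *are* those study
conditions; nothing in the experiment is tuned per run. What passing shows:
model classes remain separable from a 10 % ego sample under these
conditions. What it does not show: behaviour on empirical networks with
assortativity, noise and missing edges, or the fixed-absolute-sample-size
regime of very large networks.

## Known limitations

- k is limited to 3 and 4; no orbit-resolved counts.
- Directed, weighted and multi-graphs are out of scope; inputs are
  simplified.
- The exact supplementary parameterizations of the geometric-duplication
  and duplication-divergence models used in the original benchmarks are
  not public; ours are explicit, literature-standard choices and are not
  guaranteed identical.
- The diagnostics are heuristic proxies for the bootstrap error bound, not
  the bound itself; the formal constants are not computed.
- Statistical significance of a Netdis value is not assessed; the package
  reports distances and scores only.
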