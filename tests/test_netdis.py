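import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netdis.netdis import (
    CenteredSums,
    DegenerateComparisonError,
    DegenerateReferenceError,
    EmptySampleError,
    ExpectationTable,
    build_expectation_table,
    centered_sums,
    centered_sums_from_census,
    ego_census,
    matrix_from_sums,
    netd2s,
    pairwise_netdis,
)
from netdis.sampling import SampleSpec


def cs(vec, k=None):
    vec = np.asarray(vec, float)
    if k is None:
        k = 3 if len(vec) == 2 else 4
    return CenteredSums(k=k, S=vec, n_egos_used=1)


class TestExpectationTable:
    def test_triangle_reference(self, triangle):
        table = build_expectation_table(triangle, k=3, bin_width=0.01)
        assert len(table.bins) == 1
        (idx,) = table.bins
        assert idx == 100  # density 1.0
        assert np.allclose(table.bins[idx], [0.0, 1.0])  # (P3, K3)

    def test_er_reference_builds(self):
        ref = nx.gnm_random_graph(200, 800, seed=0)
        table = build_expectation_table(ref, k=4)
        assert all(np.isfinite(v).all() and (v >= 0).all()
                   for v in table.bins.values())

    def test_empty_reference_raises(self):
        with pytest.raises(DegenerateReferenceError):
            build_expectation_table(nx.empty_graph(5), k=3)

    def test_nearest_bin_fallback_ties_go_lower(self):
        table = ExpectationTable(
            k=3, bin_width=0.1,
            bins={2: np.array([1.0, 0.0]), 6: np.array([0.0, 1.0])},
        )
        assert table.lookup_bin(0.25) == 2   # exact bin
        assert table.lookup_bin(0.05) == 2   # below all -> nearest
        assert table.lookup_bin(0.95) == 6
        assert table.lookup_bin(0.45) == 2   # equidistant from 2 and 6

    def test_tsv_round_trip(self, tmp_path, small_reference):
        table = build_expectation_table(small_reference, k=4)
        table.to_tsv(tmp_path / "t.tsv")
        back = ExpectationTable.from_tsv(tmp_path / "t.tsv", k=4,
                                         bin_width=table.bin_width)
        assert set(back.bins) == set(table.bins)
        for i in table.bins:
            assert np.allclose(back.bins[i], table.bins[i])


class TestCenteredSums:
    def test_self_centering_identity(self, small_er):
        """A table built from G itself zeroes the full-ego sums exactly:
        within each density bin the deviations from the bin mean cancel."""
        table = build_expectation_table(small_er, k=4)
        result = centered_sums(small_er, list(small_er), table)
        assert np.allclose(result.S, 0.0, atol=1e-8)

    def test_additivity_over_disjoint_ego_sets(self, small_er,
                                               small_reference):
        table = build_expectation_table(small_reference, k=4)
        nodes = sorted(small_er, key=str)
        half1, half2 = nodes[:30], nodes[30:]
        S1 = centered_sums(small_er, half1, table).S
        S2 = centered_sums(small_er, half2, table).S
        S = centered_sums(small_er, nodes, table).S
        assert np.allclose(S1 + S2, S)

    def test_triangle_against_zero_table(self, triangle, zero_table3):
        result = centered_sums(triangle, list(triangle), zero_table3)
        assert np.allclose(result.S, [0.0, 3.0])  # each ego holds 1 triangle

    def test_small_egos_contribute_minus_expectation(self, zero_table3):
        G = nx.empty_graph(3)
        table = ExpectationTable(k=3, bin_width=0.01,
                                 bins={0: np.array([2.0, 1.0])})
        result = centered_sums(G, list(G), table)
        assert np.allclose(result.S, [-6.0, -3.0])

    def test_empty_sample_raises(self, triangle, zero_table3):
        with pytest.raises(EmptySampleError):
            centered_sums(triangle, [], zero_table3)

    def test_subset_sum_fast_path_matches(self, small_er, small_reference):
        table = build_expectation_table(small_reference, k=3)
        census = ego_census(small_er, k=3)
        subset = sorted(small_er, key=str)[:20]
        fast = centered_sums_from_census(census, table, subset)
        slow = centered_sums(small_er, subset, table)
        assert np.allclose(fast.S, slow.S)
        assert fast.n_egos_used == slow.n_egos_used == 20


class TestNetd2s:
    def test_identical_vectors(self):
        r = netd2s(cs([1, 2, 3, 4, 5, 6]), cs([1, 2, 3, 4, 5, 6]))
        assert r.netd2s == pytest.approx(1.0)
        assert r.netdis == pytest.approx(0.0)

    def test_antipodal_vectors(self):
        v = np.array([1.0, -2.0, 3.0, 0.5, -1.0, 2.0])
        r = netd2s(cs(v), cs(-v))
        assert r.netd2s == pytest.approx(-1.0)
        assert r.netdis == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        r = netd2s(cs([1, 0]), cs([0, 1]))
        assert r.netd2s == pytest.approx(0.0)
        assert r.netdis == pytest.approx(0.5)

    def test_zero_types_excluded(self):
        r_full = netd2s(cs([1, 2, 0, 0, 0, 0]), cs([2, 1, 0, 0, 0, 0]))
        r_trim = netd2s(cs([1, 2], k=4), cs([2, 1], k=4))
        assert r_full.netd2s == pytest.approx(r_trim.netd2s)

    def test_both_zero_raises(self):
        with pytest.raises(DegenerateComparisonError):
            netd2s(cs([0, 0]), cs([0, 0]))

    def test_order_mismatch_raises(self):
        with pytest.raises(ValueError):
            netd2s(cs([1, 0], k=3), cs([1, 0, 0, 0, 0, 0], k=4))

    def test_one_zero_vector_gives_half_distance(self):
        r = netd2s(cs([0, 0]), cs([1, 2]))
        assert r.netd2s == 0.0
        assert r.netdis == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=6, max_size=6),
        st.lists(st.floats(-50, 50), min_size=6, max_size=6),
        st.floats(0.01, 100),
    )
    def test_bounds_and_scale_invariance(self, a, b, c):
        a, b = np.array(a), np.array(b)
        if not (a**2 + b**2).any():
            return
        r = netd2s(cs(a), cs(b))
        assert -1.0 <= r.netd2s <= 1.0
        assert 0.0 <= r.netdis <= 1.0
        r_scaled = netd2s(cs(c * a), cs(c * b))
        assert r_scaled.netd2s == pytest.approx(r.netd2s, abs=1e-9)


class TestPairwise:
    def test_identical_graphs_distance_zero(self, small_er,
                                            small_reference):
        table = build_expectation_table(small_reference, k=4)
        G2 = small_er.copy()
        G2.graph["name"] = "er60b"
        D = pairwise_netdis([small_er, G2], table)
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_full_fraction_equals_no_sampler(self, small_reference):
        graphs = []
        for i in range(3):
            G = nx.gnm_random_graph(40, 100, seed=i)
            G.graph["name"] = f"g{i}"
            graphs.append(G)
        table = build_expectation_table(small_reference, k=3)
        D_all = pairwise_netdis(graphs, table, sampler=None)
        D_frac = pairwise_netdis(
            graphs, table, sampler=SampleSpec("fraction", 1.0, seed=9)
        )
        assert np.allclose(D_all.values, D_frac.values)

    def test_symmetry_zero_diagonal_bounds(self, small_reference):
        rng = np.random.default_rng(0)
        graphs = []
        for i in range(5):
            G = nx.gnp_random_graph(
                int(rng.integers(20, 60)), float(rng.uniform(0.1, 0.5)),
                seed=int(rng.integers(2**31)),
            )
            G.graph["name"] = f"g{i}"
            graphs.append(G)
        table = build_expectation_table(small_reference, k=4)
        D = pairwise_netdis(graphs, table)
        assert np.array_equal(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0)
        off = D.values[~np.eye(5, dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()

    def test_degenerate_pair_is_nan(self, zero_table3):
        sums = [cs([0.0, 0.0]), cs([0.0, 0.0]), cs([1.0, 2.0])]
        for i, s in enumerate(sums):
            s.name = f"s{i}"
        D = matrix_from_sums(sums)
        assert np.isnan(D.values[0, 1])
        assert np.isfinite(D.values[0, 2])
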