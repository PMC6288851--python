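"""Degree histogram, threshold filtering and component extraction."""

import networkx as nx
import numpy as np
import pytest

from conftest import make_readset, reads_from_genomes

from readbin import (
    BinSet,
    DegreeHistogram,
    OverlapGraph,
    OverlapParams,
    ThresholdConfig,
    build_graph,
    degree_histogram,
    extract_bins,
    filter_by_degree,
    run_binning,
    run_binning_bands,
)


def nx_components(graph: OverlapGraph, retained=None):
    g = nx.Graph()
    nodes = range(graph.n_nodes) if retained is None else retained
    g.add_nodes_from(nodes)
    for i, j in graph.edges():
        if retained is None or (i in retained and j in retained):
            g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return OverlapGraph.from_edges(n, edges)


class TestDegreeHistogram:
    def test_complete_graph(self):
        g = OverlapGraph.from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        assert degree_histogram(g).counts == {4: 5}

    def test_isolated_nodes(self):
        g = OverlapGraph.from_edges(3, [])
        assert degree_histogram(g).counts == {0: 3}

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_conserved(self, seed):
        g = random_graph(40, 0.1, seed)
        h = degree_histogram(g)
        assert sum(h.counts.values()) == g.n_nodes == h.n_nodes

    def test_tsv_export(self, tmp_path):
        h = DegreeHistogram({0: 2, 3: 1}, 3)
        h.to_tsv(tmp_path / "h.tsv")
        assert (tmp_path / "h.tsv").read_text() == "degree\tcount\n0\t2\n3\t1\n"

    def test_median_positive_degree_ignores_zeros(self):
        h = DegreeHistogram({0: 100, 1: 3, 5: 2, 9: 1}, 106)
        assert h.median_positive_degree() == 1
        assert DegreeHistogram({4: 1, 10: 2}, 3).median_positive_degree() == 10


def star_hubs_graph():
    """Three hubs of degree 10, 50 and 200, each the center of a star."""
    edges = []
    node = 3
    for hub, degree in ((0, 10), (1, 50), (2, 200)):
        for _ in range(degree):
            edges.append((hub, node))
            node += 1
    return OverlapGraph.from_edges(node, edges), node


class TestFilterByDegree:
    def test_band_classification_of_hubs(self):
        g, _ = star_hubs_graph()
        filtered = filter_by_degree(g, ThresholdConfig(lower=30, upper=130))
        assert 0 in filtered.excluded_low  # degree 10 < 30
        assert 1 in filtered.retained      # degree 50 in band
        assert 2 in filtered.excluded_high  # degree 200 > 130

    def test_unbounded_band_is_identity(self):
        g = random_graph(30, 0.15, 1)
        filtered = filter_by_degree(g, ThresholdConfig())
        assert filtered.retained == frozenset(range(30))
        assert [tuple(a) for a in filtered.adjacency] == list(g.adjacency)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(lower=10, upper=5)

    def test_degrees_taken_from_original_graph(self):
        # chain 0-1-2: removing node 1 (degree 2) must not re-evaluate
        # nodes 0 and 2, whose original degree 1 keeps them retained
        g = OverlapGraph.from_edges(3, [(0, 1), (1, 2)])
        filtered = filter_by_degree(g, ThresholdConfig(lower=1, upper=1))
        assert filtered.retained == frozenset({0, 2})

    def test_hub_removal_splits_barbell(self):
        clique_a = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        clique_b = [(i, j) for i in range(6, 12) for j in range(i + 1, 12)]
        hub = [(12, k) for k in range(12)]
        g = OverlapGraph.from_edges(13, clique_a + clique_b + hub)
        assert len(nx_components(g)) == 1
        cfg = ThresholdConfig(upper=11)  # hub degree 12
        filtered = filter_by_degree(g, cfg)
        bins = extract_bins(filtered, cfg)
        assert len(bins.bins) == 2
        assert nx_components(g, filtered.retained) == {
            frozenset(b) for b in bins.bins
        }


class TestExtractBins:
    def test_two_component_toy(self):
        edges = [(1, 9), (9, 6), (6, 5), (5, 8), (0, 3), (3, 7), (7, 4)]
        g = OverlapGraph.from_edges(10, edges)
        cfg = ThresholdConfig(min_bin_size=2)
        bins = extract_bins(filter_by_degree(g, cfg), cfg)
        assert [set(b) for b in bins.bins] == [{1, 9, 6, 5, 8}, {0, 3, 7, 4}]
        assert bins.small_or_singleton == {2}

    def test_min_bin_size_suppresses_small_components(self):
        g = OverlapGraph.from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        cfg = ThresholdConfig(min_bin_size=6)
        bins = extract_bins(filter_by_degree(g, cfg), cfg)
        assert bins.bins == ()
        assert len(bins.small_or_singleton) == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_networkx(self, seed):
        g = random_graph(200, 0.012, seed)
        cfg = ThresholdConfig(min_bin_size=1)
        bins = extract_bins(filter_by_degree(g, cfg), cfg)
        assert {frozenset(b) for b in bins.bins} == nx_components(g)

    def test_partition_and_no_cross_bin_edges(self):
        g = random_graph(150, 0.02, 3)
        cfg = ThresholdConfig(lower=1, upper=6, min_bin_size=3)
        filtered = filter_by_degree(g, cfg)
        bins = extract_bins(filtered, cfg)
        groups = [set(b) for b in bins.bins] + [
            set(bins.excluded_low), set(bins.excluded_high),
            set(bins.small_or_singleton),
        ]
        assert sum(len(s) for s in groups) == g.n_nodes
        assert set().union(*groups) == set(range(g.n_nodes))
        membership = {}
        for k, b in enumerate(bins.bins):
            for node in b:
                membership[node] = k
        for i in filtered.retained:
            for j in filtered.adjacency[i]:
                if i in membership and j in membership:
                    assert membership[i] == membership[j]

    def test_bins_sorted_by_size_then_smallest_ordinal(self):
        g = OverlapGraph.from_edges(8, [(4, 5), (0, 1), (2, 3), (6, 7)])
        cfg = ThresholdConfig(min_bin_size=2)
        bins = extract_bins(filter_by_degree(g, cfg), cfg)
        assert [b[0] for b in bins.bins] == [0, 2, 4, 6]

    def test_widening_band_never_drops_retained_nodes(self):
        g = random_graph(100, 0.05, 7)
        narrow = filter_by_degree(g, ThresholdConfig(lower=3, upper=6))
        wide = filter_by_degree(g, ThresholdConfig(lower=1, upper=9))
        assert narrow.retained <= wide.retained


@pytest.fixture(scope="module")
def two_genome_benchmark():
    from readbin import GenomeSpec, SequenceRead, ReadSet, build_benchmark

    specs = [GenomeSpec("gA", 8000, 10.0), GenomeSpec("gB", 8000, 10.0)]
    bench = build_benchmark(specs, seed=42, read_len=(150.0, 10.0))
    rs = ReadSet([SequenceRead(r.read_id, r.sequence) for r in bench.reads])
    return bench, rs


class TestRunBinning:
    def test_two_genomes_give_two_dominant_pure_bins(self, two_genome_benchmark):
        from readbin import score_bins

        bench, rs = two_genome_benchmark
        result = run_binning(rs, OverlapParams(b=60), ThresholdConfig())
        big = [b for b in result.bins.bins if len(b) >= 200]
        assert len(big) == 2
        scores, _ = score_bins(result.bins, rs, bench.truth, b=60)
        assert all(s.purity == 1.0 for s in scores if s.size >= 200)
        assert {s.dominant_label for s in scores if s.size >= 200} == {"gA", "gB"}

    def test_read_order_invariance_of_membership(self, two_genome_benchmark):
        from readbin import ReadSet

        bench, rs = two_genome_benchmark
        params = OverlapParams(b=60)
        cfg = ThresholdConfig()
        res1 = run_binning(rs, params, cfg)
        shuffled = ReadSet(list(rs)[::-1])
        res2 = run_binning(shuffled, params, cfg)

        def id_bins(result, readset):
            return {
                frozenset(readset[o].read_id for o in b) for b in result.bins.bins
            }

        assert id_bins(res1, rs) == id_bins(res2, shuffled)

    def test_report_contents(self, two_genome_benchmark):
        _, rs = two_genome_benchmark
        result = run_binning(rs, OverlapParams(b=60), ThresholdConfig())
        rep = result.report
        assert rep["n_reads"] == len(rs)
        assert rep["n_bins"] == len(result.bins.bins)
        assert rep["bin_sizes"] == result.bins.bin_sizes()

    def test_min_bin_size_contract(self, two_genome_benchmark):
        _, rs = two_genome_benchmark
        result = run_binning(
            rs, OverlapParams(b=60), ThresholdConfig(min_bin_size=500)
        )
        assert all(size >= 500 for size in result.bins.bin_sizes())


class TestBands:
    def test_bands_run_independently_over_shared_graph(self):
        g_seqs = reads_from_genomes([4000], 60, (80, 150), seed=17)
        rs = make_readset(g_seqs)
        results = run_binning_bands(
            rs, OverlapParams(b=40), [(0, 3), (4, None)], min_bin_size=1
        )
        assert set(results) == {(0, 3), (4, None)}
        low, high = results[(0, 3)], results[(4, None)]
        retained_low = set().union(*[set(b) for b in low.bins.bins], low.bins.small_or_singleton)
        retained_high = set().union(*[set(b) for b in high.bins.bins], high.bins.small_or_singleton)
        assert retained_low.isdisjoint(retained_high)
        assert retained_low | retained_high == set(range(len(rs)))
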