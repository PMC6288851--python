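"""Degree analysis, threshold filtering and bin extraction.

The degree of a node tracks the local abundance of its sequence: reads from
a well-covered chromosome follow a roughly normal degree profile, reads
from conserved regions shared across species sit far above it (hubs that
bridge species), and chimeric reads sit below it.  The user inspects the
degree histogram, chooses an inclusive ``[lower, upper]`` band, and reads
outside the band are removed in a single pass over the ORIGINAL degrees.
Bins are then exactly the connected components of the filtered graph, found
by breadth-first search, with components below ``min_bin_size`` set aside.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .index import OverlapGraph, OverlapParams, build_graph
from .seqio import ReadSet

__all__ = [
    "DegreeHistogram",
    "ThresholdConfig",
    "FilteredGraph",
    "BinSet",
    "BinningResult",
    "degree_histogram",
    "filter_by_degree",
    "extract_bins",
    "run_binning",
    "run_binning_bands",
]


@dataclass(frozen=True)
class DegreeHistogram:
    """Exact integer counts of nodes per degree value (no binning/smoothing)."""

    counts: Mapping[int, int]
    n_nodes: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_nodes:
            raise ValueError("histogram counts do not sum to n_nodes")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("degree\tcount\n")
            for degree in sorted(self.counts):
                fh.write(f"{degree}\t{self.counts[degree]}\n")

    def median_positive_degree(self) -> int:
        """Median degree over nodes of nonzero degree.

        This is the documented histogram-guided default for an upper
        threshold when a conserved region is suspected: the main mode of
        the histogram lies at the typical within-chromosome connectivity,
        while conserved-region hubs sit at roughly twice that value.
        """
        positive = [(d, c) for d, c in sorted(self.counts.items()) if d > 0]
        total = sum(c for _, c in positive)
        if total == 0:
            raise ValueError("no nodes with positive degree")
        half = (total + 1) // 2
        running = 0
        for d, c in positive:
            running += c
            if running >= half:
                return d
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ThresholdConfig:
    """Inclusive degree band and minimum reported bin size.

    ``upper=None`` means unbounded.  ``min_bin_size`` defaults to 2 so
    singletons are never reported as bins.
    """

    lower: int = 0
    upper: int | None = None
    min_bin_size: int = 2

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError("lower must be >= 0")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(f"lower ({self.lower}) > upper ({self.upper})")
        if self.min_bin_size < 1:
            raise ValueError("min_bin_size must be >= 1")


@dataclass(frozen=True)
class FilteredGraph:
    """Graph restricted to nodes whose original degree lies in the band."""

    n_nodes: int
    retained: frozenset[int]
    adjacency: list[tuple[int, ...]]
    excluded_low: frozenset[int]
    excluded_high: frozenset[int]


@dataclass(frozen=True)
class BinSet:
    """Partition of all read ordinals into bins and exclusion sets.

    ``bins`` are the connected components of the filtered graph with size
    >= min_bin_size, ordered by size descending (ties by smallest member
    ordinal).  ``excluded_low``/``excluded_high`` hold reads cut by the
    degree band (chimera suspects / conserved-region suspects);
    ``small_or_singleton`` holds retained reads whose component was too
    small to report.
    """

    n_nodes: int
    bins: tuple[tuple[int, ...], ...]
    excluded_low: frozenset[int]
    excluded_high: frozenset[int]
    small_or_singleton: frozenset[int]

    def __post_init__(self) -> None:
        total = (
            sum(len(b) for b in self.bins)
            + len(self.excluded_low)
            + len(self.excluded_high)
            + len(self.small_or_singleton)
        )
        if total != self.n_nodes:
            raise ValueError("bin sets do not partition the node set")

    def bin_sizes(self) -> list[int]:
        return [len(b) for b in self.bins]


def degree_histogram(graph: OverlapGraph) -> DegreeHistogram:
    """Histogram of node degrees: counts[d] = number of nodes of degree d."""
    return DegreeHistogram(dict(Counter(graph.degree)), graph.n_nodes)


def filter_by_degree(graph: OverlapGraph, cfg: ThresholdConfig) -> FilteredGraph:
    """Remove nodes whose original degree lies outside [lower, upper].

    A single pass: degrees are taken from the unfiltered graph (the
    histogram the user inspected) and are not recomputed after removal.
    Surviving nodes keep only edges to surviving nodes.
    """
    upper = cfg.upper
    degree = graph.degree
    excluded_low: set[int] = set()
    excluded_high: set[int] = set()
    retained: set[int] = set()
    for i, d in enumerate(degree):
        if d < cfg.lower:
            excluded_low.add(i)
        elif upper is not None and d > upper:
            excluded_high.add(i)
        else:
            retained.add(i)
    adjacency = [
        tuple(j for j in graph.adjacency[i] if j in retained)
        if i in retained
        else ()
        for i in range(graph.n_nodes)
    ]
    return FilteredGraph(
        graph.n_nodes,
        frozenset(retained),
        adjacency,
        frozenset(excluded_low),
        frozenset(excluded_high),
    )


def _components(filtered: FilteredGraph) -> list[list[int]]:
    """Connected components of the retained subgraph via breadth-first search."""
    seen: set[int] = set()
    components: list[list[int]] = []
    adjacency = filtered.adjacency
    for seed in sorted(filtered.retained):
        if seed in seen:
            continue
        component = [seed]
        seen.add(seed)
        queue = deque((seed,))
        while queue:
            node = queue.popleft()
            for neighbor in adjacency[node]:
                if neighbor not in seen:
                    seen.add(neighbor)
                    component.append(neighbor)
                    queue.append(neighbor)
        components.append(component)
    return components


def extract_bins(filtered: FilteredGraph, cfg: ThresholdConfig) -> BinSet:
    """Report each connected component of size >= min_bin_size as a bin.

    Membership depends only on the component structure, never on traversal
    order or seed choice.  Bins are sorted by size descending, ties broken
    by smallest contained ordinal.
    """
    bins: list[tuple[int, ...]] = []
    small: set[int] = set()
    for component in _components(filtered):
        if len(component) >= cfg.min_bin_size:
            bins.append(tuple(sorted(component)))
        else:
            small.update(component)
    bins.sort(key=lambda members: (-len(members), members[0]))
    return BinSet(
        filtered.n_nodes,
        tuple(bins),
        filtered.excluded_low,
        filtered.excluded_high,
        frozenset(small),
    )


@dataclass(frozen=True)
class BinningResult:
    graph: OverlapGraph
    histogram: DegreeHistogram
    bins: BinSet
    report: dict


def _report(
    readset: ReadSet, params: OverlapParams, cfg: ThresholdConfig, bins: BinSet,
    graph: OverlapGraph,
) -> dict:
    return {
        "n_reads": len(readset),
        "n_edges": graph.n_edges(),
        "b": params.b,
        "include_revcomp": params.include_revcomp,
        "lower": cfg.lower,
        "upper": cfg.upper,
        "min_bin_size": cfg.min_bin_size,
        "n_bins": len(bins.bins),
        "bin_sizes": bins.bin_sizes(),
        "n_excluded_low": len(bins.excluded_low),
        "n_excluded_high": len(bins.excluded_high),
        "n_small_or_singleton": len(bins.small_or_singleton),
    }


def run_binning(
    readset: ReadSet,
    params: OverlapParams,
    cfg: ThresholdConfig | None = None,
    *,
    threads: int = 1,
) -> BinningResult:
    """Full pipeline: overlap graph -> histogram -> degree filter -> bins."""
    cfg = cfg or ThresholdConfig()
    graph = build_graph(readset, params, threads=threads)
    histogram = degree_histogram(graph)
    filtered = filter_by_degree(graph, cfg)
    bins = extract_bins(filtered, cfg)
    return BinningResult(graph, histogram, bins, _report(readset, params, cfg, bins, graph))


def run_binning_bands(
    readset: ReadSet,
    params: OverlapParams,
    bands: Sequence[tuple[int, int | None]],
    min_bin_size: int = 2,
    *,
    threads: int = 1,
) -> dict[tuple[int, int | None], BinningResult]:
    """Run one independent degree band per entry, over a single shared graph.

    Covers workflows that inspect the histogram once and then bin several
    abundance strata separately (each band labels its own bins).
    """
    graph = build_graph(readset, params, threads=threads)
    histogram = degree_histogram(graph)
    results: dict[tuple[int, int | None], BinningResult] = {}
    for lower, upper in bands:
        cfg = ThresholdConfig(lower=lower, upper=upper, min_bin_size=min_bin_size)
        filtered = filter_by_degree(graph, cfg)
        bins = extract_bins(filtered, cfg)
        results[(lower, upper)] = BinningResult(
            graph, histogram, bins, _report(readset, params, cfg, bins, graph)
        )
    return results
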