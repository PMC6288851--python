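"""Exact-overlap index and graph construction.

Two reads are linked by an edge when they share an exact common substring of
at least ``b`` bases, on either strand.  The construction rests on a simple
completeness lemma: any shared substring of length >= b contains a shared
window of length exactly b, so grouping reads by their length-b windows
(strand-folded to a canonical form) finds every edge and nothing else.
Windows containing N are skipped, which makes N a match breaker — an
ambiguous base can never create an edge.

The index also keeps the sentinel-separated concatenation of all reads (and
their reverse complements) so arbitrary patterns can be located and mapped
back to a read ordinal and strand; the sentinel is outside the DNA alphabet,
so no match can span a read boundary.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterator

from .seqio import ReadSet, reverse_complement

__all__ = [
    "OverlapParams",
    "OverlapIndex",
    "OverlapGraph",
    "build_index",
    "find_neighbors",
    "build_graph",
]

_SENTINEL = "$"


@dataclass(frozen=True)
class OverlapParams:
    """Parameters of the overlap stage.

    ``b`` is the minimum exact-match length in bases required to create an
    edge (70 is typical for 454-length reads, 100 for merged Illumina pairs,
    15 for a low-coverage residual pass).  ``include_revcomp`` controls
    whether matches against the reverse complement also count.
    """

    b: int
    include_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.b < 2:
            raise ValueError(f"b must be >= 2, got {self.b}")


def _canonical(window: str) -> str:
    rc = reverse_complement(window)
    return rc if rc < window else window


def _windows(sequence: str, b: int) -> Iterator[str]:
    """All length-b windows of ``sequence`` that contain no N."""
    for j in range(len(sequence) - b + 1):
        w = sequence[j : j + b]
        if "N" not in w:
            yield w


class OverlapIndex:
    """Searchable structure over all reads (+ reverse complements).

    Supports two queries: :meth:`locate` finds every occurrence of an
    arbitrary pattern and maps it back to (read ordinal, strand, offset);
    :meth:`neighbors_of` returns the reads sharing an exact >= b-base
    substring with a given read.
    """

    def __init__(self, readset: ReadSet, params: OverlapParams):
        self.readset = readset
        self.params = params
        self.n_reads = len(readset)

        max_len = max((r.length for r in readset), default=0)
        if self.n_reads and params.b > max_len:
            warnings.warn(
                f"b={params.b} exceeds every read length ({max_len} max); "
                "the overlap graph will have no edges",
                stacklevel=3,
            )

        # Sentinel-separated concatenation: forward section, then (optionally)
        # the reverse-complement section.  Offsets map text position -> read.
        chunks: list[str] = []
        starts: list[int] = []
        origins: list[tuple[int, str]] = []
        pos = 0
        for ordinal, read in enumerate(readset):
            chunks.append(read.sequence)
            starts.append(pos)
            origins.append((ordinal, "+"))
            pos += read.length + 1
        if params.include_revcomp:
            for ordinal, read in enumerate(readset):
                chunks.append(reverse_complement(read.sequence))
                starts.append(pos)
                origins.append((ordinal, "-"))
                pos += read.length + 1
        self._text = _SENTINEL.join(chunks) + (_SENTINEL if chunks else "")
        self._starts = starts
        self._origins = origins

        # Window table: canonical length-b window -> sorted tuple of read
        # ordinals containing it (on either strand when include_revcomp).
        fold = _canonical if params.include_revcomp else (lambda w: w)
        table: dict[str, set[int]] = {}
        b = params.b
        for ordinal, read in enumerate(readset):
            for w in _windows(read.sequence, b):
                key = fold(w)
                group = table.get(key)
                if group is None:
                    table[key] = {ordinal}
                else:
                    group.add(ordinal)
        self._window_table: dict[str, tuple[int, ...]] = {
            k: tuple(sorted(v)) for k, v in table.items()
        }

    def locate(self, pattern: str) -> list[tuple[int, str, int]]:
        """All occurrences of ``pattern`` as (read ordinal, strand, offset).

        The pattern must be a non-empty {A,C,G,T,N} string; since the
        sentinel is outside that alphabet, occurrences can never span two
        reads.  N in the pattern only matches a literal N in the text, in
        keeping with exact matching.
        """
        if not pattern:
            raise ValueError("empty pattern")
        reverse_complement(pattern)  # alphabet check
        hits: list[tuple[int, str, int]] = []
        start = self._text.find(pattern)
        while start != -1:
            slot = bisect_right(self._starts, start) - 1
            ordinal, strand = self._origins[slot]
            hits.append((ordinal, strand, start - self._starts[slot]))
            start = self._text.find(pattern, start + 1)
        return hits

    def neighbors_of(self, read_ordinal: int) -> set[int]:
        """Ordinals j != i sharing an exact >= b-base substring with read i."""
        if not 0 <= read_ordinal < self.n_reads:
            raise IndexError(f"read ordinal {read_ordinal} out of range")
        params = self.params
        fold = _canonical if params.include_revcomp else (lambda w: w)
        neighbors: set[int] = set()
        seq = self.readset[read_ordinal].sequence
        for w in _windows(seq, params.b):
            group = self._window_table.get(fold(w))
            if group:
                neighbors.update(group)
        neighbors.discard(read_ordinal)
        return neighbors


@dataclass
class OverlapGraph:
    """Undirected overlap graph as an adjacency list over read ordinals.

    Symmetric, irreflexive, and edge-multiplicity-collapsed: a pair sharing
    many >= b substrings still counts as one edge, so ``degree[i]`` is the
    number of distinct neighboring reads — the abundance proxy the degree
    histogram is built from.
    """

    n_nodes: int
    adjacency: list[tuple[int, ...]]

    @property
    def degree(self) -> list[int]:
        return [len(a) for a in self.adjacency]

    def n_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def edges(self) -> Iterator[tuple[int, int]]:
        for i, neigh in enumerate(self.adjacency):
            for j in neigh:
                if i < j:
                    yield (i, j)

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "OverlapGraph":
        adj: list[set[int]] = [set() for _ in range(n_nodes)]
        for i, j in edges:
            if i == j:
                raise ValueError(f"self edge on node {i}")
            adj[i].add(j)
            adj[j].add(i)
        return cls(n_nodes, [tuple(sorted(a)) for a in adj])

    def export_adjacency(self, path) -> None:
        """Plain-text adjacency list: ``node<TAB>comma-separated neighbors``."""
        with open(path, "w") as fh:
            for i, neigh in enumerate(self.adjacency):
                fh.write(f"{i}\t{','.join(map(str, neigh))}\n")


def build_index(readset: ReadSet, params: OverlapParams) -> OverlapIndex:
    """Build the searchable overlap index (window table + located text)."""
    return OverlapIndex(readset, params)


def find_neighbors(index: OverlapIndex, read_ordinal: int) -> set[int]:
    """Reads sharing an exact >= b-base substring with ``read_ordinal``."""
    return index.neighbors_of(read_ordinal)


def build_graph(
    readset: ReadSet,
    params: OverlapParams,
    *,
    index: OverlapIndex | None = None,
    threads: int = 1,
) -> OverlapGraph:
    """Construct the overlap graph for a read set.

    Iterates the window groups of the index and links every pair within a
    group; identical groups (common when consecutive windows are covered by
    the same reads) are processed once.  ``threads`` is accepted for
    interface compatibility; the construction is sequential and its result
    is by contract independent of the value.
    """
    if threads < 1:
        raise ValueError("threads must be >= 1")
    if index is None:
        index = build_index(readset, params)
    n = len(readset)
    adj: list[set[int]] = [set() for _ in range(n)]
    seen_groups: set[tuple[int, ...]] = set()
    for group in index._window_table.values():
        if len(group) < 2 or group in seen_groups:
            continue
        seen_groups.add(group)
        for ai in range(len(group)):
            a = group[ai]
            adj_a = adj[a]
            for bi in range(ai + 1, len(group)):
                bb = group[bi]
                adj_a.add(bb)
                adj[bb].add(a)
    return OverlapGraph(n, [tuple(sorted(s)) for s in adj])
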