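"""Brute-force all-pairs overlap oracle, independent of the package.

Computes longest-common-substring lengths by dynamic programming (row
vectorised with numpy) and derives the edge set by comparing against the
minimum alignment length, in both orientations.  N never matches anything,
including another N.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")
_N = ord("N")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def lcs_length(s: str, t: str) -> int:
    """Length of the longest common substring; N matches nothing."""
    if not s or not t:
        return 0
    a = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(t.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(len(b), dtype=np.int32)
    shifted = np.empty(len(b), dtype=np.int32)
    best = 0
    for ch in a:
        if ch == _N:
            prev = np.zeros(len(b), dtype=np.int32)
            continue
        eq = b == ch
        shifted[0] = 0
        shifted[1:] = prev[:-1]
        prev = np.where(eq, shifted + 1, 0)
        m = int(prev.max())
        if m > best:
            best = m
    return best


def shares_overlap(s: str, t: str, b: int, include_revcomp: bool = True) -> bool:
    if lcs_length(s, t) >= b:
        return True
    return include_revcomp and lcs_length(s, revcomp(t)) >= b


def brute_force_edges(
    sequences: list[str], b: int, include_revcomp: bool = True
) -> set[tuple[int, int]]:
    """All-pairs edge set by exhaustive longest-common-substring comparison."""
    edges: set[tuple[int, int]] = set()
    n = len(sequences)
    for i in range(n):
        for j in range(i + 1, n):
            if shares_overlap(sequences[i], sequences[j], b, include_revcomp):
                edges.add((i, j))
    return edges


def shared_kmers_between(genome_a: str, genome_b: str, k: int) -> set[str]:
    """Exact k-mers present in both genomes, considering both strands of b.

    Genome-level oracle used to certify that two simulated genomes cannot
    produce cross-genome read overlaps of length >= k.
    """
    kmers_a = {genome_a[i : i + k] for i in range(len(genome_a) - k + 1)}
    both_b = genome_b + "#" + revcomp(genome_b)
    kmers_b = {both_b[i : i + k] for i in range(len(both_b) - k + 1) if "#" not in both_b[i : i + k]}
    return kmers_a & kmers_b
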