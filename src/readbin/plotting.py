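"""Degree-histogram plotting.

The plot is a reading aid for threshold selection; the exported TSV keeps
the exact integer counts and is the authoritative record.  When a truth
table is supplied, one curve per source genome is overlaid so the user can
see how label-specific degree profiles separate.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .binning import DegreeHistogram
from .index import OverlapGraph
from .seqio import ReadSet

__all__ = ["plot_degree_histogram"]


def _curve(counts: Mapping[int, int]) -> tuple[list[int], list[int]]:
    degrees = sorted(counts)
    return degrees, [counts[d] for d in degrees]


def plot_degree_histogram(
    histogram: DegreeHistogram,
    path,
    *,
    graph: OverlapGraph | None = None,
    readset: ReadSet | None = None,
    truth: Mapping[str, str] | None = None,
    log_counts: bool = True,
) -> None:
    """Plot the number-of-edges histogram, optionally with per-label curves."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    x, y = _curve(histogram.counts)
    ax.plot(x, y, color="red", lw=1.5, label="all reads")
    if truth is not None:
        if graph is None or readset is None:
            raise ValueError("per-label curves require graph and readset")
        degree = graph.degree
        by_label: dict[str, Counter] = {}
        for ordinal, read in enumerate(readset):
            label = truth.get(read.read_id, "unknown")
            by_label.setdefault(label, Counter())[degree[ordinal]] += 1
        for label in sorted(by_label):
            lx, ly = _curve(by_label[label])
            ax.plot(lx, ly, lw=1.0, label=label)
    ax.set_xlabel("degree (number of edges)")
    ax.set_ylabel("number of reads")
    if log_counts:
        ax.set_yscale("symlog")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
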