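"""Scoring bins against a read -> genome truth table.

Purity is the fraction of a bin's reads whose true source is the bin's
dominant genome; per-genome recall is the fraction of a genome's reads
recovered into bins dominated by that genome.  Recall is reported twice:
against reads of length >= b (reads shorter than the minimum alignment
length are unbinnable by construction) and against all reads.  The chimera
label participates exactly like a genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .binning import BinSet
from .seqio import ReadSet

__all__ = [
    "BinScore",
    "GenomeRecall",
    "load_truth",
    "score_bins",
    "score_id_bins",
    "render_report",
    "write_report",
]


@dataclass(frozen=True)
class BinScore:
    bin_id: int
    size: int
    composition: Mapping[str, int]
    purity: float
    dominant_label: str
    dominant_tie: bool


@dataclass(frozen=True)
class GenomeRecall:
    genome_label: str
    total_reads: int          # reads of length >= b (binnable denominator)
    total_reads_all: int      # all reads of this genome
    binned_in_dominant_bins: int
    recall: float             # against total_reads
    recall_all: float         # against total_reads_all


def load_truth(path) -> dict[str, str]:
    """Two-column TSV ``read_id<TAB>genome_label`` -> dict."""
    truth: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed truth line {line_no}: {line!r}")
            truth[parts[0]] = parts[1]
    if not truth:
        raise ValueError(f"empty truth table: {path}")
    return truth


def _check_known(ids, truth: Mapping[str, str]) -> None:
    missing = [i for i in ids if i not in truth]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"{len(missing)} binned read ids missing from truth table "
            f"(first 10: {shown})"
        )


def score_id_bins(
    id_bins: Sequence[Sequence[str]],
    truth: Mapping[str, str],
    *,
    lengths: Mapping[str, int] | None = None,
    b: int | None = None,
) -> tuple[list[BinScore], list[GenomeRecall]]:
    """Score bins given as lists of read ids.

    ``lengths`` (read id -> length) and ``b`` enable the length->=b recall
    denominator; without them both recall variants use all reads.
    """
    scores: list[BinScore] = []
    for bin_id, members in enumerate(id_bins):
        _check_known(members, truth)
        composition = Counter(truth[i] for i in members)
        size = len(members)
        if size == 0:
            raise ValueError(f"bin {bin_id} is empty")
        best = min(composition.items(), key=lambda kv: (-kv[1], kv[0]))
        tie = sum(1 for c in composition.values() if c == best[1]) > 1
        scores.append(
            BinScore(bin_id, size, dict(composition), best[1] / size, best[0], tie)
        )

    totals_all = Counter(truth.values())
    if lengths is not None and b is not None:
        totals_b = Counter(
            label for rid, label in truth.items() if lengths.get(rid, 0) >= b
        )
    else:
        totals_b = totals_all
    recovered: Counter[str] = Counter()
    for score in scores:
        recovered[score.dominant_label] += score.composition.get(
            score.dominant_label, 0
        )
    recalls = [
        GenomeRecall(
            label,
            totals_b.get(label, 0),
            totals_all[label],
            recovered.get(label, 0),
            recovered.get(label, 0) / totals_b[label] if totals_b.get(label) else 0.0,
            recovered.get(label, 0) / totals_all[label],
        )
        for label in sorted(totals_all)
    ]
    return scores, recalls


def score_bins(
    bins: BinSet,
    readset: ReadSet,
    truth: Mapping[str, str],
    *,
    b: int | None = None,
) -> tuple[list[BinScore], list[GenomeRecall]]:
    """Score a :class:`BinSet` (ordinal bins) against the truth table."""
    id_bins = [[readset[o].read_id for o in members] for members in bins.bins]
    lengths = {r.read_id: r.length for r in readset}
    return score_id_bins(id_bins, truth, lengths=lengths, b=b)


def render_report(
    scores: Sequence[BinScore], recalls: Sequence[GenomeRecall]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin contingency table and per-genome recall table.

    Column order is stable: bin_id, size, one count column per label in
    lexicographic order, purity, dominant_label.
    """
    labels = sorted({label for s in scores for label in s.composition})
    rows = [
        {
            "bin_id": s.bin_id,
            "size": s.size,
            **{label: s.composition.get(label, 0) for label in labels},
            "purity": s.purity,
            "dominant_label": s.dominant_label,
        }
        for s in scores
    ]
    columns = ["bin_id", "size", *labels, "purity", "dominant_label"]
    scores_df = pd.DataFrame(rows, columns=columns)
    recall_df = pd.DataFrame(
        [
            {
                "genome_label": r.genome_label,
                "total_reads": r.total_reads,
                "total_reads_all": r.total_reads_all,
                "binned_in_dominant_bins": r.binned_in_dominant_bins,
                "recall": r.recall,
                "recall_all": r.recall_all,
            }
            for r in recalls
        ],
        columns=[
            "genome_label",
            "total_reads",
            "total_reads_all",
            "binned_in_dominant_bins",
            "recall",
            "recall_all",
        ],
    )
    return scores_df, recall_df


def write_report(
    scores: Sequence[BinScore],
    recalls: Sequence[GenomeRecall],
    out_dir,
) -> tuple[Path, Path]:
    """Write ``scores.tsv`` and ``recall.tsv``; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores_df, recall_df = render_report(scores, recalls)
    scores_path = out_dir / "scores.tsv"
    recall_path = out_dir / "recall.tsv"
    scores_df.to_csv(scores_path, sep="\t", index=False)
    recall_df.to_csv(recall_path, sep="\t", index=False)
    return scores_path, recall_path
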