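"""Sequence I/O and the core read data model.

Reads are the nodes of the overlap graph; everything downstream indexes them
by their ordinal position in the input file, so this module pins down the
two determinism anchors of the whole pipeline: iteration order equals file
order, and read ids are unique.

Sequences are normalised on load: uppercased, IUPAC multi-base ambiguity
codes mapped to ``N`` (with a warning), anything else rejected.  Quality
strings in FASTQ input are discarded — quality control belongs upstream of
binning.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRead",
    "ReadSet",
    "load_reads",
    "reverse_complement",
    "write_fasta",
    "write_bins",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes other than N collapse to N (predictable index alphabet).
_IUPAC_AMBIGUOUS = "RYSWKMBDHV"
_IUPAC_TO_N = str.maketrans(_IUPAC_AMBIGUOUS, "N" * len(_IUPAC_AMBIGUOUS))
_VALID_BASES = frozenset("ACGTN")

FASTA_WRAP = 80


@dataclass(frozen=True)
class SequenceRead:
    """A single read: unique id plus an uppercase {A,C,G,T,N} sequence."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class ReadSet:
    """Ordered collection of reads; ordinal positions 0..n-1 follow input order."""

    def __init__(self, reads: Iterable[SequenceRead]):
        self.reads: list[SequenceRead] = list(reads)
        self.index: dict[str, int] = {}
        for ordinal, read in enumerate(self.reads):
            if read.read_id in self.index:
                raise ValueError(f"duplicate read id: {read.read_id!r}")
            if read.length < 1:
                raise ValueError(f"empty sequence for read {read.read_id!r}")
            self.index[read.read_id] = ordinal

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[SequenceRead]:
        return iter(self.reads)

    def __getitem__(self, ordinal: int) -> SequenceRead:
        return self.reads[ordinal]

    def ordinal(self, read_id: str) -> int:
        return self.index[read_id]

    def lengths(self) -> list[int]:
        return [r.length for r in self.reads]


def normalize_sequence(raw: str, *, context: str = "") -> str:
    """Uppercase, map IUPAC ambiguity codes to N, reject anything else."""
    seq = raw.upper()
    if not _VALID_BASES.issuperset(seq):
        mapped = seq.translate(_IUPAC_TO_N)
        if mapped != seq:
            warnings.warn(
                f"IUPAC ambiguity codes mapped to N{context}", stacklevel=3
            )
        bad = set(mapped) - _VALID_BASES
        if bad:
            raise ValueError(
                f"invalid characters {sorted(bad)} in sequence{context}"
            )
        seq = mapped
    return seq


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".fna", ".mfa"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"cannot determine sequence format of {path}")


def load_reads(path: str | os.PathLike, format: str = "auto") -> ReadSet:
    """Load a FASTA or FASTQ file into a :class:`ReadSet` in file order.

    FASTQ quality strings are discarded.  The read id is the header token up
    to the first whitespace.  Malformed records, duplicate ids and empty
    files raise ``ValueError``.
    """
    path = Path(path)
    if format not in {"fasta", "fastq", "auto"}:
        raise ValueError(f"unknown format {format!r}")
    fmt = _sniff_format(path) if format == "auto" else format

    reads: list[SequenceRead] = []
    parser = SeqIO.parse(str(path), fmt)
    ordinal = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(
                f"malformed {fmt} record at ordinal {ordinal} in {path}: {exc}"
            ) from exc
        seq = normalize_sequence(
            str(record.seq), context=f" (record {ordinal}, id {record.id!r})"
        )
        if not seq:
            raise ValueError(f"empty sequence at record {ordinal} ({record.id!r})")
        reads.append(SequenceRead(record.id, seq))
        ordinal += 1
    if not reads:
        raise ValueError(f"no sequence records found in {path}")
    return ReadSet(reads)


def reverse_complement(sequence: str) -> str:
    """Watson-Crick complement, reversed; N maps to N."""
    if not _VALID_BASES.issuperset(sequence):
        bad = sorted(set(sequence) - _VALID_BASES)
        raise ValueError(f"invalid characters {bad} in sequence")
    return sequence.translate(_COMPLEMENT)[::-1]


def write_fasta(reads: Iterable[SequenceRead], path: str | os.PathLike) -> None:
    """Write reads as 80-column-wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n")
            seq = read.sequence
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def write_bins(
    bins,
    readset: ReadSet,
    out_dir: str | os.PathLike,
    prefix: str = "bin",
) -> list[Path]:
    """Write one multi-FASTA per bin plus a TSV manifest.

    ``bins`` is a :class:`~readbin.binning.BinSet` or any sequence of
    collections of read ordinals, assumed already ordered (BinSet orders
    size-descending).  Files are numbered in that order starting at 0 and
    original read ids/sequences are preserved verbatim.  Returns the FASTA
    paths in bin order.
    """
    bin_lists: Sequence = getattr(bins, "bins", bins)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = len(readset)
    paths: list[Path] = []
    manifest_rows = []
    for bin_id, members in enumerate(bin_lists):
        for ordinal in members:
            if not 0 <= ordinal < n:
                raise ValueError(f"bin {bin_id}: ordinal {ordinal} out of range")
        path = out_dir / f"{prefix}_bin{bin_id}.fasta"
        write_fasta((readset[o] for o in sorted(members)), path)
        paths.append(path)
        manifest_rows.append((bin_id, len(members), path.name))
    with open(out_dir / f"{prefix}_manifest.tsv", "w") as fh:
        fh.write("bin_id\tn_reads\tfasta_path\n")
        for row in manifest_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    return paths
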