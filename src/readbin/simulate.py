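"""Ground-truth-labelled shotgun metagenome simulation.

Generates the data structure the binning algorithm assumes: several genomes
at unequal sequencing depths, optionally carrying an identical conserved
insert (a 16S-like region that creates cross-species hubs), with uniform
substitution errors and a controllable fraction of chimeric reads.  Every
read carries its source genome in a truth table, so bin purity and recall
are measurable without external data.

The generator is deterministic for a fixed seed — byte-identical FASTA and
truth files — which makes it the bedrock of the test suite.  The error
model is substitution-only (no indels): substitutions are the only error
mechanism an exact-match overlap criterion can see.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import SequenceRead, reverse_complement, write_fasta

__all__ = [
    "GenomeSpec",
    "SharedRegion",
    "SimulatedRead",
    "Benchmark",
    "simulate_genome",
    "simulate_reads",
    "make_chimeras",
    "build_benchmark",
    "write_truth",
    "random_sequence",
]

CHIMERA_LABEL = "chimera"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MIN_READ_LEN = 30  # truncation floor for the read-length distribution


@dataclass(frozen=True)
class SharedRegion:
    """A sequence inserted verbatim into several genomes.

    ``carriers`` maps genome name -> insertion offset, or a tuple of
    offsets for multi-copy carriers (rRNA-like operons are typically
    multi-copy; adjacent offsets form a tandem array).  Verbatim insertion
    guarantees cross-genome exact matches of at least ``b`` bases whenever
    the region is longer than ``b``.
    """

    sequence: str
    carriers: Mapping[str, int | tuple[int, ...]]

    def offsets(self, name: str) -> tuple[int, ...]:
        value = self.carriers[name]
        return (value,) if isinstance(value, int) else tuple(value)


@dataclass(frozen=True)
class GenomeSpec:
    """One genome of the simulated community.

    ``depth`` is target fold-coverage: total simulated bases divided by
    genome length.  ``gc`` is the stationary G+C fraction of the i.i.d.
    base model.
    """

    name: str
    length: int
    depth: float
    gc: float = 0.5
    conserved_insert: SharedRegion | None = None
    circular: bool = False

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("genome length must be >= 1000")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass(frozen=True)
class SimulatedRead:
    """A read plus its provenance: source genome (or 'chimera') and origin.

    ``origin`` is (genome, start, strand) for a normal read, or a tuple of
    two such triples for a chimera.
    """

    read_id: str
    sequence: str
    truth_genome: str
    origin: tuple


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_sequence(length: int, gc: float, rng) -> str:
    """i.i.d. DNA with P(G) + P(C) = gc."""
    rng = _rng(rng)
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode("ascii")


def simulate_genome(spec: GenomeSpec, seed) -> str:
    """Random genome for ``spec``; the conserved insert replaces the bases
    at its offset so genome length is preserved."""
    genome = random_sequence(spec.length, spec.gc, seed)
    region = spec.conserved_insert
    if region is not None and spec.name in region.carriers:
        insert = region.sequence
        offsets = sorted(region.offsets(spec.name))
        for prev, offset in zip(offsets, offsets[1:]):
            if offset < prev + len(insert):
                raise ValueError(
                    f"overlapping conserved-insert offsets in {spec.name!r}"
                )
        for offset in offsets:
            if offset < 0 or offset + len(insert) > spec.length:
                raise ValueError(
                    f"conserved insert does not fit genome {spec.name!r} "
                    f"(offset {offset}, insert {len(insert)} bp, "
                    f"genome {spec.length} bp)"
                )
            genome = genome[:offset] + insert + genome[offset + len(insert):]
    return genome


def _apply_errors(sequence: str, error_rate: float, rng: np.random.Generator) -> str:
    k = rng.binomial(len(sequence), error_rate)
    if k == 0:
        return sequence
    positions = rng.choice(len(sequence), size=k, replace=False)
    seq = bytearray(sequence, "ascii")
    for pos in positions:
        current = seq[pos]
        options = [base for base in b"ACGT" if base != current]
        seq[pos] = options[rng.integers(0, len(options))]
    return seq.decode("ascii")


def simulate_reads(
    genome: str,
    depth: float,
    read_len: tuple[float, float],
    error_rate: float,
    seed,
    label: str = "genome",
    circular: bool = False,
) -> list[SimulatedRead]:
    """Shotgun reads at the target depth with normal length distribution.

    Read count is round(depth * genome_length / mean_length); starts are
    uniform, strands uniform, lengths normal(mean, sd) truncated to
    [MIN_READ_LEN, genome length], substitution errors i.i.d. per base.
    With ``circular=True`` reads may wrap around the origin, giving
    uniform coverage with no terminal ramp-down.
    """
    mean, sd = read_len
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if mean < 1:
        raise ValueError("mean read length must be >= 1")
    if mean > len(genome):
        raise ValueError("mean read length exceeds genome length")
    rng = _rng(seed)
    glen = len(genome)
    n_reads = int(round(depth * glen / mean))
    lengths = np.clip(
        np.rint(rng.normal(mean, sd, size=n_reads)).astype(int), MIN_READ_LEN, glen
    )
    doubled = genome + genome if circular else genome
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        length = int(lengths[i])
        start = int(rng.integers(0, glen if circular else glen - length + 1))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = doubled[start : start + length]
        if strand == "-":
            seq = reverse_complement(seq)
        if error_rate > 0:
            seq = _apply_errors(seq, error_rate, rng)
        reads.append(
            SimulatedRead(f"{label}_r{i}", seq, label, (label, start, strand))
        )
    return reads


def make_chimeras(
    reads_by_genome: Mapping[str, Sequence[SimulatedRead]],
    fraction: float,
    seed,
) -> list[SimulatedRead]:
    """Chimeric reads: first half of a read from one genome joined to the
    second half of a read from a different genome.

    ``fraction`` is relative to the total number of source reads; the
    chimeras are additional reads labelled 'chimera' in the truth table.
    """
    if not 0 <= fraction < 1:
        raise ValueError("chimera fraction must be in [0, 1)")
    labels = sorted(reads_by_genome)
    if fraction > 0 and len(labels) < 2:
        raise ValueError("chimeras require at least 2 source genomes")
    total = sum(len(v) for v in reads_by_genome.values())
    n_chimeras = int(round(fraction * total))
    rng = _rng(seed)
    chimeras: list[SimulatedRead] = []
    for i in range(n_chimeras):
        la, lb = rng.choice(len(labels), size=2, replace=False)
        ra = reads_by_genome[labels[la]][rng.integers(0, len(reads_by_genome[labels[la]]))]
        rb = reads_by_genome[labels[lb]][rng.integers(0, len(reads_by_genome[labels[lb]]))]
        seq = ra.sequence[: len(ra.sequence) // 2] + rb.sequence[len(rb.sequence) // 2 :]
        chimeras.append(
            SimulatedRead(
                f"{CHIMERA_LABEL}_r{i}", seq, CHIMERA_LABEL, (ra.origin, rb.origin)
            )
        )
    return chimeras


@dataclass(frozen=True)
class Benchmark:
    """In-memory benchmark plus the paths it was written to (if any)."""

    reads: tuple[SimulatedRead, ...]
    truth: Mapping[str, str]
    genomes: Mapping[str, str]
    fasta_path: Path | None = None
    truth_path: Path | None = None
    spec_path: Path | None = None


def write_truth(truth: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for read_id, label in truth.items():
            fh.write(f"{read_id}\t{label}\n")


def build_benchmark(
    specs: Sequence[GenomeSpec],
    seed: int,
    *,
    read_len: tuple[float, float] = (300.0, 30.0),
    error_rate: float = 0.0,
    chimera_fraction: float = 0.0,
    out_dir: str | os.PathLike | None = None,
    prefix: str = "benchmark",
) -> Benchmark:
    """Simulate genomes and reads, shuffle, and optionally write files.

    Outputs (benchmark FASTA, truth TSV, spec JSON) are byte-identical for
    a fixed seed.  Per-genome randomness comes from spawned child seeds so
    adding a genome does not perturb the others' reads.
    """
    if not specs:
        raise ValueError("at least one genome spec required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("genome names must be unique")
    root = np.random.SeedSequence(seed)
    genome_seeds, read_seeds, chimera_seed, shuffle_seed = (
        root.spawn(len(specs)),
        root.spawn(len(specs)),
        root.spawn(1)[0],
        root.spawn(1)[0],
    )
    genomes: dict[str, str] = {}
    reads_by_genome: dict[str, list[SimulatedRead]] = {}
    for spec, gseed, rseed in zip(specs, genome_seeds, read_seeds):
        genome = simulate_genome(spec, np.random.default_rng(gseed))
        genomes[spec.name] = genome
        reads_by_genome[spec.name] = simulate_reads(
            genome,
            spec.depth,
            read_len,
            error_rate,
            np.random.default_rng(rseed),
            label=spec.name,
            circular=spec.circular,
        )
    all_reads: list[SimulatedRead] = [
        r for name in names for r in reads_by_genome[name]
    ]
    all_reads.extend(
        make_chimeras(
            reads_by_genome, chimera_fraction, np.random.default_rng(chimera_seed)
        )
    )
    order = np.random.default_rng(shuffle_seed).permutation(len(all_reads))
    shuffled = tuple(all_reads[i] for i in order)
    truth = {r.read_id: r.truth_genome for r in shuffled}

    fasta_path = truth_path = spec_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta_path = out_dir / f"{prefix}.fasta"
        truth_path = out_dir / f"{prefix}.truth.tsv"
        spec_path = out_dir / f"{prefix}.spec.json"
        write_fasta(
            (SequenceRead(r.read_id, r.sequence) for r in shuffled), fasta_path
        )
        write_truth(truth, truth_path)
        record = {
            "seed": seed,
            "read_len": list(read_len),
            "error_rate": error_rate,
            "chimera_fraction": chimera_fraction,
            "genomes": [
                {
                    "name": s.name,
                    "length": s.length,
                    "depth": s.depth,
                    "gc": s.gc,
                    "circular": s.circular,
                    "conserved_insert": (
                        None
                        if s.conserved_insert is None
                        else {
                            "length": len(s.conserved_insert.sequence),
                            "carriers": dict(s.conserved_insert.carriers),
                        }
                    ),
                }
                for s in specs
            ],
        }
        with open(spec_path, "w") as fh:
            json.dump(record, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return Benchmark(shuffled, truth, genomes, fasta_path, truth_path, spec_path)
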