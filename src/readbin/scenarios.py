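"""Canonical benchmark scenarios for validating the binning pipeline.

Each scenario fixes the community design — genome sizes, depths, read
lengths, shared regions — and leaves only the seed free, so results are
reproducible and the scenarios can serve as acceptance fixtures.  Problem
sizes are desk-scale (tens of kilobases) so a full scenario runs in
seconds; the structure, not the scale, is what the pipeline's behaviour
depends on.

``two_species``
    Two unrelated genomes at equal 10x depth, error-free 300 bp reads:
    the clean separation regime, expected to produce one pure bin per
    genome at b=70.

``conserved_region``
    Two circular genomes at 50x depth carrying an identical 1.5 kb
    rRNA-like region — a single copy in one genome, a tandem triple array
    in the other (copy-number variation across species is typical of
    ribosomal operons).  Without thresholds the shared region welds the
    genomes into one bin; an upper degree threshold below the hub peak
    removes the repeat-inflated reads and restores one pure bin per
    genome.  Circular genomes keep each backbone contiguous when the
    repeat locus is cut out, so the rescue is attributable to the
    threshold alone.

``five_species``
    Five genomes at strongly unequal depths (11.7x to 1.7x), emulating a
    community where one organism dominates: the largest bin should belong
    to the deepest genome, and per-species mean degree should rank with
    depth.
"""

from __future__ import annotations

import numpy as np

from .binning import DegreeHistogram
from .seqio import ReadSet, SequenceRead
from .simulate import Benchmark, GenomeSpec, SharedRegion, build_benchmark, random_sequence

__all__ = [
    "TWO_SPECIES_MAJOR_FLOOR",
    "two_species",
    "conserved_region",
    "five_species",
    "hub_upper_threshold",
    "readset_from_benchmark",
    "MULTI_SPECIES_DEPTHS",
]

# depth profile of the five-species scenario: one dominant organism,
# one mid-abundance, three near the detection floor
MULTI_SPECIES_DEPTHS = {
    "species1": 11.7,
    "species2": 17.4,
    "species3": 2.4,
    "species4": 2.4,
    "species5": 1.7,
}


def readset_from_benchmark(bench: Benchmark) -> ReadSet:
    return ReadSet(
        [SequenceRead(r.read_id, r.sequence) for r in bench.reads]
    )


def two_species(seed: int, *, out_dir=None) -> Benchmark:
    """Two 20 kb genomes, 10x each, error-free 300 bp reads."""
    specs = [
        GenomeSpec("genomeA", 20_000, 10.0),
        GenomeSpec("genomeB", 20_000, 10.0),
    ]
    return build_benchmark(specs, seed, read_len=(300.0, 10.0), out_dir=out_dir)


# A "major" bin of the two-species scenario holds more than half of one
# genome's expected reads (round(10 * 20000 / 300) = 667 per genome).  At
# most one component per genome can clear this floor, so counting major
# bins tests one-bin-per-genome directly; at 10x a rare coverage gap can
# split off a fragment, which this floor classifies with the small bins
# while recall still credits it to its genome.
TWO_SPECIES_MAJOR_FLOOR = round(10.0 * 20_000 / 300.0) // 2 + 1


def conserved_region(seed: int, *, out_dir=None) -> Benchmark:
    """Two circular 15 kb genomes at 50x sharing a 1.5 kb multi-copy region.

    The shared sequence is generated from a seed-independent stream spawned
    off the scenario seed, so the region is identical across carriers by
    construction.  genomeA carries one copy; genomeB a tandem triple array.
    """
    region_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]))
    region = SharedRegion(
        random_sequence(1500, 0.5, region_rng),
        {"genomeA": 5000, "genomeB": (5000, 6500, 8000)},
    )
    specs = [
        GenomeSpec("genomeA", 15_000, 50.0, conserved_insert=region, circular=True),
        GenomeSpec("genomeB", 15_000, 50.0, conserved_insert=region, circular=True),
    ]
    return build_benchmark(specs, seed, read_len=(200.0, 8.0), out_dir=out_dir)


def five_species(seed: int, *, out_dir=None) -> Benchmark:
    """Five 20 kb genomes at depths 11.7/17.4/2.4/2.4/1.7, 250 bp reads."""
    specs = [
        GenomeSpec(name, 20_000, depth)
        for name, depth in MULTI_SPECIES_DEPTHS.items()
    ]
    return build_benchmark(specs, seed, read_len=(250.0, 10.0), out_dir=out_dir)


def hub_upper_threshold(histogram: DegreeHistogram, factor: float = 1.5) -> int:
    """Histogram-guided upper degree threshold for conserved-region hubs.

    Reads of a single well-covered chromosome cluster around the main
    histogram mode; a read whose span includes a region present at k
    additional conserved-copy sites gains about half a mode's worth of
    degree per extra site, so hub populations sit near (1 + k/2) times the
    mode.  Cutting at 1.5x the median nonzero degree sits above ordinary
    coverage fluctuations while removing every read inflated by a
    multi-copy (rRNA-operon-like, k >= 2) shared region — the automated
    stand-in for a user reading the valley off the histogram.  For a
    strictly single-copy shared region the shallowest boundary reads sit
    at the cut itself and separation is inherently marginal at any
    threshold.
    """
    return int(round(factor * histogram.median_positive_degree()))
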