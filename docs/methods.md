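# Methods

## Overlap model

An edge joins two reads when they share an exact common substring of at
least *b* bases, in forward or reverse-complement orientation, located
anywhere in either read.  This is substring sharing, not suffix–prefix
(dovetail) overlap: the goal is co-chromosome evidence, not assembly
layout.  Scored alignment is deliberately absent — the whole point of
the exact-match criterion is that a single mismatch breaks the evidence,
which is what makes cross-species edges rare.

Construction rests on a completeness lemma: a shared substring of
length ≥ b contains a shared window of length exactly b.  The index
therefore maps every N-free length-b window of every read, folded to
the lexicographic minimum of the window and its reverse complement, to
the set of reads containing it; the edge set is the union of all
within-group pairs.  Window groups that repeat verbatim (consecutive
windows covered by the same reads) are processed once, which makes the
pair stage roughly linear in genome size times squared coverage.  The
lemma and the pairing are validated against an independent brute-force
oracle (numpy dynamic-programming longest common substring, both
orientations) on randomized read sets.

Consequences of the definition, all tested as properties:

* symmetry and irreflexivity; a pair sharing many substrings still
  counts as one edge (degree = number of distinct neighbours);
* monotonicity: raising b can only remove edges;
* reverse-complement closure: flipping any read's strand leaves the
  edge set unchanged;
* N matches nothing, including another N, so ambiguous bases act as
  match breakers;
* reads shorter than b have no edges and end up as singletons;
* determinism: results are independent of read order and of the
  `threads` setting.  (The implementation is sequential; `threads` is
  accepted for interface compatibility and validated as a no-op.)

The index also keeps the sentinel-separated concatenation of all reads
and their reverse complements, supporting exact location queries for
arbitrary patterns; the sentinel lies outside the DNA alphabet so no
match can span a read boundary.

## Degree analysis and binning

For a chromosome at depth c and read length L, a read's expected degree
is μ ≈ 2c(L−b)/L with Poisson-like spread, but degrees are *spatially
correlated*: all reads covering the same locus see the same local
coverage, so degree filtering removes contiguous genome stretches, not
random reads.  Two populations depart from the single-chromosome
profile:

* **hubs** — reads overlapping a region present at k additional
  conserved-copy sites (across or within genomes) gain ≈ μ/2 per extra
  site, putting them near (1 + k/2)μ;
* **chimeras** — artifactual joins of two molecules; their neighbours
  split into two genome-consistent groups, and their degree profile is
  atypically low.

Thresholds are inclusive bounds applied in a single pass over the
*original* degrees — the histogram the user actually inspected;
iterative re-filtering would invalidate that histogram.  Bins are
exactly the connected components of the filtered graph (hand-written
breadth-first search, checked against networkx), size-descending with
ties broken by smallest member ordinal; components below `min_bin_size`
(default 2, so singletons are never bins) are set aside, as are the
excluded read sets, so residual passes can re-bin the leftovers at a
smaller b.  An optional multi-band mode runs several [lower, upper]
bands independently over one shared graph, which covers workflows that
bin abundance strata separately.

The `hub_upper_threshold` heuristic automates one histogram reading:
cut at 1.5× the median nonzero degree.  This clears ordinary coverage
fluctuations (a few σ above the mode) and removes every population
inflated by a *multi-copy* shared region (k ≥ 2 extra sites → ≥ 2μ).
For a strictly single-copy shared region the shallowest boundary reads
sit at ≈ 1.5μ — on the cut itself — and no single threshold separates
cleanly; this is a property of the model, not of the implementation,
and is the reason the conserved-region benchmark uses a multi-copy
region (see below).

## Synthetic communities

The simulator generates i.i.d.-base genomes at a chosen GC fraction,
optionally splices an identical shared region into several genomes (one
or more copies per carrier; adjacent offsets form tandem arrays),
draws reads with uniform starts and strands, normal lengths truncated
to [30 bp, genome length], i.i.d. substitution errors, and optional
chimeras formed by joining half-reads from two different genomes.
Genomes may be circular, in which case reads wrap the origin and
coverage has no terminal ramp-down.  Every read carries its source
label in a truth table; fixed seeds give byte-identical FASTA/TSV
output, with per-genome child seeds so adding a genome does not perturb
the others.

What the generator does *not* emulate — and what green tests therefore
do not certify about real data: platform-specific error profiles
(notably homopolymer indels), quality-correlated errors, biased
coverage, paired-end structure, strain-level mixtures, and real
phylogenetic sequence similarity, which is far richer than an inserted
identical region.  Substitution-only errors are sufficient to exercise
the one error mechanism the exact-match criterion can see: match
breakage.

## Benchmark scenarios and their design

Problem sizes are tens of kilobases so each scenario runs in seconds;
the separation/merging behaviour depends on coverage, read length and b,
not on genome scale.

**Two species.**  2 × 20 kb linear genomes, 10×, error-free 300 bp
reads, b = 70.  Before asserting purity, tests certify the premise with
a genome-level oracle: the two genomes share no exact 70-mer on either
strand.  At 10× a coverage gap (no consecutive read starts within
L − b bases) occurs with non-negligible probability and can split off a
fragment, so the scenario defines a *major* bin as holding more than
half a genome's expected reads (334 of 667): at most one component per
genome can clear that floor, the count "exactly two major bins" tests
one-bin-per-genome directly, and recall — which credits all bins
dominated by a genome — is unaffected by such splits.

**Conserved region.**  2 × 15 kb *circular* genomes at 50×, 200 bp
reads, sharing an identical 1.5 kb region: one copy in genome A, a
tandem triple array in genome B, emulating the copy-number variation
typical of ribosomal operons.  Design rationale, in order: (i) the
region must be multi-copy, otherwise the shallowest boundary straddlers
sit exactly at the 1.5μ cut and no threshold separates (see above);
(ii) genomes are circular because excising the repeat locus from a
circle leaves one contiguous backbone per genome — on a linear genome
the same cut splits each backbone in two, and terminal placement
creates low-coverage read populations at the genome tips that defeat
any threshold; (iii) 50× keeps the filtered backbone far above its
connectivity threshold.  The upper threshold is always computed from
the run's own histogram via `hub_upper_threshold`, never from truth
labels.

**Five species.**  Five 20 kb genomes at depths 11.7/17.4/2.4/2.4/1.7×,
250 bp reads: one dominant organism, one mid-abundance, three near the
binnability floor (at 1.7× and b = 70 the expected degree is ≈ 2.4, so
those genomes fragment — intentionally).  Checks: the largest bin is
pure and belongs to the deepest genome, and per-species mean degree
rank-correlates with depth.

## Numerical and interface choices

* Sequences are uppercased on load; IUPAC ambiguity codes other than N
  map to N with a warning; anything else is an error.  FASTQ qualities
  are discarded — quality control belongs upstream.
* Read ids are header tokens up to the first whitespace and must be
  unique; output bins preserve ids and sequences verbatim.
* Bin numbering is size-descending, ties by smallest contained ordinal,
  fixed so that golden-file comparisons are meaningful.
* Purity ties (two labels with equal counts) resolve to the
  lexicographically smaller label and are flagged.
* Recall is reported against two denominators: reads of length ≥ b
  (reads shorter than b are unbinnable by construction) and all reads.
* Degenerate inputs: an empty read set yields an empty graph; b larger
  than every read length yields an edge-free graph with a warning;
  empty files, duplicate ids and malformed records are errors naming
  the offender.

## Known limitations

Binning resolution is chromosome-level co-occurrence of exact
substrings: plasmids shared across species, recent horizontal transfers
and very close strains will co-bin.  Species below a few × coverage
fragment into small bins or singletons.  Degree thresholds are a manual
(or heuristic) choice from the histogram; no automatic normality
detection is attempted.  The in-memory window table trades memory for
simplicity and is sized for desk-scale studies (up to roughly a million
read-windows), not for production-scale metagenomes.
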