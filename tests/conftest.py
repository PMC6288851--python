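import numpy as np
import pytest

from readbin import ReadSet, SequenceRead


def make_readset(sequences, prefix="r"):
    return ReadSet(
        [SequenceRead(f"{prefix}{i}", s) for i, s in enumerate(sequences)]
    )


def reads_from_genomes(genome_lengths, n_reads, read_len_range, seed, gc=0.5):
    """Random reads drawn from a small set of random genomes.

    Shared source genomes guarantee genuine overlaps, which pure random
    reads of modest length essentially never have.
    """
    from readbin.simulate import random_sequence

    rng = np.random.default_rng(seed)
    genomes = [random_sequence(L, gc, rng) for L in genome_lengths]
    lo, hi = read_len_range
    sequences = []
    for _ in range(n_reads):
        g = genomes[rng.integers(0, len(genomes))]
        length = int(rng.integers(lo, hi + 1))
        length = min(length, len(g))
        start = int(rng.integers(0, len(g) - length + 1))
        seq = g[start : start + length]
        if rng.integers(0, 2):
            from readbin import reverse_complement

            seq = reverse_complement(seq)
        sequences.append(seq)
    return sequences


@pytest.fixture()
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">r1 first read\nACGT\n>r2\nTTTT\n")
    return path


@pytest.fixture()
def tiny_fastq(tmp_path):
    path = tmp_path / "tiny.fastq"
    path.write_text("@r1 with quality\nACGTACGT\n+\nIIIIIIII\n")
    return path
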