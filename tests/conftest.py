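import numpy as np
import pytest

from micropopgen.annotation import Gene, GenomeAnnotation
from micropopgen.profiling import PileupTable, build_pileup, call_snvs
from micropopgen.reads import ReadPairSet
from micropopgen.simulate import (simulate_reference, simulate_sample_reads,
                                  simulate_strain_pool)


@pytest.fixture(scope="session")
def annotation():
    """Mid-sized random reference shared by the simulation-driven tests."""
    return simulate_reference(20000, 20, gc=0.35, seed=11)


@pytest.fixture(scope="session")
def pool(annotation):
    return simulate_strain_pool(annotation, n_strains=20, target_pi=0.02,
                                recomb_block_len=300, seed=7)


@pytest.fixture(scope="session")
def reads(pool):
    return simulate_sample_reads(pool, coverage=50, error_rate=0.0, seed=3)


@pytest.fixture(scope="session")
def pileup(reads, annotation):
    return build_pileup(reads, annotation)


@pytest.fixture(scope="session")
def snvs(pileup, annotation):
    return call_snvs(pileup, annotation)


@pytest.fixture
def tiny_annotation():
    """Hand-built two-gene contig for exact, hand-countable expectations.

    Layout: 4 bp intergenic | gene_fw (+): ATG GGG AAA TAA | 4 bp
    intergenic | gene_rv (-): revcomp(ATG CCC TAA) | 3 bp intergenic.
    """
    from micropopgen.annotation import revcomp
    fw = "ATGGGGAAATAA"
    rv = revcomp("ATGCCCTAA")
    seq = "ACGT" + fw + "TGCA" + rv + "AAA"
    genes = [
        Gene("gene_fw", "tiny", 4, 16, "+"),
        Gene("gene_rv", "tiny", 20, 29, "-"),
    ]
    annotation = GenomeAnnotation("tiny", seq, genes)
    annotation.validate()
    return annotation


def make_pileup(annotation, site_counts):
    """PileupTable with uniform deep coverage of the reference plus explicit
    per-site count overrides ({pos: {base: count}})."""
    L = annotation.length
    counts = np.zeros((L, 4), dtype=np.int32)
    counts[np.arange(L), annotation.codes] = 100
    for pos, alleles in site_counts.items():
        counts[pos] = 0
        for base, n in alleles.items():
            counts[pos, "ACGT".index(base)] = n
    return PileupTable(annotation.contig_id, counts)


def make_read_pairs(annotation, pairs, read_len=10):
    """ReadPairSet from explicit (start1, start2, seq1, seq2, source)."""
    from micropopgen.annotation import seq_to_codes
    n = len(pairs)
    start1 = np.array([p[0] for p in pairs], dtype=np.int64)
    start2 = np.array([p[1] for p in pairs], dtype=np.int64)
    if n:
        seq1 = np.vstack([seq_to_codes(p[2]) for p in pairs])
        seq2 = np.vstack([seq_to_codes(p[3]) for p in pairs])
    else:
        seq1 = np.empty((0, read_len), dtype=np.uint8)
        seq2 = np.empty((0, read_len), dtype=np.uint8)
    source = np.array([p[4] if len(p) > 4 else -1 for p in pairs],
                      dtype=np.int32)
    return ReadPairSet(annotation.contig_id, annotation.length, read_len,
                       start1, start2, seq1, seq2, source)
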