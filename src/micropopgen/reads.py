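"""In-memory paired-end read sets and SAM/FASTQ interchange.

Reads are stored as dense base-code arrays (A=0, C=1, G=2, T=3, 255=N) with
per-pair start coordinates, which keeps pileup construction vectorised.
Alignments are ungapped by construction: this pipeline is SNV-only, so
indel-containing records are rejected on import.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .annotation import GenomeAnnotation, codes_to_seq, seq_to_codes


def _codes_to_read(seq: np.ndarray) -> str:
    """Base codes to sequence string, rendering 255 as N."""
    if (seq == 255).any():
        return "".join("ACGTN"[min(int(c), 4)] for c in seq)
    return codes_to_seq(seq)


@dataclass
class ReadPairSet:
    """Mapped 2x``read_len`` read pairs on a single contig.

    ``start1``/``start2`` are 0-based leftmost reference coordinates of the
    two mates (mate2 is the rightmost).  ``source`` holds the index of the
    originating haplotype for simulated reads (-1 if unknown).
    """

    contig_id: str
    contig_length: int
    read_len: int
    start1: np.ndarray
    start2: np.ndarray
    seq1: np.ndarray
    seq2: np.ndarray
    source: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.start1)

    @property
    def insert_sizes(self) -> np.ndarray:
        """Outer fragment lengths (mate1 start to mate2 end)."""
        return self.start2 + self.read_len - self.start1

    def total_bases(self) -> int:
        return 2 * self.read_len * self.n_pairs

    # -- I/O -------------------------------------------------------------

    def to_sam(self, path: str) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.contig_id, "LN": int(self.contig_length)}],
        }
        rl = self.read_len
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for i in range(self.n_pairs):
                for mate, (start, other, seq) in enumerate(
                    [(self.start1[i], self.start2[i], self.seq1[i]),
                     (self.start2[i], self.start1[i], self.seq2[i])]
                ):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"pair{i}"
                    a.query_sequence = _codes_to_read(seq)
                    a.flag = (0x1 | 0x2 | (0x40 if mate == 0 else 0x80)
                              | (0x20 if mate == 0 else 0x10))
                    a.reference_id = 0
                    a.reference_start = int(start)
                    a.mapping_quality = 60
                    a.cigartuples = [(0, rl)]
                    a.next_reference_id = 0
                    a.next_reference_start = int(other)
                    tlen = int(self.insert_sizes[i])
                    a.template_length = tlen if mate == 0 else -tlen
                    if self.source[i] >= 0:
                        a.set_tag("XH", int(self.source[i]))
                    out.write(a)

    def to_fastq(self, path1: str, path2: str) -> None:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            qual = "I" * self.read_len
            for i in range(self.n_pairs):
                f1.write(f"@pair{i}/1\n{_codes_to_read(self.seq1[i])}\n+\n{qual}\n")
                f2.write(f"@pair{i}/2\n{_codes_to_read(self.seq2[i])}\n+\n{qual}\n")

    @classmethod
    def from_sam(cls, path: str, annotation: GenomeAnnotation) -> "ReadPairSet":
        """Load mapped pairs from a SAM/BAM file.

        Only ungapped primary alignments on the annotation's contig are
        accepted; mates are matched by query name."""
        first: dict[str, pysam.AlignedSegment] = {}
        second: dict[str, pysam.AlignedSegment] = {}
        read_len = None
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            names = list(fh.references or [])
            unknown = [n for n in names if n != annotation.contig_id]
            if unknown:
                raise ValueError(
                    f"SAM contigs not in reference: {', '.join(unknown)}")
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if any(op != 0 for op, _ in rec.cigartuples or []):
                    raise ValueError(
                        f"gapped alignment for {rec.query_name}: SNV-only "
                        "pipeline requires ungapped records")
                if read_len is None:
                    read_len = rec.query_length
                (first if rec.is_read1 else second)[rec.query_name] = rec
        common = sorted(set(first) & set(second))
        n = len(common)
        rl = read_len or 0
        start1 = np.zeros(n, dtype=np.int64)
        start2 = np.zeros(n, dtype=np.int64)
        seq1 = np.full((n, rl), 255, dtype=np.uint8)
        seq2 = np.full((n, rl), 255, dtype=np.uint8)
        source = np.full(n, -1, dtype=np.int32)
        for i, name in enumerate(common):
            r1, r2 = first[name], second[name]
            if r1.reference_start > r2.reference_start:
                r1, r2 = r2, r1
            start1[i], start2[i] = r1.reference_start, r2.reference_start
            seq1[i] = seq_to_codes(r1.query_sequence.upper())
            seq2[i] = seq_to_codes(r2.query_sequence.upper())
            if r1.has_tag("XH"):
                source[i] = r1.get_tag("XH")
        return cls(annotation.contig_id, annotation.length, rl,
                   start1, start2, seq1, seq2, source)
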