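"""Reference genomes and gene models.

All coordinates are 0-based half-open internally.  GFF3 round-trips convert
to and from the 1-based inclusive convention, writing genes as ``CDS``
features.  Gene models carry a strand; codons are always read on the coding
strand, so site-level statistics (synonymous/nonsynonymous classification,
third-codon-position masks) are strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
CODE_TO_BASE = dict(enumerate(BASES))
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)
STOP_CODONS = frozenset(CodonTable.unambiguous_dna_by_id[1].stop_codons)


def _build_codon_to_aa() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    aa = dict(table.forward_table)
    for codon in table.stop_codons:
        aa[codon] = "*"
    return aa


#: standard genetic code; stop codons translate to '*'
CODON_TO_AA = _build_codon_to_aa()

#: two-base prefixes whose four codons encode the same amino acid
FOURFOLD_PREFIXES = frozenset(
    p for p in (a + b for a in BASES for b in BASES)
    if len({CODON_TO_AA[p + c] for c in BASES}) == 1
)


def synonymous_site_weight(codon: str, position: int) -> float:
    """Fraction of the 3 possible substitutions at ``position`` that are
    synonymous (Nei-Gojobori site counting)."""
    aa = CODON_TO_AA[codon]
    syn = 0
    for b in BASES:
        if b == codon[position]:
            continue
        mutant = codon[:position] + b + codon[position + 1:]
        if CODON_TO_AA[mutant] == aa:
            syn += 1
    return syn / 3.0


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) mutational-opportunity sites of a codon."""
    s = sum(synonymous_site_weight(codon, k) for k in range(3))
    return s, 3.0 - s


def seq_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class AnnotationError(ValueError):
    """Raised when a gene model violates the coding-sequence invariants."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene on a contig (0-based half-open interval)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    frame: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def genomic_to_codon(self, pos: int) -> tuple[int, int]:
        """Map a genomic site inside the gene to (codon_index, codon_pos)
        in coding-strand orientation."""
        if not self.start <= pos < self.end:
            raise ValueError(f"position {pos} outside gene {self.gene_id}")
        offset = pos - self.start if self.strand == "+" else self.end - 1 - pos
        return offset // 3, offset % 3


@dataclass
class GenomeAnnotation:
    """A reference contig plus its non-overlapping gene models."""

    contig_id: str
    contig_seq: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contig_seq = self.contig_seq.upper()
        self._codes: np.ndarray | None = None
        self._site_gene: np.ndarray | None = None

    # -- derived arrays -------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.contig_seq)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = seq_to_codes(self.contig_seq)
        return self._codes

    @property
    def site_gene_index(self) -> np.ndarray:
        """Per-site gene index (-1 for intergenic)."""
        if self._site_gene is None:
            idx = np.full(self.length, -1, dtype=np.int32)
            for i, g in enumerate(self.genes):
                idx[g.start:g.end] = i
            self._site_gene = idx
        return self._site_gene

    def gene_at(self, pos: int) -> Gene | None:
        i = self.site_gene_index[pos]
        return None if i < 0 else self.genes[i]

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def coding_sequence(self, gene: Gene, codes: np.ndarray | None = None) -> str:
        """Coding-strand nucleotide sequence of a gene, optionally against an
        alternative base-code array (e.g. a sample consensus)."""
        arr = self.codes if codes is None else codes
        seq = codes_to_seq(arr[gene.start:gene.end])
        return revcomp(seq) if gene.strand == "-" else seq

    def third_codon_positions(self, codes: np.ndarray | None = None,
                              fourfold_only: bool = False) -> np.ndarray:
        """Genomic coordinates of third codon positions across all genes.

        With ``fourfold_only`` the set is restricted to third positions of
        4-fold degenerate codons, judged on the supplied base codes
        (defaults to the reference)."""
        out: list[np.ndarray] = []
        for g in self.genes:
            if g.strand == "+":
                pos = np.arange(g.start + 2, g.end, 3)
            else:
                pos = np.arange(g.end - 3, g.start - 1, -3)
            if fourfold_only:
                cds = self.coding_sequence(g, codes)
                keep = np.array(
                    [cds[3 * k: 3 * k + 2] in FOURFOLD_PREFIXES
                     for k in range(g.n_codons)],
                    dtype=bool,
                )
                pos = pos[keep]
            out.append(pos)
        if not out:
            return np.empty(0, dtype=np.int64)
        return np.sort(np.concatenate(out))

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check the simulator-guaranteed gene-model invariants."""
        prev_end = -1
        for g in sorted(self.genes, key=lambda g: g.start):
            if g.start < 0 or g.end > self.length or g.start >= g.end:
                raise AnnotationError(f"{g.gene_id}: interval outside contig")
            if g.length % 3:
                raise AnnotationError(f"{g.gene_id}: length not divisible by 3")
            if g.start < prev_end:
                raise AnnotationError(f"{g.gene_id}: overlaps previous gene")
            prev_end = g.end
            cds = self.coding_sequence(g)
            if cds[:3] != "ATG":
                raise AnnotationError(f"{g.gene_id}: does not start with ATG")
            internal = {cds[k:k + 3] for k in range(3, g.length - 3, 3)}
            if internal & STOP_CODONS:
                raise AnnotationError(f"{g.gene_id}: internal stop codon")

    # -- I/O -------------------------------------------------------------

    def write_fasta(self, path: str) -> None:
        rec = SeqRecord(Seq(self.contig_seq), id=self.contig_id, description="")
        SeqIO.write([rec], path, "fasta")

    def write_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.contig_id} 1 {self.length}\n")
            for g in self.genes:
                fh.write(
                    f"{self.contig_id}\tmicropopgen\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t{g.frame}\tID={g.gene_id}\n"
                )


def read_annotation(fasta_path: str, gff3_path: str) -> GenomeAnnotation:
    """Load a single-contig reference plus its CDS records."""
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if len(records) != 1:
        raise AnnotationError(
            f"expected a single contig, found {len(records)} in {fasta_path}")
    contig_id = records[0].id
    db = gffutils.create_db(gff3_path, ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[Gene] = []
    for feat in db.features_of_type("CDS"):
        if feat.seqid != contig_id:
            raise AnnotationError(f"unknown contig in GFF3: {feat.seqid}")
        gene_id = feat.attributes.get("ID", [f"gene{len(genes)}"])[0]
        frame = 0 if feat.frame in (None, ".") else int(feat.frame)
        genes.append(Gene(gene_id, contig_id, feat.start - 1, feat.end,
                          feat.strand, frame))
    genes.sort(key=lambda g: g.start)
    return GenomeAnnotation(contig_id, str(records[0].seq), genes)
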