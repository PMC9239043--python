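"""Pileups, SNV calling, and per-sample diversity statistics.

The unit of analysis is the pooled-read pileup of one sample mapped against
the reference.  SNVs are sites where at least two alleles pass frequency and
count thresholds at sufficient coverage; they are classified as synonymous,
nonsynonymous, or intergenic against the sample's consensus codon context
(the resident population's majority sequence, not the reference).
Diversity summaries follow the pooled-read definitions: per-site
pi = 1 - sum_b f_b^2 with no small-sample correction, pN/pS with
Nei-Gojobori fractional site counting on consensus codons, and a neutral
diversity computed over third positions of 4-fold degenerate codons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import (BASES, BASE_TO_CODE, COMPLEMENT_CODE, CODON_TO_AA,
                         AnnotationError, Gene, GenomeAnnotation,
                         codon_site_counts)
from .reads import ReadPairSet

DEFAULT_MIN_READ_IDENTITY = 0.94
DEFAULT_MIN_COVERAGE = 5
DEFAULT_MIN_ALLELE_FREQ = 0.05
DEFAULT_MIN_ALLELE_COUNT = 2


@dataclass
class PileupTable:
    """Per-site A/C/G/T counts for one sample on one contig."""

    contig_id: str
    counts: np.ndarray    # (L, 4) int32

    @property
    def length(self) -> int:
        return len(self.counts)

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def mean_coverage(self) -> float:
        return float(self.coverage.mean())

    @property
    def breadth(self) -> float:
        """Fraction of sites covered by at least one read."""
        return float((self.coverage > 0).mean())

    def consensus_codes(self, reference: np.ndarray) -> np.ndarray:
        """Majority base per site, falling back to the reference where
        there is no coverage."""
        cons = np.asarray(np.argmax(self.counts, axis=1), dtype=np.uint8)
        cov = self.coverage
        return np.where(cov > 0, cons, reference).astype(np.uint8)

    def frequencies(self) -> np.ndarray:
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov[:, None] > 0, self.counts / cov[:, None], 0.0)


def mate_identity(starts: np.ndarray, seqs: np.ndarray,
                  reference: np.ndarray) -> np.ndarray:
    """Per-mate fraction of bases matching the reference (N counts as a
    mismatch)."""
    read_len = seqs.shape[1]
    pos = starts[:, None] + np.arange(read_len)
    return (seqs == reference[pos]).mean(axis=1)


def build_pileup(reads: ReadPairSet, annotation: GenomeAnnotation,
                 min_read_identity: float = DEFAULT_MIN_READ_IDENTITY
                 ) -> PileupTable:
    """Tabulate per-site base counts from mapped pairs.

    Mates below the identity threshold are excluded.  Where the two mates of
    one pair overlap, the overlapped bases are counted once per pair (the
    first mate wins), so a single template molecule never contributes twice
    at a site.
    """
    if reads.contig_id != annotation.contig_id:
        raise ValueError(
            f"unknown contig in alignments: {reads.contig_id} "
            f"(reference is {annotation.contig_id})")
    L = annotation.length
    counts = np.zeros((L, 4), dtype=np.int32)
    if reads.n_pairs == 0:
        return PileupTable(annotation.contig_id, counts)
    ref = annotation.codes
    rl = reads.read_len
    offs = np.arange(rl)

    keep1 = mate_identity(reads.start1, reads.seq1, ref) >= min_read_identity
    keep2 = mate_identity(reads.start2, reads.seq2, ref) >= min_read_identity

    # mate 1 contributes everywhere it passes
    pos1 = reads.start1[keep1, None] + offs
    _accumulate(counts, pos1.ravel(), reads.seq1[keep1].ravel())

    # mate 2 skips columns already covered by a passing mate 1 of the same pair
    overlap_cols = np.maximum(
        reads.start1 + rl - reads.start2, 0)          # columns < this overlap
    first_col = np.where(keep1, overlap_cols, 0)
    col_ok = offs[None, :] >= first_col[:, None]
    sel = keep2[:, None] & col_ok
    pos2 = reads.start2[:, None] + offs
    _accumulate(counts, pos2[sel], reads.seq2[sel])
    return PileupTable(annotation.contig_id, counts)


def _accumulate(counts: np.ndarray, pos: np.ndarray, codes: np.ndarray) -> None:
    valid = codes < 4
    np.add.at(counts, (pos[valid], codes[valid].astype(np.int64)), 1)


# ---------------------------------------------------------------------------
# SNV calling and classification
# ---------------------------------------------------------------------------

def call_snvs(pileup: PileupTable, annotation: GenomeAnnotation,
              min_coverage: int = DEFAULT_MIN_COVERAGE,
              min_allele_freq: float = DEFAULT_MIN_ALLELE_FREQ,
              min_allele_count: int = DEFAULT_MIN_ALLELE_COUNT) -> pd.DataFrame:
    """Call SNVs: sites with coverage >= ``min_coverage`` where at least two
    alleles each reach ``min_allele_freq`` and ``min_allele_count``.

    Returns a table with one row per SNV: position, reference/consensus
    bases, the four allele frequencies, the biallelic projection
    (major = consensus, minor = most frequent other passing allele), the
    coding-effect class, and the host gene.  Multi-allelic sites are
    classified nonsynonymous if any called non-consensus allele is
    nonsynonymous.
    """
    if min_allele_freq >= 0.5:
        raise ValueError("min_allele_freq must be < 0.5")
    counts = pileup.counts
    cov = pileup.coverage
    eligible = cov >= min_coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(cov[:, None] > 0, counts / cov[:, None], 0.0)
    passing = (freqs >= min_allele_freq) & (counts >= min_allele_count)
    is_snv = eligible & (passing.sum(axis=1) >= 2)
    positions = np.where(is_snv)[0]

    ref = annotation.codes
    cons_all = pileup.consensus_codes(ref)
    gene_idx = annotation.site_gene_index
    cons_cds_cache: dict[int, str] = {}

    rows = []
    for pos in positions:
        consensus = int(cons_all[pos])
        pass_codes = [c for c in range(4) if passing[pos, c]]
        minors = [c for c in pass_codes if c != consensus]
        minor = max(minors, key=lambda c: counts[pos, c]) if minors else consensus
        gi = int(gene_idx[pos])
        if gi < 0:
            cls, gene_id = "intergenic", None
        else:
            gene = annotation.genes[gi]
            if gi not in cons_cds_cache:
                cons_cds_cache[gi] = annotation.coding_sequence(gene, cons_all)
            cls = _classify(gene, cons_cds_cache[gi], int(pos), consensus, minors)
            gene_id = gene.gene_id
        rows.append((annotation.contig_id, int(pos), BASES[ref[pos]],
                     BASES[consensus], *np.round(freqs[pos], 6),
                     int(cov[pos]), consensus, minor, cls, gene_id))
    return pd.DataFrame(rows, columns=[
        "contig", "position", "ref_base", "consensus_base",
        "freq_A", "freq_C", "freq_G", "freq_T",
        "coverage", "major_code", "minor_code", "snv_class", "gene_id",
    ])


def _classify(gene: Gene, cons_cds: str, pos: int, consensus: int,
              minor_codes: list[int]) -> str:
    """Coding effect of the called non-consensus alleles against the
    consensus codon context; nonsynonymous dominates ties."""
    ci, cp = gene.genomic_to_codon(pos)
    codon = cons_cds[3 * ci: 3 * ci + 3]
    for alt in minor_codes:
        code = alt if gene.strand == "+" else int(COMPLEMENT_CODE[alt])
        mutant = codon[:cp] + BASES[code] + codon[cp + 1:]
        if CODON_TO_AA[mutant] != CODON_TO_AA[codon]:
            return "nonsynonymous"
    return "synonymous"


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

@dataclass
class DiversityProfile:
    """Per-sample diversity summary; undefined quantities are None/NaN."""

    pi_site: np.ndarray                  # NaN where coverage below threshold
    pi_genome: float | None
    pi_gene: pd.Series
    pnps_gene: pd.Series | None = None
    pnps_genome: float | None = None
    pi_neutral: float | None = None
    n_neutral_sites: int = 0


def site_pi(pileup: PileupTable, min_coverage: int = DEFAULT_MIN_COVERAGE
            ) -> np.ndarray:
    """Per-site pi = 1 - sum_b f_b^2; NaN below the coverage threshold."""
    cov = pileup.coverage.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(cov[:, None] > 0, pileup.counts / cov[:, None], 0.0)
    pi = 1.0 - (f ** 2).sum(axis=1)
    pi[cov < min_coverage] = np.nan
    return pi


def nucleotide_diversity(pileup: PileupTable, annotation: GenomeAnnotation,
                         min_coverage: int = DEFAULT_MIN_COVERAGE
                         ) -> DiversityProfile:
    """Genome and per-gene nucleotide diversity over sufficiently covered
    sites.  Sites below the threshold are excluded from both numerator and
    denominator; with no eligible sites the mean is reported missing."""
    pi = site_pi(pileup, min_coverage)
    eligible = ~np.isnan(pi)
    genome = float(np.nanmean(pi)) if eligible.any() else None
    per_gene = {}
    for g in annotation.genes:
        seg = pi[g.start:g.end]
        per_gene[g.gene_id] = float(np.nanmean(seg)) if \
            (~np.isnan(seg)).any() else np.nan
    return DiversityProfile(pi, genome, pd.Series(per_gene, name="pi"))


def pnps(snvs: pd.DataFrame, annotation: GenomeAnnotation,
         pileup: PileupTable) -> tuple[pd.Series, float | None]:
    """Per-gene and genome-wide pN/pS.

    Sites of each class are counted Nei-Gojobori-style from the sample
    consensus codons; the genome value is the unweighted mean over genes
    with at least one synonymous SNV (others are undefined)."""
    cons = pileup.consensus_codes(annotation.codes)
    coding = snvs[snvs["gene_id"].notna()]
    n_by_gene = coding[coding["snv_class"] == "nonsynonymous"] \
        .groupby("gene_id").size()
    s_by_gene = coding[coding["snv_class"] == "synonymous"] \
        .groupby("gene_id").size()

    values = {}
    for g in annotation.genes:
        if g.length % 3:
            raise AnnotationError(f"{g.gene_id}: length not divisible by 3")
        cds = annotation.coding_sequence(g, cons)
        s_sites = n_sites = 0.0
        for k in range(g.n_codons):
            s, n = codon_site_counts(cds[3 * k: 3 * k + 3])
            s_sites += s
            n_sites += n
        n_snv = int(n_by_gene.get(g.gene_id, 0))
        s_snv = int(s_by_gene.get(g.gene_id, 0))
        if s_snv == 0 or s_sites == 0 or n_sites == 0:
            values[g.gene_id] = np.nan
        else:
            values[g.gene_id] = (n_snv / n_sites) / (s_snv / s_sites)
    series = pd.Series(values, name="pnps")
    defined = series.dropna()
    return series, (float(defined.mean()) if len(defined) else None)


def population_detection(pileup: PileupTable, min_coverage: float = 5.0,
                         min_breadth: float = 0.5) -> bool:
    """Presence gate: mean coverage and breadth must strictly exceed the
    thresholds (defaults 5x / 0.5; use 10x / 0.8 for diversity comparisons)."""
    return (pileup.mean_coverage > min_coverage
            and pileup.breadth > min_breadth)


def neutral_third_position_pi(pileup: PileupTable,
                              annotation: GenomeAnnotation,
                              min_coverage: int = DEFAULT_MIN_COVERAGE
                              ) -> tuple[float | None, int]:
    """Mean per-site diversity over third positions of 4-fold degenerate
    consensus codons with coverage >= ``min_coverage``; returns
    (pi_neutral, number of eligible sites), with None when no site is
    eligible."""
    cons = pileup.consensus_codes(annotation.codes)
    sites = annotation.third_codon_positions(cons, fourfold_only=True)
    if len(sites) == 0:
        return None, 0
    pi = site_pi(pileup, min_coverage)[sites]
    pi = pi[~np.isnan(pi)]
    if len(pi) == 0:
        return None, 0
    return float(pi.mean()), int(len(pi))


def effective_population_size(pi_neutral: float, mu: float = 1e-10) -> float:
    """Lower-bound effective population size from neutral diversity,
    Ne = 1.5 * pi / (mu * (3 - 4 * pi)).

    The estimate is a lower bound: third codon positions are not all
    neutral, and near-saturated neutral sites understate pi."""
    if not 0 <= pi_neutral < 0.75:
        raise ValueError("pi_neutral must lie in [0, 0.75)")
    if mu <= 0:
        raise ValueError("mu must be positive")
    return 1.5 * pi_neutral / (mu * (3.0 - 4.0 * pi_neutral))


def write_snv_vcf(snvs: pd.DataFrame, pileup: PileupTable,
                  annotation: GenomeAnnotation, path: str,
                  sample_name: str = "sample") -> None:
    """Minimal VCF 4.2 export of an SNV table with per-allele depths in the
    AD field (ref depth first, then each called alternate)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={annotation.contig_id},"
                 f"length={annotation.length}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,'
                 'Description="Coding-effect class">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
        for row in snvs.itertuples(index=False):
            pos = int(row.position)
            counts = pileup.counts[pos]
            ref_code = BASE_TO_CODE[row.ref_base]
            alts = [c for c in np.argsort(counts)[::-1]
                    if c != ref_code and counts[c] > 0]
            ad = [int(counts[ref_code])] + [int(counts[c]) for c in alts]
            fh.write("\t".join([
                annotation.contig_id, str(pos + 1), ".", row.ref_base,
                ",".join(BASES[c] for c in alts) if alts else ".",
                ".", "PASS", f"CLASS={row.snv_class}", "AD",
                ",".join(map(str, ad)),
            ]) + "\n")


def diversity_profile(pileup: PileupTable, annotation: GenomeAnnotation,
                      snvs: pd.DataFrame | None = None,
                      min_coverage: int = DEFAULT_MIN_COVERAGE
                      ) -> DiversityProfile:
    """Convenience assembly of the full diversity summary for one sample."""
    if snvs is None:
        snvs = call_snvs(pileup, annotation, min_coverage=min_coverage)
    prof = nucleotide_diversity(pileup, annotation, min_coverage)
    prof.pnps_gene, prof.pnps_genome = pnps(snvs, annotation, pileup)
    prof.pi_neutral, prof.n_neutral_sites = neutral_third_position_pi(
        pileup, annotation, min_coverage)
    return prof
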