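"""Forward simulation of strain communities with known population-genetic
ground truth.

The simulator produces every input the analysis stages consume — a reference
genome with gene models, pools of strain haplotypes with a target
nucleotide diversity and a tunable linkage length, two-deme communities with
a target FST and site-exclusive accessory genes, paired-end reads, and
time series in which chosen nonsynonymous alleles track a temperature
covariate — together with a :class:`TruthSet` recording the generating
parameters for recovery experiments.

Strains are mosaics of ancestral allele blocks rather than coalescent
samples: the genome is cut into blocks of ``recomb_block_len`` bp, each
strain draws an ancestor independently per block, and polymorphic sites
inherit the ancestor's allele.  Sites in the same block therefore share an
ancestry pattern (high linkage) while sites in different blocks are
independent (free recombination), giving direct control over both the
diversity level and the distance scale of linkage decay.  Realised diversity
is controlled exactly: candidate polymorphic sites are drawn in excess and a
random subset is kept whose summed expected heterozygosity matches the
target ``pi * L``.

Read sampling is Poisson-like: fragment start positions are uniform, the
pair count is set by the requested fold coverage, fragment lengths are
normal with median ~250 bp, and substitution errors are i.i.d. uniform over
the three alternative bases (no indels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import expit, logit

from .annotation import (BASES, COMPLEMENT_CODE, STOP_CODONS, CODON_TO_AA,
                         AnnotationError, Gene, GenomeAnnotation,
                         codes_to_seq, seq_to_codes)
from .reads import ReadPairSet

READ_LEN = 150
INSERT_MEDIAN = 250
#: log-scale sigma of the lognormal fragment-length distribution; broad
#: fragmentation so that templates span the whole 0-420 bp linkage window
INSERT_SIGMA = 0.5
INSERT_MAX = 1000


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reference genomes
# ---------------------------------------------------------------------------

def simulate_reference(length: int, n_genes: int, gc: float = 0.35,
                       seed: int = 0, min_gene_len: int = 150,
                       max_gene_len: int = 900,
                       contig_id: str = "contig_1") -> GenomeAnnotation:
    """Generate a random single-contig reference with ``n_genes``
    non-overlapping ORFs (ATG start, no internal stops, stop codon last)
    at the requested GC content.  Deterministic given ``seed``."""
    if not 0 < gc < 1:
        raise SimulationError("gc must be in (0, 1)")
    if n_genes < 0 or length <= 0:
        raise SimulationError("length and n_genes must be non-negative")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    lens = rng.integers(min_gene_len // 3, max_gene_len // 3 + 1, n_genes) * 3
    if lens.sum() + 2 * (n_genes + 1) > length:
        raise SimulationError(
            f"{n_genes} genes of {min_gene_len}-{max_gene_len} bp cannot fit "
            f"in {length} bp")

    # spread the intergenic slack uniformly over the n_genes + 1 gaps
    slack = length - int(lens.sum())
    cuts = np.sort(rng.integers(0, slack + 1, n_genes))
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))

    stop_list = sorted(STOP_CODONS)
    stop_p = np.array([np.prod([p["ACGT".index(b)] for b in s])
                       for s in stop_list])
    stop_p /= stop_p.sum()

    seq_parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for i in range(n_genes):
        gap = int(gaps[i])
        seq_parts.append(codes_to_seq(rng.choice(4, gap, p=p).astype(np.uint8)))
        pos += gap
        n_body = int(lens[i]) // 3 - 2
        body = _draw_codons(rng, n_body, p)
        stop = stop_list[rng.choice(len(stop_list), p=stop_p)]
        orf = "ATG" + body + stop
        strand = "+" if rng.random() < 0.5 else "-"
        insert = orf if strand == "+" else _revcomp_str(orf)
        seq_parts.append(insert)
        genes.append(Gene(f"gene_{i:04d}", contig_id, pos, pos + len(orf), strand))
        pos += len(orf)
    seq_parts.append(codes_to_seq(rng.choice(4, int(gaps[-1]), p=p).astype(np.uint8)))

    ann = GenomeAnnotation(contig_id, "".join(seq_parts), genes)
    ann.validate()
    return ann


def _revcomp_str(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def _draw_codons(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    """Draw ``n`` non-stop codons with per-base composition ``p``."""
    out: list[str] = []
    need = n
    while need > 0:
        batch = rng.choice(4, (need + 8, 3), p=p).astype(np.uint8)
        for row in batch:
            codon = codes_to_seq(row)
            if codon not in STOP_CODONS:
                out.append(codon)
                if len(out) == n:
                    break
        need = n - len(out)
    return "".join(out)


# ---------------------------------------------------------------------------
# strain pools
# ---------------------------------------------------------------------------

@dataclass
class StrainPool:
    """A mixture of full-genome haplotypes over a shared reference."""

    annotation: GenomeAnnotation
    haplotypes: np.ndarray            # (n_strains, L) base codes
    strain_freqs: np.ndarray          # simplex weights
    snv_positions: np.ndarray         # genomic coordinates of polymorphic sites
    site_heterozygosity: np.ndarray   # expected pi at those sites
    recomb_block_len: float
    seed: int
    # per-strain gene absence mask (True = strain lacks the gene's DNA);
    # empty dict means every strain carries every gene
    absent_genes: dict[int, list[Gene]] = field(default_factory=dict)

    @property
    def n_strains(self) -> int:
        return len(self.haplotypes)

    @property
    def expected_pi(self) -> float:
        """Genome-wide expected nucleotide diversity
        sum_sites (1 - sum_a f_a^2) / L."""
        return float(self.site_heterozygosity.sum()) / self.annotation.length

    def allele_frequencies(self, pos: int) -> np.ndarray:
        """Haplotype-weighted frequencies of A/C/G/T at ``pos``."""
        f = np.zeros(4)
        np.add.at(f, self.haplotypes[:, pos], self.strain_freqs)
        return f

    def true_site_diversity(self) -> np.ndarray:
        """Dense per-site expected pi vector."""
        h = np.zeros(self.annotation.length)
        h[self.snv_positions] = self.site_heterozygosity
        return h


def _site_heterozygosity(hap_col: np.ndarray, w: np.ndarray) -> float:
    f = np.zeros(4)
    np.add.at(f, hap_col, w)
    return 1.0 - float((f ** 2).sum())


def simulate_strain_pool(annotation: GenomeAnnotation, n_strains: int,
                         target_pi: float, recomb_block_len: float = math.inf,
                         seed: int = 0, n_ancestors: int = 6,
                         allele_freq_alpha: float = 0.5,
                         neutral_pi: float | None = None) -> StrainPool:
    """Build a strain pool whose expected genome-wide diversity matches
    ``target_pi``.

    Polymorphic sites are biallelic with ancestor-level derived-allele
    frequencies drawn Beta(``allele_freq_alpha``, ``allele_freq_alpha``);
    linkage is induced by the shared mosaic block structure.  With
    ``neutral_pi`` set, additional four-allele polymorphisms are placed at
    third positions of 4-fold degenerate reference codons until the mean
    expected diversity over those positions reaches ``neutral_pi``,
    emulating near-saturated neutral sites.
    """
    if not 0 <= target_pi <= 0.75:
        raise SimulationError("target_pi must lie in [0, 0.75]")
    if n_strains < 1:
        raise SimulationError("need at least one strain")
    if recomb_block_len <= 0:
        raise SimulationError("recomb_block_len must be positive")
    rng = np.random.default_rng(seed)
    L = annotation.length
    ref = annotation.codes

    if math.isinf(recomb_block_len):
        block_of = np.zeros(L, dtype=np.int64)
        n_blocks = 1
    else:
        block_of = (np.arange(L) // int(recomb_block_len)).astype(np.int64)
        n_blocks = int(block_of[-1]) + 1
    ancestry = rng.integers(0, n_ancestors, (n_strains, n_blocks))
    w = np.full(n_strains, 1.0 / n_strains)

    haplotypes = np.tile(ref, (n_strains, 1))
    positions: list[np.ndarray] = []
    hets: list[np.ndarray] = []

    if target_pi > 0 and n_strains > 1:
        pos, het = _place_sites(
            rng, haplotypes, ref, np.arange(L), block_of, ancestry, w,
            target_total=target_pi * L, mode="biallelic",
            alpha=allele_freq_alpha)
        positions.append(pos)
        hets.append(het)
    elif target_pi > 0:
        raise SimulationError("target_pi > 0 requires at least two strains")

    if neutral_pi is not None and n_strains > 1:
        eligible = annotation.third_codon_positions(fourfold_only=True)
        used = positions[0] if positions else np.empty(0, dtype=np.int64)
        eligible = np.setdiff1d(eligible, used)
        pos, het = _place_sites(
            rng, haplotypes, ref, eligible, block_of, ancestry, w,
            target_total=neutral_pi * len(
                annotation.third_codon_positions(fourfold_only=True)),
            mode="quad", alpha=allele_freq_alpha)
        positions.append(pos)
        hets.append(het)

    if positions:
        pos_all = np.concatenate(positions)
        het_all = np.concatenate(hets)
        order = np.argsort(pos_all)
        pos_all, het_all = pos_all[order], het_all[order]
    else:
        pos_all = np.empty(0, dtype=np.int64)
        het_all = np.empty(0)

    return StrainPool(annotation, haplotypes, w, pos_all, het_all,
                      recomb_block_len, seed)


def _place_sites(rng, haplotypes, ref, eligible, block_of, ancestry, w,
                 target_total, mode, alpha):
    """Place polymorphic sites on ``eligible`` positions until the summed
    expected heterozygosity reaches ``target_total``; mutates haplotypes."""
    n_strains, _ = haplotypes.shape
    n_anc = int(ancestry.max()) + 1 if ancestry.size else 1
    placed_pos: list[int] = []
    placed_het: list[float] = []
    total = 0.0
    remaining = rng.permutation(eligible)
    idx = 0
    # generous upper bound on mean site heterozygosity for batch sizing
    step = max(256, int(target_total / 0.05))
    while total < target_total and idx < len(remaining):
        batch = remaining[idx:idx + step]
        idx += len(batch)
        anc_alleles = _draw_ancestor_alleles(rng, len(batch), n_anc, mode,
                                             alpha, ref[batch])
        anc_of = ancestry[:, block_of[batch]]            # (n_strains, m)
        strain_alleles = np.take_along_axis(
            anc_alleles.T, anc_of, axis=0)               # (n_strains, m)
        for j, p in enumerate(batch):
            col = strain_alleles[:, j]
            h = _site_heterozygosity(col, w)
            if h <= 0:
                continue
            if total + h > target_total and \
                    abs(total + h - target_total) > abs(total - target_total):
                continue
            haplotypes[:, p] = col
            placed_pos.append(int(p))
            placed_het.append(h)
            total += h
    if total < 0.9 * target_total:
        raise SimulationError(
            "diversity target unreachable on the eligible site set "
            f"(achieved {total:.1f} of {target_total:.1f} summed pi)")
    return np.array(placed_pos, dtype=np.int64), np.array(placed_het)


def _draw_ancestor_alleles(rng, m, n_anc, mode, alpha, ref_bases):
    """Per-site ancestor allele matrix of shape (m, n_anc)."""
    if mode == "biallelic":
        f = rng.beta(alpha, alpha, m)
        carries = rng.random((m, n_anc)) < f[:, None]
        derived = (ref_bases + rng.integers(1, 4, m)) % 4
        out = np.where(carries, derived[:, None], ref_bases[:, None])
    else:  # quad: each ancestor an independent uniform base
        out = rng.integers(0, 4, (m, n_anc))
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# two-deme communities
# ---------------------------------------------------------------------------

@dataclass
class DemePair:
    """Two strain pools over one reference with controlled differentiation.

    Between-deme allele-frequency divergence follows the Balding-Nichols
    model: at each shared polymorphic site with ancestral frequency ``p``,
    the two demes draw frequencies independently from
    Beta(p(1-F)/F, (1-p)(1-F)/F), so the Hudson FST of the pooled
    frequencies concentrates on the target ``F``.
    """

    pool_a: StrainPool
    pool_b: StrainPool
    target_fst: float
    snv_positions: np.ndarray
    freqs_a: np.ndarray     # realised derived-allele frequency per site, deme A
    freqs_b: np.ndarray
    exclusive_genes_a: list[str]
    exclusive_genes_b: list[str]

    def true_gene_fst(self) -> pd.Series:
        """Hudson FST per gene from the realised haplotype frequencies
        (infinite-depth limit, ratio of sums over loci in the gene)."""
        ann = self.pool_a.annotation
        gene_idx = ann.site_gene_index[self.snv_positions]
        out = {}
        for i, gene in enumerate(ann.genes):
            sel = gene_idx == i
            if not sel.any():
                continue
            p1, p2 = self.freqs_a[sel], self.freqs_b[sel]
            num = ((p1 - p2) ** 2).sum()
            den = (p1 * (1 - p2) + p2 * (1 - p1)).sum()
            if den > 0:
                out[gene.gene_id] = num / den
        return pd.Series(out, name="fst_true")

    def true_mean_fst(self) -> float:
        return float(self.true_gene_fst().mean())


def simulate_deme_pair(annotation: GenomeAnnotation, n_strains: int = 40,
                       target_fst: float = 0.2, background_pi: float = 0.02,
                       seed: int = 0, allele_freq_alpha: float = 0.5,
                       n_exclusive_a: int = 0, n_exclusive_b: int = 0
                       ) -> DemePair:
    """Two demes sharing polymorphic sites with Balding-Nichols
    differentiation at the target FST, plus optional deme-exclusive
    accessory genes (absent from every strain of the other deme)."""
    if not 0 <= target_fst < 1:
        raise SimulationError("target_fst must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    L = annotation.length
    ref = annotation.codes

    n_sites = int(round(background_pi * L / 0.25))
    positions = np.sort(rng.choice(L, n_sites, replace=False))
    p_anc = rng.beta(allele_freq_alpha, allele_freq_alpha, n_sites)
    if target_fst > 0:
        a = p_anc * (1 - target_fst) / target_fst
        b = (1 - p_anc) * (1 - target_fst) / target_fst
        p1_raw = rng.beta(a, b)
        p2_raw = rng.beta(a, b)
        # calibrate the deviation scale so the realised mean-over-genes
        # Hudson FST (computed on the quantised strain frequencies, the
        # quantity the pair advertises as truth) hits the target
        gene_idx = annotation.site_gene_index[positions]

        def realised(scale: float) -> tuple[np.ndarray, np.ndarray, float]:
            q1 = np.round(np.clip(p_anc + scale * (p1_raw - p_anc), 0, 1)
                          * n_strains) / n_strains
            q2 = np.round(np.clip(p_anc + scale * (p2_raw - p_anc), 0, 1)
                          * n_strains) / n_strains
            values = []
            for gi in np.unique(gene_idx[gene_idx >= 0]):
                sel = gene_idx == gi
                num = ((q1[sel] - q2[sel]) ** 2).sum()
                den = (q1[sel] * (1 - q2[sel])
                       + q2[sel] * (1 - q1[sel])).sum()
                if den > 0:
                    values.append(num / den)
            return q1, q2, float(np.mean(values)) if values else 0.0

        lo, hi = 0.2, 3.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            _, _, fst_mid = realised(mid)
            if fst_mid < target_fst:
                lo = mid
            else:
                hi = mid
        p1, p2, _ = realised(0.5 * (lo + hi))
    else:
        p1 = p2 = np.round(p_anc * n_strains) / n_strains

    derived = ((ref[positions] + rng.integers(1, 4, n_sites)) % 4).astype(np.uint8)

    pools = []
    realised = []
    for pool_seed, p_target in ((seed + 1, p1), (seed + 2, p2)):
        prng = np.random.default_rng(pool_seed)
        hap = np.tile(ref, (n_strains, 1))
        k = np.round(p_target * n_strains).astype(int)
        freq = k / n_strains
        for j, pos in enumerate(positions):
            if k[j] == 0:
                continue
            carriers = prng.choice(n_strains, k[j], replace=False)
            hap[carriers, pos] = derived[j]
        w = np.full(n_strains, 1.0 / n_strains)
        het = 1.0 - freq ** 2 - (1 - freq) ** 2
        poly = het > 0
        pools.append(StrainPool(annotation, hap, w, positions[poly],
                                het[poly], math.inf, pool_seed))
        realised.append(freq)

    pool_a, pool_b = pools
    fa, fb = realised

    # deme-exclusive accessory genes: drop whole genes from every strain of
    # the other deme (reads never sample those intervals there)
    gene_ids = [g.gene_id for g in annotation.genes]
    n_excl = n_exclusive_a + n_exclusive_b
    if n_excl > len(gene_ids):
        raise SimulationError("more exclusive genes requested than genes")
    chosen = list(rng.choice(len(gene_ids), n_excl, replace=False))
    excl_a = [annotation.genes[i] for i in chosen[:n_exclusive_a]]
    excl_b = [annotation.genes[i] for i in chosen[n_exclusive_a:]]
    # genes exclusive to A are absent from B and vice versa
    if excl_a:
        pool_b.absent_genes = {s: list(excl_a) for s in range(n_strains)}
    if excl_b:
        pool_a.absent_genes = {s: list(excl_b) for s in range(n_strains)}

    keep = (fa != fb) | ((fa > 0) & (fa < 1))
    return DemePair(pool_a, pool_b, target_fst, positions[keep],
                    fa[keep], fb[keep],
                    [g.gene_id for g in excl_a], [g.gene_id for g in excl_b])


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _draw_fragments(rng: np.random.Generator, n: int, L: int,
                    insert_median: float, insert_sigma: float) -> np.ndarray:
    return np.clip(
        np.round(rng.lognormal(math.log(insert_median), insert_sigma, n)),
        READ_LEN, min(INSERT_MAX, L)).astype(np.int64)


def simulate_sample_reads(pool: StrainPool, coverage: float,
                          error_rate: float = 0.0, seed: int = 0,
                          read_len: int = READ_LEN,
                          insert_median: float = INSERT_MEDIAN,
                          insert_sigma: float = INSERT_SIGMA) -> ReadPairSet:
    """Sample 2x``read_len`` read pairs from the pool at the requested mean
    coverage.  Source haplotypes follow ``strain_freqs``; fragment lengths
    are lognormal (median ``insert_median``) with a broad tail; substitution
    errors are i.i.d. uniform over the three alternative bases."""
    if pool.n_strains == 0:
        raise SimulationError("empty strain pool")
    if coverage <= 0:
        raise SimulationError("coverage must be positive")
    if not 0 <= error_rate < 0.1:
        raise SimulationError("error_rate must lie in [0, 0.1)")
    rng = np.random.default_rng(seed)
    L = pool.annotation.length
    n = int(round(coverage * L / (2 * read_len)))

    strain = rng.choice(pool.n_strains, n, p=pool.strain_freqs).astype(np.int32)
    frag = _draw_fragments(rng, n, L, insert_median, insert_sigma)
    start1 = np.floor(rng.random(n) * (L - frag + 1)).astype(np.int64)

    if pool.absent_genes:
        start1, frag = _reject_absent(rng, pool, strain, start1, frag, L)

    start2 = start1 + frag - read_len
    offs = np.arange(read_len)
    seq1 = pool.haplotypes[strain[:, None], start1[:, None] + offs].copy()
    seq2 = pool.haplotypes[strain[:, None], start2[:, None] + offs].copy()
    if error_rate > 0:
        for seq in (seq1, seq2):
            mask = rng.random(seq.shape) < error_rate
            shift = rng.integers(1, 4, seq.shape)
            seq[mask] = ((seq[mask].astype(np.int64) + shift[mask]) % 4
                         ).astype(np.uint8)
    return ReadPairSet(pool.annotation.contig_id, L, read_len,
                       start1, start2, seq1, seq2, strain)


def _reject_absent(rng, pool, strain, start1, frag, L):
    """Resample fragments that overlap a gene their source strain lacks."""
    masks: dict[int, np.ndarray] = {}
    for s, genes in pool.absent_genes.items():
        m = np.zeros(L + 1, dtype=np.int64)
        for g in genes:
            m[g.start] += 1
            m[g.end] -= 1
        masks[s] = np.concatenate([[0], np.cumsum(np.cumsum(m)[:-1] > 0)])
    for _ in range(200):
        bad = np.zeros(len(start1), dtype=bool)
        for s, csum in masks.items():
            sel = strain == s
            if not sel.any():
                continue
            a, f = start1[sel], frag[sel]
            bad[sel] = (csum[a + f] - csum[a]) > 0
        if not bad.any():
            return start1, frag
        nb = int(bad.sum())
        frag[bad] = _draw_fragments(rng, nb, L, INSERT_MEDIAN, INSERT_SIGMA)
        start1[bad] = np.floor(rng.random(nb) * (L - frag[bad] + 1)).astype(np.int64)
    raise SimulationError("could not place fragments outside absent genes")


# ---------------------------------------------------------------------------
# environment series and responsive-allele time series
# ---------------------------------------------------------------------------

def make_env_series(n_samples: int, site: str = "HOT",
                    start: str = "2003-01-15", period_days: int = 30,
                    temp_mean: float = 22.0, temp_amplitude: float = 3.0,
                    temp_noise: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Monthly-style environmental series with a seasonal temperature cycle
    plus noise.  Columns: sample_id, iso_date, site, temperature_c."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_samples, freq=f"{period_days}D")
    doy = dates.dayofyear.to_numpy()
    temp = (temp_mean + temp_amplitude * np.sin(2 * np.pi * doy / 365.25)
            + rng.normal(0, temp_noise, n_samples))
    return pd.DataFrame({
        "sample_id": [f"{site}_{d.strftime('%Y%m%d')}" for d in dates],
        "iso_date": dates.strftime("%Y-%m-%d"),
        "site": site,
        "temperature_c": np.round(temp, 3),
    })


def validate_env_series(env: pd.DataFrame) -> None:
    required = {"sample_id", "iso_date", "site", "temperature_c"}
    missing = required - set(env.columns)
    if missing:
        raise SimulationError(f"env series missing columns: {sorted(missing)}")
    for site, grp in env.groupby("site"):
        dates = pd.to_datetime(grp["iso_date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise SimulationError(f"dates not strictly increasing at {site}")


@dataclass
class TruthSet:
    """Generating parameters of a simulated data set, for recovery tests."""

    seed: int
    pi_genome: float | None = None
    pi_gene: pd.Series | None = None
    deme_freqs: pd.DataFrame | None = None
    exclusive_gene_ids: list[str] = field(default_factory=list)
    responsive: pd.DataFrame | None = None       # position, sign, slope
    responsive_freqs: pd.DataFrame | None = None  # position x sample_id
    neutral_positions: np.ndarray | None = None

    def write_tsv(self, prefix: str) -> None:
        if self.responsive is not None:
            self.responsive.to_csv(f"{prefix}.responsive.tsv", sep="\t",
                                   index=False)
        if self.responsive_freqs is not None:
            self.responsive_freqs.to_csv(f"{prefix}.responsive_freqs.tsv",
                                         sep="\t")
        if self.pi_gene is not None:
            self.pi_gene.rename("pi_true").to_csv(f"{prefix}.pi_gene.tsv",
                                                  sep="\t")


def pool_truth(pool: StrainPool) -> TruthSet:
    """Truth record for a single pool (diversity surface)."""
    ann = pool.annotation
    h = pool.true_site_diversity()
    per_gene = pd.Series(
        {g.gene_id: float(h[g.start:g.end].mean()) for g in ann.genes})
    return TruthSet(seed=pool.seed, pi_genome=pool.expected_pi,
                    pi_gene=per_gene)


def nonsynonymous_sites(pool: StrainPool) -> np.ndarray:
    """Polymorphic sites whose non-reference alleles change the encoded
    amino acid (classified against the reference codon context)."""
    ann = pool.annotation
    out = []
    for pos in pool.snv_positions:
        gene = ann.gene_at(int(pos))
        if gene is None:
            continue
        alleles = np.unique(pool.haplotypes[:, pos])
        ref_base = int(ann.codes[pos])
        if _any_nonsyn(ann, gene, int(pos), ref_base,
                       [a for a in alleles if a != ref_base]):
            out.append(int(pos))
    return np.array(out, dtype=np.int64)


def _any_nonsyn(ann: GenomeAnnotation, gene: Gene, pos: int, ref_base: int,
                alt_codes: list[int]) -> bool:
    ci, cp = gene.genomic_to_codon(pos)
    cds = ann.coding_sequence(gene)
    codon = cds[3 * ci: 3 * ci + 3]
    for alt in alt_codes:
        base = BASES[alt] if gene.strand == "+" else \
            BASES[COMPLEMENT_CODE[alt]]
        mutant = codon[:cp] + base + codon[cp + 1:]
        if CODON_TO_AA[mutant] != CODON_TO_AA[codon]:
            return True
    return False


def simulate_time_series(pool: StrainPool, env: pd.DataFrame,
                         n_responsive: int, coupling: float, seed: int = 0,
                         coverage: float = 50.0, error_rate: float = 0.001,
                         jitter_sd: float = 0.02
                         ) -> tuple[list[ReadPairSet], TruthSet]:
    """Read sets over an environmental series in which ``n_responsive``
    nonsynonymous alleles track temperature.

    Responsive allele frequencies follow a logistic function of temperature,
    freq(t) = expit(a + b*T(t)) + N(0, ``jitter_sd``), with the slope
    magnitude ``coupling`` (logit units per degree C) and alternating sign;
    all other polymorphisms get exchangeable resampling noise only.
    ``coupling = 0`` yields an empty responsive set.
    """
    validate_env_series(env)
    if len(env) < 4:
        raise SimulationError("need at least 4 time points")
    rng = np.random.default_rng(seed)
    temps = env["temperature_c"].to_numpy(float)

    if coupling == 0 or n_responsive == 0:
        resp_pos = np.empty(0, dtype=np.int64)
    else:
        candidates = nonsynonymous_sites(pool)
        if n_responsive > len(candidates):
            raise SimulationError(
                f"{n_responsive} responsive SNVs requested but only "
                f"{len(candidates)} nonsynonymous sites available")
        resp_pos = np.sort(rng.choice(candidates, n_responsive, replace=False))

    signs = np.where(np.arange(len(resp_pos)) % 2 == 0, 1.0, -1.0)
    # centre each trajectory on the site's standing frequency
    ref = pool.annotation.codes
    base_freq = np.empty(len(resp_pos))
    derived_code = np.empty(len(resp_pos), dtype=np.uint8)
    for j, pos in enumerate(resp_pos):
        f = pool.allele_frequencies(int(pos))
        ref_base = int(ref[pos])
        alt = int(np.argmax(np.delete(f, ref_base)))
        alt = alt if alt < ref_base else alt + 1
        derived_code[j] = alt
        base_freq[j] = np.clip(f[alt], 0.05, 0.95)
    a = logit(base_freq) - coupling * signs * temps.mean()

    freq_matrix = expit(a[:, None] + coupling * signs[:, None] * temps[None, :])
    freq_matrix = np.clip(
        freq_matrix + rng.normal(0, jitter_sd, freq_matrix.shape), 0.01, 0.99)

    read_sets = []
    for t in range(len(env)):
        rs = simulate_sample_reads(pool, coverage, error_rate,
                                   seed=int(rng.integers(2 ** 31)))
        _impose_frequencies(rng, rs, resp_pos, derived_code, ref,
                            freq_matrix[:, t], error_rate)
        read_sets.append(rs)

    truth = TruthSet(
        seed=seed, pi_genome=pool.expected_pi,
        responsive=pd.DataFrame({
            "position": resp_pos,
            "derived_base": [BASES[c] for c in derived_code],
            "sign": signs.astype(int) if len(resp_pos) else signs,
            "slope": coupling * signs,
        }),
        responsive_freqs=pd.DataFrame(
            freq_matrix, index=resp_pos, columns=env["sample_id"].tolist()),
        neutral_positions=np.setdiff1d(pool.snv_positions, resp_pos),
    )
    return read_sets, truth


def _impose_frequencies(rng, rs: ReadPairSet, positions, derived_code, ref,
                        freqs, error_rate) -> None:
    """Overwrite responsive sites on each template to hit target allele
    frequencies; the draw is per pair so both mates stay consistent."""
    for j, pos in enumerate(positions):
        target = freqs[j]
        carries = rng.random(rs.n_pairs) < target
        base = np.where(carries, derived_code[j], ref[pos]).astype(np.uint8)
        if error_rate > 0:
            err = rng.random(rs.n_pairs) < error_rate
            shift = rng.integers(1, 4, rs.n_pairs)
            base = np.where(err, (base.astype(np.int64) + shift) % 4,
                            base).astype(np.uint8)
        for starts, seq in ((rs.start1, rs.seq1), (rs.start2, rs.seq2)):
            off = pos - starts
            cover = (off >= 0) & (off < rs.read_len)
            rows = np.where(cover)[0]
            seq[rows, off[rows]] = base[rows]


# ---------------------------------------------------------------------------
# pangenome presence/absence with a target openness
# ---------------------------------------------------------------------------

def simulate_presence_absence(n_genomes: int, gamma: float,
                              kappa: float = 100.0, seed: int = 0
                              ) -> pd.DataFrame:
    """Genomes x gene-cluster binary matrix whose expected gene accumulation
    curve follows Heaps' law P(N) = kappa * N**gamma.

    Gene clusters are exchangeable across genomes: a cluster of multiplicity
    k occupies a uniformly random subset of k genomes, and the multiplicity
    spectrum m_k is fitted by non-negative least squares so that
    E[P(N)] = sum_k m_k * (1 - C(n-k, N)/C(n, N)) matches the target curve.
    """
    if n_genomes < 4:
        raise SimulationError("need at least 4 genomes")
    rng = np.random.default_rng(seed)
    n = n_genomes
    target = kappa * np.arange(1, n + 1) ** gamma

    # design[N-1, k-1] = P(cluster of multiplicity k seen in first N genomes)
    design = np.empty((n, n))
    for k in range(1, n + 1):
        for N in range(1, n + 1):
            design[N - 1, k - 1] = 1.0 - math.comb(n - k, N) / math.comb(n, N) \
                if n - k >= N else 1.0
    m, _ = nnls(design, target)

    cols = []
    for k in range(1, n + 1):
        for _ in range(int(round(m[k - 1]))):
            col = np.zeros(n, dtype=np.int8)
            col[rng.choice(n, k, replace=False)] = 1
            cols.append(col)
    rng.shuffle(cols)
    mat = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8)
    return pd.DataFrame(mat, index=[f"genome_{i:03d}" for i in range(n)],
                        columns=[f"cluster_{j:05d}" for j in range(mat.shape[1])])
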