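"""Between-sample population differentiation.

Per-gene FST between two pooled metagenome samples uses a Hudson-style
estimator with a finite-depth correction: at each biallelic locus with
pooled frequencies p1, p2 and two-allele depths n1, n2,

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

and the gene value is the ratio of sums over its loci.  Slightly negative
values are legitimate finite-depth outcomes and are retained (clamping
would bias genome-wide means upward).  Loci must clear a depth floor in
both samples and sit within 2 SD of each sample's mean SNV-locus depth.

Sample-pair mean FSTs feed a principal-coordinate analysis; the Cailliez
additive constant makes an arbitrary dissimilarity matrix Euclidean before
the classical MDS eigendecomposition.  Divergence between two populations
is dated from consensus differences at third codon positions under a
constant per-generation mutation rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, Gene
from .profiling import (DEFAULT_MIN_ALLELE_COUNT, DEFAULT_MIN_ALLELE_FREQ,
                        PileupTable, call_snvs)
from .stats import bh_adjust

DEFAULT_MIN_DEPTH = 20
DEFAULT_SD_FILTER = 2.0


def snv_union_positions(pileup_a: PileupTable, pileup_b: PileupTable,
                        annotation: GenomeAnnotation,
                        min_coverage: int = DEFAULT_MIN_DEPTH,
                        min_allele_freq: float = DEFAULT_MIN_ALLELE_FREQ,
                        min_allele_count: int = DEFAULT_MIN_ALLELE_COUNT
                        ) -> np.ndarray:
    """Candidate FST loci: SNV positions called in either sample or in the
    pooled counts of the pair.

    Pooled calling is what exposes fixed differences — sites monomorphic
    within each sample but for different alleles — which carry most of the
    differentiation signal at high FST."""
    pooled = PileupTable(pileup_a.contig_id, pileup_a.counts + pileup_b.counts)
    pos = set()
    for p in (pileup_a, pileup_b, pooled):
        snvs = call_snvs(p, annotation, min_coverage=min_coverage,
                         min_allele_freq=min_allele_freq,
                         min_allele_count=min_allele_count)
        pos.update(snvs["position"].tolist())
    return np.array(sorted(pos), dtype=np.int64)


def _locus_filter(pileup: PileupTable, loci: np.ndarray, min_depth: float,
                  sd_filter: float) -> np.ndarray:
    """Depth gate per sample: depth >= min_depth and within
    mean +/- sd_filter * SD of the sample's depth over the candidate loci."""
    depth = pileup.coverage[loci].astype(float)
    ok = depth >= min_depth
    if ok.any() and sd_filter is not None:
        mu, sd = depth.mean(), depth.std()
        ok &= np.abs(depth - mu) <= sd_filter * sd
    return ok


def _hudson_terms(counts_a: np.ndarray, counts_b: np.ndarray
                  ) -> tuple[float, float] | None:
    """Numerator/denominator contribution of one locus; None when it cannot
    be evaluated (depth < 2 or no shared biallelic signal)."""
    pooled = counts_a + counts_b
    order = np.argsort(pooled)[::-1]
    major, minor = int(order[0]), int(order[1])
    if pooled[minor] == 0:
        return None
    n1 = int(counts_a[major] + counts_a[minor])
    n2 = int(counts_b[major] + counts_b[minor])
    if n1 < 2 or n2 < 2:
        return None
    p1 = counts_a[major] / n1
    p2 = counts_b[major] / n2
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst_gene(pileup_a: PileupTable, pileup_b: PileupTable, gene: Gene,
                    loci: np.ndarray,
                    min_depth: float = DEFAULT_MIN_DEPTH,
                    sd_filter: float = DEFAULT_SD_FILTER,
                    depth_ok_a: np.ndarray | None = None,
                    depth_ok_b: np.ndarray | None = None) -> float:
    """Gene-level Hudson FST over the qualifying loci inside ``gene``.

    ``loci`` are candidate SNV positions (genome-wide); the depth/SD gates
    may be passed in precomputed for efficiency.  NaN when no locus
    qualifies or the summed denominator is zero."""
    if depth_ok_a is None:
        depth_ok_a = _locus_filter(pileup_a, loci, min_depth, sd_filter)
    if depth_ok_b is None:
        depth_ok_b = _locus_filter(pileup_b, loci, min_depth, sd_filter)
    in_gene = (loci >= gene.start) & (loci < gene.end)
    use = loci[in_gene & depth_ok_a & depth_ok_b]
    num = den = 0.0
    any_locus = False
    for pos in use:
        terms = _hudson_terms(pileup_a.counts[pos], pileup_b.counts[pos])
        if terms is None:
            continue
        any_locus = True
        num += terms[0]
        den += terms[1]
    if not any_locus or den == 0:
        return np.nan
    return num / den


def gene_fst_table(pileup_a: PileupTable, pileup_b: PileupTable,
                   annotation: GenomeAnnotation,
                   min_depth: float = DEFAULT_MIN_DEPTH,
                   sd_filter: float = DEFAULT_SD_FILTER,
                   min_gene_depth: float = DEFAULT_MIN_DEPTH,
                   snv_min_coverage: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-gene FST between two samples over genes covered at
    >= ``min_gene_depth`` in both."""
    loci = snv_union_positions(pileup_a, pileup_b, annotation,
                               min_coverage=snv_min_coverage)
    ok_a = _locus_filter(pileup_a, loci, min_depth, sd_filter)
    ok_b = _locus_filter(pileup_b, loci, min_depth, sd_filter)
    cov_a, cov_b = pileup_a.coverage, pileup_b.coverage
    rows = []
    for gene in annotation.genes:
        da = float(cov_a[gene.start:gene.end].mean())
        db = float(cov_b[gene.start:gene.end].mean())
        if da < min_gene_depth or db < min_gene_depth:
            continue
        in_gene = (loci >= gene.start) & (loci < gene.end)
        fst = hudson_fst_gene(pileup_a, pileup_b, gene, loci,
                              min_depth, sd_filter, ok_a, ok_b)
        rows.append({"gene_id": gene.gene_id, "fst": fst,
                     "n_snvs": int(in_gene.sum()),
                     "depth_a": da, "depth_b": db})
    return pd.DataFrame(rows)


def pairwise_mean_fst(pileups: dict[str, PileupTable],
                      annotation: GenomeAnnotation,
                      min_genome_coverage: float = DEFAULT_MIN_DEPTH,
                      min_depth: float = DEFAULT_MIN_DEPTH,
                      sd_filter: float = DEFAULT_SD_FILTER) -> pd.DataFrame:
    """Symmetric sample-by-sample matrix of mean gene FST.

    Only samples whose genome-wide mean coverage exceeds
    ``min_genome_coverage`` enter; each pair's mean runs over genes covered
    at >= ``min_depth`` in both samples with a defined gene FST.  The
    diagonal is zero by construction."""
    kept = {s: p for s, p in pileups.items()
            if p.mean_coverage > min_genome_coverage}
    if len(kept) < 2:
        raise ValueError(
            f"need >= 2 samples above {min_genome_coverage}x coverage, "
            f"have {len(kept)}")
    samples = sorted(kept)
    mat = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            table = gene_fst_table(kept[a], kept[b], annotation,
                                   min_depth=min_depth, sd_filter=sd_filter,
                                   min_gene_depth=min_depth)
            mean = float(table["fst"].dropna().mean()) if len(table) else np.nan
            mat.loc[a, b] = mat.loc[b, a] = mean
    return mat


def fst_outlier_test(gene_fsts: pd.Series, alpha: float = 0.05
                     ) -> pd.DataFrame:
    """Right-tailed Z test for elevated per-gene FST.

    z-scores against the mean/SD of all defined gene FSTs, one-sided upper
    normal p-values, Benjamini-Hochberg adjustment, flag at adjusted
    p < ``alpha``."""
    defined = gene_fsts.dropna()
    if len(defined) < 10:
        raise ValueError("need >= 10 genes with defined FST")
    mu, sd = float(defined.mean()), float(defined.std(ddof=0))
    out = pd.DataFrame({"fst": defined})
    if sd <= 1e-12 * max(1.0, abs(mu)):
        warnings.warn("zero FST dispersion: no outliers callable")
        out["z"] = 0.0
        out["p"] = 1.0
        out["adj_p"] = 1.0
        out["outlier"] = False
        return out
    out["z"] = (defined - mu) / sd
    out["p"] = stats.norm.sf(out["z"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["outlier"] = out["adj_p"] < alpha
    return out


# ---------------------------------------------------------------------------
# principal coordinates with the Cailliez correction
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    samples: list[str]
    coordinates: pd.DataFrame        # samples x axes
    eigenvalues: np.ndarray
    explained: np.ndarray            # fraction of positive-eigenvalue variance
    cailliez_constant: float


def _double_centre(mat: np.ndarray) -> np.ndarray:
    n = len(mat)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ mat @ j


def cailliez_constant(d: np.ndarray, tol: float = 1e-9) -> float:
    """Smallest additive constant c such that the dissimilarities d_ij + c
    (off-diagonal) admit an exact Euclidean embedding: the largest real
    eigenvalue of the 2n x 2n companion matrix
    [[0, 2*D1], [-I, -4*D2]], with D1/D2 the double-centred -d^2/2 and
    -d/2 matrices."""
    n = len(d)
    d1 = _double_centre(-0.5 * d ** 2)
    d2 = _double_centre(-0.5 * d)
    block = np.block([
        [np.zeros((n, n)), 2.0 * d1],
        [-np.eye(n), -4.0 * d2],
    ])
    eig = np.linalg.eigvals(block)
    c = float(np.max(eig.real))
    return max(c, 0.0) if c > tol else 0.0


def pcoa_cailliez(distance_matrix: pd.DataFrame, eig_tol: float = 1e-8
                  ) -> PCoAResult:
    """Classical MDS of a sample dissimilarity matrix after the Cailliez
    correction; axes are ordered by eigenvalue and the returned coordinates
    reproduce the corrected dissimilarities."""
    d = np.asarray(distance_matrix, dtype=float)
    samples = [str(s) for s in distance_matrix.index]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")

    c = 0.0 if np.allclose(d, 0) else cailliez_constant(d)
    dc = d + c
    np.fill_diagonal(dc, 0.0)
    gram = _double_centre(-0.5 * dc ** 2)
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > eig_tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    total = eigval[positive].sum()
    explained = eigval[positive] / total if total > 0 else eigval[positive]
    frame = pd.DataFrame(
        coords, index=samples,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])])
    return PCoAResult(samples, frame, eigval, explained, c)


# ---------------------------------------------------------------------------
# consensus-SNP divergence dating
# ---------------------------------------------------------------------------

@dataclass
class DivergenceEstimate:
    """Lower-bound divergence between two populations from third-position
    consensus differences."""

    n_consensus_snps: int
    n_sites: int
    d3: float
    generations: float
    years: float


def consensus_divergence_time(pileup_a: PileupTable, pileup_b: PileupTable,
                              annotation: GenomeAnnotation,
                              mu: float = 1e-10,
                              generation_days: float = 7.0,
                              min_coverage: int = 5) -> DivergenceEstimate:
    """Date the split of two populations from consensus SNPs at third codon
    positions: d3 = differences / jointly covered third-position sites,
    T = d3 / (2 mu) generations (both lineages accumulate mutations),
    years = T * generation_days / 365.25.  A lower bound, since saturated
    neutral sites understate the true divergence."""
    third = annotation.third_codon_positions()
    if len(third) == 0:
        raise ValueError("annotation contains no coding third positions")
    cov_a = pileup_a.coverage[third] >= min_coverage
    cov_b = pileup_b.coverage[third] >= min_coverage
    for name, covered in (("A", cov_a), ("B", cov_b)):
        if covered.mean() < 0.5:
            raise ValueError(
                f"profile {name} covers {covered.mean():.0%} of third codon "
                "positions at the coverage floor; need >= 50%")
    joint = third[cov_a & cov_b]
    if len(joint) == 0:
        raise ValueError("no jointly covered third-position sites")
    cons_a = pileup_a.consensus_codes(annotation.codes)[joint]
    cons_b = pileup_b.consensus_codes(annotation.codes)[joint]
    diffs = int((cons_a != cons_b).sum())
    d3 = diffs / len(joint)
    generations = d3 / (2.0 * mu)
    years = generations * generation_days / 365.25
    return DivergenceEstimate(diffs, len(joint), d3, generations, years)
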