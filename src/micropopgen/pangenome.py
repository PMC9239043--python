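"""Gene-content variation between sites and pangenome openness.

Gene presence in a pooled metagenome sample is proxied by relative gene
coverage r = (gene mean depth) / (genome mean depth): r near 1 means the
whole population carries the gene, r near 0 means almost nobody does.
Entries with r > 3 are masked (the reads likely belong to another species
or a binning error) and never contribute to downstream tests; masked is
distinct from zero.  Differential presence between two sites is a one-way
ANOVA per gene with Benjamini-Hochberg correction; differential genes are
classified site-specific when detected (r > 0.10) at one site and never
reaching r >= 0.10 at the other.  Pangenome openness is the Heaps-law
exponent of the gene accumulation curve over genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .profiling import PileupTable
from .stats import bh_adjust

MASK_THRESHOLD = 3.0
DETECT_THRESHOLD = 0.10
DIFFERENTIAL_P = 0.001
BASIN_GATE_P = 0.01


@dataclass
class GeneCoverageMatrix:
    """Genes x samples relative coverage with an explicit mask channel."""

    values: pd.DataFrame       # relative coverage, NaN where masked
    masked: pd.DataFrame       # True where r > MASK_THRESHOLD
    site_labels: pd.Series     # sample -> site

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def relative_gene_coverage(gene_depths: pd.Series, genome_depth: float,
                           mask_threshold: float = MASK_THRESHOLD
                           ) -> tuple[pd.Series, pd.Series]:
    """One sample's relative-coverage column and its mask.

    r = gene depth / genome mean depth; entries with r strictly above the
    mask threshold are masked (NaN in the value column, True in the mask);
    the boundary r == threshold is retained."""
    if genome_depth <= 0:
        raise ValueError("genome mean depth must be positive")
    r = gene_depths.astype(float) / genome_depth
    masked = r > mask_threshold
    return r.where(~masked), masked


def gene_coverage_matrix(pileups: dict[str, PileupTable],
                         annotation: GenomeAnnotation,
                         site_labels: dict[str, str],
                         mask_threshold: float = MASK_THRESHOLD
                         ) -> GeneCoverageMatrix:
    """Relative gene coverage across samples from per-sample pileups."""
    values = {}
    masks = {}
    for sample, pileup in pileups.items():
        cov = pileup.coverage
        depths = pd.Series(
            {g.gene_id: float(cov[g.start:g.end].mean())
             for g in annotation.genes})
        genome_depth = pileup.mean_coverage
        if genome_depth <= 0:
            continue    # sample excluded: genome not covered
        values[sample], masks[sample] = relative_gene_coverage(
            depths, genome_depth, mask_threshold)
    vals = pd.DataFrame(values)
    return GeneCoverageMatrix(vals, pd.DataFrame(masks),
                              pd.Series({s: site_labels[s]
                                         for s in vals.columns}))


def differential_gene_presence(matrix: GeneCoverageMatrix,
                               alpha: float = DIFFERENTIAL_P) -> pd.DataFrame:
    """Per-gene one-way ANOVA of relative coverage across the two site
    groups, BH-adjusted over tested genes, flagged at adjusted p < alpha.

    Masked entries are excluded; a gene with fewer than two unmasked values
    in either group is reported untested."""
    sites = sorted(matrix.site_labels.unique())
    if len(sites) != 2:
        raise ValueError(f"expected exactly 2 sites, found {sites}")
    groups = {s: matrix.site_labels[matrix.site_labels == s].index
              for s in sites}
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("need >= 2 samples per site")
    rows = []
    for gene in matrix.genes:
        a = matrix.values.loc[gene, groups[sites[0]]].dropna()
        b = matrix.values.loc[gene, groups[sites[1]]].dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append((gene, np.nan, np.nan, False))
            continue
        if a.var() == 0 and b.var() == 0:
            f, p = (np.nan, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            f, p = stats.f_oneway(a, b)
        rows.append((gene, float(f), float(p), True))
    out = pd.DataFrame(rows, columns=["gene_id", "F", "p", "tested"]) \
        .set_index("gene_id")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["differential"] = out["adj_p"] < alpha
    return out


def basin_specific_genes(matrix: GeneCoverageMatrix,
                         differential: pd.DataFrame,
                         detect_threshold: float = DETECT_THRESHOLD,
                         gate_p: float = BASIN_GATE_P) -> pd.Series:
    """Classify gated differential genes as site-specific or shared.

    A gene is specific to site A when it is detected (r strictly above the
    detection threshold) in at least one A sample and r stays strictly
    below the threshold in every unmasked B sample; symmetric for B;
    everything else is shared.  The gate is adjusted p < ``gate_p``."""
    sites = sorted(matrix.site_labels.unique())
    groups = {s: matrix.site_labels[matrix.site_labels == s].index
              for s in sites}
    gated = differential[differential["tested"]
                         & (differential["adj_p"] < gate_p)].index
    out = {}
    for gene in gated:
        calls = {}
        for s in sites:
            vals = matrix.values.loc[gene, groups[s]].dropna()
            calls[s] = {
                "detected": bool((vals > detect_threshold).any()),
                "absent": bool((vals < detect_threshold).all()) and len(vals) > 0,
            }
        a, b = sites
        if calls[a]["detected"] and calls[b]["absent"]:
            out[gene] = a
        elif calls[b]["detected"] and calls[a]["absent"]:
            out[gene] = b
        else:
            out[gene] = "shared"
    return pd.Series(out, name="classification", dtype=object)


# ---------------------------------------------------------------------------
# pangenome openness (Heaps' law)
# ---------------------------------------------------------------------------

@dataclass
class OpennessFit:
    gamma: float
    kappa: float
    n_permutations: int
    curve: pd.DataFrame     # N, median, q25, q75 accumulation counts


def accumulation_curve(pa: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Distinct gene clusters after each genome in ``order``."""
    seen = np.logical_or.accumulate(pa[order].astype(bool), axis=0)
    return seen.sum(axis=1)


def pangenome_openness(pa: pd.DataFrame, n_permutations: int = 100,
                       seed: int = 0) -> OpennessFit:
    """Heaps-law openness from a genomes x gene-clusters binary matrix.

    Accumulation curves are computed over random genome orders; the
    power-law P(N) = kappa * N**gamma is fitted by least squares on the
    log-log median curve."""
    mat = pa.to_numpy()
    n = mat.shape[0]
    if n < 4:
        raise ValueError("need at least 4 genomes")
    if mat.shape[1] == 0 or (mat.sum(axis=0) == 0).any():
        raise ValueError("presence/absence matrix has empty gene clusters")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, n), dtype=np.int64)
    for r in range(n_permutations):
        curves[r] = accumulation_curve(mat, rng.permutation(n))
    q25, med, q75 = np.percentile(curves, [25, 50, 75], axis=0)
    N = np.arange(1, n + 1)
    slope, intercept = np.polyfit(np.log(N), np.log(med), 1)
    return OpennessFit(
        gamma=float(slope), kappa=float(np.exp(intercept)),
        n_permutations=n_permutations,
        curve=pd.DataFrame({"N": N, "median": med, "q25": q25, "q75": q75}))
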