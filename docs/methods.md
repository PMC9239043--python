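# Methods

`micropopgen` measures strain-level population structure of a microbial
population from pooled, mapped metagenomic read pairs, and ships a forward
simulator that generates communities with known ground truth so every
estimator can be validated end to end. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish about real data.

## The measurement model

All statistics are computed from a per-sample pileup: per-site A/C/G/T
counts over reads mapped to a single reference contig with gene models
(GFF3 `CDS` records; coordinates are 0-based half-open internally and
converted at the I/O boundary). Reads below a per-mate identity threshold
against the reference (default 0.94) are excluded as likely mismappings;
where the two mates of a pair overlap, overlapped bases are counted once
per template (first mate wins).

**SNVs.** A site is an SNV when coverage ≥ 5 and at least two alleles each
reach frequency ≥ 0.05 and count ≥ 2. SNVs are classified synonymous /
nonsynonymous / intergenic against the *sample consensus* codon context
(majority base per site), not the reference — classification should
describe the resident population. At multi-allelic sites nonsynonymous
dominates: if any called non-consensus allele changes the amino acid the
site is nonsynonymous (conservative for pN).

**Diversity.** Per-site π = 1 − Σ_b f_b², averaged over sites with
coverage ≥ 5 (sites below the floor are excluded from numerator and
denominator). No (n/(n−1)) small-sample correction is applied — this is
the pooled-read definition; users comparing against corrected estimators
should expect a downward difference of order 1/coverage. pN/pS per gene is
(N_snv/N_sites)/(S_snv/S_sites) with Nei–Gojobori fractional site counting
on the consensus codons (each codon position contributes the fraction of
its three substitutions that are synonymous; substitutions to or from stop
codons count as nonsynonymous). Genes with no synonymous SNV have
undefined pN/pS; the genome value is the unweighted mean over defined
genes. Neutral diversity π_neutral is the mean per-site π over third
positions of 4-fold degenerate consensus codons ("nonconserved third
positions" is operationalised as 4-fold degeneracy; whether 2-fold sites
or cross-sample-variable sites should also qualify is genuinely open, and
the 4-fold choice is the stricter one). The lower-bound effective
population size is Ne = 1.5·π_neutral/(μ(3 − 4π_neutral)) with
μ = 1e-10 per bp per generation; it is a lower bound because third
positions are not all neutral and saturated sites understate π_neutral.

**Detection.** A population is analysed in a sample only when mean
coverage and breadth strictly exceed 5× and 0.5 (strict inequalities match
the source thresholds written as ">"); diversity comparisons use the
stricter 10× / 0.8 preset.

## Linkage

r² between two SNVs is estimated from the read pairs that carry a called
allele at both sites (union of the two mates; a pair observing conflicting
bases at a site is discarded for site pairs involving that site). Each SNV
is projected to its two top alleles. Pairs qualify up to 420 bp apart with
at least 20 connecting pairs, and r² is normalised by rarefying to exactly
20 connecting pairs (100 hypergeometric subsamples, fixed seed; replicates
with a monomorphic margin are redrawn, at most 10× the replicate count,
else the value is undefined). When exactly 20 pairs connect, the rarefied
value equals the raw value by construction. Decay curves bin distances at
30 bp and stratify by N-N / N-S / S-S over coding SNVs only.

A geometric fact worth recording: with a ~250 bp median insert the
expected number of templates connecting two sites d apart is roughly
(coverage/300)·E[min(frag − d, 150)⁺], so the 300–420 bp bins clear the
20-pair threshold only in deep samples. The packaged LD-decay experiment
therefore uses a ~300× sample; at survey coverages (≤100×) those bins are
legitimately empty, as they are in shallow field samples.

## Between-sample differentiation

Per-gene FST between two samples is Hudson-style with a finite-depth
correction. Candidate loci are SNVs called in either sample *or in the
pooled counts of the pair* — pooled calling is what exposes fixed
differences, which are monomorphic within each sample yet carry most of
the differentiation. Loci need depth ≥ 20 in both samples and must lie
within 2 SD of each sample's mean depth over candidate loci (two-sided,
per sample). At a biallelic locus with frequencies p₁, p₂ and two-allele
depths n₁, n₂:

    num = (p₁ − p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    den = p₁(1−p₂) + p₂(1−p₁)

and the gene value is Σnum/Σden over its loci (ratio of sums — lower
variance than averaging per-locus ratios). Slightly negative values are
legitimate finite-depth outcomes and are retained; clamping would bias
genome means upward. Sample-pair mean FST averages defined gene values
over genes covered ≥ 20× in both samples; the self-pair is defined as 0 so
the matrix is a proper dissimilarity. Outlier genes are flagged by a
right-tailed Z test against the mean/SD of all defined gene FSTs
(normal tail, BH, adjusted p < 0.05; gene counts are large in intended
use, so no t correction).

**Ordination.** Classical MDS after the Cailliez correction: the smallest
additive constant c making the off-diagonal dissimilarities Euclidean is
the largest real eigenvalue of the 2n×2n companion matrix
[[0, 2Δ₁], [−I, −4Δ₂]] (Δ₁, Δ₂ the double-centred −d²/2 and −d/2
matrices); coordinates come from the eigendecomposition of the corrected
Gram matrix and reproduce the corrected dissimilarities to 1e−6.

**Divergence dating.** Consensus SNPs at third codon positions between two
profiles give d₃ = differences / jointly covered third-position sites
(coverage ≥ 5 in both, and each profile must cover ≥ 50 % of third
positions); T = d₃/(2μ) generations — both lineages accumulate mutations —
and years = T·g/365.25 with g = 7 days. A lower bound, as saturation
understates d₃.

## Gene-content flexibility

Relative gene coverage r = gene mean depth / genome mean depth proxies the
carrier fraction. Entries with r > 3 are masked (foreign reads or binning
error) and are distinguishable from 0; masked values never enter any test.
Differential presence between two sites is a per-gene one-way ANOVA with
BH control; two thresholds are kept deliberately because the source
analysis used both: `differential_p = 0.001` defines the differential set
and `basin_gate_p = 0.01` gates the site-specificity classification.
A gene is site-A-specific when detected (r strictly > 0.10) in ≥ 1 A
sample and r stays strictly < 0.10 in every unmasked B sample; exactly
r = 0.10 counts as neither detected nor absence-qualified. Openness fits
Heaps' law P(N) = κ·N^γ by least squares on the log-log *median*
accumulation curve over 100 random genome orders (the median is robust to
ordering extremes).

## The simulator

The simulator is first-class code: it defines the conditions under which
every estimator is validated.

**Reference.** Random intergenic sequence at a target GC (default 0.35,
realised within ±0.02) with non-overlapping ORFs (ATG start, no internal
stop, random strand, 150–900 bp).

**Strain pools: mosaic-of-ancestral-blocks.** The genome is cut into
blocks of `recomb_block_len` bp; each of `n_strains` strains draws one of
`n_ancestors` (default 6) ancestors independently per block. A polymorphic
site inherits the ancestor's allele, so sites in one block share an
ancestry pattern (high linkage) and sites in different blocks are
independent — block length is the controlled analogue of recombination
rate. Ancestor-level derived-allele frequencies are Beta(0.5, 0.5)
(yielding both common and rare variants). Diversity is controlled exactly:
candidate sites are drawn in excess and a subset is kept whose summed
expected heterozygosity matches π·L, so the pool's advertised truth is
the realised one (within one site's heterozygosity). An optional
`neutral_pi` places additional four-allele polymorphisms at 4-fold
third positions, emulating near-saturated neutral sites. This is not a
coalescent: it trades demographic realism for exact, tunable targets.

**Reads.** 2×150 bp pairs; pair count set by requested fold coverage
(coverage is counted in emitted bases; the template-level pileup depth is
~10–15 % lower because overlapping mates are deduplicated). Fragment
lengths are lognormal with median 250 bp and log-sd 0.5 — the broad tail
is a deliberate choice so that some templates span the whole 0–420 bp
linkage window; a narrow fragment distribution at this median leaves the
far bins structurally empty. Fragment starts are uniform (per-site depth
is then Poisson-like; no depth model was specified and this is the
simplest). Errors are i.i.d. substitutions, uniform over the three
alternative bases; no indels, matching the SNV-only scope.

**Two demes.** Shared polymorphic sites with Balding–Nichols
between-deme frequencies at a target FST; frequencies are quantised onto
equal-weight strains, and the deviation scale is calibrated internally
(bisection) so the realised mean-over-genes Hudson FST of the quantised
frequencies equals the requested target — per-gene ratio-of-sums over
finite loci would otherwise sit ~10 % off the nominal parameter.
Deme-exclusive accessory genes are modelled as whole-gene deletions in
every strain of the other deme: fragments overlapping a deleted gene are
resampled, so the gene's coverage there is exactly zero.

**Time series.** Chosen nonsynonymous alleles follow
freq(t) = logistic(a + b·T(t)) + N(0, 0.02) with the slope magnitude set
by `coupling` (logit units per °C, alternating sign) and `a` centred on
the allele's standing frequency; the allele is imposed per template (one
draw per read pair) so mates stay consistent. All other sites carry only
resampling noise. Temperatures follow a seasonal sinusoid plus noise.

**Pangenomes.** Gene clusters are exchangeable across genomes: a cluster
of multiplicity k occupies a uniform random k-subset of genomes, and the
multiplicity spectrum is fitted by non-negative least squares so the
expected accumulation curve equals κ·N^γ exactly.

## What the synthetic validation shows — and does not

Passing recovery tests show the estimators are correct under the stated
generative model: unbiased pileups, a single known reference, no
mismapping, no indels or structural variation, panmictic pools with
block-exchangeable ancestry, and deletion-style gene absence. They do not
validate robustness to mismapping against close relatives (the identity
filter is the production guard for that, and the recovery experiments
disable it precisely because the simulator contains no mismapping),
reference bias, chimeric assembly, uneven GC-dependent coverage, or
gene-content variation mediated by mobile elements. The
diversity-vs-linkage association experiment builds in the
recombination-maintains-diversity coupling (higher-π pools get shorter
blocks); its negative Spearman correlation demonstrates that the
estimators resolve that coupling, not that the coupling exists in nature.

## Problem sizes and defaults used in the packaged experiments

Chosen so the whole validation runs on one CPU in a few minutes while
keeping every comparison statistically stable: π recovery on a 20 kb / 20
gene reference at 50× (targets 0.005, 0.02, 0.1; tolerance 10 %); FST
recovery on 40 kb / 40 genes at 50× with 40 strains per deme (targets
0.05, 0.2, 0.45; tolerance 15 %); Heaps γ = 0.4 with 20 genomes ×3 seeds
(tolerance ±0.05); LD decay on 12 kb at 300×; spike-in of 20 exclusive
genes among 480 core genes at 30×, 8 samples per site (the
differential-presence design assumes a multi-timepoint series; 3 per site
leaves the df-(1,4) ANOVA underpowered for the 0.01 gate); 20 responsive
SNVs over 12 timepoints at 50× with coupling 1.0. Null calibrations use
1000 genes / 1000 SNVs and report flagged fractions at the nominal gates.

## Known limitations

- Single-contig references only; multi-contig support would need
  per-contig coordinate bookkeeping throughout.
- The π estimator's pooled-read definition slightly underestimates at low
  coverage (no small-sample correction by design).
- The Heaps fit assumes the power law holds over the observed genome
  range; κ is poorly identified when γ ≈ 0.
- Gene FST is undefined (NaN) for genes whose loci all fail the depth/SD
  gates; pairwise means skip them silently.
- The simulator's allele-frequency spectrum (Beta 0.5, 0.5) is a
  convenience, not a fitted demographic spectrum.
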