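"""Parameter-recovery and error-control experiments on synthetic
communities.

Each experiment builds a community with the simulator, runs the relevant
analysis stage end to end, and reports the estimate alongside the generating
truth.  They exist so the whole pipeline can be validated without external
sequencing data; the problem sizes are chosen to make the statistical
comparison stable on a single CPU in minutes.

A note on the read-identity filter: the production default (0.94) removes
mismapped reads on the real-data path.  The simulator produces no
mismapping, and at simulated diversities far above the study's level a
fixed identity cutoff would censor genuine strain divergence, so the
recovery experiments build pileups with the filter disabled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import fst_outlier_test, gene_fst_table
from .linkage import enumerate_linked_pairs, linkage_decay_curve, mean_genome_r2
from .pangenome import (basin_specific_genes, differential_gene_presence,
                        gene_coverage_matrix, pangenome_openness)
from .profiling import build_pileup, call_snvs, nucleotide_diversity
from .simulate import (make_env_series, simulate_deme_pair,
                       simulate_presence_absence, simulate_reference,
                       simulate_sample_reads, simulate_strain_pool,
                       simulate_time_series)
from .temporal import covariate_correlated_snvs, snv_frequency_matrix


def pi_recovery(targets=(0.005, 0.02, 0.1), length: int = 20000,
                n_genes: int = 20, coverage: float = 50.0, seed: int = 0
                ) -> pd.DataFrame:
    """Nucleotide-diversity recovery from error-free reads at the given
    coverage, one strain pool per target."""
    ann = simulate_reference(length, n_genes, 0.35, seed=seed)
    rows = []
    for k, target in enumerate(targets):
        pool = simulate_strain_pool(ann, 20, target, seed=seed + 10 + k)
        reads = simulate_sample_reads(pool, coverage, 0.0, seed=seed + 40 + k)
        pileup = build_pileup(reads, ann, min_read_identity=0.0)
        est = nucleotide_diversity(pileup, ann).pi_genome
        rows.append({"target": target, "truth": pool.expected_pi,
                     "estimate": est,
                     "rel_error": (est - target) / target})
    return pd.DataFrame(rows)


def fst_recovery(targets=(0.05, 0.2, 0.45), length: int = 40000,
                 n_genes: int = 40, coverage: float = 50.0, seed: int = 0
                 ) -> pd.DataFrame:
    """Two-deme mean gene FST recovery at the given targets."""
    ann = simulate_reference(length, n_genes, 0.35, seed=seed)
    rows = []
    for k, target in enumerate(targets):
        dp = simulate_deme_pair(ann, 40, target, 0.02, seed=seed + 20 + k)
        pa = build_pileup(simulate_sample_reads(
            dp.pool_a, coverage, 0.0, seed=seed + 60 + k), ann, 0.0)
        pb = build_pileup(simulate_sample_reads(
            dp.pool_b, coverage, 0.0, seed=seed + 80 + k), ann, 0.0)
        est = float(gene_fst_table(pa, pb, ann)["fst"].dropna().mean())
        rows.append({"target": target, "truth": dp.true_mean_fst(),
                     "estimate": est,
                     "rel_error": (est - target) / target})
    return pd.DataFrame(rows)


def heaps_recovery(gamma: float = 0.4, n_genomes: int = 20,
                   n_seeds: int = 3, seed: int = 0) -> pd.DataFrame:
    """Openness-exponent recovery from exchangeable pangenomes built with a
    target Heaps exponent."""
    rows = []
    for k in range(n_seeds):
        pa = simulate_presence_absence(n_genomes, gamma, kappa=100,
                                       seed=seed + k)
        fit = pangenome_openness(pa, seed=seed + k)
        rows.append({"target": gamma, "estimate": fit.gamma,
                     "error": fit.gamma - gamma})
    return pd.DataFrame(rows)


def linkage_decay_experiment(length: int = 12000, n_genes: int = 12,
                             block_len: float = 200.0,
                             coverage: float = 300.0, seed: int = 0) -> dict:
    """LD decay on a deep sample of a recombining pool: mean rarefied r^2
    in the near (0-90 bp) versus far (300-420 bp) distance bins.

    Populating the far bins at the 20-connecting-pair threshold requires a
    deep sample, because few 250 bp-median templates span 300+ bp."""
    ann = simulate_reference(length, n_genes, 0.35, seed=seed)
    pool = simulate_strain_pool(ann, 20, 0.02, block_len, seed=seed + 1)
    reads = simulate_sample_reads(pool, coverage, 0.0, seed=seed + 2)
    pileup = build_pileup(reads, ann, 0.0)
    snvs = call_snvs(pileup, ann)
    pairs = enumerate_linked_pairs(snvs, reads, seed=seed + 3)
    curve = linkage_decay_curve(pairs)
    sub = curve[curve["stratum"] == "all"]

    def _bin_mean(frame):
        weights = frame["n_pairs"].to_numpy(float)
        values = frame["mean_r2"].fillna(0.0).to_numpy()
        return float((values * weights).sum() / weights.sum())

    near = sub[sub["bin_end"] <= 90]
    far = sub[sub["bin_start"] >= 300]
    means = sub.dropna(subset=["mean_r2"])["mean_r2"].to_numpy()
    return {
        "near_mean_r2": _bin_mean(near),
        "far_mean_r2": _bin_mean(far),
        "far_n_pairs": int(far["n_pairs"].sum()),
        "monotone_trend": float(stats.spearmanr(
            np.arange(len(means)), means).statistic),
    }


def r2_pi_correlation(length: int = 12000, n_genes: int = 12,
                      coverage: float = 50.0, seed: int = 0) -> dict:
    """Mean genome r^2 against nucleotide diversity across pools in which
    higher diversity comes with more recombination (shorter blocks),
    mirroring the recombination-maintained diversity of the field
    populations."""
    settings = [(0.005, 420.0), (0.01, 300.0), (0.02, 200.0),
                (0.05, 100.0), (0.1, 60.0)]
    ann = simulate_reference(length, n_genes, 0.35, seed=seed)
    pis, r2s = [], []
    for k, (pi_target, block) in enumerate(settings):
        pool = simulate_strain_pool(ann, 20, pi_target, block,
                                    seed=seed + 5 + k)
        reads = simulate_sample_reads(pool, coverage, 0.0, seed=seed + 25 + k)
        pileup = build_pileup(reads, ann, 0.0)
        snvs = call_snvs(pileup, ann)
        pairs = enumerate_linked_pairs(snvs, reads, seed=seed + 45 + k)
        pis.append(nucleotide_diversity(pileup, ann).pi_genome)
        r2s.append(mean_genome_r2(pairs))
    rho = stats.spearmanr(pis, r2s)
    return {"pi": pis, "mean_r2": r2s, "spearman_rho": float(rho.statistic)}


def anova_null_calibration(n_genes: int = 1000, n_per_site: int = 8,
                           seed: int = 0) -> dict:
    """Differential-presence ANOVA under the null: identical lognormal
    coverage distributions at the two sites."""
    from .pangenome import GeneCoverageMatrix
    rng = np.random.default_rng(seed)
    genes = [f"g{k}" for k in range(n_genes)]
    values = {f"A{k}": rng.lognormal(0, 0.3, n_genes)
              for k in range(n_per_site)}
    values |= {f"B{k}": rng.lognormal(0, 0.3, n_genes)
               for k in range(n_per_site)}
    vals = pd.DataFrame(values, index=genes)
    matrix = GeneCoverageMatrix(vals, vals > 3.0,
                                pd.Series({s: s[0] for s in values}))
    result = differential_gene_presence(matrix, alpha=0.001)
    tested = result[result["tested"]]
    return {
        "flagged_fraction": float(result["differential"].mean()),
        "ks_uniform_p": float(stats.kstest(tested["p"], "uniform").pvalue),
    }


def fst_outlier_null(length: int = 20000, n_genes: int = 20,
                     coverage: float = 50.0, n_seeds: int = 3,
                     seed: int = 0) -> dict:
    """Outlier Z test under the null: two read draws from one pool."""
    ann = simulate_reference(length, n_genes, 0.35, seed=seed)
    fractions = []
    for k in range(n_seeds):
        pool = simulate_strain_pool(ann, 20, 0.02, seed=seed + 7 + k)
        pa = build_pileup(simulate_sample_reads(
            pool, coverage, 0.0, seed=seed + 100 + 2 * k), ann, 0.0)
        pb = build_pileup(simulate_sample_reads(
            pool, coverage, 0.0, seed=seed + 101 + 2 * k), ann, 0.0)
        table = gene_fst_table(pa, pb, ann)
        result = fst_outlier_test(table.set_index("gene_id")["fst"])
        fractions.append(float(result["outlier"].mean()))
    return {"flagged_fractions": fractions,
            "mean_flagged": float(np.mean(fractions))}


def spikein_gene_recovery(n_core: int = 480, n_exclusive: int = 20,
                          coverage: float = 30.0, n_per_site: int = 8,
                          seed: int = 0) -> dict:
    """Recovery of deme-exclusive accessory genes from relative coverage:
    sensitivity over the spiked genes and false calls among core genes.

    Eight samples per site mirror the multi-timepoint series the
    differential-presence design assumes."""
    n_genes = n_core + n_exclusive
    length = n_genes * 260
    ann = simulate_reference(length, n_genes, 0.35, seed=seed,
                             min_gene_len=150, max_gene_len=300)
    dp = simulate_deme_pair(ann, 30, 0.1, 0.02, seed=seed + 1,
                            n_exclusive_a=n_exclusive // 2,
                            n_exclusive_b=n_exclusive - n_exclusive // 2)
    pileups, labels = {}, {}
    for site, pool in (("A", dp.pool_a), ("B", dp.pool_b)):
        for k in range(n_per_site):
            name = f"{site}{k}"
            reads = simulate_sample_reads(pool, coverage, 0.001,
                                          seed=seed + 50 + 10 * k +
                                          (0 if site == "A" else 5))
            pileups[name] = build_pileup(reads, ann, 0.0)
            labels[name] = site
    matrix = gene_coverage_matrix(pileups, ann, labels)
    diff = differential_gene_presence(matrix, alpha=0.001)
    classes = basin_specific_genes(matrix, diff)
    spiked = set(dp.exclusive_genes_a) | set(dp.exclusive_genes_b)
    called_specific = set(classes[classes != "shared"].index)
    true_calls = spiked & called_specific
    false_calls = called_specific - spiked
    return {
        "n_spiked": len(spiked),
        "sensitivity": len(true_calls) / len(spiked),
        "n_false_specific": len(false_calls),
    }


def responsive_snv_recovery(length: int = 20000, n_genes: int = 20,
                            n_responsive: int = 20, n_timepoints: int = 12,
                            coupling: float = 1.0, coverage: float = 50.0,
                            seed: int = 0) -> dict:
    """Recovery of temperature-responsive nonsynonymous alleles over a
    seasonal series: sensitivity and false-discovery proportion of the
    Spearman screen."""
    ann = simulate_reference(length, n_genes, 0.35, seed=seed)
    pool = simulate_strain_pool(ann, 20, 0.02, 300, seed=seed + 1)
    env = make_env_series(n_timepoints, seed=seed + 2)
    read_sets, truth = simulate_time_series(
        pool, env, n_responsive, coupling, seed=seed + 3, coverage=coverage)
    pileups = {env["sample_id"][t]: build_pileup(read_sets[t], ann, 0.0)
               for t in range(n_timepoints)}
    covariate = env.set_index("sample_id")["temperature_c"].astype(float)
    traj = snv_frequency_matrix(pileups, ann, covariate)
    corr = covariate_correlated_snvs(traj)
    responsive = set(int(p) for p in truth.responsive["position"])
    flagged = set(int(p) for p in corr[corr["correlated"]].index)
    hits = responsive & flagged
    return {
        "n_responsive": len(responsive),
        "n_flagged": len(flagged),
        "sensitivity": len(hits) / len(responsive) if responsive else np.nan,
        "false_discovery_proportion":
            len(flagged - responsive) / len(flagged) if flagged else 0.0,
    }


def temporal_null_calibration(n_snvs: int = 1000, n_timepoints: int = 12,
                              seed: int = 0) -> dict:
    """Spearman screen under a permuted-covariate null at the trajectory
    level."""
    from .temporal import TrajectoryMatrix
    rng = np.random.default_rng(seed)
    temps = rng.permutation(np.linspace(10, 30, n_timepoints))
    samples = [f"s{k}" for k in range(n_timepoints)]
    freqs = rng.uniform(0.2, 0.8, (n_snvs, n_timepoints))
    traj = TrajectoryMatrix(
        pd.DataFrame(freqs, index=pd.Index(range(n_snvs), name="position"),
                     columns=samples),
        pd.Series(temps, index=samples),
        pd.Series({p: "nonsynonymous" for p in range(n_snvs)}),
        pd.Series({p: "G" for p in range(n_snvs)}))
    corr = covariate_correlated_snvs(traj)
    tested = corr[corr["tested"]]
    return {
        "flagged_fraction": float(corr["correlated"].mean()),
        "ks_uniform_p": float(stats.kstest(tested["p"], "uniform").pvalue),
    }
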