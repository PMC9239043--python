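"""Pileup construction, SNV calling/classification, diversity, pN/pS, and
effective population size."""

import numpy as np
import pytest

from micropopgen.annotation import CODON_TO_AA, codon_site_counts, revcomp
from micropopgen.profiling import (build_pileup, call_snvs,
                                   diversity_profile,
                                   effective_population_size,
                                   neutral_third_position_pi,
                                   nucleotide_diversity, pnps,
                                   population_detection, site_pi)
from micropopgen.simulate import simulate_sample_reads, simulate_strain_pool

from conftest import make_pileup, make_read_pairs


class TestPileup:
    def test_empty_alignments_give_empty_pileup(self, tiny_annotation, reads):
        empty = make_read_pairs(tiny_annotation, [])
        empty.read_len = 10
        pileup = build_pileup(empty, tiny_annotation)
        assert pileup.coverage.sum() == 0
        assert pileup.breadth == 0.0

    def test_hand_counted_base_tallies(self, tiny_annotation):
        # three pairs whose first mates cover position 4 with A, A, C; the
        # far-away second mates keep the pair geometry valid
        ref = tiny_annotation.contig_seq
        pairs = [
            (0, 18, ref[0:10], ref[18:28]),
            (2, 18, ref[2:12], ref[18:28]),
            (4, 18, "C" + ref[5:14], ref[18:28]),
        ]
        pileup = build_pileup(make_read_pairs(tiny_annotation, pairs),
                              tiny_annotation, min_read_identity=0.9)
        assert pileup.counts[4, 0] == 2          # A from the first two mates
        assert pileup.counts[4, 1] == 1          # C from the third
        assert pileup.coverage[4] == 3

    def test_low_identity_mate_excluded(self, tiny_annotation):
        ref = tiny_annotation.contig_seq
        bad = "GGGG" + ref[4:10]                 # 60% identity
        pairs = [(0, 18, bad, ref[18:28])]
        pileup = build_pileup(make_read_pairs(tiny_annotation, pairs),
                              tiny_annotation, min_read_identity=0.94)
        assert pileup.counts[:10].sum() == 0     # mate 1 dropped entirely
        assert pileup.counts[18:28].sum() == 10  # mate 2 retained

    def test_overlapping_mates_counted_once(self, tiny_annotation):
        ref = tiny_annotation.contig_seq
        # mates overlap on [5, 10); the template must contribute once there
        pairs = [(0, 5, ref[0:10], ref[5:15])]
        pileup = build_pileup(make_read_pairs(tiny_annotation, pairs),
                              tiny_annotation)
        assert (pileup.coverage[0:15] == 1).all()

    def test_contig_mismatch_raises(self, tiny_annotation, reads):
        with pytest.raises(ValueError, match="contig"):
            build_pileup(reads, tiny_annotation)


class TestCallSnvs:
    def test_monomorphic_site_not_called(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {4: {"A": 100}})
        snvs = call_snvs(pileup, tiny_annotation)
        assert 4 not in set(snvs["position"])

    def test_thresholds_applied_by_hand(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {0: {"A": 90, "G": 10}})
        snvs = call_snvs(pileup, tiny_annotation)
        row = snvs[snvs["position"] == 0].iloc[0]
        assert row["freq_G"] == pytest.approx(0.10)
        assert row["snv_class"] == "intergenic"
        # frequencies over all four bases sum to one
        assert row[["freq_A", "freq_C", "freq_G", "freq_T"]].sum() == \
            pytest.approx(1.0)

    def test_below_min_coverage_masked(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {0: {"A": 2, "G": 2}})
        assert len(call_snvs(pileup, tiny_annotation)) == 0

    def test_rare_allele_fails_frequency_gate(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {0: {"A": 97, "G": 3}})
        assert 0 not in set(call_snvs(pileup, tiny_annotation)["position"])

    def test_invalid_threshold_rejected(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {})
        with pytest.raises(ValueError):
            call_snvs(pileup, tiny_annotation, min_allele_freq=0.5)

    def test_classification_forward_and_reverse_strand(self, tiny_annotation):
        # gene_fw codon 2 is GGG at positions 7-9; third position 9:
        # G->A is synonymous (GGA=Gly)
        pileup = make_pileup(tiny_annotation, {9: {"G": 60, "A": 40}})
        snvs = call_snvs(pileup, tiny_annotation)
        row = snvs[snvs["position"] == 9].iloc[0]
        assert row["snv_class"] == "synonymous"
        assert row["gene_id"] == "gene_fw"
        # first position 7: G->A gives AGG (Arg) != Gly: nonsynonymous
        pileup = make_pileup(tiny_annotation, {7: {"G": 60, "A": 40}})
        row = call_snvs(pileup, tiny_annotation).iloc[0]
        assert row["snv_class"] == "nonsynonymous"
        # reverse-strand gene: genomic position maps through the complement;
        # gene_rv codon 2 = CCC (Pro); its third position sits at genomic
        # start of the gene interval's G-run
        g = tiny_annotation.gene_by_id("gene_rv")
        # coding-strand offset 5 = third base of the CCC codon
        third_genomic = g.end - 1 - 5
        pileup = make_pileup(
            tiny_annotation, {third_genomic: {"G": 60, "A": 40}})
        row = call_snvs(pileup, tiny_annotation).iloc[0]
        # complement of A is T: CCT is still Pro -> synonymous
        assert row["snv_class"] == "synonymous"

    def test_class_partition_covers_all_snvs(self, snvs):
        counts = snvs["snv_class"].value_counts()
        assert counts.sum() == len(snvs)
        assert set(counts.index) <= {"synonymous", "nonsynonymous",
                                     "intergenic"}
        intergenic = snvs["gene_id"].isna()
        assert (snvs.loc[intergenic, "snv_class"] == "intergenic").all()
        assert (snvs.loc[~intergenic, "snv_class"] != "intergenic").all()


class TestDiversity:
    def test_site_pi_hand_values(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {
            0: {"A": 50, "C": 50},
            1: {"A": 25, "C": 25, "G": 25, "T": 25},
        })
        pi = site_pi(pileup)
        assert pi[0] == pytest.approx(0.5)
        assert pi[1] == pytest.approx(0.75)
        assert pi[2] == pytest.approx(0.0)

    def test_low_coverage_sites_excluded_from_mean(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {0: {"A": 2, "C": 2}})
        prof = nucleotide_diversity(pileup, tiny_annotation)
        assert np.isnan(prof.pi_site[0])
        # the masked site contributes to neither numerator nor denominator
        assert prof.pi_genome == pytest.approx(0.0)

    def test_no_eligible_sites_reported_missing(self, tiny_annotation):
        pileup = make_pileup(
            tiny_annotation,
            {p: {"A": 1} for p in range(tiny_annotation.length)})
        prof = nucleotide_diversity(pileup, tiny_annotation)
        assert prof.pi_genome is None

    def test_pi_recovery_on_simulated_reads(self, annotation):
        pool = simulate_strain_pool(annotation, 20, 0.02, seed=21)
        reads = simulate_sample_reads(pool, 50, 0.0, seed=22)
        pileup = build_pileup(reads, annotation)
        prof = nucleotide_diversity(pileup, annotation)
        assert abs(prof.pi_genome - pool.expected_pi) / pool.expected_pi < 0.10


class TestPnps:
    def test_ggg_codon_site_partition(self):
        # enumerating the 9 single-base changes of GGG: the three
        # third-position changes are synonymous (all glycine), the six
        # first/second-position changes are not
        s, n = codon_site_counts("GGG")
        assert s == pytest.approx(1.0)
        assert n == pytest.approx(2.0)

    def test_site_counts_match_exhaustive_enumeration(self, annotation,
                                                      pileup):
        # independent oracle: per-codon enumeration of all 9 substitutions
        # through the translation table
        cons = pileup.consensus_codes(annotation.codes)
        for gene in annotation.genes[:5]:
            cds = annotation.coding_sequence(gene, cons)
            syn = nonsyn = 0.0
            for k in range(len(cds) // 3):
                codon = cds[3 * k: 3 * k + 3]
                for p in range(3):
                    for b in "ACGT":
                        if b == codon[p]:
                            continue
                        mutant = codon[:p] + b + codon[p + 1:]
                        if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
                            syn += 1 / 3
                        else:
                            nonsyn += 1 / 3
            s_pkg = sum(codon_site_counts(cds[3 * k: 3 * k + 3])[0]
                        for k in range(len(cds) // 3))
            assert s_pkg == pytest.approx(syn)
            assert len(cds) - s_pkg == pytest.approx(nonsyn)

    def test_only_synonymous_snvs_give_zero(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {9: {"G": 60, "A": 40}})
        snvs = call_snvs(pileup, tiny_annotation)
        per_gene, _ = pnps(snvs, tiny_annotation, pileup)
        assert per_gene["gene_fw"] == pytest.approx(0.0)

    def test_genome_value_is_unweighted_mean(self, tiny_annotation):
        # build SNVs giving different defined ratios in the two genes, then
        # check the genome-wide figure is their arithmetic mean
        pileup = make_pileup(tiny_annotation, {
            9: {"G": 60, "A": 40},    # gene_fw synonymous
            7: {"G": 60, "A": 40},    # gene_fw nonsynonymous
            23: {"G": 60, "A": 40},   # gene_rv CCC->CCT synonymous
            24: {"G": 60, "T": 40},   # gene_rv CCC->CAC nonsynonymous
        })
        snvs = call_snvs(pileup, tiny_annotation)
        per_gene, genome = pnps(snvs, tiny_annotation, pileup)
        defined = per_gene.dropna()
        assert len(defined) == 2
        assert genome == pytest.approx(defined.mean())

    def test_gene_without_synonymous_snv_undefined(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {7: {"G": 60, "A": 40}})
        snvs = call_snvs(pileup, tiny_annotation)
        per_gene, genome = pnps(snvs, tiny_annotation, pileup)
        assert np.isnan(per_gene["gene_fw"])


class TestDetectionAndNeutralPi:
    def test_detection_gate_is_strict(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {})   # uniform 100x
        assert population_detection(pileup, 5, 0.5)
        assert not population_detection(pileup, 100, 0.5)   # strict >
        empty = make_pileup(
            tiny_annotation,
            {p: {} for p in range(tiny_annotation.length)})
        assert not population_detection(empty, 5, 0.5)

    def test_breadth_failure_blocks_detection(self, tiny_annotation):
        L = tiny_annotation.length
        overrides = {p: {} for p in range(L // 2, L)}
        pileup = make_pileup(tiny_annotation, overrides)
        assert pileup.mean_coverage > 10
        assert not population_detection(pileup, 10, 0.8)

    def test_neutral_pi_counts_fourfold_sites(self, annotation):
        pool = simulate_strain_pool(annotation, 1, 0.0, seed=1)
        reads = simulate_sample_reads(pool, 30, 0.0, seed=2)
        pileup = build_pileup(reads, annotation)
        value, n = neutral_third_position_pi(pileup, annotation)
        expected = annotation.third_codon_positions(fourfold_only=True)
        covered = (pileup.coverage[expected] >= 5).sum()
        assert n == covered
        assert value == pytest.approx(0.0)

    def test_single_polymorphic_fourfold_site(self, tiny_annotation):
        # gene_fw GGG third position (9) is 4-fold; make it 50/50
        pileup = make_pileup(tiny_annotation, {9: {"G": 50, "A": 50}})
        value, n = neutral_third_position_pi(pileup, tiny_annotation)
        assert n > 0
        assert value == pytest.approx(0.5 / n)


class TestEffectivePopulationSize:
    def test_printed_field_estimate(self):
        ne = effective_population_size(0.284, 1e-10)
        assert ne == pytest.approx(2.3e9, rel=0.05)

    def test_arithmetic_example(self):
        assert effective_population_size(0.1, 1e-9) == \
            pytest.approx(0.15 / (1e-9 * 2.6))

    def test_zero_diversity_zero_ne(self):
        assert effective_population_size(0.0) == 0.0

    def test_monotone_in_diversity(self):
        grid = np.linspace(0.001, 0.74, 50)
        values = [effective_population_size(p) for p in grid]
        assert np.all(np.diff(values) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            effective_population_size(0.75)
        with pytest.raises(ValueError):
            effective_population_size(0.1, mu=0)
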