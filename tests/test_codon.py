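"""Codon counting against enumeration oracles and the simulator's books."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from fastz import (
    CodonAlignment,
    SimTruth,
    count_polymorphism_divergence,
    count_sites,
    emit_alignments,
    pairwise_diversity,
    pool_counts,
    simulate_counts,
)


def syn_sites_oracle(codon: str) -> float:
    """Independent Nei-Gojobori site count via biopython translation."""
    aa = str(Seq(codon).translate())
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1 :]
            new_aa = str(Seq(new).translate())
            if new_aa == aa and new_aa != "*":
                syn += 1
    return syn / 3.0


def make_aln(ingroup, outgroup, gene_id="g"):
    return CodonAlignment(gene_id=gene_id, ingroup_seqs=list(ingroup), outgroup_seq=outgroup)


class TestCountSites:
    @pytest.mark.parametrize("codon", ["TTT", "ATG", "TGG", "CTG", "CGA", "GGG", "ATA"])
    def test_single_codon_matches_enumeration(self, codon):
        aln = make_aln([codon] * 4, codon)
        L_n, L_s, used = count_sites(aln)
        expected_s = syn_sites_oracle(codon)
        assert L_s == pytest.approx(expected_s)
        assert L_n == pytest.approx(3.0 - expected_s)
        assert used == 1

    def test_phenylalanine_third_position(self):
        # TTT: only T->C at position 3 is synonymous among the 9 changes
        aln = make_aln(["TTT"] * 4, "TTT")
        L_n, L_s, _ = count_sites(aln)
        assert L_s == pytest.approx(1.0 / 3.0)
        assert L_n == pytest.approx(8.0 / 3.0)

    @pytest.mark.parametrize("bad", ["TNT", "T-T"])
    def test_ambiguous_codon_excluded(self, bad):
        aln = make_aln(["TTT", "TTT", bad, "TTT"], "TTT")
        L_n, L_s, used = count_sites(aln)
        assert (L_n, L_s, used) == (0.0, 0.0, 0)

    def test_stop_in_any_sequence_excludes_codon(self):
        aln = make_aln(["TTTTGA"] * 4, "TTTGGA")  # second codon TGA = stop
        _, _, used = count_sites(aln)
        assert used == 1


class TestPolymorphismDivergence:
    def test_single_nonsynonymous_fixed_difference(self):
        # ingroup Met (ATG), outgroup Ile (ATA): amino acid changes
        counts = count_polymorphism_divergence(make_aln(["ATG", "ATG"], "ATA"), min_ingroup=2)
        assert counts.D_n == 1 and counts.D_s == 0
        assert counts.P_n == counts.P_s == 0

    def test_single_synonymous_snp_with_sfs_placement(self):
        # GGT/GGC both Gly; derived allele (C) in 1 of 4 haplotypes
        aln = make_aln(["GGT", "GGT", "GGT", "GGC"], "GGT")
        counts = count_polymorphism_divergence(aln)
        assert counts.P_s == 1 and counts.P_n == 0
        assert counts.sfs_s[0] == 1 and counts.sfs_s[1:].sum() == 0

    def test_identical_sequences_give_zero_everything(self):
        aln = make_aln(["ATGGCT"] * 5, "ATGGCT")
        counts = count_polymorphism_divergence(aln)
        assert counts.P_n == counts.P_s == counts.D_n == counts.D_s == 0

    def test_site_both_polymorphic_and_divergent_counts_polymorphism_only(self):
        # ingroup segregates T/C; outgroup carries a third state G
        aln = make_aln(["GGT", "GGT", "GGC", "GGT"], "GGG")
        counts = count_polymorphism_divergence(aln)
        assert counts.P_s == 1
        assert counts.D_s == 0 and counts.D_n == 0
        assert counts.n_unpolarized == 1  # outgroup does not match either allele

    def test_too_few_ingroup_sequences_rejected(self):
        with pytest.raises(ValueError, match="min_ingroup"):
            count_polymorphism_divergence(make_aln(["ATG"] * 3, "ATG"))

    def test_multi_position_codon_divergence_uses_pathway_average(self):
        # TTT (Phe) vs outgroup TTA at pos 3 and CTT at pos 1 -> CTA
        # paths: TTT->CTT(Leu,nonsyn)->CTA(syn) or TTT->TTA(Leu,nonsyn)->CTA(syn)
        counts = count_polymorphism_divergence(make_aln(["TTT"] * 4, "CTA"))
        assert counts.D_n + counts.D_s == pytest.approx(2.0)
        assert counts.D_n == pytest.approx(1.0)
        assert counts.D_s == pytest.approx(1.0)


class TestPairwiseDiversity:
    def test_one_pair_one_synonymous_difference(self):
        # two sequences, one synonymous difference across 34 usable codons
        base = "GGT" * 34
        other = "GGC" + "GGT" * 33
        aln = make_aln([base, other], base)
        pi_n, pi_s = pairwise_diversity(aln)
        L_s = count_sites(aln)[1]
        assert pi_s == pytest.approx(1.0 / L_s)
        assert pi_n == 0.0

    def test_matches_bruteforce_pair_average_on_simulated_genes(self):
        truth = SimTruth(n_genes=4, seed=31, mean_codons=200, n_alleles=8)
        genes = simulate_counts(truth)
        alns = emit_alignments(genes, truth)
        for gene_id, aln in alns.items():
            pi_n, pi_s = pairwise_diversity(aln)
            L_n, L_s, _ = count_sites(aln)
            n = aln.n_ingroup
            diffs_s = diffs_n = 0.0
            n_pairs = 0
            counted = count_polymorphism_divergence(aln, min_ingroup=2)
            for a in range(n):
                for b in range(a + 1, n):
                    n_pairs += 1
                    for j in range(aln.length // 3):
                        ca = aln.ingroup_seqs[a][3 * j : 3 * j + 3]
                        cb = aln.ingroup_seqs[b][3 * j : 3 * j + 3]
                        for pos in range(3):
                            if ca[pos] != cb[pos]:
                                aa_a = str(Seq(ca).translate())
                                aa_b = str(Seq(cb).translate())
                                if aa_a == aa_b:
                                    diffs_s += 1
                                else:
                                    diffs_n += 1
            assert pi_s == pytest.approx(diffs_s / n_pairs / L_s)
            assert pi_n == pytest.approx(diffs_n / n_pairs / L_n)


class TestRoundTrip:
    def test_counting_reproduces_simulator_bookkeeping_exactly(self):
        truth = SimTruth(n_genes=12, seed=41)
        genes = simulate_counts(truth)
        alns = emit_alignments(genes, truth)
        for g in genes:
            c = count_polymorphism_divergence(alns[g.gene_id])
            assert np.array_equal(c.sfs_s, g.sfs_s), g.gene_id
            assert np.array_equal(c.sfs_n, g.sfs_n), g.gene_id
            assert c.D_s == g.D_s and c.D_n == g.D_n

    def test_zero_variation_gene_emits_identical_sequences(self):
        truth = SimTruth(n_genes=1, theta_s=1e-9, div_s=1e-9, seed=42)
        genes = simulate_counts(truth)
        aln = emit_alignments(genes, truth)[genes[0].gene_id]
        assert len(set(aln.ingroup_seqs + [aln.outgroup_seq])) == 1

    def test_emitted_alignment_structure(self):
        truth = SimTruth(n_genes=3, seed=43)
        genes = simulate_counts(truth)
        for aln in emit_alignments(genes, truth).values():
            assert aln.length % 3 == 0
            assert aln.n_ingroup == truth.n_alleles
            # no in-frame stop anywhere (construction avoids them entirely)
            for s in aln.ingroup_seqs + [aln.outgroup_seq]:
                codons = {s[3 * j : 3 * j + 3] for j in range(len(s) // 3)}
                assert codons.isdisjoint({"TAA", "TAG", "TGA"})


class TestPooling:
    def test_doubling_preserves_ratios(self, default_genes):
        from fastz import genes_to_counts

        counts = genes_to_counts(default_genes[:5])
        one = pool_counts(counts)
        two = pool_counts(counts + counts)
        assert two.P_s == 2 * one.P_s
        assert two.dN / two.dS == pytest.approx(one.dN / one.dS)

    def test_mixed_sample_sizes_rejected(self, default_genes):
        from fastz import genes_to_counts
        from dataclasses import replace

        counts = genes_to_counts(default_genes[:2])
        other = replace(
            counts[1], n_alleles=10, sfs_s=np.zeros(9), sfs_n=np.zeros(9)
        )
        with pytest.raises(ValueError, match="n_alleles"):
            pool_counts([counts[0], other])

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_counts([])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_seqs=st.integers(4, 8),
    n_codons=st.integers(1, 12),
    data=st.data(),
)
def test_conservation_and_sfs_consistency_on_arbitrary_alignments(
    n_seqs, n_codons, data
):
    """L_n + L_s = 3 x codons_used and sum(sfs) = P for any input."""
    alphabet = "ACGTN-"
    seqs = [
        "".join(data.draw(st.sampled_from(alphabet)) for _ in range(3 * n_codons))
        for _ in range(n_seqs + 1)
    ]
    aln = CodonAlignment(gene_id="h", ingroup_seqs=seqs[:-1], outgroup_seq=seqs[-1])
    counts = count_polymorphism_divergence(aln)
    assert counts.L_n + counts.L_s == pytest.approx(3.0 * counts.codons_used)
    assert counts.P_s == counts.sfs_s.sum()
    assert counts.P_n == counts.sfs_n.sum()
    assert min(counts.P_n, counts.P_s, counts.D_n, counts.D_s) >= 0
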