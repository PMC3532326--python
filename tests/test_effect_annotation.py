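"""SO classification, joint same-codon SNV evaluation, Grantham grading."""

import itertools
import random

import pytest

from jointvar.effects import (CONSERVATIVE_MISSENSE, FRAMESHIFT, INFRAME,
                              NON_CONSERVATIVE_MISSENSE, SILENT, SPLICE_ACCEPTOR,
                              SPLICE_DONOR, STOP_GAINED, STOP_LOST, SYNONYMOUS,
                              classify_indel, classify_snv, collect_multi_category,
                              default_grantham_matrix, grantham_classify,
                              missense_category, variant_codon)
from jointvar.genome import translate
from jointvar.ingest import DELETION, INSERTION, SNV, ComponentVariant

from conftest import make_locus, random_disjoint_variants, random_locus

AA20 = "ARNDCQEGHILKMFPSTWYV"


class TestGrantham:
    def test_leu_ser_is_moderately_radical(self):
        g = grantham_classify("L", "S")
        assert (g.score, g.label) == (145, "MODERATELY_RADICAL")
        assert missense_category(g) == NON_CONSERVATIVE_MISSENSE

    def test_ile_val_is_conservative(self):
        g = grantham_classify("I", "V")
        assert (g.score, g.label) == (29, "CONSERVATIVE")
        assert missense_category(g) == CONSERVATIVE_MISSENSE

    def test_identical_residues_rejected(self):
        with pytest.raises(ValueError):
            grantham_classify("L", "L")

    def test_stop_rejected(self):
        with pytest.raises(ValueError):
            grantham_classify("L", "*")

    def test_symmetric_over_all_190_pairs(self):
        for a, b in itertools.combinations(AA20, 2):
            assert grantham_classify(a, b) == grantham_classify(b, a)

    def test_class_is_monotone_in_score(self):
        order = ["CONSERVATIVE", "MODERATELY_CONSERVATIVE",
                 "MODERATELY_RADICAL", "RADICAL"]
        matrix = default_grantham_matrix()
        for a, b in itertools.combinations(AA20, 2):
            g = grantham_classify(a, b)
            bounds = {0: (0, 50), 1: (51, 100), 2: (101, 150), 3: (151, 10**6)}
            lo, hi = bounds[order.index(g.label)]
            assert lo <= g.score <= hi


def snv_at(genome, chrom, pos, coding_alt, strand="+"):
    from jointvar.genome import complement
    ref = genome.base(chrom, pos)
    alt = coding_alt if strand == "+" else complement(coding_alt)
    return ComponentVariant(SNV, chrom, pos, ref, alt)


class TestVariantCodon:
    # CDS: ATG CTG TGC TAA at 11-22 (codon 1 is CTG)
    def _locus(self):
        return make_locus("A" * 10 + "ATGCTGTGCTAA" + "C" * 10, [(11, 22)])

    def test_all_cooccurring_snvs_applied_jointly(self):
        genome, t = self._locus()
        s1 = snv_at(genome, "chr1", 14, "T")  # C->T at codon position 1
        s2 = snv_at(genome, "chr1", 15, "C")  # T->C at codon position 2
        assert variant_codon(t, genome, 1, [s1, s2]) == ("CTG", "TCG")

    def test_single_snv(self):
        genome, t = self._locus()
        s1 = snv_at(genome, "chr1", 14, "T")
        assert variant_codon(t, genome, 1, [s1]) == ("CTG", "TTG")

    def test_no_snvs_identity(self):
        genome, t = self._locus()
        assert variant_codon(t, genome, 1, []) == ("CTG", "CTG")

    def test_minus_strand_complements_substitutions(self):
        # coding CTG at codon 1 of a minus-strand gene
        cds = "ATGCTGTGCTAA"
        from jointvar.genome import revcomp
        genome, t = make_locus("A" * 10 + revcomp(cds) + "C" * 10, [(11, 22)], strand="-")
        # coding offset 3 (codon 1 pos 0) is genomic position 22 - 3 = 19
        s = snv_at(genome, "chr1", 19, "T", strand="-")
        assert variant_codon(t, genome, 1, [s]) == ("CTG", "TTG")


class TestClassifySnv:
    def test_joint_codon_turns_synonymous_into_missense(self):
        genome, t = make_locus("A" * 10 + "ATGCTGTGCTAA" + "C" * 10, [(11, 22)])
        s1 = snv_at(genome, "chr1", 14, "T")
        s2 = snv_at(genome, "chr1", 15, "C")
        alone = classify_snv(s1, t, genome, cooccurring_snvs=[])
        joint = classify_snv(s1, t, genome, cooccurring_snvs=[s1, s2])
        assert alone.category == SYNONYMOUS and alone.var_codon == "TTG"
        assert joint.category == NON_CONSERVATIVE_MISSENSE
        assert (joint.ref_codon, joint.var_codon) == ("CTG", "TCG")
        assert (joint.ref_aa, joint.var_aa) == ("L", "S")
        assert joint.grantham.score == 145

    def test_synonymous_third_position(self):
        genome, t = make_locus("A" * 10 + "ATGCTTTGCTAA" + "C" * 10, [(11, 22)])
        s = snv_at(genome, "chr1", 16, "C")  # CTT -> CTC, Leu
        ann = classify_snv(s, t, genome)
        assert ann.category == SYNONYMOUS

    def test_stop_gained_and_lost(self):
        genome, t = make_locus("A" * 10 + "ATGTACTGCTAA" + "C" * 10, [(11, 22)])
        gained = classify_snv(snv_at(genome, "chr1", 16, "A"), t, genome)  # TAC->TAA
        assert gained.category == STOP_GAINED
        lost = classify_snv(snv_at(genome, "chr1", 22, "T"), t, genome)  # TAA->TAT
        assert lost.category == STOP_LOST
        assert (lost.ref_codon, lost.var_codon) == ("TAA", "TAT")

    def test_splice_donor_hit(self):
        genome, t = make_locus("ATGCCC" + "GT" + "A" * 10 + "AG" + "TGCTAA" + "C" * 5,
                               [(1, 6), (21, 26)])
        donor = ComponentVariant(SNV, "chr1", 7, "G", "A")
        acceptor = ComponentVariant(SNV, "chr1", 20, "G", "C")
        assert classify_snv(donor, t, genome).category == SPLICE_DONOR
        assert classify_snv(acceptor, t, genome).category == SPLICE_ACCEPTOR

    def test_in_window_but_noncoding_is_silent(self):
        genome, t = make_locus("ATGCCC" + "GTAAAAAAAAAG" + "TGCTAA" + "C" * 5,
                               [(1, 6), (19, 24)])
        intronic = ComponentVariant(SNV, "chr1", 12, genome.base("chr1", 12), "C")
        assert classify_snv(intronic, t, genome).category == SILENT

    def test_reference_mismatch_skipped(self):
        genome, t = make_locus("A" * 10 + "ATGCTGTGCTAA" + "C" * 10, [(11, 22)])
        bad = ComponentVariant(SNV, "chr1", 14, "G", "T")  # genome has C
        assert classify_snv(bad, t, genome) is None

    def test_translation_consistency_on_random_loci(self):
        rng = random.Random(21)
        checked = 0
        for _ in range(80):
            genome, t = random_locus(rng)
            for v in random_disjoint_variants(rng, genome, t, n=3):
                if v.kind != SNV:
                    continue
                ann = classify_snv(v, t, genome)
                if ann is not None and ann.ref_codon:
                    assert translate(ann.ref_codon) == ann.ref_aa
                    assert translate(ann.var_codon) == ann.var_aa
                    checked += 1
        assert checked > 20


class TestClassifyIndel:
    def _locus(self):
        return make_locus("A" * 10 + "ATGCTGTGCGGGTAA" + "C" * 10, [(11, 25)])

    def test_inframe_insertion(self):
        genome, t = self._locus()
        ins = ComponentVariant(INSERTION, "chr1", 15, "", "GCTGCCGCCTCCAAAGCC")
        ann = classify_indel(ins, t, genome)
        assert ann.category == INFRAME and ann.coding_length_delta == 18

    def test_frameshift_single_base_insertion(self):
        genome, t = self._locus()
        ins = ComponentVariant(INSERTION, "chr1", 15, "", "G")
        assert classify_indel(ins, t, genome).category == FRAMESHIFT

    def test_boundary_insertion_before_exon_is_silent(self):
        genome, t = make_locus("ATGCCC" + "GT" + "A" * 10 + "AG" + "TGCTAA" + "C" * 5,
                               [(1, 6), (21, 26)])
        before = ComponentVariant(INSERTION, "chr1", 20, "", "C")  # last intron base
        after = ComponentVariant(INSERTION, "chr1", 6, "", "C")    # last exon base
        assert classify_indel(before, t, genome).category == SILENT
        assert classify_indel(after, t, genome).category == SILENT

    def test_deletion_overlapping_splice_window_is_splice(self):
        genome, t = make_locus("ATGCCC" + "GT" + "A" * 10 + "AG" + "TGCTAA" + "C" * 5,
                               [(1, 6), (21, 26)])
        d = ComponentVariant(DELETION, "chr1", 6, genome.fetch("chr1", 6, 8), "")
        assert classify_indel(d, t, genome).category == SPLICE_DONOR

    def test_multiple_of_three_never_frameshift(self):
        rng = random.Random(22)
        for _ in range(50):
            genome, t = random_locus(rng, n_exons=1)
            while t.cds_length < 12:
                genome, t = random_locus(rng, n_exons=1)
            length = 3 * rng.randint(1, 3)
            pos = rng.randint(t.start, t.end - length)
            d = ComponentVariant(DELETION, t.chrom, pos,
                                 genome.fetch(t.chrom, pos, pos + length - 1), "")
            ann = classify_indel(d, t, genome)
            assert ann.category in (INFRAME, SPLICE_DONOR, SPLICE_ACCEPTOR)


class TestMultiCategory:
    def test_differing_categories_listed_once(self):
        genome, t1 = make_locus("A" * 10 + "ATGCTGTGCTAA" + "C" * 10, [(11, 22)],
                                tid="t1")
        _, t2 = make_locus(genome.sequences["chr1"], [(12, 20)], tid="t2")
        s = snv_at(genome, "chr1", 16, "C")  # CTG->CTC synonymous in t1
        a1 = classify_snv(s, t1, genome)
        a2 = classify_snv(s, t2, genome)
        assert a1.category != a2.category  # frames differ between the two models
        listed = collect_multi_category([a1, a2])
        assert len(listed) == 1 and listed[0][0] == s

    def test_agreeing_or_single_not_listed(self):
        genome, t = make_locus("A" * 10 + "ATGCTTTGCTAA" + "C" * 10, [(11, 22)])
        ann = classify_snv(snv_at(genome, "chr1", 16, "C"), t, genome)
        assert collect_multi_category([ann]) == []
        twin = type(ann)(ann.variant, "t2", ann.category, ann.ref_codon,
                         ann.var_codon, ann.ref_aa, ann.var_aa, ann.grantham)
        assert collect_multi_category([ann, twin]) == []
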