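"""Joint variant application, ORF status, internal stops, exon alignments."""

import random

import pytest

from jointvar.fixtures import CG_CODONS, NON_STOP_CODONS, build_locus
from jointvar.genome import spliced_cds, translate
from jointvar.ingest import DELETION, INSERTION, SNV, ComponentVariant
from jointvar.reconstruct import (FULLY_DELETED, ORF_DISRUPTED, ORF_INTACT,
                                  ORF_PRESERVED, apply_variants, exon_alignment,
                                  first_internal_stop_percentage, orf_status)

from conftest import (chromosome_edit_cds_oracle, make_locus,
                      random_disjoint_variants, random_locus)


class TestApplyVariants:
    def test_no_variants_is_intact(self):
        genome, t = make_locus("A" * 10 + "ATGCTGTGCTAA" + "C" * 10, [(11, 22)])
        vt = apply_variants(t, genome, [])
        assert vt.orf_status == ORF_INTACT
        assert vt.var_cds == spliced_cds(t, genome)

    def test_paired_indels_preserve_orf(self):
        # insertion at 15, deletion at 19: the frames cancel within C/G codons
        genome, t = make_locus("A" * 10 + "ATGCCCGGCCGGTAA" + "C" * 10, [(11, 25)])
        ins = ComponentVariant(INSERTION, "chr1", 15, "", "C")
        dele = ComponentVariant(DELETION, "chr1", 19, genome.base("chr1", 19), "")
        vt = apply_variants(t, genome, [ins, dele])
        assert vt.orf_status == ORF_PRESERVED
        assert len(vt.var_cds) == t.cds_length

    def test_whole_span_deletion_is_fully_deleted(self):
        genome, t = make_locus("A" * 10 + "ATGCTGTGCTAA" + "C" * 10, [(11, 22)])
        d = ComponentVariant(DELETION, "chr1", 9, genome.fetch("chr1", 9, 24), "")
        vt = apply_variants(t, genome, [d])
        assert vt.orf_status == FULLY_DELETED
        assert vt.var_cds == "" and vt.var_protein == ""

    def test_matches_whole_chromosome_edit_oracle(self):
        rng = random.Random(31)
        for _ in range(200):
            genome, t = random_locus(rng)
            variants = random_disjoint_variants(rng, genome, t)
            vt = apply_variants(t, genome, variants)
            expected = chromosome_edit_cds_oracle(genome, t, variants)
            if vt.orf_status != FULLY_DELETED:
                assert vt.var_cds == expected


class TestOrfStatus:
    def test_frameshift_without_new_stop_is_preserved(self):
        assert first_internal_stop_percentage("MAKLV*", "MAKVRT") is None

    def test_reference_internal_stop_disables_stop_criterion(self):
        ref = "MA*KLV*"  # reference model already truncated
        var = "MV*TTT*"
        assert first_internal_stop_percentage(ref, var) is None

        class Ann:
            category = "frameshift_variant"

        assert orf_status(ref, var, [Ann()]) == ORF_PRESERVED

    def test_splice_annotation_forces_disruption(self):
        class Ann:
            category = "splice_donor_variant"

        assert orf_status("MAK*", "MAK*", [Ann()]) == ORF_DISRUPTED

    def test_new_internal_stop_disrupts(self):
        class Ann:
            category = "frameshift_variant"

        assert orf_status("MAKLVTTTT*", "MA*KLVTTT*", [Ann()]) == ORF_DISRUPTED

    def test_untouched_transcript_intact(self):
        assert orf_status("MAK*", "MAK*", []) == ORF_INTACT

    def test_stop_at_final_codon_is_not_internal(self):
        assert first_internal_stop_percentage("MAKLVTTTT*", "MAKLVTTTT*") is None


class TestFirstInternalStopPercentage:
    def test_formula(self):
        assert first_internal_stop_percentage("M" * 9 + "*", "MA*KLVTTT*") == 30.0

    def test_none_without_stop(self):
        assert first_internal_stop_percentage("MAKLV*", "MAKLVT") is None

    def test_seventy_percent_boundary(self):
        var = "M" * 6 + "*" + "M" * 3
        assert first_internal_stop_percentage("M" * 10, var) == 70.0


class TestExonAlignment:
    def test_snv_marked_uppercase_in_both_rows(self):
        genome, t = make_locus("ACGTCC", [(1, 4)])
        snv = ComponentVariant(SNV, "chr1", 2, "C", "G")
        (aln,) = exon_alignment(t, genome, [snv])
        assert (aln.ref_seq, aln.var_seq) == ("aCgt", "aGgt")

    def test_deletion_gapped_in_variant_row(self):
        genome, t = make_locus("ACGTCC", [(1, 4)])
        d = ComponentVariant(DELETION, "chr1", 2, "CG", "")
        (aln,) = exon_alignment(t, genome, [d])
        assert (aln.ref_seq, aln.var_seq) == ("aCGt", "a--t")

    def test_insertion_gapped_in_reference_row(self):
        genome, t = make_locus("ACGTCC", [(1, 4)])
        ins = ComponentVariant(INSERTION, "chr1", 2, "", "AA")
        (aln,) = exon_alignment(t, genome, [ins])
        assert (aln.ref_seq, aln.var_seq) == ("ac--gt", "acAAgt")

    def test_stripping_gaps_and_case_restores_sequences(self):
        rng = random.Random(32)
        for _ in range(100):
            genome, t = random_locus(rng)
            variants = random_disjoint_variants(rng, genome, t)
            vt = apply_variants(t, genome, variants)
            rebuilt = []
            for aln, exon in zip(vt.exon_alignments, t.exons):
                ref = aln.ref_seq.replace("-", "").upper()
                assert ref == genome.fetch(t.chrom, exon.start, exon.end)
                rebuilt.append(aln.var_seq.replace("-", "").upper())
            var_cds = "".join(rebuilt)
            if t.strand == "-":
                from jointvar.genome import revcomp
                var_cds = revcomp(var_cds)
            if vt.orf_status != FULLY_DELETED:
                assert var_cds == vt.var_cds


class TestFrameRestorationProperty:
    def _restoring_pair(self, rng):
        """Random transcript with two indels whose length deltas cancel mod 3
        inside a stop-free C/G-only stretch."""
        pre = rng.randint(2, 5)
        post = rng.randint(2, 5)
        codons = (["ATG"] + [rng.choice(NON_STOP_CODONS) for _ in range(pre)]
                  + [rng.choice(CG_CODONS) for _ in range(10)]
                  + [rng.choice(NON_STOP_CODONS) for _ in range(post)] + ["TAA"])
        strand = rng.choice("+-")
        seq, t = build_locus(rng, "t1", strand, ["".join(codons)])
        from jointvar.genome import ReferenceGenome, cds_offset_to_genomic, complement, revcomp
        genome = ReferenceGenome({"chr1": seq})
        region0 = 3 * (1 + pre)
        ins_len = rng.randint(1, 4)
        del_len = ins_len % 3 or 3
        ins_gap = region0 + 2
        del_off = ins_gap + rng.randint(3, 6)
        coding_ins = "".join(rng.choice("CG") for _ in range(ins_len))
        if strand == "+":
            anchor = cds_offset_to_genomic(t, ins_gap)
            fwd_ins = coding_ins
        else:
            anchor = cds_offset_to_genomic(t, ins_gap + 1)
            fwd_ins = revcomp(coding_ins)
        ins = ComponentVariant(INSERTION, "chr1", anchor, "", fwd_ins)
        del_positions = sorted(cds_offset_to_genomic(t, del_off + i) for i in range(del_len))
        del_start = del_positions[0]
        ref = genome.fetch("chr1", del_start, del_start + del_len - 1)
        dele = ComponentVariant(DELETION, "chr1", del_start, ref, "")
        return genome, t, ins, dele

    def test_cancelling_indels_preserve_orf(self):
        rng = random.Random(33)
        for _ in range(100):
            genome, t, ins, dele = self._restoring_pair(rng)
            assert (len(ins.alt_seq) - len(dele.ref_seq)) % 3 == 0
            vt = apply_variants(t, genome, sorted([ins, dele], key=lambda v: v.pos))
            assert vt.orf_status == ORF_PRESERVED, (t.strand, ins, dele, vt.var_protein)

    def test_single_frameshift_with_planted_stop_disrupts(self):
        rng = random.Random(34)
        for _ in range(30):
            n_middle = rng.randint(10, 18)
            codons = ["ATG"] + [rng.choice(NON_STOP_CODONS) for _ in range(n_middle)] + ["TAA"]
            k = rng.randint(2, n_middle - 2)
            codons[k], codons[k + 1] = "ATA", "AGC"
            strand = rng.choice("+-")
            seq, t = build_locus(rng, "t1", strand, ["".join(codons)])
            from jointvar.genome import ReferenceGenome, cds_offset_to_genomic
            genome = ReferenceGenome({"chr1": seq})
            pos = cds_offset_to_genomic(t, 3 * k)
            d = ComponentVariant(DELETION, "chr1", pos, genome.base("chr1", pos), "")
            vt = apply_variants(t, genome, [d])
            assert vt.orf_status == ORF_DISRUPTED
            assert vt.first_internal_stop_pct == pytest.approx(100.0 * (k + 1) / len(codons))
            assert vt.first_internal_stop_pct < 100
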