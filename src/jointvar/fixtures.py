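"""Deterministic synthetic fixtures with known joint-effect truth.

Each scenario builds a small genome, one or two transcript models and a
set of variants whose per-variant Sequence Ontology category and
per-transcript ORF status are known *by construction* (not by running the
annotator).  Scenarios encode the phenomena the annotator exists for:
frame restoration by paired indels, jointly-missense same-codon SNVs,
splice-overlap false positives of compound alleles, boundary insertions,
and compound-allele decomposition.

The same seed always reproduces identical files and truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from . import genome as gm
from .effects import (FRAMESHIFT, INFRAME, NON_CONSERVATIVE_MISSENSE, SILENT,
                      SPLICE_DONOR, SYNONYMOUS)
from .genome import CodingExon, ReferenceGenome, TranscriptModel, revcomp
from .ingest import (DELETION, INSERTION, SNV, ComponentVariant,
                     RawVariantRecord)
from .reconstruct import (FULLY_DELETED, ORF_DISRUPTED, ORF_INTACT,
                          ORF_PRESERVED)

_STOPS = {"TAA", "TAG", "TGA"}
NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
# codons over {C,G} can never form a stop in any reading frame
CG_CODONS = sorted(a + b + c for a in "CG" for b in "CG" for c in "CG")

SCENARIOS = (
    "intact", "synonymous", "missense_joint_codon", "frame_restore",
    "frameshift_stop", "boundary_insertion", "splice_hit", "full_deletion",
    "splice_guard", "compound_decomposition",
)


@dataclass
class FixtureTruth:
    scenario: str
    seed: int
    records: list[RawVariantRecord] = field(default_factory=list)
    # per input record, the atomic components it must decompose into
    expected_components: list[list[ComponentVariant]] = field(default_factory=list)
    # component -> {transcript_id: SO category}
    expected_categories: dict[ComponentVariant, dict[str, str]] = field(default_factory=dict)
    expected_orf: dict[str, str] = field(default_factory=dict)
    expected_stop_pct: dict[str, float | None] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


@dataclass
class FixtureBundle:
    truth: FixtureTruth
    genome: ReferenceGenome
    transcripts: list[TranscriptModel]
    fasta_path: Path | None = None
    gff_path: Path | None = None
    vcf_path: Path | None = None


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

def _rand_bases(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_cds_codons(rng: random.Random, n_middle: int) -> list[str]:
    """ATG + n stop-free codons + TAA."""
    return ["ATG"] + [rng.choice(NON_STOP_CODONS) for _ in range(n_middle)] + ["TAA"]


def build_locus(rng: random.Random, tid: str, strand: str,
                coding_chunks: list[str], chrom: str = "chr1",
                introns: list[str] | None = None,
                flank: int | None = None) -> tuple[str, TranscriptModel]:
    """Assemble a chromosome around one transcript.

    ``coding_chunks`` split the CDS (coding orientation) into exons; for
    minus-strand loci the chunks are reverse-complemented and their genomic
    order reversed.  Introns get canonical GT..AG motifs in coding
    orientation unless explicit forward sequences are supplied.
    """
    n_exons = len(coding_chunks)
    if strand == "+":
        exon_seqs = list(coding_chunks)
    else:
        exon_seqs = [revcomp(c) for c in reversed(coding_chunks)]
    if introns is None:
        introns = []
        for _ in range(n_exons - 1):
            inner = _rand_bases(rng, rng.randint(15, 30))
            fwd = "GT" + inner + "AG" if strand == "+" else "CT" + inner + "AC"
            introns.append(fwd)
    flank = rng.randint(30, 60) if flank is None else flank
    left = _rand_bases(rng, flank)
    right = _rand_bases(rng, flank)

    seq_parts = [left]
    exons: list[CodingExon] = []
    pos = len(left) + 1
    for i, ex_seq in enumerate(exon_seqs):
        exons.append(CodingExon(chrom, pos, pos + len(ex_seq) - 1, strand, tid))
        seq_parts.append(ex_seq)
        pos += len(ex_seq)
        if i < len(introns):
            seq_parts.append(introns[i])
            pos += len(introns[i])
    seq_parts.append(right)
    return "".join(seq_parts), TranscriptModel(tid, chrom, strand, exons)


def _snv_record(genome: ReferenceGenome, t: TranscriptModel, coding_offset: int,
                coding_alt: str) -> tuple[RawVariantRecord, ComponentVariant]:
    """VCF record + expected component for a substitution at a CDS offset."""
    pos = gm.cds_offset_to_genomic(t, coding_offset)
    ref = genome.base(t.chrom, pos)
    alt = coding_alt if t.strand == "+" else gm.complement(coding_alt)
    rec = RawVariantRecord(t.chrom, pos, ref, alt)
    return rec, ComponentVariant(SNV, t.chrom, pos, ref, alt)


def _insertion_record(genome: ReferenceGenome, t: TranscriptModel,
                      coding_gap_after: int, coding_ins: str
                      ) -> tuple[RawVariantRecord, ComponentVariant]:
    """Insertion into the coding gap after ``coding_gap_after`` (0-based)."""
    if t.strand == "+":
        anchor = gm.cds_offset_to_genomic(t, coding_gap_after)
        fwd_ins = coding_ins
    else:
        anchor = gm.cds_offset_to_genomic(t, coding_gap_after + 1)
        fwd_ins = revcomp(coding_ins)
    ref = genome.base(t.chrom, anchor)
    rec = RawVariantRecord(t.chrom, anchor, ref, ref + fwd_ins)
    return rec, ComponentVariant(INSERTION, t.chrom, anchor, "", fwd_ins)


def _deletion_record(genome: ReferenceGenome, chrom: str, start: int, end: int
                     ) -> tuple[RawVariantRecord, ComponentVariant]:
    """VCF-style deletion of genomic bases start..end (anchored one left)."""
    anchor = start - 1
    ref = genome.fetch(chrom, anchor, end)
    rec = RawVariantRecord(chrom, anchor, ref, ref[0])
    return rec, ComponentVariant(DELETION, chrom, start, ref[1:], "")


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def _scenario_intact(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    codons = random_cds_codons(rng, rng.randint(10, 20))
    cds = "".join(codons)
    strand = rng.choice("+-")
    cut = 3 * rng.randint(3, len(codons) - 3)
    seq, t = build_locus(rng, "t1", strand, [cds[:cut], cds[cut:]])
    genome = ReferenceGenome({"chr1": seq})
    truth.expected_orf["t1"] = ORF_INTACT
    truth.expected_stop_pct["t1"] = None
    return FixtureBundle(truth, genome, [t])


def _scenario_synonymous(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    codons = random_cds_codons(rng, rng.randint(10, 20))
    k = rng.randint(2, len(codons) - 3)
    codons[k] = "CTT"  # CTT -> CTC is Leu -> Leu
    strand = rng.choice("+-")
    seq, t = build_locus(rng, "t1", strand, ["".join(codons)])
    genome = ReferenceGenome({"chr1": seq})
    rec, comp = _snv_record(genome, t, 3 * k + 2, "C")
    truth.records = [rec]
    truth.expected_components = [[comp]]
    truth.expected_categories[comp] = {"t1": SYNONYMOUS}
    truth.expected_orf["t1"] = ORF_PRESERVED
    truth.expected_stop_pct["t1"] = None
    return FixtureBundle(truth, genome, [t])


def _scenario_missense_joint_codon(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    codons = random_cds_codons(rng, rng.randint(10, 20))
    k = rng.randint(2, len(codons) - 3)
    codons[k] = "CTG"  # with both SNVs: TCG (Ser); first alone: TTG (Leu, syn.)
    strand = rng.choice("+-")
    seq, t = build_locus(rng, "t1", strand, ["".join(codons)])
    genome = ReferenceGenome({"chr1": seq})
    rec1, comp1 = _snv_record(genome, t, 3 * k, "T")
    rec2, comp2 = _snv_record(genome, t, 3 * k + 1, "C")
    truth.records = [rec1, rec2]
    truth.expected_components = [[comp1], [comp2]]
    truth.expected_categories[comp1] = {"t1": NON_CONSERVATIVE_MISSENSE}
    truth.expected_categories[comp2] = {"t1": NON_CONSERVATIVE_MISSENSE}
    truth.expected_orf["t1"] = ORF_PRESERVED
    truth.expected_stop_pct["t1"] = None
    truth.extra["joint_codon"] = ("CTG", "TCG")
    truth.extra["joint_aa"] = ("L", "S")
    truth.extra["codon_index"] = k
    return FixtureBundle(truth, genome, [t])


def _scenario_frame_restore(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    pre = rng.randint(3, 6)
    post = rng.randint(3, 6)
    codons = (["ATG"] + [rng.choice(NON_STOP_CODONS) for _ in range(pre)]
              + [rng.choice(CG_CODONS) for _ in range(8)]
              + [rng.choice(NON_STOP_CODONS) for _ in range(post)] + ["TAA"])
    strand = rng.choice("+-")
    seq, t = build_locus(rng, "t1", strand, ["".join(codons)])
    genome = ReferenceGenome({"chr1": seq})
    region0 = 3 * (1 + pre)  # first coding offset of the C/G-only region
    ins_gap = region0 + 2
    del_off = ins_gap + rng.randint(4, 8)
    rec_ins, comp_ins = _insertion_record(genome, t, ins_gap, "C")
    del_pos = gm.cds_offset_to_genomic(t, del_off)
    rec_del, comp_del = _deletion_record(genome, t.chrom, del_pos, del_pos)
    truth.records = [rec_ins, rec_del]
    truth.expected_components = [[comp_ins], [comp_del]]
    truth.expected_categories[comp_ins] = {"t1": FRAMESHIFT}
    truth.expected_categories[comp_del] = {"t1": FRAMESHIFT}
    truth.expected_orf["t1"] = ORF_PRESERVED
    truth.expected_stop_pct["t1"] = None
    return FixtureBundle(truth, genome, [t])


def _scenario_frameshift_stop(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    n_middle = rng.randint(10, 20)
    codons = random_cds_codons(rng, n_middle)
    k = rng.randint(2, n_middle - 2)
    codons[k], codons[k + 1] = "ATA", "AGC"  # deleting the A shifts to TAA
    strand = rng.choice("+-")
    seq, t = build_locus(rng, "t1", strand, ["".join(codons)])
    genome = ReferenceGenome({"chr1": seq})
    del_pos = gm.cds_offset_to_genomic(t, 3 * k)
    rec, comp = _deletion_record(genome, t.chrom, del_pos, del_pos)
    truth.records = [rec]
    truth.expected_components = [[comp]]
    truth.expected_categories[comp] = {"t1": FRAMESHIFT}
    truth.expected_orf["t1"] = ORF_DISRUPTED
    truth.expected_stop_pct["t1"] = 100.0 * (k + 1) / len(codons)
    return FixtureBundle(truth, genome, [t])


def _scenario_boundary_insertion(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    codons = random_cds_codons(rng, rng.randint(10, 20))
    cds = "".join(codons)
    cut = 3 * rng.randint(3, len(codons) - 3) + rng.randint(0, 2)
    seq, t = build_locus(rng, "t1", "+", [cds[:cut], cds[cut:]])
    genome = ReferenceGenome({"chr1": seq})
    exon1, exon2 = t.exons
    recs, comps = [], []
    for anchor, ins in ((exon2.start - 1, "C"),  # right before the exon
                        (exon1.end, "G")):       # right after the exon
        ref = genome.base(t.chrom, anchor)
        recs.append(RawVariantRecord(t.chrom, anchor, ref, ref + ins))
        comps.append(ComponentVariant(INSERTION, t.chrom, anchor, "", ins))
    truth.records = recs
    truth.expected_components = [[c] for c in comps]
    for c in comps:
        truth.expected_categories[c] = {"t1": SILENT}
    truth.expected_orf["t1"] = ORF_PRESERVED
    truth.expected_stop_pct["t1"] = None
    return FixtureBundle(truth, genome, [t])


def _scenario_splice_hit(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    codons = random_cds_codons(rng, rng.randint(10, 20))
    cds = "".join(codons)
    strand = rng.choice("+-")
    cut = 3 * rng.randint(3, len(codons) - 3)
    seq, t = build_locus(rng, "t1", strand, [cds[:cut], cds[cut:]])
    genome = ReferenceGenome({"chr1": seq})
    exon1, exon2 = t.exons
    if strand == "+":
        pos = exon1.end + 1  # first donor base, reference 'G'
    else:
        pos = exon2.start - 1  # donor first base on the minus strand
    ref = genome.base(t.chrom, pos)
    alt = "A" if ref != "A" else "T"
    rec = RawVariantRecord(t.chrom, pos, ref, alt)
    comp = ComponentVariant(SNV, t.chrom, pos, ref, alt)
    truth.records = [rec]
    truth.expected_components = [[comp]]
    truth.expected_categories[comp] = {"t1": SPLICE_DONOR}
    truth.expected_orf["t1"] = ORF_DISRUPTED
    truth.expected_stop_pct["t1"] = None
    return FixtureBundle(truth, genome, [t])


def _scenario_full_deletion(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    codons = random_cds_codons(rng, rng.randint(10, 20))
    seq, t = build_locus(rng, "t1", rng.choice("+-"), ["".join(codons)], flank=40)
    genome = ReferenceGenome({"chr1": seq})
    rec, comp = _deletion_record(genome, t.chrom, t.start - 5, t.end + 5)
    truth.records = [rec]
    truth.expected_components = [[comp]]
    truth.expected_categories[comp] = {"t1": INFRAME}
    truth.expected_orf["t1"] = FULLY_DELETED
    truth.expected_stop_pct["t1"] = None
    return FixtureBundle(truth, genome, [t])


def _scenario_splice_guard(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    """Compound allele spanning a donor dinucleotide whose only mismatch is a
    synonymous coding SNV — must not be called a splice variant."""
    codons = random_cds_codons(rng, rng.randint(8, 14))
    codons[1] = "CCA"  # CCA -> CCG is Pro -> Pro at the 3' edge of the 5' exon
    cds = "".join(codons)
    intron_inner = _rand_bases(rng, rng.randint(12, 20))
    intron_fwd = "CT" + intron_inner + "CCCAG"  # minus-strand intron, ends at donor
    seq, t = build_locus(rng, "t1", "-", [cds[:6], cds[6:]], introns=[intron_fwd])
    genome = ReferenceGenome({"chr1": seq})
    exon2 = t.exons[1]  # genomically right = coding-first exon
    g = exon2.start
    assert genome.fetch(t.chrom, g - 5, g) == "CCCAGT"
    rec = RawVariantRecord(t.chrom, g - 5, "CCCAGT", "CCCAGC")
    comp = ComponentVariant(SNV, t.chrom, g, "T", "C")
    truth.records = [rec]
    truth.expected_components = [[comp]]
    truth.expected_categories[comp] = {"t1": SYNONYMOUS}
    truth.expected_orf["t1"] = ORF_PRESERVED
    truth.expected_stop_pct["t1"] = None
    return FixtureBundle(truth, genome, [t])


# compound ref/alt allele pairs with their expected decomposition shape:
# (ref, alt, [(kind, pos_offset, ref_seq, alt_seq), ...])
COMPOUND_ALLELE_PAIRS = [
    ("ATG", "AC", [(SNV, 1, "T", "C"), (DELETION, 2, "G", "")]),
    ("GGGTCAGGACGCG", "GGGTCAGGACGCC", [(SNV, 12, "G", "C")]),
    ("CT", "CCGCTGCCGCCTCCAAAGCC", [(SNV, 1, "T", "C"),
                                    (INSERTION, 1, "", "GCTGCCGCCTCCAAAGCC")]),
    ("CCCAGT", "CCCAGC", [(SNV, 5, "T", "C")]),
    ("CGTAA", "TGTAA", [(SNV, 0, "C", "T")]),
    ("TACCA", "TACCG", [(SNV, 4, "A", "G")]),
    ("GTG", "GTA", [(SNV, 2, "G", "A")]),
    ("TGCAGAGGAGC", "TGCGGAGGAGCCGCAGGCTGGGGCTGCAGGGC",
     [(SNV, 3, "A", "G"), (INSERTION, 10, "", "CGCAGGCTGGGGCTGCAGGGC")]),
]


def _scenario_compound_decomposition(rng: random.Random, truth: FixtureTruth) -> FixtureBundle:
    spacing = 200
    chrom_parts = []
    pos = 1
    records, expected = [], []
    for ref, alt, comps in COMPOUND_ALLELE_PAIRS:
        pad = _rand_bases(rng, spacing - len(ref))
        chrom_parts.append(pad)
        start = pos + len(pad)
        chrom_parts.append(ref)
        records.append(RawVariantRecord("chrC", start, ref, alt))
        expected.append([
            ComponentVariant(kind, "chrC", start + off, r, a)
            for kind, off, r, a in comps
        ])
        pos = start + len(ref)
    chrom_parts.append(_rand_bases(rng, 100))
    chrom_c = "".join(chrom_parts)

    codons = random_cds_codons(rng, 10)
    seq_t, t = build_locus(rng, "t1", "+", ["".join(codons)], chrom="chrT")
    genome = ReferenceGenome({"chrC": chrom_c, "chrT": seq_t})
    truth.records = records
    truth.expected_components = expected
    truth.expected_orf["t1"] = ORF_INTACT
    truth.expected_stop_pct["t1"] = None
    return FixtureBundle(truth, genome, [t])


_BUILDERS = {
    "intact": _scenario_intact,
    "synonymous": _scenario_synonymous,
    "missense_joint_codon": _scenario_missense_joint_codon,
    "frame_restore": _scenario_frame_restore,
    "frameshift_stop": _scenario_frameshift_stop,
    "boundary_insertion": _scenario_boundary_insertion,
    "splice_hit": _scenario_splice_hit,
    "full_deletion": _scenario_full_deletion,
    "splice_guard": _scenario_splice_guard,
    "compound_decomposition": _scenario_compound_decomposition,
}


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fixture_files(bundle: FixtureBundle, outdir: str | Path) -> FixtureBundle:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(bundle.genome.sequences):
            fh.write(f">{chrom}\n")
            seq = bundle.genome.sequences[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    gff = outdir / "transcripts.gff3"
    lines = ["##gff-version 3"]
    for t in bundle.transcripts:
        lines.append("\t".join([t.chrom, "fixture", "mRNA", str(t.start), str(t.end),
                                ".", t.strand, ".", f"ID={t.id}"]))
        for i, e in enumerate(t.exons):
            lines.append("\t".join([t.chrom, "fixture", "CDS", str(e.start), str(e.end),
                                    ".", t.strand, "0",
                                    f"ID=cds_{t.id}_{i};Parent={t.id}"]))
    gff.write_text("\n".join(lines) + "\n")

    vcf = outdir / "variants.vcf"
    vlines = ["##fileformat=VCFv4.2"]
    for chrom in sorted(bundle.genome.sequences):
        vlines.append(f"##contig=<ID={chrom},length={bundle.genome.length(chrom)}>")
    vlines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(bundle.truth.records, key=lambda r: (r.chrom, r.pos)):
        vlines.append(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref_allele}\t{rec.alt_allele}\t.\t.\t.")
    vcf.write_text("\n".join(vlines) + "\n")

    bundle.fasta_path, bundle.gff_path, bundle.vcf_path = fasta, gff, vcf
    return bundle


def generate_fixture(scenario: str, seed: int,
                     outdir: str | Path | None = None) -> FixtureBundle:
    """Build one scenario; optionally write genome.fa/transcripts.gff3/variants.vcf."""
    if scenario not in _BUILDERS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = random.Random(seed)
    truth = FixtureTruth(scenario=scenario, seed=seed)
    bundle = _BUILDERS[scenario](rng, truth)
    if outdir is not None:
        write_fixture_files(bundle, outdir)
    return bundle
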