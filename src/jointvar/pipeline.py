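"""End-to-end annotation run: ingest -> assign -> classify -> reconstruct -> write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import genome as gm
from .effects import (Annotation, GranthamMatrix, SnvAnnotation, classify_indel,
                      classify_snv, collect_multi_category)
from .genome import InputFormatError, ReferenceGenome, TranscriptModel
from .ingest import (SNV, ComponentVariant, RawVariantRecord, assign_variants,
                     build_transcript_index, decompose, parse_tab, parse_vcf)
from .outputs import (RunStats, compute_stats, write_circos_tracks, write_fasta,
                      write_gvf, write_stats, write_transcript_gff)
from .reconstruct import VariantTranscript, apply_variants

log = logging.getLogger(__name__)


@dataclass
class AnnotationResult:
    genome: ReferenceGenome
    transcripts: list[TranscriptModel]
    records: list[RawVariantRecord]
    components: list[ComponentVariant]
    unassigned: list[ComponentVariant]
    assignments: dict[str, list[ComponentVariant]]
    annotations: list[Annotation]
    variant_transcripts: dict[str, VariantTranscript]
    multi_category: list
    stats: RunStats
    skip_counts: dict = field(default_factory=dict)


def _verify_reference(components: list[ComponentVariant], genome: ReferenceGenome,
                      skip_counts: dict) -> list[ComponentVariant]:
    """Drop components whose stated reference bases disagree with the genome."""
    kept = []
    for v in components:
        if v.chrom not in genome:
            raise InputFormatError(f"chromosome '{v.chrom}' from the variant file "
                                   "is not present in the reference genome")
        if v.ref_seq:
            observed = genome.fetch(v.chrom, v.pos, v.pos + len(v.ref_seq) - 1)
            if observed != v.ref_seq:
                log.warning("reference mismatch at %s:%d (variant says %s, genome %s); skipped",
                            v.chrom, v.pos, v.ref_seq, observed)
                skip_counts["ref_mismatch"] = skip_counts.get("ref_mismatch", 0) + 1
                continue
        kept.append(v)
    return kept


def annotate(variant_path: str | Path, ref_path: str | Path, exons_path: str | Path,
             fmt: str = "vcf",
             codon_table: gm.CodonTable | None = None,
             grantham_matrix: GranthamMatrix | None = None) -> AnnotationResult:
    """Run the full annotation pipeline in memory."""
    genome = gm.load_reference(ref_path)
    transcripts = gm.load_coding_exons(exons_path)
    for t in transcripts:
        if t.chrom not in genome:
            raise InputFormatError(f"chromosome '{t.chrom}' from the exon annotation "
                                   "is not present in the reference genome")
        if t.end > genome.length(t.chrom):
            raise InputFormatError(f"transcript {t.id} exceeds bounds of chromosome '{t.chrom}'")

    skip_counts: dict = {}
    parser = parse_vcf if fmt == "vcf" else parse_tab
    records = parser(variant_path, stats=skip_counts)

    components: list[ComponentVariant] = []
    for rec in records:
        components.extend(decompose(rec))
    components = _verify_reference(components, genome, skip_counts)

    index = build_transcript_index(transcripts)
    assignments = assign_variants(components, index, stats=skip_counts)
    assigned = {v for vlist in assignments.values() for v in vlist}
    unassigned = [v for v in components if v not in assigned]

    annotations: list[Annotation] = []
    variant_transcripts: dict[str, VariantTranscript] = {}
    for t in transcripts:
        vlist = assignments.get(t.id, [])
        cds = gm.spliced_cds(t, genome)
        windows = gm.splice_site_windows(t)
        snvs = [v for v in vlist if v.kind == SNV]
        for v in vlist:
            if v.kind == SNV:
                ann = classify_snv(v, t, genome, cooccurring_snvs=snvs,
                                   codon_table=codon_table, matrix=grantham_matrix,
                                   cds=cds, windows=windows)
            else:
                ann = classify_indel(v, t, genome, windows=windows)
            if ann is not None:
                annotations.append(ann)
        variant_transcripts[t.id] = apply_variants(t, genome, vlist,
                                                   codon_table=codon_table)

    snv_annotations = [a for a in annotations if isinstance(a, SnvAnnotation)]
    multi = collect_multi_category(snv_annotations)
    stats = compute_stats(annotations, variant_transcripts, all_variants=components)
    return AnnotationResult(genome, transcripts, records, components, unassigned,
                            assignments, annotations, variant_transcripts, multi,
                            stats, skip_counts)


def run_annotate(variant_path: str | Path, ref_path: str | Path,
                 exons_path: str | Path, outdir: str | Path,
                 fmt: str = "vcf", circos: bool = False, bin_size: int = 100_000,
                 codon_table: gm.CodonTable | None = None,
                 grantham_matrix: GranthamMatrix | None = None,
                 stop_report_threshold: float = 70.0) -> AnnotationResult:
    """Run :func:`annotate` and serialize every output file into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = annotate(variant_path, ref_path, exons_path, fmt=fmt,
                      codon_table=codon_table, grantham_matrix=grantham_matrix)

    write_gvf(result.annotations, outdir / "variants.gvf", unassigned=result.unassigned)
    write_transcript_gff(result.transcripts, result.variant_transcripts,
                         outdir / "transcripts.gff3", annotations=result.annotations)

    vt = result.variant_transcripts
    ordered = sorted(vt)
    write_fasta([(f"{tid} orf_status={vt[tid].orf_status}", vt[tid].var_cds)
                 for tid in ordered], outdir / "variant_cds.fasta")
    write_fasta([(f"{tid} orf_status={vt[tid].orf_status}", vt[tid].var_protein)
                 for tid in ordered], outdir / "variant_proteins.fasta")

    ref_exons, var_exons = [], []
    by_id = {t.id: t for t in result.transcripts}
    for tid in ordered:
        for aln in vt[tid].exon_alignments:
            name = f"{tid}.exon{aln.exon_index + 1}"
            ref_exons.append((name, aln.ref_seq.replace("-", "").upper()))
            var_exons.append((name, aln.var_seq.replace("-", "").upper()))
    write_fasta(ref_exons, outdir / "reference_exons.fasta")
    write_fasta(var_exons, outdir / "variant_exons.fasta")

    aln_lines = []
    for tid in ordered:
        t = by_id[tid]
        for aln in vt[tid].exon_alignments:
            e = t.exons[aln.exon_index]
            aln_lines.append(f">{tid} exon {aln.exon_index + 1} "
                             f"{t.chrom}:{e.start}-{e.end} ({t.strand})")
            aln_lines.append("ref  " + aln.ref_seq)
            aln_lines.append("var  " + aln.var_seq)
    (outdir / "alignments.txt").write_text("\n".join(aln_lines) + "\n")

    write_stats(result.stats, outdir)

    mc_lines = ["#chrom\tpos\tref\talt\tcategories"]
    for variant, cats in result.multi_category:
        cat_s = ",".join(f"{tid}:{cat}" for tid, cat in sorted(cats.items()))
        mc_lines.append(f"{variant.chrom}\t{variant.pos}\t{variant.ref_seq or '-'}"
                        f"\t{variant.alt_seq or '-'}\t{cat_s}")
    (outdir / "multi_category_snvs.tsv").write_text("\n".join(mc_lines) + "\n")

    if circos:
        write_circos_tracks(result.components, result.transcripts, result.genome,
                            bin_size, outdir / "circos")

    early = sum(1 for x in vt.values()
                if x.first_internal_stop_pct is not None
                and x.first_internal_stop_pct <= stop_report_threshold)
    summary = [
        f"input records: {len(result.records)}",
        f"component variants: {len(result.components)}",
        f"transcripts: {len(result.transcripts)}",
    ]
    for status in ("ORF_INTACT", "ORF_PRESERVED", "ORF_DISRUPTED", "FULLY_DELETED"):
        summary.append(f"{status}: {result.stats.orf_status_counts.get(status, 0)}")
    summary.append(f"transcripts with first internal stop within the first "
                   f"{stop_report_threshold:g}% of the reference peptide: {early}")
    for key in sorted(result.skip_counts):
        summary.append(f"skipped ({key}): {result.skip_counts[key]}")
    (outdir / "run_summary.txt").write_text("\n".join(summary) + "\n")
    return result
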