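"""Serialization of annotation results.

Writers are deterministic byte-for-byte given the same inputs: records are
emitted in (chromosome, start, kind) order and attribute lists are sorted,
so outputs can be compared as golden files.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .effects import (SPLICE_CATEGORIES, SYNONYMOUS, Annotation, IndelAnnotation,
                      SnvAnnotation)
from .genome import ReferenceGenome, TranscriptModel
from .ingest import DELETION, INSERTION, SNV, ComponentVariant
from .reconstruct import VariantTranscript

log = logging.getLogger(__name__)

GVF_PRAGMA = "##gvf-version 1.05"
SOURCE = "jointvar"

# GVF column-3 terms for variants with no transcript-level effect
_KIND_SO_TERM = {SNV: "SNV", INSERTION: "insertion", DELETION: "deletion"}


def _variant_coords(v: ComponentVariant) -> tuple[int, int]:
    if v.kind == DELETION:
        return v.pos, v.pos + len(v.ref_seq) - 1
    return v.pos, v.pos  # SNV and insertion (anchor base)


def _fasta_wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width)) or ""


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            if seq:
                fh.write(_fasta_wrap(seq) + "\n")


# ---------------------------------------------------------------------------
# GVF
# ---------------------------------------------------------------------------

def write_gvf(annotations: list[Annotation], path: str | Path,
              unassigned: list[ComponentVariant] = ()) -> None:
    """Write one GVF record per component variant.

    Per-transcript effects are folded into comma-separated
    ``Variant_effect`` values; codon/amino-acid changes and Grantham
    grades go into namespaced attributes.  Variants that overlap no
    transcript window are written with their structural kind as type.
    """
    by_variant: dict[ComponentVariant, list[Annotation]] = defaultdict(list)
    for ann in annotations:
        by_variant[ann.variant].append(ann)
    records: list[tuple[tuple, str]] = []

    def sort_key(v: ComponentVariant) -> tuple:
        return (v.chrom, v.pos, v.kind, v.ref_seq, v.alt_seq)

    all_variants = sorted(set(by_variant) | set(unassigned), key=sort_key)
    lines = [GVF_PRAGMA]
    for n, v in enumerate(all_variants, 1):
        anns = sorted(by_variant.get(v, []), key=lambda a: a.transcript_id)
        start, end = _variant_coords(v)
        so_type = anns[0].category if anns else _KIND_SO_TERM[v.kind]
        attrs = [
            f"ID=GV_{n}",
            f"Variant_seq={v.alt_seq or '-'}",
            f"Reference_seq={v.ref_seq or '-'}",
            f"jointvar_kind={v.kind}",
        ]
        if anns:
            effects = ",".join(f"{a.category} 0 mRNA {a.transcript_id}" for a in anns)
            attrs.append(f"Variant_effect={effects}")
            codon = [f"{a.transcript_id}:{a.ref_codon}>{a.var_codon}"
                     for a in anns if isinstance(a, SnvAnnotation) and a.ref_codon]
            aa = [f"{a.transcript_id}:{a.ref_aa}>{a.var_aa}"
                  for a in anns if isinstance(a, SnvAnnotation) and a.ref_aa]
            gr = [f"{a.transcript_id}:{a.grantham.label}:{a.grantham.score}"
                  for a in anns if isinstance(a, SnvAnnotation) and a.grantham]
            if codon:
                attrs.append("jointvar_codon_change=" + ",".join(codon))
            if aa:
                attrs.append("jointvar_aa_change=" + ",".join(aa))
            if gr:
                attrs.append("jointvar_grantham=" + ",".join(gr))
        lines.append("\t".join(
            [v.chrom, SOURCE, so_type, str(start), str(end), ".", "+", ".",
             ";".join(attrs)]
        ))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GvfRecord:
    chrom: str
    source: str
    so_type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str]
    raw: str


def read_gvf(path: str | Path):
    """Iterate over GVF data lines (header pragmas are skipped)."""
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        yield GvfRecord(f[0], f[1], f[2], int(f[3]), int(f[4]), f[6], attrs, line)


# ---------------------------------------------------------------------------
# Transcript GFF
# ---------------------------------------------------------------------------

def write_transcript_gff(transcripts: list[TranscriptModel],
                         variant_transcripts: dict[str, VariantTranscript],
                         path: str | Path,
                         annotations: list[Annotation] = ()) -> None:
    """GFF3 with transcript models, their ORF status, and GV child features."""
    anns_by_tid: dict[str, list[Annotation]] = defaultdict(list)
    for ann in annotations:
        anns_by_tid[ann.transcript_id].append(ann)

    lines = ["##gff-version 3"]
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id)):
        vt = variant_transcripts[t.id]
        attrs = [f"ID={t.id}", f"orf_status={vt.orf_status}"]
        if vt.first_internal_stop_pct is not None:
            attrs.append(f"first_internal_stop_pct={vt.first_internal_stop_pct:.1f}")
        lines.append("\t".join([t.chrom, SOURCE, "mRNA", str(t.start), str(t.end),
                                ".", t.strand, ".", ";".join(attrs)]))
        for e in t.exons:
            lines.append("\t".join([t.chrom, SOURCE, "CDS", str(e.start), str(e.end),
                                    ".", t.strand, ".", f"Parent={t.id}"]))
        for ann in sorted(anns_by_tid.get(t.id, []),
                          key=lambda a: (a.variant.pos, a.variant.kind, a.variant.alt_seq)):
            v = ann.variant
            start, end = _variant_coords(v)
            gv_attrs = (f"Parent={t.id};jointvar_kind={v.kind};"
                        f"Variant_seq={v.alt_seq or '-'};Reference_seq={v.ref_seq or '-'}")
            lines.append("\t".join([t.chrom, SOURCE, ann.category, str(start), str(end),
                                    ".", t.strand, ".", gv_attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class RunStats:
    orf_status_counts: Counter = field(default_factory=Counter)
    variant_combo_counts: Counter = field(default_factory=Counter)
    internal_stop_pct_bins: Counter = field(default_factory=Counter)
    codon_bias: dict[str, list[int]] = field(default_factory=dict)  # codon -> [syn, nonsyn]
    indel_length_genome: Counter = field(default_factory=Counter)
    indel_length_cds: Counter = field(default_factory=Counter)


_MISSENSE_LIKE = ("conservative_missense_codon", "non_conservative_missense_codon",
                  "stop_gained", "stop_lost")


def compute_stats(annotations: list[Annotation],
                  variant_transcripts: dict[str, VariantTranscript],
                  all_variants: list[ComponentVariant] = ()) -> RunStats:
    """Aggregate run-level statistics.

    ``all_variants`` (every decomposed component, assigned or not) feeds the
    genome-wide indel length histogram; the CDS-impacting histogram counts
    indels whose annotation has a non-zero coding length delta.
    """
    stats = RunStats()
    for vt in variant_transcripts.values():
        stats.orf_status_counts[vt.orf_status] += 1
        if vt.first_internal_stop_pct is not None:
            decile = min(int(vt.first_internal_stop_pct // 10) * 10, 90)
            stats.internal_stop_pct_bins[f"{decile}-{decile + 10}%"] += 1

    kinds_by_tid: dict[str, set] = defaultdict(set)
    cds_indels: set[ComponentVariant] = set()
    for ann in annotations:
        kinds_by_tid[ann.transcript_id].add(ann.variant.kind)
        if isinstance(ann, SnvAnnotation) and ann.ref_codon:
            row = stats.codon_bias.setdefault(ann.ref_codon, [0, 0])
            if ann.category == SYNONYMOUS:
                row[0] += 1
            elif ann.category in _MISSENSE_LIKE:
                row[1] += 1
        if isinstance(ann, IndelAnnotation) and ann.coding_length_delta != 0:
            cds_indels.add(ann.variant)
    for kinds in kinds_by_tid.values():
        stats.variant_combo_counts["+".join(sorted(kinds))] += 1

    for v in all_variants:
        if v.kind == INSERTION:
            stats.indel_length_genome[len(v.alt_seq)] += 1
        elif v.kind == DELETION:
            stats.indel_length_genome[-len(v.ref_seq)] += 1
    for v in cds_indels:
        length = len(v.alt_seq) if v.kind == INSERTION else -len(v.ref_seq)
        stats.indel_length_cds[length] += 1
    return stats


def write_stats(stats: RunStats, outdir: str | Path) -> None:
    outdir = Path(outdir)
    lines = ["# transcript ORF status"]
    for status in ("ORF_INTACT", "ORF_PRESERVED", "ORF_DISRUPTED", "FULLY_DELETED"):
        lines.append(f"{status}\t{stats.orf_status_counts.get(status, 0)}")
    lines.append("")
    lines.append("# transcripts by impacting variant-kind combination")
    for combo in sorted(stats.variant_combo_counts):
        lines.append(f"{combo}\t{stats.variant_combo_counts[combo]}")
    lines.append("")
    lines.append("# location of first new internal stop (% of reference peptide)")
    for b in sorted(stats.internal_stop_pct_bins, key=lambda s: int(s.split("-")[0])):
        lines.append(f"{b}\t{stats.internal_stop_pct_bins[b]}")
    (outdir / "variant.stat").write_text("\n".join(lines) + "\n")

    rows = ["codon\tsynonymous\tnon_synonymous"]
    for codon in sorted(stats.codon_bias):
        syn, nonsyn = stats.codon_bias[codon]
        rows.append(f"{codon}\t{syn}\t{nonsyn}")
    (outdir / "codon_bias.tsv").write_text("\n".join(rows) + "\n")

    for name, counter in (("indel_lengths_genome.tsv", stats.indel_length_genome),
                          ("indel_lengths_cds.tsv", stats.indel_length_cds)):
        rows = ["length\tcount"]
        for length in sorted(counter):
            rows.append(f"{length}\t{counter[length]}")
        (outdir / name).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Circos-compatible density tracks
# ---------------------------------------------------------------------------

def write_circos_tracks(variants: list[ComponentVariant],
                        transcripts: list[TranscriptModel],
                        genome: ReferenceGenome,
                        bin_size: int,
                        outdir: str | Path) -> None:
    """Fixed-width bin counts of SNVs, insertions, deletions and coding exons.

    One file per feature class with lines ``chrom start end count``; a
    feature is counted in the bin containing its start position.  Bins tile
    every chromosome of the reference.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    starts: dict[str, list[tuple[str, int]]] = {SNV: [], INSERTION: [], DELETION: [],
                                                "coding_exon": []}
    for v in variants:
        starts[v.kind].append((v.chrom, v.pos))
    for t in transcripts:
        for e in t.exons:
            starts["coding_exon"].append((e.chrom, e.start))

    names = {SNV: "snvs.txt", INSERTION: "insertions.txt", DELETION: "deletions.txt",
             "coding_exon": "coding_exons.txt"}
    for kind, fname in names.items():
        counts: Counter = Counter()
        for chrom, pos in starts[kind]:
            counts[(chrom, (pos - 1) // bin_size)] += 1
        lines = []
        for chrom in sorted(genome.sequences):
            length = genome.length(chrom)
            nbins = max(1, -(-length // bin_size))
            for b in range(nbins):
                start = b * bin_size + 1
                end = min((b + 1) * bin_size, length)
                lines.append(f"{chrom}\t{start}\t{end}\t{counts.get((chrom, b), 0)}")
        (outdir / fname).write_text("\n".join(lines) + "\n")
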