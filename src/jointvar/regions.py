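"""Protein-to-genome coordinate mapping and region overlap annotation.

``protein_to_genome`` projects amino-acid ranges (e.g. protein domains)
through a transcript's exon structure onto the genome; ``annotate_regions``
then marks variants in a GVF file with the regions they overlap.  The
overlap step is generic: any GFF3 file of genomic intervals works, not just
domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from intervaltree import IntervalTree

from .genome import TranscriptModel
from .outputs import read_gvf

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRegion:
    transcript_id: str
    aa_start: int  # 1-based inclusive
    aa_end: int
    label: str


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    label: str

    def __len__(self) -> int:
        return self.end - self.start + 1


def protein_to_genome(region: ProteinRegion,
                      transcript: TranscriptModel) -> list[GenomicInterval]:
    """Genomic intervals covered by an amino-acid range of a transcript.

    The aa range maps to CDS nucleotides 3(aa_start-1)+1 .. 3*aa_end, then
    through the exon structure; one interval is emitted per exon crossed,
    in coding order.  Interval lengths always sum to 3x the aa span.
    """
    if region.aa_start < 1 or region.aa_start > region.aa_end:
        raise ValueError(f"invalid amino-acid range {region.aa_start}..{region.aa_end}")
    if transcript.cds_length < 3 * region.aa_end:
        raise ValueError(
            f"aa range {region.aa_start}..{region.aa_end} exceeds CDS of {transcript.id}"
        )
    nt_lo = 3 * (region.aa_start - 1)      # 0-based CDS offsets, inclusive
    nt_hi = 3 * region.aa_end - 1

    intervals: list[GenomicInterval] = []
    cum = 0
    for exon in transcript.exons_in_coding_order():
        lo, hi = max(nt_lo, cum), min(nt_hi, cum + len(exon) - 1)
        if lo <= hi:
            if transcript.strand == "+":
                g1 = exon.start + (lo - cum)
                g2 = exon.start + (hi - cum)
            else:
                g1 = exon.end - (hi - cum)
                g2 = exon.end - (lo - cum)
            intervals.append(GenomicInterval(exon.chrom, g1, g2, transcript.strand,
                                             region.label))
        cum += len(exon)
    return intervals


def parse_protein_regions(path: str | Path) -> list[ProteinRegion]:
    """Tab format: transcript_id, aa_start, aa_end, label ('#' comments)."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        tid, lo, hi, label = line.rstrip("\n").split("\t")[:4]
        regions.append(ProteinRegion(tid, int(lo), int(hi), label))
    return regions


def write_regions_gff(intervals: list[GenomicInterval], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for iv in intervals:
        lines.append("\t".join([iv.chrom, "jointvar", "region", str(iv.start),
                                str(iv.end), ".", iv.strand, ".",
                                f"Name={iv.label}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def parse_regions_gff(path: str | Path) -> list[GenomicInterval]:
    """Read genomic regions from GFF3; label from Name=, falling back to ID=."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            log.warning("short GFF line skipped: %r", line)
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        label = attrs.get("Name", attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"))
        regions.append(GenomicInterval(f[0], int(f[3]), int(f[4]),
                                       f[6] if f[6] in "+-" else "+", label))
    return regions


def overlapping_labels(chrom: str, start: int, end: int, is_insertion: bool,
                       trees: dict[str, IntervalTree]) -> list[str]:
    """Labels of regions overlapped by one variant footprint.

    Plain intervals overlap on >=1 shared base; an insertion (zero-length
    reference footprint, anchored after ``start``) overlaps a region only
    when its anchor gap lies strictly inside it.
    """
    tree = trees.get(chrom)
    if tree is None:
        return []
    if is_insertion:
        hits = [iv for iv in tree.overlap(start, start + 2)
                if iv.data.start <= start and start + 1 <= iv.data.end]
    else:
        hits = list(tree.overlap(start, end + 1))
    return sorted({iv.data.label for iv in hits})


def annotate_regions(gvf_path: str | Path, regions_gff_path: str | Path,
                     out_path: str | Path) -> int:
    """Annotate GVF records with overlapping region labels.

    Records gaining >=1 overlap get an ``overlapping_regions`` attribute;
    all other lines pass through unchanged.  Returns the number of records
    annotated.
    """
    regions = parse_regions_gff(regions_gff_path)
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r)

    n_annotated = 0
    out_lines = []
    for line in Path(gvf_path).read_text().splitlines():
        if not line or line.startswith("#"):
            out_lines.append(line)
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        is_insertion = attrs.get("jointvar_kind") == "insertion" or \
            (attrs.get("Reference_seq") == "-" and "jointvar_kind" not in attrs)
        labels = overlapping_labels(f[0], int(f[3]), int(f[4]), is_insertion, trees)
        if labels:
            f[8] = f[8] + ";overlapping_regions=" + ",".join(labels)
            n_annotated += 1
        out_lines.append("\t".join(f))
    Path(out_path).write_text("\n".join(out_lines) + "\n")
    return n_annotated
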