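"""Reference genome and protein-coding transcript models.

All genomic coordinates in this package are 1-based and inclusive, matching
the conventions of FASTA-indexed positions, GFF/GTF and VCF.  A transcript
model is the ordered set of its coding (CDS) exons on one strand; the spliced
CDS always reads 5'->3' in coding orientation, i.e. minus-strand transcripts
are reverse-complemented after splicing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class InputFormatError(Exception):
    """Fatal problem with an input file (bad format, missing chromosome...)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Uppercased chromosome sequences keyed by chromosome id."""

    sequences: dict[str, str]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` between 1-based inclusive ``start`` and ``end``."""
        if chrom not in self.sequences:
            raise InputFormatError(f"chromosome '{chrom}' not found in reference genome")
        if start < 1 or end > len(self.sequences[chrom]):
            raise InputFormatError(
                f"coordinates {start}-{end} exceed bounds of chromosome '{chrom}'"
            )
        return self.sequences[chrom][start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def load_reference(fasta_path: str | Path) -> ReferenceGenome:
    """Load a multi-record FASTA file into memory.

    The chromosome id is the header token before the first whitespace; any
    description is dropped.  Sequences are uppercased.  Duplicate ids and
    empty files are fatal.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise InputFormatError(f"duplicate chromosome id '{rec.id}' in {fasta_path}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise InputFormatError(f"no FASTA records found in {fasta_path}")
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingExon:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    transcript_id: str

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """Ordered coding exons of one protein-coding transcript.

    ``exons`` are stored in genomic order (ascending start) regardless of
    strand; coding order is derived on demand.
    """

    id: str
    chrom: str
    strand: str
    exons: list[CodingExon]

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exons_in_coding_order(self) -> list[CodingExon]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass(frozen=True)
class SpliceWindow:
    """Two intronic bases adjacent to an exon edge (donor or acceptor)."""

    chrom: str
    start: int
    end: int
    kind: str  # "donor" | "acceptor"


def load_coding_exons(gff_or_gtf_path: str | Path) -> list[TranscriptModel]:
    """Read CDS features from a GFF3 or GTF file and group them by transcript.

    The dialect is auto-detected.  Transcript ids come from ``Parent``
    (GFF3), ``transcript_id`` (GTF) or, as a last resort, ``ID``.  A CDS
    segment with several parents contributes to each of them.  Transcripts
    with mixed strands or chromosomes, overlapping exons, or a total CDS
    length below one codon are rejected with a warning.
    """
    try:
        db = gffutils.create_db(
            str(gff_or_gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad syntax
        raise InputFormatError(f"cannot parse exon annotation {gff_or_gtf_path}: {exc}") from exc

    by_transcript: dict[str, list[CodingExon]] = {}
    for feat in db.features_of_type("CDS"):
        parents = (
            feat.attributes.get("Parent")
            or feat.attributes.get("transcript_id")
            or feat.attributes.get("ID")
        )
        if not parents:
            log.warning("CDS feature at %s:%d-%d has no transcript id; skipped",
                        feat.seqid, feat.start, feat.end)
            continue
        for tid in parents:
            by_transcript.setdefault(tid, []).append(
                CodingExon(feat.seqid, feat.start, feat.end, feat.strand, tid)
            )

    models: list[TranscriptModel] = []
    for tid, exons in by_transcript.items():
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1 or strands - {"+", "-"}:
            log.warning("transcript %s rejected: inconsistent chromosome/strand", tid)
            continue
        exons = sorted(exons, key=lambda e: (e.start, e.end))
        overlapping = any(a.end >= b.start for a, b in zip(exons, exons[1:]))
        if overlapping:
            log.warning("transcript %s rejected: overlapping CDS exons", tid)
            continue
        if sum(len(e) for e in exons) < 3:
            log.warning("transcript %s rejected: CDS shorter than one codon", tid)
            continue
        models.append(TranscriptModel(tid, exons[0].chrom, exons[0].strand, exons))
    models.sort(key=lambda t: (t.chrom, t.start, t.id))
    return models


# ---------------------------------------------------------------------------
# Splicing, translation, coordinate mapping
# ---------------------------------------------------------------------------

def spliced_cds(transcript: TranscriptModel, genome: ReferenceGenome) -> str:
    """Concatenated exon sequence read 5'->3' in coding orientation."""
    parts = [genome.fetch(e.chrom, e.start, e.end) for e in transcript.exons]
    cds = "".join(parts)
    return revcomp(cds) if transcript.strand == "-" else cds


# 64-entry codon -> amino-acid map; '*' marks stop codons.
CodonTable = dict[str, str]


def standard_codon_table() -> CodonTable:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    ncbi = unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for codon in ncbi.stop_codons:
        table[codon] = "*"
    assert len(table) == 64
    return table


def load_codon_table(path: str | Path) -> CodonTable:
    """Read a user-supplied codon table: one ``CODON<TAB>AA`` pair per line."""
    table: CodonTable = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, aa = line.split()[:2]
        table[codon.upper()] = aa.upper() if aa != "*" else "*"
    if len(table) != 64:
        raise InputFormatError(f"codon table {path} has {len(table)} entries, expected 64")
    return table


def translate(cds: str, table: CodonTable | None = None) -> str:
    """Translate ``cds`` codon by codon without halting at internal stops.

    A trailing partial codon is ignored; codons containing ambiguous bases
    translate to 'X'; stops render as '*'.
    """
    n = len(cds) - len(cds) % 3
    if table is None:
        return str(Seq(cds[:n]).translate())
    return "".join(table.get(cds[i : i + 3], "X") for i in range(0, n, 3))


def genomic_to_cds_offset(transcript: TranscriptModel, genomic_pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS, or None.

    The offset counts in coding orientation: for minus-strand transcripts
    offset 0 is the genomically rightmost coding base.
    """
    cum = 0
    for exon in transcript.exons_in_coding_order():
        if exon.start <= genomic_pos <= exon.end:
            if transcript.strand == "+":
                return cum + (genomic_pos - exon.start)
            return cum + (exon.end - genomic_pos)
        cum += len(exon)
    return None


def cds_offset_to_genomic(transcript: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`genomic_to_cds_offset` (raises on out-of-range)."""
    if offset < 0:
        raise ValueError("negative CDS offset")
    cum = 0
    for exon in transcript.exons_in_coding_order():
        if offset < cum + len(exon):
            within = offset - cum
            if transcript.strand == "+":
                return exon.start + within
            return exon.end - within
        cum += len(exon)
    raise ValueError(f"CDS offset {offset} beyond CDS length {cum} of {transcript.id}")


def splice_site_windows(transcript: TranscriptModel) -> list[SpliceWindow]:
    """Donor/acceptor dinucleotide windows for every intron of a transcript.

    The donor window holds the 2 intronic bases adjacent to the coding-
    upstream exon, the acceptor window the 2 adjacent to the downstream
    exon; for minus-strand transcripts the roles are swapped relative to
    genomic order.  Windows are clamped to the intron (relevant for introns
    shorter than 2 bp).
    """
    windows: list[SpliceWindow] = []
    for left, right in zip(transcript.exons, transcript.exons[1:]):
        intron_start, intron_end = left.end + 1, right.start - 1
        if intron_start > intron_end:
            continue
        after_left = SpliceWindow(
            transcript.chrom, intron_start, min(intron_start + 1, intron_end), ""
        )
        before_right = SpliceWindow(
            transcript.chrom, max(intron_end - 1, intron_start), intron_end, ""
        )
        if transcript.strand == "+":
            windows.append(SpliceWindow(after_left.chrom, after_left.start, after_left.end, "donor"))
            windows.append(SpliceWindow(before_right.chrom, before_right.start, before_right.end, "acceptor"))
        else:
            windows.append(SpliceWindow(before_right.chrom, before_right.start, before_right.end, "donor"))
            windows.append(SpliceWindow(after_left.chrom, after_left.start, after_left.end, "acceptor"))
    return windows
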