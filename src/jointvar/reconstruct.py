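"""Joint application of all variants of a transcript and ORF-status calling.

The ORF verdict is transcript-level: ORF_INTACT (no variants), ORF_PRESERVED
(variants present but no new internal stop and no splice-site hit),
ORF_DISRUPTED (new internal stop or splice-site variant), FULLY_DELETED
(deletions remove the entire transcript span).  A transcript whose
*reference* translation already contains an internal stop is exempt from the
internal-stop criterion: an existing oddity of the gene model must not be
blamed on the variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import genome as gm
from .effects import SPLICE_CATEGORIES, splice_hit
from .genome import ReferenceGenome, TranscriptModel
from .ingest import DELETION, INSERTION, SNV, ComponentVariant

log = logging.getLogger(__name__)

ORF_INTACT = "ORF_INTACT"
ORF_PRESERVED = "ORF_PRESERVED"
ORF_DISRUPTED = "ORF_DISRUPTED"
FULLY_DELETED = "FULLY_DELETED"


@dataclass
class ExonAlignment:
    """Gapped rendering of one exon: unchanged bases lowercase, variant
    bases UPPERCASE, '-' for gaps.  Rows are in genomic orientation."""

    exon_index: int
    ref_seq: str
    var_seq: str


@dataclass
class VariantTranscript:
    transcript_id: str
    var_cds: str
    var_protein: str
    orf_status: str
    first_internal_stop_pct: float | None
    exon_alignments: list[ExonAlignment] = field(default_factory=list)
    ref_cds: str = ""
    ref_protein: str = ""


def _has_internal_stop(protein: str, limit: int) -> bool:
    """Any '*' strictly before 0-based index ``limit``."""
    return "*" in protein[:limit]


def first_internal_stop_percentage(ref_protein: str, var_protein: str) -> float | None:
    """Location of the first NEW internal stop as % of reference length.

    "Internal" means before the final codon of the reference-length
    translation.  Returns None when the variant peptide has no internal
    stop, or when the reference itself already carries one (no stop can
    then be called new).
    """
    if not ref_protein:
        return None
    limit = len(ref_protein) - 1
    if _has_internal_stop(ref_protein, limit):
        return None
    for i, aa in enumerate(var_protein[:limit]):
        if aa == "*":
            return 100.0 * (i + 1) / len(ref_protein)
    return None


def _status(ref_protein: str, var_protein: str, splice_disrupted: bool,
            touched: bool, fully_deleted: bool) -> str:
    if fully_deleted:
        return FULLY_DELETED
    if splice_disrupted:
        return ORF_DISRUPTED
    if first_internal_stop_percentage(ref_protein, var_protein) is not None:
        return ORF_DISRUPTED
    return ORF_PRESERVED if touched else ORF_INTACT


def orf_status(ref_protein: str, var_protein: str, annotations,
               fully_deleted_flag: bool = False) -> str:
    """Transcript-level ORF verdict from its annotations and peptides."""
    splice = any(a.category in SPLICE_CATEGORIES for a in annotations)
    return _status(ref_protein, var_protein, splice, bool(annotations), fully_deleted_flag)


def _fully_deleted(transcript: TranscriptModel, variants: list[ComponentVariant]) -> bool:
    """True when deletion spans jointly cover the whole transcript span."""
    spans = sorted((v.pos, v.pos + len(v.ref_seq) - 1)
                   for v in variants if v.kind == DELETION)
    covered_to = transcript.start - 1
    for s, e in spans:
        if s > covered_to + 1:
            return False
        covered_to = max(covered_to, e)
        if covered_to >= transcript.end:
            return True
    return False


def apply_variants(transcript: TranscriptModel, genome: ReferenceGenome,
                   variants: list[ComponentVariant],
                   codon_table: gm.CodonTable | None = None) -> VariantTranscript:
    """Apply ALL variants of a transcript jointly and rebuild CDS + protein.

    Edits are expressed per reference position (substitution, removal, or
    sequence inserted after a base), which makes the application order
    immaterial: overlap conflicts were already resolved at ingest.
    Insertions enter the CDS only when their anchor gap lies strictly
    inside an exon.
    """
    windows = gm.splice_site_windows(transcript)
    splice_disrupted = any(splice_hit(v, transcript, windows) is not None for v in variants)

    var_exons: list[str] = []
    alignments: list[ExonAlignment] = []
    for idx, exon in enumerate(transcript.exons):
        seq = genome.fetch(exon.chrom, exon.start, exon.end)
        sub: dict[int, str] = {}      # exon offset -> replacement base
        deleted: set[int] = set()     # exon offsets removed
        ins_after: dict[int, str] = {}  # exon offset -> bases inserted after it
        for v in variants:
            if v.kind == SNV:
                if exon.start <= v.pos <= exon.end:
                    sub[v.pos - exon.start] = v.alt_seq
            elif v.kind == DELETION:
                lo = max(v.pos, exon.start)
                hi = min(v.pos + len(v.ref_seq) - 1, exon.end)
                deleted.update(range(lo - exon.start, hi - exon.start + 1))
            else:  # insertion: gap strictly inside this exon
                if exon.start <= v.pos < exon.end:
                    ins_after[v.pos - exon.start] = v.alt_seq

        var_parts: list[str] = []
        ref_row: list[str] = []
        var_row: list[str] = []
        for i, base in enumerate(seq):
            if i in deleted:
                ref_row.append(base.upper())
                var_row.append("-")
            elif i in sub:
                ref_row.append(base.upper())
                var_row.append(sub[i].upper())
                var_parts.append(sub[i])
            else:
                ref_row.append(base.lower())
                var_row.append(base.lower())
                var_parts.append(base)
            if i in ins_after:
                ins = ins_after[i]
                ref_row.append("-" * len(ins))
                var_row.append(ins.upper())
                var_parts.append(ins)
        var_exons.append("".join(var_parts))
        alignments.append(ExonAlignment(idx, "".join(ref_row), "".join(var_row)))

    var_cds = "".join(var_exons)
    ref_cds = gm.spliced_cds(transcript, genome)
    if transcript.strand == "-":
        var_cds = gm.revcomp(var_cds)
    var_cds = var_cds.upper()

    ref_protein = gm.translate(ref_cds, codon_table)
    var_protein = gm.translate(var_cds, codon_table)

    fully_deleted = _fully_deleted(transcript, variants)
    status = _status(ref_protein, var_protein, splice_disrupted,
                     touched=bool(variants), fully_deleted=fully_deleted)
    stop_pct = None
    if not fully_deleted:
        stop_pct = first_internal_stop_percentage(ref_protein, var_protein)

    return VariantTranscript(
        transcript_id=transcript.id,
        var_cds="" if fully_deleted else var_cds,
        var_protein="" if fully_deleted else var_protein,
        orf_status=status,
        first_internal_stop_pct=stop_pct,
        exon_alignments=alignments,
        ref_cds=ref_cds,
        ref_protein=ref_protein,
    )


def exon_alignment(transcript: TranscriptModel, genome: ReferenceGenome,
                   variants: list[ComponentVariant]) -> list[ExonAlignment]:
    """Per-exon gapped reference/variant rendering (see :class:`ExonAlignment`)."""
    return apply_variants(transcript, genome, variants).exon_alignments
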