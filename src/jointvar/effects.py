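"""Sequence Ontology classification of component variants per transcript.

SNVs falling in the same codon are evaluated jointly: the variant codon
carries ALL co-occurring substitutions at once, so a substitution that
looks synonymous on its own can correctly emerge as missense (and vice
versa).  Missense changes are graded with the Grantham (1974) amino-acid
distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from . import genome as gm
from .genome import ReferenceGenome, SpliceWindow, TranscriptModel
from .ingest import DELETION, INSERTION, SNV, ComponentVariant

log = logging.getLogger(__name__)

# Sequence Ontology categories (GVF 1.05 vocabulary)
SILENT = "silent_mutation"
SYNONYMOUS = "synonymous_codon"
CONSERVATIVE_MISSENSE = "conservative_missense_codon"
NON_CONSERVATIVE_MISSENSE = "non_conservative_missense_codon"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
SPLICE_ACCEPTOR = "splice_acceptor_variant"
SPLICE_DONOR = "splice_donor_variant"
FRAMESHIFT = "frameshift_variant"
INFRAME = "inframe_variant"

SPLICE_CATEGORIES = (SPLICE_DONOR, SPLICE_ACCEPTOR)

# Grantham-score class boundaries (Li et al. convention)
GRANTHAM_CLASSES = (
    (50, "CONSERVATIVE"),
    (100, "MODERATELY_CONSERVATIVE"),
    (150, "MODERATELY_RADICAL"),
    (float("inf"), "RADICAL"),
)


@dataclass(frozen=True)
class GranthamClass:
    label: str
    score: int


@dataclass(frozen=True)
class SnvAnnotation:
    variant: ComponentVariant
    transcript_id: str
    category: str
    ref_codon: str | None = None
    var_codon: str | None = None
    ref_aa: str | None = None
    var_aa: str | None = None
    grantham: GranthamClass | None = None


@dataclass(frozen=True)
class IndelAnnotation:
    variant: ComponentVariant
    transcript_id: str
    category: str
    coding_length_delta: int = 0


Annotation = SnvAnnotation | IndelAnnotation


# ---------------------------------------------------------------------------
# Grantham matrix
# ---------------------------------------------------------------------------

class GranthamMatrix:
    """Symmetric 20x20 amino-acid distance matrix."""

    def __init__(self, scores: dict[tuple[str, str], int]):
        self.scores = scores

    @classmethod
    def from_file(cls, path: str | Path) -> "GranthamMatrix":
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")[1:]
        scores: dict[tuple[str, str], int] = {}
        for line in lines[1:]:
            fields = line.split("\t")
            row_aa = fields[0]
            for col_aa, val in zip(header, fields[1:]):
                scores[(row_aa, col_aa)] = int(val)
        return cls(scores)

    @classmethod
    def default(cls) -> "GranthamMatrix":
        ref = resources.files("jointvar.data").joinpath("grantham.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def score(self, aa_ref: str, aa_alt: str) -> int:
        return self.scores[(aa_ref, aa_alt)]


_DEFAULT_MATRIX: GranthamMatrix | None = None


def default_grantham_matrix() -> GranthamMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = GranthamMatrix.default()
    return _DEFAULT_MATRIX


def grantham_classify(aa_ref: str, aa_alt: str,
                      matrix: GranthamMatrix | None = None) -> GranthamClass:
    """Grade an amino-acid substitution by its Grantham distance.

    Both residues must be standard amino acids and differ; stop-involving
    changes are handled upstream as stop_gained/stop_lost.
    """
    if aa_ref == aa_alt:
        raise ValueError("grantham_classify requires two different amino acids")
    if "*" in (aa_ref, aa_alt):
        raise ValueError("stop codons have no Grantham distance")
    matrix = matrix or default_grantham_matrix()
    score = matrix.score(aa_ref, aa_alt)
    for cutoff, label in GRANTHAM_CLASSES:
        if score <= cutoff:
            return GranthamClass(label, score)
    raise AssertionError("unreachable")


def missense_category(gclass: GranthamClass) -> str:
    if gclass.label in ("CONSERVATIVE", "MODERATELY_CONSERVATIVE"):
        return CONSERVATIVE_MISSENSE
    return NON_CONSERVATIVE_MISSENSE


# ---------------------------------------------------------------------------
# Splice-window hits
# ---------------------------------------------------------------------------

def splice_hit(variant: ComponentVariant, transcript: TranscriptModel,
               windows: list[SpliceWindow] | None = None) -> str | None:
    """Splice window kind hit by a variant, or None.

    SNVs hit a window when the substituted base lies inside it; deletions
    when >=1 deleted base does; insertions only when their anchor gap lies
    strictly BETWEEN the two window bases — an insertion next to, but
    outside, the dinucleotide leaves the splice site itself untouched.
    """
    windows = gm.splice_site_windows(transcript) if windows is None else windows
    for w in windows:
        if variant.kind == SNV:
            if w.start <= variant.pos <= w.end:
                return w.kind
        elif variant.kind == DELETION:
            del_start, del_end = variant.pos, variant.pos + len(variant.ref_seq) - 1
            if del_start <= w.end and w.start <= del_end:
                return w.kind
        else:  # insertion: gap between pos and pos+1 strictly inside window
            if w.start <= variant.pos and variant.pos + 1 <= w.end:
                return w.kind
    return None


def _gap_inside_cds(transcript: TranscriptModel, anchor_pos: int) -> bool:
    """True when the insertion gap (anchor..anchor+1) lies strictly inside the CDS."""
    left = gm.genomic_to_cds_offset(transcript, anchor_pos)
    right = gm.genomic_to_cds_offset(transcript, anchor_pos + 1)
    return left is not None and right is not None and abs(left - right) == 1


# ---------------------------------------------------------------------------
# SNV classification
# ---------------------------------------------------------------------------

def variant_codon(transcript: TranscriptModel, genome: ReferenceGenome,
                  codon_index: int, cooccurring_snvs: list[ComponentVariant],
                  cds: str | None = None) -> tuple[str, str]:
    """Reference and variant codon with ALL co-occurring SNVs applied at once.

    Substituted bases are complemented for minus-strand transcripts so the
    codon reads in coding orientation.
    """
    cds = gm.spliced_cds(transcript, genome) if cds is None else cds
    ref_codon = cds[3 * codon_index : 3 * codon_index + 3]
    bases = list(ref_codon)
    for snv in cooccurring_snvs:
        off = gm.genomic_to_cds_offset(transcript, snv.pos)
        if off is None or off // 3 != codon_index:
            raise ValueError(f"SNV at {snv.chrom}:{snv.pos} not in codon {codon_index}")
        base = snv.alt_seq if transcript.strand == "+" else gm.complement(snv.alt_seq)
        bases[off % 3] = base
    return ref_codon, "".join(bases)


def classify_snv(snv: ComponentVariant, transcript: TranscriptModel,
                 genome: ReferenceGenome,
                 cooccurring_snvs: list[ComponentVariant] = (),
                 codon_table: gm.CodonTable | None = None,
                 matrix: GranthamMatrix | None = None,
                 cds: str | None = None,
                 windows: list[SpliceWindow] | None = None) -> SnvAnnotation | None:
    """Classify one SNV against one transcript, joint with same-codon SNVs.

    Returns None (with a warning) when the reference base at the SNV
    position disagrees with the genome.
    """
    if genome.base(snv.chrom, snv.pos) != snv.ref_seq:
        log.warning("reference mismatch at %s:%d (expected %s, genome has %s); variant skipped",
                    snv.chrom, snv.pos, snv.ref_seq, genome.base(snv.chrom, snv.pos))
        return None

    hit = splice_hit(snv, transcript, windows)
    if hit is not None:
        category = SPLICE_DONOR if hit == "donor" else SPLICE_ACCEPTOR
        return SnvAnnotation(snv, transcript.id, category)

    offset = gm.genomic_to_cds_offset(transcript, snv.pos)
    if offset is None:
        return SnvAnnotation(snv, transcript.id, SILENT)

    codon_index = offset // 3
    same_codon = [
        s for s in cooccurring_snvs
        if s.kind == SNV
        and (o := gm.genomic_to_cds_offset(transcript, s.pos)) is not None
        and o // 3 == codon_index
    ]
    if snv not in same_codon:
        same_codon.append(snv)
    ref_codon, var_codon = variant_codon(transcript, genome, codon_index, same_codon, cds=cds)
    ref_aa = gm.translate(ref_codon, codon_table)
    var_aa = gm.translate(var_codon, codon_table)

    grantham = None
    if var_aa == "*" and ref_aa != "*":
        category = STOP_GAINED
    elif ref_aa == "*" and var_aa != "*":
        category = STOP_LOST
    elif ref_aa == var_aa:
        category = SYNONYMOUS
    else:
        try:
            grantham = grantham_classify(ref_aa, var_aa, matrix)
            category = missense_category(grantham)
        except KeyError:  # ambiguous residue; cannot be graded
            category = NON_CONSERVATIVE_MISSENSE
    return SnvAnnotation(snv, transcript.id, category,
                         ref_codon=ref_codon, var_codon=var_codon,
                         ref_aa=ref_aa, var_aa=var_aa, grantham=grantham)


# ---------------------------------------------------------------------------
# Indel classification
# ---------------------------------------------------------------------------

def coding_length_delta(indel: ComponentVariant, transcript: TranscriptModel) -> int:
    """Signed change in spliced-CDS length caused by an indel.

    Insertions count only when the anchor gap lies strictly inside the CDS
    (a boundary insertion next to an exon edge leaves the CDS unchanged);
    deletions count only the deleted bases that fall inside coding exons.
    """
    if indel.kind == INSERTION:
        return len(indel.alt_seq) if _gap_inside_cds(transcript, indel.pos) else 0
    if indel.kind == DELETION:
        del_start, del_end = indel.pos, indel.pos + len(indel.ref_seq) - 1
        removed = 0
        for exon in transcript.exons:
            lo, hi = max(del_start, exon.start), min(del_end, exon.end)
            if lo <= hi:
                removed += hi - lo + 1
        return -removed
    raise ValueError("coding_length_delta is defined for indels only")


def classify_indel(indel: ComponentVariant, transcript: TranscriptModel,
                   genome: ReferenceGenome | None = None,
                   windows: list[SpliceWindow] | None = None) -> IndelAnnotation | None:
    """Classify one insertion or deletion against one transcript.

    A splice-window hit takes precedence over codon-level reasoning (a
    broken splice site invalidates the exon structure).  Otherwise the
    verdict follows the coding length delta: not a multiple of 3 ->
    frameshift; a non-zero multiple of 3 -> inframe; zero (no CDS
    contact) -> silent.
    """
    if indel.kind == DELETION and genome is not None:
        observed = genome.fetch(indel.chrom, indel.pos, indel.pos + len(indel.ref_seq) - 1)
        if observed != indel.ref_seq:
            log.warning("reference mismatch at %s:%d (expected %s, genome has %s); variant skipped",
                        indel.chrom, indel.pos, indel.ref_seq, observed)
            return None

    hit = splice_hit(indel, transcript, windows)
    if hit is not None:
        category = SPLICE_DONOR if hit == "donor" else SPLICE_ACCEPTOR
        return IndelAnnotation(indel, transcript.id, category,
                               coding_length_delta(indel, transcript))

    delta = coding_length_delta(indel, transcript)
    if delta % 3 != 0:
        category = FRAMESHIFT
    elif delta != 0:
        category = INFRAME
    else:
        category = SILENT
    return IndelAnnotation(indel, transcript.id, category, delta)


# ---------------------------------------------------------------------------
# Multi-category report
# ---------------------------------------------------------------------------

def collect_multi_category(snv_annotations: list[SnvAnnotation]
                           ) -> list[tuple[ComponentVariant, dict[str, str]]]:
    """SNVs classified differently across the transcripts they impact.

    Returns (variant, {transcript_id: category}) for every SNV whose
    per-transcript categories are not all identical.
    """
    by_variant: dict[ComponentVariant, dict[str, str]] = {}
    for ann in snv_annotations:
        by_variant.setdefault(ann.variant, {})[ann.transcript_id] = ann.category
    out = []
    for variant in sorted(by_variant, key=lambda v: (v.chrom, v.pos, v.alt_seq)):
        cats = by_variant[variant]
        if len(set(cats.values())) >= 2:
            out.append((variant, cats))
    return out
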