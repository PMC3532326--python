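"""Variant parsing, compound-allele decomposition, and transcript assignment.

A VCF record may encode several atomic changes in one ref/alt allele pair
(a "compound" variant).  :func:`decompose` splits such records into atomic
SNVs plus at most one tail indel by left-aligned positionwise comparison,
so that downstream annotation sees exactly the bases that differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pysam
from intervaltree import IntervalTree

from .genome import TranscriptModel

log = logging.getLogger(__name__)

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

_ALPHABET = set("ACGTN")

# flank beyond the outermost coding exons still assigned to a transcript;
# wide enough to catch the splice dinucleotides.
ANNOTATION_FLANK = 2


@dataclass(frozen=True)
class RawVariantRecord:
    """One input variant line: first ALT only, alleles uppercased."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref_allele: str
    alt_allele: str


@dataclass(frozen=True)
class ComponentVariant:
    """One atomic SNV, insertion or deletion after decomposition.

    ``pos`` is the substituted base (SNV), the first deleted base
    (deletion), or the base AFTER which the new sequence is inserted
    (insertion; the "anchor" base).
    """

    kind: str
    chrom: str
    pos: int
    ref_seq: str  # SNV: 1 base; deletion: deleted bases; insertion: ""
    alt_seq: str  # SNV: 1 base; insertion: inserted bases; deletion: ""

    def __post_init__(self):
        if self.kind == SNV:
            assert len(self.ref_seq) == 1 and len(self.alt_seq) == 1 and self.ref_seq != self.alt_seq
        elif self.kind == INSERTION:
            assert self.ref_seq == "" and self.alt_seq
        elif self.kind == DELETION:
            assert self.alt_seq == "" and self.ref_seq
        else:  # pragma: no cover
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive genomic footprint used for overlap queries.

        An insertion has no reference footprint; its span covers the two
        bases flanking the anchor gap.
        """
        if self.kind == DELETION:
            return self.pos, self.pos + len(self.ref_seq) - 1
        if self.kind == INSERTION:
            return self.pos, self.pos + 1
        return self.pos, self.pos


def _valid_alleles(*alleles: str) -> bool:
    return all(a and set(a) <= _ALPHABET for a in alleles)


def parse_vcf(path: str | Path, stats: dict | None = None) -> list[RawVariantRecord]:
    """Read a VCF 4.x file, keeping only the first ALT allele of each record.

    Symbolic ALTs (``<DEL>`` etc.), breakends and records with missing or
    non-ACGTN alleles are skipped with a warning.
    """
    stats = stats if stats is not None else {}
    records: list[RawVariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        it = iter(vcf)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as exc:
                log.warning("skipping malformed VCF line: %s", exc)
                stats["malformed"] = stats.get("malformed", 0) + 1
                continue
            if not rec.alts:
                log.warning("skipping %s:%d: no ALT allele", rec.chrom, rec.pos)
                stats["no_alt"] = stats.get("no_alt", 0) + 1
                continue
            if len(rec.alts) > 1:
                stats["extra_alts_dropped"] = stats.get("extra_alts_dropped", 0) + 1
            alt = rec.alts[0].upper()
            ref = rec.ref.upper()
            if alt.startswith("<") or any(c in alt for c in "[]."):
                log.warning("skipping %s:%d: symbolic/breakend ALT %s", rec.chrom, rec.pos, alt)
                stats["symbolic"] = stats.get("symbolic", 0) + 1
                continue
            if not _valid_alleles(ref, alt):
                log.warning("skipping %s:%d: non-ACGTN allele", rec.chrom, rec.pos)
                stats["bad_allele"] = stats.get("bad_allele", 0) + 1
                continue
            records.append(RawVariantRecord(rec.chrom, rec.pos, ref, alt))
    return records


def parse_tab(path: str | Path, stats: dict | None = None) -> list[RawVariantRecord]:
    """Read the simple 4-column tab format: chrom, pos, ref_allele, alt_allele.

    Lines starting with '#' are comments.  Lines with the wrong column
    count or invalid fields are skipped with a warning.
    """
    stats = stats if stats is not None else {}
    records: list[RawVariantRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            log.warning("%s line %d: expected 4 tab-separated columns; skipped", path, lineno)
            stats["malformed"] = stats.get("malformed", 0) + 1
            continue
        chrom, pos_s, ref, alt = fields[0], fields[1], fields[2].upper(), fields[3].upper()
        if not pos_s.isdigit() or not _valid_alleles(ref, alt):
            log.warning("%s line %d: invalid position or allele; skipped", path, lineno)
            stats["malformed"] = stats.get("malformed", 0) + 1
            continue
        records.append(RawVariantRecord(chrom, int(pos_s), ref, alt))
    return records


def decompose(record: RawVariantRecord) -> list[ComponentVariant]:
    """Split one ref/alt allele pair into atomic component variants.

    The first min(|ref|, |alt|) bases are compared position by position and
    each mismatch becomes an SNV; a longer ref leaves a single tail
    deletion, a longer alt a single tail insertion anchored after the last
    compared reference base.  Identical alleles decompose to nothing.
    """
    ref, alt = record.ref_allele, record.alt_allele
    components: list[ComponentVariant] = []
    m = min(len(ref), len(alt))
    for i in range(m):
        if ref[i] != alt[i]:
            components.append(ComponentVariant(SNV, record.chrom, record.pos + i, ref[i], alt[i]))
    if len(ref) > len(alt):
        components.append(
            ComponentVariant(DELETION, record.chrom, record.pos + len(alt), ref[m:], "")
        )
    elif len(alt) > len(ref):
        components.append(
            ComponentVariant(INSERTION, record.chrom, record.pos + len(ref) - 1, "", alt[m:])
        )
    return components


def apply_components_to_allele(record: RawVariantRecord,
                               components: list[ComponentVariant]) -> str:
    """Re-apply components to ``ref_allele``; used as the round-trip check."""
    bases = list(record.ref_allele)
    inserts: dict[int, str] = {}
    for comp in components:
        off = comp.pos - record.pos
        if comp.kind == SNV:
            bases[off] = comp.alt_seq
        elif comp.kind == DELETION:
            for i in range(off, off + len(comp.ref_seq)):
                bases[i] = ""
        else:
            inserts[off] = comp.alt_seq
    out = []
    for i, b in enumerate(bases):
        out.append(b)
        out.append(inserts.get(i, ""))
    return "".join(out)


# ---------------------------------------------------------------------------
# Transcript assignment
# ---------------------------------------------------------------------------

class TranscriptIndex:
    """Interval-tree index over transcript annotation windows.

    The window extends ``flank`` bp beyond the outermost coding exons so
    that splice-dinucleotide variants still map to their transcript.
    """

    def __init__(self, transcripts: list[TranscriptModel], flank: int = ANNOTATION_FLANK):
        self.flank = flank
        self.transcripts = {t.id: t for t in transcripts}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            # IntervalTree is half-open; +1 converts from inclusive end
            tree.addi(max(1, t.start - flank), t.end + flank + 1, t.id)

    def query(self, chrom: str, start: int, end: int) -> list[str]:
        """Transcript ids whose window overlaps the inclusive range."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end + 1))


def build_transcript_index(transcripts: list[TranscriptModel],
                           flank: int = ANNOTATION_FLANK) -> TranscriptIndex:
    return TranscriptIndex(transcripts, flank)


def assign_variants(variants: list[ComponentVariant],
                    index: TranscriptIndex,
                    stats: dict | None = None) -> dict[str, list[ComponentVariant]]:
    """Attach each component variant to every transcript window it overlaps.

    Per transcript the list is sorted by position.  Variants whose
    reference span falls inside a region already removed by an earlier
    (lower-coordinate) deletion on the same transcript are dropped with a
    warning: co-occurring variants must edit disjoint reference bases for
    their joint application to be well defined.
    """
    stats = stats if stats is not None else {}
    per_transcript: dict[str, list[ComponentVariant]] = {}
    for v in variants:
        start, end = v.span
        for tid in index.query(v.chrom, start, end):
            per_transcript.setdefault(tid, []).append(v)

    resolved: dict[str, list[ComponentVariant]] = {}
    for tid, vlist in per_transcript.items():
        vlist.sort(key=lambda v: (v.pos, v.kind, v.ref_seq, v.alt_seq))
        kept: list[ComponentVariant] = []
        deleted_spans: list[tuple[int, int]] = []
        for v in vlist:
            if v.kind == INSERTION:
                vs, ve = v.pos, v.pos  # conflict only if the anchor base is gone
            elif v.kind == DELETION:
                vs, ve = v.pos, v.pos + len(v.ref_seq) - 1
            else:
                vs, ve = v.pos, v.pos
            if any(vs <= de and ds <= ve for ds, de in deleted_spans):
                log.warning("variant %s:%d overlaps an earlier deletion on %s; dropped",
                            v.chrom, v.pos, tid)
                stats["conflicting_dropped"] = stats.get("conflicting_dropped", 0) + 1
                continue
            kept.append(v)
            if v.kind == DELETION:
                deleted_spans.append((v.pos, v.pos + len(v.ref_seq) - 1))
        resolved[tid] = kept
    return resolved
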