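"""Shared helpers: tiny hand-built loci and brute-force oracles.

The oracles here deliberately avoid the package's per-exon editing code:
they edit whole chromosome strings position by position, or scan all pairs,
so they can disagree with the implementation when it is wrong.
"""

from __future__ import annotations

import random

import pytest

from jointvar.genome import (CodingExon, ReferenceGenome, TranscriptModel,
                             revcomp)
from jointvar.ingest import DELETION, INSERTION, SNV, ComponentVariant


def make_locus(chrom_seq: str, exon_bounds: list[tuple[int, int]],
               strand: str = "+", tid: str = "t1", chrom: str = "chr1"
               ) -> tuple[ReferenceGenome, TranscriptModel]:
    """Wrap a raw chromosome string and explicit exon bounds into model objects."""
    exons = [CodingExon(chrom, s, e, strand, tid) for s, e in exon_bounds]
    return ReferenceGenome({chrom: chrom_seq.upper()}), TranscriptModel(tid, chrom, strand, exons)


def random_locus(rng: random.Random, n_exons: int | None = None,
                 strand: str | None = None
                 ) -> tuple[ReferenceGenome, TranscriptModel]:
    """Random transcript with 1-4 exons on a random chromosome string."""
    n_exons = n_exons or rng.randint(1, 4)
    strand = strand or rng.choice("+-")
    pieces = []
    bounds = []
    pos = 1
    pad = rng.randint(10, 30)
    pieces.append("".join(rng.choice("ACGT") for _ in range(pad)))
    pos += pad
    for i in range(n_exons):
        ex_len = rng.randint(3, 30)
        bounds.append((pos, pos + ex_len - 1))
        pieces.append("".join(rng.choice("ACGT") for _ in range(ex_len)))
        pos += ex_len
        if i < n_exons - 1:
            intron = rng.randint(5, 25)
            pieces.append("".join(rng.choice("ACGT") for _ in range(intron)))
            pos += intron
    pieces.append("".join(rng.choice("ACGT") for _ in range(rng.randint(10, 30))))
    return make_locus("".join(pieces), bounds, strand=strand)


def random_disjoint_variants(rng: random.Random, genome: ReferenceGenome,
                             transcript: TranscriptModel,
                             n: int | None = None) -> list[ComponentVariant]:
    """Random SNVs/insertions/deletions with pairwise disjoint footprints
    inside the transcript's annotation window."""
    n = n if n is not None else rng.randint(0, 6)
    chrom = transcript.chrom
    seq = genome.sequences[chrom]
    lo = max(2, transcript.start - 2)
    hi = min(len(seq) - 2, transcript.end + 2)
    variants: list[ComponentVariant] = []
    used: set[int] = set()
    for _ in range(n * 4):
        if len(variants) >= n:
            break
        kind = rng.choice([SNV, SNV, INSERTION, DELETION])
        pos = rng.randint(lo, hi)
        if kind == DELETION:
            length = rng.randint(1, 4)
            span = set(range(pos, pos + length))
            if pos + length - 1 > hi or span & used:
                continue
            variants.append(ComponentVariant(DELETION, chrom, pos,
                                             seq[pos - 1 : pos - 1 + length], ""))
            used |= span
        elif kind == INSERTION:
            if pos in used or pos + 1 in used:
                continue
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 5)))
            variants.append(ComponentVariant(INSERTION, chrom, pos, "", ins))
            used |= {pos, pos + 1}  # keep the anchor gap clear of other edits
        else:
            if pos in used:
                continue
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(ComponentVariant(SNV, chrom, pos, ref, alt))
            used.add(pos)
    variants.sort(key=lambda v: v.pos)
    return variants


def chromosome_edit_cds_oracle(genome: ReferenceGenome,
                               transcript: TranscriptModel,
                               variants: list[ComponentVariant]) -> str:
    """Brute-force variant CDS: edit the whole chromosome position-wise,
    then re-splice.  Insertions attach to their anchor base and enter an
    exon only when the anchor gap is interior to it."""
    seq = genome.sequences[transcript.chrom]
    subs: dict[int, str] = {}
    deleted: set[int] = set()
    inserted: dict[int, str] = {}
    for v in variants:
        if v.kind == SNV:
            subs[v.pos] = v.alt_seq
        elif v.kind == DELETION:
            deleted.update(range(v.pos, v.pos + len(v.ref_seq)))
        else:
            inserted[v.pos] = v.alt_seq
    parts = []
    for exon in transcript.exons:
        out = []
        for p in range(exon.start, exon.end + 1):
            if p not in deleted:
                out.append(subs.get(p, seq[p - 1]))
            if p in inserted and p < exon.end:
                out.append(inserted[p])
        parts.append("".join(out))
    cds = "".join(parts)
    return revcomp(cds) if transcript.strand == "-" else cds


@pytest.fixture
def simple_plus_locus():
    """Single-exon plus-strand transcript: ATG GCT TGC TAA at positions 11-22."""
    seq = "A" * 10 + "ATGGCTTGCTAA" + "C" * 10
    return make_locus(seq, [(11, 22)], strand="+")
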