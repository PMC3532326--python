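# Methods

## Scope and model

`jointvar` annotates the effect of genomic variants on protein-coding
transcripts using only a reference genome, CDS coordinates and the
variants themselves. The unit of reasoning is the transcript model: the
ordered, non-overlapping coding exons of one transcript on one strand.
The supplied CDS segments are taken to be the complete ORF read from
offset 0 — the GFF/GTF phase column is ignored and only `CDS`-typed
features are consumed; UTR and non-coding annotation is out of scope.
Translation uses the standard genetic code by default (a 64-entry codon
table can be supplied), renders stops as `*`, translates ambiguous codons
as `X`, ignores a trailing partial codon, and never halts at internal
stops, so their positions can be located.

All coordinates are 1-based inclusive, matching VCF and GFF. Transcripts
lacking a terminal stop codon are accepted (a gene model question, not a
variant question).

## Compound-allele decomposition

VCF ref/alt pairs often encode several atomic changes. The decomposition
is a left-aligned position-wise comparison over the first
min(|ref|, |alt|) bases — each mismatch becomes an SNV — followed by at
most one tail indel: a deletion of the unmatched reference tail, or an
insertion of the unmatched alternative tail anchored after the last
compared reference base. Consequences: identical alleles decompose to
nothing, every decomposition re-applies to reconstruct the alt allele
exactly (a fuzz-tested invariant), and at most one indel is emitted per
record. Only the first ALT allele of multi-allelic records is used;
symbolic alleles and breakends are skipped with a warning.

A note on counting: a pair like `AGA→TGC` contains two mismatching
positions under this rule (A→T and A→C) and therefore emits two SNVs;
position-wise comparison is the only self-consistent reading of such
alleles, and the round-trip invariant holds either way.

## Variant-to-transcript assignment

Variants are assigned with per-chromosome interval trees over each
transcript's *annotation window*: the coding span extended by a 2-bp
flank, exactly enough to capture the intronic splice dinucleotides.
Variants outside all windows are reported with their structural kind only.
Within one transcript, variants are processed in coordinate order and a
variant whose reference footprint falls into bases already removed by an
earlier deletion is dropped with a warning — joint application is only
well defined when variants edit disjoint reference bases.

## Classification rules

**SNVs.** A hit inside a splice window is `splice_donor_variant` /
`splice_acceptor_variant`. Inside the CDS, the variant codon is built
with *all* co-occurring same-codon SNVs applied simultaneously (bases
complemented for minus-strand transcripts), then compared to the
reference codon: equal amino acids → `synonymous_codon`; a new stop →
`stop_gained`; a lost stop → `stop_lost`; otherwise missense, graded by
the Grantham distance. Variants inside the annotation window that touch
neither CDS nor splice dinucleotides are `silent_mutation` — a documented
convention of this package for "near the gene but inert". A stated
reference allele that disagrees with the genome causes the variant to be
skipped (warned and counted), not a fatal error.

**Indels.** Splice-window overlap takes precedence over codon logic,
since a broken splice site invalidates the annotated exon structure.
Otherwise the verdict follows the signed coding-length delta: deletions
count only the removed bases that lie inside coding exons; insertions
count only when their anchor gap (between `pos` and `pos+1`) lies
*strictly inside* an exon. delta ≢ 0 (mod 3) → `frameshift_variant`;
a non-zero multiple of 3 → `inframe_variant`; zero → `silent_mutation`.
The anchor-gap rule is what makes "boundary indels" — insertions hugging
an exon edge — inert: an insertion anchored at the last intronic base
before an exon, or at the last base of an exon, changes neither the CDS
nor the splice dinucleotides themselves, so it is not a frameshift and
not a splice variant. The same strictly-inside rule is applied to
insertions versus splice windows and, in the region-overlap tool, versus
arbitrary regions.

**Grantham grading.** The shipped 20×20 matrix is the published Grantham
(1974) physico-chemical distance. Class cut-offs are 0–50 CONSERVATIVE,
51–100 MODERATELY_CONSERVATIVE, 101–150 MODERATELY_RADICAL, >150 RADICAL;
the first two map to `conservative_missense_codon`, the last two to
`non_conservative_missense_codon`. Grading is symmetric by construction.

## Joint application and ORF status

All surviving variants of a transcript are expressed as per-position
edits (substitution, removal, insertion-after) of the exon sequences,
which makes application order immaterial; the edited exons are spliced
and reverse-complemented as needed, and translated. "Internal stop"
means a `*` strictly before the final codon position of the
reference-length translation. The status rules:

- `FULLY_DELETED` — deletions jointly cover the whole transcript span.
  A deletion removing whole exons but not the whole span is ordinary CDS
  deletion (inframe/frameshift by delta).
- `ORF_DISRUPTED` — any splice-window variant is present, or the variant
  peptide contains a new internal stop. If the *reference* peptide
  already has an internal stop, the stop criterion is disabled for that
  transcript entirely: a pre-broken gene model cannot be disrupted by
  this evidence. The first new internal stop is also reported as
  100 × (1-based stop position) / (reference peptide length).
- `ORF_PRESERVED` — variants were applied but neither condition holds.
  This includes frameshifts that alter the downstream protein without
  introducing a stop, and cancelling indel pairs whose deltas sum to a
  multiple of 3 (frame restoration). `stop_lost` is reported at the
  variant level only and does not change the status.
- `ORF_INTACT` — no variants touched the transcript's window.

The run summary additionally counts transcripts whose first internal stop
falls within the first `--stop-report-threshold` percent (default 70) of
the reference peptide — a reporting aid, never a classifier.

## Outputs

One GVF 1.05 record per component variant, typed by its consequence (or
by its structural kind when no transcript is hit — the GVF convention for
untyped variants), with per-transcript effects in `Variant_effect` and
codon/amino-acid changes and Grantham grades in `jointvar_`-namespaced
attributes. A GFF3 file carries the transcript models with
`orf_status` / `first_internal_stop_pct` attributes, CDS features and GV
child features. FASTA outputs are 60-column wrapped. All writers emit
records in (chromosome, start, kind) order so outputs are byte-identical
across runs. Circos tracks bin SNVs, insertions, deletions and coding
exons by start position into fixed-width bins (default 100 kb,
`--bin-size`); bins tile every chromosome and each track sums to its
feature total.

## Synthetic fixtures

The fixture generator builds loci whose truth is known by construction,
never by running the annotator: CDSs are assembled from an ATG, stop-free
filler codons and a terminal TAA; introns get canonical GT..AG motifs in
coding orientation; strands are drawn at random where the scenario
allows. Scenario-specific constructions:

- *frame_restore* plants a 1-bp insertion and a nearby 1-bp deletion
  inside a run of codons drawn from {C,G}³ — no reading frame over such a
  region can form a stop, so ORF preservation is guaranteed analytically.
- *frameshift_stop* plants the codons `ATA AGC` and deletes the leading
  A, forcing the shifted frame to read `TAA` at a known codon, which
  fixes the expected stop percentage exactly.
- *missense_joint_codon* plants `CTG` with substitutions at codon
  positions 1 and 2 (jointly `TCG`, serine; the first alone `TTG`,
  synonymous).
- *splice_guard* builds a minus-strand locus whose intron ends in
  `CCCAG` directly before an exon starting with `T`, so the compound
  allele `CCCAGT→CCCAGC` spans the donor dinucleotide while its only
  mismatch is a synonymous third-position change.
- *boundary_insertion*, *splice_hit*, *full_deletion*, *synonymous*,
  *intact* and *compound_decomposition* (the worked ref/alt allele pairs,
  embedded verbatim into a fixture chromosome) cover the remaining
  behaviors.

What the fixtures do **not** emulate: real splice-site sequence context
beyond the dinucleotides, genotype/phasing structure (all variants are
treated as co-occurring), sequencing error, multi-ALT sites, structural
variants, or realistic genome/transcript sizes. Passing tests therefore
demonstrate correctness of the annotation logic, not calibration against
any particular organism's variant spectrum.

## Problem sizes and numerics

The test and acceptance workloads use small random loci (CDS ≤ ~120 bp,
1–4 exons) at counts chosen to exercise the combinatorics thoroughly:
10⁴ decomposition fuzz pairs, 10³ joint-application oracle comparisons,
10³ interval-tree queries against an all-pairs scan, 10² frame-restoration
cases, all 190 Grantham pairs. Reported percentages are exact rational
arithmetic in floating point; the only tolerance used in tests is
`pytest.approx` on stop percentages. Ties and degenerate inputs are
handled deterministically: introns shorter than 2 bp clamp their splice
windows to the intron; an indel overlapping both CDS and a splice window
is splice-classified; empty variant sets yield `ORF_INTACT`.

## Known limitations

- Splice sites are modelled as the AG/GT dinucleotides only; no strength
  model, and no re-prediction of splicing after a splice hit.
- Compound records are decomposed against the reference orientation
  only; alleles are not re-left-aligned against the genome beyond the
  record's own coordinates.
- The VCF reader skips malformed records where the underlying htslib
  parser can recover; an irrecoverably corrupt stream is fatal.
- No NMD prediction; the 70% internal-stop threshold is reporting-only.
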