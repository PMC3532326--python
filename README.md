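# jointvar

Database-independent annotation of the **joint** impact of co-occurring
genomic variants (SNVs, insertions, deletions) on protein-coding
transcripts.

## The problem

Most variant-effect annotators score each variant against a transcript in
isolation. That is wrong whenever nearby variants alter each other's
effect: a 1-bp deletion can restore the open reading frame broken by a
nearby 1-bp insertion, and two substitutions in the same codon can turn an
apparently synonymous change into a missense one. Tools tied to annotation
databases are also unusable for organisms absent from those databases.

`jointvar` needs only three inputs — variants (VCF 4.x or a simple
tab-delimited format), a reference genome (FASTA), and protein-coding exon
(CDS) coordinates (GFF3 or GTF) — and evaluates **all variants affecting a
transcript together**.

## What it computes

1. **Compound-allele decomposition.** A VCF record with ref `ATG` and alt
   `AC` encodes two atomic changes. The first min(|ref|, |alt|) bases are
   compared position-wise (each mismatch is an SNV) and the unmatched tail
   becomes a single insertion or deletion, so `ATG→AC` yields the SNV T→C
   plus a 1-bp deletion of G.
2. **Per-variant Sequence Ontology categories** (GVF 1.05 vocabulary):
   `synonymous_codon`, `conservative_missense_codon`,
   `non_conservative_missense_codon`, `stop_gained`, `stop_lost`,
   `splice_acceptor_variant`, `splice_donor_variant`, `silent_mutation`
   for SNVs; `frameshift_variant`, `inframe_variant`, splice and silent
   categories for indels. The variant codon carries *all* co-occurring
   same-codon substitutions at once. Missense changes are graded by the
   Grantham (1974) amino-acid distance *d*: CONSERVATIVE (*d* ≤ 50),
   MODERATELY_CONSERVATIVE (≤ 100), MODERATELY_RADICAL (≤ 150), RADICAL
   (> 150); the first two map to `conservative_missense_codon`, the last
   two to `non_conservative_missense_codon`.
3. **Per-transcript ORF status** after applying all variants jointly:
   `ORF_INTACT` (untouched), `ORF_PRESERVED` (variants present, but no new
   internal stop and no splice-dinucleotide hit), `ORF_DISRUPTED` (new
   internal stop or splice-site variant — with the location of the first
   internal stop as a percentage of the reference peptide length), and
   `FULLY_DELETED`. A transcript whose *reference* translation already
   contains an internal stop is exempt from the internal-stop criterion.
4. **Sequence outputs**: variant CDS and protein FASTA, per-exon reference
   and variant FASTA, and per-exon reference/variant alignments with
   variant bases in UPPERCASE and `-` gaps.
5. **Summaries**: ORF-status counts, synonymous-vs-non-synonymous codon
   bias, indel length histograms (genome-wide vs CDS-impacting), a
   multi-category SNV list (variants classified differently across
   transcripts), and optional Circos-compatible density tracks.
6. **Region tools**: `map-protein` projects amino-acid ranges (e.g.
   protein domains) through the exon structure to genomic coordinates;
   `annotate-regions` marks GVF variants with any overlapping regions via
   interval trees.

## Worked example

```bash
jointvar make-fixture --scenario missense_joint_codon --seed 1 --out demo
jointvar annotate --vcf demo/variants.vcf --ref demo/genome.fa \
                  --exons demo/transcripts.gff3 --out demo/out
```

prints

```
annotated 2 component variants against 1 transcripts (0 intact, 1 preserved, 0 disrupted, 0 fully deleted)
```

The fixture plants two SNVs (`chr1:58 C→T` and `chr1:59 T→C`) in one codon
of a transcript whose reference codon is `CTG` (leucine). Each SNV alone
would be harmless or mild — `C→T` alone gives `TTG`, still leucine — but
together they produce `TCG` (serine). `demo/out/variants.gvf` reports
exactly that joint call for both substitutions:

```
chr1  jointvar  non_conservative_missense_codon  58  58  .  +  .  ID=GV_1;Variant_seq=T;Reference_seq=C;jointvar_kind=SNV;Variant_effect=non_conservative_missense_codon 0 mRNA t1;jointvar_codon_change=t1:CTG>TCG;jointvar_aa_change=t1:L>S;jointvar_grantham=t1:MODERATELY_RADICAL:145
```

The Grantham distance L↔S is 145 (MODERATELY_RADICAL), hence
`non_conservative_missense_codon`. The transcript keeps its reading frame,
so `demo/out/transcripts.gff3` records `orf_status=ORF_PRESERVED`.

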