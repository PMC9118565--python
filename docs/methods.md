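# Methods

## Coordinates and interval arithmetic

All coordinates are 0-based half-open internally; GTF/GFF3/RepeatMasker/
VCF are converted on read and restored on write. Every overlap statistic
reduces to three primitives (union-merge, union length, two-pointer
intersection of unions) in `lncscape.intervals`; the tests check each of
them, and every downstream overlap quantity, against per-base brute-force
oracles. Overlaps are always computed on interval *unions*, so a base
covered by two exons or two TE copies of the same transcript is never
counted twice (TE copies in `te_class_distribution` are the one deliberate
exception: composition is tallied per TE record, since two inserted
copies genuinely contribute two stretches of TE sequence).

## Identification and classification

A candidate transcript becomes a lncRNA iff (I) spliced length > 200 bp,
(II) noncoding by both coding-potential predictors, (III) free of
Swiss-Prot/Pfam/Rfam homologs, and (IV) max-across-tissues FPKM > 0.5 for
single-exon or > 0.1 for multi-exon transcripts. All inequalities are
strict, exactly as printed; a transcript of length 200 or FPKM 0.5 fails.
Criteria II–III are consumed as a boolean flag table — running the
predictors is out of scope. Every failed criterion is recorded, not just
the first. The expression criterion uses the maximum over tissues (the
per-tissue-any variant is a flag): a transcript well expressed in one
tissue should survive.

Survivors are classed by strand-aware exon overlap with coding genes:

- **sense_overlap_excluded** — ≥ 1 bp exon overlap with a same-strand
  coding exon. This takes precedence over the antisense test: a
  transcript sharing sense exonic sequence with a coding gene cannot be
  distinguished from an isoform fragment and is excluded before antisense
  classing. (Which order applies when a transcript overlaps exons on
  both strands is not externally specified; this is the package's
  choice, and the category is reported, not dropped.)
- **lncNAT** — ≥ 1 bp of exon overlap antisense to a coding exon
  (threshold configurable; no minimum is externally specified).
- **intronic** — inside a gene span but exon-free on both strands;
  reported separately and excluded from the two headline classes.
- **lincRNA** — everything else: outside all gene spans. No distance
  buffer is applied by default (configurable, default 0).

The classifier is validated against a per-base brute-force classifier on
100 seeded random annotations and recovers 100 % of the classes planted
by the synthetic generator.

## Molecular features

Length is spliced (exonic) length. The splicing ratio of a class is the
fraction of transcripts with ≥ 2 exons; junction-read-based definitions
need raw reads, which are out of scope. GC is computed over the exon
union with ambiguous bases (N) removed from numerator and denominator.
SNP density divides the filtered SNP count inside the class exon union by
the union length in kb — normalizing per class union, not per transcript,
so overlapping transcripts are not double counted. SNPs are retained at
QUAL > 10 and depth > 5 (strict); "quality" is taken as VCF QUAL
(genotype quality is a configurable alternative; the source of depth is
INFO/DP falling back to summed FORMAT/DP). Intergenic control intervals
are drawn uniformly from the complement of gene spans with lengths
resampled from a caller-supplied sampler (typically the lincRNA length
distribution) for a fair GC/conservation comparison.

Splice-site profiles cover `2*flank + 2` bases per junction in transcript
orientation, centered on the donor GT / acceptor AG dinucleotide;
minus-strand windows are reverse-complemented, so a locus flipped to the
other strand yields the identical profile (asserted in tests).

## TE origination

A TE-lncRNA has ≥ 5 bp of exonic TE overlap; gene-body overlap uses the
genomic span. For coding genes the "exonic" variant uses the CDS (a
UTR-inclusive mode exists). Promoters are the 1 kb immediately upstream
of the TSS, strand-aware, clipped at chromosome ends — no promoter extent
is externally specified and 1 kb is the common plant convention. A
promoter is TE-derived when a TE covers the TSS base OR TE coverage of
the window is ≥ 50 % (both clauses configurable); the TSS clause captures
the case of a TE directly providing the transcription start. A TF site
originates from a TE when a ChIP peak summit falls inside the
intersection of the promoter window with a TE; peaks without summits fall
back to their midpoints (logged). Class I = retrotransposons
(LINE/SINE/LTR/Retroposon RepeatMasker families), Class II = DNA
transposons (DNA/RC/Helitron/TIR/MITE); other repeat families are
excluded from the I:II normalization and reported separately.

## Conservation

Scores live on a per-base track in [0, 1] (PhastCons-style; produced
externally, consumed as bedGraph). Per-transcript means and the patch
scan run over the *spliced* transcript — concatenated exons, 5'→3' —
so introns never contribute; whether the original analysis used exonic
or full-locus bases is unstated, and exonic matches the statistic's
purpose (describing the transcript). Missing bases are excluded from
means; a window containing any missing base is disqualified rather than
imputed (configurable by re-scoring the track). A conserved patch needs a
12 bp window mean > 0.6 (strict) inside a transcript with overall mean
< 0.3 (strict); transcripts shorter than the window are flagged, never
called. Note the patch list contains *every* qualifying window position,
including windows partially covering a planted run.

Homology retention between species a and b is the fraction of a's
lincRNAs with ≥ 1 blastn hit to b's genome passing e-value ≤ 1e-5 and
alignment length ≥ 50 bp. No cutoffs are externally specified; these
defaults are standard blastn practice, configurable, and echoed into the
output metadata. Matrix entries are monotone in both thresholds
(asserted).

## Tissue specificity

For an expression vector normalized to p, the specificity against tissue
t is `1 − sqrt(JSD₂(p, e_t))` with the Jensen-Shannon divergence in bits
(0·log 0 := 0) and e_t the indicator distribution; the transcript's JS
score is the maximum over tissues, ties broken by tissue order. A score
of 1 means expression confined to one tissue. A perfectly uniform vector
does **not** score 0 — the indicator comparison has a positive floor
(≈ 0.219 for five tissues) that shrinks with the tissue count; the
informal reading "0 = expressed in all tissues" holds only approximately
and is documented rather than silently "fixed". All-zero vectors are
flagged as undefined, not scored 0. Scores are computed on raw FPKM by
default with a log10(x+1) flag (whether the original tooling
log-transforms first is unknown). TS calls use JS ≥ 0.9, inclusive as
printed.

Co-expression candidates: lncNATs expressed (FPKM ≥ 0.1, configurable —
"expressed in a tissue" needs a floor) in exactly 1–2 tissues with max
FPKM in the top 10 % of lncNAT max-FPKMs (ranked within the
tissue-count-passing set by default; whole-class ranking by flag);
lincRNAs in 1–2 tissues with max FPKM > 1 (strict); mRNAs with max
FPKM > 1. Network construction itself is out of scope.

## Synthetic data

The generator emits one chromosome (default 400 kb) carrying
non-overlapping gene loci, lincRNAs ≥ 1.5 kb from any gene, lncNATs
placed antisense over host-gene exons, and decoys failing exactly one
identification criterion each plus one sense-overlapping and one
intronic transcript. Defaults mirror reported plant lncRNA structure:
65 % single-exon lincRNAs, 82 % single-exon lncNATs, 22 % single-exon
mRNAs; TE-lncRNA fraction 0.40; TE-promoter fractions 0.38 (lincRNA) and
0.27 (lncNAT); conservation gradient CDS ≈ 0.7 > UTR ≈ 0.4 > lncRNA
exons 0.03 > intergenic 0.02 with five planted 12 bp patches at 0.9;
SNP densities 4/3/1 per kb for lincRNA/lncNAT/CDS; lncRNA expression low
(FPKM 2–30) and tissue-skewed (40 % single-tissue, 20 % two-tissue)
against high broad mRNA expression (20–200). Splice junctions are written
as canonical GT..AG. Randomness uses one fixed substream per component,
so adding a component never perturbs the others, and identical seeds
give byte-identical files.

What the generator does *not* emulate: realistic sequence content of
repeats (TEs are coordinates with class labels), read-level noise,
isoform structure, overlapping genes, multi-chromosome genomes, or
biologically calibrated FPKM distributions. A green planted-truth test
therefore establishes the *logic* of each statistic (thresholds, strand
handling, coordinate arithmetic), not performance on real data.

A separate boundary bundle plants transcripts straddling every printed
threshold: lengths 199/200/201; max FPKM at and 1e-6 above 0.5 and 0.1;
TE exon overlap 4 vs 5 bp; 12 bp window means 0.55/0.60/0.65 plus the
50-base worked case (whole mean 12·0.9/50 = 0.216, best window 0.9);
and JS 1e-4 below/above 0.9. JS boundary vectors are solved numerically
(Brent's method on the two-tissue score); a vector whose score is
bit-exactly 0.9 is not representable robustly, so the inclusive
threshold semantics is asserted directly on an exact 0.9 score in unit
tests.

## Numerical choices

- Window means use a cumulative-sum scan (O(n) per transcript) with a
  parallel cumulative count of missing bases to disqualify windows.
- JS divergence is delegated to `scipy.spatial.distance.jensenshannon`
  (base 2); tests cross-check against a hand-written entropy formula to
  1e-9. Pearson correlations delegate to `scipy.stats.pearsonr`,
  cross-checked against the covariance formula to 1e-12.
- Zero-variance vectors yield NaN correlations (flagged), never errors;
  empty region sets yield NaN fractions.
- Intergenic control placement retries up to 200 times per interval and
  then reports the deficit, rather than looping forever on a crowded
  genome.

## Known limitations

- lncNAT/antisense pairing is exon-overlap based; chromatin-level or
  head-to-head (divergent-promoter) antisense relationships are not
  modeled.
- Coding-potential, database-homology and peak calling are consumed as
  upstream results; the package neither runs nor re-implements CPC,
  PLEK, BLAST or MACS.
- The homology matrix counts hit existence only; it does not align
  transcripts or assess synteny.
- bedGraph tracks are fully expanded in memory (fine for desk-scale
  genomes; a chromosome of hundreds of Mb would need a chunked reader).
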