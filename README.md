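# lncscape

Strand-specific identification, classification and characterization of
plant long non-coding RNAs (lncRNAs) from genome annotations.

Plant transcriptomes contain tens of thousands of lncRNAs, most of them
either **lincRNAs** (transcribed from intergenic regions) or **lncNATs**
(natural antisense transcripts overlapping exons of coding genes on the
opposite strand). Telling the two apart — and characterizing how they
arise (transposable-element insertion), how conserved they are, and where
they are expressed — requires stranded transcript models and careful
strand-aware interval arithmetic. `lncscape` packages that analysis as a
tested Python library for researchers working with stranded RNA-seq
assemblies of plant (or any eukaryotic) genomes.

## What it computes

- **Identification** — a transcript is accepted as a lncRNA iff
  1. spliced length > 200 bp (strict);
  2. predicted noncoding by both coding-potential predictors (CPC/PLEK
     consumed as a boolean flag table);
  3. no homolog in Swiss-Prot/Pfam/Rfam (flag table);
  4. max FPKM across tissues > 0.5 (single-exon) or > 0.1 (multi-exon).
- **Classification** — survivors with ≥ 1 bp of exon overlap antisense to
  a coding exon are lncNATs; survivors clear of all genes are lincRNAs;
  sense-exonic and intron-only overlappers are surfaced as explicit
  categories.
- **Molecular features** — spliced length, exon count, splicing ratio
  (fraction with ≥ 2 exons), GC over exonic sequence, SNPs per kb of the
  class exon union (VCF filtered at QUAL > 10 and DP > 5), splice-site
  base profiles, length-matched intergenic controls.
- **TE origination** — TE-lncRNAs (≥ 5 bp exonic TE overlap), Class I/II
  TE base composition per region set, TE-derived promoters (TE covers the
  TSS, or ≥ 50 % of the 1 kb upstream window), TF-peak summits inside
  TE-derived promoter segments, and the across-species Pearson
  correlation of TE-promoter fraction vs genomic TE content.
- **Conservation** — per-transcript mean PhastCons score over the spliced
  sequence; conserved patches (a 12 bp sliding window with mean > 0.6
  inside a transcript whose overall mean is < 0.3); a species × species
  homolog-retention matrix from blastn tabular hits.
- **Expression** — Jensen-Shannon tissue specificity
  `JS = max_t (1 − sqrt(JSD₂(p, e_t)))` with JSD in bits, TS calls at
  JS ≥ 0.9, per-tissue log₁₀(FPKM+1) summaries, lncNAT/antisense-gene
  correlation, and co-expression (WGCNA input) candidate selection.
- **Synthetic data** — a seeded generator that emits every input file
  format with planted ground truth, so the whole pipeline is testable
  offline; identical seeds give byte-identical bundles.

## Worked example

```python
import tempfile
from lncscape import GeneratorConfig, generate_dataset
from lncscape.classify import (apply_identification_filters,
                               classify_transcripts)

b = generate_dataset(GeneratorConfig(seed=42), tempfile.mkdtemp())
ftab = apply_identification_filters(b.candidates, b.flags, b.expression)
pending = [t for t in b.candidates if t.transcript_id
           in set(ftab.loc[ftab.cls == "pending", "transcript_id"])]
print(classify_transcripts(pending, b.genes)["cls"].value_counts())
```

prints

```
lincRNA                   25
lncNAT                    15
sense_overlap_excluded     1
intronic                   1
```

— the 25 intergenic and 15 antisense lncRNAs planted by the generator are
recovered exactly; the transcript overlapping a coding exon on the same
strand and the intron-confined transcript are reported in their own
categories rather than silently dropped (four further decoys fail the
identification criteria, one per criterion).

The `examples/` directory walks every capability end to end
(`python examples/02_identify_and_classify.py`, ...), each printing the
numbers it computes and what they mean. `examples/07_full_pipeline.py`
runs all stages from files through one `RunConfig` and writes a
checksummed output manifest; optional inputs that are absent skip their
stage with an explicit `skipped` status.

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantity from
scratch — it runs `js_specificity` on an expression vector confined to
one of five tissues and reports the resulting JS score — and additionally
runs the full pipeline on a freshly generated synthetic bundle as a
self-check:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/lncscape/` — `intervals`, `models`, `io`, `classify`, `features`,
  `te_origin`, `conservation`, `expression`, `synthetic`, `pipeline`
- `tests/` — unit + property tests with per-base brute-force oracles,
  plus an acceptance suite (`tests/test_acceptance.py`)
- `docs/methods.md` — the model, parameter defaults, numerical choices
  and known limitations
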