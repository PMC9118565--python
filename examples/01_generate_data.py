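"""Generate a seeded synthetic input bundle and look at its ground truth.

The bundle contains every file the pipeline consumes (genome FASTA,
gene GFF3, candidate GTF, RepeatMasker table, conservation bedGraph, VCF,
expression/flag TSVs, ChIP narrowPeak, blastn hit tables) plus a truth
table of the planted labels. Identical seeds give byte-identical files.
"""

import tempfile

from lncscape import GeneratorConfig, generate_dataset

bundle = generate_dataset(GeneratorConfig(seed=42), tempfile.mkdtemp())

print(f"bundle written to {bundle.outdir}")
print(f"{len(bundle.genes)} coding genes, {len(bundle.candidates)} candidate "
      f"transcripts, {len(bundle.tes)} TE copies, "
      f"{len(bundle.variants)} VCF records")
print("\nplanted class counts (what a perfect classifier must recover):")
print(bundle.truth.transcripts["planted_cls"].value_counts().to_string())
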