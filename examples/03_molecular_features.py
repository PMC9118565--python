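"""Per-class molecular features: length, exons, splicing, GC, SNP density.

lncRNAs are expected shorter, less spliced and SNP-denser than mRNAs;
the table below is computed from the synthetic bundle, where those
contrasts are planted.
"""

import tempfile

from lncscape import GeneratorConfig, generate_dataset
from lncscape.classify import apply_identification_filters, classify_transcripts
from lncscape.features import feature_summary, splice_site_profile
from lncscape.io import read_vcf_filtered

b = generate_dataset(GeneratorConfig(seed=42), tempfile.mkdtemp())
ftab = apply_identification_filters(b.candidates, b.flags, b.expression)
pending = [t for t in b.candidates
           if t.transcript_id in set(ftab.loc[ftab.cls == "pending", "transcript_id"])]
cls = classify_transcripts(pending, b.genes).set_index("transcript_id")["cls"]

by_class = {
    "lincRNA": [t for t in pending if cls[t.transcript_id] == "lincRNA"],
    "lncNAT": [t for t in pending if cls[t.transcript_id] == "lncNAT"],
    "mRNA": [g.transcripts[0] for g in b.genes],
}
variants = read_vcf_filtered(str(b.paths["vcf"]))  # qual > 10, depth > 5

summary = feature_summary(by_class, genome=b.genome, variants=variants)
print("per-class feature panel (length = spliced length, snp_per_kb over "
      "the class exon union):")
print(summary.round(3).to_string())

prof = splice_site_profile([t for t in pending if t.n_exons > 1], b.genome)
d0, d1 = prof.core
gt = prof.donor_counts.loc[d0, "G"] + prof.donor_counts.loc[d1, "T"]
print(f"\n{prof.n_junctions} junctions profiled; GT at the donor core "
      f"{gt}/{2 * prof.n_junctions} bases (canonical splicing)")
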