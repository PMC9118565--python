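"""Identify lncRNAs (the four criteria) and split them into lincRNA/lncNAT.

A transcript survives identification iff it is longer than 200 bp,
noncoding by both predictors, database-homology-free, and expressed above
the FPKM floor (0.5 single-exon / 0.1 multi-exon, strict). Survivors with
>= 1 bp of exon overlap antisense to a coding exon are lncNATs; survivors
clear of all genes are lincRNAs.
"""

import tempfile

from lncscape import GeneratorConfig, generate_dataset
from lncscape.classify import (
    apply_identification_filters,
    classification_report,
    classify_transcripts,
)

b = generate_dataset(GeneratorConfig(seed=42), tempfile.mkdtemp())

ftab = apply_identification_filters(b.candidates, b.flags, b.expression)
pending_ids = set(ftab.loc[ftab.cls == "pending", "transcript_id"])
pending = [t for t in b.candidates if t.transcript_id in pending_ids]
ctab = classify_transcripts(pending, b.genes)
report = classification_report(ftab, ctab)

print("class counts (filtered_out = failed an identification criterion):")
print(report["cls"].value_counts().to_string())

failed = report[report["cls"] == "filtered_out"]
print("\nwhy candidates were filtered out:")
for r in failed.itertuples():
    print(f"  {r.transcript_id}: {', '.join(sorted(r.fail_reasons))}")

nats = report[report["cls"] == "lncNAT"].head(3)
print("\nfirst lncNATs with their antisense partners and overlap (bp):")
for r in nats.itertuples():
    print(f"  {r.transcript_id}: {r.antisense_partner_genes} "
          f"({r.antisense_overlap_bp} bp antisense exon overlap)")
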