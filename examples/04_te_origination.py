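"""TE origination: exonic TE overlap, TE-derived promoters, TF sites.

A TE-lncRNA has >= 5 bp of exon sequence overlapping a transposable
element. A promoter (1 kb upstream of the TSS, strand-aware) is
TE-derived when a TE covers the TSS base or at least half of the window.
"""

import tempfile

import pandas as pd

from lncscape import GeneratorConfig, generate_dataset
from lncscape.classify import apply_identification_filters, classify_transcripts
from lncscape.te_origin import (
    te_class_distribution,
    te_derived_promoters,
    te_overlap,
    te_promoter_genome_correlation,
    tf_sites_in_te_promoters,
)

b = generate_dataset(GeneratorConfig(seed=42), tempfile.mkdtemp())
ftab = apply_identification_filters(b.candidates, b.flags, b.expression)
pending = [t for t in b.candidates
           if t.transcript_id in set(ftab.loc[ftab.cls == "pending", "transcript_id"])]
cls = classify_transcripts(pending, b.genes).set_index("transcript_id")["cls"]
by_class = {c: [t for t in pending if cls[t.transcript_id] == c]
            for c in ("lincRNA", "lncNAT")}

table, ratios = te_overlap({**by_class, "coding": b.genes}, b.tes, min_bp=5)
print("fraction of each class with >= 5 bp exonic TE overlap "
      "(CDS for coding genes):")
print(ratios.round(3).to_string())

regions = {
    "genome": {"chr1": [(0, b.chrom_sizes["chr1"])]},
    "lincRNA": {"chr1": [p for t in by_class["lincRNA"] for p in t.exon_pairs]},
}
dist = te_class_distribution(b.tes, regions)
print("\nClass I (retrotransposon) vs II (DNA transposon) TE bases:")
print(dist[["class_I_frac", "class_II_frac"]].round(3).to_string())

calls, fractions = te_derived_promoters(by_class, b.tes, chrom_sizes=b.chrom_sizes)
print("\nfraction of transcripts with TE-derived promoters:")
print(fractions.round(3).to_string())

tf_table, freq = tf_sites_in_te_promoters(calls, b.peaks, b.tes)
n_in_te = int(tf_table["tf_hit_in_te"].sum())
print(f"\n{n_in_te} transcripts carry a TF peak summit inside a TE-derived "
      f"promoter segment (TF binding supplied by the TE)")

# across hypothetical species: TE-promoter fraction tracks genomic TE content
per_species = pd.DataFrame(
    {"genome_te_frac": [0.1, 0.25, 0.4, 0.6, 0.8],
     "lincRNA": [0.15, 0.3, 0.42, 0.55, 0.78]}
)
r = te_promoter_genome_correlation(per_species)["lincRNA"]
print(f"\nPearson r (TE-promoter fraction vs genomic TE content): {r:.3f}")
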