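"""Run the whole pipeline from files via one config and read the manifest.

Every stage consumes the file formats a real analysis would (GTF, GFF3,
FASTA, RepeatMasker .out, bedGraph, VCF, narrowPeak, TSV); optional
inputs that are missing skip their stage with an explicit status.
"""

import json
import tempfile
from pathlib import Path

from lncscape import GeneratorConfig, RunConfig, generate_dataset, run

tmp = Path(tempfile.mkdtemp())
b = generate_dataset(GeneratorConfig(seed=42), tmp / "bundle")

res = run(RunConfig(
    gtf=str(b.paths["gtf"]),
    flags=str(b.paths["flags"]),
    expression=str(b.paths["expression"]),
    genes_gff3=str(b.paths["genes_gff3"]),
    fasta=str(b.paths["fasta"]),
    repeats=str(b.paths["repeats"]),
    bedgraph=str(b.paths["bedgraph"]),
    vcf=str(b.paths["vcf"]),
    peaks=str(b.paths["peaks"]),
    out_dir=str(tmp / "out"),
    seed=42,
))

man = json.loads(res.manifest_path.read_text())
print("stage statuses:")
for name, info in man["stages"].items():
    print(f"  {name}: {info['status']}")
print("\nclassification counts:", man["stages"]["classify"]["counts"])
print("TE-lncRNA ratio per class:",
      {k: round(v, 3) for k, v in man["stages"]["te"]["te_lnc_ratio"].items()})
print("\noutputs (checksummed in the manifest):")
for fname in man["outputs"]:
    print(f"  {res.out_dir / fname}")
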