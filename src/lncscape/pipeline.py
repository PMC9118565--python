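"""End-to-end orchestration: classify -> features -> TE -> conservation ->
expression, from a single config, with a checksummed output manifest.

Each stage is an ordinary library function; ``run`` wires them together
on file inputs, logs row counts, skips stages whose optional inputs are
absent (recording an explicit "skipped" status) and aborts with the stage
name on failure. Outputs are deterministic for fixed inputs and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as lio
from .classify import (
    IdentificationThresholds,
    apply_identification_filters,
    classification_report,
    classify_transcripts,
)
from .conservation import conserved_patch_scan, homology_conservation_matrix
from .expression import call_ts, wgcna_candidate_selection
from .features import feature_summary
from .te_origin import PromoterRule, te_derived_promoters, te_overlap, tf_sites_in_te_promoters

logger = logging.getLogger("lncscape")

__all__ = ["RunConfig", "RunResult", "run"]


@dataclass
class RunConfig:
    """Inputs plus every analysis threshold (defaults = printed values)."""

    gtf: str
    flags: str
    expression: str
    genes_gff3: Optional[str] = None
    fasta: Optional[str] = None
    repeats: Optional[str] = None
    bedgraph: Optional[str] = None
    vcf: Optional[str] = None
    peaks: Optional[str] = None
    blast_hits: tuple[tuple[str, str, str], ...] = ()  # (path, qspecies, sspecies)
    species_transcripts: Optional[str] = None  # JSON: species -> transcript ids
    out_dir: str = "lncscape_out"
    seed: int = 0
    # identification (criteria I-IV)
    length_min: int = 200
    fpkm_single: float = 0.5
    fpkm_multi: float = 0.1
    # TE analyses
    te_min_bp: int = 5
    promoter_size: int = 1000
    promoter_cover_frac: float = 0.5
    # conservation
    patch_window: int = 12
    patch_min: float = 0.6
    whole_max: float = 0.3
    evalue_max: float = 1e-5
    min_len: int = 50
    # expression
    ts_threshold: float = 0.9
    expressed_min: float = 0.1
    top_frac: float = 0.10
    fpkm_min: float = 1.0
    # SNP filter
    vcf_qual: float = 10.0
    vcf_depth: int = 5


@dataclass
class RunResult:
    out_dir: Path
    stages: dict[str, dict]
    manifest_path: Path

    def status(self, stage: str) -> str:
        return self.stages[stage]["status"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    outputs: list[Path] = []

    def stage(name: str):
        def deco(fn):
            try:
                info = fn()
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            stages[name] = {"status": "ok", **(info or {})}
            logger.info("stage %s: %s", name, stages[name])
            return None
        return deco

    def skip(name: str, why: str):
        stages[name] = {"status": "skipped", "reason": why}
        logger.info("stage %s skipped: %s", name, why)

    # ---- load shared inputs ----
    transcripts = lio.read_gtf(config.gtf)
    flags = lio.read_flags_tsv(config.flags)
    expr = lio.read_expression_tsv(config.expression)
    genes = lio.read_gff3_genes(config.genes_gff3) if config.genes_gff3 else []

    thresholds = IdentificationThresholds(
        length_min=config.length_min,
        fpkm_single=config.fpkm_single,
        fpkm_multi=config.fpkm_multi,
    )

    state: dict = {}

    @stage("classify")
    def _classify():
        ftab = apply_identification_filters(transcripts, flags, expr, thresholds)
        pending_ids = set(ftab.loc[ftab["cls"] == "pending", "transcript_id"])
        pending = [t for t in transcripts if t.transcript_id in pending_ids]
        ctab = classify_transcripts(pending, genes)
        report = classification_report(ftab, ctab)
        by_id = dict(zip(report["transcript_id"], report["cls"]))
        lnc = [t for t in pending if by_id[t.transcript_id] in ("lincRNA", "lncNAT")]
        lio.write_gff3(
            lnc, out / "lncRNAs.gff3",
            classes={t.transcript_id: by_id[t.transcript_id] for t in lnc},
        )
        rep = report.copy()
        rep["fail_reasons"] = rep["fail_reasons"].map(lambda s: ";".join(sorted(s)))
        rep["antisense_partner_genes"] = rep["antisense_partner_genes"].map(
            lambda g: ";".join(g)
        )
        rep.to_csv(out / "classification.tsv", sep="\t", index=False)
        outputs.extend([out / "lncRNAs.gff3", out / "classification.tsv"])
        state["report"] = report
        state["by_class"] = {
            cls: [t for t in pending if by_id[t.transcript_id] == cls]
            for cls in ("lincRNA", "lncNAT")
        }
        counts = report["cls"].value_counts().to_dict()
        return {"rows": len(report), "counts": counts}

    by_class = dict(state["by_class"])
    mrnas = [g.transcripts[0] for g in genes if g.transcripts]
    if mrnas:
        by_class["mRNA"] = mrnas

    genome = lio.read_fasta(config.fasta) if config.fasta else None

    if config.vcf and Path(config.vcf).exists():
        variants = lio.read_vcf_filtered(
            config.vcf, min_qual=config.vcf_qual, min_depth=config.vcf_depth
        )
        stages["snp_filter"] = {"status": "ok", "rows": len(variants)}
    else:
        variants = None
        skip("snp_filter", "no VCF provided")

    @stage("features")
    def _features():
        summary = feature_summary(by_class, genome=genome, variants=variants)
        summary.to_csv(out / "feature_summary.tsv", sep="\t")
        outputs.append(out / "feature_summary.tsv")
        return {"rows": len(summary)}

    if config.repeats and Path(config.repeats).exists():
        tes = lio.read_repeatmasker_out(config.repeats)

        @stage("te")
        def _te():
            units = dict(by_class)
            if genes:
                units["coding"] = genes  # CDS used for the exonic variant
            table, ratios = te_overlap(units, tes, min_bp=config.te_min_bp)
            table.to_csv(out / "te_overlap.tsv", sep="\t", index=False)
            lnc_classes = {
                c: by_class[c] for c in ("lincRNA", "lncNAT") if c in by_class
            }
            calls, fractions = te_derived_promoters(
                lnc_classes, tes,
                PromoterRule(size=config.promoter_size,
                             cover_frac=config.promoter_cover_frac),
            )
            calls.to_csv(out / "te_promoters.tsv", sep="\t", index=False)
            with open(out / "te_promoters.bed", "w") as fh:
                for r in calls[calls["te_derived"]].itertuples():
                    fh.write(
                        f"{r.chrom}\t{r.promoter_start}\t{r.promoter_end}\t"
                        f"{r.transcript_id}\t0\t{r.strand}\n"
                    )
            outputs.extend(
                [out / "te_overlap.tsv", out / "te_promoters.tsv", out / "te_promoters.bed"]
            )
            info = {"rows": len(table), "te_lnc_ratio": ratios.to_dict(),
                    "te_promoter_frac": fractions.to_dict()}
            if config.peaks and Path(config.peaks).exists():
                peaks = lio.read_peaks(config.peaks)
                tf_table, freq = tf_sites_in_te_promoters(calls, peaks, tes)
                tf_out = tf_table.copy()
                tf_out["tf_hits"] = tf_out["tf_hits"].map(lambda x: ";".join(x))
                tf_out.to_csv(out / "tf_in_te_promoters.tsv", sep="\t", index=False)
                outputs.append(out / "tf_in_te_promoters.tsv")
                info["tf_in_te_count"] = int(tf_table["tf_hit_in_te"].sum())
            return info
    else:
        skip("te", "no RepeatMasker table provided")

    if config.bedgraph and Path(config.bedgraph).exists():
        track = lio.read_conservation_bedgraph(config.bedgraph)

        @stage("conservation")
        def _conservation():
            rows = []
            for cls in ("lincRNA", "lncNAT"):
                for t in by_class.get(cls, []):
                    call = conserved_patch_scan(
                        t, track, window=config.patch_window,
                        patch_min=config.patch_min, whole_max=config.whole_max,
                    )
                    rows.append(
                        {
                            "transcript_id": call.transcript_id, "cls": cls,
                            "whole_mean": call.whole_mean,
                            "best_window_mean": call.best_window_mean,
                            "n_patches": len(call.patches),
                            "has_conserved_patch": call.has_conserved_patch,
                            "flagged": call.flagged,
                        }
                    )
            patch_df = pd.DataFrame(rows)
            patch_df.to_csv(out / "conserved_patches.tsv", sep="\t", index=False)
            outputs.append(out / "conserved_patches.tsv")
            return {"rows": len(patch_df),
                    "n_with_patch": int(patch_df["has_conserved_patch"].sum())
                    if len(patch_df) else 0}
    else:
        skip("conservation", "no conservation bedGraph provided")

    if config.blast_hits and config.species_transcripts:
        @stage("homology")
        def _homology():
            hits = []
            for path, qsp, ssp in config.blast_hits:
                hits.extend(lio.read_blast_tab(path, qsp, ssp))
            with open(config.species_transcripts) as fh:
                species_tx = json.load(fh)
            mat = homology_conservation_matrix(
                hits, species_tx,
                evalue_max=config.evalue_max, min_len=config.min_len,
            )
            mat.to_csv(out / "homology_matrix.tsv", sep="\t")
            outputs.append(out / "homology_matrix.tsv")
            return {"rows": len(mat), "evalue_max": config.evalue_max,
                    "min_len": config.min_len}
    else:
        skip("homology", "no blast hit tables provided")

    @stage("expression")
    def _expression():
        scores = call_ts(expr, ts_threshold=config.ts_threshold)
        scores.to_csv(out / "js_scores.tsv", sep="\t")
        class_ids = {c: [t.transcript_id for t in ts] for c, ts in by_class.items()}
        selection = wgcna_candidate_selection(
            expr, class_ids,
            expressed_min=config.expressed_min,
            top_frac=config.top_frac, fpkm_min=config.fpkm_min,
        )
        with open(out / "wgcna_candidates.json", "w") as fh:
            json.dump(
                {"lncNAT": list(selection.lncNAT),
                 "lincRNA": list(selection.lincRNA),
                 "mRNA": list(selection.mRNA),
                 "params": selection.params},
                fh, indent=1,
            )
        outputs.extend([out / "js_scores.tsv", out / "wgcna_candidates.json"])
        return {"rows": len(scores), "n_ts": int(scores["is_ts"].sum()),
                "n_selected": len(selection.all_selected)}

    manifest = {
        "config": asdict(config),
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return RunResult(out_dir=out, stages=stages, manifest_path=manifest_path)
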