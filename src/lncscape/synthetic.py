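"""Seeded synthetic genome/annotation bundles with planted ground truth.

The generator emits every input the pipeline consumes — genome FASTA,
coding-gene GFF3, candidate-transcript GTF, RepeatMasker-style TE table,
conservation bedGraph, VCF, expression TSV, candidate-flag TSV, ChIP
narrowPeak, blastn outfmt-6 hit tables — together with a ``SyntheticTruth``
table sufficient to score every analysis stage exactly.

Defaults mirror the reported structure of real plant data: 65% of
lincRNAs and 82% of lncNATs are single-exon against 22% of mRNAs; TE
class mix leans retrotransposon; conservation is graded CDS > UTR >
lncRNA > intergenic; lncRNA expression is low and tissue-skewed while
mRNA expression is high and broad. Identical seeds give byte-identical
bundles (one substream per component, so adding a component never
perturbs the others).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .intervals import GenomicInterval, merge_intervals, overlap_bp
from .models import (
    ConservationTrack,
    GeneModel,
    HomologyHit,
    Peak,
    TERecord,
    TranscriptModel,
    VariantRecord,
)

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticBundle",
           "generate_dataset", "plant_boundary_cases"]

# substream ids — fixed forever so adding components never reseeds others
_STREAMS = {
    "layout": 0, "sequence": 1, "expression": 2, "te": 3,
    "conservation": 4, "snp": 5, "peaks": 6, "homology": 7, "boundary": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass
class GeneratorConfig:
    seed: int = 0
    chrom: str = "chr1"
    genome_length: int = 400_000
    n_genes: int = 25
    n_lincRNA: int = 25
    n_lncNAT: int = 15
    tissues: tuple[str, ...] = ("root", "stem", "leaf", "flower", "seed")
    # single-exon fractions per class (reported plant structure)
    single_exon_linc: float = 0.65
    single_exon_nat: float = 0.82
    single_exon_mrna: float = 0.22
    # TE landscape
    n_background_te: int = 40
    te_class_I_frac: float = 0.6
    te_lnc_frac: float = 0.4          # lincRNAs with >= 5 bp exonic TE
    te_promoter_frac_linc: float = 0.38
    te_promoter_frac_nat: float = 0.27
    # conservation gradient (per-base PhastCons-like means)
    score_cds: float = 0.7
    score_utr: float = 0.4
    score_lnc: float = 0.03
    score_intergenic: float = 0.02
    n_patch_linc: int = 5             # lincRNAs with a planted conserved patch
    patch_score: float = 0.9
    patch_len: int = 12
    # expression profile mix for lncRNAs (single / two / broad)
    ts_frac: float = 0.4
    two_tissue_frac: float = 0.2
    # SNP density per kb of exon union
    snp_per_kb_linc: float = 4.0
    snp_per_kb_nat: float = 3.0
    snp_per_kb_cds: float = 1.0
    # homologs
    species: tuple[str, ...] = ("SppA", "SppB", "SppC")
    homology_fracs: tuple[tuple[str, str, float], ...] = (
        ("SppA", "SppB", 0.5), ("SppB", "SppA", 0.45),
        ("SppA", "SppC", 0.05), ("SppC", "SppA", 0.05),
        ("SppB", "SppC", 0.1), ("SppC", "SppB", 0.1),
    )
    n_te_tf_lnc: int = 6              # planted TF-summit-in-TE-promoter lncRNAs

    def validate(self) -> None:
        for name in ("single_exon_linc", "single_exon_nat", "single_exon_mrna",
                     "te_class_I_frac", "te_lnc_frac", "te_promoter_frac_linc",
                     "te_promoter_frac_nat", "ts_frac", "two_tissue_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_lncNAT > self.n_genes:
            raise ValueError("n_lncNAT must be <= n_genes (one host gene each)")
        if min(self.n_genes, self.n_lincRNA, self.n_lncNAT) < 0:
            raise ValueError("negative feature counts")
        if len(self.tissues) < 2:
            raise ValueError("need >= 2 tissues")


@dataclass
class SyntheticTruth:
    """Planted labels, one row per candidate transcript, plus side tables."""

    transcripts: pd.DataFrame      # indexed by transcript_id
    homology_expected: pd.DataFrame
    species_transcripts: dict[str, list[str]]
    snp_kept: int = 0
    snp_dropped: int = 0

    def write(self, outdir: Path) -> dict[str, Path]:
        paths = {
            "truth": outdir / "truth.tsv",
            "truth_homology": outdir / "truth_homology.tsv",
        }
        self.transcripts.to_csv(paths["truth"], sep="\t", index_label="transcript_id")
        self.homology_expected.to_csv(paths["truth_homology"], sep="\t")
        return paths


@dataclass
class SyntheticBundle:
    outdir: Path
    paths: dict[str, Path]
    truth: SyntheticTruth
    chrom_sizes: dict[str, int]
    # in-memory copies of everything written, for fast downstream use
    genome: dict[str, str]
    genes: list[GeneModel]
    candidates: list[TranscriptModel]
    tes: list[TERecord]
    peaks: list[Peak]
    variants: list[VariantRecord]
    hits: list[HomologyHit]
    expression: pd.DataFrame
    flags: pd.DataFrame
    track: ConservationTrack


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def spliced_to_genomic(
    exons: Sequence[GenomicInterval], strand: str, a: int, b: int
) -> list[tuple[int, int]]:
    """Map the spliced range [a, b) to genomic (start, end) pieces."""
    ordered = list(exons) if strand == "+" else list(exons)[::-1]
    out = []
    off = 0
    for ex in ordered:
        lo, hi = max(a, off), min(b, off + ex.length)
        if lo < hi:
            if strand == "+":
                out.append((ex.start + (lo - off), ex.start + (hi - off)))
            else:
                out.append((ex.end - (hi - off), ex.end - (lo - off)))
        off += ex.length
    return sorted(out)


def _make_exons(
    rng: np.random.Generator, chrom: str, start: int, strand: str,
    n_exons: int, exon_len: tuple[int, int], intron_len: tuple[int, int],
    forced_intron: Optional[int] = None,
) -> tuple[GenomicInterval, ...]:
    pos = start
    exons = []
    for i in range(n_exons):
        elen = int(rng.integers(exon_len[0], exon_len[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < n_exons - 1:
            ilen = forced_intron if (forced_intron and i == 0) else int(
                rng.integers(intron_len[0], intron_len[1] + 1)
            )
            pos += ilen
    return tuple(exons)


def _carve_gene_features(t: TranscriptModel):
    """Split a transcript's spliced length into 5'UTR / CDS / 3'UTR pieces."""
    L = t.length
    u5 = min(100, max(10, L // 5))
    u3 = min(100, max(10, L // 5))
    pieces = {
        "utr5": spliced_to_genomic(t.exons, t.strand, 0, u5),
        "cds": spliced_to_genomic(t.exons, t.strand, u5, L - u3),
        "utr3": spliced_to_genomic(t.exons, t.strand, L - u3, L),
    }
    mk = lambda pairs: tuple(
        GenomicInterval(t.chrom, s, e, t.strand) for s, e in pairs
    )
    return mk(pieces["cds"]), mk(pieces["utr5"]), mk(pieces["utr3"])


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig, outdir) -> SyntheticBundle:
    """Generate the full input bundle plus truth; deterministic per seed."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = config.chrom

    # ---- layout: interleave gene and lincRNA loci with >= 1.5 kb gaps ----
    rng = _rng(config.seed, "layout")
    genes: list[GeneModel] = []
    candidates: list[TranscriptModel] = []
    truth_rows: dict[str, dict] = {}

    n_decoy_filters = 4  # length / coding / homology / expression failures
    items = (
        ["gene"] * config.n_genes
        + ["linc"] * config.n_lincRNA
        + ["decoy_filter"] * n_decoy_filters
        + ["decoy_sense", "decoy_intronic"]
    )
    rng.shuffle(items)

    cursor = 2000
    gene_idx = linc_idx = decoy_idx = 0
    intronic_host: Optional[int] = None
    decoy_kinds = iter(["length", "coding", "homology", "expression"])
    pending_sense = pending_intronic = False
    for item in items:
        if item == "gene":
            gene_idx += 1
            gid, tid = f"G{gene_idx:04d}", f"G{gene_idx:04d}.t1"
            strand = "+" if rng.random() < 0.5 else "-"
            single = rng.random() < config.single_exon_mrna
            n_ex = 1 if single else int(rng.integers(2, 6))
            forced = None
            if intronic_host is None and n_ex >= 2:
                forced = 600  # roomy first intron to host the intronic decoy
                intronic_host = len(genes)
            exons = _make_exons(
                rng, chrom, cursor, strand, n_ex, (200, 450), (100, 250), forced
            )
            span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
            tx = TranscriptModel(tid, gid, span, exons, biotype_hint="mRNA")
            cds, u5, u3 = _carve_gene_features(tx)
            genes.append(GeneModel(gid, span, (tx,), cds, u5, u3))
            cursor = span.end + int(rng.integers(1500, 2500))
        elif item in ("linc", "decoy_filter", "decoy_sense", "decoy_intronic"):
            if item == "decoy_sense":
                pending_sense = True
                continue
            if item == "decoy_intronic":
                pending_intronic = True
                continue
            if item == "linc":
                linc_idx += 1
                tid = f"LINC{linc_idx:04d}"
                planted_cls, reasons = "lincRNA", ""
            else:
                decoy_idx += 1
                kind = next(decoy_kinds)
                tid = f"DECOY_{kind.upper()}"
                planted_cls = "filtered_out"
                reasons = {"length": "length", "coding": "coding_potential",
                           "homology": "homology", "expression": "expression"}[kind]
            single = rng.random() < config.single_exon_linc
            if planted_cls == "filtered_out" and reasons == "length":
                exons = _make_exons(rng, chrom, cursor, "+", 1, (150, 150), (0, 0))
            elif single:
                exons = _make_exons(
                    rng, chrom, cursor,
                    "+" if rng.random() < 0.5 else "-", 1, (300, 700), (0, 0),
                )
            else:
                exons = _make_exons(
                    rng, chrom, cursor,
                    "+" if rng.random() < 0.5 else "-",
                    int(rng.integers(2, 4)), (150, 400), (90, 200),
                )
            span = GenomicInterval(
                chrom, exons[0].start, exons[-1].end, exons[0].strand
            )
            candidates.append(TranscriptModel(tid, tid, span, exons))
            truth_rows[tid] = {"planted_cls": planted_cls, "fail_reasons": reasons}
            cursor = span.end + int(rng.integers(1500, 2500))

    # lncNATs: one per distinct host gene, antisense over an exon
    host_ids = rng.choice(len(genes), size=config.n_lncNAT, replace=False)
    for k, gi in enumerate(host_ids, start=1):
        g = genes[int(gi)]
        host_tx = g.transcripts[0]
        ex = host_tx.exons[int(rng.integers(0, host_tx.n_exons))]
        strand = "-" if g.strand == "+" else "+"
        # single-exon NAT centered on the host exon, clipped to the gene span
        single = rng.random() < config.single_exon_nat
        length = int(rng.integers(300, 700))
        mid = (ex.start + ex.end) // 2
        start = max(g.interval.start, mid - length // 2)
        end = min(g.interval.end, start + length)
        if end - start < 250:
            start, end = ex.start, min(g.interval.end, ex.start + 300)
        tid = f"NAT{k:04d}"
        if single or end - start < 500:
            exons = (GenomicInterval(chrom, start, end, strand),)
        else:
            half = (end - start - 120) // 2
            exons = (
                GenomicInterval(chrom, start, start + half, strand),
                GenomicInterval(chrom, end - half, end, strand),
            )
        span = GenomicInterval(chrom, start, end, strand)
        nat = TranscriptModel(tid, tid, span, exons)
        candidates.append(nat)
        anti_bp = overlap_bp(
            merge_intervals(nat.exon_pairs), g.exon_pairs
        )
        truth_rows[tid] = {
            "planted_cls": "lncNAT", "fail_reasons": "",
            "planted_partner_gene": g.gene_id,
            "planted_antisense_bp": anti_bp,
        }

    # positional decoys: sense-overlap and intronic
    if pending_sense:
        g = genes[0]
        ex = g.transcripts[0].exons[0]
        start = max(0, ex.start - 100)
        iv = GenomicInterval(chrom, start, ex.start + 150, g.strand)
        candidates.append(
            TranscriptModel("DECOY_SENSE", "DECOY_SENSE", iv, (iv,))
        )
        truth_rows["DECOY_SENSE"] = {
            "planted_cls": "sense_overlap_excluded", "fail_reasons": "",
        }
    if pending_intronic:
        g = genes[intronic_host] if intronic_host is not None else None
        if g is not None and g.introns:
            istart, iend = g.introns[0]
            iv = GenomicInterval(chrom, istart + 50, istart + 50 + 300, "+")
            candidates.append(
                TranscriptModel("DECOY_INTRONIC", "DECOY_INTRONIC", iv, (iv,))
            )
            truth_rows["DECOY_INTRONIC"] = {
                "planted_cls": "intronic", "fail_reasons": "",
            }

    tail_start = cursor + 1000
    needed = tail_start + 50_000
    if config.genome_length < needed:
        raise ValueError(
            f"genome_length {config.genome_length} too small for requested "
            f"features; need >= {needed} (deficit {needed - config.genome_length})"
        )

    # ---- genome sequence: baseline GC, CDS-rich GC, canonical splice sites
    srng = _rng(config.seed, "sequence")
    codes = _random_seq(srng, config.genome_length, gc=0.36)
    for g in genes:
        for iv in g.cds:
            codes[iv.start:iv.end] = _random_seq(srng, iv.length, gc=0.55)
    b = {"A": 0, "C": 1, "G": 2, "T": 3}
    all_tx = [g.transcripts[0] for g in genes] + list(candidates)
    for t in all_tx:
        for istart, iend in t.introns:
            if t.strand == "+":
                codes[istart], codes[istart + 1] = b["G"], b["T"]
                codes[iend - 2], codes[iend - 1] = b["A"], b["G"]
            else:  # GT..AG on the minus strand reads CT..AC on the reference
                codes[iend - 1], codes[iend - 2] = b["C"], b["A"]
                codes[istart + 1], codes[istart] = b["T"], b["C"]
    genome = {chrom: "".join(_BASES[codes])}
    chrom_sizes = {chrom: config.genome_length}

    # ---- TEs: planted exonic overlaps, planted promoters, background ----
    terng = _rng(config.seed, "te")
    tes: list[TERecord] = []
    fam_I = ["LTR/Gypsy", "LTR/Copia", "LINE/L1", "SINE/tRNA"]
    fam_II = ["DNA/MuDR", "DNA/hAT", "RC/Helitron", "DNA/CMC-EnSpm"]

    def new_te(start: int, end: int, strand: str = "+") -> TERecord:
        is_I = terng.random() < config.te_class_I_frac
        fam = (fam_I if is_I else fam_II)[int(terng.integers(0, 4))]
        te = TERecord(
            GenomicInterval(chrom, start, end, strand),
            repeat_name=f"TE{len(tes) + 1:04d}", repeat_family=fam,
        )
        tes.append(te)
        return te

    lincs = [t for t in candidates if t.transcript_id.startswith("LINC")]
    nats = [t for t in candidates if t.transcript_id.startswith("NAT")]
    te_segments: dict[str, list[tuple[int, int]]] = {
        t.transcript_id: [] for t in candidates
    }
    for t in candidates:
        truth_rows[t.transcript_id].setdefault("planted_te_promoter", False)

    def plant_exonic_te(t: TranscriptModel, ov: int):
        # TE enters the 3' terminal exon from the downstream side so it
        # never covers the TSS (which would trip the promoter TSS clause)
        if t.strand == "+":
            ex = t.exons[-1]
            new_te(ex.end - ov, ex.end + int(terng.integers(50, 200)))
            te_segments[t.transcript_id].append((ex.end - ov, ex.end))
        else:
            ex = t.exons[0]
            new_te(max(0, ex.start - int(terng.integers(50, 200))), ex.start + ov)
            te_segments[t.transcript_id].append((ex.start, ex.start + ov))

    n_te_lnc = int(round(config.te_lnc_frac * len(lincs)))
    for t in lincs[:n_te_lnc]:
        ex = t.exons[-1] if t.strand == "+" else t.exons[0]
        plant_exonic_te(t, int(terng.integers(5, min(100, ex.length) + 1)))
    # a couple of sub-threshold (4 bp) overlaps to exercise the boundary
    for t in lincs[n_te_lnc : n_te_lnc + 2]:
        plant_exonic_te(t, 4)

    def plant_promoter_te(t: TranscriptModel, use_tss_clause: bool):
        tss = t.tss
        if use_tss_clause:  # TE covers the TSS base, barely entering the exon
            if t.strand == "+":
                te = new_te(max(0, tss - 200), tss + 2)
                te_segments[t.transcript_id].append((tss, tss + 2))
            else:
                te = new_te(tss - 1, tss + 201)
                te_segments[t.transcript_id].append((tss - 1, tss + 1))
        else:  # 70% coverage of the promoter window, TSS untouched
            if t.strand == "+":
                te = new_te(max(0, tss - 1000), tss - 300)
            else:
                te = new_te(tss + 301, tss + 1001)
        truth_rows[t.transcript_id]["planted_te_promoter"] = True
        return te

    n_prom_linc = int(round(config.te_promoter_frac_linc * len(lincs)))
    n_prom_nat = int(round(config.te_promoter_frac_nat * len(nats)))
    prom_tx: list[TranscriptModel] = []
    for i, t in enumerate(lincs[:n_prom_linc]):
        plant_promoter_te(t, use_tss_clause=(i % 2 == 0))
        prom_tx.append(t)
    for i, t in enumerate(nats[:n_prom_nat]):
        plant_promoter_te(t, use_tss_clause=(i % 2 == 0))
        prom_tx.append(t)

    # truth records the UNION of planted exonic TE segments per transcript
    for tid, segs in te_segments.items():
        truth_rows[tid]["planted_te_exonic_bp"] = (
            sum(e - s for s, e in merge_intervals(segs)) if segs else 0
        )

    # background TEs confined to the tail region (never touches loci)
    pos = tail_start
    for _ in range(config.n_background_te):
        length = int(terng.integers(200, 2000))
        if pos + length > config.genome_length - 100:
            break
        new_te(pos, pos + length, "-" if terng.random() < 0.5 else "+")
        pos += length + int(terng.integers(100, 500))

    # ---- conservation track ----
    crng = _rng(config.seed, "conservation")
    track_arr = np.full(config.genome_length, config.score_intergenic)
    for g in genes:
        for iv in g.utr5 + g.utr3:
            track_arr[iv.start:iv.end] = float(
                np.clip(crng.normal(config.score_utr, 0.03), 0.2, 0.6)
            )
        for iv in g.cds:
            track_arr[iv.start:iv.end] = float(
                np.clip(crng.normal(config.score_cds, 0.03), 0.5, 0.95)
            )
    single_lincs = [t for t in lincs if t.n_exons == 1]
    patch_tx = single_lincs[: config.n_patch_linc]
    patch_ids = {t.transcript_id for t in patch_tx}
    for t in lincs + nats:
        if t.transcript_id in patch_ids:
            continue
        for ex in t.exons:
            region = track_arr[ex.start:ex.end]
            # lncNAT exons keep any gene-feature score they overlap
            mask = region <= config.score_intergenic
            region[mask] = config.score_lnc
    for t in patch_tx:
        ex = t.exons[0]
        track_arr[ex.start:ex.end] = 0.0
        max_off = ex.length - config.patch_len
        off = int(crng.integers(5, max(6, max_off - 5)))
        g0 = ex.start + off if t.strand == "+" else ex.end - off - config.patch_len
        track_arr[g0 : g0 + config.patch_len] = config.patch_score
        truth_rows[t.transcript_id]["planted_patch"] = True
        truth_rows[t.transcript_id]["planted_patch_offset"] = off
        truth_rows[t.transcript_id]["planted_whole_mean"] = (
            config.patch_len * config.patch_score / t.length
        )
    for t in candidates:
        truth_rows[t.transcript_id].setdefault("planted_patch", False)
    # explicit missing stretches in the tail
    for _ in range(5):
        s = int(crng.integers(tail_start, config.genome_length - 400))
        track_arr[s : s + 300] = np.nan
    track = ConservationTrack({chrom: track_arr})

    # ---- expression ----
    erng = _rng(config.seed, "expression")
    tissues = list(config.tissues)
    T = len(tissues)
    expr_rows: dict[str, np.ndarray] = {}

    def profile(tid: str, kind: str, base: float) -> np.ndarray:
        v = np.zeros(T)
        if kind == "single":
            ti = int(erng.integers(0, T))
            v[ti] = base
            truth_rows.setdefault(tid, {})["planted_tissue"] = tissues[ti]
        elif kind == "two":
            ti = int(erng.integers(0, T))
            tj = (ti + 1 + int(erng.integers(0, T - 1))) % T
            v[ti], v[tj] = base, 0.4 * base
        else:
            v[:] = base * erng.uniform(0.5, 1.5, size=T)
        return v

    for t in candidates:
        tid = t.transcript_id
        row = truth_rows[tid]
        if row.get("fail_reasons") == "expression":
            floor = 0.5 if t.n_exons == 1 else 0.1
            expr_rows[tid] = profile(tid, "broad", floor * 0.3)
            row["planted_profile"], row["planted_is_ts"] = "broad", False
            continue
        u = erng.random()
        kind = (
            "single" if u < config.ts_frac
            else "two" if u < config.ts_frac + config.two_tissue_frac
            else "broad"
        )
        expr_rows[tid] = profile(tid, kind, float(erng.uniform(2.0, 30.0)))
        row["planted_profile"] = kind
        row["planted_is_ts"] = kind == "single"
    for g in genes:
        tid = g.transcripts[0].transcript_id
        expr_rows[tid] = profile(tid, "broad", float(erng.uniform(20.0, 200.0)))
    expression = pd.DataFrame.from_dict(expr_rows, orient="index", columns=tissues)
    expression.index.name = "transcript_id"

    # ---- candidate flags ----
    flags = pd.DataFrame(
        False, index=[t.transcript_id for t in candidates],
        columns=lio.FLAG_COLUMNS,
    )
    if "DECOY_CODING" in flags.index:
        flags.loc["DECOY_CODING", "coding_by_cpc"] = True
    if "DECOY_HOMOLOGY" in flags.index:
        flags.loc["DECOY_HOMOLOGY", "has_pfam_hit"] = True
    flags.index.name = "transcript_id"

    # ---- SNPs ----
    vrng = _rng(config.seed, "snp")
    variants: list[VariantRecord] = []

    def plant_snps(pairs, per_kb, qual_rng=(20.0, 60.0), depth_rng=(8, 30)):
        if not pairs:
            return 0
        pairs = merge_intervals(pairs)
        positions = np.concatenate([np.arange(s, e) for s, e in pairs])
        n = int(round(per_kb * len(positions) / 1000.0))
        if n == 0:
            return 0
        chosen = vrng.choice(positions, size=min(n, len(positions)), replace=False)
        for p in sorted(int(x) for x in chosen):
            ref = genome[chrom][p]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}.get(ref, "A")
            variants.append(
                VariantRecord(
                    chrom, p, ref, alt,
                    qual=float(np.round(vrng.uniform(*qual_rng), 1)),
                    depth=int(vrng.integers(depth_rng[0], depth_rng[1] + 1)),
                )
            )
        return len(chosen)

    linc_pairs = [p for t in lincs for p in t.exon_pairs]
    nat_pairs_iv = [p for t in nats for p in t.exon_pairs]
    cds_pairs = [(iv.start, iv.end) for g in genes for iv in g.cds]
    n_kept = (
        plant_snps(linc_pairs, config.snp_per_kb_linc)
        + plant_snps(nat_pairs_iv, config.snp_per_kb_nat)
        + plant_snps(cds_pairs, config.snp_per_kb_cds)
    )
    # below-threshold and non-SNP records that the filter must drop
    dropped: list[VariantRecord] = []
    for i in range(5):
        p = tail_start + 100 + 37 * i
        dropped.append(VariantRecord(chrom, p, genome[chrom][p], "A", qual=8.0, depth=20))
        p2 = tail_start + 400 + 41 * i
        dropped.append(VariantRecord(chrom, p2, genome[chrom][p2], "C", qual=30.0, depth=4))

    # ---- peaks ----
    prng = _rng(config.seed, "peaks")
    tf_names = ["MADS29", "LFY", "NLP7", "P1", "HSFB2A"]
    peaks: list[Peak] = []
    for t in candidates:
        truth_rows[t.transcript_id].setdefault("planted_tf_hit", False)
        truth_rows[t.transcript_id].setdefault("planted_tf_in_te", False)

    def add_peak(summit: int, tf: str):
        peaks.append(
            Peak(
                GenomicInterval(chrom, max(0, summit - 75), summit + 75, "."),
                tf_name=tf, score=float(np.round(prng.uniform(5, 50), 1)),
                summit=summit,
            )
        )

    for i, t in enumerate(prom_tx[: config.n_te_tf_lnc]):
        tss = t.tss
        # summit inside promoter ∩ TE: TSS-clause TEs span [tss-200, tss+2),
        # coverage-clause TEs span [tss-1000, tss-300) (mirrored on -)
        in_tss_te = any(
            te.interval.start <= tss < te.interval.end for te in tes
        )
        if in_tss_te:
            summit = tss - 50 if t.strand == "+" else tss + 50
        else:
            summit = tss - 650 if t.strand == "+" else tss + 650
        add_peak(summit, tf_names[i % len(tf_names)])
        truth_rows[t.transcript_id]["planted_tf_hit"] = True
        truth_rows[t.transcript_id]["planted_tf_in_te"] = True
    # promoter peaks outside any TE, on TE-free-promoter lincRNAs
    no_te_prom = [
        t for t in lincs
        if not truth_rows[t.transcript_id]["planted_te_promoter"]
        and truth_rows[t.transcript_id]["planted_cls"] == "lincRNA"
    ]
    for i, t in enumerate(no_te_prom[:4]):
        tss = t.tss
        add_peak(tss - 400 if t.strand == "+" else tss + 400, tf_names[i % len(tf_names)])
        truth_rows[t.transcript_id]["planted_tf_hit"] = True
    # background peaks far from every promoter
    for i in range(5):
        add_peak(tail_start + 30_000 + 700 * i, tf_names[i % len(tf_names)])

    # ---- homology hits ----
    hrng = _rng(config.seed, "homology")
    species_tx: dict[str, list[str]] = {
        config.species[0]: [t.transcript_id for t in lincs]
    }
    for sp in config.species[1:]:
        species_tx[sp] = [f"{sp}_L{i:03d}" for i in range(1, 41)]
    hits: list[HomologyHit] = []
    expected = pd.DataFrame(
        np.eye(len(config.species)), index=config.species, columns=config.species
    )
    for qsp, ssp, frac in config.homology_fracs:
        ids = species_tx[qsp]
        n_pass = int(round(frac * len(ids)))
        for qid in ids[:n_pass]:
            hits.append(
                HomologyHit(qid, qsp, ssp,
                            identity_pct=float(np.round(hrng.uniform(80, 99), 1)),
                            align_len=int(hrng.integers(60, 300)),
                            evalue=1e-20)
            )
        for qid in ids[n_pass : n_pass + 3]:  # sub-threshold hits: must not count
            hits.append(
                HomologyHit(qid, qsp, ssp, identity_pct=90.0,
                            align_len=30, evalue=1e-3)
            )
        expected.loc[qsp, ssp] = n_pass / len(ids)

    # ---- write everything ----
    paths: dict[str, Path] = {}

    def p(name: str, fname: str) -> Path:
        paths[name] = outdir / fname
        return paths[name]

    lio.write_fasta(genome, p("fasta", "genome.fa"))
    lio.write_gff3_genes(genes, p("genes_gff3", "genes.gff3"))
    lio.write_gtf(candidates, p("gtf", "candidates.gtf"))
    lio.write_repeatmasker_out(tes, p("repeats", "repeats.out"))
    lio.write_bedgraph({chrom: track_arr}, p("bedgraph", "conservation.bedGraph"))
    lio.write_vcf(variants + dropped, p("vcf", "variants.vcf"), contigs=chrom_sizes)
    lio.write_expression_tsv(expression, p("expression", "expression.tsv"))
    lio.write_flags_tsv(flags, p("flags", "flags.tsv"))
    lio.write_narrowpeak(peaks, p("peaks", "peaks.narrowPeak"))
    by_pair: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in hits:
        by_pair.setdefault((h.query_species, h.subject_species), []).append(h)
    for (qsp, ssp), hh in sorted(by_pair.items()):
        lio.write_blast_tab(hh, p(f"blast_{qsp}_to_{ssp}", f"hits_{qsp}_to_{ssp}.tsv"))
    with open(p("chrom_sizes", "chrom.sizes"), "w") as fh:
        fh.write(f"{chrom}\t{config.genome_length}\n")

    truth_df = pd.DataFrame.from_dict(truth_rows, orient="index").fillna(
        {"planted_te_exonic_bp": 0, "planted_te_promoter": False,
         "planted_patch": False, "planted_tf_hit": False,
         "planted_tf_in_te": False}
    )
    truth_df.index.name = "transcript_id"
    truth = SyntheticTruth(
        transcripts=truth_df,
        homology_expected=expected,
        species_transcripts=species_tx,
        snp_kept=n_kept,
        snp_dropped=len(dropped),
    )
    paths.update(truth.write(outdir))
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, default=list)
    paths["config"] = outdir / "config.json"

    return SyntheticBundle(
        outdir=outdir, paths=paths, truth=truth, chrom_sizes=chrom_sizes,
        genome=genome, genes=genes, candidates=candidates, tes=tes,
        peaks=peaks, variants=variants + dropped, hits=hits,
        expression=expression, flags=flags, track=track,
    )


# ---------------------------------------------------------------------------
# boundary-case bundle
# ---------------------------------------------------------------------------

def _two_tissue_vector_for_score(target: float, n_tissues: int = 5) -> np.ndarray:
    """A (a, 1-a, 0, ...) vector whose JS specificity equals ``target``."""
    from scipy.optimize import brentq

    from .expression import js_specificity

    f = lambda a: js_specificity([a, 1.0 - a]).js_score - target
    a = brentq(f, 0.5, 1.0 - 1e-12, xtol=1e-15)
    v = np.zeros(n_tissues)
    v[0], v[1] = a, 1.0 - a
    return v


def plant_boundary_cases(config: GeneratorConfig, outdir) -> SyntheticBundle:
    """A compact bundle of transcripts straddling every printed threshold.

    Covers: spliced length 199/200/201 vs the ">200 bp" rule; max FPKM at
    and just above 0.5 (single-exon) and 0.1 (multi-exon); TE exon overlap
    of 4 vs 5 bp; 12-bp window means 0.55/0.60/0.65 against the ">0.6"
    patch rule (plus the 50-base worked example, whole mean 0.216); JS
    specificity just below/above the inclusive 0.9 TS threshold. Expected
    outcomes are in ``truth.transcripts`` under the ``expected_*`` columns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, "boundary")
    chrom = "chrB"
    glen = 60_000
    tissues = list(config.tissues)
    T = len(tissues)

    candidates: list[TranscriptModel] = []
    truth: dict[str, dict] = {}
    cursor = 2000

    def add_tx(tid: str, exon_lens: Sequence[int], intron: int = 120) -> TranscriptModel:
        nonlocal cursor
        pos = cursor
        exons = []
        for i, L in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + L, "+"))
            pos += L + (intron if i < len(exon_lens) - 1 else 0)
        t = TranscriptModel(
            tid, tid, GenomicInterval(chrom, exons[0].start, exons[-1].end, "+"),
            tuple(exons),
        )
        candidates.append(t)
        cursor = pos + 1500
        return t

    expr: dict[str, np.ndarray] = {}

    def broad(v: float) -> np.ndarray:
        return np.full(T, v)

    # -- length boundary (all else passing; FPKM 2.0 broad)
    for L, passes in ((199, False), (200, False), (201, True)):
        tid = f"LEN{L}"
        add_tx(tid, [L])
        expr[tid] = broad(2.0)
        truth[tid] = {
            "case": "length", "expected_pass_filters": passes,
            "expected_fail_reasons": "" if passes else "length",
        }
    # -- FPKM boundary, strict ">"
    eps = 1e-6
    for tid, exon_lens, fpkm, passes in (
        ("FPKM_S_AT", [400], 0.5, False),
        ("FPKM_S_ABOVE", [400], 0.5 + eps, True),
        ("FPKM_M_AT", [250, 250], 0.1, False),
        ("FPKM_M_ABOVE", [250, 250], 0.1 + eps, True),
    ):
        add_tx(tid, exon_lens)
        v = np.zeros(T)
        v[0] = fpkm
        expr[tid] = v
        truth[tid] = {
            "case": "fpkm", "expected_pass_filters": passes,
            "expected_fail_reasons": "" if passes else "expression",
        }
    # -- TE exonic overlap 4 vs 5 bp
    tes: list[TERecord] = []
    for tid, ov in (("TEOV4", 4), ("TEOV5", 5)):
        t = add_tx(tid, [400])
        expr[tid] = broad(2.0)
        ex = t.exons[0]
        tes.append(
            TERecord(GenomicInterval(chrom, ex.start - 100, ex.start + ov, "+"),
                     f"TE_{tid}", "LTR/Gypsy")
        )
        truth[tid] = {"case": "te_overlap", "expected_is_te_lnc": ov >= 5,
                      "planted_te_exonic_bp": ov}
    # -- conserved-patch windows at 0.55 / 0.60 / 0.65, and the worked case
    track_arr = np.zeros(glen)
    for val in (0.55, 0.60, 0.65):
        tid = f"PATCH{int(val * 100)}"
        t = add_tx(tid, [50])
        expr[tid] = broad(2.0)
        ex = t.exons[0]
        track_arr[ex.start + 20 : ex.start + 32] = val
        truth[tid] = {
            "case": "patch", "expected_has_patch": val > 0.6,
            "expected_best_window": val,
            "expected_whole_mean": 12 * val / 50,
        }
    t = add_tx("PATCH_WORKED", [50])
    expr["PATCH_WORKED"] = broad(2.0)
    ex = t.exons[0]
    track_arr[ex.start + 10 : ex.start + 22] = 0.9
    truth["PATCH_WORKED"] = {
        "case": "patch", "expected_has_patch": True,
        "expected_best_window": 0.9, "expected_whole_mean": 0.216,
    }
    # -- JS around the inclusive 0.9 threshold
    from .expression import js_specificity

    for tid, target, expect in (("JS_BELOW", 0.9 - 1e-4, False),
                                ("JS_ABOVE", 0.9 + 1e-4, True)):
        v = _two_tissue_vector_for_score(target, T)
        got = js_specificity(v).js_score
        assert (got >= 0.9) == expect, "boundary vector landed on wrong side"
        expr[tid] = v
        truth[tid] = {"case": "js", "expected_is_ts": expect}
    v = np.zeros(T)
    v[2] = 7.0
    expr["JS_SINGLE"] = v
    truth["JS_SINGLE"] = {"case": "js", "expected_is_ts": True,
                          "expected_tissue": tissues[2]}
    expr["JS_UNIFORM"] = np.full(T, 3.0)
    truth["JS_UNIFORM"] = {"case": "js", "expected_is_ts": False}

    flags = pd.DataFrame(
        False, index=[t.transcript_id for t in candidates], columns=lio.FLAG_COLUMNS
    )
    flags.index.name = "transcript_id"
    expression = pd.DataFrame.from_dict(expr, orient="index", columns=tissues)
    expression.index.name = "transcript_id"
    track = ConservationTrack({chrom: track_arr})

    paths: dict[str, Path] = {}
    lio.write_gtf(candidates, outdir / "candidates.gtf")
    lio.write_flags_tsv(flags, outdir / "flags.tsv")
    lio.write_expression_tsv(expression, outdir / "expression.tsv")
    lio.write_repeatmasker_out(tes, outdir / "repeats.out")
    lio.write_bedgraph({chrom: track_arr}, outdir / "conservation.bedGraph")
    for name in ("candidates.gtf", "flags.tsv", "expression.tsv",
                 "repeats.out", "conservation.bedGraph"):
        paths[name.split(".")[0]] = outdir / name

    truth_df = pd.DataFrame.from_dict(truth, orient="index")
    truth_df.index.name = "transcript_id"
    truth_obj = SyntheticTruth(
        transcripts=truth_df,
        homology_expected=pd.DataFrame(),
        species_transcripts={},
    )
    paths.update(truth_obj.write(outdir))
    return SyntheticBundle(
        outdir=outdir, paths=paths, truth=truth_obj,
        chrom_sizes={chrom: glen}, genome={}, genes=[], candidates=candidates,
        tes=tes, peaks=[], variants=[], hits=[], expression=expression,
        flags=flags, track=track,
    )
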