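"""Transposable-element origination analyses.

Covers: gene-body vs exonic TE overlap (a TE-lncRNA has >= 5 bp of exonic
TE sequence), Class I/II composition of TE bases per region set,
TE-derived promoter calls (TSS covered by a TE, or the promoter window
mostly TE), TF peaks falling inside TE-derived promoter segments, and the
across-species correlation between genomic TE content and the TE-promoter
fraction.

Coding genes use CDS for the "exonic" variant of the overlap statistic;
pass ``exonic="cds"`` items built from GeneModels for that comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, merge_intervals, overlap_bp
from .models import GeneModel, Peak, TERecord, TranscriptModel

__all__ = [
    "te_overlap",
    "te_class_distribution",
    "promoter_window",
    "PromoterRule",
    "te_derived_promoters",
    "tf_sites_in_te_promoters",
    "te_promoter_genome_correlation",
]

Unit = Union[TranscriptModel, GeneModel]


def _unit_regions(unit: Unit) -> tuple[str, str, list, list]:
    """(id, chrom, span pairs, exonic pairs) for a transcript or gene.

    Genes contribute their CDS as the exonic region; transcripts their
    exon union.
    """
    if isinstance(unit, GeneModel):
        span = [(unit.interval.start, unit.interval.end)]
        exonic = unit.cds_pairs or unit.exon_pairs
        return unit.gene_id, unit.chrom, span, exonic
    span = [(unit.interval.start, unit.interval.end)]
    return unit.transcript_id, unit.chrom, span, merge_intervals(unit.exon_pairs)


def _te_pairs_by_chrom(tes: Sequence[TERecord]) -> dict[str, list]:
    out: dict[str, list] = {}
    for te in tes:
        out.setdefault(te.interval.chrom, []).append(
            (te.interval.start, te.interval.end)
        )
    return out


def te_overlap(
    units_by_class: Mapping[str, Sequence[Unit]],
    tes: Sequence[TERecord],
    min_bp: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """TE overlap per transcript/gene and the per-class TE-lncRNA ratio.

    ``gene_body_te_bp`` uses the genomic span, ``exonic_te_bp`` the exon
    union (CDS for genes); ``is_te_lnc`` is exonic overlap >= ``min_bp``.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    te_pairs = _te_pairs_by_chrom(tes)
    rows = []
    for cls, units in units_by_class.items():
        for u in units:
            uid, chrom, span, exonic = _unit_regions(u)
            pairs = te_pairs.get(chrom, [])
            body = overlap_bp(span, pairs) if pairs else 0
            exo = overlap_bp(exonic, pairs) if pairs and exonic else 0
            rows.append(
                {
                    "transcript_id": uid,
                    "cls": cls,
                    "gene_body_te_bp": body,
                    "exonic_te_bp": exo,
                    "is_te_lnc": exo >= min_bp,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["transcript_id", "cls", "gene_body_te_bp", "exonic_te_bp", "is_te_lnc"],
    )
    ratios = table.groupby("cls")["is_te_lnc"].mean()
    return table, ratios


def te_class_distribution(
    tes: Sequence[TERecord],
    region_sets: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
) -> pd.DataFrame:
    """Fraction of Class I vs Class II TE bases inside each region set.

    ``region_sets`` maps a set name (genome, lincRNA, lncNAT, coding...) to
    {chrom: interval pairs}. Fractions are over Class I + II TE bases
    only; te_class "other" bases are reported separately and excluded from
    the I/II normalization. Empty or TE-free region sets yield NaN.
    """
    rows = []
    for name, regions in region_sets.items():
        bases = {"I": 0, "II": 0, "other": 0}
        for te in tes:
            pairs = regions.get(te.interval.chrom)
            if not pairs:
                continue
            bases[te.te_class] += overlap_bp(
                [(te.interval.start, te.interval.end)], list(pairs)
            )
        total = bases["I"] + bases["II"]
        rows.append(
            {
                "region_set": name,
                "class_I_bp": bases["I"],
                "class_II_bp": bases["II"],
                "other_bp": bases["other"],
                "class_I_frac": bases["I"] / total if total else float("nan"),
                "class_II_frac": bases["II"] / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("region_set")


def promoter_window(
    t: TranscriptModel,
    size: int = 1000,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> GenomicInterval:
    """The ``size``-bp window immediately upstream of the TSS, strand-aware,
    clipped at chromosome bounds."""
    if t.strand not in ("+", "-"):
        raise ValueError(f"transcript {t.transcript_id}: promoter needs strand +/-")
    if t.strand == "+":
        start, end = t.interval.start - size, t.interval.start
    else:
        start, end = t.interval.end, t.interval.end + size
    start = max(start, 0)
    if chrom_sizes is not None:
        end = min(end, chrom_sizes[t.chrom])
    if start >= end:
        raise ValueError(
            f"transcript {t.transcript_id}: promoter empty after clipping"
        )
    return GenomicInterval(t.chrom, start, end, t.strand)


@dataclass(frozen=True)
class PromoterRule:
    """When does a TE "provide" a promoter: the TSS base lies in a TE, or
    TE coverage of the promoter window reaches ``cover_frac``."""

    size: int = 1000
    cover_frac: float = 0.5
    tss_clause: bool = True


def te_derived_promoters(
    transcripts_by_class: Mapping[str, Sequence[TranscriptModel]],
    tes: Sequence[TERecord],
    rule: PromoterRule = PromoterRule(),
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Call TE-derived promoters and the per-class fraction."""
    te_pairs = _te_pairs_by_chrom(tes)
    rows = []
    for cls, ts in transcripts_by_class.items():
        for t in ts:
            prom = promoter_window(t, rule.size, chrom_sizes)
            pairs = te_pairs.get(t.chrom, [])
            cov = overlap_bp([(prom.start, prom.end)], pairs) if pairs else 0
            tss = t.tss
            tss_in_te = any(s <= tss < e for s, e in pairs)
            derived = (rule.tss_clause and tss_in_te) or (
                cov / prom.length >= rule.cover_frac
            )
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "cls": cls,
                    "chrom": prom.chrom,
                    "promoter_start": prom.start,
                    "promoter_end": prom.end,
                    "strand": t.strand,
                    "te_cover_bp": cov,
                    "tss_in_te": tss_in_te,
                    "te_derived": derived,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "cls", "chrom", "promoter_start", "promoter_end",
            "strand", "te_cover_bp", "tss_in_te", "te_derived",
        ],
    )
    fractions = table.groupby("cls")["te_derived"].mean()
    return table, fractions


def tf_sites_in_te_promoters(
    promoter_calls: pd.DataFrame,
    peaks: Sequence[Peak],
    tes: Sequence[TERecord],
) -> tuple[pd.DataFrame, pd.Series]:
    """TF peaks in promoters, and specifically inside TE-derived segments.

    A TF-in-TE hit needs a peak summit inside (promoter window ∩ some TE).
    Returns the per-transcript table (tf_hits, tf_hit_in_te) and the
    per-class fraction of transcripts with any promoter-summit overlap
    (the TF binding frequency).
    """
    te_pairs = _te_pairs_by_chrom(tes)
    rows = []
    for rec in promoter_calls.itertuples():
        lo, hi = rec.promoter_start, rec.promoter_end
        tf_hits: list[str] = []
        in_te = False
        for p in peaks:
            if p.interval.chrom != rec.chrom:
                continue
            pos = p.summit_pos
            if lo <= pos < hi:
                tf_hits.append(p.tf_name)
                if any(
                    s <= pos < e
                    for s, e in te_pairs.get(rec.chrom, [])
                ):
                    in_te = True
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "cls": rec.cls,
                "tf_hits": tf_hits,
                "has_tf_hit": bool(tf_hits),
                "tf_hit_in_te": in_te,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["transcript_id", "cls", "tf_hits", "has_tf_hit", "tf_hit_in_te"],
    )
    binding_freq = table.groupby("cls")["has_tf_hit"].mean()
    return table, binding_freq


def te_promoter_genome_correlation(per_species: pd.DataFrame) -> pd.Series:
    """Pearson r between genomic TE fraction and per-class TE-promoter
    fraction across species.

    ``per_species``: rows = species, one column ``genome_te_frac`` plus one
    column per class of TE-promoter fractions. Zero-variance columns give
    NaN.
    """
    if len(per_species) < 3:
        raise ValueError("need at least 3 species rows")
    x = per_species["genome_te_frac"].to_numpy(dtype=float)
    out = {}
    for col in per_species.columns:
        if col == "genome_te_frac":
            continue
        y = per_species[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[col] = float("nan")
        else:
            out[col] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(out, name="pearson_r")
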