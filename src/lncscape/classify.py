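"""lncRNA identification and lincRNA/lncNAT classification.

A candidate transcript is accepted as a lncRNA when it

  I)   is longer than 200 bp (spliced length, strict),
  II)  is predicted noncoding by both coding-potential predictors,
  III) has no homolog in the protein/RNA family databases, and
  IV)  exceeds the expression floor: max FPKM across tissues > 0.5 for
       single-exon or > 0.1 for multi-exon transcripts (strict).

Accepted transcripts are then classed by strand-aware exon overlap with
coding genes: >= 1 bp of exon overlap on the opposite strand makes a
lncNAT (a natural antisense transcript); no exon overlap on either strand
and lying outside all gene spans makes a lincRNA (intergenic). Transcripts
whose exons overlap a coding exon on the same strand, or that sit wholly
within introns, are surfaced as explicit categories rather than silently
dropped.

Coding-potential and homology calls are consumed as a boolean flag table
(running CPC/PLEK/BLAST is outside this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intervals import merge_intervals, overlap_bp
from .models import GeneModel, TranscriptModel

__all__ = [
    "IdentificationThresholds",
    "apply_identification_filters",
    "antisense_exon_overlap",
    "classify_transcripts",
    "classification_report",
]

FAIL_LENGTH = "length"
FAIL_CODING = "coding_potential"
FAIL_HOMOLOGY = "homology"
FAIL_EXPRESSION = "expression"


@dataclass(frozen=True)
class IdentificationThresholds:
    """Printed thresholds of the identification criteria (all strict)."""

    length_min: int = 200
    fpkm_single: float = 0.5
    fpkm_multi: float = 0.1
    expression_mode: str = "max"  # "max" across tissues or "any" per tissue


def apply_identification_filters(
    transcripts: Sequence[TranscriptModel],
    flags: pd.DataFrame,
    expr: pd.DataFrame,
    thresholds: IdentificationThresholds = IdentificationThresholds(),
) -> pd.DataFrame:
    """Apply criteria I-IV; returns one row per transcript.

    Columns: transcript_id, cls ("pending" or "filtered_out"), fail_reasons
    (frozenset). Every failed criterion is recorded, not just the first.
    """
    rows = []
    for t in transcripts:
        if t.transcript_id not in flags.index:
            raise KeyError(f"no candidate-flags row for transcript {t.transcript_id}")
        if t.transcript_id not in expr.index:
            raise KeyError(f"no expression row for transcript {t.transcript_id}")
        frow = flags.loc[t.transcript_id]
        evec = expr.loc[t.transcript_id]
        reasons = set()
        if not t.length > thresholds.length_min:
            reasons.add(FAIL_LENGTH)
        if bool(frow["coding_by_cpc"]) or bool(frow["coding_by_plek"]):
            reasons.add(FAIL_CODING)
        if bool(frow["has_swissprot_hit"]) or bool(frow["has_pfam_hit"]) or bool(
            frow["has_rfam_hit"]
        ):
            reasons.add(FAIL_HOMOLOGY)
        floor = thresholds.fpkm_single if t.n_exons == 1 else thresholds.fpkm_multi
        if thresholds.expression_mode == "max":
            passes_expr = float(evec.max()) > floor
        else:
            passes_expr = bool((evec > floor).any())
        if not passes_expr:
            reasons.add(FAIL_EXPRESSION)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "cls": "filtered_out" if reasons else "pending",
                "fail_reasons": frozenset(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["transcript_id", "cls", "fail_reasons"])


def _gene_exons_by_strand(genes: Iterable[GeneModel], chrom: str):
    """Merged coding-exon unions per strand, restricted to one chromosome."""
    plus: list = []
    minus: list = []
    for g in genes:
        if g.chrom != chrom:
            continue
        pairs = g.exon_pairs
        (plus if g.strand == "+" else minus).extend(pairs)
    return (
        merge_intervals(plus) if plus else [],
        merge_intervals(minus) if minus else [],
    )


def antisense_exon_overlap(
    t: TranscriptModel, genes: Sequence[GeneModel]
) -> tuple[int, list[str]]:
    """Bases of ``t``'s exons overlapping coding exons on the opposite strand.

    Double counting is suppressed by taking interval unions before summing.
    Returns (bp, partner gene ids with any exon-level antisense overlap).
    """
    if t.strand not in ("+", "-"):
        raise ValueError(
            f"transcript {t.transcript_id}: antisense overlap needs strand +/-"
        )
    opposite = "-" if t.strand == "+" else "+"
    opp_pairs = []
    partners = []
    exon_union = merge_intervals(t.exon_pairs)
    for g in genes:
        if g.chrom != t.chrom or g.strand != opposite:
            continue
        gp = g.exon_pairs
        if gp and overlap_bp(exon_union, gp) > 0:
            partners.append(g.gene_id)
            opp_pairs.extend(gp)
    bp = overlap_bp(exon_union, opp_pairs) if opp_pairs else 0
    return bp, partners


def classify_transcripts(
    pending: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    min_antisense_bp: int = 1,
    lincRNA_buffer: int = 0,
) -> pd.DataFrame:
    """Assign each surviving transcript to a positional class.

    Classes: ``lncNAT`` (>= ``min_antisense_bp`` exon bases antisense to a
    coding exon), ``lincRNA`` (no coding-exon overlap on either strand and
    outside every gene span, optionally padded by ``lincRNA_buffer``),
    ``sense_overlap_excluded`` (exon overlap with a same-strand coding
    exon; takes precedence over lncNAT), or ``intronic`` (inside a gene
    span but exon-free on both strands).
    """
    rows = []
    for t in pending:
        if t.strand not in ("+", "-"):
            raise ValueError(f"transcript {t.transcript_id}: strand must be + or -")
        exon_union = merge_intervals(t.exon_pairs)
        plus_exons, minus_exons = _gene_exons_by_strand(genes, t.chrom)
        same = plus_exons if t.strand == "+" else minus_exons
        sense_bp = overlap_bp(exon_union, same) if same else 0
        anti_bp, partners = antisense_exon_overlap(t, genes)
        in_gene_span = any(
            g.chrom == t.chrom
            and t.interval.start < g.interval.end + lincRNA_buffer
            and g.interval.start - lincRNA_buffer < t.interval.end
            for g in genes
        )
        if sense_bp > 0:
            cls = "sense_overlap_excluded"
        elif anti_bp >= min_antisense_bp:
            cls = "lncNAT"
        elif in_gene_span:
            cls = "intronic"
        else:
            cls = "lincRNA"
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "cls": cls,
                "antisense_overlap_bp": anti_bp if cls == "lncNAT" else 0,
                "antisense_partner_genes": partners if cls == "lncNAT" else [],
                "sense_overlap_bp": sense_bp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "cls", "antisense_overlap_bp",
            "antisense_partner_genes", "sense_overlap_bp",
        ],
    )


def classification_report(
    filter_table: pd.DataFrame, class_table: pd.DataFrame
) -> pd.DataFrame:
    """Merge the filter and positional-class tables into one result table.

    Filtered-out transcripts keep cls ``filtered_out``; the partition
    property (each transcript gets exactly one cls) holds over the union.
    """
    failed = filter_table[filter_table["cls"] == "filtered_out"].copy()
    failed["antisense_overlap_bp"] = 0
    failed["antisense_partner_genes"] = [[] for _ in range(len(failed))]
    failed["sense_overlap_bp"] = 0
    classed = class_table.copy()
    classed["fail_reasons"] = [frozenset() for _ in range(len(classed))]
    cols = [
        "transcript_id", "cls", "fail_reasons",
        "antisense_overlap_bp", "antisense_partner_genes", "sense_overlap_bp",
    ]
    out = pd.concat([classed[cols], failed[cols]], ignore_index=True)
    if out["transcript_id"].duplicated().any():
        raise ValueError("transcript classified twice")
    return out
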