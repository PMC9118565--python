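"""Domain containers: transcripts, genes, repeats, variants, tracks.

These are thin validated dataclasses; tabular data (expression matrices,
candidate flags, reports) live in pandas DataFrames with documented column
contracts rather than bespoke classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Pair, merge_intervals, union_length

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "TERecord",
    "VariantRecord",
    "Peak",
    "HomologyHit",
    "ConservationTrack",
    "classify_repeat_family",
    "validate_expression_matrix",
    "TE_CLASS_I_PREFIXES",
    "TE_CLASS_II_PREFIXES",
]


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript; the unit of classification.

    ``length`` is the spliced (exonic) length, the quantity every filter and
    statistic here operates on; the genomic span is ``interval``.
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype_hint: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon chrom/strand mismatch"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = ex.end
        if (
            self.exons[0].start < self.interval.start
            or self.exons[-1].end > self.interval.end
        ):
            raise ValueError(
                f"transcript {self.transcript_id}: exons outside transcript span"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return sum(ex.length for ex in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_pairs(self) -> list[Pair]:
        return [(ex.start, ex.end) for ex in self.exons]

    @property
    def introns(self) -> list[Pair]:
        return [
            (self.exons[i].end, self.exons[i + 1].start)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start (5' end, strand-aware)."""
        if self.strand == "+":
            return self.interval.start
        if self.strand == "-":
            return self.interval.end - 1
        raise ValueError(
            f"transcript {self.transcript_id}: TSS undefined for strand '.'"
        )


@dataclass(frozen=True)
class GeneModel:
    """A coding gene with CDS/UTR sub-features and derived introns."""

    gene_id: str
    interval: GenomicInterval
    transcripts: tuple[TranscriptModel, ...] = ()
    cds: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for iv in (*self.cds, *self.utr5, *self.utr3):
            if iv.start < self.interval.start or iv.end > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_id}: sub-feature outside gene span"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def exon_pairs(self) -> list[Pair]:
        """Union of exons over all transcripts (falls back to CDS+UTRs)."""
        pairs: list[Pair] = []
        for t in self.transcripts:
            pairs.extend(t.exon_pairs)
        if not pairs:
            pairs = [(iv.start, iv.end) for iv in (*self.cds, *self.utr5, *self.utr3)]
        return merge_intervals(pairs) if pairs else []

    @property
    def cds_pairs(self) -> list[Pair]:
        return merge_intervals([(iv.start, iv.end) for iv in self.cds]) if self.cds else []

    @property
    def introns(self) -> list[Pair]:
        out: list[Pair] = []
        for t in self.transcripts:
            out.extend(t.introns)
        return merge_intervals(out) if out else []


# RepeatMasker class/family vocabulary -> the two TE classes.
# Class I = retrotransposons (copy-and-paste via an RNA intermediate),
# Class II = DNA transposons (cut-and-paste); anything else (simple repeats,
# low complexity, satellites, rRNA...) is not a TE for this analysis.
TE_CLASS_I_PREFIXES = ("LINE", "SINE", "LTR", "Retroposon")
TE_CLASS_II_PREFIXES = ("DNA", "RC", "Helitron", "TIR", "MITE")


def classify_repeat_family(repeat_family: str, warn_unknown: bool = False) -> str:
    """Map a RepeatMasker class/family string to {"I", "II", "other"}."""
    head = repeat_family.split("/")[0].rstrip("?")
    if head in TE_CLASS_I_PREFIXES:
        return "I"
    if head in TE_CLASS_II_PREFIXES:
        return "II"
    if warn_unknown:
        warnings.warn(f"repeat family {repeat_family!r} not a known TE class")
    return "other"


@dataclass(frozen=True)
class TERecord:
    interval: GenomicInterval
    repeat_name: str
    repeat_family: str
    te_class: str = field(default="")

    def __post_init__(self) -> None:
        if not self.te_class:
            object.__setattr__(
                self, "te_class", classify_repeat_family(self.repeat_family)
            )
        if self.te_class not in ("I", "II", "other"):
            raise ValueError(f"invalid te_class {self.te_class!r}")


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant that survived quality/depth filtering."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    qual: float
    depth: int

    def __post_init__(self) -> None:
        if self.qual < 0 or self.depth < 0:
            raise ValueError("negative qual/depth")


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak; ``summit`` is an absolute genomic position."""

    interval: GenomicInterval
    tf_name: str
    score: float = 0.0
    summit: Optional[int] = None

    @property
    def summit_pos(self) -> int:
        if self.summit is not None:
            return self.summit
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class HomologyHit:
    """One blastn-style alignment of a query transcript to another genome."""

    query_id: str
    query_species: str
    subject_species: str
    identity_pct: float
    align_len: int
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity_pct <= 100):
            raise ValueError("identity_pct outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative evalue")


class ConservationTrack:
    """Per-base conservation probabilities in [0, 1]; NaN marks missing bases.

    Backed by one float array per chromosome; positions beyond the stored
    array are treated as missing.
    """

    def __init__(self, scores: Mapping[str, np.ndarray]):
        self._scores: dict[str, np.ndarray] = {}
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{chrom}: conservation score outside [0, 1]")
            self._scores[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self._scores)

    def scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); uncovered bases are NaN."""
        out = np.full(end - start, np.nan)
        arr = self._scores.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the transcripts x tissues FPKM contract and return the frame."""
    if expr.shape[1] < 1:
        raise ValueError("expression matrix needs at least one tissue column")
    if not expr.index.is_unique:
        raise ValueError("duplicate transcript ids in expression matrix")
    if (expr.to_numpy() < 0).any():
        raise ValueError("negative FPKM values")
    return expr
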