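"""Per-class molecular features: length, exon count, splicing ratio,
GC content, SNP density, splice-site base profiles, intergenic controls.

The "splicing ratio" of a class is the fraction of its transcripts with
two or more exons (junction-read-based definitions need raw reads, which
are out of scope). SNP density is normalized by the class's exon-union
length so overlapping transcripts are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, complement_intervals, merge_intervals
from .io import SequenceSource, chrom_length, fetch_seq
from .models import GeneModel, TranscriptModel, VariantRecord

__all__ = [
    "gc_content",
    "feature_summary",
    "snp_density",
    "sample_intergenic_controls",
    "splice_site_profile",
    "SpliceSiteProfile",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_content(
    intervals: Sequence[GenomicInterval], genome: SequenceSource
) -> float:
    """(G+C)/(A+C+G+T) over the union of intervals; Ns excluded entirely."""
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    gc = total = 0
    for chrom, pairs in by_chrom.items():
        for s, e in merge_intervals(pairs):
            seq = fetch_seq(genome, chrom, s, e)
            gc += seq.count("G") + seq.count("C")
            total += sum(seq.count(b) for b in "ACGT")
    if total == 0:
        raise ValueError("no unambiguous bases in the given intervals")
    return gc / total


def _class_exon_union(transcripts: Sequence[TranscriptModel]):
    by_chrom: dict[str, list] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).extend(t.exon_pairs)
    return {c: merge_intervals(p) for c, p in by_chrom.items()}


def snp_density(
    transcripts: Sequence[TranscriptModel], variants: Sequence[VariantRecord]
) -> float:
    """SNPs per kb of the class's exon union."""
    union = _class_exon_union(transcripts)
    union_len = sum(e - s for pairs in union.values() for s, e in pairs)
    if union_len == 0:
        return float("nan")
    n = 0
    for v in variants:
        pairs = union.get(v.chrom)
        if pairs and any(s <= v.pos < e for s, e in pairs):
            n += 1
    return n / (union_len / 1000.0)


def feature_summary(
    transcripts_by_class: Mapping[str, Sequence[TranscriptModel]],
    genome: Optional[SequenceSource] = None,
    variants: Optional[Sequence[VariantRecord]] = None,
) -> pd.DataFrame:
    """The per-class feature panel (one row per class).

    Columns: n, length_median, exon_mean, splicing_ratio, gc (if a genome
    is given), snp_per_kb (if variants are given). Empty classes are
    omitted with a warning.
    """
    import warnings

    rows = []
    for cls, ts in transcripts_by_class.items():
        if not ts:
            warnings.warn(f"class {cls!r} has zero transcripts; omitted")
            continue
        lengths = np.array([t.length for t in ts])
        n_exons = np.array([t.n_exons for t in ts])
        row = {
            "cls": cls,
            "n": len(ts),
            "length_median": float(np.median(lengths)),
            "exon_mean": float(n_exons.mean()),
            "splicing_ratio": float((n_exons >= 2).mean()),
        }
        if genome is not None:
            row["gc"] = gc_content([ex for t in ts for ex in t.exons], genome)
        if variants is not None:
            row["snp_per_kb"] = snp_density(ts, variants)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cls")


def sample_intergenic_controls(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    n: int,
    length_sampler: Callable[[np.random.Generator], int],
    seed: int,
    max_tries_per_interval: int = 200,
) -> list[GenomicInterval]:
    """Draw ``n`` control intervals uniformly from intergenic space.

    Interval lengths come from ``length_sampler(rng)`` — pass e.g. a
    resampler over the lincRNA length distribution for a matched control.
    Deterministic under ``seed``. Raises if placement repeatedly fails
    (intergenic space too small for the requested lengths).
    """
    rng = np.random.default_rng(seed)
    gaps: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        spans = [
            (g.interval.start, g.interval.end) for g in genes if g.chrom == chrom
        ]
        for s, e in complement_intervals(spans, size) if spans else [(0, size)]:
            gaps.append((chrom, s, e))
    if not gaps:
        raise ValueError("no intergenic space available")
    weights = np.array([e - s for _, s, e in gaps], dtype=float)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    for k in range(n):
        placed = False
        for _ in range(max_tries_per_interval):
            length = int(length_sampler(rng))
            gi = rng.choice(len(gaps), p=weights)
            chrom, gs, ge = gaps[gi]
            if ge - gs < length:
                continue
            start = int(rng.integers(gs, ge - length + 1))
            out.append(GenomicInterval(chrom, start, start + length, "."))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place intergenic control {k + 1}/{n}; "
                f"{n - k} intervals still needed"
            )
    return out


@dataclass
class SpliceSiteProfile:
    """Base counts around splice donors and acceptors.

    Rows are window positions in transcript orientation; columns A,C,G,T.
    ``core`` marks the two intronic positions of the donor GT / acceptor AG
    dinucleotide within each window.
    """

    donor_counts: pd.DataFrame
    acceptor_counts: pd.DataFrame
    core: tuple[int, int]
    n_junctions: int
    n_skipped: int = 0


def _count_window(counts: np.ndarray, seq: str) -> None:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, b in enumerate(seq):
        j = idx.get(b)
        if j is not None:
            counts[i, j] += 1


def splice_site_profile(
    transcripts: Sequence[TranscriptModel],
    genome: SequenceSource,
    flank: int = 10,
) -> SpliceSiteProfile:
    """Base distribution around splice junctions of multi-exon transcripts.

    Each window is ``2*flank + 2`` bases in transcript orientation: the
    donor window is centered on the first two intronic bases at the 5'
    intron end, the acceptor window on the last two at the 3' end.
    Minus-strand windows are reverse-complemented. Junctions whose window
    would run off the chromosome are skipped (counted).
    """
    w = 2 * flank + 2
    donor = np.zeros((w, 4), dtype=int)
    acceptor = np.zeros((w, 4), dtype=int)
    n_junctions = 0
    n_skipped = 0
    for t in transcripts:
        if t.n_exons < 2:
            continue
        clen = chrom_length(genome, t.chrom)
        for istart, iend in t.introns:
            if t.strand == "+":
                d_lo, d_hi = istart - flank, istart + flank + 2
                a_lo, a_hi = iend - flank - 2, iend + flank
            else:
                # 5' intron end is at iend on the minus strand
                d_lo, d_hi = iend - flank - 2, iend + flank
                a_lo, a_hi = istart - flank, istart + flank + 2
            if d_lo < 0 or a_lo < 0 or d_hi > clen or a_hi > clen:
                n_skipped += 1
                continue
            dseq = fetch_seq(genome, t.chrom, d_lo, d_hi)
            aseq = fetch_seq(genome, t.chrom, a_lo, a_hi)
            if t.strand == "-":
                dseq = reverse_complement(dseq)
                aseq = reverse_complement(aseq)
            _count_window(donor, dseq)
            _count_window(acceptor, aseq)
            n_junctions += 1
    cols = list("ACGT")
    return SpliceSiteProfile(
        donor_counts=pd.DataFrame(donor, columns=cols),
        acceptor_counts=pd.DataFrame(acceptor, columns=cols),
        core=(flank, flank + 1),
        n_junctions=n_junctions,
        n_skipped=n_skipped,
    )
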