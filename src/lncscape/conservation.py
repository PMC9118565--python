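"""Conservation analyses on a per-base PhastCons-style track.

Scores are read over the spliced transcript (concatenated exons, 5'->3');
introns never contribute. A "conserved patch" is a 12-bp sliding window
with mean score above 0.6 inside a transcript whose overall mean is below
0.3 — a short conserved island in an otherwise non-conserved transcript.
Cross-species homology is summarized from precomputed blastn hit tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ConservationTrack, HomologyHit, TranscriptModel

__all__ = [
    "spliced_scores",
    "transcript_mean_score",
    "PatchCall",
    "conserved_patch_scan",
    "class_conservation_profiles",
    "homology_conservation_matrix",
]


def spliced_scores(t: TranscriptModel, track: ConservationTrack) -> np.ndarray:
    """Per-base scores along the spliced transcript, 5' to 3'.

    Exon scores are concatenated in genomic order and reversed for minus
    strand transcripts; missing bases are NaN.
    """
    parts = [track.scores(t.chrom, ex.start, ex.end) for ex in t.exons]
    arr = np.concatenate(parts)
    if t.strand == "-":
        arr = arr[::-1]
    return arr


def transcript_mean_score(t: TranscriptModel, track: ConservationTrack) -> float:
    """Mean score over scored exonic bases; NaN when no base is scored."""
    arr = spliced_scores(t, track)
    if np.isnan(arr).all():
        return float("nan")
    return float(np.nanmean(arr))


@dataclass(frozen=True)
class PatchCall:
    transcript_id: str
    whole_mean: float
    best_window_mean: float
    patches: tuple[tuple[int, float], ...]  # (spliced offset, window mean)
    has_conserved_patch: bool
    flagged: str = ""  # "unscored" / "too_short" when the scan is degenerate


def _window_means(arr: np.ndarray, window: int) -> np.ndarray:
    """Means of all step-1 windows; windows containing NaN give NaN."""
    bad = np.isnan(arr)
    filled = np.where(bad, 0.0, arr)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    cbad = np.concatenate([[0], np.cumsum(bad)])
    sums = csum[window:] - csum[:-window]
    nbad = cbad[window:] - cbad[:-window]
    means = sums / window
    means[nbad > 0] = np.nan
    return means


def conserved_patch_scan(
    t: TranscriptModel,
    track: ConservationTrack,
    window: int = 12,
    patch_min: float = 0.6,
    whole_max: float = 0.3,
) -> PatchCall:
    """Slide a ``window``-bp window along the spliced transcript.

    A conserved patch requires a window mean strictly above ``patch_min``
    while the whole-transcript mean is strictly below ``whole_max``. The
    best (highest) window mean is reported regardless. Windows touching a
    missing-score base are disqualified rather than imputed.
    """
    arr = spliced_scores(t, track)
    if np.isnan(arr).all():
        return PatchCall(t.transcript_id, float("nan"), float("nan"), (), False, "unscored")
    whole = float(np.nanmean(arr))
    if len(arr) < window:
        return PatchCall(t.transcript_id, whole, float("nan"), (), False, "too_short")
    means = _window_means(arr, window)
    if np.isnan(means).all():
        return PatchCall(t.transcript_id, whole, float("nan"), (), False, "unscored")
    best = float(np.nanmax(means))
    patch_idx = np.flatnonzero(means > patch_min)
    patches = tuple((int(i), float(means[i])) for i in patch_idx)
    has_patch = whole < whole_max and len(patches) > 0
    return PatchCall(t.transcript_id, whole, best, patches, has_patch)


def class_conservation_profiles(
    classes: Mapping[str, Sequence[TranscriptModel]],
    track: ConservationTrack,
    cutoffs: Sequence[float] = (0.0, 0.6),
) -> pd.DataFrame:
    """Pool per-transcript mean scores by class.

    Returns one row per class with the mean vector (``means``), the
    fraction of scored transcripts with mean strictly above each cutoff,
    the fraction with mean exactly 0, and the empirical cumulative curve
    (sorted means) for plotting.
    """
    rows = []
    for cls, ts in classes.items():
        means = np.array([transcript_mean_score(t, track) for t in ts])
        scored = means[~np.isnan(means)]
        row = {
            "cls": cls,
            "n": len(ts),
            "n_scored": len(scored),
            "means": scored,
            "cumulative": np.sort(scored),
            "frac_zero": float((scored == 0).mean()) if len(scored) else float("nan"),
        }
        for c in cutoffs:
            row[f"frac_gt_{c:g}"] = (
                float((scored > c).mean()) if len(scored) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("cls")


def homology_conservation_matrix(
    hits: Sequence[HomologyHit],
    transcripts_per_species: Mapping[str, Sequence[str]],
    evalue_max: float = 1e-5,
    min_len: int = 50,
) -> pd.DataFrame:
    """Species x species matrix of homolog-retention fractions.

    Entry (a, b) is the fraction of species ``a`` transcripts with at
    least one hit to species ``b`` passing ``evalue <= evalue_max`` and
    ``align_len >= min_len``. Diagonal is 1 by convention.
    """
    species = list(transcripts_per_species)
    known = {sp: set(map(str, ids)) for sp, ids in transcripts_per_species.items()}
    passing: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        if h.query_species not in known:
            raise KeyError(f"hit from unknown species {h.query_species!r}")
        if h.query_id not in known[h.query_species]:
            raise KeyError(
                f"hit for unknown query {h.query_id!r} ({h.query_species})"
            )
        if h.evalue <= evalue_max and h.align_len >= min_len:
            passing.setdefault((h.query_species, h.subject_species), set()).add(
                h.query_id
            )
    mat = pd.DataFrame(0.0, index=species, columns=species)
    for a in species:
        n = len(known[a])
        for b in species:
            if a == b:
                mat.loc[a, b] = 1.0
            elif n:
                mat.loc[a, b] = len(passing.get((a, b), ())) / n
    return mat
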