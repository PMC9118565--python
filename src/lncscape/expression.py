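"""Tissue specificity (Jensen-Shannon score), expression summaries,
antisense-pair correlation and co-expression candidate selection.

The JS specificity of an expression vector p (normalized to sum 1) against
tissue t is ``1 - sqrt(JSD2(p, e_t))`` where JSD2 is the Jensen-Shannon
divergence in bits and e_t the indicator distribution of tissue t; the
transcript's score is the maximum over tissues. A score of 1 means
expression confined to one tissue. Note a perfectly uniform vector does
NOT score 0 — the comparison against an indicator keeps a positive floor
that shrinks as the tissue count grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy import stats

__all__ = [
    "js_specificity",
    "call_ts",
    "tissue_summary",
    "nat_pair_correlation",
    "wgcna_candidate_selection",
    "SpecificityScore",
    "SelectionReport",
]


@dataclass(frozen=True)
class SpecificityScore:
    transcript_id: str
    js_score: float
    argmax_tissue: str
    is_ts: bool


def js_specificity(
    vector: Sequence[float],
    tissues: Optional[Sequence[str]] = None,
    transcript_id: str = "",
    ts_threshold: float = 0.9,
    log_transform: bool = False,
) -> SpecificityScore:
    """JS tissue-specificity score of one expression vector.

    Raises on all-zero vectors (specificity is undefined, not 0). Ties in
    the per-tissue scores break by tissue order. Scale-invariant in the
    input; ``log_transform`` applies log10(x+1) first.
    """
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D vector over >= 2 tissues")
    if (v < 0).any():
        raise ValueError("negative expression values")
    if log_transform:
        v = np.log10(v + 1.0)
    total = v.sum()
    if total == 0:
        raise ValueError(
            f"transcript {transcript_id or '<anon>'}: all-zero expression, "
            "JS specificity undefined"
        )
    if tissues is None:
        tissues = [f"tissue_{i}" for i in range(len(v))]
    p = v / total
    scores = np.empty(len(v))
    for i in range(len(v)):
        e = np.zeros(len(v))
        e[i] = 1.0
        scores[i] = 1.0 - jensenshannon(p, e, base=2)
    best = int(np.argmax(scores))
    js = float(scores[best])
    return SpecificityScore(
        transcript_id=transcript_id,
        js_score=js,
        argmax_tissue=str(tissues[best]),
        is_ts=js >= ts_threshold,
    )


def ts_call_from_score(js_score: float, ts_threshold: float = 0.9) -> bool:
    """Tissue-specific iff js_score >= threshold (inclusive)."""
    return js_score >= ts_threshold


def call_ts(
    matrix: pd.DataFrame,
    ts_threshold: float = 0.9,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Score every row of an FPKM matrix and call TS transcripts.

    All-zero rows are flagged (``flagged`` column) and carry NaN scores
    rather than being silently scored 0.
    """
    tissues = list(matrix.columns)
    rows = []
    for tid, vec in matrix.iterrows():
        v = vec.to_numpy(dtype=float)
        if v.sum() == 0:
            rows.append(
                {
                    "transcript_id": tid,
                    "js_score": float("nan"),
                    "argmax_tissue": None,
                    "is_ts": False,
                    "flagged": True,
                }
            )
            continue
        s = js_specificity(
            v, tissues, transcript_id=str(tid),
            ts_threshold=ts_threshold, log_transform=log_transform,
        )
        rows.append(
            {
                "transcript_id": tid,
                "js_score": s.js_score,
                "argmax_tissue": s.argmax_tissue,
                "is_ts": s.is_ts,
                "flagged": False,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def tissue_summary(
    matrix: pd.DataFrame, classes: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-class per-tissue mean of log10(FPKM+1), plus pooled raw means.

    Returns (summary table with classes as rows and tissues as columns,
    per-class pooled mean FPKM).
    """
    log_rows = {}
    pooled = {}
    for cls, ids in classes.items():
        sub = matrix.loc[list(ids)]
        log_rows[cls] = np.log10(sub + 1.0).mean(axis=0)
        pooled[cls] = float(sub.to_numpy().mean())
    return pd.DataFrame(log_rows).T, pd.Series(pooled, name="mean_fpkm")


def nat_pair_correlation(
    matrix: pd.DataFrame,
    nat_pairs: Sequence[tuple[str, str]],
    genes_without_nat: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Pearson r across tissues for each (lncNAT, antisense gene) pair.

    Zero-variance members are flagged with NaN r rather than an error.
    Also returns the expression-level vectors (pooled mean FPKM per row)
    for genes with lncNATs vs without, for distribution comparison by the
    caller; test statistics are out of scope here.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 tissues for a correlation")
    rows = []
    for nat_id, gene_id in nat_pairs:
        for rid in (nat_id, gene_id):
            if rid not in matrix.index:
                raise KeyError(f"unknown id {rid!r} in nat_pairs")
        a = matrix.loc[nat_id].to_numpy(dtype=float)
        b = matrix.loc[gene_id].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            rows.append(
                {"lncNAT": nat_id, "gene": gene_id, "r": float("nan"), "flagged": True}
            )
        else:
            rows.append(
                {
                    "lncNAT": nat_id,
                    "gene": gene_id,
                    "r": float(stats.pearsonr(a, b).statistic),
                    "flagged": False,
                }
            )
    pairs_df = pd.DataFrame(rows, columns=["lncNAT", "gene", "r", "flagged"])
    dists: dict[str, np.ndarray] = {}
    genes_with = [g for _, g in nat_pairs]
    dists["genes_with_nat"] = matrix.loc[genes_with].mean(axis=1).to_numpy()
    if genes_without_nat is not None:
        dists["genes_without_nat"] = (
            matrix.loc[list(genes_without_nat)].mean(axis=1).to_numpy()
        )
    return pairs_df, dists


@dataclass(frozen=True)
class SelectionReport:
    """Co-expression-network candidates per selection rule."""

    lncNAT: tuple[str, ...]
    lincRNA: tuple[str, ...]
    mRNA: tuple[str, ...]
    params: dict

    @property
    def all_selected(self) -> set:
        return set(self.lncNAT) | set(self.lincRNA) | set(self.mRNA)


def wgcna_candidate_selection(
    matrix: pd.DataFrame,
    classes: Mapping[str, Sequence[str]],
    expressed_min: float = 0.1,
    top_frac: float = 0.10,
    fpkm_min: float = 1.0,
    rank_within_passing: bool = True,
) -> SelectionReport:
    """Select network-construction candidates per class.

    - lncNATs: expressed (FPKM >= ``expressed_min``) in exactly one or two
      tissues AND max FPKM in the top ``top_frac`` (default 10%) of lncNAT
      max-FPKMs; ranking is within the tissue-count-passing set by default
      (``rank_within_passing=False`` ranks against the whole class).
    - lincRNAs: expressed in one or two tissues AND max FPKM > ``fpkm_min``.
    - mRNAs: max FPKM > ``fpkm_min``.
    """
    def sub(ids):
        return matrix.loc[[i for i in ids if i in matrix.index]]

    nat = sub(classes.get("lncNAT", []))
    linc = sub(classes.get("lincRNA", []))
    mrna = sub(classes.get("mRNA", []))

    def tissue_count_ok(df):
        counts = (df >= expressed_min).sum(axis=1)
        return counts.isin([1, 2])

    nat_sel: tuple[str, ...] = ()
    if len(nat):
        ok = tissue_count_ok(nat)
        maxes = nat.max(axis=1)
        pool = maxes[ok] if rank_within_passing else maxes
        if len(pool):
            cutoff = pool.quantile(1.0 - top_frac)
            nat_sel = tuple(maxes.index[(ok) & (maxes >= cutoff)])
    linc_sel: tuple[str, ...] = ()
    if len(linc):
        linc_sel = tuple(
            linc.index[tissue_count_ok(linc) & (linc.max(axis=1) > fpkm_min)]
        )
    mrna_sel: tuple[str, ...] = ()
    if len(mrna):
        mrna_sel = tuple(mrna.index[mrna.max(axis=1) > fpkm_min])
    return SelectionReport(
        lncNAT=nat_sel,
        lincRNA=linc_sel,
        mRNA=mrna_sel,
        params={
            "expressed_min": expressed_min,
            "top_frac": top_frac,
            "fpkm_min": fpkm_min,
            "rank_within_passing": rank_within_passing,
        },
    )
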