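"""Independent brute-force oracles and small builders shared by the tests.

Everything here recomputes quantities per-base / by direct formula,
deliberately avoiding the package's interval arithmetic so the two routes
stay independent.
"""

from __future__ import annotations

import math

import numpy as np

from lncscape.intervals import GenomicInterval
from lncscape.models import GeneModel, TranscriptModel


def make_tx(tid, chrom, strand, exons, gene_id=None):
    exs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons))
    span = GenomicInterval(chrom, exs[0].start, exs[-1].end, strand)
    return TranscriptModel(tid, gene_id or tid, span, exs)


def make_gene(gid, chrom, strand, exons, cds=None):
    tx = make_tx(gid + ".t1", chrom, strand, exons, gene_id=gid)
    cds_ivs = tuple(
        GenomicInterval(chrom, s, e, strand) for s, e in (cds or [])
    )
    return GeneModel(gid, tx.interval, (tx,), cds_ivs, (), ())


def baseset(pairs) -> set[int]:
    return {p for s, e in pairs for p in range(s, e)}


def brute_overlap_bp(a_pairs, b_pairs) -> int:
    """Per-base membership count of the intersection of two interval sets."""
    return len(baseset(a_pairs) & baseset(b_pairs))


def brute_classify(t: TranscriptModel, genes) -> str:
    """Per-base positional classifier mirroring the documented precedence:
    sense exon overlap > antisense exon overlap > intronic > intergenic."""
    tbases = baseset(t.exon_pairs)
    sense = antisense = 0
    in_span = False
    for g in genes:
        if g.chrom != t.chrom:
            continue
        gbases = baseset(g.exon_pairs)
        hit = len(tbases & gbases)
        if g.strand == t.strand:
            sense += hit
        else:
            antisense += hit
        if (
            g.interval.start < t.interval.end
            and t.interval.start < g.interval.end
        ):
            in_span = True
    if sense > 0:
        return "sense_overlap_excluded"
    if antisense >= 1:
        return "lncNAT"
    if in_span:
        return "intronic"
    return "lincRNA"


def entropy_bits(p) -> float:
    """Shannon entropy in bits with the 0*log0 := 0 convention."""
    return float(-sum(x * math.log2(x) for x in p if x > 0))


def js_score_oracle(vector, tissue: int) -> float:
    """1 - sqrt(JSD in bits) against the indicator of one tissue, by the
    textbook entropy formula."""
    v = np.asarray(vector, dtype=float)
    p = v / v.sum()
    e = np.zeros(len(p))
    e[tissue] = 1.0
    m = (p + e) / 2.0
    jsd = entropy_bits(m) - (entropy_bits(p) + entropy_bits(e)) / 2.0
    return 1.0 - math.sqrt(max(jsd, 0.0))


def js_best_oracle(vector) -> float:
    return max(js_score_oracle(vector, i) for i in range(len(vector)))


def pearson_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def brute_window_means(arr, window) -> list[float]:
    """Window means by direct summation; NaN if any base missing."""
    out = []
    for i in range(len(arr) - window + 1):
        chunk = arr[i : i + window]
        out.append(float("nan") if np.isnan(chunk).any() else float(np.mean(chunk)))
    return out


def random_annotation(rng, genome_len=50_000, n_genes=15, n_tx=20):
    """A random small gene landscape + candidate transcripts (<= 50 kb)."""
    genes = []
    pos = int(rng.integers(0, 500))
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        exons = []
        for _ in range(n_ex):
            elen = int(rng.integers(80, 300))
            if pos + elen > genome_len - 1000:
                break
            exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(50, 150))
        if not exons:
            break
        genes.append(make_gene(f"g{i}", "c", strand, exons))
        pos += int(rng.integers(100, 800))
    txs = []
    for i in range(n_tx):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, genome_len - 2000))
        n_ex = int(rng.integers(1, 3))
        exons = []
        p = start
        for _ in range(n_ex):
            elen = int(rng.integers(150, 600))
            exons.append((p, p + elen))
            p += elen + int(rng.integers(60, 200))
        txs.append(make_tx(f"t{i}", "c", strand, exons))
    return genes, txs
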