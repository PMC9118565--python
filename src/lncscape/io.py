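"""Readers and writers for the standard formats the pipeline touches.

All genomic formats are normalized on read to 0-based half-open
coordinates (GTF/GFF3/RepeatMasker/VCF are 1-based on disk) and restored
on write, so the rest of the package only ever sees one convention.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .intervals import GenomicInterval
from .models import (
    ConservationTrack,
    GeneModel,
    HomologyHit,
    Peak,
    TERecord,
    TranscriptModel,
    VariantRecord,
    classify_repeat_family,
    validate_expression_matrix,
)

logger = logging.getLogger("lncscape")

SequenceSource = Union[Mapping[str, str], "pyfaidx.Fasta"]  # noqa: F821


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

def _parse_feature(line: str, lineno: int, path: str):
    if line.count("\t") < 8:
        raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
    try:
        return feature_from_line(line)
    except Exception as exc:  # malformed row or attribute field
        raise ValueError(f"{path}:{lineno}: cannot parse feature line ({exc})") from exc


def read_gtf(path: str) -> list[TranscriptModel]:
    """Read exon features from a GTF into transcript models.

    Exons are grouped by ``transcript_id``, sorted by start, and converted
    from 1-based closed to internal 0-based half-open coordinates.
    """
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    gene_of: dict[str, str] = {}
    biotype_of: dict[str, Optional[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_feature(line, lineno, path)
            if feat.featuretype != "exon":
                continue
            if "transcript_id" not in feat.attributes:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes.get("gene_id", [tid])[0]
            if tid not in exons:
                order.append(tid)
            exons[tid].append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
            gene_of[tid] = gid
            hint = feat.attributes.get("transcript_biotype") or feat.attributes.get(
                "biotype"
            )
            biotype_of[tid] = hint[0] if hint else None
    out = []
    for tid in order:
        exs = tuple(sorted(exons[tid], key=lambda iv: iv.start))
        span = GenomicInterval(
            exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand
        )
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of[tid],
                interval=span,
                exons=exs,
                biotype_hint=biotype_of[tid],
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str, source: str = "lncscape") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for ex in t.exons:
                attrs = f'transcript_id "{t.transcript_id}"; gene_id "{t.gene_id}";'
                if t.biotype_hint:
                    attrs += f' transcript_biotype "{t.biotype_hint}";'
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def write_gff3(
    transcripts: Iterable[TranscriptModel],
    path: str,
    classes: Optional[Mapping[str, str]] = None,
    source: str = "lncscape",
) -> None:
    """Write transcripts as GFF3 with an optional ``class=`` attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            attrs = f"ID={t.transcript_id};gene_id={t.gene_id}"
            if classes and t.transcript_id in classes:
                attrs += f";class={classes[t.transcript_id]}"
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for k, ex in enumerate(t.exons, start=1):
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={t.transcript_id}.exon{k};"
                    f"Parent={t.transcript_id}\n"
                )


_UTR5_TYPES = {"five_prime_UTR", "5UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR", "three_prime_utr"}


def read_gff3_genes(path: str) -> list[GeneModel]:
    """Read a coding-gene annotation (gene/mRNA/exon/CDS/UTR hierarchy)."""
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_feats: dict[str, dict[str, list[GenomicInterval]]] = defaultdict(
        lambda: defaultdict(list)
    )
    tx_span: dict[str, GenomicInterval] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_feature(line, lineno, path)
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            ftype = feat.featuretype
            if ftype == "gene":
                gid = feat.attributes["ID"][0]
                genes[gid] = {"interval": iv}
                order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                tid = feat.attributes["ID"][0]
                parent = feat.attributes.get("Parent") or feat.attributes.get("gene_id")
                if parent:  # orphan transcripts (no gene feature) are skipped
                    tx_parent[tid] = parent[0]
                tx_span[tid] = iv
            elif ftype in ("exon", "CDS") or ftype in _UTR5_TYPES or ftype in _UTR3_TYPES:
                parent = feat.attributes["Parent"][0]
                key = (
                    "utr5" if ftype in _UTR5_TYPES
                    else "utr3" if ftype in _UTR3_TYPES
                    else ftype
                )
                tx_feats[parent][key].append(iv)

    out: list[GeneModel] = []
    by_gene_tx: dict[str, list[str]] = defaultdict(list)
    for tid, gid in tx_parent.items():
        by_gene_tx[gid].append(tid)
    for gid in order:
        rec = genes[gid]
        transcripts = []
        cds: list[GenomicInterval] = []
        utr5: list[GenomicInterval] = []
        utr3: list[GenomicInterval] = []
        for tid in by_gene_tx.get(gid, []):
            feats = tx_feats[tid]
            exs = tuple(sorted(feats.get("exon", []), key=lambda x: x.start))
            if not exs:  # fall back to CDS+UTRs as the exon structure
                exs = tuple(
                    sorted(
                        feats.get("CDS", []) + feats.get("utr5", []) + feats.get("utr3", []),
                        key=lambda x: x.start,
                    )
                )
            if not exs:
                continue
            span = tx_span.get(
                tid,
                GenomicInterval(exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand),
            )
            transcripts.append(
                TranscriptModel(tid, gid, span, exs, biotype_hint="mRNA")
            )
            cds.extend(feats.get("CDS", []))
            utr5.extend(feats.get("utr5", []))
            utr3.extend(feats.get("utr3", []))
        out.append(
            GeneModel(
                gene_id=gid,
                interval=rec["interval"],
                transcripts=tuple(transcripts),
                cds=tuple(cds),
                utr5=tuple(utr5),
                utr3=tuple(utr3),
            )
        )
    return out


def write_gff3_genes(genes: Iterable[GeneModel], path: str, source: str = "lncscape") -> None:
    def row(iv: GenomicInterval, ftype: str, attrs: str) -> str:
        return (
            f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(row(g.interval, "gene", f"ID={g.gene_id}"))
            for t in g.transcripts:
                fh.write(row(t.interval, "mRNA", f"ID={t.transcript_id};Parent={g.gene_id}"))
                for k, ex in enumerate(t.exons, start=1):
                    fh.write(
                        row(ex, "exon", f"ID={t.transcript_id}.e{k};Parent={t.transcript_id}")
                    )
            tid0 = g.transcripts[0].transcript_id if g.transcripts else g.gene_id
            for iv in g.utr5:
                fh.write(row(iv, "five_prime_UTR", f"Parent={tid0}"))
            for iv in g.cds:
                fh.write(row(iv, "CDS", f"Parent={tid0}"))
            for iv in g.utr3:
                fh.write(row(iv, "three_prime_UTR", f"Parent={tid0}"))


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: str) -> list[TERecord]:
    """Parse a RepeatMasker ``.out`` annotation (3 header lines, 1-based
    inclusive query coordinates, strand 'C' meaning minus)."""
    out: list[TERecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        fields = line.split()
        if not fields:
            continue
        if len(fields) < 11:
            raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
        chrom, qbegin, qend = fields[4], int(fields[5]), int(fields[6])
        strand = "-" if fields[8] == "C" else "+"
        repeat_name, family = fields[9], fields[10]
        te_class = classify_repeat_family(family)
        if te_class == "other":
            logger.warning(
                "%s:%d: repeat family %r mapped to te_class 'other'",
                path, lineno, family,
            )
        out.append(
            TERecord(
                interval=GenomicInterval(chrom, qbegin - 1, qend, strand),
                repeat_name=repeat_name,
                repeat_family=family,
                te_class=te_class,
            )
        )
    return out


def write_repeatmasker_out(tes: Iterable[TERecord], path: str) -> None:
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, te in enumerate(tes, start=1):
            iv = te.interval
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"  225  10.0  0.0  0.0  {iv.chrom}  {iv.start + 1}  {iv.end}  (0)  "
                f"{strand}  {te.repeat_name}  {te.repeat_family}  1  {iv.length}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_filtered(
    path: str, min_qual: float = 10.0, min_depth: int = 5
) -> list[VariantRecord]:
    """Read SNPs passing strict quality/depth thresholds.

    A record is kept iff qual > ``min_qual`` AND depth > ``min_depth`` AND
    both ref and alt are single bases. Depth comes from INFO/DP, falling
    back to the summed per-sample FORMAT/DP. Records sharing a position
    (e.g. merged calls from several libraries) collapse to one.
    """
    from cyvcf2 import VCF

    out: dict[tuple[str, int], VariantRecord] = {}
    n_missing_dp = 0
    vcf = VCF(path)
    for v in vcf:
        qual = v.QUAL
        if qual is None:
            n_missing_dp += 1
            continue
        depth = v.INFO.get("DP")
        if depth is None:
            try:
                dps = v.format("DP")
            except Exception:
                dps = None
            if dps is None:
                n_missing_dp += 1
                continue
            depth = int(np.nansum(np.where(np.asarray(dps) < 0, 0, dps)))
        if qual <= min_qual or depth <= min_depth:
            continue
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            continue
        key = (v.CHROM, v.POS - 1)
        if key not in out:
            out[key] = VariantRecord(
                chrom=v.CHROM, pos=v.POS - 1, ref=v.REF, alt=v.ALT[0],
                qual=float(qual), depth=int(depth),
            )
    vcf.close()
    if n_missing_dp:
        logger.warning("%s: dropped %d records without QUAL/DP", path, n_missing_dp)
    return sorted(out.values(), key=lambda r: (r.chrom, r.pos))


def write_vcf(
    records: Iterable[VariantRecord],
    path: str,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        for chrom, size in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t{r.qual:g}\t.\t"
                f"DP={r.depth}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph conservation track
# ---------------------------------------------------------------------------

def read_conservation_bedgraph(
    path: str, chrom_sizes: Optional[Mapping[str, int]] = None
) -> ConservationTrack:
    """Expand a bedGraph of per-base conservation probabilities.

    Intervals are 0-based half-open; overlapping intervals or values
    outside [0, 1] are contract violations and raise. Uncovered bases are
    NaN (missing).
    """
    spans: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    max_end: dict[str, int] = defaultdict(int)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph row needs 4 columns")
            chrom, start, end, value = (
                fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
            )
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: conservation score {value} outside [0, 1]"
                )
            spans[chrom].append((start, end, value))
            max_end[chrom] = max(max_end[chrom], end)
    arrays: dict[str, np.ndarray] = {}
    for chrom, rows in spans.items():
        size = chrom_sizes[chrom] if chrom_sizes else max_end[chrom]
        arr = np.full(size, np.nan)
        covered = np.zeros(size, dtype=bool)
        for start, end, value in rows:
            if covered[start:end].any():
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
            arr[start:end] = value
            covered[start:end] = True
        arrays[chrom] = arr
    return ConservationTrack(arrays)


def write_bedgraph(track_values: Mapping[str, np.ndarray], path: str) -> None:
    """Write per-base arrays as a run-length-compressed bedGraph (NaN = gap)."""
    with open(path, "w") as fh:
        for chrom in sorted(track_values):
            arr = np.asarray(track_values[chrom], dtype=float)
            i = 0
            n = len(arr)
            while i < n:
                if np.isnan(arr[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and not np.isnan(arr[j]) and arr[j] == arr[i]:
                    j += 1
                fh.write(f"{chrom}\t{i}\t{j}\t{arr[i]:.6g}\n")
                i = j


# ---------------------------------------------------------------------------
# FASTA and sequence access
# ---------------------------------------------------------------------------

def read_fasta(path: str):
    """Open a FASTA for random access (pyfaidx; writes a .fai sidecar)."""
    import pyfaidx

    return pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def fetch_seq(genome: SequenceSource, chrom: str, start: int, end: int) -> str:
    """Uppercase sequence of [start, end); works on pyfaidx.Fasta or a dict."""
    if isinstance(genome, Mapping):
        seq = genome[chrom][start:end]
    else:
        seq = str(genome[chrom][start:end])
    if len(seq) != end - start:
        raise ValueError(
            f"interval {chrom}:{start}-{end} extends beyond sequence end"
        )
    return seq.upper()


def chrom_length(genome: SequenceSource, chrom: str) -> int:
    if isinstance(genome, Mapping):
        return len(genome[chrom])
    return len(genome[chrom])


# ---------------------------------------------------------------------------
# Peaks (BED6 / narrowPeak)
# ---------------------------------------------------------------------------

def read_peaks(path: str) -> list[Peak]:
    """Read ChIP-seq peaks from BED6 or narrowPeak.

    The peak name column carries the TF name. narrowPeak column 10 is the
    summit offset; a missing/-1 summit falls back to the peak midpoint
    (logged).
    """
    out: list[Peak] = []
    n_no_summit = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), ".")
            tf = f[3] if len(f) > 3 else "peak"
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            summit = None
            if len(f) >= 10:
                off = int(f[9])
                if off >= 0:
                    summit = iv.start + off
            if summit is None:
                n_no_summit += 1
            out.append(Peak(interval=iv, tf_name=tf, score=score, summit=summit))
    if n_no_summit:
        logger.warning("%s: %d peaks without summit; using midpoints", path, n_no_summit)
    return out


def write_narrowpeak(peaks: Iterable[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            offset = (p.summit - iv.start) if p.summit is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.tf_name}\t{p.score:g}\t.\t"
                f"0\t-1\t-1\t{offset}\n"
            )


# ---------------------------------------------------------------------------
# Tables: expression, candidate flags, BLAST outfmt 6
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str) -> pd.DataFrame:
    """Transcripts x tissues FPKM table; first column = transcript id."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    return validate_expression_matrix(expr)


def write_expression_tsv(expr: pd.DataFrame, path: str) -> None:
    expr.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6g")


FLAG_COLUMNS = [
    "coding_by_cpc", "coding_by_plek",
    "has_swissprot_hit", "has_pfam_hit", "has_rfam_hit",
]


def read_flags_tsv(path: str) -> pd.DataFrame:
    """Coding-potential / homology flag table, one row per candidate."""
    flags = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in FLAG_COLUMNS if c not in flags.columns]
    if missing:
        raise ValueError(f"{path}: missing flag columns {missing}")
    return flags[FLAG_COLUMNS].astype(bool)


def write_flags_tsv(flags: pd.DataFrame, path: str) -> None:
    flags.to_csv(path, sep="\t", index_label="transcript_id")


def read_blast_tab(path: str, query_species: str, subject_species: str) -> list[HomologyHit]:
    """Read blastn tabular output (outfmt 6) for one species pair."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    try:
        df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    except pd.errors.EmptyDataError:
        return []
    return [
        HomologyHit(
            query_id=str(r.qseqid),
            query_species=query_species,
            subject_species=subject_species,
            identity_pct=float(r.pident),
            align_len=int(r.length),
            evalue=float(r.evalue),
        )
        for r in df.itertuples()
    ]


def write_blast_tab(hits: Iterable[HomologyHit], path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\tsubject\t{h.identity_pct:g}\t{h.align_len}\t0\t0\t"
                f"1\t{h.align_len}\t1\t{h.align_len}\t{h.evalue:g}\t100\n"
            )
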