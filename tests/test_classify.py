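"""Identification filters and lincRNA/lncNAT classification."""

import numpy as np
import pandas as pd
import pytest

from lncscape.classify import (
    IdentificationThresholds,
    antisense_exon_overlap,
    apply_identification_filters,
    classification_report,
    classify_transcripts,
)
from lncscape.io import FLAG_COLUMNS
from oracle_utils import brute_classify, brute_overlap_bp, make_gene, make_tx


def _flags(ids, **overrides):
    df = pd.DataFrame(False, index=list(ids), columns=FLAG_COLUMNS)
    for tid, cols in overrides.items():
        for c in cols:
            df.loc[tid, c] = True
    return df


def _expr(values):  # {tid: vector}
    return pd.DataFrame.from_dict(values, orient="index")


class TestIdentificationFilters:
    def test_passing_single_exon(self):
        t = make_tx("t", "c", "+", [(0, 300)])
        out = apply_identification_filters(
            [t], _flags(["t"]), _expr({"t": [0.6, 0.0]})
        )
        assert out.loc[0, "cls"] == "pending"
        assert out.loc[0, "fail_reasons"] == frozenset()

    def test_length_exactly_200_fails(self):
        """'longer than 200 bp' is strict: 200 is out, 201 is in."""
        t200 = make_tx("a", "c", "+", [(0, 200)])
        t201 = make_tx("b", "c", "+", [(0, 201)])
        out = apply_identification_filters(
            [t200, t201], _flags(["a", "b"]), _expr({"a": [2.0], "b": [2.0]})
        ).set_index("transcript_id")
        assert out.loc["a", "fail_reasons"] == frozenset({"length"})
        assert out.loc["b", "cls"] == "pending"

    def test_fpkm_thresholds_strict_and_exon_dependent(self):
        single = make_tx("s", "c", "+", [(0, 400)])
        multi = make_tx("m", "c", "+", [(0, 300), (500, 800)])
        out = apply_identification_filters(
            [single, multi],
            _flags(["s", "m"]),
            _expr({"s": [0.5, 0.2], "m": [0.1, 0.05]}),
        ).set_index("transcript_id")
        assert out.loc["s", "fail_reasons"] == frozenset({"expression"})
        assert out.loc["m", "fail_reasons"] == frozenset({"expression"})
        out2 = apply_identification_filters(
            [single, multi],
            _flags(["s", "m"]),
            _expr({"s": [0.51, 0.2], "m": [0.11, 0.05]}),
        )
        assert (out2["cls"] == "pending").all()

    def test_all_failed_criteria_recorded(self):
        t = make_tx("t", "c", "+", [(0, 150)])
        out = apply_identification_filters(
            [t],
            _flags(["t"], t=["coding_by_cpc", "has_rfam_hit"]),
            _expr({"t": [0.01]}),
        )
        assert out.loc[0, "fail_reasons"] == frozenset(
            {"length", "coding_potential", "homology", "expression"}
        )

    def test_missing_rows_raise(self):
        t = make_tx("t", "c", "+", [(0, 300)])
        with pytest.raises(KeyError, match="t"):
            apply_identification_filters([t], _flags([]), _expr({"t": [1.0]}))
        with pytest.raises(KeyError, match="t"):
            apply_identification_filters([t], _flags(["t"]), _expr({"x": [1.0]}))

    def test_pending_count_monotone_in_thresholds(self, bundle):
        """Raising any FPKM threshold never increases survivors."""
        prev = None
        for fpkm in (0.0, 0.1, 0.5, 2.0, 10.0):
            th = IdentificationThresholds(fpkm_single=fpkm, fpkm_multi=fpkm)
            n = (
                apply_identification_filters(
                    bundle.candidates, bundle.flags, bundle.expression, th
                )["cls"]
                == "pending"
            ).sum()
            if prev is not None:
                assert n <= prev
            prev = n


class TestAntisenseOverlap:
    def test_direct_intersection(self):
        t = make_tx("t", "c", "-", [(100, 200)])
        g = make_gene("g", "c", "+", [(150, 250)])
        bp, partners = antisense_exon_overlap(t, [g])
        assert bp == 50 and partners == ["g"]

    def test_same_strand_ignored(self):
        t = make_tx("t", "c", "-", [(100, 200)])
        g = make_gene("g", "c", "-", [(150, 250)])
        assert antisense_exon_overlap(t, [g]) == (0, [])

    def test_multi_exon_union(self):
        t = make_tx("t", "c", "+", [(0, 100), (200, 300)])
        g = make_gene("g", "c", "-", [(50, 250)])
        bp, _ = antisense_exon_overlap(t, [g])
        assert bp == brute_overlap_bp(t.exon_pairs, g.exon_pairs) == 100

    def test_no_double_counting_across_genes(self):
        t = make_tx("t", "c", "+", [(0, 100)])
        g1 = make_gene("g1", "c", "-", [(10, 60)])
        g2 = make_gene("g2", "c", "-", [(40, 90)])
        bp, partners = antisense_exon_overlap(t, [g1, g2])
        assert bp == 80  # union (10, 90), not 50 + 50
        assert partners == ["g1", "g2"]


class TestClassify:
    def test_intergenic_is_lincRNA(self):
        t = make_tx("t", "c", "+", [(50_000, 50_400)])
        g = make_gene("g", "c", "+", [(0, 1000)])
        out = classify_transcripts([t], [g])
        assert out.loc[0, "cls"] == "lincRNA"

    def test_antisense_within_exon_is_lncNAT(self):
        g = make_gene("g", "c", "+", [(1000, 2000)])
        t = make_tx("t", "c", "-", [(1200, 1700)])
        out = classify_transcripts([t], [g])
        assert out.loc[0, "cls"] == "lncNAT"
        assert out.loc[0, "antisense_overlap_bp"] == 500
        assert out.loc[0, "antisense_partner_genes"] == ["g"]

    def test_sense_overlap_excluded(self):
        g = make_gene("g", "c", "+", [(1000, 2000)])
        t = make_tx("t", "c", "+", [(1970, 2300)])
        out = classify_transcripts([t], [g])
        assert out.loc[0, "cls"] == "sense_overlap_excluded"
        assert out.loc[0, "sense_overlap_bp"] == 30

    def test_intronic_only_overlap(self):
        g = make_gene("g", "c", "+", [(0, 200), (1000, 1200)])
        t = make_tx("t", "c", "+", [(300, 700)])
        out = classify_transcripts([t], [g])
        assert out.loc[0, "cls"] == "intronic"

    def test_unstranded_transcript_rejected(self):
        t = make_tx("t", "c", ".", [(0, 300)])
        with pytest.raises(ValueError, match="strand"):
            classify_transcripts([t], [])

    def test_partition_property(self, bundle, classified):
        """Every candidate gets exactly one class; counts sum to input."""
        report = classified["report"]
        assert len(report) == len(bundle.candidates)
        assert report.index.is_unique
        assert report["cls"].isin(
            ["lincRNA", "lncNAT", "sense_overlap_excluded", "intronic", "filtered_out"]
        ).all()

    def test_matches_per_base_bruteforce_on_random_annotations(self):
        """Interval-tree classification equals a per-base classifier."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes, txs = random_annotation_safe(rng)
            out = classify_transcripts(txs, genes).set_index("transcript_id")
            for t in txs:
                assert out.loc[t.transcript_id, "cls"] == brute_classify(t, genes), (
                    f"seed={seed} tx={t.transcript_id}"
                )


def random_annotation_safe(rng):
    from oracle_utils import random_annotation

    return random_annotation(rng)


def test_classification_report_merges_and_rejects_duplicates():
    t = make_tx("t", "c", "+", [(0, 300)])
    ftab = apply_identification_filters([t], _flags(["t"]), _expr({"t": [2.0]}))
    ctab = classify_transcripts([t], [])
    rep = classification_report(ftab, ctab)
    assert list(rep["cls"]) == ["lincRNA"]
    dup = pd.concat([ctab, ctab], ignore_index=True)
    with pytest.raises(ValueError, match="twice"):
        classification_report(ftab, dup)
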