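"""TE overlap, class composition, TE-derived promoters, TF sites."""

import numpy as np
import pandas as pd
import pytest

from lncscape.intervals import GenomicInterval
from lncscape.models import Peak, TERecord
from lncscape.te_origin import (
    PromoterRule,
    promoter_window,
    te_class_distribution,
    te_derived_promoters,
    te_overlap,
    te_promoter_genome_correlation,
    tf_sites_in_te_promoters,
)
from oracle_utils import brute_overlap_bp, make_gene, make_tx, pearson_oracle


def _te(s, e, fam="LTR/Gypsy", name="TE"):
    return TERecord(GenomicInterval("c", s, e, "+"), name, fam)


class TestTEOverlap:
    def test_five_bp_threshold(self):
        t = make_tx("t", "c", "+", [(100, 200)])
        table, _ = te_overlap({"lincRNA": [t]}, [_te(195, 210)])
        assert table.loc[0, "exonic_te_bp"] == 5
        assert bool(table.loc[0, "is_te_lnc"])
        table4, _ = te_overlap({"lincRNA": [t]}, [_te(196, 210)])
        assert table4.loc[0, "exonic_te_bp"] == 4
        assert not bool(table4.loc[0, "is_te_lnc"])

    def test_gene_body_vs_exonic(self):
        t = make_tx("t", "c", "+", [(0, 100), (900, 1000)])
        table, _ = te_overlap({"lincRNA": [t]}, [_te(400, 500)])
        assert table.loc[0, "gene_body_te_bp"] == 100
        assert table.loc[0, "exonic_te_bp"] == 0
        assert not bool(table.loc[0, "is_te_lnc"])

    def test_gene_uses_cds_for_exonic(self):
        g = make_gene("g", "c", "+", [(0, 1000)], cds=[(200, 800)])
        table, _ = te_overlap({"coding": [g]}, [_te(0, 150)])
        assert table.loc[0, "gene_body_te_bp"] == 150
        assert table.loc[0, "exonic_te_bp"] == 0  # outside CDS

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        tes = [
            _te(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 5000, 30), rng.integers(10, 300, 30))
        ]
        te_pairs = [(te.interval.start, te.interval.end) for te in tes]
        for i in range(10):
            start = int(rng.integers(0, 4000))
            t = make_tx(f"t{i}", "c", "+", [(start, start + 400)])
            table, _ = te_overlap({"x": [t]}, tes)
            assert table.loc[0, "exonic_te_bp"] == brute_overlap_bp(
                t.exon_pairs, te_pairs
            )

    def test_is_te_lnc_monotone_in_min_bp(self, bundle):
        counts = []
        for min_bp in (1, 5, 20, 100, 1000):
            table, _ = te_overlap({"all": bundle.candidates}, bundle.tes, min_bp)
            counts.append(int(table["is_te_lnc"].sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_min_bp_validation(self):
        with pytest.raises(ValueError):
            te_overlap({}, [], min_bp=0)


class TestClassDistribution:
    def test_fractions(self):
        tes = [_te(0, 100, "LTR/Gypsy"), _te(200, 250, "DNA/MuDR")]
        out = te_class_distribution(tes, {"r": {"c": [(0, 300)]}})
        assert out.loc["r", "class_I_frac"] == pytest.approx(2 / 3)
        assert out.loc["r", "class_II_frac"] == pytest.approx(1 / 3)

    def test_partial_intersection_and_other(self):
        tes = [_te(0, 100, "LTR/Gypsy"), _te(500, 600, "Simple_repeat")]
        out = te_class_distribution(tes, {"r": {"c": [(50, 700)]}})
        assert out.loc["r", "class_I_frac"] == 1.0
        assert out.loc["r", "other_bp"] == 100

    def test_empty_region_is_nan(self):
        out = te_class_distribution([_te(0, 10)], {"r": {}})
        assert np.isnan(out.loc["r", "class_I_frac"])

    def test_matches_per_base_tally(self):
        rng = np.random.default_rng(9)
        fams = ["LTR/Gypsy", "DNA/hAT", "LINE/L1", "RC/Helitron"]
        tes = []
        for s in rng.integers(0, 8000, 40):
            tes.append(_te(int(s), int(s) + int(rng.integers(20, 200)),
                           fams[int(rng.integers(0, 4))]))
        region = {"c": [(1000, 6000)]}
        out = te_class_distribution(tes, {"r": region})
        tally = {"I": 0, "II": 0}
        for te in tes:
            if te.te_class in tally:
                tally[te.te_class] += brute_overlap_bp(
                    [(te.interval.start, te.interval.end)], region["c"]
                )
        # brute force double counts overlapping TE copies exactly as the
        # implementation does (per TE record, not per unique base)
        total = tally["I"] + tally["II"]
        assert out.loc["r", "class_I_bp"] == tally["I"]
        assert out.loc["r", "class_I_frac"] == pytest.approx(tally["I"] / total)


class TestPromoters:
    def test_window_plus_minus_clip(self):
        tp = make_tx("p", "c", "+", [(5000, 5800)])
        assert promoter_window(tp) == GenomicInterval("c", 4000, 5000, "+")
        tm = make_tx("m", "c", "-", [(2000, 3000)])
        assert promoter_window(tm) == GenomicInterval("c", 3000, 4000, "-")
        tc = make_tx("x", "c", "+", [(400, 900)])
        assert promoter_window(tc) == GenomicInterval("c", 0, 400, "+")

    def test_zero_length_after_clip_raises(self):
        t = make_tx("t", "c", "-", [(0, 500)])
        with pytest.raises(ValueError, match="empty"):
            promoter_window(t, size=1000, chrom_sizes={"c": 500})

    def test_tss_clause(self):
        t = make_tx("t", "c", "+", [(5000, 5600)])
        _, frac = te_derived_promoters({"x": [t]}, [_te(4950, 5010)])
        assert frac["x"] == 1.0

    def test_coverage_clause(self):
        t = make_tx("t", "c", "+", [(5000, 5600)])
        _, frac60 = te_derived_promoters({"x": [t]}, [_te(4100, 4700)])
        assert frac60["x"] == 1.0  # 600/1000 >= 0.5
        _, frac10 = te_derived_promoters({"x": [t]}, [_te(4100, 4200)])
        assert frac10["x"] == 0.0

    def test_fraction_monotone_in_cover_frac_without_tss_clause(self, bundle):
        lincs = [t for t in bundle.candidates if t.transcript_id.startswith("LINC")]
        fracs = []
        for cf in (0.1, 0.3, 0.5, 0.8, 1.0):
            _, f = te_derived_promoters(
                {"lincRNA": lincs}, bundle.tes,
                PromoterRule(cover_frac=cf, tss_clause=False),
                chrom_sizes=bundle.chrom_sizes,
            )
            fracs.append(float(f["lincRNA"]))
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestTFSites:
    def _calls(self, t, tes):
        calls, _ = te_derived_promoters({"x": [t]}, tes)
        return calls

    def test_summit_in_te_segment_counted(self):
        t = make_tx("t", "c", "+", [(5000, 5600)])
        tes = [_te(4400, 4800)]
        calls = self._calls(t, tes)
        peaks = [Peak(GenomicInterval("c", 4500, 4700), "TF1", summit=4600)]
        table, freq = tf_sites_in_te_promoters(calls, peaks, tes)
        assert bool(table.loc[0, "tf_hit_in_te"])
        assert table.loc[0, "tf_hits"] == ["TF1"]
        assert freq["x"] == 1.0

    def test_summit_in_promoter_outside_te(self):
        t = make_tx("t", "c", "+", [(5000, 5600)])
        tes = [_te(4400, 4500)]
        calls = self._calls(t, tes)
        peaks = [Peak(GenomicInterval("c", 4800, 4950), "TF1", summit=4900)]
        table, _ = tf_sites_in_te_promoters(calls, peaks, tes)
        assert bool(table.loc[0, "has_tf_hit"])
        assert not bool(table.loc[0, "tf_hit_in_te"])

    def test_summit_outside_promoter_ignored(self):
        t = make_tx("t", "c", "+", [(5000, 5600)])
        calls = self._calls(t, [])
        peaks = [Peak(GenomicInterval("c", 100, 300), "TF1", summit=200)]
        table, freq = tf_sites_in_te_promoters(calls, peaks, [])
        assert not bool(table.loc[0, "has_tf_hit"])
        assert freq["x"] == 0.0


class TestCorrelation:
    def test_perfect_linear(self):
        df = pd.DataFrame(
            {"genome_te_frac": [0.1, 0.2, 0.3, 0.4],
             "lincRNA": [0.2, 0.4, 0.6, 0.8],
             "lncNAT": [0.8, 0.6, 0.4, 0.2]}
        )
        r = te_promoter_genome_correlation(df)
        assert r["lincRNA"] == pytest.approx(1.0)
        assert r["lncNAT"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {"genome_te_frac": rng.random(8), "lincRNA": rng.random(8)}
        )
        r = te_promoter_genome_correlation(df)["lincRNA"]
        assert r == pytest.approx(
            pearson_oracle(df["genome_te_frac"], df["lincRNA"]), abs=1e-12
        )

    def test_few_rows_and_zero_variance(self):
        with pytest.raises(ValueError, match="3 species"):
            te_promoter_genome_correlation(
                pd.DataFrame({"genome_te_frac": [0.1, 0.2], "x": [0.1, 0.2]})
            )
        df = pd.DataFrame(
            {"genome_te_frac": [0.1, 0.2, 0.3], "x": [0.5, 0.5, 0.5]}
        )
        assert np.isnan(te_promoter_genome_correlation(df)["x"])
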