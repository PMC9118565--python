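"""JS tissue specificity, TS calls, summaries, NAT pairs, candidate selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncscape.expression import (
    call_ts,
    js_specificity,
    nat_pair_correlation,
    tissue_summary,
    ts_call_from_score,
    wgcna_candidate_selection,
)
from oracle_utils import js_best_oracle, js_score_oracle


class TestJSSpecificity:
    def test_single_tissue_scores_exactly_one(self):
        s = js_specificity([0, 0, 7, 0, 0], list("abcde"))
        assert s.js_score == pytest.approx(1.0, abs=1e-12)
        assert s.argmax_tissue == "c"
        assert s.is_ts

    def test_two_tissue_uniform_matches_entropy_oracle(self):
        """(1,1) scores 1 - sqrt(JSD) with JSD = 0.3113 bits."""
        s = js_specificity([1.0, 1.0])
        assert s.js_score == pytest.approx(js_score_oracle([1, 1], 0), abs=1e-9)
        assert s.js_score == pytest.approx(0.44208, abs=5e-5)

    def test_uniform_five_tissue_oracle(self):
        """Uniform over 5 tissues: positive but far below the TS threshold
        (the indicator comparison never reaches 0 for finite tissue counts)."""
        s = js_specificity([3.0] * 5)
        assert s.js_score == pytest.approx(js_best_oracle([3.0] * 5), abs=1e-9)
        assert s.js_score == pytest.approx(0.21898, abs=5e-5)
        assert not s.is_ts

    def test_scale_invariance(self):
        v = [0.2, 3.0, 1.4, 0.0]
        assert js_specificity(v).js_score == pytest.approx(
            js_specificity([100 * x for x in v]).js_score, abs=1e-12
        )

    def test_permutation_equivariance(self):
        v = np.array([0.2, 3.0, 1.4, 0.7, 0.0])
        perm = [3, 0, 4, 1, 2]
        s1 = js_specificity(v, list("abcde"))
        s2 = js_specificity(v[perm], [list("abcde")[i] for i in perm])
        assert s1.js_score == pytest.approx(s2.js_score, abs=1e-12)
        assert s1.argmax_tissue == s2.argmax_tissue

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            js_specificity([0.0, 0.0, 0.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=8).filter(
            lambda v: sum(v) > 0
        )
    )
    def test_score_in_unit_interval_and_matches_oracle(self, v):
        s = js_specificity(v)
        assert -1e-12 <= s.js_score <= 1 + 1e-12
        assert s.js_score == pytest.approx(js_best_oracle(v), abs=1e-9)


class TestCallTS:
    def test_threshold_is_inclusive(self):
        """JS >= 0.9 is TS, as printed ('> =')."""
        assert ts_call_from_score(0.9)
        assert not ts_call_from_score(0.9 - 1e-12)

    def test_matrix_calls_and_flagging(self):
        m = pd.DataFrame(
            {"root": [9.0, 1.0, 0.0], "leaf": [0.0, 1.0, 0.0], "seed": [0.0, 1.0, 0.0]},
            index=["ts", "broad", "silent"],
        )
        out = call_ts(m)
        assert bool(out.loc["ts", "is_ts"]) and out.loc["ts", "argmax_tissue"] == "root"
        assert not bool(out.loc["broad", "is_ts"])
        assert bool(out.loc["silent", "flagged"]) and np.isnan(out.loc["silent", "js_score"])

    def test_count_monotone_in_threshold(self, bundle):
        expr = bundle.expression
        counts = [
            int(call_ts(expr, ts_threshold=th)["is_ts"].sum())
            for th in (0.0, 0.5, 0.9, 0.99, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_planted_single_tissue_recovery(self, bundle):
        """TS recall is 1.0 and the argmax tissue equals the planted one."""
        truth = bundle.truth.transcripts
        planted = truth[truth["planted_profile"] == "single"]
        out = call_ts(bundle.expression.loc[planted.index])
        assert out["is_ts"].all()
        assert (out["argmax_tissue"] == planted["planted_tissue"]).all()


class TestTissueSummary:
    def test_log_transform_cell(self):
        m = pd.DataFrame({"root": [9.0], "leaf": [0.0]}, index=["a"])
        summary, pooled = tissue_summary(m, {"x": ["a"]})
        assert summary.loc["x", "root"] == pytest.approx(1.0)  # log10(9+1)
        assert summary.loc["x", "leaf"] == 0.0
        assert pooled["x"] == pytest.approx(4.5)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.random((6, 4)) * 50, columns=list("wxyz"),
            index=[f"t{i}" for i in range(6)],
        )
        classes = {"a": ["t0", "t1", "t2"], "b": ["t3", "t4", "t5"]}
        summary, pooled = tissue_summary(m, classes)
        expect = np.log10(m.loc[classes["a"]] + 1).mean(axis=0)
        np.testing.assert_allclose(summary.loc["a"], expect)
        assert pooled["b"] == pytest.approx(m.loc[classes["b"]].to_numpy().mean())


class TestNatPairs:
    def test_identical_vectors_r1_and_flat_flagged(self):
        m = pd.DataFrame(
            {"r": [1.0, 1.0, 5.0], "s": [2.0, 2.0, 5.0], "l": [3.0, 3.0, 5.0]},
            index=["nat", "gene", "flat"],
        )
        pairs, _ = nat_pair_correlation(m, [("nat", "gene"), ("nat", "flat")])
        assert pairs.loc[0, "r"] == pytest.approx(1.0)
        assert bool(pairs.loc[1, "flagged"]) and np.isnan(pairs.loc[1, "r"])

    def test_unknown_id_and_too_few_tissues(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["x"])
        with pytest.raises(KeyError):
            nat_pair_correlation(m, [("x", "zz")])
        m2 = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["x"])
        with pytest.raises(ValueError, match="3 tissues"):
            nat_pair_correlation(m2, [("x", "x")])

    def test_independent_pairs_have_small_mean_abs_r(self):
        """200 independently drawn pairs over 30 samples: E|r| is about
        sqrt(2/(pi*n)) ~= 0.15, so the seeded mean stays below 0.2."""
        rng = np.random.default_rng(42)
        n_pairs, T = 200, 30
        rows = {}
        pairs = []
        for i in range(n_pairs):
            rows[f"n{i}"] = rng.random(T) * 10
            rows[f"g{i}"] = rng.random(T) * 10
            pairs.append((f"n{i}", f"g{i}"))
        m = pd.DataFrame.from_dict(rows, orient="index")
        out, _ = nat_pair_correlation(m, pairs)
        assert out["r"].abs().mean() < 0.2

    def test_distribution_vectors_returned(self):
        m = pd.DataFrame(
            {"a": [1.0, 4.0, 7.0], "b": [2.0, 5.0, 8.0], "c": [3.0, 6.0, 9.0]},
            index=["nat", "g1", "g2"],
        )
        _, dists = nat_pair_correlation(m, [("nat", "g1")], genes_without_nat=["g2"])
        assert dists["genes_with_nat"][0] == pytest.approx(5.0)
        assert dists["genes_without_nat"][0] == pytest.approx(8.0)


class TestWGCNASelection:
    def _matrix(self):
        return pd.DataFrame(
            {
                "root": [1.5, 5.0, 0.0, 1.0, 80.0, 0.9],
                "stem": [0.5, 4.0, 0.0, 0.0, 10.0, 0.0],
                "leaf": [0.0, 3.0, 0.0, 0.0, 5.0, 0.0],
            },
            index=["linc2t", "linc3t", "silent", "mrna_at_1", "nat_hi", "nat_lo"],
        )

    def test_lincRNA_rule(self):
        """Expressed in <= 2 tissues AND max FPKM strictly above 1."""
        m = self._matrix()
        rep = wgcna_candidate_selection(
            m, {"lincRNA": ["linc2t", "linc3t", "silent"], "lncNAT": [], "mRNA": []}
        )
        assert rep.lincRNA == ("linc2t",)  # linc3t fails the tissue-count clause

    def test_mrna_strict_threshold(self):
        m = self._matrix()
        rep = wgcna_candidate_selection(
            m, {"lincRNA": [], "lncNAT": [], "mRNA": ["mrna_at_1", "nat_hi"]}
        )
        assert rep.mRNA == ("nat_hi",)  # max FPKM exactly 1 is excluded

    def test_nat_top_fraction(self):
        rng = np.random.default_rng(1)
        n = 50
        m = pd.DataFrame(
            {"root": np.linspace(1, 50, n), "stem": 0.0, "leaf": 0.0},
            index=[f"nat{i}" for i in range(n)],
        )
        rep = wgcna_candidate_selection(
            m, {"lncNAT": list(m.index), "lincRNA": [], "mRNA": []}, top_frac=0.10
        )
        # top 10% of max-FPKMs among the passing set
        assert len(rep.lncNAT) == 5
        assert set(rep.lncNAT) == {f"nat{i}" for i in range(45, 50)}

    def test_selected_sets_disjoint(self, bundle, classified):
        ids = {
            "lincRNA": [t.transcript_id for t in classified["by_class"]["lincRNA"]],
            "lncNAT": [t.transcript_id for t in classified["by_class"]["lncNAT"]],
            "mRNA": [g.transcripts[0].transcript_id for g in bundle.genes],
        }
        rep = wgcna_candidate_selection(bundle.expression, ids)
        assert not (set(rep.lincRNA) & set(rep.lncNAT))
        assert not (set(rep.lincRNA) & set(rep.mRNA))
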