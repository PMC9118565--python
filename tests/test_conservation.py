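"""Conservation: spliced means, patch scan, class profiles, homology matrix."""

import numpy as np
import pytest

from lncscape.conservation import (
    class_conservation_profiles,
    conserved_patch_scan,
    homology_conservation_matrix,
    spliced_scores,
    transcript_mean_score,
)
from lncscape.models import ConservationTrack, HomologyHit
from oracle_utils import brute_window_means, make_tx


def _track(arr):
    return ConservationTrack({"c": np.asarray(arr, dtype=float)})


class TestMeanScore:
    def test_all_zero_and_half(self):
        t = make_tx("t", "c", "+", [(0, 100)])
        assert transcript_mean_score(t, _track(np.zeros(100))) == 0.0
        arr = np.concatenate([np.ones(50), np.zeros(50)])
        assert transcript_mean_score(t, _track(arr)) == pytest.approx(0.5)

    def test_two_exons_match_bruteforce(self):
        rng = np.random.default_rng(2)
        arr = rng.random(1000)
        t = make_tx("t", "c", "+", [(100, 250), (400, 480)])
        expect = np.mean(np.concatenate([arr[100:250], arr[400:480]]))
        assert transcript_mean_score(t, _track(arr)) == pytest.approx(expect)

    def test_missing_excluded_and_all_missing_flagged(self):
        arr = np.full(100, np.nan)
        arr[:10] = 0.8
        t = make_tx("t", "c", "+", [(0, 100)])
        assert transcript_mean_score(t, _track(arr)) == pytest.approx(0.8)
        assert np.isnan(transcript_mean_score(t, _track(np.full(100, np.nan))))

    def test_minus_strand_reverses_spliced_order(self):
        arr = np.linspace(0, 1, 100)
        tm = make_tx("t", "c", "-", [(0, 100)])
        s = spliced_scores(tm, _track(arr))
        np.testing.assert_allclose(s, arr[::-1])


class TestPatchScan:
    def test_worked_example_50bp(self):
        """50-base transcript, one 12-base run at 0.9: whole mean 0.216,
        best window 0.9, positive patch call."""
        arr = np.zeros(60)
        arr[10:22] = 0.9
        t = make_tx("t", "c", "+", [(0, 50)])
        call = conserved_patch_scan(t, _track(arr))
        assert call.whole_mean == pytest.approx(0.216)
        assert call.best_window_mean == pytest.approx(0.9)
        assert call.has_conserved_patch

    def test_uniform_06_is_not_a_patch(self):
        """'more than 0.6' is strict: a window mean of exactly 0.6 fails."""
        t = make_tx("t", "c", "+", [(0, 50)])
        call = conserved_patch_scan(t, _track(np.full(50, 0.6)))
        assert call.best_window_mean == pytest.approx(0.6)
        assert not call.has_conserved_patch

    def test_uniformly_high_transcript_is_not_a_patch(self):
        """Whole mean >= 0.3 disqualifies: conserved overall, not a patch."""
        t = make_tx("t", "c", "+", [(0, 50)])
        call = conserved_patch_scan(t, _track(np.full(50, 0.9)))
        assert call.best_window_mean == pytest.approx(0.9)
        assert not call.has_conserved_patch

    def test_window_means_match_bruteforce(self):
        rng = np.random.default_rng(5)
        arr = rng.random(200)
        arr[40:55] = np.nan
        t = make_tx("t", "c", "+", [(0, 80), (100, 220)])
        spliced = np.concatenate([arr[0:80], arr[100:220]])
        call = conserved_patch_scan(t, _track(arr))
        oracle = brute_window_means(spliced, 12)
        finite = [m for m in oracle if not np.isnan(m)]
        assert call.best_window_mean == pytest.approx(max(finite))
        # min window mean <= whole mean <= max window mean
        assert min(finite) <= call.whole_mean + 1e-12
        assert call.whole_mean <= max(finite) + 1e-12

    def test_short_transcript_flagged(self):
        t = make_tx("t", "c", "+", [(0, 8)])
        call = conserved_patch_scan(t, _track(np.full(8, 0.9)))
        assert not call.has_conserved_patch and call.flagged == "too_short"

    def test_missing_base_disqualifies_window(self):
        arr = np.zeros(50)
        arr[10:22] = 0.9
        arr[15] = np.nan  # poisons every window containing it
        t = make_tx("t", "c", "+", [(0, 50)])
        call = conserved_patch_scan(t, _track(arr))
        assert not call.has_conserved_patch

    def test_patch_offsets_reported_in_spliced_coordinates(self):
        arr = np.zeros(100)
        arr[30:42] = 0.95
        t = make_tx("t", "c", "+", [(0, 100)])
        call = conserved_patch_scan(t, _track(arr))
        best = max(call.patches, key=lambda p: p[1])
        assert best == (30, pytest.approx(0.95))  # full-coverage window
        # windows partially covering the run also pass (8 * 0.95 / 12 > 0.6)
        assert min(o for o, _ in call.patches) < 30
        tm = make_tx("t", "c", "-", [(0, 100)])
        callm = conserved_patch_scan(tm, _track(arr))
        bestm = max(callm.patches, key=lambda p: p[1])
        assert bestm == (100 - 42, pytest.approx(0.95))  # 5'->3' on minus


class TestClassProfiles:
    def test_all_zero_class(self):
        ts = [make_tx(f"t{i}", "c", "+", [(i * 100, i * 100 + 50)]) for i in range(3)]
        out = class_conservation_profiles({"x": ts}, _track(np.zeros(1000)))
        assert out.loc["x", "frac_gt_0.6"] == 0.0
        assert out.loc["x", "frac_zero"] == 1.0

    def test_planted_gradient_recovered(self, bundle, classified):
        """Planted ordering: CDS-backed mRNA > lincRNA > intergenic."""
        mrna = [g.transcripts[0] for g in bundle.genes]
        lincs = classified["by_class"]["lincRNA"]
        out = class_conservation_profiles(
            {"mRNA": mrna, "lincRNA": lincs}, bundle.track
        )
        m_mrna = np.mean(out.loc["mRNA", "means"])
        m_linc = np.mean(out.loc["lincRNA", "means"])
        assert m_mrna > m_linc > 0.0
        # intergenic baseline planted below the lincRNA exon score
        assert m_linc < 0.3

    def test_cumulative_curve_is_sorted(self, bundle, classified):
        out = class_conservation_profiles(
            {"lincRNA": classified["by_class"]["lincRNA"]}, bundle.track
        )
        cum = out.loc["lincRNA", "cumulative"]
        assert (np.diff(cum) >= 0).all()


class TestHomologyMatrix:
    def _tx(self):
        return {"A": [f"a{i}" for i in range(100)], "B": ["b0", "b1"]}

    def test_no_hits_all_zero_offdiag(self):
        mat = homology_conservation_matrix([], self._tx())
        assert mat.loc["A", "B"] == 0.0 and mat.loc["A", "A"] == 1.0

    def test_all_pass_gives_one(self):
        hits = [
            HomologyHit(f"a{i}", "A", "B", 95.0, 100, 1e-30) for i in range(100)
        ]
        mat = homology_conservation_matrix(hits, self._tx())
        assert mat.loc["A", "B"] == 1.0

    def test_five_percent(self):
        hits = [HomologyHit(f"a{i}", "A", "B", 95.0, 100, 1e-30) for i in range(5)]
        mat = homology_conservation_matrix(hits, self._tx())
        assert mat.loc["A", "B"] == pytest.approx(0.05)

    def test_unknown_query_raises(self):
        with pytest.raises(KeyError):
            homology_conservation_matrix(
                [HomologyHit("zz", "A", "B", 95.0, 100, 1e-30)], self._tx()
            )

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        hits = [
            HomologyHit(
                f"a{i}", "A", "B", 90.0,
                int(rng.integers(20, 200)), float(10.0 ** -rng.integers(2, 30)),
            )
            for i in range(60)
        ]
        tx = self._tx()
        by_len = [
            homology_conservation_matrix(hits, tx, min_len=L).loc["A", "B"]
            for L in (20, 50, 100, 150)
        ]
        assert all(a >= b for a, b in zip(by_len, by_len[1:]))
        by_ev = [
            homology_conservation_matrix(hits, tx, evalue_max=e).loc["A", "B"]
            for e in (1e-25, 1e-10, 1e-5, 1.0)
        ]
        assert all(a <= b for a, b in zip(by_ev, by_ev[1:]))

    def test_planted_fractions_recovered(self, bundle):
        mat = homology_conservation_matrix(
            bundle.hits, bundle.truth.species_transcripts
        )
        expected = bundle.truth.homology_expected
        for a in expected.index:
            for b in expected.columns:
                assert mat.loc[a, b] == pytest.approx(expected.loc[a, b])
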