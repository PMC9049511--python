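"""Windowing, shared-segment detection, pair totals, significance rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplodate.io import MISSING
from haplodate.sharing import (SharingParams, breed_pair_summary,
                               detect_segments, pair_total,
                               significance_call, window_partition)

from brute import naive_segments
from conftest import make_markers, make_panel


class TestWindowPartition:
    @pytest.mark.parametrize("n,expected", [
        (1000, [(0, 1000)]),
        (2000, [(0, 1000), (975, 1975), (1950, 2000)]),
        (500, [(0, 500)]),
    ])
    def test_default_layout(self, n, expected):
        assert window_partition(n) == expected

    @given(n=st.integers(2, 5000), window=st.integers(2, 1200),
           overlap=st.integers(0, 400))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_coverage_and_overlap(self, n, window, overlap):
        if overlap >= window:
            overlap = window - 1
        params = SharingParams(window, overlap, min_markers=1, min_cm=0.0)
        wins = window_partition(n, params)
        assert wins[0][0] == 0 and wins[-1][1] == n
        covered = set()
        for a, b in wins:
            assert b > a
            covered.update(range(a, b))
        assert covered == set(range(n))
        for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
            assert a2 == a1 + (window - overlap)


def _pair_panel(h1, h2, **kw):
    """Panel with two haploid-identical samples (each sample's two
    haplotypes equal) so only the (0,0) combination is informative —
    multiplied out by the 4 combinations in totals."""
    return make_panel([h1, h1, h2, h2], breeds=["X", "Y"], **kw)


class TestDetectSegments:
    def test_identical_haplotypes_single_full_segment(self):
        n = 1200
        markers = make_markers(n, bp_step=4000, cm_step=0.01)  # ~5 Mb, 12 cM
        h = np.random.default_rng(0).integers(0, 2, n).astype(np.int8)
        panel = _pair_panel(h, h, markers=markers)
        segs = detect_segments(panel, ("X_0", "Y_1"))
        assert len(segs) == 4                     # one per haplotype pair
        for s in segs:
            assert (s.start, s.end) == (0, n)
            assert s.bp_length == int(markers.bp[-1] - markers.bp[0] + 1)

    def test_all_mismatched_no_segments(self):
        n = 600
        h = np.zeros(n, dtype=np.int8)
        panel = _pair_panel(h, 1 - h, cm_step=0.05)
        assert detect_segments(panel, (0, 1)) == []

    def test_planted_tract_exact_boundaries(self):
        # 60-marker identical tract (2.0 cM at 0.0339 cM spacing) inside
        # otherwise alternating-mismatch haplotypes
        rng = np.random.default_rng(42)
        n = 2000
        markers = make_markers(n, bp_step=2500, cm_step=2.0 / 59)
        h1 = rng.integers(0, 2, n).astype(np.int8)
        h2 = 1 - h1                                # mismatch everywhere
        h2[700:760] = h1[700:760]                  # planted tract
        panel = _pair_panel(h1, h2, markers=markers)
        params = SharingParams(min_markers=25, min_cm=1.0)
        segs = [s for s in detect_segments(panel, (0, 1), params)
                if (s.hap1, s.hap2) == (0, 0)]
        assert [(s.start, s.end) for s in segs] == [(700, 760)]
        assert segs[0].n_markers == 60

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_scanner(self, seed):
        rng = np.random.default_rng(seed)
        n = 2000
        markers = make_markers(n, bp_step=3000, cm_step=0.02)
        # blocky haplotypes so that runs of many lengths occur
        h1 = rng.integers(0, 2, n).astype(np.int8)
        h2 = h1.copy()
        mism = rng.random(n) < 0.01
        h2[mism] = 1 - h2[mism]
        h1[rng.random(n) < 0.02] = MISSING
        h2[rng.random(n) < 0.02] = MISSING
        panel = _pair_panel(h1, h2, markers=markers)
        params = SharingParams(min_markers=25, min_cm=1.0)
        segs = [(s.start, s.end, s.bp_length)
                for s in detect_segments(panel, (0, 1), params)
                if (s.hap1, s.hap2) == (0, 0)]
        expected = naive_segments(h1, h2, markers.cm, markers.bp, 25, 1.0)
        assert segs == expected

    def test_window_step_invariance(self):
        rng = np.random.default_rng(9)
        n = 5000
        markers = make_markers(n, bp_step=2000, cm_step=0.02)
        h1 = rng.integers(0, 2, n).astype(np.int8)
        h2 = h1.copy()
        mism = rng.random(n) < 0.005
        h2[mism] = 1 - h2[mism]
        panel = _pair_panel(h1, h2, markers=markers)
        base = SharingParams(scan="genome")
        for window, overlap in ((1000, 25), (500, 25), (300, 100)):
            params = SharingParams(window, overlap)
            a = [(s.hap1, s.hap2, s.start, s.end)
                 for s in detect_segments(panel, (0, 1), params)]
            b = [(s.hap1, s.hap2, s.start, s.end)
                 for s in detect_segments(panel, (0, 1), base)]
            assert a == b

    def test_symmetric_in_pair(self):
        rng = np.random.default_rng(3)
        n = 1500
        h1, h2 = rng.integers(0, 2, (2, n)).astype(np.int8)
        panel = _pair_panel(h1, h2, cm_step=0.05)
        params = SharingParams(min_markers=10, min_cm=0.2)
        ab = {(s.hap1, s.hap2, s.start, s.end)
              for s in detect_segments(panel, (0, 1), params)}
        ba = {(s.hap2, s.hap1, s.start, s.end)
              for s in detect_segments(panel, (1, 0), params)}
        assert ab == ba

    def test_extra_mismatches_never_increase_total(self):
        rng = np.random.default_rng(17)
        n = 3000
        markers = make_markers(n, bp_step=2000, cm_step=0.02)
        h1 = rng.integers(0, 2, n).astype(np.int8)
        h2 = h1.copy()
        params = SharingParams()
        prev = pair_total(detect_segments(
            _pair_panel(h1, h2, markers=markers), (0, 1), params))
        for k in range(6):
            pos = rng.integers(0, n, 5)
            h2[pos] = 1 - h1[pos]
            cur = pair_total(detect_segments(
                _pair_panel(h1, h2, markers=markers), (0, 1), params))
            assert cur <= prev
            prev = cur


class TestPairTotal:
    def test_empty(self):
        assert pair_total([]) == 0

    def test_single_segment_length(self):
        from haplodate.sharing import SharedSegment
        seg = SharedSegment("a", "b", 0, 0, "1", 0, 10, 1_234_567, 2.0, 10)
        assert pair_total([seg]) == 1_234_567

    def test_diploid_clones_four_times_span(self):
        n = 1200
        markers = make_markers(n, bp_step=4000, cm_step=0.01)
        rng = np.random.default_rng(1)
        h = rng.integers(0, 2, n).astype(np.int8)
        panel = make_panel([h, h, h, h], breeds=["X", "Y"], markers=markers)
        total = pair_total(detect_segments(panel, (0, 1)))
        span = int(markers.bp[-1] - markers.bp[0] + 1)
        assert total == 4 * span


class TestBreedPairSummary:
    def _panel(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 800
        markers = make_markers(n, bp_step=3000, cm_step=0.03)
        haps = rng.integers(0, 2, (8, n)).astype(np.int8)
        return make_panel(haps, breeds=["X", "X", "Y", "Y"], markers=markers)

    def test_single_sample_breeds(self):
        rng = np.random.default_rng(2)
        h = rng.integers(0, 2, (4, 900)).astype(np.int8)
        panel = make_panel(h, breeds=["X", "Y"], cm_step=0.03)
        s = breed_pair_summary(panel, "X", "Y")
        assert s.n_pairs == 1
        assert s.median_bp == s.totals[0]

    def test_symmetric_in_breed_order(self):
        panel = self._panel()
        a = breed_pair_summary(panel, "X", "Y")
        b = breed_pair_summary(panel, "Y", "X")
        assert a.median_bp == b.median_bp
        assert sorted(a.totals) == sorted(b.totals)

    def test_within_breed_mode(self):
        panel = self._panel()
        s = breed_pair_summary(panel, "X", "X")
        assert s.within_breed and s.n_pairs == 1   # C(2,2) pairs


class TestSignificance:
    def _summaries(self, medians, breeds):
        from haplodate.sharing import PairSharingSummary
        return [PairSharingSummary(a, b, np.array([m]), float(m), 1)
                for (a, b), m in zip(breeds, medians)]

    def test_equal_medians_nothing_flagged(self):
        pairs = [("A1", "B1"), ("A2", "B2"), ("A1", "B2")]
        clades = {"A1": "ca", "A2": "ca", "B1": "cb", "B2": "cb"}
        sig = significance_call(self._summaries([7.0] * 3, pairs), clades)
        assert sig.threshold_bp == 7.0
        assert not any(sig.flagged.values())

    def test_percentile_interpolation(self):
        # across-clade medians 1..100 -> type-7 95th percentile = 95.05
        pairs = [(f"A{i}", f"B{i}") for i in range(100)]
        clades = {f"A{i}": "ca" for i in range(100)}
        clades.update({f"B{i}": "cb" for i in range(100)})
        sig = significance_call(
            self._summaries(np.arange(1.0, 101.0), pairs), clades)
        assert sig.threshold_bp == pytest.approx(95.05)
        flagged = [k for k, v in sig.flagged.items() if v]
        assert len(flagged) == 5                   # medians 96..100

    def test_pair_totals_threshold_basis(self):
        # across-clade pairs: mostly-zero totals with a thin positive tail;
        # within-clade pair far above. Pooled-totals basis leaves every
        # across-clade pair unflagged, while the medians basis necessarily
        # flags the top across-clade pair.
        from haplodate.sharing import PairSharingSummary
        rng = np.random.default_rng(0)
        summaries = []
        for i in range(20):
            totals = np.zeros(50)
            totals[: rng.integers(0, 4)] = rng.uniform(1e6, 5e6, size=None)
            totals[0] = (i + 1) * 1e5        # distinct small medians? keep 0
            totals = np.sort(totals)
            summaries.append(PairSharingSummary(
                f"A{i}", f"B{i}", totals, float(np.median(totals)), 50))
        # give two across pairs small positive medians
        for k, bump in ((5, 2e5), (11, 3e5)):
            s = summaries[k]
            s.totals[:] = bump
            s.median_bp = bump
        within = PairSharingSummary("A0", "A1", np.full(50, 5e7), 5e7, 50)
        clades = {f"A{i}": "ca" for i in range(20)}
        clades.update({f"B{i}": "cb" for i in range(20)})
        sig_med = significance_call(summaries + [within], clades)
        sig_tot = significance_call(summaries + [within], clades,
                                    threshold_basis="pair-totals")
        across_keys = [s.key for s in summaries]
        assert any(sig_med.flagged[k] for k in across_keys)
        assert not any(sig_tot.flagged[k] for k in across_keys)
        assert sig_med.flagged[within.key] and sig_tot.flagged[within.key]

    def test_requires_across_clade_pairs(self):
        pairs = [("A1", "A2")]
        clades = {"A1": "ca", "A2": "ca"}
        with pytest.raises(ValueError, match="across-clade"):
            significance_call(self._summaries([1.0], pairs), clades)
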