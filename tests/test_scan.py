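import numpy as np
import pytest

import mosaicscan as ms
from mosaicscan import Alignment, ScanConfig, binomial_tail, build_triplet_profile
from mosaicscan.errors import SizeError
from mosaicscan.scan import (
    CandidateRegion,
    TripletProfile,
    demarcate_breakpoints,
    n_windows,
)


class TestTripletProfile:
    def test_no_variation(self):
        aln = Alignment(["a", "b", "c"], ["ACG", "ACG", "ACG"])
        assert build_triplet_profile(aln, 0, 1, 2).n_informative == 0

    def test_pattern_assignment(self):
        aln = Alignment(["a", "b", "c"], ["A", "A", "C"])
        prof = build_triplet_profile(aln, 0, 1, 2)
        assert list(prof.informative_positions) == [0]
        assert list(prof.support_pattern) == [0]  # 'ab'

    def test_hand_enumerated_columns(self):
        # col0 AAA: no variation; col1 A,A,C -> ab; cols2,3 A,C,C -> bc
        aln = Alignment(["a", "b", "c"], ["AAAA", "AACC", "ACCC"])
        prof = build_triplet_profile(aln, 0, 1, 2)
        assert list(prof.informative_positions) == [1, 2, 3]
        assert list(prof.support_pattern) == [0, 2, 2]

    def test_gapped_and_three_way_columns_skipped(self):
        # col0 gap in c, col1 all distinct, col2 informative
        aln = Alignment(["a", "b", "c"], ["AGA", "ACA", "-TC"])
        prof = build_triplet_profile(aln, 0, 1, 2)
        assert list(prof.informative_positions) == [2]

    def test_too_few_sequences(self):
        aln = Alignment(["a", "b"], ["AC", "AG"])
        with pytest.raises(SizeError):
            build_triplet_profile(aln, 0, 1, 1)


class TestBinomialTail:
    def test_all_minor_window_closed_form(self):
        assert binomial_tail(20, 20, 0.5) == pytest.approx(0.5**20, rel=1e-9)

    def test_monotone_in_count(self):
        tails = binomial_tail(np.arange(1, 21), 20, 0.3)
        assert np.all(np.diff(tails) < 0)


class TestDemarcation:
    def _profile(self, positions, patterns):
        return TripletProfile(
            (0, 1, 2),
            np.asarray(positions),
            np.asarray(patterns, dtype=np.int8),
        )

    def test_midpoint_rule(self):
        # background site at column 90, region starts at column 100
        prof = self._profile([90, 100, 110, 120, 130], [0, 1, 1, 1, 0])
        region = CandidateRegion(1, 1, 3, 1e-9, 3)
        begin, end = demarcate_breakpoints(region, prof, 1000, bg_pattern=0)
        assert begin == 95
        assert end == (120 + 130) // 2

    def test_terminus_rule(self):
        prof = self._profile([0, 10, 20], [1, 1, 1])
        region = CandidateRegion(1, 0, 2, 1e-9, 3)
        begin, end = demarcate_breakpoints(region, prof, 500, bg_pattern=0)
        assert begin == 0 and end == 500


class TestScanAll:
    def test_identical_sequences_give_no_events(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT" * 50] * 4)
        assert ms.scan_all(aln) == []

    def test_fewer_than_three_sequences(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGA"])
        with pytest.raises(SizeError):
            ms.scan_all(aln)

    def test_corrected_p_uses_triplet_x_window_factor(self):
        """On a 5-sequence mosaic, p_corrected = p_raw x C(5,3) x windows."""
        from math import comb

        aln, tree = ms.simulate_clonal(5, 4000, 0.08, seed=11)
        aln, truth = ms.implant_events(aln, tree, 1, 1200, 1200, 0.08, seed=12)
        cfg = ScanConfig()
        events = ms.scan_all(aln, cfg)
        assert events
        ev = events[0]
        # reconstruct the factor for the exemplar's own triplet
        names = {ev.recombinant, ev.major_parent, ev.minor_parent}
        idx = sorted(aln.index(n) for n in names)
        prof = build_triplet_profile(aln, *idx)
        factor = comb(5, 3) * n_windows(prof.n_informative, cfg)
        assert ev.p_corrected == pytest.approx(
            min(1.0, ev.p_raw * factor), rel=1e-12
        )
        assert ev.p_corrected < cfg.alpha

    def test_event_invariants(self):
        aln, tree = ms.simulate_clonal(8, 6000, 0.1, seed=5)
        aln, _ = ms.implant_events(aln, tree, 1, 1000, 1500, 0.1, seed=6)
        for ev in ms.scan_all(aln):
            assert ev.p_corrected >= ev.p_raw
            assert 0 < ev.p_raw <= 1
            assert ev.recombinant not in (ev.major_parent, ev.minor_parent)
            b, e = ev.breakpoints
            assert 0 <= b < e <= aln.length

    def test_determinism(self):
        aln, tree = ms.simulate_clonal(8, 5000, 0.1, seed=3)
        aln, _ = ms.implant_events(aln, tree, 1, 800, 1200, 0.08, seed=4)
        t1 = ms.events_to_frame(ms.scan_all(aln)).to_csv(index=False)
        t2 = ms.events_to_frame(ms.scan_all(aln)).to_csv(index=False)
        assert t1 == t2

    def test_row_order_invariance(self):
        """Permuting sequence order changes names' bindings only."""
        aln, tree = ms.simulate_clonal(8, 5000, 0.1, seed=3)
        aln, _ = ms.implant_events(aln, tree, 1, 800, 1200, 0.08, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.n_seqs)
        shuffled = aln.take_rows(perm)
        ev1 = {
            (e.recombinant, e.breakpoints, round(e.p_raw, 12))
            for e in ms.scan_all(aln)
        }
        ev2 = {
            (e.recombinant, e.breakpoints, round(e.p_raw, 12))
            for e in ms.scan_all(shuffled)
        }
        assert ev1 == ev2

    def test_single_event_recovered_with_correct_recombinant(self):
        hits = 0
        for s in range(10):
            aln, tree = ms.simulate_clonal(10, 8000, 0.1, seed=100 + s)
            aln, truth = ms.implant_events(aln, tree, 1, 1200, 1500, 0.1, seed=200 + s)
            events = ms.scan_all(aln)
            tr = truth.events[0]
            if (
                len(events) == 1
                and events[0].recombinant == tr.acceptor
                and events[0].breakpoints[0] < tr.end
                and events[0].breakpoints[1] > tr.begin
            ):
                hits += 1
        assert hits >= 9

    def test_clonal_alignment_rarely_fires(self):
        fired = sum(
            bool(ms.scan_all(ms.simulate_clonal(8, 4000, 0.05, seed=300 + s)[0]))
            for s in range(10)
        )
        assert fired <= 2
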