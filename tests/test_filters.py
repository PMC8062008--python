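import numpy as np
import pytest

import mosaicscan as ms
from mosaicscan import Alignment, VetConfig, hudson_kaplan_rm, pair_incompatibility, phi_test
from mosaicscan.errors import InsufficientDataError
from mosaicscan.filters import _max_disjoint_intervals, incompatibility_matrix
from mosaicscan.scan import RecombinationEvent

from _oracles import max_disjoint_intervals_dp, min_extra_mutations


def columns_to_alignment(col_i, col_j):
    """Two integer-coded columns -> a 2-column alignment."""
    bases = "ACGT"
    rows = [bases[a] + bases[b] for a, b in zip(col_i, col_j)]
    return Alignment([f"t{k}" for k in range(len(rows))], rows)


class TestPairIncompatibility:
    def test_three_gametes_compatible(self):
        aln = columns_to_alignment([0, 0, 1], [0, 1, 0])
        assert pair_incompatibility(aln, 0, 1) == 0

    def test_four_gametes(self):
        aln = columns_to_alignment([0, 0, 1, 1], [0, 1, 0, 1])
        assert pair_incompatibility(aln, 0, 1) == 1

    def test_monomorphic_column_undefined(self):
        aln = columns_to_alignment([0, 0, 0], [0, 1, 2])
        assert pair_incompatibility(aln, 0, 1) is None

    def test_symmetry(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 8))
            ci = rng.integers(0, 3, n).tolist()
            cj = rng.integers(0, 3, n).tolist()
            aln = columns_to_alignment(ci, cj)
            assert pair_incompatibility(aln, 0, 1) == pair_incompatibility(aln, 1, 0)

    def test_against_exhaustive_fitch_oracle(self, rng):
        """Score == minimum extra mutations over all unrooted topologies."""
        checked = 0
        for _ in range(60):
            n = int(rng.integers(4, 7))
            ci = rng.integers(0, 3, n).tolist()
            cj = rng.integers(0, 3, n).tolist()
            if len(set(ci)) < 2 or len(set(cj)) < 2:
                continue
            aln = columns_to_alignment(ci, cj)
            assert pair_incompatibility(aln, 0, 1) == min_extra_mutations(ci, cj)
            checked += 1
        assert checked >= 30

    def test_matrix_agrees_with_scalar(self, random_aln_factory):
        aln = random_aln_factory(6, 30)
        S = incompatibility_matrix(aln.codes().T)
        for i in range(0, 30, 7):
            for j in range(i + 1, 30, 5):
                scalar = pair_incompatibility(aln, i, j)
                if scalar is None:
                    assert np.isnan(S[i, j])
                else:
                    assert S[i, j] == scalar


def tree_compatible_alignment():
    """Sites generated on one tree, one mutation each: no homoplasy."""
    # tree ((a,b),(c,d),(e,f)); each column mutates exactly one clade edge
    clades = [(0, 1), (2, 3), (4, 5), (0, 1, 2, 3)]
    rows = [[] for _ in range(6)]
    for rep in range(20):
        for clade in clades:
            for t in range(6):
                rows[t].append("C" if t in clade else "A")
    return Alignment([f"t{k}" for k in range(6)], ["".join(r) for r in rows])


class TestPhi:
    def test_zero_on_tree_compatible_sites(self):
        res = phi_test(tree_compatible_alignment(), w=100, n_perm=50, seed=1)
        assert res.phi == 0.0

    def test_no_permutations_degenerates_to_one(self):
        res = phi_test(tree_compatible_alignment(), w=100, n_perm=0, seed=1)
        assert res.p_perm == 1.0

    def test_p_perm_bounds(self):
        aln, _ = ms.simulate_clonal(10, 1000, 0.05, seed=9)
        res = phi_test(aln, n_perm=99, seed=2)
        assert 1 / 100 <= res.p_perm <= 1.0

    def test_insufficient_data(self):
        aln = Alignment(["a", "b", "c"], ["AAA", "AAA", "AAA"])
        with pytest.raises(InsufficientDataError):
            phi_test(aln)

    def test_recombination_shrinks_p(self):
        aln, tree = ms.simulate_clonal(12, 3000, 0.08, seed=21)
        aln2, _ = ms.implant_events(aln, tree, 3, 500, 900, 0.05, seed=22)
        p_clonal = phi_test(aln, n_perm=200, seed=3).p_perm
        p_mosaic = phi_test(aln2, n_perm=200, seed=3).p_perm
        assert p_mosaic < p_clonal

    def test_row_order_and_column_reversal_invariance(self):
        aln, tree = ms.simulate_clonal(10, 1500, 0.06, seed=31)
        base = phi_test(aln, n_perm=0, seed=0).phi
        shuffled = aln.take_rows(np.random.default_rng(1).permutation(10))
        reversed_aln = Alignment(aln.names, [r[::-1] for r in aln.rows])
        assert phi_test(shuffled, n_perm=0, seed=0).phi == pytest.approx(base)
        assert phi_test(reversed_aln, n_perm=0, seed=0).phi == pytest.approx(base)


class TestHudsonKaplan:
    def test_classic_four_haplotypes(self):
        aln = Alignment(["a", "b", "c", "d"], ["AA", "AC", "CA", "CC"])
        assert hudson_kaplan_rm(aln).rm == 1

    def test_tree_compatible_alignment_zero(self):
        assert hudson_kaplan_rm(tree_compatible_alignment()).rm == 0

    def test_against_dp_oracle(self, rng):
        """Greedy + containment pruning equals interval-scheduling DP."""
        for _ in range(30):
            n, L = int(rng.integers(5, 9)), int(rng.integers(6, 13))
            rows = ["".join("ACGT"[b] for b in rng.integers(0, 2, L)) for _ in range(n)]
            aln = Alignment([f"t{k}" for k in range(n)], rows)
            res = hudson_kaplan_rm(aln)
            assert res.rm == max_disjoint_intervals_dp(res.incompatible_pairs)

    def test_monotone_under_adding_sequences(self):
        aln, tree = ms.simulate_clonal(10, 2000, 0.08, seed=41)
        aln, _ = ms.implant_events(aln, tree, 2, 300, 600, 0.05, seed=42)
        last = 0
        for k in range(4, 11):
            rm = hudson_kaplan_rm(aln.take_rows(range(k))).rm
            assert rm >= last
            last = rm

    def test_greedy_containment_reduction(self):
        # (0,9) contains (2,5): only minimal intervals are scheduled
        assert _max_disjoint_intervals([(0, 9), (2, 5), (5, 8)]) == 2
        assert _max_disjoint_intervals([]) == 0


class TestVetEvent:
    def test_all_gap_block_flags_misalignment(self):
        aln, tree = ms.simulate_clonal(8, 2000, 0.08, seed=51)
        rows = [r[:900] + "-" * 20 + r[920:] for r in aln.rows]
        gappy = Alignment(aln.names, rows)
        ev = RecombinationEvent(
            recombinant=aln.names[0],
            major_parent=aln.names[1],
            minor_parent=aln.names[2],
            breakpoints=(850, 980),
            p_raw=1e-9,
            p_corrected=1e-4,
        )
        vetted = ms.vet_event(ev, gappy, VetConfig(n_perm=50, seed=1))
        assert "misalignment_suspect" in vetted.flags

    def test_true_event_unflagged(self):
        aln, tree = ms.simulate_clonal(10, 6000, 0.1, seed=61)
        aln, truth = ms.implant_events(aln, tree, 1, 1200, 1500, 0.1, seed=62)
        events = ms.scan_all(aln)
        tr = truth.events[0]
        target = [e for e in events if e.recombinant == tr.acceptor]
        assert target
        vetted = ms.vet_event(target[0], aln, VetConfig(n_perm=200, seed=1))
        assert not vetted.flags

    def test_pseudo_event_on_clonal_data_flagged(self):
        flagged = 0
        for s in range(6):
            aln, _ = ms.simulate_clonal(10, 3000, 0.05, seed=70 + s)
            ev = RecombinationEvent(
                recombinant=aln.names[0],
                major_parent=aln.names[1],
                minor_parent=aln.names[2],
                breakpoints=(1000, 1400),
                p_raw=1e-9,
                p_corrected=1e-4,
            )
            vetted = ms.vet_event(ev, aln, VetConfig(n_perm=200, seed=s))
            flagged += bool(vetted.flags)
        assert flagged >= 4

    def test_tiny_subalignment_records_untestable(self):
        aln = Alignment(["a", "b", "c"], ["ACGTACGT" * 10] * 2 + ["ACGAACGA" * 10])
        ev = RecombinationEvent(
            recombinant="a", major_parent="b", minor_parent="c",
            breakpoints=(10, 40), p_raw=1e-6, p_corrected=1e-3,
        )
        vetted = ms.vet_event(ev, aln, VetConfig(n_perm=10, seed=0))
        assert "phi_untestable" in vetted.method
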