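import pytest

import mosaicscan as ms
from mosaicscan import Alignment
from mosaicscan.annotation import AnnotationTrack, Feature
from mosaicscan.errors import ConfigError, SizeError
from mosaicscan.scan import RecombinationEvent


def ev(rec, begin, end, flags=frozenset()):
    return RecombinationEvent(rec, "p1", "p2", (begin, end), 1e-9, 1e-5, flags)


@pytest.fixture
def aln10(random_aln_factory):
    return random_aln_factory(10, 120)


class TestStrip:
    def test_empty_events_identity(self, aln10):
        assert ms.strip_recombinants(aln10, []) == aln10

    def test_two_recombinants_removed_order_preserved(self, aln10):
        events = [ev("r3", 0, 10), ev("r7", 20, 30), ev("r3", 50, 60)]
        out = ms.strip_recombinants(aln10, events)
        assert out.n_seqs == 8
        assert out.names == [n for n in aln10.names if n not in ("r3", "r7")]

    def test_flagged_events_ignored_by_default(self, aln10):
        events = [ev("r3", 0, 10, frozenset({"phi_suspect"}))]
        assert ms.strip_recombinants(aln10, events) == aln10
        assert ms.strip_recombinants(aln10, events, include_flagged=True).n_seqs == 9

    def test_refuses_to_leave_fewer_than_two(self):
        aln = Alignment(["a", "b", "c"], ["ACGT"] * 3)
        with pytest.raises(SizeError):
            ms.strip_recombinants(aln, [ev("a", 0, 2), ev("b", 0, 2)])


class TestMask:
    def test_exact_mask_extent(self, aln10):
        out = ms.mask_recombinant_fragments(aln10, [ev("r2", 10, 20)])
        row = out.rows[1]
        assert row[10:20] == "N" * 10
        assert row[:10] == aln10.rows[1][:10] and row[20:] == aln10.rows[1][20:]
        assert out.rows[0] == aln10.rows[0]

    def test_overlapping_events_union(self, aln10):
        out = ms.mask_recombinant_fragments(
            aln10, [ev("r2", 10, 20), ev("r2", 15, 30)]
        )
        assert out.rows[1][10:30] == "N" * 20

    def test_invalid_missing_char(self, aln10):
        with pytest.raises(ConfigError):
            ms.mask_recombinant_fragments(aln10, [ev("r2", 0, 5)], missing_char="X")

    def test_idempotent(self, aln10):
        events = [ev("r2", 10, 40)]
        once = ms.mask_recombinant_fragments(aln10, events)
        assert ms.mask_recombinant_fragments(once, events) == once


class TestSplit:
    def test_row_count_one_event(self, aln10):
        out = ms.split_recombinants(aln10, [ev("r4", 30, 60)])
        assert out.n_seqs == aln10.n_seqs + 1
        assert "r4_bb" in out.names and "r4_ev1" in out.names

    def test_backbone_and_parts_complementary_and_conservative(self, aln10):
        events = [ev("r4", 30, 60), ev("r4", 80, 100)]
        out = ms.split_recombinants(aln10, events)
        bb = out.rows[out.names.index("r4_bb")]
        p1 = out.rows[out.names.index("r4_ev1")]
        p2 = out.rows[out.names.index("r4_ev2")]
        orig = aln10.rows[3]
        for c in range(aln10.length):
            chars = [r[c] for r in (bb, p1, p2)]
            non_missing = [ch for ch in chars if ch != "N"]
            assert len(non_missing) == 1 and non_missing[0] == orig[c]

    def test_name_collision_suffixed(self, random_aln_factory):
        aln = random_aln_factory(4, 40)
        aln = Alignment(["a", "a_bb", "b", "c"], aln.rows)
        with pytest.warns(UserWarning, match="collision"):
            out = ms.split_recombinants(aln, [ev("a", 5, 15)])
        assert len(set(out.names)) == out.n_seqs


class TestPartition:
    def test_no_breakpoints_single_partition(self, aln10):
        parts, table = ms.partition_alignment(aln10, [])
        assert len(parts) == 1 and parts[0][1] == aln10

    def test_concatenation_is_identity(self, aln10):
        parts, _ = ms.partition_alignment(aln10, [ev("r2", 30, 70)])
        assert len(parts) == 3
        rebuilt = ["".join(sub.rows[i] for _, sub in parts) for i in range(10)]
        assert rebuilt == aln10.rows

    def test_duplicate_and_terminus_breakpoints(self, aln10):
        parts, table = ms.partition_alignment(aln10, [0, 40, 40, 120])
        assert len(parts) == 2
        assert "dropped" in str(table[-1]["end_1based"])

    def test_table_coordinates_one_based(self, aln10):
        _, table = ms.partition_alignment(aln10, [40])
        assert (table[0]["begin_1based"], table[0]["end_1based"]) == (1, 40)
        assert (table[1]["begin_1based"], table[1]["end_1based"]) == (41, 120)


class TestGeneExtraction:
    def test_single_exon_slice(self):
        aln = Alignment(["a", "b"], ["ACGTACGTACGT", "ACGAACGAACGA"])
        track = AnnotationTrack([Feature("g", "CDS", ((2, 11),), "+", (0,))])
        out = ms.extract_gene_alignments(aln, track)
        assert out["g"].rows[0] == aln.rows[0][2:11]

    def test_partial_codon_trimmed(self):
        aln = Alignment(["a", "b"], ["ACGTACGTAC", "ACGAACGAAC"])
        track = AnnotationTrack([Feature("g", "CDS", ((0, 10),), "+", (0,))])
        out = ms.extract_gene_alignments(aln, track, drop_partial_codons=True)
        assert out["g"].length == 9

    def test_minus_strand_reverse_complement(self):
        # CDS (3,9) on ACGTACGTA: slice TACGTA -> revcomp TACGTA
        row = "ACGTACGTA"
        aln = Alignment(["a"], [row])
        track = AnnotationTrack([Feature("g", "CDS", ((3, 9),), "-", (0,))])
        out = ms.extract_gene_alignments(aln, track)
        expected = row[3:9].translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert out["g"].rows[0] == expected

    def test_frameshift_gap_codon_removed_synchronously(self):
        aln = Alignment(["a", "b"], ["ACGTACGTA", "ACG-ACGTA"])
        track = AnnotationTrack([Feature("g", "CDS", ((0, 9),), "+", (0,))])
        out = ms.extract_gene_alignments(aln, track)
        # middle codon has a single gap in b -> removed for both rows
        assert out["g"].rows == ["ACGGTA", "ACGGTA"]
        assert out["g"].length % 3 == 0

    def test_phase_honored(self):
        aln = Alignment(["a"], ["ACGTACGTA"])
        track = AnnotationTrack([Feature("g", "CDS", ((0, 9),), "+", (1,))])
        out = ms.extract_gene_alignments(aln, track, drop_partial_codons=False)
        assert out["g"].rows[0] == "CGTACGTA"

    def test_no_cds_warns_and_empty(self):
        aln = Alignment(["a"], ["ACGTACGTA"])
        track = AnnotationTrack([Feature("g", "gene", ((0, 9),), "+")])
        with pytest.warns(UserWarning):
            assert ms.extract_gene_alignments(aln, track) == {}

    def test_output_length_multiple_of_three(self, random_aln_factory):
        aln = random_aln_factory(5, 100, with_gaps=True)
        track = AnnotationTrack(
            [
                Feature("g1", "CDS", ((3, 47),), "+", (0,)),
                Feature("g2", "CDS", ((50, 98),), "-", (0,)),
            ]
        )
        for ga in ms.extract_gene_alignments(aln, track).values():
            assert ga.length % 3 == 0
            assert ga.n_seqs == 5
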