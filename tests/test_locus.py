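"""Restriction-fragment map construction and coordinate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loop3c.errors import FormatError, InvalidInputError, OutOfRangeError
from loop3c.locus import (
    GenomicInterval,
    assign_tss_distances,
    build_locus_model,
    digest_sequence,
    find_motif_positions,
    locate_fragment,
    read_fragments_bed,
    read_locus_fasta,
    write_fragments_bed,
)


class TestDigestSequence:
    def test_no_cut_sites_gives_single_fragment(self):
        frags = digest_sequence("ACGTACGT", "AAGCTT")
        assert len(frags) == 1
        assert (frags[0].interval.start, frags[0].interval.end) == (0, 8)

    def test_two_sites_give_three_fragments_at_motif_starts(self):
        # CC AAGCTTGG AAGCTTCC -> cuts at 2 and 10
        frags = digest_sequence("CCAAGCTTGGAAGCTTCC", "AAGCTT")
        assert [(f.interval.start, f.interval.end) for f in frags] == [
            (0, 2),
            (2, 10),
            (10, 18),
        ]

    def test_cut_offset_shifts_boundaries_within_motif(self):
        frags = digest_sequence("CCAAGCTTGG", "AAGCTT", cut_offset=1)
        assert [(f.interval.start, f.interval.end) for f in frags] == [(0, 3), (3, 10)]

    def test_motif_at_sequence_start_produces_no_empty_fragment(self):
        frags = digest_sequence("AAGCTTCC", "AAGCTT")
        assert len(frags) == 1

    def test_n_bases_never_match_the_motif(self):
        assert find_motif_positions("CCANGCTTGG", "AAGCTT") == []

    @pytest.mark.parametrize(
        "sequence, motif",
        [("", "AAGCTT"), ("ACGT", "AAG"), ("ACGT", "AAGCTX"), ("ACXT", "AAGCTT")],
    )
    def test_invalid_inputs_rejected(self, sequence, motif):
        with pytest.raises(InvalidInputError):
            digest_sequence(sequence, motif)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=10_000),
        st.sampled_from(["AAGCTT", "GAATTC", "GGATCC"]),
    )
    def test_matches_naive_scan_and_tiles_exactly(self, sequence, motif):
        """Digest boundaries equal a brute-force substring scan, and the
        fragments tile the sequence with no gaps or overlaps."""
        frags = digest_sequence(sequence, motif)
        naive = [
            i
            for i in range(len(sequence) - len(motif) + 1)
            if sequence[i : i + len(motif)] == motif and 0 < i < len(sequence)
        ]
        expected_bounds = [0, *naive, len(sequence)]
        bounds = [frags[0].interval.start] + [f.interval.end for f in frags]
        assert bounds == expected_bounds
        assert sum(f.length for f in frags) == len(sequence)
        for a, b in zip(frags, frags[1:]):
            assert a.interval.end == b.interval.start


class TestTssDistances:
    def test_upstream_on_plus_strand_is_negative(self):
        frags = digest_sequence("A" * 4000, "AAGCTT")
        out = assign_tss_distances(frags, 3000, "+")
        assert out[0].tss_distance_kb == pytest.approx(-1.0)

    def test_strand_flip_reverses_sign(self):
        frags = digest_sequence("A" * 4000, "AAGCTT")
        out = assign_tss_distances(frags, 3000, "-")
        assert out[0].tss_distance_kb == pytest.approx(1.0)

    def test_tss_outside_span_rejected(self):
        frags = digest_sequence("A" * 100, "AAGCTT")
        with pytest.raises(OutOfRangeError):
            assign_tss_distances(frags, 500, "+")

    def test_distances_monotone_in_fragment_order(self, pc3m_locus):
        d = [f.tss_distance_kb for f in pc3m_locus.locus.fragments]
        assert all(b > a for a, b in zip(d, d[1:]))


@pytest.fixture(scope="module")
def four_fragment_locus():
    # 3 internal cuts -> 4 fragments
    seq = "C" * 100 + "AAGCTT" + "C" * 94 + "AAGCTT" + "C" * 94 + "AAGCTT" + "C" * 94
    return build_locus_model(seq, 10, "+")


class TestLocateFragment:
    @pytest.fixture
    def locus(self, four_fragment_locus):
        return four_fragment_locus

    def test_fragment_start_belongs_to_fragment(self, locus):
        f3 = locus.fragments[3]
        assert locate_fragment(locus, f3.interval.start) == 3

    def test_fragment_end_belongs_to_next_fragment(self, locus):
        f2 = locus.fragments[2]
        assert locate_fragment(locus, f2.interval.end) == 3

    def test_out_of_span_rejected(self, locus):
        with pytest.raises(OutOfRangeError):
            locate_fragment(locus, locus.span.end)


class TestGeneratorGroundTruth:
    def test_digest_recovers_planted_cut_positions(self, pc3m_locus):
        frags = pc3m_locus.locus.fragments
        boundaries = [f.interval.end for f in frags[:-1]]
        assert boundaries == pc3m_locus.cut_positions

    def test_seven_anchors_map_to_seven_distinct_fragments(self, pc3m_locus):
        ids = pc3m_locus.anchor_map["fragment_id"]
        assert len(ids) == 7
        assert ids.nunique() == 7

    def test_anchor_fragment_midpoints_sit_on_the_anchors(self, pc3m_locus, pc3m_scenario):
        tss = pc3m_scenario.locus.tss_position
        for _, row in pc3m_locus.anchor_map.iterrows():
            frag = pc3m_locus.locus.fragment(int(row["fragment_id"]))
            assert frag.midpoint == pytest.approx(tss + row["anchor_kb"] * 1000, abs=1000)

    def test_bait_fragment_contains_tss(self, pc3m_locus, pc3m_scenario):
        bait = pc3m_locus.locus.bait_fragment
        tss = pc3m_scenario.locus.tss_position
        assert bait.interval.start <= tss < bait.interval.end


class TestIO:
    def test_bed_round_trip_preserves_intervals(self, pc3m_locus, tmp_path):
        path = tmp_path / "frags.bed"
        write_fragments_bed(pc3m_locus.locus, path)
        back = read_fragments_bed(path)
        orig = pc3m_locus.locus.fragments
        assert [(f.fragment_id, f.interval.start, f.interval.end) for f in back] == [
            (f.fragment_id, f.interval.start, f.interval.end) for f in orig
        ]

    def test_multi_record_fasta_rejected(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(FormatError, match="two.fasta"):
            read_locus_fasta(path)

    def test_fasta_round_trip(self, tmp_path):
        from loop3c.io import write_fasta

        path = tmp_path / "locus.fasta"
        write_fasta("locus", "ACGTAAGCTTACGT", path)
        name, seq = read_locus_fasta(path)
        assert name == "locus"
        assert seq == "ACGTAAGCTTACGT"
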