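"""TAST core: ORF finding, HSP chaining, collinearity, boundary error."""

import random

import pytest

from conftest import make_hsp

from tastkit import (
    AlignmentBlock,
    SequenceRecord,
    chain_transcript_alignments,
    classify_block,
    detect_collinearity,
    find_orfs,
    render_tast_plot,
    splice_boundary_error,
)
from tastkit.tast import LONGEST_ORF, MINOR_ORF, NON_ORF, OrfRegion, TranscriptAlignment


class TestFindOrfs:
    def test_single_complete_orf(self):
        orfs = find_orfs(SequenceRecord("t", "ATGTGCTGTTAA"))
        assert len(orfs) == 1
        orf = orfs[0]
        assert (orf.start, orf.end) == (0, 12)
        assert orf.protein == "MCC"
        assert orf.cysteine_count == 2
        assert orf.is_longest

    def test_no_atg_gives_empty(self):
        assert find_orfs(SequenceRecord("t", "CCCCCC")) == []

    def test_atg_off_frame_zero(self):
        orfs = find_orfs(SequenceRecord("t", "GGATGAAATGA"))
        assert len(orfs) == 1
        assert (orfs[0].start, orfs[0].end) == (2, 11)
        assert orfs[0].protein == "MK"

    def test_stop_required_by_default(self):
        assert find_orfs(SequenceRecord("t", "ATGAAAAAA")) == []
        orfs = find_orfs(SequenceRecord("t", "ATGAAAAAA"), require_stop=False)
        assert len(orfs) == 1
        assert orfs[0].protein == "MKK"
        assert not orfs[0].has_stop

    def test_interval_arithmetic_invariant(self):
        # protein length == (end - start)/3 - 1 when the stop is inside
        seq = "GG" + "ATG" + "TGT" * 7 + "TAG" + "CCATG"
        for orf in find_orfs(SequenceRecord("t", seq)):
            assert (orf.end - orf.start) % 3 == 0
            assert len(orf.protein) == (orf.end - orf.start) // 3 - 1

    def test_longest_tie_broken_five_prime(self):
        # two ORFs of equal length in different frames
        seq = "ATGTAA" + "C" + "ATGTAA"  # [0,6) and [7,13)
        orfs = find_orfs(SequenceRecord("t", seq))
        longest = [o for o in orfs if o.is_longest]
        assert len(longest) == 1
        assert longest[0].start == 0


class TestChaining:
    def test_two_exon_chain(self, hsp_factory):
        hsps = [hsp_factory(0, 40, 1000, 1040), hsp_factory(40, 100, 5000, 5060)]
        (aln,) = chain_transcript_alignments(hsps, {"tx1": 100}, 10000, 0.9)
        assert [b.order_index for b in aln.blocks] == [0, 1]
        assert aln.coverage == 1.0

    def test_long_gap_splits_and_low_coverage_drops(self, hsp_factory):
        hsps = [hsp_factory(0, 40, 1000, 1040), hsp_factory(40, 100, 5000, 5060)]
        # genomic gap 3960 > 2000 disconnects; best side covers 60/100 < 0.9
        assert chain_transcript_alignments(hsps, {"tx1": 100}, 2000, 0.9) == []

    def test_query_overlap_counts_union_coverage(self, hsp_factory):
        hsps = [hsp_factory(0, 50, 1000, 1050), hsp_factory(40, 100, 1100, 1160)]
        (aln,) = chain_transcript_alignments(
            hsps, {"tx1": 100}, 10000, 0.9, trim_overlaps=False
        )
        assert aln.coverage == 1.0

    def test_unknown_transcript_id_rejected(self, hsp_factory):
        with pytest.raises(ValueError, match="tx1"):
            chain_transcript_alignments(
                [hsp_factory(0, 40, 0, 40)], {"other": 100}, 1000, 0.5
            )

    def test_min_coverage_validated(self, hsp_factory):
        with pytest.raises(ValueError):
            chain_transcript_alignments(
                [hsp_factory(0, 40, 0, 40)], {"tx1": 100}, 1000, 1.5
            )

    def test_overlap_trimmed_from_lower_identity_block(self, hsp_factory):
        noisy = hsp_factory(0, 50, 1000, 1050, percent_identity=90.0)
        clean = hsp_factory(45, 100, 2045, 2100, percent_identity=100.0)
        (aln,) = chain_transcript_alignments(
            [noisy, clean], {"tx1": 100}, 10000, 0.5
        )
        first, second = aln.blocks
        assert first.hsp.q_end == 45          # trimmed by the 5 bp overlap
        assert first.hsp.s_end == 1045
        assert second.hsp.q_start == 45       # untouched

    def _random_instance(self, rng, n_blocks):
        hsps = []
        q = 0
        for _ in range(n_blocks):
            q += rng.randint(0, 30)
            span = rng.randint(10, 60)
            s = rng.randint(0, 20000)
            hsps.append(
                (q, q + span, s, s + span, round(rng.uniform(1, 100), 1))
            )
            q += span
        return hsps

    def test_fragment_choice_matches_brute_force(self, hsp_factory):
        """Oracle: best contiguous run whose internal gaps respect max_intron."""

        def gap(a, b):
            if b[2] >= a[3]:
                return b[2] - a[3]
            if a[2] >= b[3]:
                return a[2] - b[3]
            return 0

        rng = random.Random(42)
        for _ in range(200):
            n = rng.randint(1, 6)
            raw = self._random_instance(rng, n)
            max_intron = rng.choice([100, 1000, 5000, 20000])
            hsps = [
                hsp_factory(q0, q1, s0, s1, bitscore=bits)
                for q0, q1, s0, s1, bits in raw
            ]
            # brute force over all contiguous q-ordered runs
            best_score, best_run = -1.0, None
            for i in range(n):
                for j in range(i, n):
                    run = raw[i : j + 1]
                    if any(gap(a, b) > max_intron for a, b in zip(run, run[1:])):
                        continue
                    score = sum(r[4] for r in run)
                    if score > best_score:
                        best_score, best_run = score, run
            (aln,) = chain_transcript_alignments(
                hsps, {"tx1": 10000}, max_intron, 0.0, trim_overlaps=False
            )
            got = [(b.hsp.q_start, b.hsp.q_end) for b in aln.blocks]
            assert got == [(r[0], r[1]) for r in best_run]

    def test_relaxing_coverage_never_loses_transcripts(self, hsp_factory):
        rng = random.Random(7)
        for _ in range(30):
            hsps = []
            for t in range(3):
                for q0, q1, s0, s1, bits in self._random_instance(rng, rng.randint(1, 4)):
                    hsps.append(
                        hsp_factory(q0, q1, s0, s1, query_id=f"t{t}", bitscore=bits)
                    )
            lengths = {f"t{t}": 500 for t in range(3)}
            strict = chain_transcript_alignments(hsps, lengths, 5000, 0.5)
            loose = chain_transcript_alignments(hsps, lengths, 5000, 0.0)
            assert len(loose) >= len(strict)
            for aln in loose:
                assert 0.0 <= aln.coverage <= 1.0
                assert sorted(b.order_index for b in aln.blocks) == list(
                    range(len(aln.blocks))
                )


class TestCollinearity:
    def _blocks(self, spec):
        """spec: list of (s_start, s_end, order_index)."""
        return [
            AlignmentBlock(make_hsp(0, 10, s0, s1), idx) for s0, s1, idx in spec
        ]

    def test_sequential_or_repeated_indices_collinear(self):
        blocks = self._blocks([(0, 10, 1), (20, 30, 2), (40, 50, 3), (60, 70, 3)])
        assert detect_collinearity(blocks) == [(0, 70)]

    def test_non_monotone_steps_break_runs(self):
        blocks = self._blocks([(0, 10, 0), (20, 30, 2), (40, 50, 1)])
        assert detect_collinearity(blocks) == [(0, 10), (20, 30), (40, 50)]

    def test_single_block_trivially_collinear(self):
        blocks = self._blocks([(5, 15, 0)])
        assert detect_collinearity(blocks) == [(5, 15)]

    def test_runs_partition_blocks(self):
        rng = random.Random(3)
        for _ in range(50):
            spec = []
            pos = 0
            for _ in range(rng.randint(1, 10)):
                pos += rng.randint(15, 40)
                spec.append((pos, pos + 10, rng.randint(0, 5)))
            blocks = self._blocks(spec)
            runs = detect_collinearity(blocks)
            # disjoint, ordered intervals covering every block exactly once
            for (a0, a1), (b0, b1) in zip(runs, runs[1:]):
                assert a1 <= b0
            covered = sum(
                1
                for b in blocks
                for (r0, r1) in runs
                if r0 <= b.hsp.s_start and b.hsp.s_end <= r1
            )
            assert covered == len(blocks)


class TestClassifyBlock:
    LONGEST = OrfRegion(10, 100, 0, "M" * 29, 0, is_longest=True)
    MINOR = OrfRegion(2, 8, 2, "M", 0)

    def _block(self, q0, q1):
        return AlignmentBlock(make_hsp(q0, q1, 0, q1 - q0), 0)

    def test_overlapping_longest(self):
        assert classify_block(self._block(0, 30), [self.LONGEST, self.MINOR]) == LONGEST_ORF

    def test_overlapping_minor_only(self):
        assert classify_block(self._block(0, 5), [self.LONGEST, self.MINOR]) == MINOR_ORF

    def test_no_overlap(self):
        assert classify_block(self._block(200, 250), [self.LONGEST, self.MINOR]) == NON_ORF


class TestSpliceBoundaryError:
    def _aln(self, intervals):
        blocks = [
            AlignmentBlock(make_hsp(i * 10, i * 10 + 10, s0, s1), i)
            for i, (s0, s1) in enumerate(intervals)
        ]
        return TranscriptAlignment("tx1", 100, blocks, 1.0)

    def test_exact_edges_score_zero(self):
        aln = self._aln([(100, 140), (500, 540)])
        assert splice_boundary_error(aln, [100, 140, 500, 540]) == 0

    def test_single_off_by_one(self):
        aln = self._aln([(100, 141), (500, 540)])
        assert splice_boundary_error(aln, [100, 140, 500, 540]) == 1

    def test_sum_of_edge_errors(self):
        aln = self._aln([(100, 141), (498, 540)])
        assert splice_boundary_error(aln, [100, 140, 500, 540]) == 3

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            splice_boundary_error(self._aln([(0, 10)]), [])


class TestRendering:
    def _aln(self, tx_id, s0, s1):
        b = AlignmentBlock(make_hsp(0, s1 - s0, s0, s1, query_id=tx_id), 0)
        return TranscriptAlignment(tx_id, s1 - s0, [b], 1.0, [(s0, s1)])

    def test_smoke_file_created(self, tmp_path):
        target = SequenceRecord("g1", "A" * 3000)
        alns = [self._aln("t1", 0, 900), self._aln("t2", 1000, 1900),
                self._aln("t3", 2000, 2900)]
        out = render_tast_plot(alns, target, tmp_path / "plot.png")
        assert out.exists() and out.stat().st_size > 0

    def test_empty_alignments_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            render_tast_plot([], SequenceRecord("g1", "AAAA"), tmp_path / "x.png")

    def test_row_packing_greedy(self):
        from tastkit.tast import _pack_rows

        non_overlapping = [self._aln("a", 0, 10), self._aln("b", 20, 30),
                           self._aln("c", 40, 50)]
        assert _pack_rows(non_overlapping) == [0, 0, 0]
        overlapping = [self._aln("a", 0, 100), self._aln("b", 50, 150)]
        assert sorted(_pack_rows(overlapping)) == [0, 1]
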