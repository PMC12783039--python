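"""Self-alignment depth, trough splitting, k-mer clustering of monomers."""

import numpy as np
import pytest

from conftest import make_hsp

from tastkit import (
    DepthProfile,
    LocusSpec,
    RepeatMonomer,
    RepeatSpec,
    SequenceRecord,
    cluster_monomers,
    kmer_feature_matrix,
    monomer_stats,
    naive_local_align,
    render_repeat_map,
    self_alignment_depth,
    simulate_locus,
    split_monomers_at_troughs,
    tandem_pair_hsps,
)


def self_hsp(q0, q1, s0, s1, strand="forward"):
    return make_hsp(q0, q1, s0, s1, query_id="g1", subject_id="g1", strand=strand)


class TestDepth:
    def test_identity_hsp_excluded(self):
        profile = self_alignment_depth([self_hsp(0, 100, 0, 100)], 100)
        assert not profile.depth.any()

    def test_off_diagonal_counts_both_intervals(self):
        profile = self_alignment_depth([self_hsp(10, 20, 30, 40)], 50)
        expected = np.zeros(50, dtype=int)
        expected[10:20] = 1
        expected[30:40] = 1
        assert (profile.depth == expected).all()

    def test_mirror_pairs_counted_once(self):
        hsps = [self_hsp(10, 20, 30, 40), self_hsp(30, 40, 10, 20)]
        profile = self_alignment_depth(hsps, 50)
        assert profile.depth.max() == 1

    def test_depth_sum_and_symmetry(self):
        rng = np.random.default_rng(5)
        hsps = []
        for _ in range(20):
            q0 = int(rng.integers(0, 400))
            s0 = int(rng.integers(0, 400))
            ln = int(rng.integers(5, 50))
            if (q0, q0 + ln) == (s0, s0 + ln):
                continue
            hsps.append(self_hsp(q0, q0 + ln, s0, s0 + ln))
        profile = self_alignment_depth(hsps, 500)
        swapped = [self_hsp(h.s_start, h.s_end, h.q_start, h.q_end) for h in hsps]
        profile_swapped = self_alignment_depth(swapped, 500)
        assert (profile.depth == profile_swapped.depth).all()
        # every counted HSP contributes its two interval lengths
        keys = {tuple(sorted((h.q_interval, h.s_interval))) for h in hsps}
        expected_sum = sum((a[1] - a[0]) + (b[1] - b[0]) for a, b in keys)
        assert profile.depth.sum() == expected_sum

    def test_out_of_range_hsp_rejected(self):
        with pytest.raises(ValueError):
            self_alignment_depth([self_hsp(0, 10, 90, 101)], 100)

    def test_mixed_sequence_ids_rejected(self):
        with pytest.raises(ValueError):
            self_alignment_depth(
                [make_hsp(0, 10, 20, 30, query_id="a", subject_id="b")], 100
            )

    def test_tandem_array_deeper_than_flanks(self):
        """A simulated repeat array stands out of the unique background."""
        monomer = "".join(
            np.random.default_rng(11).choice(list("ACGT"), 180)
        )
        spec = LocusSpec(
            seed=11,
            intron_lengths=[2000, 800, 800],
            repeat_spec=RepeatSpec([monomer], [5], sub_rate=0.0),
        )
        truth = simulate_locus(spec)
        hsps = naive_local_align(truth.genome, truth.genome, word_size=8,
                                 min_hsp_len=40)
        profile = self_alignment_depth(hsps, len(truth.genome.residues))
        a0 = truth.monomer_intervals[0][0]
        a1 = truth.monomer_intervals[-1][1]
        flank = np.concatenate([profile.depth[:200], profile.depth[-200:]])
        assert profile.depth[a0:a1].mean() > flank.mean()


class TestMonomerSplitting:
    def test_explicit_breakpoints(self):
        seq = SequenceRecord("g1", "A" * 200)
        profile = DepthProfile("g1", np.ones(200, dtype=int))
        monomers = split_monomers_at_troughs(
            seq, (0, 200), profile, breakpoints=[0, 100, 200]
        )
        assert [m.length for m in monomers] == [100, 100]

    def test_zero_depth_region_rejected(self):
        seq = SequenceRecord("g1", "A" * 200)
        profile = DepthProfile("g1", np.zeros(200, dtype=int))
        with pytest.raises(ValueError, match="no repeat signal"):
            split_monomers_at_troughs(seq, (0, 200), profile)

    def test_trough_splitting_recovers_monomer_count(self):
        """Junction-eroded pair HSPs produce troughs at monomer boundaries."""
        rng = np.random.default_rng(2)
        monomer_len, copies = 180, 5
        start = 300
        intervals = [
            (start + i * monomer_len, start + (i + 1) * monomer_len)
            for i in range(copies)
        ]
        seq = SequenceRecord("g1", "".join(rng.choice(list("ACGT"), 2000)))
        hsps = tandem_pair_hsps("g1", intervals, seed=2)
        profile = self_alignment_depth(hsps, 2000)
        monomers = split_monomers_at_troughs(
            seq, (start, start + copies * monomer_len), profile
        )
        assert len(monomers) == copies
        mean_len = sum(m.length for m in monomers) / len(monomers)
        assert abs(mean_len - monomer_len) <= 25


class TestKmerFeatures:
    def test_overlapping_occurrences_counted(self):
        m = RepeatMonomer("A" * 11, (0, 11))
        clustering = kmer_feature_matrix([m], k=10)
        assert clustering.kmers == ["A" * 10]
        assert clustering.feature_matrix[0, 0] == 2

    def test_short_monomer_zero_row(self):
        mats = kmer_feature_matrix(
            [RepeatMonomer("ACGTACGTA", (0, 9)), RepeatMonomer("ACGTACGTAC", (0, 10))],
            k=10,
        )
        assert mats.feature_matrix[0].sum() == 0
        assert mats.feature_matrix[1].sum() == 1

    def test_identical_monomers_identical_rows(self):
        ms = [RepeatMonomer("ACGTACGTACGT", (0, 12))] * 2
        mat = kmer_feature_matrix(ms, k=10).feature_matrix
        assert (mat[0] == mat[1]).all()

    def test_row_sums_law(self):
        rng = np.random.default_rng(0)
        ms = [
            RepeatMonomer("".join(rng.choice(list("ACGT"), int(n))), (0, int(n)))
            for n in rng.integers(5, 60, size=12)
        ]
        mat = kmer_feature_matrix(ms, k=10).feature_matrix
        for m, row in zip(ms, mat):
            assert row.sum() == max(0, m.length - 10 + 1)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            kmer_feature_matrix([], k=10)


def two_template_monomers(seed, n_per_template=20, sub_rate=0.02, length=180):
    """Monomers simulated from two random templates with substitutions."""
    rng = np.random.default_rng(seed)
    templates = ["".join(rng.choice(list("ACGT"), length)) for _ in range(2)]
    monomers, labels = [], []
    for t_idx, template in enumerate(templates):
        arr = np.array(list(template))
        for _ in range(n_per_template):
            copy = arr.copy()
            hits = np.flatnonzero(rng.random(length) < sub_rate)
            for i in hits:
                copy[i] = rng.choice([b for b in "ACGT" if b != copy[i]])
            monomers.append(RepeatMonomer("".join(copy), (0, length)))
            labels.append(t_idx)
    return monomers, labels


class TestClustering:
    def test_two_templates_perfectly_separated(self):
        from sklearn.metrics import adjusted_rand_score

        monomers, truth = two_template_monomers(seed=1)
        clustering = kmer_feature_matrix(monomers, k=10)
        clustering = cluster_monomers(clustering)
        assert len(set(clustering.labels)) == 2
        assert adjusted_rand_score(truth, clustering.labels) == 1.0
        assert 0.0 <= clustering.variance_captured <= 1.0

    def test_identical_monomers_single_cluster_by_convention(self):
        ms = [RepeatMonomer("ACGTACGTACGTACGT", (0, 16))] * 5
        clustering = cluster_monomers(kmer_feature_matrix(ms, k=10))
        assert clustering.variance_captured == 1.0
        assert len(set(clustering.labels)) == 1
        assert -1 not in set(clustering.labels)

    def test_nonpositive_eps_rejected(self):
        ms, _ = two_template_monomers(seed=2, n_per_template=3)
        with pytest.raises(ValueError):
            cluster_monomers(kmer_feature_matrix(ms), eps=0.0)


class TestStats:
    def test_matches_brute_force_recomputation(self):
        ms, _ = two_template_monomers(seed=3, n_per_template=5)
        stats = monomer_stats(ms)
        raw = [m.sequence for m in ms]
        assert stats["min_length"] == min(len(s) for s in raw)
        assert stats["max_length"] == max(len(s) for s in raw)
        assert stats["mean_length"] == pytest.approx(
            sum(len(s) for s in raw) / len(raw)
        )
        gc = [(s.count("G") + s.count("C")) / len(s) for s in raw]
        assert stats["mean_gc"] == pytest.approx(sum(gc) / len(gc))

    def test_simple_gc_values(self):
        assert monomer_stats([RepeatMonomer("ACGT", (0, 4))])["mean_gc"] == 0.5
        stats = monomer_stats(
            [RepeatMonomer("GGCC", (0, 4)), RepeatMonomer("AATT", (0, 4))]
        )
        assert stats["mean_gc"] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            monomer_stats([])


class TestRenderRepeatMap:
    def test_smoke_and_label_mismatch(self, tmp_path):
        ms = [RepeatMonomer("ACGT" * 10, (i * 40, (i + 1) * 40)) for i in range(3)]
        profile = DepthProfile("g1", np.ones(200, dtype=int))
        out = render_repeat_map(200, profile, ms, [0, 0, 1], tmp_path / "m.png")
        assert out.exists() and out.stat().st_size > 0
        with pytest.raises(ValueError):
            render_repeat_map(200, profile, ms, [0, 0], tmp_path / "n.png")

    def test_flat_zero_profile_renders(self, tmp_path):
        profile = DepthProfile("g1", np.zeros(100, dtype=int))
        out = render_repeat_map(100, profile, [], [], tmp_path / "z.png")
        assert out.exists()
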