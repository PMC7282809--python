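"""Pileups, gap filling, meta-profiles (against brute-force oracles),
chromosome medians, and occupancy change."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chipcalib as cc
from chipcalib.occupancy import read_bed_anchors, read_depth_tsv


def brute_force_pileup(reads, chrom_lengths):
    """Per-position membership count; the O(n x L) oracle."""
    out = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()}
    for chrom, start, length in reads:
        for p in range(start, start + length):
            out[chrom][p - 1] += 1
    return out


def brute_force_meta(tracks, anchors, window):
    """Double loop over (anchor, offset); mean over contributing anchors."""
    offsets = range(-window, window + 1)
    means, counts = [], []
    for o in offsets:
        vals = []
        for a in anchors:
            pos = a.anchor + o
            if 1 <= pos <= tracks.chrom_lengths[a.chromosome]:
                vals.append(tracks.values[a.chromosome][pos - 1])
        counts.append(len(vals))
        means.append(sum(vals) / len(vals) if vals else math.nan)
    return np.array(means, dtype=float), np.array(counts)


class TestPileup:
    def test_single_interval(self):
        t = cc.pileup([("chr1", 11, 50)], {"chr1": 100})
        d = t.values["chr1"]
        assert d[10:60].tolist() == [1] * 50
        assert d[:10].sum() == 0 and d[60:].sum() == 0

    def test_additivity_of_identical_reads(self):
        t = cc.pileup([("chr1", 5, 10), ("chr1", 5, 10)], {"chr1": 30})
        assert t.values["chr1"][4:14].tolist() == [2] * 10

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(0)
        lengths = {"chr1": 300, "chr2": 120}
        reads = []
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            length = int(rng.integers(5, 40))
            start = int(rng.integers(1, lengths[chrom] - length + 2))
            reads.append((chrom, start, length))
        t = cc.pileup(reads, lengths)
        oracle = brute_force_pileup(reads, lengths)
        for c in lengths:
            assert np.array_equal(t.values[c], oracle[c])

    def test_out_of_range_read_named_in_error(self):
        with pytest.raises(ValueError, match="chr1:95"):
            cc.pileup([("chr1", 95, 10)], {"chr1": 100})


class TestFillGaps:
    def test_single_position(self):
        assert cc.fill_gaps({3: 7}, 5).tolist() == [0, 0, 7, 0, 0]

    def test_empty_map(self):
        assert cc.fill_gaps({}, 4).tolist() == [0, 0, 0, 0]

    def test_dense_input_is_identity(self):
        dense = {i: i * 2 for i in range(1, 6)}
        assert cc.fill_gaps(dense, 5).tolist() == [2, 4, 6, 8, 10]

    def test_out_of_range_key_rejected(self):
        with pytest.raises(ValueError):
            cc.fill_gaps({6: 1}, 5)

    @given(
        length=st.integers(min_value=1, max_value=500),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conserves_depth_and_length(self, length, data):
        sparse = data.draw(
            st.dictionaries(
                st.integers(min_value=1, max_value=length),
                st.integers(min_value=0, max_value=1000),
                max_size=50,
            )
        )
        dense = cc.fill_gaps(sparse, length)
        assert len(dense) == length
        assert dense.sum() == sum(sparse.values())


def toy_tracks(rng, n_chrom, min_len=30, max_len=120):
    lengths = {
        f"chr{i}": int(rng.integers(min_len, max_len + 1)) for i in range(n_chrom)
    }
    values = {c: rng.integers(0, 20, size=n).astype(np.int64) for c, n in lengths.items()}
    return cc.DepthTrack(values=values, chrom_lengths=lengths)


class TestMetaProfile:
    def test_uniform_depth_gives_constant_profile(self):
        lengths = {"chr1": 100, "chr2": 100}
        tracks = cc.DepthTrack(
            values={c: np.full(n, 4, dtype=np.int64) for c, n in lengths.items()},
            chrom_lengths=lengths,
        )
        anchors = [cc.CentromereAnchor("chr1", 50), cc.CentromereAnchor("chr2", 50)]
        prof = cc.meta_profile(tracks, anchors, window=10, total_reads=10**6)
        assert np.allclose(prof.mean_depth, 4.0)

    def test_matches_brute_force_on_toy_fixture(self):
        rng = np.random.default_rng(3)
        tracks = toy_tracks(rng, 2)
        anchors = [
            cc.CentromereAnchor(c, int(rng.integers(1, n + 1)))
            for c, n in tracks.chrom_lengths.items()
        ]
        prof = cc.meta_profile(tracks, anchors, window=25, total_reads=10**6)
        means, counts = brute_force_meta(tracks, anchors, 25)
        assert np.array_equal(prof.n_contributing, counts)
        assert np.allclose(prof.mean_depth, means, equal_nan=True)

    def test_boundary_truncation_reduces_contributors(self):
        lengths = {"chr1": 5, "chr2": 100}
        tracks = cc.DepthTrack(
            values={c: np.ones(n, dtype=np.int64) for c, n in lengths.items()},
            chrom_lengths=lengths,
        )
        anchors = [cc.CentromereAnchor("chr1", 2), cc.CentromereAnchor("chr2", 50)]
        prof = cc.meta_profile(tracks, anchors, window=3, total_reads=10**6)
        # offsets -3, -2 fall before chr1 base 1; +4.. beyond length 5
        by_offset = dict(zip(prof.offsets.tolist(), prof.n_contributing.tolist()))
        assert by_offset[-3] == 1 and by_offset[-2] == 1
        assert by_offset[-1] == 2 and by_offset[0] == 2 and by_offset[3] == 2
        assert by_offset[2] == 2  # chr1 position 4 still inside

    def test_shift_equivariance(self):
        rng = np.random.default_rng(9)
        lengths = {"chr1": 80}
        base = rng.integers(0, 15, size=60)
        k = 10
        v1 = np.concatenate([base, np.zeros(20, dtype=np.int64)])
        v2 = np.concatenate([np.zeros(k, dtype=np.int64), base, np.zeros(20 - k, dtype=np.int64)])
        t1 = cc.DepthTrack(values={"chr1": v1}, chrom_lengths=lengths)
        t2 = cc.DepthTrack(values={"chr1": v2}, chrom_lengths=lengths)
        a1 = [cc.CentromereAnchor("chr1", 30)]
        a2 = [cc.CentromereAnchor("chr1", 30 + k)]
        p1 = cc.meta_profile(t1, a1, window=15, total_reads=10**6)
        p2 = cc.meta_profile(t2, a2, window=15, total_reads=10**6)
        assert np.allclose(p1.mean_depth, p2.mean_depth)

    def test_calibration_factor_applied(self):
        lengths = {"chr1": 50}
        tracks = cc.DepthTrack(
            values={"chr1": np.full(50, 3, dtype=np.int64)}, chrom_lengths=lengths
        )
        prof = cc.meta_profile(
            tracks, [cc.CentromereAnchor("chr1", 25)], window=5,
            or_=cc.OccupancyRatio(2.0), total_reads=500_000,
        )
        assert np.allclose(prof.mean_depth, 3 * 2.0 * 1e6 / 500_000)

    def test_missing_chromosome_errors(self, toy_depth):
        with pytest.raises(ValueError, match="missing"):
            cc.meta_profile(toy_depth, [cc.CentromereAnchor("nope", 5)], window=3)


class TestChromosomeMedian:
    def test_constant_track(self):
        t = cc.ScaledTrack(
            values={"chr1": np.full(9, 2.5)}, chrom_lengths={"chr1": 9},
            or_value=1.0, total_reads=1,
        )
        assert cc.chromosome_median(t, "chr1") == 2.5

    def test_odd_count_median(self):
        t = cc.ScaledTrack(
            values={"chr1": np.array([1.0, 2, 3, 4, 100])}, chrom_lengths={"chr1": 5},
            or_value=1.0, total_reads=1,
        )
        assert cc.chromosome_median(t, "chr1") == 3.0

    def test_even_count_midpoint_convention(self):
        t = cc.ScaledTrack(
            values={"chr1": np.array([1.0, 2, 3, 4])}, chrom_lengths={"chr1": 4},
            or_value=1.0, total_reads=1,
        )
        assert cc.chromosome_median(t, "chr1") == 2.5

    def test_permutation_invariance_and_linearity(self):
        rng = np.random.default_rng(5)
        v = rng.random(101)
        t = cc.ScaledTrack(
            values={"chr1": v}, chrom_lengths={"chr1": 101}, or_value=1.0, total_reads=1
        )
        tp = cc.ScaledTrack(
            values={"chr1": rng.permutation(v)}, chrom_lengths={"chr1": 101},
            or_value=1.0, total_reads=1,
        )
        t3 = cc.ScaledTrack(
            values={"chr1": 3 * v}, chrom_lengths={"chr1": 101}, or_value=1.0, total_reads=1
        )
        m = cc.chromosome_median(t, "chr1")
        assert cc.chromosome_median(tp, "chr1") == pytest.approx(m)
        assert cc.chromosome_median(t3, "chr1") == pytest.approx(3 * m)

    def test_missing_chromosome_errors(self):
        t = cc.ScaledTrack(
            values={"chr1": np.zeros(3)}, chrom_lengths={"chr1": 3},
            or_value=1.0, total_reads=1,
        )
        with pytest.raises(ValueError):
            cc.chromosome_median(t, "chr2")


def scaled(values):
    return cc.ScaledTrack(
        values={c: np.asarray(v, dtype=float) for c, v in values.items()},
        chrom_lengths={c: len(v) for c, v in values.items()},
        or_value=1.0, total_reads=1,
    )


class TestOccupancyChange:
    def test_identity(self):
        t = scaled({"chr1": [1, 2, 3], "chr2": [4, 5, 6]})
        change = cc.occupancy_change(t, t)
        assert all(v == 1.0 for v in change.per_chromosome.values())
        assert change.genome_wide == 1.0

    def test_halving(self):
        before = scaled({"chr1": [2.0, 4, 6], "chr2": [8.0, 10, 12]})
        after = scaled({c: 0.5 * v for c, v in before.values.items()})
        change = cc.occupancy_change(before, after)
        assert change.genome_wide == pytest.approx(0.5)

    def test_zero_before_median_reported_as_nan(self):
        before = scaled({"chr1": [0.0, 0, 0, 1], "chr2": [1.0, 2, 3]})
        after = scaled({"chr1": [1.0, 1, 1, 1], "chr2": [2.0, 4, 6]})
        change = cc.occupancy_change(before, after)
        assert math.isnan(change.per_chromosome["chr1"])
        assert change.genome_wide == pytest.approx(2.0)

    def test_mismatched_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            cc.occupancy_change(scaled({"chr1": [1.0]}), scaled({"chr2": [1.0]}))


class TestTextIO:
    def test_bed_midpoint_anchor(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t110\t135\tCDEIII\nchr2\t0\t1\tCDEIII\n")
        anchors = read_bed_anchors(path)
        # 0-based [110, 135) covers 1-based 111..135; midpoint base 123
        assert anchors[0] == cc.CentromereAnchor("chr1", 123)
        assert anchors[1] == cc.CentromereAnchor("chr2", 1)

    def test_depth_tsv_round_trip(self, tmp_path, toy_depth):
        from chipcalib.occupancy import write_depth_tsv

        path = tmp_path / "d.tsv"
        write_depth_tsv(toy_depth, path, sparse=True)
        back = read_depth_tsv(path, toy_depth.chrom_lengths)
        for c in toy_depth.values:
            assert np.array_equal(back.values[c], toy_depth.values[c])
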