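"""Binning, log2-ratio computation and binary segmentation."""
import numpy as np
import pytest

from cndiff.cnr import (
    BinTrack,
    CNRSegmenter,
    Log2RatioTrack,
    bin_genome,
    cnr_from_log2,
    compute_log2_ratio,
    segment_log2_ratios,
)
from cndiff.core import GenomicInterval, ValidationError

BIN = 50_000


def ratio_track(values, valid=None, chrom="chr1"):
    n = len(values)
    bins = [GenomicInterval(chrom, i * BIN, (i + 1) * BIN) for i in range(n)]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return Log2RatioTrack(bins=bins, ratio=np.asarray(values, float), valid=valid)


class TestBinGenome:
    def test_tiling_arithmetic(self):
        bins, mask = bin_genome({"chr1": 125_000}, bin_size=BIN)
        coords = [(b.start, b.end) for b in bins]
        assert coords == [(0, 50_000), (50_000, 100_000), (100_000, 125_000)]
        assert not mask.any()

    def test_exclusion_majority_rule(self):
        # 60% of bin 1 covered -> masked; 40% of bin 2 -> kept
        excl = [
            GenomicInterval("chr1", 50_000, 80_000),
            GenomicInterval("chr1", 100_000, 120_000),
        ]
        _, mask = bin_genome({"chr1": 150_000}, bin_size=BIN, exclude=excl)
        assert mask.tolist() == [False, True, False]

    def test_exclusion_union_not_double_counted(self):
        # two overlapping 20 kb intervals cover only 30 kb of bin 0
        excl = [
            GenomicInterval("chr1", 0, 20_000),
            GenomicInterval("chr1", 10_000, 30_000),
        ]
        _, mask = bin_genome({"chr1": 50_000}, bin_size=BIN, exclude=excl)
        assert mask.tolist() == [True]  # 30 kb > 25 kb

    def test_empty_chrom_sizes_rejected(self):
        with pytest.raises(ValidationError):
            bin_genome({}, bin_size=BIN)


class TestLog2Ratio:
    def _track(self, cov_test, cov_control, mask=None):
        n = len(cov_test)
        bins = [GenomicInterval("chr1", i * BIN, (i + 1) * BIN) for i in range(n)]
        if mask is None:
            mask = np.zeros(n, dtype=bool)
        return BinTrack(bins, np.asarray(cov_test, float), np.asarray(cov_control, float), mask)

    def test_identical_coverage_gives_zero(self):
        t = compute_log2_ratio(self._track([100] * 20, [100] * 20))
        np.testing.assert_allclose(t.ratio[t.valid], 0.0, atol=1e-12)

    def test_minority_doubling_centered_on_majority(self):
        cov_c = [100] * 100
        cov_t = [100] * 90 + [200] * 10
        t = compute_log2_ratio(self._track(cov_t, cov_c))
        np.testing.assert_allclose(t.ratio[:90], 0.0, atol=1e-6)
        np.testing.assert_allclose(t.ratio[90:], 1.0, atol=1e-6)

    def test_zero_control_bin_invalid_only_there(self):
        cov_c = [100] * 10
        cov_c[3] = 0
        t = compute_log2_ratio(self._track([100] * 10, cov_c))
        assert not t.valid[3]
        assert t.valid.sum() == 9

    def test_median_of_valid_ratios_is_zero(self):
        rng = np.random.default_rng(2)
        t = compute_log2_ratio(
            self._track(rng.poisson(200, 50), rng.poisson(100, 50))
        )
        assert abs(np.median(t.ratio[t.valid])) < 1e-6

    def test_all_invalid_rejected(self):
        with pytest.raises(ValidationError):
            compute_log2_ratio(self._track([100] * 4, [0] * 4))


class TestSegmentation:
    def test_constant_track_single_segment(self):
        segs = segment_log2_ratios(ratio_track(np.zeros(100)))
        assert len(segs) == 1
        assert segs[0].log2cnr == pytest.approx(0.0)
        assert (segs[0].interval.start, segs[0].interval.end) == (0, 100 * BIN)

    def test_single_step_recovered(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([np.zeros(50), np.ones(50)]) + rng.normal(0, 0.2, 100)
        segs = segment_log2_ratios(ratio_track(x))
        assert len(segs) == 2
        breakpoint_bin = segs[1].interval.start // BIN
        assert abs(breakpoint_bin - 50) <= 2

    def test_three_level_signal(self):
        rng = np.random.default_rng(7)
        truth = np.concatenate([np.zeros(60), np.full(60, 0.585), np.full(60, -1.0)])
        x = truth + rng.normal(0, 0.15, 180)
        segs = segment_log2_ratios(ratio_track(x))
        assert len(segs) == 3
        for seg, expected in zip(segs, (0.0, 0.585, -1.0)):
            assert seg.log2cnr == pytest.approx(expected, abs=0.1)

    def test_segment_mean_equals_member_bin_mean(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([np.zeros(40), np.ones(40)]) + rng.normal(0, 0.1, 80)
        track = ratio_track(x)
        for seg in segment_log2_ratios(track):
            members = [
                r
                for b, r in zip(track.bins, track.ratio)
                if seg.interval.start <= b.start < seg.interval.end
            ]
            assert seg.log2cnr == pytest.approx(np.mean(members), abs=1e-12)

    def test_idempotent_on_noise_free_track(self):
        x = np.concatenate([np.zeros(30), np.full(30, 0.8), np.zeros(30)])
        first = segment_log2_ratios(ratio_track(x))
        rebuilt = np.concatenate(
            [
                np.full((s.interval.end - s.interval.start) // BIN, s.log2cnr)
                for s in first
            ]
        )
        second = segment_log2_ratios(ratio_track(rebuilt))
        assert [(s.interval.start, s.interval.end) for s in first] == [
            (s.interval.start, s.interval.end) for s in second
        ]
        for a, b in zip(first, second):
            assert a.log2cnr == pytest.approx(b.log2cnr, abs=1e-12)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(21)
        n = 120
        bins = [GenomicInterval("chr1", i * BIN, (i + 1) * BIN) for i in range(n)]
        lam = 300 * 2.0 ** np.concatenate([np.zeros(60), np.ones(60)])
        track = BinTrack(
            bins, rng.poisson(lam).astype(float), rng.poisson(300, n).astype(float),
            np.zeros(n, bool),
        )
        fwd = CNRSegmenter().fit(track).segments_
        rev = CNRSegmenter().fit(track.swapped()).segments_
        assert [(s.interval.start, s.interval.end) for s in fwd] == [
            (s.interval.start, s.interval.end) for s in rev
        ]
        for a, b in zip(fwd, rev):
            assert a.log2cnr == pytest.approx(-b.log2cnr, abs=1e-6)

    def test_breakpoint_recovery_rate(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.concatenate([np.zeros(50), np.ones(50)]) + rng.normal(0, 0.25, 100)
            segs = segment_log2_ratios(ratio_track(x - np.median(x)))
            bps = [s.interval.start // BIN for s in segs[1:]]
            if any(abs(b - 50) <= 2 for b in bps):
                hits += 1
        assert hits >= 45  # >= 90% of 50 seeded step signals

    def test_invalid_gap_inherits_preceding_segment(self):
        x = np.concatenate([np.zeros(30), np.ones(30)])
        valid = np.ones(60, dtype=bool)
        valid[25:28] = False
        segs = segment_log2_ratios(ratio_track(x, valid=valid))
        assert len(segs) == 2
        # gap bins 25-27 fall inside the first segment's span
        assert segs[0].interval.end == 30 * BIN
        assert segs[1].interval.start == 30 * BIN

    def test_too_few_bins_single_segment_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than"):
            segs = segment_log2_ratios(ratio_track([0.3, 0.3, 0.3]))
        assert len(segs) == 1


class TestCnrFromLog2:
    @pytest.mark.parametrize(
        "log2,expected",
        [(0.0, 1.0), (np.log2(1.5), 1.5), (-6.0, 0.0625), (10.0, 16.0)],
    )
    def test_conversion_and_clipping(self, log2, expected):
        assert cnr_from_log2(log2, clip=(0.0625, 16)) == pytest.approx(expected)

    def test_bad_clip_rejected(self):
        with pytest.raises(ValidationError):
            cnr_from_log2(0.0, clip=(-1, 2))


def test_estimator_params_round_trip():
    seg = CNRSegmenter(penalty=7.5, min_seg_bins=4)
    assert seg.get_params()["penalty"] == 7.5
    seg.set_params(min_delta=0.2)
    assert seg.min_delta == 0.2
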