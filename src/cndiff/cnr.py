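"""Copy-number-ratio estimation from binned coverage of two samples.

The estimator follows the standard read-depth route: tile the genome into
fixed-width bins (default 50 kb), mask bins dominated by assembly gaps or
blacklisted regions, compute depth-normalized per-bin log2 coverage ratios
(test / control) centered at their median, segment each chromosome into runs
of constant ratio by recursive binary segmentation, and report one
copy-number ratio per segment.

Only the *ratio* between the two samples is estimated — no absolute
copy-number calling, purity or ploidy modelling.  Median centering assumes
the modal genomic state has ratio 1; for genome-doubled samples supply
externally derived segment files instead.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from sklearn.base import BaseEstimator

from .core import GenomicInterval, Segment, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 50_000
DEFAULT_MIN_SEG_BINS = 5
DEFAULT_PENALTY = 5.0
DEFAULT_MIN_DELTA = 0.1
DEFAULT_CLIP = (0.0625, 16.0)


@dataclass
class BinTrack:
    """Fixed-width genome bins with per-bin coverage of both samples."""

    bins: List[GenomicInterval]
    cov_test: np.ndarray
    cov_control: np.ndarray
    mask: np.ndarray  # True = excluded

    def __post_init__(self) -> None:
        self.cov_test = np.asarray(self.cov_test, dtype=float)
        self.cov_control = np.asarray(self.cov_control, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.bins)
        if not (len(self.cov_test) == len(self.cov_control) == len(self.mask) == n):
            raise ValidationError("BinTrack arrays must all match the number of bins")
        if np.any(self.cov_test < 0) or np.any(self.cov_control < 0):
            raise ValidationError("coverage must be non-negative")

    def swapped(self) -> "BinTrack":
        """Exchange the roles of test and control."""
        return BinTrack(self.bins, self.cov_control.copy(), self.cov_test.copy(), self.mask.copy())


@dataclass
class Log2RatioTrack:
    """Median-centered per-bin log2 coverage ratios."""

    bins: List[GenomicInterval]
    ratio: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.bins) == len(self.ratio) == len(self.valid)):
            raise ValidationError("Log2RatioTrack arrays must match the number of bins")
        if not np.all(np.isfinite(self.ratio[self.valid])):
            raise ValidationError("ratio must be finite wherever valid")


def bin_genome(
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    exclude: Sequence[GenomicInterval] = (),
) -> Tuple[List[GenomicInterval], np.ndarray]:
    """Tile each chromosome with non-overlapping ``bin_size`` bins.

    The last bin per chromosome may be shorter.  A bin is masked when its
    overlap with ``exclude`` intervals exceeds 50% of the bin's own width.
    """
    if not chrom_sizes:
        raise ValidationError("chrom_sizes is empty")
    if bin_size < 1000:
        raise ValidationError(f"bin_size must be >= 1000 bp, got {bin_size}")
    excl_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in exclude:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)

    bins: List[GenomicInterval] = []
    mask: List[bool] = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValidationError(f"chromosome {chrom} has non-positive length {length}")
        excl = sorted(excl_by_chrom.get(chrom, []), key=lambda iv: iv.start)
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            b = GenomicInterval(chrom, start, end)
            covered = _union_overlap(b, excl)
            bins.append(b)
            mask.append(covered > 0.5 * b.length)
    return bins, np.asarray(mask, dtype=bool)


def _union_overlap(bin_iv: GenomicInterval, sorted_excl: List[GenomicInterval]) -> int:
    """Total bp of ``bin_iv`` covered by the union of exclusion intervals."""
    covered = 0
    cursor = bin_iv.start
    for iv in sorted_excl:
        if iv.end <= cursor:
            continue
        if iv.start >= bin_iv.end:
            break
        lo = max(iv.start, cursor)
        hi = min(iv.end, bin_iv.end)
        if hi > lo:
            covered += hi - lo
            cursor = hi
    return covered


def compute_log2_ratio(track: BinTrack) -> Log2RatioTrack:
    """Depth-normalized, median-centered per-bin log2 (test / control) ratio.

    Per valid bin b: ``log2((cov_test_b / N_test) / (cov_control_b / N_control))``
    with N the total coverage over valid bins of each sample, then the median
    over valid bins is subtracted.  Masked bins and bins with zero control
    coverage are invalid.
    """
    valid = (~track.mask) & (track.cov_control > 0)
    # zero-test bins would give -inf; treat as invalid as well
    valid &= track.cov_test > 0
    if not valid.any():
        raise ValidationError("no valid bins: all masked or zero coverage")
    n_test = track.cov_test[valid].sum()
    n_control = track.cov_control[valid].sum()
    if n_test <= 0 or n_control <= 0:
        raise ValidationError("total valid coverage must be positive in both samples")
    ratio = np.full(len(track.bins), np.nan)
    ratio[valid] = np.log2(
        (track.cov_test[valid] / n_test) / (track.cov_control[valid] / n_control)
    )
    ratio[valid] -= np.median(ratio[valid])
    return Log2RatioTrack(bins=track.bins, ratio=ratio, valid=valid)


def _robust_sigma(x: np.ndarray) -> float:
    """Robust noise sd from first differences: 1.4826 * MAD(diff) / sqrt(2).

    First differences cancel the piecewise-constant signal except at the few
    changepoints, to which the MAD is insensitive.
    """
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _best_split(x: np.ndarray, min_seg: int, sigma: float) -> Tuple[Optional[int], float, float]:
    """Best binary split of x: returns (index k, t-statistic, |delta mean|).

    Split point k means left = x[:k], right = x[k:].  The statistic is
    |mean_L - mean_R| / (sigma * sqrt(1/n_L + 1/n_R)).
    """
    n = len(x)
    if n < 2 * min_seg:
        return None, 0.0, 0.0
    csum = np.cumsum(x)
    total = csum[-1]
    ks = np.arange(min_seg, n - min_seg + 1)
    n_l = ks.astype(float)
    n_r = n - n_l
    mean_l = csum[ks - 1] / n_l
    mean_r = (total - csum[ks - 1]) / n_r
    delta = np.abs(mean_l - mean_r)
    denom = max(sigma, 1e-12) * np.sqrt(1.0 / n_l + 1.0 / n_r)
    stat = delta / denom
    i = int(np.argmax(stat))
    return int(ks[i]), float(stat[i]), float(delta[i])


def _segment_indices(
    x: np.ndarray, min_seg: int, penalty: float, min_delta: float, sigma: float
) -> List[Tuple[int, int]]:
    """Recursive binary segmentation; returns half-open index runs."""
    out: List[Tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        k, stat, delta = _best_split(x[lo:hi], min_seg, sigma)
        if k is not None and stat > penalty and delta >= min_delta:
            recurse(lo, lo + k)
            recurse(lo + k, hi)
        else:
            out.append((lo, hi))

    recurse(0, len(x))
    return out


def segment_log2_ratios(
    track: Log2RatioTrack,
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    penalty: float = DEFAULT_PENALTY,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> List[Segment]:
    """Segment each chromosome's valid bins into runs of constant log2 ratio.

    Breakpoints maximize the two-sample t-like statistic
    ``|mean_L - mean_R| / (s * sqrt(1/n_L + 1/n_R))`` with the noise sd ``s``
    estimated robustly from first differences; a split is accepted iff the
    statistic exceeds ``penalty``, both sides keep >= ``min_seg_bins`` bins
    and the mean shift is >= ``min_delta`` log2 units.  Segment boundaries
    snap to bin boundaries; invalid-bin gaps inherit the preceding (or for a
    leading gap, the following) segment, so segments tile each chromosome's
    binned extent.  The segment log2cnr is the mean of its member valid bins.
    """
    if min_seg_bins < 2:
        raise ValidationError(f"min_seg_bins must be >= 2, got {min_seg_bins}")
    chrom_order: List[str] = []
    for iv in track.bins:
        if not chrom_order or chrom_order[-1] != iv.chrom:
            if iv.chrom in chrom_order:
                raise ValidationError("bins must be grouped by chromosome")
            chrom_order.append(iv.chrom)

    segments: List[Segment] = []
    idx = np.arange(len(track.bins))
    chroms = np.array([iv.chrom for iv in track.bins])
    for chrom in chrom_order:
        on_chrom = idx[chroms == chrom]
        vbins = on_chrom[track.valid[on_chrom]]
        chrom_start = track.bins[on_chrom[0]].start
        chrom_end = track.bins[on_chrom[-1]].end
        if len(vbins) == 0:
            logger.warning("chromosome %s has no valid bins; skipped", chrom)
            continue
        x = track.ratio[vbins]
        if len(vbins) < min_seg_bins:
            warnings.warn(
                f"chromosome {chrom} has fewer than {min_seg_bins} valid bins; "
                "emitting a single whole-chromosome segment",
                stacklevel=2,
            )
            runs = [(0, len(x))]
        else:
            sigma = _robust_sigma(x)
            runs = _segment_indices(x, min_seg_bins, penalty, min_delta, sigma)
        for r, (lo, hi) in enumerate(runs):
            start = chrom_start if r == 0 else track.bins[vbins[lo]].start
            end = chrom_end if r == len(runs) - 1 else track.bins[vbins[hi]].start
            segments.append(
                Segment(GenomicInterval(chrom, start, end), log2cnr=float(np.mean(x[lo:hi])))
            )
    if not segments:
        raise ValidationError("no chromosome yielded any valid bins")
    return segments


def cnr_from_log2(log2cnr: float, clip: Tuple[float, float] = DEFAULT_CLIP) -> float:
    """Convert a log2 copy-number ratio back to the ratio scale, clipped."""
    lo, hi = clip
    if lo <= 0 or hi < lo:
        raise ValidationError(f"invalid clip range {clip}")
    return float(min(max(2.0 ** log2cnr, lo), hi))


class CNRSegmenter(BaseEstimator):
    """Estimate constant-CNR segments from a two-sample :class:`BinTrack`.

    Parameters
    ----------
    min_seg_bins : minimum bins on each side of an accepted breakpoint.
    penalty : t-statistic threshold for accepting a split.
    min_delta : minimum |mean shift| (log2 units) for accepting a split.

    Attributes (after ``fit``)
    --------------------------
    ratio_track_ : the median-centered :class:`Log2RatioTrack`.
    segments_ : list of :class:`cndiff.core.Segment`.
    """

    def __init__(
        self,
        min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
        penalty: float = DEFAULT_PENALTY,
        min_delta: float = DEFAULT_MIN_DELTA,
    ) -> None:
        self.min_seg_bins = min_seg_bins
        self.penalty = penalty
        self.min_delta = min_delta

    def fit(self, track: BinTrack, y=None) -> "CNRSegmenter":
        self.ratio_track_ = compute_log2_ratio(track)
        self.segments_ = segment_log2_ratios(
            self.ratio_track_,
            min_seg_bins=self.min_seg_bins,
            penalty=self.penalty,
            min_delta=self.min_delta,
        )
        return self

    def fit_predict(self, track: BinTrack, y=None) -> List[Segment]:
        return self.fit(track).segments_
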