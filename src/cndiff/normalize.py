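"""Copy-number normalization of peak counts — the pipeline's core step.

Each peak is assigned to its overlapping CN segment (maximal overlap; ties
broken by midpoint distance, then leftmost) or, failing that, the nearest
segment on the same chromosome.  The segment's copy-number ratio r then
rescales the count matrix *towards the lower-copy side*:

* r >= 1 (copy gain in the test sample): test-condition counts are divided
  by r;
* r < 1 (copy loss in the test sample): control-condition counts are
  multiplied by r.

Shrinking the higher-copy side, rather than inflating the lower-copy one,
avoids manufacturing statistical power out of reads that were never
sequenced.  Scaling happens after signal quantification but *before* any
data normalization, so size factors downstream are computed on the
corrected matrix.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cnr import DEFAULT_CLIP, cnr_from_log2
from .core import (
    CONTROL,
    TEST,
    CountMatrix,
    Peak,
    Segment,
    ValidationError,
    validate_segments,
)

logger = logging.getLogger(__name__)

ASSIGN_OVERLAP = "overlap"
ASSIGN_NEAREST = "nearest"
ASSIGN_FALLBACK = "fallback"


@dataclass(frozen=True)
class PeakAssignment:
    """The CN segment a peak is corrected with."""

    peak_name: str
    segment_index: Optional[int]
    log2cnr: float
    cnr: float  # the (clipped) scaling ratio actually applied
    kind: str  # overlap | nearest | fallback
    distance: int  # bp gap to the segment (0 when overlapping)

    def __post_init__(self) -> None:
        if self.cnr <= 0:
            raise ValidationError("assignment cnr must be > 0")
        if self.kind == ASSIGN_FALLBACK and self.cnr != 1.0:
            raise ValidationError("fallback assignments must carry cnr = 1")


def assign_peaks(
    peaks: Sequence[Peak],
    segments: Sequence[Segment],
    clip: Tuple[float, float] = DEFAULT_CLIP,
) -> List[PeakAssignment]:
    """Assign every peak to a CN segment.

    Overlapping segments win by overlap length; ties go to the segment whose
    midpoint is nearest the peak midpoint, then to the leftmost.  Peaks with
    no overlapping segment take the nearest segment on their chromosome by
    gap distance.  Chromosomes without any segment fall back to cnr = 1 (and
    a warning is logged); no peak is ever dropped.  The applied ratio is
    ``2**log2cnr`` clipped to ``clip``.
    """
    validate_segments(segments)
    by_chrom: Dict[str, List[Tuple[int, Segment]]] = {}
    for i, seg in enumerate(segments):
        by_chrom.setdefault(seg.chrom, []).append((i, seg))

    out: List[PeakAssignment] = []
    n_fallback = 0
    for peak in peaks:
        candidates = by_chrom.get(peak.chrom, [])
        if not candidates:
            n_fallback += 1
            out.append(
                PeakAssignment(peak.name, None, 0.0, 1.0, ASSIGN_FALLBACK, distance=-1)
            )
            continue
        overlaps = [
            (i, seg, seg.interval.overlap_length(peak.interval))
            for i, seg in candidates
        ]
        overlapping = [(i, seg, o) for i, seg, o in overlaps if o > 0]
        if overlapping:
            best_o = max(o for _, _, o in overlapping)
            tied = [(i, seg) for i, seg, o in overlapping if o == best_o]
            if len(tied) > 1:
                pm = peak.interval.midpoint
                best_d = min(abs(seg.interval.midpoint - pm) for _, seg in tied)
                tied = [
                    (i, seg)
                    for i, seg in tied
                    if abs(seg.interval.midpoint - pm) == best_d
                ]
            i, seg = min(tied, key=lambda t: t[1].interval.start)
            out.append(
                PeakAssignment(
                    peak.name, i, seg.log2cnr, cnr_from_log2(seg.log2cnr, clip),
                    ASSIGN_OVERLAP, distance=0,
                )
            )
        else:
            gaps = [(seg.interval.gap_to(peak.interval), i, seg) for i, seg in candidates]
            best_gap = min(g for g, _, _ in gaps)
            i, seg = min(
                ((i, seg) for g, i, seg in gaps if g == best_gap),
                key=lambda t: t[1].interval.start,
            )
            out.append(
                PeakAssignment(
                    peak.name, i, seg.log2cnr, cnr_from_log2(seg.log2cnr, clip),
                    ASSIGN_NEAREST, distance=int(best_gap),
                )
            )
    if n_fallback:
        logger.warning(
            "%d peak(s) on chromosomes without CN segments; left uncorrected (cnr = 1)",
            n_fallback,
        )
    return out


ROUND_NONE = "none"
ROUND_HALF_EVEN = "half_even"


def scale_counts(
    matrix: CountMatrix,
    assignments: Sequence[PeakAssignment],
    rounding: str = ROUND_HALF_EVEN,
) -> CountMatrix:
    """Rescale counts to a common copy number, per peak, per the CNR rule.

    For a peak with ratio r: r >= 1 divides all test-condition counts by r;
    r < 1 multiplies all control-condition counts by r.  The untouched
    condition's columns are returned bit-identical.  With
    ``rounding="half_even"`` the scaled matrix is rounded to the nearest
    integer (ties to even) and the pre-rounding matrix is kept in
    ``metadata["unrounded_counts"]``.
    """
    if rounding not in (ROUND_NONE, ROUND_HALF_EVEN):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    by_name = {a.peak_name: a for a in assignments}
    missing = [p.name for p in matrix.peaks if p.name not in by_name]
    if missing:
        raise ValidationError(f"peaks without assignment: {missing[:5]}")
    ratios = np.array([by_name[p.name].cnr for p in matrix.peaks])
    test_cols = matrix.columns(TEST)
    control_cols = matrix.columns(CONTROL)

    scaled = matrix.counts.copy()
    gain = ratios >= 1.0
    loss = ~gain
    scaled[np.ix_(np.where(gain)[0], test_cols)] /= ratios[gain, None]
    scaled[np.ix_(np.where(loss)[0], control_cols)] *= ratios[loss, None]

    out = matrix.copy()
    if rounding == ROUND_HALF_EVEN:
        out.counts = np.round(scaled)  # numpy rounds half to even
        out.metadata["unrounded_counts"] = scaled
    else:
        out.counts = scaled
    out.metadata["cn_scaled"] = True
    return out


def assignment_report(
    assignments: Sequence[PeakAssignment], segments: Sequence[Segment]
) -> pd.DataFrame:
    """Per-peak table: segment coordinates, log2cnr, applied ratio, kind."""
    rows = []
    for a in assignments:
        seg = segments[a.segment_index] if a.segment_index is not None else None
        rows.append(
            {
                "peak": a.peak_name,
                "segment_chrom": seg.chrom if seg else ".",
                "segment_start": seg.interval.start if seg else -1,
                "segment_end": seg.interval.end if seg else -1,
                "log2cnr": a.log2cnr,
                "cnr": a.cnr,
                "kind": a.kind,
                "distance": a.distance,
            }
        )
    return pd.DataFrame(rows)


def normalize_pipeline(
    peaks: Sequence[Peak],
    segments: Sequence[Segment],
    matrix: CountMatrix,
    clip: Tuple[float, float] = DEFAULT_CLIP,
    rounding: str = ROUND_HALF_EVEN,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Assign peaks to segments, rescale the matrix, and report.

    Returns the corrected matrix plus the per-peak assignment report.  Size
    factors downstream must be computed on the returned matrix, never the
    raw one — scaling deliberately precedes data normalization.
    """
    normalizer = CopyNumberNormalizer(clip=clip, rounding=rounding).fit(peaks, segments)
    return normalizer.transform(matrix), normalizer.report_


class CopyNumberNormalizer(BaseEstimator):
    """Transformer applying segment-CNR scaling to count matrices.

    Parameters
    ----------
    clip : (lo, hi) bounds on the applied ratio, guarding against near-zero
        ratios annihilating control counts on homozygous-deletion segments.
    rounding : "half_even" (default; keeps the matrix valid for
        integer-count engines) or "none".

    Attributes (after ``fit``)
    --------------------------
    assignments_ : list of :class:`PeakAssignment`, one per peak.
    report_ : per-peak assignment DataFrame.
    """

    def __init__(
        self,
        clip: Tuple[float, float] = DEFAULT_CLIP,
        rounding: str = ROUND_HALF_EVEN,
    ) -> None:
        self.clip = clip
        self.rounding = rounding

    def fit(self, peaks: Sequence[Peak], segments: Sequence[Segment]) -> "CopyNumberNormalizer":
        self.segments_ = list(segments)
        self.assignments_ = assign_peaks(peaks, self.segments_, clip=self.clip)
        self.report_ = assignment_report(self.assignments_, self.segments_)
        return self

    def transform(self, matrix: CountMatrix) -> CountMatrix:
        if not hasattr(self, "assignments_"):
            raise ValidationError("CopyNumberNormalizer must be fit before transform")
        return scale_counts(matrix, self.assignments_, rounding=self.rounding)

    def fit_transform(
        self, peaks: Sequence[Peak], segments: Sequence[Segment], matrix: CountMatrix
    ) -> CountMatrix:
        return self.fit(peaks, segments).transform(matrix)
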