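"""Domain containers shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention); any 1-based
source is converted at the I/O boundary.  Strand is ignored throughout: the
method operates on strand-agnostic fragment counts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a structural contract (dimensions, signs, overlap)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if disjoint or trans)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp to ``other`` on the same chromosome; 0 if overlapping."""
        if self.chrom != other.chrom:
            return None
        if self.overlap_length(other) > 0:
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class Peak:
    """A region of enriched assay signal (open chromatin or binding)."""

    interval: GenomicInterval
    name: str
    score: Optional[float] = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class Segment:
    """Genomic run of constant copy-number ratio (test vs control).

    ``cnr = 2 ** log2cnr`` is maintained as an invariant; the ratio is the
    local copy number of the test sample divided by that of the control, so
    log2cnr = 0 means equal copies.
    """

    interval: GenomicInterval
    log2cnr: float
    cnr: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cnr is None:
            object.__setattr__(self, "cnr", float(2.0 ** self.log2cnr))
        if self.cnr <= 0:
            raise ValidationError(f"segment CNR must be > 0, got {self.cnr}")
        if not math.isclose(self.cnr, 2.0 ** self.log2cnr, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"segment cnr={self.cnr} inconsistent with log2cnr={self.log2cnr}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def validate_peaks(peaks: Sequence[Peak]) -> None:
    """Names must be unique within a peak set."""
    names = [p.name for p in peaks]
    if len(set(names)) != len(names):
        dupes = pd.Series(names)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise ValidationError(f"duplicate peak names: {dupes[:5]}")


def validate_segments(segments: Sequence[Segment]) -> None:
    """Segments on one chromosome must be sorted and non-overlapping."""
    by_chrom: Dict[str, List[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        for a, b in zip(segs, segs[1:]):
            if b.interval.start < a.interval.end:
                raise ValidationError(
                    f"segments overlap or are unsorted on {chrom}: "
                    f"[{a.interval.start},{a.interval.end}) vs "
                    f"[{b.interval.start},{b.interval.end})"
                )


TEST = "test"
CONTROL = "control"


@dataclass
class CountMatrix:
    """Peaks x samples matrix of fragment counts with condition labels.

    Counts may be fractional: matrices that have passed copy-number scaling
    are no longer integer-valued.  ``metadata`` carries side information such
    as the pre-rounding matrix after scaling.
    """

    peaks: List[Peak]
    samples: List[str]
    condition: Dict[str, str]
    counts: np.ndarray
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.samples)} samples"
            )
        validate_peaks(self.peaks)
        missing = [s for s in self.samples if s not in self.condition]
        if missing:
            raise ValidationError(f"samples missing a condition label: {missing}")
        bad = {c for c in self.condition.values()} - {TEST, CONTROL}
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        labels = [self.condition[s] for s in self.samples]
        for lab in (TEST, CONTROL):
            if lab not in labels:
                raise ValidationError(f"no sample labelled '{lab}'")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite")

    @property
    def peak_names(self) -> List[str]:
        return [p.name for p in self.peaks]

    def columns(self, condition: str) -> np.ndarray:
        """Indices of samples carrying the given condition label."""
        return np.array(
            [j for j, s in enumerate(self.samples) if self.condition[s] == condition],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.peak_names, name="peak"), columns=self.samples
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            peaks=list(self.peaks),
            samples=list(self.samples),
            condition=dict(self.condition),
            counts=self.counts.copy(),
            metadata=dict(self.metadata),
        )
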