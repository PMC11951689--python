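"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* narrowPeak / BED (tab-separated, 0-based half-open) for peaks,
* the ``cns`` segment dialect (header ``chromosome  start  end  gene  log2``,
  extra columns ignored) and BED + 4th-column log2 for CN segments,
* TSV count matrices (rows = peaks, columns = samples),
* two-column condition maps, bedGraph / TSV bin coverage, chrom sizes.

All readers return the containers of :mod:`cndiff.core`; every reader/writer
pair is an inverse on valid inputs (round-trip identity within float
tolerance).  Chromosome names are matched exactly; pass ``strip_chr=True``
to drop a leading ``"chr"`` at the boundary instead of silently renaming.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    CONTROL,
    TEST,
    CountMatrix,
    GenomicInterval,
    ParseError,
    Peak,
    Segment,
    ValidationError,
    validate_segments,
)


def _maybe_strip(chrom: str, strip_chr: bool) -> str:
    if strip_chr and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def _data_lines(path) -> Iterable[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_narrowpeak(path, strip_chr: bool = False) -> List[Peak]:
    """Read peaks from a narrowPeak/BED file (0-based half-open).

    Lines need >= 3 tab-separated columns; a missing 4th column gets the
    synthesized name ``peak_<i>`` (1-based file order).
    """
    peaks: List[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
        chrom = _maybe_strip(fields[0], strip_chr)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{len(peaks) + 1}"
        score: Optional[float] = None
        if len(fields) > 4 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from exc
        try:
            peaks.append(Peak(GenomicInterval(chrom, start, end), name=name, score=score))
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(path, peaks: Sequence[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score}\t.\n")


_CNS_COLUMNS = ("chromosome", "start", "end", "gene", "log2")


def read_segments(path, dialect: str = "cns", strip_chr: bool = False) -> List[Segment]:
    """Read CN segments; ``cnr`` is recomputed as ``2**log2``.

    ``dialect="cns"``: tab file with a header naming at least
    ``chromosome, start, end, log2`` (extra columns ignored).
    ``dialect="bed_log2"``: headerless BED3 plus a 4th log2 column.
    Per-chromosome sort order and non-overlap are verified.
    """
    segments: List[Segment] = []
    if dialect == "cns":
        table = pd.read_csv(path, sep="\t")
        needed = {"chromosome", "start", "end", "log2"}
        if not needed.issubset(table.columns):
            raise ParseError(
                f"{path}: cns dialect requires columns {sorted(needed)}, "
                f"found {list(table.columns)}"
            )
        for i, row in table.iterrows():
            try:
                log2 = float(row["log2"])
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: row {i + 1}: non-numeric log2 {row['log2']!r}") from exc
            if not np.isfinite(log2):
                raise ParseError(f"{path}: row {i + 1}: non-finite log2")
            chrom = _maybe_strip(str(row["chromosome"]), strip_chr)
            segments.append(
                Segment(GenomicInterval(chrom, int(row["start"]), int(row["end"])), log2cnr=log2)
            )
    elif dialect == "bed_log2":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bed_log2 requires 4 columns")
            try:
                log2 = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric log2 {fields[3]!r}") from exc
            chrom = _maybe_strip(fields[0], strip_chr)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            segments.append(Segment(GenomicInterval(chrom, start, end), log2cnr=log2))
    else:
        raise ValueError(f"unknown segment dialect {dialect!r}")
    validate_segments(segments)
    return segments


def write_segments(path, segments: Sequence[Segment], dialect: str = "cns") -> None:
    if dialect == "cns":
        with open(path, "w") as fh:
            fh.write("\t".join(_CNS_COLUMNS) + "\n")
            for s in segments:
                fh.write(
                    f"{s.chrom}\t{s.interval.start}\t{s.interval.end}\t-\t{s.log2cnr:.17g}\n"
                )
    elif dialect == "bed_log2":
        with open(path, "w") as fh:
            for s in segments:
                fh.write(f"{s.chrom}\t{s.interval.start}\t{s.interval.end}\t{s.log2cnr:.17g}\n")
    else:
        raise ValueError(f"unknown segment dialect {dialect!r}")


def read_count_matrix(
    path,
    condition_map: Dict[str, str],
    peaks: Optional[Sequence[Peak]] = None,
) -> CountMatrix:
    """Read a TSV count matrix (first column peak names, header = samples).

    ``peaks`` supplies intervals matched by name; without it, placeholder
    1 bp intervals on chromosome ``"."`` are synthesized so that purely
    count-level operations (size factors, testing) still work.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dupes = sorted(table.index[table.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate peak names {dupes[:5]}")
    missing = [s for s in table.columns if s not in condition_map]
    if missing:
        raise ValidationError(f"{path}: samples without condition label: {missing}")
    counts = table.to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValidationError(f"{path}: negative counts present")
    if peaks is not None:
        by_name = {p.name: p for p in peaks}
        absent = [n for n in table.index if n not in by_name]
        if absent:
            raise ValidationError(f"{path}: peaks not in peak set: {absent[:5]}")
        peak_list = [by_name[n] for n in table.index]
    else:
        peak_list = [
            Peak(GenomicInterval(".", i, i + 1), name=str(n))
            for i, n in enumerate(table.index)
        ]
    return CountMatrix(
        peaks=peak_list,
        samples=[str(c) for c in table.columns],
        condition={s: condition_map[s] for s in table.columns},
        counts=counts,
    )


def write_count_matrix(path, matrix: CountMatrix, float_format: str = "%.10g") -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=float_format)


def read_conditions(path) -> Dict[str, str]:
    """Two-column TSV ``sample<TAB>condition`` with condition in {test, control}."""
    mapping: Dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'sample<TAB>condition'")
        sample, cond = fields[0], fields[1].strip().lower()
        if cond in ("sample", "condition"):  # tolerated header
            continue
        if cond not in (TEST, CONTROL):
            raise ParseError(
                f"{path}:{lineno}: condition must be '{TEST}' or '{CONTROL}', got {cond!r}"
            )
        mapping[sample] = cond
    if not mapping:
        raise ParseError(f"{path}: no sample/condition rows")
    return mapping


def write_conditions(path, condition: Dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\n")
        for sample, cond in condition.items():
            fh.write(f"{sample}\t{cond}\n")


def read_bed(path, strip_chr: bool = False) -> List[GenomicInterval]:
    """Plain BED3 intervals (exclusion lists: assembly gaps, blacklists)."""
    out: List[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            out.append(
                GenomicInterval(_maybe_strip(fields[0], strip_chr), int(fields[1]), int(fields[2]))
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_chrom_sizes(path, strip_chr: bool = False) -> Dict[str, int]:
    """Two-column ``chrom<TAB>length`` table."""
    sizes: Dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        try:
            sizes[_maybe_strip(fields[0], strip_chr)] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer length") from exc
    if not sizes:
        raise ParseError(f"{path}: empty chrom sizes")
    return sizes


def read_bedgraph(path, strip_chr: bool = False) -> List[Tuple[GenomicInterval, float]]:
    """bedGraph records ``chrom start end value``."""
    out: List[Tuple[GenomicInterval, float]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
        try:
            iv = GenomicInterval(_maybe_strip(fields[0], strip_chr), int(fields[1]), int(fields[2]))
            out.append((iv, float(fields[3])))
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_bin_coverage(path, strip_chr: bool = False):
    """TSV bin coverage with columns chrom, start, end, cov_test, cov_control.

    Returns a :class:`cndiff.cnr.BinTrack` (unmasked).
    """
    from .cnr import BinTrack  # local import to avoid a cycle

    table = pd.read_csv(path, sep="\t")
    needed = {"chrom", "start", "end", "cov_test", "cov_control"}
    if not needed.issubset(table.columns):
        raise ParseError(f"{path}: coverage TSV requires columns {sorted(needed)}")
    bins = [
        GenomicInterval(_maybe_strip(str(r.chrom), strip_chr), int(r.start), int(r.end))
        for r in table.itertuples()
    ]
    return BinTrack(
        bins=bins,
        cov_test=table["cov_test"].to_numpy(dtype=float),
        cov_control=table["cov_control"].to_numpy(dtype=float),
        mask=np.zeros(len(bins), dtype=bool),
    )


def write_bin_coverage(path, track) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcov_test\tcov_control\n")
        for iv, t, c in zip(track.bins, track.cov_test, track.cov_control):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t:.10g}\t{c:.10g}\n")
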