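"""Synthetic two-condition experiments with known copy-number structure.

The generator emulates the data-generating assumptions behind count-based
chromatin assays contrasted across samples that differ in copy number:

* the genome is partitioned into segments of constant test copy number
  (control fixed at two copies);
* the expected fragment count of peak i in sample j is

  ``mean_ij = L_j * [frip * lam_i * delta_ij + (1 - frip) * beta * w_i]
  * g_ij * c_s / 2``

  with L_j a log-normal library scale, lam_i a log-normal per-peak signal
  rate, delta the CN-independent differential effect (test condition,
  flagged peaks only), beta the background rate per bp, w_i the peak width,
  g_ij a per-copy modulation used by the trisomy compensation classes, and
  c_s the copy number of the enclosing segment.  Background fragments
  inside peaks scale with copy number — the mechanism by which low
  signal-to-noise (low FRiP) amplifies copy-number bias;
* counts are negative-binomial with a common dispersion; bin coverage for
  CNR estimation is Poisson around ``bin_depth * c / 2``.

Everything is deterministic given ``seed``; independent sub-streams per
component keep draws stable when unrelated parts of the config change.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cnr import BinTrack, bin_genome
from .core import CONTROL, TEST, CountMatrix, GenomicInterval, Peak, Segment, ValidationError

TRISOMY_CLASSES = ("dosage", "compensatory", "overcompensatory", "extra_increase")
_CLASS_CATEGORY = {
    "dosage": "IV",
    "compensatory": "III",
    "overcompensatory": "II",
    "extra_increase": "V",
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe a desk-scale analogue of a chromosomally unstable
    cell-line comparison: a mostly CN-neutral genome with occasional losses
    and gains, deeply covered consensus peaks (150 expected fragments per
    peak at two copies), low cell-line replicate dispersion (0.02) and a
    FRiP of 0.4.
    """

    n_chrom: int = 2
    chrom_length: int = 10_000_000
    bin_size: int = 50_000
    segments_per_chrom: int = 8
    copy_states: Tuple[int, ...] = (1, 2, 3, 4)
    copy_weights: Tuple[float, ...] = (0.2, 0.6, 0.1, 0.1)
    n_peaks: int = 2000
    peak_width: int = 500
    n_reps: int = 3
    depth: float = 150.0
    dispersion: float = 0.02
    frip: float = 0.4
    frac_true_diff: float = 0.0
    effect_log2fc: float = 1.0
    rate_sigma: float = 0.75
    library_sigma: float = 0.1
    bin_depth: float = 200.0
    seed: int = 0
    signal_tracks_cn: bool = True
    trisomy_chrom: Optional[str] = None
    trisomy_fractions: Tuple[float, float, float, float] = (0.8, 0.1, 0.05, 0.05)

    def __post_init__(self) -> None:
        if not (0 < self.frip <= 1):
            raise ValidationError(f"frip must be in (0, 1], got {self.frip}")
        if not set(self.copy_states) <= {0, 1, 2, 3, 4}:
            raise ValidationError(f"copy_states must be within 0..4, got {self.copy_states}")
        if not (0 <= self.frac_true_diff <= 1):
            raise ValidationError("frac_true_diff must be in [0, 1]")
        if len(self.copy_weights) != len(self.copy_states):
            raise ValidationError("copy_weights must match copy_states")
        if self.n_peaks < 1 or self.n_reps < 1:
            raise ValidationError("need at least one peak and one replicate per condition")
        if abs(sum(self.trisomy_fractions) - 1.0) > 1e-9:
            raise ValidationError("trisomy_fractions must sum to 1")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated experiment."""

    true_segments: List[Segment]
    peak_segment_index: np.ndarray  # index into true_segments per peak
    copy_state: np.ndarray  # test copies of the peak's segment
    lam: np.ndarray  # per-peak signal rate at two copies
    is_true_diff: np.ndarray  # CN-independent effect planted?
    true_percopy_log2fc: np.ndarray  # log2 of delta * g per peak
    library_scales: np.ndarray  # per sample, matrix column order
    trisomy_class: np.ndarray  # per peak: none | dosage | ... (object dtype)
    expected_category: np.ndarray  # per peak: I..V or "" (object dtype)


@dataclass
class SimulationResult:
    peaks: List[Peak]
    matrix: CountMatrix
    bin_track: BinTrack
    truth: SimulationTruth
    config: Optional[SimulationConfig] = None


def _substream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, offset])


def _draw_segments(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-chromosome segment layout and test copy states.

    The euploid state (two test copies) is guaranteed to be the
    length-majority of the drawn genome (trisomy chromosome excluded):
    median centering of log2 ratios and median-of-ratios size factors both
    assume the modal state is neutral, and the generator emulates genomes
    in that regime (draws are repeated otherwise).
    """
    n_bins = cfg.chrom_length // cfg.bin_size
    k = cfg.segments_per_chrom
    if n_bins < k:
        raise ValidationError(
            f"{k} segments per chromosome need at least {k} bins, got {n_bins}"
        )
    min_seg_bins = max(5, n_bins // (k * 3))
    gap = max(1, min(min_seg_bins, n_bins // k))
    weights = np.asarray(cfg.copy_weights, float)
    weights = weights / weights.sum()

    chrom_bounds: Dict[str, np.ndarray] = {}
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        # uniform segment layout with every segment >= gap bins: draw cuts in
        # the reduced problem (parts >= 1) and expand by gap - 1 per part
        if k > 1:
            m = n_bins - k * (gap - 1)
            ys = np.sort(rng.choice(np.arange(1, m), size=k - 1, replace=False))
            cuts = ys + np.arange(1, k) * (gap - 1)
            bounds = np.concatenate([[0], cuts, [n_bins]])
        else:
            bounds = np.array([0, n_bins])
        chrom_bounds[chrom] = bounds

    free_chroms = [c for c in chrom_bounds if c != cfg.trisomy_chrom]
    can_be_neutral = 2 in cfg.copy_states
    for _ in range(1000):
        states: Dict[str, np.ndarray] = {}
        neutral_len = 0
        total_len = 0
        for chrom in free_chroms:
            k = len(chrom_bounds[chrom]) - 1
            st = rng.choice(np.asarray(cfg.copy_states), size=k, p=weights)
            states[chrom] = st
            seg_len = np.diff(chrom_bounds[chrom])
            neutral_len += int(seg_len[st == 2].sum())
            total_len += int(seg_len.sum())
        if not can_be_neutral or total_len == 0 or neutral_len * 2 >= total_len:
            break
    if cfg.trisomy_chrom is not None:
        states[cfg.trisomy_chrom] = np.full(
            len(chrom_bounds[cfg.trisomy_chrom]) - 1, 3, dtype=int
        )

    segments: List[Segment] = []
    layout: Dict[str, List[Tuple[int, int, int]]] = {}
    for chrom, bounds in chrom_bounds.items():
        k = len(bounds) - 1
        layout[chrom] = []
        for s in range(k):
            start = int(bounds[s] * cfg.bin_size)
            end = int(bounds[s + 1] * cfg.bin_size) if s < k - 1 else cfg.chrom_length
            state = int(states[chrom][s])
            log2cnr = float(np.log2(max(state, 0.5) / 2.0))
            segments.append(Segment(GenomicInterval(chrom, start, end), log2cnr=log2cnr))
            layout[chrom].append((start, end, state))
    return segments, layout


def _place_peaks(cfg: SimulationConfig, rng: np.random.Generator) -> List[Peak]:
    width = cfg.peak_width
    pad = max(1, cfg.chrom_length - width)
    per_chrom = rng.multinomial(cfg.n_peaks, [1.0 / cfg.n_chrom] * cfg.n_chrom)
    peaks: List[Peak] = []
    i = 0
    ndigits = len(str(cfg.n_peaks))
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        starts = np.sort(rng.integers(0, pad, size=per_chrom[c]))
        for s in starts:
            i += 1
            peaks.append(
                Peak(GenomicInterval(chrom, int(s), int(s) + width), name=f"peak_{i:0{ndigits}d}")
            )
    return peaks


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if alpha < 1e-8:
        return rng.poisson(mean).astype(float)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate_experiment(config: SimulationConfig) -> SimulationResult:
    """Generate peaks, counts, bin coverage and the underlying truth."""
    cfg = config
    rng_seg = _substream(cfg.seed, 1)
    rng_place = _substream(cfg.seed, 2)
    rng_rate = _substream(cfg.seed, 3)
    rng_flag = _substream(cfg.seed, 4)
    rng_lib = _substream(cfg.seed, 5)
    rng_count = _substream(cfg.seed, 6)
    rng_cov = _substream(cfg.seed, 7)

    segments, layout = _draw_segments(cfg, rng_seg)
    peaks = _place_peaks(cfg, rng_place)

    # map peaks to their (unique) generating segment by midpoint
    seg_index = np.empty(cfg.n_peaks, dtype=int)
    copy_state = np.empty(cfg.n_peaks, dtype=int)
    spans: Dict[str, List[Tuple[int, int, int, int]]] = {}  # start, end, state, index
    offset = 0
    for chrom, chrom_spans in layout.items():
        spans[chrom] = [
            (s, e, st, offset + k) for k, (s, e, st) in enumerate(chrom_spans)
        ]
        offset += len(chrom_spans)
    for i, p in enumerate(peaks):
        mid = p.interval.midpoint
        s, e, st, idx = spans[p.chrom][-1]
        for s, e, st, idx in spans[p.chrom]:
            if s <= mid < e:
                break
        seg_index[i] = idx
        copy_state[i] = st

    lam = cfg.depth * np.exp(
        rng_rate.normal(0.0, cfg.rate_sigma, cfg.n_peaks) - 0.5 * cfg.rate_sigma**2
    )
    is_diff = rng_flag.random(cfg.n_peaks) < cfg.frac_true_diff
    sign = np.where(rng_flag.random(cfg.n_peaks) < 0.5, 1.0, -1.0)
    delta_log2 = np.where(is_diff, sign * cfg.effect_log2fc, 0.0)

    # trisomy compensation classes on the designated chromosome
    tri_class = np.full(cfg.n_peaks, "none", dtype=object)
    expected_cat = np.full(cfg.n_peaks, "", dtype=object)
    g_log2 = np.zeros(cfg.n_peaks)
    if cfg.trisomy_chrom is not None:
        on_tri = np.array([p.chrom == cfg.trisomy_chrom for p in peaks])
        draws = rng_flag.choice(
            len(TRISOMY_CLASSES), size=int(on_tri.sum()), p=np.asarray(cfg.trisomy_fractions)
        )
        tri_class[on_tri] = [TRISOMY_CLASSES[d] for d in draws]
        comp = np.log2(2.0 / 3.0)
        class_g = {
            "dosage": 0.0,
            "compensatory": comp,
            "overcompensatory": comp - cfg.effect_log2fc,
            "extra_increase": cfg.effect_log2fc,
        }
        g_log2[on_tri] = [class_g[t] for t in tri_class[on_tri]]
        expected_cat[on_tri] = [_CLASS_CATEGORY[t] for t in tri_class[on_tri]]
        # planted CN-independent effects are reserved for euploid chromosomes
        delta_log2[on_tri] = 0.0
        is_diff[on_tri] = False

    samples = [f"{TEST}_{r + 1}" for r in range(cfg.n_reps)] + [
        f"{CONTROL}_{r + 1}" for r in range(cfg.n_reps)
    ]
    condition = {s: (TEST if s.startswith(TEST) else CONTROL) for s in samples}
    lib = np.exp(
        rng_lib.normal(0.0, cfg.library_sigma, len(samples)) - 0.5 * cfg.library_sigma**2
    )

    beta_bg = cfg.depth / cfg.peak_width  # background fragments per bp at 2 copies
    widths = np.array([p.interval.length for p in peaks], dtype=float)
    is_test = np.array([condition[s] == TEST for s in samples])
    cn = np.where(is_test[None, :], copy_state[:, None] / 2.0, 1.0)
    signal = cfg.frip * lam[:, None] * np.ones((1, len(samples)))
    signal[:, is_test] *= 2.0 ** delta_log2[:, None]
    if cfg.signal_tracks_cn:
        signal = signal * cn
    # background inside peaks always tracks DNA content; with
    # signal_tracks_cn=False the signal is CN-independent and background
    # alone drags the apparent fold change towards the CNR (low-SNR bias)
    background = (1.0 - cfg.frip) * beta_bg * widths[:, None] * cn
    percopy = np.ones((cfg.n_peaks, len(samples)))
    percopy[:, is_test] = 2.0 ** g_log2[:, None]
    means = lib[None, :] * (signal + background) * percopy
    counts = _nb_draw(rng_count, means, cfg.dispersion)

    matrix = CountMatrix(peaks=peaks, samples=samples, condition=condition, counts=counts)

    # bin coverage for CNR estimation
    chrom_sizes = {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chrom)}
    bins, mask = bin_genome(chrom_sizes, cfg.bin_size)
    bin_copy = np.empty(len(bins), dtype=float)
    for b, iv in enumerate(bins):
        mid = iv.midpoint
        state = spans[iv.chrom][-1][2]
        for s, e, st, _ in spans[iv.chrom]:
            if s <= mid < e:
                state = st
                break
        bin_copy[b] = state
    cov_test = rng_cov.poisson(cfg.bin_depth * np.maximum(bin_copy, 0.05) / 2.0).astype(float)
    cov_control = rng_cov.poisson(np.full(len(bins), cfg.bin_depth)).astype(float)
    track = BinTrack(bins=bins, cov_test=cov_test, cov_control=cov_control, mask=mask)

    truth = SimulationTruth(
        true_segments=segments,
        peak_segment_index=seg_index,
        copy_state=copy_state,
        lam=lam,
        is_true_diff=is_diff,
        true_percopy_log2fc=delta_log2 + g_log2,
        library_scales=lib,
        trisomy_class=tri_class,
        expected_category=expected_cat,
    )
    return SimulationResult(
        peaks=peaks, matrix=matrix, bin_track=track, truth=truth, config=cfg
    )


def make_trisomy_config(
    base: SimulationConfig,
    chrom: str = "chr1",
    fractions: Tuple[float, float, float, float] = (0.8, 0.1, 0.05, 0.05),
) -> SimulationConfig:
    """Derive a trisomy-21-style config: one chromosome at three test copies,
    every other chromosome euploid (two copies in both samples).

    Peaks on the trisomic chromosome are split into pure-dosage,
    compensatory (per-copy rate x 2/3, so the expected total equals the
    control's), over-compensatory and CN-independent-increase classes, with
    the class recorded in the truth.  Give the config several chromosomes so
    the trisomic one carries a minority of peaks, as chromosome 21 does in a
    real peak set — with half the genome at three copies, median-of-ratios
    size factors lose their euploid anchor.
    """
    return replace(
        base,
        trisomy_chrom=chrom,
        trisomy_fractions=fractions,
        copy_states=(2,),
        copy_weights=(1.0,),
    )


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write peaks, counts, conditions, coverage, truth and true segments."""
    from pathlib import Path

    import pandas as pd

    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_narrowpeak(outdir / "peaks.narrowPeak", result.peaks)
    cio.write_count_matrix(outdir / "counts.tsv", result.matrix)
    cio.write_conditions(outdir / "conditions.tsv", result.matrix.condition)
    cio.write_bin_coverage(outdir / "coverage.tsv", result.bin_track)
    cio.write_segments(outdir / "true_segments.cns", result.truth.true_segments, dialect="cns")
    truth = result.truth
    pd.DataFrame(
        {
            "peak": [p.name for p in result.peaks],
            "segment_index": truth.peak_segment_index,
            "copy_state": truth.copy_state,
            "lam": truth.lam,
            "is_true_diff": truth.is_true_diff.astype(int),
            "true_percopy_log2fc": truth.true_percopy_log2fc,
            "trisomy_class": truth.trisomy_class,
            "expected_category": truth.expected_category,
        }
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
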