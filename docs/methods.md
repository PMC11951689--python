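# Methods

## The problem and the model

Two samples (condition labels *test* and *control*) are contrasted on a
shared set of peaks. Fragment counts in a peak are proportional to the
local DNA copy number times the per-copy chromatin signal, plus background
fragments that are proportional to the local DNA content alone. With
regional copy-number ratio `CNR = c_test / c_control`, the expected
uncorrected fold change of a region whose per-copy biology is unchanged is
exactly the CNR — so differential calls in gained/lost regions confound
copy number with regulation.

The pipeline separates the two by estimating the CNR per region and
rescaling counts to a common copy number **before** data normalization
(size factors are always computed on the corrected matrix). Rescaling
always shrinks the higher-copy side: for peak ratio `r ≥ 1` the
test-condition counts are divided by `r`; for `r < 1` the control counts
are multiplied by `r`. Shrinking rather than inflating avoids manufacturing
statistical power from fragments that were never sequenced. Only the ratio
between the samples is modelled; absolute copy number, purity and ploidy
are out of scope.

## CNR estimation

* **Binning.** Non-overlapping bins, default 50 kb, tiled per chromosome
  (`bin_genome`); bins whose overlap with exclusion intervals (assembly
  gaps, blacklists) exceeds half the bin width are masked.
* **Per-bin ratio.** `log2((cov_test/N_test)/(cov_control/N_control))` with
  `N` the total valid coverage of each sample, median-centered over valid
  bins. Bins with zero coverage in either sample are invalid. Median
  centering assumes the modal genomic state has ratio 1; it fails under
  genome doubling, in which case externally produced segment files should
  be supplied (the `.cns` dialect and BED+log2 are read directly).
* **Segmentation.** Recursive binary segmentation per chromosome. A split
  maximizes `|mean_L − mean_R| / (s·sqrt(1/n_L + 1/n_R))` and is accepted
  iff the statistic exceeds `penalty` (default 5.0), both sides keep at
  least `min_seg_bins` bins (default 5) and the mean shift is at least
  `min_delta` (default 0.1 log2 units). The noise scale `s` is estimated
  robustly from first differences, `s = 1.4826·MAD(diff)/√2`, which is
  insensitive to the changepoints themselves. Segment boundaries snap to
  bin boundaries; invalid-bin gaps inherit the preceding segment, so
  segments tile each chromosome's binned extent. The segment value is the
  mean of its member bins, converted as `CNR = 2^log2cnr` and clipped to
  `[1/16, 16]` before use as a scaling factor (guarding against near-zero
  ratios annihilating control counts over homozygous deletions).
* No GC or mappability correction is applied: both samples share those
  biases and they largely cancel in the ratio.

Changepoints whose t-statistic sits near the threshold (short segments with
sub-0.5 log2 steps at moderate bin coverage) are occasionally merged into a
neighbour; the affected peaks are then corrected with the neighbour's CNR.
This is the dominant error mode of the estimator and the reason end-to-end
results with estimated segments are slightly noisier than with the
generating ones.

## Peak assignment and scaling

Each peak takes the segment with maximal overlap; ties go to the nearer
segment midpoint, then leftmost. Peaks without overlap take the nearest
segment on their chromosome (no distance bound is imposed, but the gap is
reported); chromosomes without segments fall back to `r = 1` with a
warning. Peaks spanning a boundary take the maximal-overlap segment rather
than an overlap-weighted average — deterministic and faithful to
"overlapping or closest segment" semantics. One CNR track applies per pair
of conditions: all replicates of a condition receive the same scaling.

Scaled counts are fractional. By default they are rounded half-to-even so
the matrix remains valid for integer-count engines, with the unrounded
matrix retained as metadata (`rounding="none"` skips rounding; the NB
likelihood below is evaluated through its Γ-function continuous extension,
so either path is testable).

## The negative-binomial engine

A deliberately compact DESeq2-style procedure; no equivalence with any
named tool is claimed, and calibration is established by simulation only.

* **Size factors.** Median-of-ratios over peaks positive in every sample.
* **Dispersions.** Per-peak method-of-moments on normalized counts pooled
  within condition, `α̂ = max(floor, (s² − μ̄)/μ̄²)`, floor `1e-8`; a trend
  `α(μ) = a₁/μ + a₀` fitted by Huber robust regression over informative
  peaks; final `α = exp(½·log α̂ + ½·log α_trend)`. Peaks whose sample
  variance is at or below the Poisson level are censored from below — the
  moments estimator carries no information there — and take the trend value
  instead of dragging the geometric mean toward zero. (Without this, a few
  percent of peaks at small replicate numbers receive near-Poisson
  dispersions and anticonservative tests; with it, the null rejection
  fraction at n = 3/group stays below 1%.)
* **Wald test.** Group means fitted by Newton–Raphson maximum likelihood
  with fixed dispersion on size-factor-offset counts; `log2FC =
  log2(q_test/q_control)`, standard error from the expected Fisher
  information `Σ μ/(1+αμ)` per group, two-sided normal p, BH adjustment
  over tested peaks. All-zero peaks get `p = padj = 1`; peaks with one
  all-zero group are flagged untested and excluded from the BH family.
  Status: `up`/`down` iff `padj < 0.05` with the matching sign, else `nd`.
* Omitted on purpose: independent filtering, LFC shrinkage, outlier
  refitting, multi-factor designs.

## Diagnostics

The bias trend is a LOESS (tricube weights, locally linear, span 0.3) of
log2FC on assigned log2CNR over ≥ 30 peaks, evaluated on an even grid, with
a 95% band from the local residual spread and a global OLS slope. LOESS was
standardized on (a GAM gives the same qualitative trend). The enrichment
test is a Pearson χ² on the 2×3 (set × status) homogeneity table, df = 2,
computed directly from the formula so tables with structural zeros are
handled; when the subset is contained in the reference the comparison rows
are subset versus reference-minus-subset. Plots are emitted as data tables;
figures are never part of the test surface.

## Dosage / compensation categories

The run without normalization tests *total* signal; the run with
normalization tests *per-copy* signal. The five named categories cover the
pairs (nd,nd)→I, (down,down)→II, (nd,down)→III, (up,nd)→IV, (up,up)→V. The
four remaining combinations are biologically unanticipated and reported as
`other` with a warning rather than coerced — the algebra allows nine cells,
the biology names five, and silent coercion would fabricate a category.
Trisomy of a whole chromosome needs no special-casing: it is a one-segment
track with `CNR = 3/2`.

## The simulator

`simulate_experiment` draws, per chromosome, a segment layout on bin
boundaries (every segment at least `max(5, n_bins/(3k))` bins; the layout is
sampled uniformly over feasible cut placements) with test copy states from
`copy_states` (control fixed at two copies); peak positions uniform; per-peak
signal rates log-normal with mean `depth` (σ = 0.75, a few-fold spread of
peak strengths); library scales log-normal (σ = 0.1). Counts are NB with
mean

    L_j · [frip·λ_i·δ_ij + (1 − frip)·β·w_i] · g_ij · c_s/2

where `δ` is a CN-independent effect on flagged peaks (test condition,
random sign), `β·w_i` the in-peak background (β chosen so an average peak's
background mean equals `depth` at FRiP → 0), `g` the per-copy modulation of
the trisomy compensation classes, and `c_s` the segment's copy number. Bin
coverage for CNR estimation is Poisson around `bin_depth·c/2` (default
200 / bin, deep-library 50 kb bins).

Default study conditions: 2 chromosomes × 10 Mb, 2,000 peaks of 500 bp,
n = 3 replicates per condition, `depth = 150` expected fragments per peak
at two copies (deeply sequenced consensus peaks), dispersion 0.02
(cell-line replicates), FRiP 0.4, copy states (1,2,3,4) with weights
(0.2,0.6,0.1,0.1). The weights balance the length-weighted mean log2CNR
near zero and the generator additionally guarantees the euploid state is
the length-majority of every drawn genome: that is the regime in which
median centering and median-of-ratios size factors are anchored, and it
mirrors a chromosomally unstable but predominantly diploid cell line whose
genome-wide MA plot is unskewed. A genome dominated by gains would instead
shift the size-factor anchor and every fold change with it — a real
phenomenon, but a different study.

Two deliberate modelling choices:

* **Background inside peaks scales with copy number.** With
  `signal_tracks_cn=True` (default) the signal does too, so a pure-CN
  simulation has fold change exactly CNR at any FRiP — under this model the
  FRiP level barely affects false-positive counts (only through the spread
  of peak means). The signal-to-noise amplification of copy-number bias
  arises when per-copy *signal* does not follow DNA content while
  background does; `signal_tracks_cn=False` models exactly that regime
  (apparent FC = 1.40 at FRiP 0.2 versus 1.17 at FRiP 0.6 for a CNR 1.5
  segment with equal signal and background rates), and is the configuration
  under which the SNR property is asserted.
* **Trisomy compensation classes scale the peak's whole per-copy rate**
  (signal and in-peak background), so a compensated peak's expected total
  equals the control's exactly (3 copies × 2/3 rate) at any FRiP — the
  algebraic definition of compensation used by the classifier.

`make_trisomy_config` fixes one chromosome at three test copies, all other
chromosomes euploid, and partitions its peaks into 80% pure dosage, 10%
compensatory, 5% over-compensatory, 5% extra-increase.

## Problem sizes used by tests

Bias-removal and SNR runs use the default conditions above (seeds 1–3).
Changepoint recovery uses 50 step signals of 100 bins (step 1.0, σ = 0.25);
CNR recovery reports the median per-bin RMSE over three seeded genomes —
a single marginal changepoint (a short segment with a 0.4 log2 step at
per-bin noise 0.14) can push one seed's RMSE above the typical ~0.05.
Calibration uses direct NB draws: a 2,000-peak global null at n = 3, a
200-peak 4-fold power run at n = 5 with fixed dispersion 0.01, and
dispersion-recovery runs at n = 10 (Poisson) and n = 50 (α = 0.2). The
dosage-classification run uses 6 chromosomes, n = 6, depth 400: at
n = 3 the dispersion term alone caps the per-copy |log2FC| = 0.585 Wald
z-score near 2, so category fractions could not be recovered at the
bias-run size for any depth — the classification conditions are chosen to
be power-adequate while remaining desk scale (seconds).

## Known limitations

* The NB engine is intentionally minimal; its padj values agree with
  standard engines qualitatively, not numerically.
* Median centering and the majority-euploid assumption fail for genome
  doubling; supply external segments there.
* The segmenter's global per-chromosome noise scale slightly underweights
  heteroscedasticity between copy states; steps below ~3 bin-noise
  standard deviations on short segments are merged by design (penalty 5).
* Simulations generate fragment counts, not reads: no GC bias, fragment
  lengths, Tn5 insertion preference, or mappability structure. Passing
  tests show the *statistical* pipeline behaves as designed under its
  generative assumptions, not that real-data artifacts are handled.
* One CNR track serves all replicates of a condition; per-replicate
  karyotype heterogeneity (subclonal CNVs) is not modelled.
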