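# cndiff — copy-number-aware differential analysis for chromatin assays

Count-based chromatin assays (ATAC-seq, ChIP-seq) quantify signal as the
number of fragments falling in peaks. When the two contrasted samples differ
in DNA copy number — aneuploid or chromosomally unstable cell lines, tumors,
trisomies — fragment counts track DNA dosage: a region at three copies in
the test sample yields ~1.5× the fragments of the two-copy control even when
nothing about its chromatin changed. Standard differential pipelines
(median-of-ratios normalization + negative-binomial testing) cannot remove
this, because it is a *regional* property of the data, not a library-size
effect. The result is a trend of log2 fold change versus local copy-number
ratio with slope ≈ 1 and a flood of spurious differential calls in gained
and lost regions.

`cndiff` implements a copy-number-aware pipeline for two-sample contrasts:

1. **CNR estimation** (`cndiff.cnr`): coverage in non-overlapping 50 kb bins
   for both samples → depth-normalized, median-centered per-bin
   log2 ratios → recursive binary segmentation into runs of constant
   copy-number ratio `CNR = 2^log2ratio` (test / control). Externally
   produced segment tables (the `.cns` tab dialect or BED+log2) can be used
   instead.
2. **CN normalization** (`cndiff.normalize`): each peak is assigned to its
   overlapping (maximal-overlap) or nearest segment; with ratio `r`, counts
   of the *higher-copy* side are shrunk — `r ≥ 1` divides the test counts by
   `r`, `r < 1` multiplies the control counts by `r` — so both conditions
   are compared at a common copy number without inflating statistical power.
   For a trisomic chromosome against a diploid control this is simply
   dividing the test counts by `CNR = 3/2`.
3. **Differential testing** (`cndiff.diff`): a self-contained two-group
   negative-binomial engine (median-of-ratios size factors, trended
   moment dispersions, Wald test on `log2FC` with Benjamini–Hochberg
   adjustment; significant = adjusted *P* < 0.05).
4. **Bias diagnostics** (`cndiff.diagnostics`): LOESS trend of log2FC vs
   log2CNR with its OLS slope, MA tables, per-CNR-bin status proportions,
   and a χ² test of a region's up/down/nd composition against a reference.
5. **Dosage classification** (`cndiff.classify`): combining the run without
   normalization (total signal) and with normalization (per-copy signal)
   assigns each region one of five categories — I no change, II
   over-compensatory, III compensatory (total constant, per-copy down),
   IV pure dosage (total up, per-copy unchanged), V dosage plus
   CN-independent increase.
6. **Simulation** (`cndiff.simulate`): synthetic experiments with known
   segment structure, per-copy rates, NB noise and a tunable fraction of
   fragments in peaks (FRiP), so every stage can be validated against
   ground truth.

The core stages are scikit-learn-style estimators (`CNRSegmenter`,
`CopyNumberNormalizer`, `NegativeBinomialDE`) with plain-function wrappers,
plus a `cndiff` command-line interface.

## Worked example

```python
from cndiff import (
    SimulationConfig, simulate_experiment, CNRSegmenter,
    CopyNumberNormalizer, NegativeBinomialDE, bias_trend, status_proportions,
)

res = simulate_experiment(SimulationConfig(seed=1))        # pure-CN truth
segments = CNRSegmenter().fit_predict(res.bin_track)       # estimate CNR
print(f"estimated {len(segments)} CNR segments "
      f"(log2 range {min(s.log2cnr for s in segments):+.2f} to "
      f"{max(s.log2cnr for s in segments):+.2f})")
norm = CopyNumberNormalizer().fit(res.peaks, segments)
raw = NegativeBinomialDE().fit(res.matrix).results_
cn = NegativeBinomialDE().fit(norm.transform(res.matrix)).results_
for label, r in (("without CN normalization", raw), ("with CN normalization", cn)):
    p = status_proportions(r).proportions
    slope = bias_trend(r, norm.assignments_).slope
    print(f"{label}: up {p['up']:.2f}%  down {p['down']:.2f}%  "
          f"nd {p['nd']:.2f}%  bias slope {slope:+.3f}")
```

prints

```
estimated 9 CNR segments (log2 range -1.02 to +0.91)
without CN normalization: up 9.25%  down 17.65%  nd 73.10%  bias slope +0.995
with CN normalization: up 0.75%  down 2.40%  nd 96.85%  bias slope -0.005
```

The simulation contains *no* CN-independent biology: every differential call
is driven by copy number. Uncorrected, 26.9% of peaks are called
differential and the fold changes track log2CNR with slope ≈ 1; after CN
normalization with the estimated segments the trend is flat and the call
rate collapses to the few percent left by imperfect segment recovery (with
the generating segments it falls below 1%).

The same analysis from the shell:

```sh
cndiff simulate --seed 1 -o sim/
cndiff pipeline --peaks sim/peaks.narrowPeak --counts sim/counts.tsv \
    --conditions sim/conditions.tsv --coverage sim/coverage.tsv --out run/
```

`run/` then holds `segments.cns`, `corrected.tsv`, `results_raw.tsv`,
`results_cn.tsv`, bias-trend tables for both runs, `categories.tsv` with the
five dosage/compensation classes, and a `manifest.json` recording version,
parameters and input digests.

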