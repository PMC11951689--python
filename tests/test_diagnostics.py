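"""Bias-trend fitting, status tables and the chi-square enrichment test."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cndiff.core import GenomicInterval, Peak, Segment, ValidationError
from cndiff.diagnostics import (
    bias_trend,
    cnr_binned_status,
    enrichment_chisq,
    ma_data,
    pearson_chi2,
    status_proportions,
)
from cndiff.normalize import assign_peaks


def make_results(log2fc, status=None, peaks=None):
    n = len(log2fc)
    return pd.DataFrame(
        {
            "peak": peaks if peaks is not None else [f"p{i:04d}" for i in range(n)],
            "base_mean": np.full(n, 100.0),
            "log2fc": log2fc,
            "se": np.full(n, 0.1),
            "stat": np.zeros(n),
            "p": np.full(n, 0.5),
            "padj": np.full(n, 0.5),
            "status": status if status is not None else ["nd"] * n,
        }
    )


def spread_assignments(log2cnr_values):
    """One single-peak segment per value, so x varies freely."""
    peaks = []
    segments = []
    pos = 0
    for i, v in enumerate(log2cnr_values):
        peaks.append(Peak(GenomicInterval("chr1", pos + 100, pos + 600), f"p{i:04d}"))
        segments.append(Segment(GenomicInterval("chr1", pos, pos + 1000), log2cnr=float(v)))
        pos += 1000
    return peaks, assign_peaks(peaks, segments, clip=(1e-4, 1e4))


class TestBiasTrend:
    def test_identity_construction(self):
        x = np.linspace(-1, 1, 200)
        _, assignments = spread_assignments(x)
        trend = bias_trend(make_results(x), assignments, span=0.3)
        assert trend.slope == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(trend.fitted, trend.grid, atol=1e-6)
        assert np.all(trend.ci_low <= trend.fitted + 1e-12)
        assert np.all(trend.fitted <= trend.ci_high + 1e-12)

    def test_flat_curve(self):
        x = np.linspace(-1, 1, 100)
        _, assignments = spread_assignments(x)
        trend = bias_trend(make_results(np.zeros(100)), assignments)
        assert trend.slope == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(trend.fitted, 0.0, atol=1e-9)

    def test_constant_shift_moves_intercept_not_slope(self):
        rng = np.random.default_rng(0)
        x = np.linspace(-1, 1, 150)
        y = 0.8 * x + rng.normal(0, 0.05, 150)
        _, assignments = spread_assignments(x)
        t0 = bias_trend(make_results(y), assignments)
        t1 = bias_trend(make_results(y + 2.5), assignments)
        assert t1.slope == pytest.approx(t0.slope, abs=1e-9)
        assert t1.intercept == pytest.approx(t0.intercept + 2.5, abs=1e-9)

    def test_too_few_peaks_rejected(self):
        x = np.linspace(-1, 1, 10)
        _, assignments = spread_assignments(x)
        with pytest.raises(ValidationError, match=">= 30"):
            bias_trend(make_results(x), assignments)


class TestStatusProportions:
    def test_printed_genome_wide_percentages(self):
        # 143,460 peaks: 42,831 up, 46,685 down
        status = ["up"] * 42831 + ["down"] * 46685 + ["nd"] * (143460 - 89516)
        table = status_proportions(make_results(np.zeros(len(status)), status=status))
        assert table.proportions["up"] == 29.86
        assert table.proportions["down"] == 32.54
        assert table.proportions["up"] + table.proportions["down"] == 62.40

    def test_zero_significant(self):
        table = status_proportions(make_results(np.zeros(10)))
        assert table.proportions == {"up": 0.0, "down": 0.0, "nd": 100.0}

    def test_small_set_arithmetic(self):
        status = ["up"] * 3 + ["down"] * 2 + ["nd"] * 5
        table = status_proportions(make_results(np.zeros(10), status=status))
        assert table.proportions == {"up": 30.0, "down": 20.0, "nd": 50.0}

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            status = rng.choice(["up", "down", "nd"], size=int(rng.integers(3, 997)))
            table = status_proportions(make_results(np.zeros(len(status)), status=list(status)))
            assert sum(table.proportions.values()) == pytest.approx(100.0, abs=0.02)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValidationError):
            status_proportions(make_results(np.zeros(5)), subset=["absent"])


class TestEnrichmentChisq:
    def test_homogeneous_subset_zero_statistic(self):
        table = enrichment_chisq((10, 20, 70), (100, 200, 700))
        assert table.chi2 == pytest.approx(0.0, abs=1e-9)
        assert table.df == 2

    def test_matches_scipy_on_nondegenerate_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            sub = tuple(int(v) for v in rng.integers(1, 50, 3))
            other = tuple(int(v) for v in rng.integers(1, 50, 3))
            ref = tuple(s + o for s, o in zip(sub, other))
            table = enrichment_chisq(sub, ref)
            expected = stats.chi2_contingency(
                np.vstack([sub, other]), correction=False
            )
            assert table.chi2 == pytest.approx(expected.statistic, rel=1e-10)
            assert table.p == pytest.approx(expected.pvalue, rel=1e-8)

    def test_brute_force_equivalence_small_tables(self):
        """Pearson formula vs literal sum over cells for systematic small tables."""

        def brute(table):
            table = np.asarray(table, float)
            total = table.sum()
            chi2 = 0.0
            for i in range(table.shape[0]):
                for j in range(table.shape[1]):
                    e = table[i].sum() * table[:, j].sum() / total
                    if e > 0:
                        chi2 += (table[i, j] - e) ** 2 / e
            return chi2

        values = (0, 1, 2, 5, 20)
        for cells in itertools.product(values, repeat=6):
            table = np.array(cells, float).reshape(2, 3)
            if table.sum() == 0:
                continue
            chi2, df = pearson_chi2(table)
            assert chi2 == pytest.approx(brute(table), abs=1e-9)
            assert df == 2

    def test_small_expected_counts_warn(self):
        table = enrichment_chisq((1, 1, 1), (2, 2, 400))
        assert table.warning is not None

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_chisq((1, 1, 1), (0, 5, 5))


class TestMaData:
    def test_row_count_and_significance(self):
        res = make_results(np.zeros(20), status=["up"] * 3 + ["nd"] * 17)
        ma = ma_data(res)
        assert len(ma) == 20
        assert ma["significant"].sum() == 3

    def test_all_nd_no_significant(self):
        ma = ma_data(make_results(np.zeros(5)))
        assert not ma["significant"].any()

    def test_tsv_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(3)
        res = make_results(rng.normal(0, 1, 30))
        ma = ma_data(res)
        path = tmp_path / "ma.tsv"
        ma.to_csv(path, sep="\t", index=False, float_format="%.12g")
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back["log2fc"], ma["log2fc"], atol=1e-9)
        np.testing.assert_allclose(back["base_mean"], ma["base_mean"], atol=1e-9)


class TestCnrBinnedStatus:
    def test_single_bin_matches_global(self):
        x = np.zeros(50)
        _, assignments = spread_assignments(x)
        status = ["up"] * 10 + ["down"] * 5 + ["nd"] * 35
        res = make_results(x, status=status)
        out = cnr_binned_status(res, assignments, [-1, 1])
        assert out.loc[0, "n"] == 50
        assert out.loc[0, "prop_up"] == pytest.approx(0.2)

    def test_empty_bin_reported(self):
        x = np.zeros(40)
        _, assignments = spread_assignments(x)
        out = cnr_binned_status(make_results(x), assignments, [-2, -1, 1])
        assert out.loc[0, "n"] == 0
        assert np.isnan(out.loc[0, "prop_up"])

    def test_unsorted_edges_rejected(self):
        x = np.zeros(40)
        _, assignments = spread_assignments(x)
        with pytest.raises(ValidationError):
            cnr_binned_status(make_results(x), assignments, [1, -1])
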