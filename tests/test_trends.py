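"""Bin means, the k-of-(B-1) trend call, ranking and trajectories."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exprtrend import ConfigurationError, DataError, make_bins
from exprtrend.cohort_io import ExpressionMatrix
from exprtrend.trends import (
    TrendParams,
    bin_means,
    call_all,
    call_trend,
    high_expression_proportion,
    partition_calls,
    top_table,
)

from conftest import clinical_from_years

P8 = TrendParams(k_min=6, epsilon=1e-9).resolve(8)


def _matrix(rng, n_genes, n_patients):
    values = rng.uniform(0.0, 10.0, size=(n_genes, n_patients))
    return ExpressionMatrix(pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"p{i:03d}" for i in range(n_patients)],
    ))


class TestBinMeans:
    def test_matches_naive_double_loop(self, rng):
        expr = _matrix(rng, 20, 40)
        years = rng.integers(1990, 1998, size=40)
        binning = make_bins(clinical_from_years(years), n_bins=4)
        means = bin_means(expr, binning)
        for b in range(4):
            patients = binning.bin_patients(b)
            for g in expr.gene_ids:
                total = sum(expr.values.loc[g, p] for p in patients)
                assert means.loc[g].iloc[b] == pytest.approx(
                    total / len(patients), rel=1e-12)

    def test_constant_gene_has_equal_means(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[5.0] * 6], index=["g0"], columns=[f"p{i:03d}" for i in range(6)]))
        binning = make_bins(clinical_from_years([1, 1, 2, 2, 3, 3]), n_bins=3)
        assert set(bin_means(expr, binning).loc["g0"]) == {5.0}

    def test_missing_patient_is_config_error(self, rng):
        expr = _matrix(rng, 3, 5)
        binning = make_bins(clinical_from_years([1, 1, 2, 2, 3, 3]), n_bins=3)
        with pytest.raises(ConfigurationError, match="absent"):
            bin_means(expr, binning)


class TestCallTrend:
    def test_strictly_monotone_up(self):
        call = call_trend([1, 2, 3, 4, 5, 6, 7, 8], P8, "g")
        assert call.direction == "up"
        assert call.n_increase == 7 and call.n_decrease == 0
        assert call.log2fc == pytest.approx(3.0, abs=1e-6)
        assert call.drop_magnitudes == ()

    def test_one_counter_step_still_up(self):
        call = call_trend([1, 2, 3, 2, 5, 6, 7, 8], P8, "g")
        assert (call.n_increase, call.n_decrease) == (6, 1)
        assert call.direction == "up"
        assert call.drop_magnitudes == pytest.approx(
            (math.log2(3 + 1e-9) - math.log2(2 + 1e-9),))

    def test_all_ties_is_none(self):
        call = call_trend([5.0] * 8, P8, "g")
        assert call.n_tie == 7 and call.direction == "none"
        assert call.log2fc == 0.0

    def test_nan_mean_is_data_error(self):
        with pytest.raises(DataError, match="NaN"):
            call_trend([1, 2, np.nan, 4, 5, 6, 7, 8], P8, "g")

    @pytest.mark.parametrize("n_bins", [4, 5])
    def test_exhaustive_small_b(self, n_bins):
        """All 3^(B-1) step patterns agree with direct symbol counting."""
        params = TrendParams(k_min=n_bins - 1, epsilon=1e-9).resolve(n_bins)
        for pattern in itertools.product((1, -1, 0), repeat=n_bins - 1):
            means = [100.0]
            for step in pattern:
                means.append(means[-1] + step)
            call = call_trend(means, params, "g")
            n_up = sum(s == 1 for s in pattern)
            n_down = sum(s == -1 for s in pattern)
            assert call.n_increase == n_up
            assert call.n_decrease == n_down
            expected = ("up" if n_up >= params.k_min
                        else "down" if n_down >= params.k_min else "none")
            assert call.direction == expected


@st.composite
def trajectories(draw):
    b = draw(st.integers(min_value=4, max_value=9))
    return draw(st.lists(
        st.floats(min_value=0.0, max_value=1e6,
                  allow_nan=False, allow_infinity=False),
        min_size=b, max_size=b))


@st.composite
def scale_safe_trajectories(draw):
    """Exact zeros or comfortably-normal floats: strict orderings survive
    multiplication by c in [0.01, 100] without underflow artefacts."""
    b = draw(st.integers(min_value=4, max_value=9))
    value = st.one_of(st.just(0.0),
                      st.floats(min_value=1e-3, max_value=1e6))
    return draw(st.lists(value, min_size=b, max_size=b))


class TestTrendProperties:
    @settings(max_examples=200, deadline=None)
    @given(trajectories())
    def test_reversal_swaps_direction_and_negates_log2fc(self, means):
        params = TrendParams(epsilon=1e-6).resolve(len(means))
        fwd = call_trend(means, params, "g")
        rev = call_trend(means[::-1], params, "g")
        assert rev.n_increase == fwd.n_decrease
        assert rev.n_tie == fwd.n_tie
        assert rev.log2fc == -fwd.log2fc
        swap = {"up": "down", "down": "up", "none": "none"}
        assert rev.direction == swap[fwd.direction]

    @settings(max_examples=200, deadline=None)
    @given(scale_safe_trajectories(), st.floats(min_value=0.01, max_value=100.0))
    def test_scaling_with_matched_epsilon(self, means, c):
        eps = 1e-6
        base = call_trend(means, TrendParams(epsilon=eps).resolve(len(means)), "g")
        scaled = call_trend([c * m for m in means],
                            TrendParams(epsilon=c * eps).resolve(len(means)), "g")
        assert scaled.direction == base.direction
        assert scaled.n_increase == base.n_increase
        assert scaled.log2fc == pytest.approx(base.log2fc, abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(trajectories())
    def test_counts_partition_comparisons(self, means):
        call = call_trend(means, TrendParams(epsilon=1e-6).resolve(len(means)), "g")
        assert call.n_increase + call.n_decrease + call.n_tie == len(means) - 1
        assert not (call.direction == "up" and call.n_decrease >= call.n_increase)


class TestTopTable:
    def _call(self, gene, log2fc, direction="up"):
        from exprtrend.trends import TrendCall
        return TrendCall(gene_id=gene, bin_means=(1.0,) * 8, n_increase=7,
                         n_decrease=0, n_tie=0, direction=direction,
                         log2fc=log2fc, drop_magnitudes=())

    def test_up_sorted_descending_down_ascending(self):
        calls = [self._call("a", 2.0), self._call("b", 2.5),
                 self._call("c", -1.8, "down"), self._call("d", -1.1, "down")]
        table = top_table(calls, P8, [str(i) for i in range(8)])
        assert list(table["gene_id"]) == ["b", "a", "c", "d"]
        assert list(table["rank"]) == [1, 2, 1, 2]

    def test_paper_style_ordering_is_preserved(self):
        fcs = [2.5, 2.3, 2.2, 2.1, 2.0]
        calls = [self._call(f"g{i}", fc) for i, fc in enumerate(fcs)]
        table = top_table(calls[::-1], P8, [str(i) for i in range(8)])
        assert list(table["log2fc"]) == fcs

    def test_equal_log2fc_breaks_lexicographically(self):
        calls = [self._call("zz", 1.5), self._call("aa", 1.5)]
        table = top_table(calls, P8, [str(i) for i in range(8)])
        assert list(table["gene_id"]) == ["aa", "zz"]

    def test_truncates_to_top_n(self):
        params = TrendParams(k_min=6, epsilon=1e-9, top_n=3).resolve(8)
        calls = [self._call(f"g{i}", float(i)) for i in range(10)]
        table = top_table(calls, params, [str(i) for i in range(8)])
        assert len(table) == 3 and table["log2fc"].iloc[0] == 9.0


class TestHighExpressionProportion:
    def _setup(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g0"],
            columns=[f"p{i:03d}" for i in range(6)]))
        binning = make_bins(clinical_from_years([1, 1, 1, 2, 2, 2]), n_bins=2)
        return expr, binning

    def test_strictly_above_cutpoint(self):
        expr, binning = self._setup()
        props = high_expression_proportion(expr, binning, {"g0": 2.0})
        assert list(props.loc["g0"]) == pytest.approx([1 / 3, 1.0])

    def test_cutpoint_below_minimum_gives_all_ones(self):
        expr, binning = self._setup()
        props = high_expression_proportion(expr, binning, {"g0": 0.5})
        assert list(props.loc["g0"]) == [1.0, 1.0]

    def test_missing_gene_is_config_error(self):
        expr, binning = self._setup()
        with pytest.raises(ConfigurationError, match="gX"):
            high_expression_proportion(expr, binning, {"gX": 1.0})


def test_call_all_preserves_gene_order_and_planted_recovery(small_cohort):
    binning = make_bins(small_cohort.clinical, n_bins=8)
    calls = call_all(small_cohort.expression, binning)
    assert [c.gene_id for c in calls] == small_cohort.expression.gene_ids
    parts = partition_calls(calls)
    called_up = {c.gene_id for c in parts["up"]}
    truth_up = small_cohort.truth.up_genes
    # delta=0.8, sigma=0.5 at 30/bin: planted trends should dominate the calls
    assert len(called_up & truth_up) / len(truth_up) >= 0.8
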