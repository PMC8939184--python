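"""Kaplan-Meier curves, log-rank tests and best-cutpoint selection."""

import math

import numpy as np
import pandas as pd
import pytest

from exprtrend import DataError, best_cutpoint, km_fit, km_for_gene, logrank
from exprtrend.survival import logrank_scan, median_split_logrank


def naive_logrank_chisq(times, events, group):
    """Term-by-term U^2/V over distinct event times (test oracle)."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group, bool)
    U = V = 0.0
    for tt in sorted(set(t[e == 1])):
        at = t >= tt
        n, n1 = at.sum(), (at & g).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & g).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U * U / V if V > 0 else 0.0


def naive_best_cutpoint(values, times, events, minprop=0.1):
    """Exhaustive candidate scan with the naive statistic (test oracle)."""
    values = np.asarray(values, float)
    n = len(values)
    distinct = np.unique(values)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        mid = (lo + hi) / 2
        high = values > mid
        if high.sum() < minprop * n or (~high).sum() < minprop * n:
            continue
        chisq = naive_logrank_chisq(times, events, high)
        if best is None or chisq > best[1]:
            best = (mid, chisq)
    return best


class TestKMFit:
    def test_all_events_closed_form(self):
        curve = km_fit([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.survival == pytest.approx((2 / 3, 1 / 3, 0.0), abs=1e-12)
        assert curve.at_risk == (3, 2, 1)

    def test_all_censored_flat_curve(self):
        curve = km_fit([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.event_times == ()
        assert curve.median_survival == math.inf

    def test_hand_computed_mixed_fixture(self):
        # subjects: events at 1, 3, 5, 6; censored at 2 and 4
        curve = km_fit([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1])
        assert curve.event_times == (1.0, 3.0, 5.0, 6.0)
        # S: 5/6, then 5/6*3/4=5/8, then 5/8*1/2=5/16, then 0
        assert curve.survival == pytest.approx(
            (5 / 6, 5 / 8, 5 / 16, 0.0), abs=1e-12)
        assert curve.median_survival == 5.0

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            km_fit([], [])


class TestLogrank:
    def test_symmetric_data_gives_zero(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        chisq, p = logrank(times, events, [0, 0, 0, 0, 1, 1, 1, 1])
        assert chisq == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_no_events_degenerate(self):
        chisq, p = logrank([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert (chisq, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError, match="non-empty"):
            logrank([1, 2, 3], [1, 1, 1], [1, 1, 1])

    def test_matches_naive_oracle_random(self, rng):
        for _ in range(20):
            n = 40
            times = np.round(rng.exponential(5.0, n), 1)  # force some ties
            events = rng.integers(0, 2, n)
            group = rng.integers(0, 2, n).astype(bool)
            if events.sum() == 0 or group.all() or (~group).all():
                continue
            chisq, _ = logrank(times, events, group)
            assert chisq == pytest.approx(
                naive_logrank_chisq(times, events, group), rel=1e-8, abs=1e-10)

    def test_label_swap_invariance(self, rng):
        times = rng.exponential(5.0, 30)
        events = rng.integers(0, 2, 30)
        group = rng.integers(0, 2, 30).astype(bool)
        a, _ = logrank(times, events, group)
        b, _ = logrank(times, events, ~group)
        assert a == pytest.approx(b, rel=1e-12)

    def test_time_shift_invariance(self, rng):
        times = rng.exponential(5.0, 30)
        events = rng.integers(0, 2, 30)
        group = np.arange(30) < 15
        a, _ = logrank(times, events, group)
        b, _ = logrank(times + 7.5, events, group)
        assert a == pytest.approx(b, rel=1e-12)


class TestLogrankScan:
    def test_scan_matches_naive_per_candidate(self, rng):
        n = 50
        times = np.round(rng.exponential(5.0, n), 1)
        events = rng.integers(0, 2, n)
        events[0] = 1
        values = rng.normal(size=n)
        mids = (np.sort(values)[:-1] + np.sort(values)[1:]) / 2
        chisq = logrank_scan(times, events, values[None, :] > mids[:, None])
        for i in rng.choice(len(mids), 10, replace=False):
            assert chisq[i] == pytest.approx(
                naive_logrank_chisq(times, events, values > mids[i]),
                rel=1e-8, abs=1e-10)


class TestBestCutpoint:
    def test_constant_expression_rejected(self):
        with pytest.raises(DataError, match="no split|constant"):
            best_cutpoint(np.ones(20), np.arange(1, 21), np.ones(20, int))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(15, 61))
            times = np.round(rng.exponential(5.0, n), 1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            values = np.round(rng.normal(size=n), 2)
            if len(np.unique(values)) < 2:
                continue
            oracle = naive_best_cutpoint(values, times, events)
            res = best_cutpoint(values, times, events)
            assert res.logrank_chisq == pytest.approx(
                oracle[1], rel=1e-8, abs=1e-10)

    def test_separating_cutpoint_recovered(self, rng):
        # two hazard classes split exactly at expression 10 vs 20
        n = 60
        values = np.r_[np.full(30, 10.0), np.full(30, 20.0)]
        times = np.r_[rng.exponential(1.0, 30), rng.exponential(20.0, 30)]
        events = np.ones(n, int)
        res = best_cutpoint(values, times, events)
        assert 10.0 < res.cutpoint < 20.0
        assert res.n_high == 30 and res.n_low == 30

    def test_minprop_respected(self, rng):
        values = np.arange(30, dtype=float)
        times = rng.exponential(5.0, 30)
        events = np.ones(30, int)
        res = best_cutpoint(values, times, events, minprop=0.2)
        assert res.n_high >= 6 and res.n_low >= 6

    def test_permutation_adjustment_flag(self, rng):
        values = rng.normal(size=40)
        times = rng.exponential(5.0, 40)
        events = np.ones(40, int)
        res = best_cutpoint(values, times, events, adjust="permutation",
                            n_permutations=50, rng=rng)
        assert res.p_adjusted is not None
        assert res.p_adjusted >= res.p_naive - 1e-12


class TestKMForGene:
    def test_planted_prognostic_gene_detected(self, small_cohort):
        gene = next(iter(small_cohort.truth.prognostic_genes))
        result, km_high, km_low = km_for_gene(
            small_cohort.expression, small_cohort.clinical, gene)
        assert result.p_naive < 0.05
        sign = small_cohort.truth.prognostic_genes[gene]
        if sign > 0:  # high expression raises hazard -> shorter median
            assert km_high.median_survival <= km_low.median_survival
        else:
            assert km_high.median_survival >= km_low.median_survival

    def test_missing_gene_rejected(self, small_cohort):
        with pytest.raises(DataError, match="nope"):
            km_for_gene(small_cohort.expression, small_cohort.clinical, "nope")


def test_median_split_null_pvalue_uniformish(rng):
    """Fixed-median split keeps roughly nominal size under the null."""
    rejections = 0
    reps = 200
    for _ in range(reps):
        n = 120
        values = rng.normal(size=n)
        times = rng.exponential(5.0, n)
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        _, p = median_split_logrank(values, times, events)
        rejections += p < 0.05
    assert rejections / reps < 0.11  # 3 binomial SE above nominal
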