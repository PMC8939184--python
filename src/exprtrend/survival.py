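"""Kaplan-Meier curves, log-rank tests and optimal expression cutpoints.

Patients are stratified into high/low expression groups at the threshold
maximising the two-group log-rank statistic over all candidate splits
(midpoints between consecutive distinct expression values) that leave at
least ``minprop`` of the cohort on each side — the "auto best cutoff" of
maximally selected rank statistics.  The p-value reported by default is the
naive 1-df chi-square tail at the selected cutpoint.  Because the cutpoint
is chosen to maximise the statistic, this naive p is anti-conservative under
the null; an optional permutation adjustment that accounts for the selection
is available but off by default, so results mirror the common
survminer-style workflow.

Single-curve estimation and fixed-split tests go through lifelines; the
multi-candidate scan uses a vectorised counting-process implementation of
the log-rank statistic (U^2/V over distinct event times).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import chi2

from .cohort_io import ClinicalTable, ExpressionMatrix, drop_missing_survival
from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve", "CutpointResult", "km_fit", "logrank", "median_split_logrank",
    "best_cutpoint", "km_for_gene", "logrank_scan",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    event_times: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    survival: tuple[float, ...]
    median_survival: float  # inf when the curve never reaches 0.5


@dataclass(frozen=True)
class CutpointResult:
    """Best log-rank split of one gene's expression values."""

    gene_id: str
    cutpoint: float
    n_high: int
    n_low: int
    logrank_chisq: float
    p_naive: float
    minprop: float
    candidates_evaluated: int
    p_adjusted: float | None = None


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    event_times = tuple(float(t) for t in ev.index)
    median = kmf.median_survival_time_
    return KMCurve(
        event_times=event_times,
        at_risk=tuple(int(v) for v in ev["at_risk"]),
        events=tuple(int(v) for v in ev["observed"]),
        survival=tuple(float(surv.loc[t]) for t in ev.index),
        median_survival=float(median) if np.isfinite(median) else math.inf,
    )


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Degenerate inputs with no events (zero variance) return (0, 1); an
    empty group is a data error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise DataError("both groups must be non-empty")
    if events.sum() == 0:
        return 0.0, 1.0
    res = logrank_test(times[group], times[~group],
                       event_observed_A=events[group],
                       event_observed_B=events[~group])
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, float(res.p_value)


def median_split_logrank(values, times, events) -> tuple[float, float]:
    """Log-rank test at the fixed median-expression split (high = > median)."""
    values = np.asarray(values, dtype=float)
    return logrank(times, events, values > np.median(values))


def logrank_scan(times, events, high_matrix) -> np.ndarray:
    """Log-rank chi-square for every candidate high-group assignment.

    ``high_matrix`` is (n_candidates, n_subjects) boolean.  Implements
    U = sum_j (d1_j - d_j n1_j / n_j) and the hypergeometric variance
    V = sum_j d_j (n1_j/n_j)(1 - n1_j/n_j)(n_j - d_j)/(n_j - 1) over the
    distinct event times; candidates with V = 0 score 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    H = np.asarray(high_matrix, dtype=float)
    n = times.size
    order = np.argsort(times, kind="stable")
    t, e, H = times[order], events[order], H[:, order]

    # block starts of distinct observed times
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, starts)                      # events per distinct time
    d1 = np.add.reduceat(H * e, starts, axis=1)         # high-group events
    # at-risk counts at each distinct time
    n_at_risk = n - starts
    suffix = np.cumsum(H[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, starts]

    ev = d > 0
    dj, n_j = d[ev], n_at_risk[ev]
    d1j, n1j = d1[:, ev], n1[:, ev]
    frac = n1j / n_j
    U = (d1j - dj * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = dj * frac * (1.0 - frac) * (n_j - dj) / (n_j - 1.0)
    var_terms = np.where(n_j > 1, var_terms, 0.0)
    V = var_terms.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chisq = np.where(V > 0, U * U / V, 0.0)
    return chisq


def _candidate_cutpoints(values: np.ndarray, minprop: float):
    """Midpoints between consecutive distinct values obeying minprop."""
    distinct, counts = np.unique(values, return_counts=True)
    if distinct.size < 2:
        raise DataError("constant expression vector admits no split")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_low = np.cumsum(counts)[:-1]          # subjects <= each midpoint
    n = values.size
    n_high = n - n_low
    floor = minprop * n
    valid = (n_low >= floor) & (n_high >= floor)
    return mids[valid], n_low[valid], n_high[valid]


def best_cutpoint(
    expr_values,
    times,
    events,
    minprop: float = 0.1,
    gene_id: str = "",
    adjust: str | None = None,
    n_permutations: int = 200,
    rng: np.random.Generator | None = None,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for one gene.

    Evaluates every minprop-valid midpoint split, returns the one with the
    largest log-rank chi-square (ties: the lowest cutpoint).  ``p_naive`` is
    the uncorrected chi-square tail at the maximum.  ``adjust="permutation"``
    additionally estimates a selection-adjusted p by re-running the scan on
    label permutations.
    """
    values = np.asarray(expr_values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if values.size < math.ceil(1.0 / minprop):
        raise DataError(f"need at least {math.ceil(1.0 / minprop)} subjects "
                        f"at minprop={minprop}")
    if events.sum() < 1:
        raise DataError("need at least one event")
    mids, n_low, n_high = _candidate_cutpoints(values, minprop)
    if mids.size == 0:
        raise DataError("no candidate cutpoint satisfies the minprop constraint")
    chisq = logrank_scan(times, events, values[None, :] > mids[:, None])
    best = int(np.argmax(chisq))            # first max -> lowest cutpoint
    result = CutpointResult(
        gene_id=gene_id,
        cutpoint=float(mids[best]),
        n_high=int(n_high[best]),
        n_low=int(n_low[best]),
        logrank_chisq=float(chisq[best]),
        p_naive=float(chi2.sf(chisq[best], 1)),
        minprop=minprop,
        candidates_evaluated=int(mids.size),
    )
    if adjust == "permutation":
        rng = rng or np.random.default_rng()
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(values.size)
            null_max = logrank_scan(times[perm], events[perm],
                                    values[None, :] > mids[:, None]).max()
            exceed += null_max >= result.logrank_chisq
        result = CutpointResult(**{
            **result.__dict__,
            "p_adjusted": (exceed + 1) / (n_permutations + 1),
        })
    elif adjust is not None:
        raise DataError(f"unknown adjustment {adjust!r}")
    return result


def km_for_gene(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    gene_id: str,
    minprop: float = 0.1,
) -> tuple[CutpointResult, KMCurve, KMCurve]:
    """Stratify one gene at its best cutpoint; returns (result, high, low)."""
    if gene_id not in expr.values.index:
        raise DataError(f"gene {gene_id!r} not in expression matrix")
    clin = drop_missing_survival(clinical)
    df = clin.table.set_index("patient_id")
    shared = [p for p in expr.values.columns if p in df.index]
    if not shared:
        raise DataError("no patients shared between expression and clinical data")
    values = expr.values.loc[gene_id, shared].to_numpy(dtype=float)
    times = df.loc[shared, "os_time"].to_numpy(dtype=float)
    events = df.loc[shared, "event"].to_numpy(dtype=int)
    result = best_cutpoint(values, times, events, minprop=minprop, gene_id=gene_id)
    high = values > result.cutpoint
    return (
        result,
        km_fit(times[high], events[high]),
        km_fit(times[~high], events[~high]),
    )
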