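"""Per-gene temporal trend calling over diagnosis-year bins.

A gene's trajectory is its mean expression per bin, mu_{g,0..B-1}.  Over the
B-1 consecutive bin comparisons, a gene is called *up-regulated* when its
bin mean strictly exceeds the previous bin's mean in at least ``k_min``
comparisons (default 6 of 7 at B=8), *down-regulated* symmetrically, and
unchanged otherwise.  Ties count as neither an increase nor a decrease.  The
effect size is the log2 fold-change of the last bin mean over the first,
stabilised with a pseudocount so zero means stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix, GroupBinning
from .errors import ConfigurationError, DataError

__all__ = [
    "TrendParams", "TrendCall", "bin_means", "call_trend", "call_all",
    "top_table", "high_expression_proportion",
]


@dataclass(frozen=True)
class TrendParams:
    """Tunables of the consecutive-comparison trend call.

    k_min
        Minimum number of strict same-direction consecutive steps (out of
        B-1) for a call.  ``None`` resolves to B-2, i.e. 6 when B=8.  Must
        exceed (B-1)/2 so a gene can never be both up and down.
    epsilon
        Pseudocount added inside both log2 terms of the fold-change.
        ``None`` resolves per matrix to half the smallest positive value
        (1e-6 if the matrix has no positive entries).
    top_n
        Number of genes per direction in the ranked report (default 50).
    """

    k_min: int | None = None
    epsilon: float | None = None
    top_n: int = 50

    def resolve(self, n_bins: int, expr: ExpressionMatrix | None = None) -> "TrendParams":
        """Fill the data-dependent defaults for a B-bin analysis."""
        k = self.k_min if self.k_min is not None else n_bins - 2
        if not (n_bins - 1) / 2 < k <= n_bins - 1:
            raise ConfigurationError(
                f"k_min={k} must satisfy (B-1)/2 < k_min <= B-1 for B={n_bins}"
            )
        eps = self.epsilon
        if eps is None:
            if expr is not None:
                arr = expr.values.to_numpy()
                pos = arr[arr > 0]
                eps = float(pos.min()) * 0.5 if pos.size else 1e-6
            else:
                eps = 1e-6
        if eps <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")
        return replace(self, k_min=int(k), epsilon=float(eps))


@dataclass(frozen=True)
class TrendCall:
    """Trend decision and trajectory summary for one gene."""

    gene_id: str
    bin_means: tuple[float, ...]
    n_increase: int
    n_decrease: int
    n_tie: int
    direction: str  # "up" | "down" | "none"
    log2fc: float
    drop_magnitudes: tuple[float, ...]  # |log2 step| of counter-directional steps


def bin_means(expr: ExpressionMatrix, binning: GroupBinning) -> pd.DataFrame:
    """Arithmetic mean expression of every gene in every bin.

    Returns a genes x bins DataFrame with the binning's labels as columns.
    Every bin must be non-empty and every binned patient present in the
    matrix.
    """
    sizes = binning.bin_sizes()
    if (sizes == 0).any():
        empty = int(np.argmin(sizes))
        raise ConfigurationError(f"bin {binning.bin_labels[empty]!r} is empty")
    missing = binning.assignment.index.difference(expr.values.columns)
    if len(missing):
        raise ConfigurationError(
            f"{len(missing)} binned patients absent from expression matrix "
            f"(first: {missing[0]!r})"
        )
    sub = expr.values[binning.assignment.index]
    means = {
        label: sub.iloc[:, np.flatnonzero(binning.assignment.to_numpy() == b)]
        .mean(axis=1)
        for b, label in enumerate(binning.bin_labels)
    }
    return pd.DataFrame(means, index=expr.values.index)


def _classify(steps: np.ndarray, k_min: int) -> tuple[int, int, int, str]:
    n_inc = int((steps > 0).sum())
    n_dec = int((steps < 0).sum())
    n_tie = int((steps == 0).sum())
    if n_inc >= k_min:
        direction = "up"
    elif n_dec >= k_min:
        direction = "down"
    else:
        direction = "none"
    return n_inc, n_dec, n_tie, direction


def call_trend(means: Sequence[float], params: TrendParams,
               gene_id: str = "") -> TrendCall:
    """Classify one trajectory of B bin means.

    ``params`` must be resolved (``k_min`` and ``epsilon`` concrete), e.g.
    via ``TrendParams().resolve(n_bins)``.
    """
    mu = np.asarray(means, dtype=float)
    if mu.ndim != 1 or len(mu) < 2:
        raise DataError("need at least two bin means")
    if np.isnan(mu).any():
        raise DataError(f"NaN bin mean for gene {gene_id!r}")
    if params.k_min is None or params.epsilon is None:
        params = params.resolve(len(mu))
    steps = np.diff(mu)
    n_inc, n_dec, n_tie, direction = _classify(steps, params.k_min)
    log_mu = np.log2(mu + params.epsilon)
    log2fc = float(log_mu[-1] - log_mu[0])
    log_steps = np.diff(log_mu)
    if direction == "up":
        counter = log_steps[steps < 0]
    elif direction == "down":
        counter = log_steps[steps > 0]
    else:
        counter = np.empty(0)
    return TrendCall(
        gene_id=gene_id,
        bin_means=tuple(float(m) for m in mu),
        n_increase=n_inc,
        n_decrease=n_dec,
        n_tie=n_tie,
        direction=direction,
        log2fc=log2fc,
        drop_magnitudes=tuple(float(abs(s)) for s in counter),
    )


def call_all(
    expr: ExpressionMatrix,
    binning: GroupBinning,
    params: TrendParams | None = None,
) -> list[TrendCall]:
    """Trend-call every gene of the matrix; output order = input gene order."""
    params = (params or TrendParams()).resolve(binning.n_bins, expr)
    means = bin_means(expr, binning)
    return [
        call_trend(means.iloc[i].to_numpy(), params, gene_id=str(gene))
        for i, gene in enumerate(means.index)
    ]


def partition_calls(calls: Iterable[TrendCall]) -> dict[str, list[TrendCall]]:
    """Split calls into {"up": [...], "down": [...], "none": [...]}."""
    out: dict[str, list[TrendCall]] = {"up": [], "down": [], "none": []}
    for c in calls:
        out[c.direction].append(c)
    return out


def calls_frame(calls: Iterable[TrendCall], bin_labels: Sequence[str]) -> pd.DataFrame:
    """Tabular view of trend calls (one row per gene, means in bin order)."""
    rows = []
    for c in calls:
        row = {
            "gene_id": c.gene_id,
            "direction": c.direction,
            "n_increase": c.n_increase,
            "n_decrease": c.n_decrease,
            "n_tie": c.n_tie,
            "log2fc": c.log2fc,
            "abs_log2fc": abs(c.log2fc),
        }
        row.update({f"mean_{lab}": m for lab, m in zip(bin_labels, c.bin_means)})
        rows.append(row)
    return pd.DataFrame(rows)


def top_table(calls: Iterable[TrendCall], params: TrendParams,
              bin_labels: Sequence[str]) -> pd.DataFrame:
    """Ranked top-N report per direction, with per-bin means for heatmaps.

    Up-regulated genes are ordered by log2 fold-change descending, down-
    regulated ascending (largest decrease first); ties break on gene id.
    """
    parts = partition_calls(calls)
    up = sorted(parts["up"], key=lambda c: (-c.log2fc, c.gene_id))[: params.top_n]
    down = sorted(parts["down"], key=lambda c: (c.log2fc, c.gene_id))[: params.top_n]
    frame = calls_frame(up + down, bin_labels)
    if not frame.empty:
        frame.insert(2, "rank", list(range(1, len(up) + 1))
                     + list(range(1, len(down) + 1)))
    return frame


def high_expression_proportion(
    expr: ExpressionMatrix,
    binning: GroupBinning,
    cutpoints: Mapping[str, float],
) -> pd.DataFrame:
    """Per-bin fraction of patients strictly above each gene's cutpoint.

    Mirrors the trajectory report of the high-expression population share
    across the diagnosis-year periods; rows are the genes of ``cutpoints``.
    """
    genes = list(cutpoints)
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ConfigurationError(f"cutpoint genes absent from matrix: {missing}")
    sub = expr.values.loc[genes, binning.assignment.index].to_numpy()
    cuts = np.array([cutpoints[g] for g in genes])[:, None]
    above = sub > cuts
    bins = binning.assignment.to_numpy()
    out = {}
    for b, label in enumerate(binning.bin_labels):
        mask = bins == b
        if not mask.any():
            raise ConfigurationError(f"bin {label!r} is empty")
        out[label] = above[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"))
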