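"""Gene-set over-representation testing (Fisher / EASE).

For a query list of n genes drawn from a universe of N, a pathway with K
members in the universe and k of them in the query is scored by the
upper-tail hypergeometric probability

    p = sum_{i=k..min(K,n)} C(K,i) C(N-K,n-i) / C(N,n)

(one-sided Fisher exact).  The EASE variant — the default score of the DAVID
annotation service — replaces k by max(k-1, 0) before taking the same tail,
a deliberately conservative penalty on single-gene overlaps.  Fold
enrichment is (k/n)/(K/N).  No multiple-testing correction is applied by
default; Benjamini-Hochberg q-values are available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cohort_io import GeneSetCollection
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "enrich", "enrichment_frame", "default_universe"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation score of one pathway against one query list."""

    pathway_id: str
    N: int
    K: int
    n: int
    k: int
    fold_enrichment: float
    p_value: float
    neg_log10_p: float
    significant: bool
    q_value: float | None = None


def _tail_p(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def default_universe(matrix_genes: Iterable[str],
                     sets: GeneSetCollection) -> frozenset[str]:
    """Matrix genes appearing in at least one gene set (DAVID-like background)."""
    annotated = frozenset().union(*sets.sets.values()) if len(sets) else frozenset()
    return frozenset(matrix_genes) & annotated


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    method: str = "ease",
    alpha: float = 0.05,
    correct: bool = False,
) -> list[EnrichmentResult]:
    """Score every gene set for over-representation of ``query``.

    Query genes outside the universe are dropped with a logged count.
    Results are sorted by p ascending, ties by pathway id; pathways with no
    overlap are reported (fold enrichment 0), not dropped.  ``correct=True``
    adds Benjamini-Hochberg q-values; ``significant`` always refers to the
    raw p against ``alpha``.
    """
    if method not in ("fisher", "ease"):
        raise ConfigurationError(f"unknown enrichment method {method!r}")
    uni = frozenset(universe)
    if not uni:
        raise ConfigurationError("empty universe")
    if not len(sets):
        raise ConfigurationError("empty gene-set collection")
    q = frozenset(query)
    dropped = q - uni
    if dropped:
        logger.warning("dropping %d query genes outside the universe", len(dropped))
    q &= uni
    N, n = len(uni), len(q)

    results = []
    for pid in sets:
        members = sets[pid] & uni
        K = len(members)
        k = len(members & q)
        k_eff = max(k - 1, 0) if method == "ease" else k
        p = _tail_p(k_eff, N, K, n) if K else 1.0
        fold = (k / n) / (K / N) if (k and n and K) else 0.0
        results.append(EnrichmentResult(
            pathway_id=pid, N=N, K=K, n=n, k=k,
            fold_enrichment=fold, p_value=p,
            neg_log10_p=float(-np.log10(p)),
            significant=p < alpha,
        ))
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    if correct and results:
        pvals = np.array([r.p_value for r in results])
        m = len(pvals)
        # BH step-up on the already p-sorted results
        qvals = np.minimum.accumulate((pvals * m / np.arange(1, m + 1))[::-1])[::-1]
        results = [
            EnrichmentResult(**{**r.__dict__, "q_value": float(min(qv, 1.0))})
            for r, qv in zip(results, qvals)
        ]
    return results


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabular enrichment report (one row per pathway)."""
    cols = ["pathway_id", "N", "K", "n", "k", "fold_enrichment",
            "p_value", "neg_log10_p", "significant", "q_value"]
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return pd.DataFrame(columns=cols)
    if df["q_value"].isna().all():
        df = df.drop(columns=["q_value"])
    return df
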