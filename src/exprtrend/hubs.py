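"""Hub-gene selection: the four-part filter on trend-called genes.

A trend-called gene is a *hub* when

1. it is not a lincRNA (catalog membership),
2. its Kaplan-Meier log-rank p at the best expression cutpoint is < 0.05,
3. its |log2 fold-change| (last vs first diagnosis-year bin) exceeds 1, and
4. its trajectory has at most one counter-directional step, and every such
   step's log2 magnitude is under one-third of the total log2 change.

Rule 4 is applied direction-symmetrically: for a down-regulated gene the
counter-directional step is a rise.  "Total change" is |log2fc| between the
last and first bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .cohort_io import AnnotationCatalog
from .errors import ConfigurationError
from .survival import CutpointResult
from .trends import TrendCall

__all__ = ["HubCriteria", "HubDecision", "select_hubs", "hubs_frame"]


@dataclass(frozen=True)
class HubCriteria:
    """Thresholds of the four hub-gene rules."""

    require_not_lincrna: bool = True
    p_threshold: float = 0.05
    abs_log2fc_threshold: float = 1.0
    max_counter_steps: int = 1
    counter_step_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.abs_log2fc_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")
        if not 0 < self.counter_step_fraction < 1:
            raise ConfigurationError("counter_step_fraction must be in (0,1)")
        if self.max_counter_steps < 0:
            raise ConfigurationError("max_counter_steps must be >= 0")


@dataclass(frozen=True)
class HubDecision:
    """Pass/fail outcome of one gene with per-criterion diagnostics."""

    gene_id: str
    direction: str
    passed: bool
    failed_criteria: tuple[str, ...]
    p_naive: float
    log2fc: float
    n_counter_steps: int
    max_counter_step: float  # 0 when the trajectory is strictly monotone


def _evaluate(call: TrendCall, cut: CutpointResult,
              catalog: AnnotationCatalog, criteria: HubCriteria) -> HubDecision:
    failed: list[str] = []
    if criteria.require_not_lincrna and call.gene_id in catalog.lincrnas:
        failed.append("lincrna")
    if not cut.p_naive < criteria.p_threshold:
        failed.append("km_p")
    total = abs(call.log2fc)
    if not total > criteria.abs_log2fc_threshold:
        failed.append("log2fc")
    drops = call.drop_magnitudes
    if len(drops) > criteria.max_counter_steps or any(
        not d < criteria.counter_step_fraction * total for d in drops
    ):
        failed.append("trajectory")
    return HubDecision(
        gene_id=call.gene_id,
        direction=call.direction,
        passed=not failed,
        failed_criteria=tuple(failed),
        p_naive=cut.p_naive,
        log2fc=call.log2fc,
        n_counter_steps=len(drops),
        max_counter_step=max(drops, default=0.0),
    )


def select_hubs(
    calls: Iterable[TrendCall],
    survival_results: Mapping[str, CutpointResult],
    catalog: AnnotationCatalog,
    criteria: HubCriteria | None = None,
) -> list[HubDecision]:
    """Evaluate the hub rules on every up/down-called gene.

    Every candidate needs a cutpoint result; a missing one is a
    configuration error naming the gene.  Output is ordered by |log2fc|
    descending (ties by gene id).
    """
    criteria = criteria or HubCriteria()
    candidates = [c for c in calls if c.direction in ("up", "down")]
    decisions = []
    for call in candidates:
        if call.gene_id not in survival_results:
            raise ConfigurationError(
                f"no survival result for candidate gene {call.gene_id!r}"
            )
        decisions.append(
            _evaluate(call, survival_results[call.gene_id], catalog, criteria)
        )
    decisions.sort(key=lambda d: (-abs(d.log2fc), d.gene_id))
    return decisions


def hubs_frame(decisions: Iterable[HubDecision]) -> pd.DataFrame:
    rows = [{
        "gene_id": d.gene_id,
        "direction": d.direction,
        "log2fc": d.log2fc,
        "p_naive": d.p_naive,
        "n_counter_steps": d.n_counter_steps,
        "max_counter_step": d.max_counter_step,
        "passed": d.passed,
        "failed_criteria": ",".join(d.failed_criteria),
    } for d in decisions]
    return pd.DataFrame(rows, columns=[
        "gene_id", "direction", "log2fc", "p_naive", "n_counter_steps",
        "max_counter_step", "passed", "failed_criteria",
    ])
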