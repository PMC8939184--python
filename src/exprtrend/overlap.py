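"""Venn-style intersection of trend-called gene lists with annotation catalogs.

Each called gene is assigned to exactly one region of the three-catalog Venn
diagram (oncogene / TSG / lincRNA membership combinations, eight regions
including "unannotated"), so region counts always sum to the called-set size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .cohort_io import AnnotationCatalog
from .trends import TrendCall, partition_calls

_CATALOGS = ("oncogene", "tsg", "lincrna")


def _region_name(member_of: tuple[str, ...]) -> str:
    return "&".join(member_of) if member_of else "unannotated"

#: All eight region names, unannotated first, then by catalog order.
REGION_NAMES = [
    _region_name(tuple(c for i, c in enumerate(_CATALOGS) if (mask >> i) & 1))
    for mask in range(8)
]


@dataclass(frozen=True)
class OverlapReport:
    """Exact Venn regions of the up- and down-regulated gene sets.

    ``regions[direction][region]`` lists the member genes; ``lincrna_fraction``
    is the share of the called set belonging to the lincRNA catalog
    (any region containing "lincrna").
    """

    regions: Mapping[str, Mapping[str, tuple[str, ...]]]
    set_sizes: Mapping[str, int]
    lincrna_fraction: Mapping[str, float]

    def counts(self, direction: str) -> dict[str, int]:
        return {r: len(g) for r, g in self.regions[direction].items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for direction, regs in self.regions.items():
            for region, genes in regs.items():
                rows.append({
                    "direction": direction,
                    "region": region,
                    "count": len(genes),
                    "genes": ",".join(genes),
                })
        return pd.DataFrame(rows)


def overlap(calls: Iterable[TrendCall], catalog: AnnotationCatalog) -> OverlapReport:
    """Assign every up/down-called gene to its exact Venn region."""
    parts = partition_calls(calls)
    lookups = (catalog.oncogenes, catalog.tsgs, catalog.lincrnas)
    regions: dict[str, dict[str, tuple[str, ...]]] = {}
    sizes: dict[str, int] = {}
    linc_frac: dict[str, float] = {}
    for direction in ("up", "down"):
        genes = sorted(c.gene_id for c in parts[direction])
        buckets: dict[str, list[str]] = {name: [] for name in REGION_NAMES}
        n_linc = 0
        for g in genes:
            member = tuple(name for name, s in zip(_CATALOGS, lookups) if g in s)
            buckets[_region_name(member)].append(g)
            n_linc += "lincrna" in member
        regions[direction] = {r: tuple(v) for r, v in buckets.items()}
        sizes[direction] = len(genes)
        linc_frac[direction] = n_linc / len(genes) if genes else 0.0
    return OverlapReport(regions=regions, set_sizes=sizes,
                         lincrna_fraction=linc_frac)
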