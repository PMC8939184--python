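"""Cohort input/output and diagnosis-year binning.

The pipeline consumes four plain-text inputs sharing one gene-identifier
namespace:

* ``expression.tsv`` — genes (rows) x patients (columns), non-negative values;
* ``clinical.tsv``   — ``patient_id, diagnosis_year, os_time, event, subtype``;
* ``*.txt``          — one gene id per line, ``#`` comments (annotation lists);
* ``pathways.gmt``   — standard GMT: name, description, then member gene ids.

Patients are grouped into diagnosis-year bins (default eight) either by
count-balancing quantile edges on whole years or by explicit edges.  Years are
never split across bins: each bin is a left-closed year interval, with the
last interval closed on both ends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError

logger = logging.getLogger(__name__)

#: Recognised PAM50 intrinsic-subtype labels; anything else maps to "NA".
VALID_SUBTYPES = ("LumA", "LumB", "Basal", "Her2")

#: Number of year-boundary partitions below which balanced binning is solved
#: by exhaustive search rather than the greedy quantile heuristic.
_EXHAUSTIVE_PARTITION_LIMIT = 500_000


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x patients non-negative expression values.

    ``values`` is a DataFrame indexed by gene id with patient-id columns.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate patient id: {dup!r}")
        arr = df.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite expression value for gene {df.index[bad[0]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative expression value for gene {df.index[bad[0]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClinicalTable:
    """Per-patient diagnosis year, overall survival and subtype label.

    ``table`` columns: patient_id, diagnosis_year, os_time, event, subtype.
    ``event`` is 1 for death, 0 for censoring; ``os_time`` is time from
    diagnosis in the unit the source declares (the synthetic cohort uses
    years).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = ["patient_id", "diagnosis_year", "os_time", "event", "subtype"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise FormatError(f"duplicate patient id: {dup!r}")
        ok_time = df["os_time"].isna() | (df["os_time"] >= 0)
        if not ok_time.all():
            row = df.index[~ok_time][0]
            raise FormatError(f"negative os_time at row {row}")
        ok_event = df["event"].isna() | df["event"].isin([0, 1])
        if not ok_event.all():
            row = df.index[~ok_event][0]
            raise FormatError(f"event must be 0 or 1 (row {row})")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GroupBinning:
    """Assignment of patients to ordered diagnosis-year bins.

    ``bin_edges`` holds B+1 year boundaries: bin *b* covers years
    ``[edges[b], edges[b+1])`` except the last bin, which also includes its
    right edge.  A single-year last bin is encoded by equal final edges
    (e.g. ``(..., 2011, 2011)`` for a lone 2011 group).
    """

    bin_edges: tuple[int, ...]
    bin_labels: tuple[str, ...]
    assignment: pd.Series  # patient_id -> bin index

    def __post_init__(self) -> None:
        edges = self.bin_edges
        if len(edges) < 3:
            raise ConfigurationError("need at least 2 bins (3 edges)")
        increasing = all(b > a for a, b in zip(edges[:-1], edges[1:-1]))
        if not increasing or edges[-1] < edges[-2]:
            raise ConfigurationError(f"bin edges not increasing: {edges}")
        if len(self.bin_labels) != len(edges) - 1:
            raise ConfigurationError("bin_labels length must equal number of bins")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_patients(self, b: int) -> list[str]:
        return list(self.assignment.index[self.assignment == b])

    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment.to_numpy(), minlength=self.n_bins)


@dataclass(frozen=True)
class AnnotationCatalog:
    """Oncogene, tumor-suppressor and lincRNA gene-id sets (may overlap)."""

    oncogenes: frozenset[str] = frozenset()
    tsgs: frozenset[str] = frozenset()
    lincrnas: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("oncogenes", "tsgs", "lincrnas"):
            if "" in getattr(self, name):
                raise FormatError(f"empty gene id in {name}")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets with free-text descriptions."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.sets.items():
            if not members:
                raise FormatError(f"empty gene set: {pid!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.sets[pid]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-patients TSV (first column gene ids, header patient ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    arr = values.to_numpy()
    bad_rows = np.argwhere(~np.isfinite(arr) | (arr < 0))
    if bad_rows.size:
        # +2: header line plus 1-based numbering
        line = int(bad_rows[0][0]) + 2
        raise FormatError(
            f"{path}: invalid expression value on line {line} "
            f"(gene {values.index[bad_rows[0][0]]!r})"
        )
    try:
        return ExpressionMatrix(values)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV; unknown subtype strings become NA with a warning."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "subtype": str})
    required = ["patient_id", "diagnosis_year", "os_time", "event", "subtype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    unknown = ~(df["subtype"].isin(VALID_SUBTYPES) | df["subtype"].isna()
                | (df["subtype"] == "NA"))
    if unknown.any():
        labels = sorted(df.loc[unknown, "subtype"].unique())
        logger.warning("%s: %d unknown subtype labels %s mapped to NA",
                       path, int(unknown.sum()), labels)
        df.loc[unknown, "subtype"] = "NA"
    df["subtype"] = df["subtype"].fillna("NA")
    try:
        return ClinicalTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a one-id-per-line gene list; ``#`` starts a comment."""
    path = Path(path)
    genes: set[str] = set()
    for raw in path.read_text().splitlines():
        entry = raw.split("#", 1)[0].strip()
        if entry:
            genes.add(entry)
    if not genes:
        logger.warning("%s: empty gene list", path)
    return frozenset(genes)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line name, description, then member gene ids."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT line needs "
                              "name, description and at least one gene")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate pathway {name!r}")
        sets[name] = frozenset(genes)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _cut_enumeration(n_years: int, n_bins: int) -> np.ndarray:
    """All (M, B-1) boundary placements over n_years distinct years."""
    return np.array(list(combinations(range(1, n_years), n_bins - 1)),
                    dtype=np.int64)


def _best_cuts(year_counts: np.ndarray, n_bins: int) -> tuple[int, ...]:
    """Boundary placement minimising the max/min bin-occupancy ratio.

    Evaluates every placement (vectorised); ties resolve to the
    lexicographically smallest cuts because the enumeration is in
    lexicographic order and argmin returns the first minimum.
    """
    cuts = _cut_enumeration(len(year_counts), n_bins)
    cum = np.concatenate([[0], np.cumsum(year_counts)])
    bounds = np.hstack([
        np.zeros((len(cuts), 1), dtype=np.int64),
        cuts,
        np.full((len(cuts), 1), len(year_counts), dtype=np.int64),
    ])
    sizes = cum[bounds[:, 1:]] - cum[bounds[:, :-1]]
    mn, mx = sizes.min(axis=1), sizes.max(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(mn > 0, mx / np.maximum(mn, 1), np.inf)
    return tuple(int(c) for c in cuts[int(np.argmin(ratio))])


def make_bins(
    clinical: ClinicalTable,
    n_bins: int = 8,
    mode: str = "quantile",
    explicit_edges: Sequence[int] | None = None,
) -> GroupBinning:
    """Partition patients into diagnosis-year bins.

    ``quantile`` mode places whole-year boundaries so that bin patient counts
    are as balanced as year-resolution boundaries allow (exhaustive search
    over boundary placements when tractable, minimising the max/min occupancy
    ratio; ties resolved to the earliest boundaries).  ``explicit`` mode uses
    ``explicit_edges`` verbatim.  Patients with a missing diagnosis year are
    dropped with a logged count.
    """
    df = clinical.table
    has_year = df["diagnosis_year"].notna()
    if (n_dropped := int((~has_year).sum())):
        logger.warning("dropping %d patients with missing diagnosis year", n_dropped)
    years = df.loc[has_year, "diagnosis_year"].astype(int).to_numpy()
    patients = df.loc[has_year, "patient_id"].to_numpy()

    if mode == "explicit":
        if explicit_edges is None:
            raise ConfigurationError("explicit mode requires explicit_edges")
        edges = tuple(int(e) for e in explicit_edges)
    elif mode == "quantile":
        if n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        distinct = np.unique(years)
        if len(distinct) < n_bins:
            raise ConfigurationError(
                f"only {len(distinct)} distinct diagnosis years for {n_bins} bins"
            )
        order = np.searchsorted(distinct, years)
        year_counts = np.bincount(order, minlength=len(distinct))
        n_gaps = len(distinct) - 1
        if math.comb(n_gaps, n_bins - 1) <= _EXHAUSTIVE_PARTITION_LIMIT:
            cuts = _best_cuts(year_counts, n_bins)
        else:  # greedy quantile fallback for pathological many-year inputs
            targets = np.linspace(0, len(years), n_bins + 1)[1:-1]
            cum = np.cumsum(year_counts)
            cuts = tuple(
                int(np.argmin(np.abs(cum - t))) + 1 for t in targets
            )
            cuts = tuple(sorted(set(cuts)))
            if len(cuts) != n_bins - 1:
                raise ConfigurationError("greedy quantile binning failed to "
                                         "place distinct year boundaries")
        edges = (int(distinct[0]),
                 *(int(distinct[c]) for c in cuts),
                 int(distinct[-1]))
    else:
        raise ConfigurationError(f"unknown binning mode {mode!r}")

    internal = np.array(edges[1:-1])
    in_range = (years >= edges[0]) & (years <= edges[-1])
    idx = np.searchsorted(internal, years[in_range], side="right")
    assignment = pd.Series(idx, index=pd.Index(patients[in_range], name="patient_id"))

    labels = []
    for b in range(len(edges) - 1):
        lo = edges[b]
        hi = edges[b + 1] - (0 if b == len(edges) - 2 else 1)
        labels.append(str(lo) if lo == hi else f"{lo}-{hi}")
    return GroupBinning(bin_edges=tuple(edges), bin_labels=tuple(labels),
                        assignment=assignment)


def drop_missing_survival(clinical: ClinicalTable) -> ClinicalTable:
    """Remove patients lacking os_time or event, logging the count."""
    df = clinical.table
    keep = df["os_time"].notna() & df["event"].notna()
    if (n := int((~keep).sum())):
        logger.warning("dropping %d patients with missing survival data", n)
    return ClinicalTable(df.loc[keep].reset_index(drop=True))
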