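"""Synthetic breast-cancer expression cohorts with known planted structure.

The generator emulates the statistical shape of a diagnosis-year-binned
RNA-seq cohort: ~1000 patients diagnosed over a 24-year window split into 8
count-balanced year bins, log-normal expression (log2-scale Gaussian noise)
with a linear per-bin drift of ``delta`` log2 units planted on a subset of
genes, expression-dependent exponential survival with uniform censoring,
multinomial PAM50 subtype labels, and pathway gene sets enriched for the
planted genes.  Every downstream stage therefore has exact ground truth
(``SimTruth``) to score against.

All randomness flows from one ``numpy`` generator seeded by ``seed``:
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import (
    AnnotationCatalog,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    VALID_SUBTYPES,
    make_bins,
)
from .errors import ConfigurationError

__all__ = ["SimConfig", "SimTruth", "Cohort", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings.

    Expression for gene g in bin b is 2**Normal(mu_g + s_g*delta*b, sigma^2)
    with s_g in {+1,-1,0} for planted-up, planted-down and null genes; mu_g
    is a per-gene baseline drawn uniformly on [3, 8] log2 units.  Survival
    time is exponential with rate baseline_hazard * exp(sum of signed beta
    over the patient's high-expression indicators of the prognostic genes),
    censored by an independent Uniform(0, censor_horizon) draw.  Time units
    are years; baseline_hazard is events per patient-year.
    """

    n_patients: int = 1000
    n_genes: int = 2000
    n_bins: int = 8
    year_range: tuple[int, int] = (1988, 2011)
    frac_up: float = 0.05
    frac_down: float = 0.05
    delta: float = 0.3
    sigma: float = 1.0
    frac_prognostic: float = 0.05
    beta: float = 1.0
    baseline_hazard: float = 0.15
    censor_horizon: float = 20.0
    subtype_probs: tuple[float, float, float, float] = (0.45, 0.24, 0.20, 0.11)
    n_pathways: int = 20
    pathway_size: int = 50
    n_enriched_pathways: int = 5
    planted_enrichment_frac: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        def _check(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise ConfigurationError(f"{name}: {msg}")

        _check(self.n_patients >= 1, "n_patients", "must be >= 1")
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.n_bins >= 2, "n_bins", "must be >= 2")
        lo, hi = self.year_range
        _check(hi - lo + 1 >= self.n_bins, "year_range",
               f"must span >= n_bins={self.n_bins} distinct years")
        for name in ("frac_up", "frac_down", "frac_prognostic",
                     "planted_enrichment_frac"):
            _check(0.0 <= getattr(self, name) <= 1.0, name, "must be in [0,1]")
        _check(self.frac_up + self.frac_down <= 1.0, "frac_up",
               "frac_up + frac_down must be <= 1")
        _check(self.sigma > 0, "sigma", "must be positive")
        _check(self.baseline_hazard > 0, "baseline_hazard", "must be positive")
        _check(self.censor_horizon > 0, "censor_horizon", "must be positive")
        _check(len(self.subtype_probs) == 4, "subtype_probs", "needs 4 entries")
        _check(all(p >= 0 for p in self.subtype_probs), "subtype_probs",
               "must be non-negative")
        _check(abs(sum(self.subtype_probs) - 1.0) <= 1e-9, "subtype_probs",
               "must sum to 1")
        _check(self.n_pathways >= 0, "n_pathways", "must be >= 0")
        _check(self.pathway_size >= 1, "pathway_size", "must be >= 1")
        _check(0 <= self.n_enriched_pathways <= self.n_pathways,
               "n_enriched_pathways", "must be between 0 and n_pathways")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth: which genes drift, which carry survival signal."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    null_genes: frozenset[str]
    prognostic_genes: Mapping[str, int]  # gene -> hazard sign (+1 / -1)
    enriched_pathways: frozenset[str]


@dataclass(frozen=True)
class Cohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    pathways: GeneSetCollection
    catalog: AnnotationCatalog
    truth: SimTruth | None = None


def _ids(prefix: str, n: int, width: int) -> list[str]:
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw one synthetic cohort; deterministic in ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, P, B = config.n_genes, config.n_patients, config.n_bins
    gene_ids = np.array(_ids("g", G, 4))
    patient_ids = np.array(_ids("p", P, 4))

    # diagnosis years: uniform over the window, redrawn until the bin count
    # is attainable (>= n_bins distinct years)
    lo, hi = config.year_range
    for _ in range(1000):
        years = rng.integers(lo, hi + 1, size=P)
        if len(np.unique(years)) >= B:
            break
    else:
        raise ConfigurationError(
            "year_range/n_patients: could not draw >= n_bins distinct years"
        )

    # subtype labels and provisional clinical table (needed for binning)
    subtype = rng.choice(np.array(VALID_SUBTYPES), size=P,
                         p=np.asarray(config.subtype_probs))
    clin_df = pd.DataFrame({
        "patient_id": patient_ids,
        "diagnosis_year": years,
        "os_time": np.nan,
        "event": np.nan,
        "subtype": subtype,
    })
    binning = make_bins(ClinicalTable(clin_df), n_bins=B, mode="quantile")
    bin_idx = binning.assignment.loc[patient_ids].to_numpy()

    # planted trend structure
    n_up = int(round(config.frac_up * G))
    n_down = int(round(config.frac_down * G))
    perm = rng.permutation(G)
    up_idx, down_idx = perm[:n_up], perm[n_up:n_up + n_down]
    s = np.zeros(G)
    s[up_idx], s[down_idx] = 1.0, -1.0

    mu = rng.uniform(3.0, 8.0, size=G)
    loc = mu[:, None] + s[:, None] * config.delta * bin_idx[None, :]
    log2_expr = rng.normal(loc, config.sigma)
    expr_df = pd.DataFrame(np.exp2(log2_expr),
                           index=pd.Index(gene_ids, name="gene_id"),
                           columns=patient_ids)

    # prognostic genes: a fraction of the planted genes, hazard sign = trend
    planted_idx = np.concatenate([up_idx, down_idx])
    n_prog = int(round(config.frac_prognostic * planted_idx.size))
    prog_idx = rng.choice(planted_idx, size=n_prog, replace=False) \
        if n_prog else np.array([], dtype=int)
    log_rate = np.full(P, np.log(config.baseline_hazard))
    prognostic: dict[str, int] = {}
    for gi in prog_idx:
        sign = int(s[gi])
        x = expr_df.iloc[gi].to_numpy()
        high = x > np.median(x)
        log_rate += sign * config.beta * high
        prognostic[str(gene_ids[gi])] = sign
    T = rng.exponential(1.0 / np.exp(log_rate))
    U = rng.uniform(0.0, config.censor_horizon, size=P)
    clin_df = clin_df.assign(os_time=np.minimum(T, U), event=(T <= U).astype(int))

    # pathway sets: the first n_enriched_pathways draw a planted core
    null_idx = perm[n_up + n_down:]
    width = max(2, len(str(config.n_pathways)))
    path_ids = _ids("path", config.n_pathways, width)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    enriched: set[str] = set()
    size = min(config.pathway_size, G)
    for j, pid in enumerate(path_ids):
        if j < config.n_enriched_pathways and planted_idx.size:
            n_core = min(int(round(config.planted_enrichment_frac * size)),
                         planted_idx.size)
            core = rng.choice(planted_idx, size=n_core, replace=False)
            n_rest = min(size - n_core, null_idx.size)
            rest = rng.choice(null_idx, size=n_rest, replace=False)
            members = np.concatenate([core, rest])
            enriched.add(pid)
            descriptions[pid] = "planted-enriched pathway"
        else:
            members = rng.choice(G, size=size, replace=False)
            descriptions[pid] = "background pathway"
        sets[pid] = frozenset(gene_ids[members])

    # annotation catalogs: uniform samples of the gene universe
    def _sample(frac: float) -> frozenset[str]:
        k = int(round(frac * G))
        return frozenset(gene_ids[rng.choice(G, size=k, replace=False)])

    catalog = AnnotationCatalog(
        oncogenes=_sample(0.05), tsgs=_sample(0.05), lincrnas=_sample(0.10),
    )

    truth = SimTruth(
        up_genes=frozenset(gene_ids[up_idx]),
        down_genes=frozenset(gene_ids[down_idx]),
        null_genes=frozenset(gene_ids[null_idx]),
        prognostic_genes=prognostic,
        enriched_pathways=frozenset(enriched),
    )
    return Cohort(
        expression=ExpressionMatrix(expr_df),
        clinical=ClinicalTable(clin_df),
        pathways=GeneSetCollection(sets=sets, descriptions=descriptions),
        catalog=catalog,
        truth=truth,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, str]:
    """Write the cohort's files; returns a name -> path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _register(name: str, path: Path) -> Path:
        manifest[name] = str(path)
        return path

    cohort.expression.values.to_csv(
        _register("expression", out / "expression.tsv"), sep="\t")
    cohort.clinical.table.to_csv(
        _register("clinical", out / "clinical.tsv"), sep="\t", index=False)

    gmt_lines = [
        "\t".join([pid, cohort.pathways.descriptions.get(pid, ""),
                   *sorted(cohort.pathways[pid])])
        for pid in cohort.pathways
    ]
    _register("pathways", out / "pathways.gmt").write_text(
        "\n".join(gmt_lines) + "\n")

    for name, genes in (("oncogenes", cohort.catalog.oncogenes),
                        ("tsgs", cohort.catalog.tsgs),
                        ("lincrnas", cohort.catalog.lincrnas)):
        _register(name, out / f"{name}.txt").write_text(
            "\n".join(sorted(genes)) + "\n")

    truth = {
        "up_genes": sorted(cohort.truth.up_genes),
        "down_genes": sorted(cohort.truth.down_genes),
        "null_genes": sorted(cohort.truth.null_genes),
        "prognostic_genes": dict(sorted(cohort.truth.prognostic_genes.items())),
        "enriched_pathways": sorted(cohort.truth.enriched_pathways),
    }
    _register("truth", out / "truth.json").write_text(
        json.dumps(truth, indent=1) + "\n")
    return manifest
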