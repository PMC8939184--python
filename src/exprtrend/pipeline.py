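"""End-to-end orchestration: whole-cohort analysis plus per-subtype reruns.

Stage order mirrors the study design: bin the cohort by diagnosis year,
trend-call every gene, intersect the called lists with the annotation
catalogs, test pathway over-representation of the up- and down-lists
separately, stratify survival of every called gene at its best expression
cutpoint, apply the hub filter, and report the high-expression-population
trajectories.  The trend-call + enrichment stages are then repeated inside
each PAM50 subtype, re-using the whole-cohort bin edges.

All outputs are plain TSV/JSON under the run's output directory; a
``run_manifest.json`` records the config echo, seed, row counts and wall
time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_io import (
    AnnotationCatalog,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    GroupBinning,
    VALID_SUBTYPES,
    drop_missing_survival,
    make_bins,
    read_clinical,
    read_expression,
    read_gene_list,
    read_gmt,
)
from .enrichment import default_universe, enrich, enrichment_frame
from .errors import ConfigurationError, ExprTrendError
from .hubs import HubCriteria, hubs_frame, select_hubs
from .overlap import overlap
from .simulate import Cohort, SimConfig, generate_cohort, write_cohort
from .survival import CutpointResult, best_cutpoint, km_fit
from .trends import (
    TrendParams,
    call_all,
    calls_frame,
    high_expression_proportion,
    partition_calls,
    top_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Settings of one pipeline run (file inputs XOR a simulate block)."""

    out_dir: str = "exprtrend_run"
    expression_path: str | None = None
    clinical_path: str | None = None
    oncogenes_path: str | None = None
    tsgs_path: str | None = None
    lincrnas_path: str | None = None
    gmt_path: str | None = None
    simulate: SimConfig | None = None
    n_bins: int = 8
    binning_mode: str = "quantile"
    explicit_edges: tuple[int, ...] | None = None
    trend: TrendParams = field(default_factory=TrendParams)
    hub: HubCriteria = field(default_factory=HubCriteria)
    enrichment_method: str = "ease"
    alpha: float = 0.05
    minprop: float = 0.1
    subtypes: tuple[str, ...] = VALID_SUBTYPES
    min_subtype_n: int = 20
    seed: int = 0

    def validate(self) -> None:
        has_files = self.expression_path is not None
        if has_files == (self.simulate is not None):
            raise ConfigurationError(
                "exactly one of {input paths, simulate block} must be given"
            )
        if has_files and self.clinical_path is None:
            raise ConfigurationError("clinical_path is required with file inputs")
        if has_files:
            for name in ("expression_path", "clinical_path", "oncogenes_path",
                         "tsgs_path", "lincrnas_path", "gmt_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"{name}: {p} does not exist")


def _load_inputs(config: RunConfig) -> Cohort:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        return generate_cohort(sim)
    expr = read_expression(config.expression_path)
    clinical = read_clinical(config.clinical_path)
    catalog = AnnotationCatalog(
        oncogenes=read_gene_list(config.oncogenes_path)
        if config.oncogenes_path else frozenset(),
        tsgs=read_gene_list(config.tsgs_path)
        if config.tsgs_path else frozenset(),
        lincrnas=read_gene_list(config.lincrnas_path)
        if config.lincrnas_path else frozenset(),
    )
    pathways = read_gmt(config.gmt_path) if config.gmt_path \
        else GeneSetCollection(sets={})
    return Cohort(expression=expr, clinical=clinical, pathways=pathways,
                  catalog=catalog, truth=None)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def _enrichment_stage(
    calls, pathways: GeneSetCollection, expr: ExpressionMatrix,
    config: RunConfig, out_dir: Path, prefix: str = "",
) -> dict[str, str]:
    outputs = {}
    if not len(pathways):
        logger.warning("no pathway sets given; enrichment skipped")
        return outputs
    universe = default_universe(expr.gene_ids, pathways)
    parts = partition_calls(calls)
    for direction in ("up", "down"):
        query = {c.gene_id for c in parts[direction]}
        results = enrich(query, pathways, universe,
                         method=config.enrichment_method, alpha=config.alpha)
        path = out_dir / f"{prefix}enrichment_{direction}.tsv"
        _write_tsv(enrichment_frame(results), path)
        outputs[f"{prefix}enrichment_{direction}"] = str(path)
    return outputs


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns the run manifest (also written to disk)."""
    from . import __version__

    t0 = time.perf_counter()
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    logging.getLogger("exprtrend").addHandler(log_handler)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config": _config_echo(config),
        "outputs": {},
        "counts": {},
        "complete": False,
    }
    stage = "load"
    try:
        cohort = _load_inputs(config)
        if config.simulate is not None:
            manifest["outputs"].update(write_cohort(cohort, out_dir / "cohort"))
        expr, clinical = cohort.expression, cohort.clinical
        manifest["counts"]["genes"] = expr.n_genes
        manifest["counts"]["patients"] = expr.n_patients

        stage = "binning"
        binning = make_bins(clinical, n_bins=config.n_bins,
                            mode=config.binning_mode,
                            explicit_edges=config.explicit_edges)
        manifest["counts"]["bin_sizes"] = [int(x) for x in binning.bin_sizes()]

        stage = "trend_calling"
        params = config.trend.resolve(binning.n_bins, expr)
        calls = call_all(expr, binning, params)
        _write_tsv(calls_frame(calls, binning.bin_labels),
                   out_dir / "trend_calls.tsv")
        _write_tsv(top_table(calls, params, binning.bin_labels),
                   out_dir / "top50_matrix.tsv")
        manifest["outputs"]["trend_calls"] = str(out_dir / "trend_calls.tsv")
        manifest["outputs"]["top50_matrix"] = str(out_dir / "top50_matrix.tsv")
        parts = partition_calls(calls)
        manifest["counts"]["up_genes"] = len(parts["up"])
        manifest["counts"]["down_genes"] = len(parts["down"])

        stage = "annotation_overlap"
        report = overlap(calls, cohort.catalog)
        _write_tsv(report.to_frame(), out_dir / "overlap_report.tsv")
        (out_dir / "overlap_regions.json").write_text(json.dumps({
            "regions": {d: {r: list(g) for r, g in regs.items()}
                        for d, regs in report.regions.items()},
            "set_sizes": dict(report.set_sizes),
            "lincrna_fraction": dict(report.lincrna_fraction),
        }, indent=1))
        manifest["outputs"]["overlap_report"] = str(out_dir / "overlap_report.tsv")
        manifest["outputs"]["overlap_regions"] = str(out_dir / "overlap_regions.json")

        stage = "enrichment"
        manifest["outputs"].update(
            _enrichment_stage(calls, cohort.pathways, expr, config, out_dir))

        stage = "survival"
        called = parts["up"] + parts["down"]
        clin = drop_missing_survival(clinical)
        df = clin.table.set_index("patient_id")
        shared = [p for p in expr.patient_ids if p in df.index]
        times = df.loc[shared, "os_time"].to_numpy(dtype=float)
        events = df.loc[shared, "event"].to_numpy(dtype=int)
        cut_results: dict[str, CutpointResult] = {}
        surv_rows, curve_rows = [], []
        for call in called:
            values = expr.values.loc[call.gene_id, shared].to_numpy(dtype=float)
            res = best_cutpoint(values, times, events,
                                minprop=config.minprop, gene_id=call.gene_id)
            cut_results[call.gene_id] = res
            high = values > res.cutpoint
            km_high = km_fit(times[high], events[high])
            km_low = km_fit(times[~high], events[~high])
            surv_rows.append({
                "gene_id": call.gene_id, "direction": call.direction,
                "cutpoint": res.cutpoint, "n_high": res.n_high,
                "n_low": res.n_low, "logrank_chisq": res.logrank_chisq,
                "p_naive": res.p_naive,
                "median_survival_high": km_high.median_survival,
                "median_survival_low": km_low.median_survival,
            })
            for label, curve in (("high", km_high), ("low", km_low)):
                for t, r, d, srv in zip(curve.event_times, curve.at_risk,
                                        curve.events, curve.survival):
                    curve_rows.append({
                        "gene_id": call.gene_id, "group": label, "time": t,
                        "at_risk": r, "events": d, "survival": srv,
                    })
        surv_cols = ["gene_id", "direction", "cutpoint", "n_high", "n_low",
                     "logrank_chisq", "p_naive", "median_survival_high",
                     "median_survival_low"]
        curve_cols = ["gene_id", "group", "time", "at_risk", "events", "survival"]
        _write_tsv(pd.DataFrame(surv_rows, columns=surv_cols),
                   out_dir / "survival.tsv")
        _write_tsv(pd.DataFrame(curve_rows, columns=curve_cols),
                   out_dir / "km_curves.tsv")
        manifest["outputs"]["survival"] = str(out_dir / "survival.tsv")
        manifest["outputs"]["km_curves"] = str(out_dir / "km_curves.tsv")

        stage = "hub_selection"
        decisions = select_hubs(called, cut_results, cohort.catalog, config.hub)
        _write_tsv(hubs_frame(decisions), out_dir / "hub_genes.tsv")
        manifest["outputs"]["hub_genes"] = str(out_dir / "hub_genes.tsv")
        manifest["counts"]["hub_genes"] = sum(d.passed for d in decisions)

        stage = "trajectories"
        cutpoints = {g: r.cutpoint for g, r in cut_results.items()}
        if cutpoints:
            traj = high_expression_proportion(expr, binning, cutpoints)
        else:
            traj = pd.DataFrame(columns=list(binning.bin_labels))
            traj.index.name = "gene_id"
        _write_tsv(traj, out_dir / "high_expression_proportion.tsv", index=True)
        manifest["outputs"]["high_expression_proportion"] = str(
            out_dir / "high_expression_proportion.tsv")

        stage = "subtypes"
        manifest["counts"]["subtypes"] = _subtype_stage(
            cohort, binning, config, out_dir, manifest["outputs"])

        manifest["complete"] = True
    except ExprTrendError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _finish(manifest, out_dir, t0, log_handler)
        raise ExprTrendError(f"stage {stage!r} failed: {exc}") from exc
    return _finish(manifest, out_dir, t0, log_handler)


def _subtype_stage(cohort: Cohort, binning: GroupBinning, config: RunConfig,
                   out_dir: Path, outputs: dict[str, str]) -> dict[str, Any]:
    """Trend-call + enrichment inside each subtype, on the cohort bin edges."""
    counts: dict[str, Any] = {}
    clin = cohort.clinical.table
    if "subtype" not in clin.columns or (clin["subtype"] == "NA").all():
        logger.warning("no subtype labels; per-subtype analyses skipped")
        return counts
    for subtype in config.subtypes:
        patients = clin.loc[clin["subtype"] == subtype, "patient_id"]
        if len(patients) < config.min_subtype_n:
            logger.warning("subtype %s has %d patients (< %d); skipped",
                           subtype, len(patients), config.min_subtype_n)
            counts[subtype] = {"patients": int(len(patients)), "skipped": True}
            continue
        keep = binning.assignment.index.intersection(patients)
        sub_assign = binning.assignment.loc[keep]
        sizes = np.bincount(sub_assign.to_numpy(), minlength=binning.n_bins)
        if (sizes == 0).any():
            logger.warning("subtype %s leaves an empty year bin; skipped", subtype)
            counts[subtype] = {"patients": int(len(patients)), "skipped": True}
            continue
        sub_binning = GroupBinning(bin_edges=binning.bin_edges,
                                   bin_labels=binning.bin_labels,
                                   assignment=sub_assign)
        sub_expr = ExpressionMatrix(cohort.expression.values[list(keep)])
        params = config.trend.resolve(binning.n_bins, sub_expr)
        calls = call_all(sub_expr, sub_binning, params)
        sub_dir = out_dir / f"subtype_{subtype}"
        _write_tsv(calls_frame(calls, binning.bin_labels),
                   sub_dir / "trend_calls.tsv")
        outputs[f"subtype_{subtype}_trend_calls"] = str(sub_dir / "trend_calls.tsv")
        outputs.update(_enrichment_stage(
            calls, cohort.pathways, sub_expr, config, sub_dir,
            prefix=f"subtype_{subtype}_"))
        parts = partition_calls(calls)
        counts[subtype] = {
            "patients": int(len(keep)),
            "up_genes": len(parts["up"]),
            "down_genes": len(parts["down"]),
            "skipped": False,
        }
    return counts


def _config_echo(config: RunConfig) -> dict[str, Any]:
    def _plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [_plain(v) for v in obj]
        return obj
    return _plain(config)


def _finish(manifest: dict[str, Any], out_dir: Path, t0: float,
            log_handler: logging.Handler) -> dict[str, Any]:
    manifest["wall_time_s"] = round(time.perf_counter() - t0, 3)
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    logging.getLogger("exprtrend").removeHandler(log_handler)
    log_handler.close()
    return manifest


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file, with keyword overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return config_from_dict(raw)


def config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    data = dict(raw)
    if (sim := data.get("simulate")) is not None and not isinstance(sim, SimConfig):
        sim = dict(sim)
        if "year_range" in sim:
            sim["year_range"] = tuple(sim["year_range"])
        if "subtype_probs" in sim:
            sim["subtype_probs"] = tuple(sim["subtype_probs"])
        data["simulate"] = SimConfig(**sim)
    if (tr := data.get("trend")) is not None and not isinstance(tr, TrendParams):
        data["trend"] = TrendParams(**tr)
    if (hb := data.get("hub")) is not None and not isinstance(hb, HubCriteria):
        data["hub"] = HubCriteria(**hb)
    for key in ("explicit_edges", "subtypes"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    unknown = set(data) - {f.name for f in dataclasses.fields(RunConfig)}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
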