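"""End-to-end orchestration: focus -> grid search -> QC gate -> smooth ->
metrics -> RSEA -> ensemble, per branch, with deterministic seeding."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .association_metrics import ALL_METRICS
from .baselines_eval import curve_to_frame, precision_recall
from .io_formats import BranchMatrix, MarkerSet, Regulon, write_results
from .pseudotime_prep import UnbinnableBranch, focus_branch, raw_bypass_bins
from .rsea import run_rsea_branch
from .spline_model import (
    CV_THRESHOLD,
    DEFAULT_BINS_GRID,
    DEFAULT_SMOOTHING_GRID,
    hyperparameter_search,
    smooth_branch,
    stable_seed,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run; every key has a default."""

    iqr_factor: float = 1.5
    min_cells_per_bin: int = 10
    raw_bypass: bool = False
    bins_grid: tuple[int, ...] = DEFAULT_BINS_GRID
    smoothing_grid: tuple[float, ...] = DEFAULT_SMOOTHING_GRID
    subsample_frac: float = 0.8
    subsample_reps: int = 30
    cv_threshold: float = CV_THRESHOLD
    n_search_genes: int = 100
    metrics: tuple[str, ...] = ALL_METRICS
    n_mi_bins: int = 8
    max_lag: int | None = None
    focus_percentile: float = 25.0
    alpha: float = 0.05
    background_mode: str = "shared_max"
    background_repeats: int = 5
    min_targets: int = 3
    seed: int = 0
    threads: int = 1

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BranchReport:
    branch_id: str
    n_cells: int
    n_removed_by_focusing: int
    qc: object | None
    status: str  # analyzed | rejected_qc | unbinnable
    reason: str = ""
    results: list = field(default_factory=list)
    ensemble: list = field(default_factory=list)
    untestable: list = field(default_factory=list)


def analyze_branch(
    branch: BranchMatrix, regulons: list[Regulon], config: RunConfig
) -> BranchReport:
    """Run the full per-branch analysis; never raises on QC rejection."""
    focused, n_removed = focus_branch(branch, iqr_factor=config.iqr_factor)
    report = BranchReport(
        branch_id=branch.branch_id,
        n_cells=branch.n_cells,
        n_removed_by_focusing=n_removed,
        qc=None,
        status="analyzed",
    )
    branch_seed = stable_seed(config.seed, f"branch:{branch.branch_id}")
    try:
        qc = hyperparameter_search(
            focused,
            bins_grid=config.bins_grid,
            smoothing_grid=config.smoothing_grid,
            n_search_genes=config.n_search_genes,
            seed=branch_seed,
            frac=config.subsample_frac,
            reps=config.subsample_reps,
            cv_threshold=config.cv_threshold,
            min_cells_per_bin=config.min_cells_per_bin,
            threads=config.threads,
        )
    except UnbinnableBranch as exc:
        report.status = "unbinnable"
        report.reason = str(exc)
        return report
    report.qc = qc
    if not qc.accepted:
        report.status = "rejected_qc"
        report.reason = f"coefficient of variation {qc.cv:.4g} exceeds {config.cv_threshold}"
        return report
    if config.raw_bypass:
        binned = raw_bypass_bins(focused)
        from .spline_model import fit_gene_spline

        smoothed_values = np.stack([
            fit_gene_spline(binned.bin_means[i], binned.bin_counts, qc.chosen_smoothing).fitted_values
            for i in range(focused.n_genes)
        ])
    else:
        smoothed_values = smooth_branch(focused, qc, min_cells_per_bin=config.min_cells_per_bin)
    smoothed = pd.DataFrame(smoothed_values, index=focused.gene_ids)
    results, ensemble, untestable = run_rsea_branch(
        smoothed,
        regulons,
        metrics=config.metrics,
        alpha=config.alpha,
        seed=branch_seed,
        focus_percentile=config.focus_percentile,
        min_targets=config.min_targets,
        max_lag=config.max_lag,
        n_mi_bins=config.n_mi_bins,
        background_mode=config.background_mode,
        background_repeats=config.background_repeats,
        branch_id=branch.branch_id,
    )
    report.results = results
    report.ensemble = ensemble
    report.untestable = untestable
    return report


def run(
    matrix_path: str | Path,
    cells_path: str | Path,
    regulons_path: str | Path,
    output_dir: str | Path,
    config: RunConfig,
    genes_path: str | Path | None = None,
    cell_names_path: str | Path | None = None,
    species: str = "human",
    ortholog_map: str | Path | None = None,
) -> list[BranchReport]:
    """Full pipeline over every branch; writes result tables, a QC report and
    a machine-readable manifest to ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = io_formats.read_expression(matrix_path, genes_path, cell_names_path)
    records = io_formats.read_cell_metadata(cells_path)
    regulons = io_formats.read_regulons(
        regulons_path, species=species, ortholog_map=ortholog_map,
        min_targets=config.min_targets,
    )
    branches = io_formats.split_branches(matrix, records)
    reports = []
    ens_rows = []
    qc_rows = []
    for branch in branches:
        rep = analyze_branch(branch, regulons, config)
        reports.append(rep)
        qc_rows.append(
            {
                "branch_id": rep.branch_id,
                "n_cells": rep.n_cells,
                "n_removed_by_focusing": rep.n_removed_by_focusing,
                "chosen_n_bins": rep.qc.chosen_n_bins if rep.qc else "",
                "chosen_smoothing": rep.qc.chosen_smoothing if rep.qc else "",
                "mean_aic": rep.qc.mean_aic if rep.qc else "",
                "cv": rep.qc.cv if rep.qc else "",
                "accepted": rep.qc.accepted if rep.qc else False,
                "status": rep.status,
                "reason": rep.reason,
            }
        )
        if rep.status != "analyzed":
            continue
        write_results(rep.results, out / f"results_{rep.branch_id}.tsv")
        for e in rep.ensemble:
            row = {"tf": e.tf, "branch_id": e.branch_id,
                   "best_metric": e.best_metric, "best_fdr": e.best_fdr}
            row.update({f"fdr_{m}": e.per_metric.get(m, np.nan) for m in config.metrics})
            ens_rows.append(row)
        if rep.untestable:
            pd.DataFrame(
                [{"tf": u.tf, "metric": u.metric, "reason": u.reason} for u in rep.untestable]
            ).to_csv(out / f"untestable_{rep.branch_id}.tsv", sep="\t", index=False)
    pd.DataFrame(qc_rows).to_csv(out / "qc_report.tsv", sep="\t", index=False,
                                 float_format="%.12g")
    ens_df = pd.DataFrame(ens_rows)
    ens_df.to_csv(out / "ensemble.tsv", sep="\t", index=False, float_format="%.12g")
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_branches": len(branches),
        "n_regulons": len(regulons),
        "package_version": _version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return reports


def evaluate(
    results_path: str | Path,
    markers: MarkerSet,
    output_dir: str | Path | None = None,
) -> dict[str, object]:
    """Precision-recall evaluation of an ensemble table against marker TFs.

    Produces one curve per branch plus an aggregate curve over pooled
    (TF, branch) pairs.
    """
    df = pd.read_csv(results_path, sep="\t", dtype={"tf": str, "branch_id": str})
    if df.empty:
        raise ValueError("empty results table")
    curves: dict[str, object] = {}
    for branch_id, grp in df.groupby("branch_id"):
        ranked = list(zip(grp["tf"], grp["best_fdr"].astype(float)))
        try:
            curves[str(branch_id)] = precision_recall(ranked, markers)
        except ValueError as exc:
            logger.warning("branch %s: %s", branch_id, exc)
    ranked_all = list(zip(df["tf"], df["best_fdr"].astype(float)))
    curves["aggregate"] = precision_recall(ranked_all, markers)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, curve in curves.items():
            curve_to_frame(curve).to_csv(out / f"curve_{name}.tsv", sep="\t",
                                         index=False, float_format="%.12g")
    return curves


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("branchtf")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
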