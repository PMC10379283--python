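"""Per-species orchestration of the full analysis with one reproducible report.

One invocation runs, per species: locality ingestion, optional resampling of
the predictor stack, point extraction with complete-case filtering, Pearson
screening, PCA + HCPC, the island/mainland Wilcoxon test, the tree-count
grid search, jackknife validation, importance normalisation, MESS against
the training localities, the validity mask, and the masked Ho projection.
A stage failure aborts that species with a machine-readable failure record;
other species continue.  All randomness derives from the single config seed
via a stage-name hash, and the JSON report contains no timestamps so two
identical runs produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import multivariate, plots
from .grid import (
    PREDICTORS,
    Raster,
    extract_at_points,
    read_stack,
    resample_stack,
    write_ascii_grid,
)
from .localities import read_localities
from .mess import compute_mess, validity_mask
from .projection import project_ho
from .rf import RFConfig, grid_search_trees, jackknife_validate, normalize_importance

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    localities: Path
    rasters: Path
    output: Path
    species: tuple[str, ...] = ("rattus", "norvegicus")
    seed: int = 0
    resolution_arcmin: Optional[float] = None   # resample target; None = as-is
    rf: RFConfig = field(default_factory=RFConfig)
    mask_rule: str = "median_positive"
    pca_include_ho: bool = True
    localities_columns: dict = field(default_factory=dict)
    write_plots: bool = True
    do_projection: bool = True  # False: stop after the statistics + forest

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        rf_raw = raw.get("rf", {})
        rf = RFConfig(
            tree_grid=tuple(rf_raw.get("tree_grid", RFConfig().tree_grid)),
            variables_per_split=rf_raw.get("variables_per_split", 2),
            min_node_size=rf_raw.get("min_node_size", 5),
            seed=raw.get("seed", 0),
        )
        cfg = cls(
            localities=Path(raw["localities"]),
            rasters=Path(raw["rasters"]),
            output=Path(raw["output"]),
            species=tuple(raw.get("species", ("rattus", "norvegicus"))),
            seed=int(raw.get("seed", 0)),
            resolution_arcmin=raw.get("resolution_arcmin"),
            rf=rf,
            mask_rule=raw.get("mask_rule", "median_positive"),
            pca_include_ho=bool(raw.get("pca_include_ho", True)),
            localities_columns=dict(
                raw.get("localities", {}).get("columns", {})
                if isinstance(raw.get("localities"), dict)
                else raw.get("localities_columns", {})
            ),
            write_plots=bool(raw.get("write_plots", True)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.localities, self.rasters):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def stage_seed(base: int, species: str, stage: str) -> int:
    """Deterministic per-stage seed: stage name hashed with the base seed."""
    return (zlib.crc32(f"{species}:{stage}".encode()) ^ base) % (2**31)


def _run_species(config: RunConfig, species: str, stack) -> dict:
    out_dir = Path(config.output) / species
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"species": species}

    records, parse_report = read_localities(
        config.localities, species_filter=species,
        columns=config.localities_columns or None,
    )
    report["counts"] = {
        "read": parse_report.n_read,
        "rejected": dict(parse_report.rejected),
        "duplicates": parse_report.n_duplicates,
        "input": len(records),
    }
    table, dropped = extract_at_points(stack, records)
    ins = table.meta["insularity"]
    report["counts"].update(
        {
            "dropped_nodata": dropped,
            "retained": table.n,
            "island": int((ins == "island").sum()),
            "mainland": int((ins == "mainland").sum()),
        }
    )
    assert report["counts"]["input"] == table.n + dropped

    corr = multivariate.correlation_screen(table)
    corr.to_csv(out_dir / "correlations.csv")
    report["correlations"] = {
        name: {"r": _num(row.r), "p": _num(row.p)}
        for name, row in corr.table.iterrows()
    }

    pca = multivariate.run_pca(table, include_ho=config.pca_include_ho)
    clusters = multivariate.hcpc(pca)
    labels_df = table.meta[["study_id", "site", "lon", "lat"]].copy()
    labels_df["cluster"] = clusters.labels
    labels_df.to_csv(out_dir / "clusters.csv", index=False)
    report["pca"] = {
        "explained": [float(e) for e in pca.explained],
        "include_ho": config.pca_include_ho,
    }
    report["hcpc"] = {
        "k": int(clusters.k),
        "n_components_used": int(clusters.n_components_used),
    }

    try:
        w_stat, w_p = multivariate.island_mainland_test(table)
        report["wilcoxon_island_mainland"] = {"U": w_stat, "p": w_p}
    except ValueError as exc:  # a group may be empty; not fatal to the run
        report["wilcoxon_island_mainland"] = {"error": str(exc)}

    rf_config = RFConfig(
        tree_grid=config.rf.tree_grid,
        variables_per_split=config.rf.variables_per_split,
        min_node_size=config.rf.min_node_size,
        seed=stage_seed(config.seed, species, "rf"),
    )
    fit = grid_search_trees(table, rf_config)
    jk_config = RFConfig(
        tree_grid=rf_config.tree_grid,
        variables_per_split=rf_config.variables_per_split,
        min_node_size=rf_config.min_node_size,
        seed=stage_seed(config.seed, species, "jackknife"),
    )
    pred, jk_rmse, r2, p = jackknife_validate(table, jk_config, fit.n_trees)
    fit.jackknife_pred, fit.jackknife_rmse = pred, jk_rmse
    fit.obs_pred_r2, fit.obs_pred_p = r2, p
    importance_norm = normalize_importance(fit.importance_raw)
    report["random_forest"] = {
        "n_trees": fit.n_trees,
        "oob_rmse": _num(fit.oob_rmse),
        "oob_rmse_grid": {str(k): _num(v) for k, v in fit.oob_rmse_grid.items()},
        "oob_coverage": _num(fit.oob_coverage),
        "importance_raw": {k: _num(v) for k, v in fit.importance_raw.items()},
        "importance_norm": {k: _num(v) for k, v in importance_norm.items()},
        "jackknife_rmse": _num(jk_rmse),
        "obs_pred_r2": _num(r2),
        "obs_pred_p": _num(p),
        "seed": rf_config.seed,
        "jackknife_seed": jk_config.seed,
    }
    imp_path = out_dir / "importance.csv"
    with imp_path.open("w") as fh:
        fh.write("predictor,importance_raw,importance_norm\n")
        for name in PREDICTORS:
            fh.write(f"{name},{fit.importance_raw[name]!r},{importance_norm[name]!r}\n")

    if not config.do_projection:
        if config.write_plots:
            plots.pca_biplot(pca, table, out_dir / "pca_biplot.png")
            plots.obs_vs_pred(table.ho, pred, r2, p, out_dir / "obs_vs_pred.png")
        return report

    mess_result = compute_mess(table, stack)
    mask = validity_mask(mess_result, rule=config.mask_rule)
    write_ascii_grid(
        Raster(values=mess_result.mess, geometry=stack.geometry),
        out_dir / "mess.asc",
    )
    write_ascii_grid(
        Raster(values=mask.keep.astype(float), geometry=stack.geometry, nodata=255),
        out_dir / "mask.asc", fmt="%d",
    )
    report["mess"] = {
        "threshold": _num(mask.threshold),
        "rule": mask.rule,
        "n_positive": int(np.sum(mess_result.mess[np.isfinite(mess_result.mess)] > 0)),
        "n_keep": int(mask.keep.sum()),
    }

    projection = project_ho(fit, stack, mask)
    write_ascii_grid(projection.predicted, out_dir / "predicted_ho.asc")
    write_ascii_grid(projection.unmasked, out_dir / "predicted_ho_unmasked.asc")
    finite = projection.predicted.values[np.isfinite(projection.predicted.values)]
    report["projection"] = {
        "n_predicted": projection.n_predicted,
        "ho_range_training": [float(v) for v in projection.ho_range],
        "ho_range_predicted": (
            [float(finite.min()), float(finite.max())] if finite.size else None
        ),
    }

    if config.write_plots:
        plots.pca_biplot(pca, table, out_dir / "pca_biplot.png")
        plots.obs_vs_pred(table.ho, pred, r2, p, out_dir / "obs_vs_pred.png")

    return report


def _num(x) -> Optional[float]:
    x = float(x)
    return None if not np.isfinite(x) else x


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline for every configured species; write the report.

    Returns the report dict (also written to ``<output>/report.json``).  A
    failed species carries ``{"failed": ..., "stage": ...}`` instead of
    results; remaining species still run.
    """
    config.validate()
    out_dir = Path(config.output)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = read_stack(config.rasters)
    if config.resolution_arcmin is not None:
        stack = resample_stack(stack, config.resolution_arcmin)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "mask_rule": config.mask_rule,
        "resolution_arcmin": config.resolution_arcmin,
        "species": {},
    }
    for species in config.species:
        try:
            report["species"][species] = _run_species(config, species, stack)
        except Exception as exc:  # keep other species alive
            logger.exception("species %s failed", species)
            report["species"][species] = {
                "failed": str(exc),
                "stage": type(exc).__name__,
            }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
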