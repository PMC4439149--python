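"""End-to-end orchestration: simulate -> ingest -> grid -> terrain ->
autocorrelation -> hotspots -> reef metrics -> model -> report.

Every stage writes plain-text artefacts (CSV, GeoJSON, ASCII grid, JSON)
into the output directory, and a run manifest records the configuration
hash, input digests and per-stage counts so any artefact can be traced to
the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .gridding import aggregate_cpue, assign_to_cells, build_grid, \
    cpue_layers_to_geojson
from .hotspots import binarize, cumulative_overlay, hotspot_recovery_score, \
    reef_fraction_fished
from .ingest import ingest, load_logbook, load_swipes
from .raster import Raster, mask_to_geojson, read_ascii, write_ascii
from .spatial import build_weights, local_gi_star, morans_profile, \
    profile_to_frame
from .synth import FisheryConfig, GroundTruth, SeafloorConfig, \
    default_scenario, generate_dem, generate_fishery
from .terrain import cell_means, compute_stack, screen_collinearity
from .cpue_model import CPUEModel, build_model_frame


@dataclass
class RunManifest:
    config_digest: str
    package_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 swipes_path: str | Path | None = None,
                 logbook_path: str | Path | None = None,
                 dem_path: str | Path | None = None,
                 reef_mask_path: str | Path | None = None) -> dict:
    """Execute the full workflow; returns key results and artefact paths.

    With ``config.simulate`` (the default) the synthetic scenario generates
    the inputs; otherwise paths to swipes/logbook CSVs, a DEM ASCII grid and
    a reef mask ASCII grid must be supplied.  Idempotent given identical
    configuration and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_digest=config.digest(),
                           package_version=__version__)
    truth: GroundTruth | None = None

    # -- inputs ---------------------------------------------------------
    if config.simulate:
        sea, fishery, _, _ = default_scenario(config.seed)
        dem, reef_mask = sea.dem, sea.reef_mask
        swipes, effort, truth = fishery.swipes, fishery.effort, fishery.truth
        write_ascii(dem, outdir / "dem.asc")
        write_ascii(reef_mask.like(reef_mask.data.astype(float)),
                    outdir / "reef_mask.asc")
        mask_to_geojson(reef_mask, outdir / "reef_mask.geojson")
        swipes.to_csv(outdir / "swipes.csv", index=False)
        effort.to_csv(outdir / "logbook.csv", index=False)
        truth.to_json(outdir / "ground_truth.json")
    else:
        if not all([swipes_path, logbook_path, dem_path, reef_mask_path]):
            raise ValueError("simulate=False requires swipes, logbook, DEM "
                             "and reef-mask paths")
        swipes = load_swipes(swipes_path)
        effort = load_logbook(logbook_path)
        dem = read_ascii(dem_path)
        rm = read_ascii(reef_mask_path)
        reef_mask = rm.like(rm.data > 0.5)
        for name, p in [("swipes", swipes_path), ("logbook", logbook_path),
                        ("dem", dem_path), ("reef_mask", reef_mask_path)]:
            manifest.input_digests[name] = _file_digest(Path(p))
    manifest.stage_counts["swipes_in"] = len(swipes)

    # -- ingest -----------------------------------------------------------
    retained, report = ingest(swipes, effort, reef_mask,
                              speed_threshold_m_s=config.speed_threshold,
                              buffer_m=config.reef_buffer)
    report.to_json(outdir / "filter_report.json")
    retained.to_csv(outdir / "retained_records.csv", index=False)
    manifest.stage_counts["swipes_retained"] = len(retained)
    manifest.warnings.extend(report.warnings)

    # -- gridding ----------------------------------------------------------
    grid = build_grid(dem.extent, config.cell_size, origin=(dem.x0, dem.y0))
    tagged, n_outside = assign_to_cells(retained, grid)
    if n_outside:
        manifest.warnings.append(f"{n_outside} records outside the grid extent")
    cpue = aggregate_cpue(tagged, grid)
    cpue.to_csv(outdir / "cell_cpue.csv", index=False)
    cpue_layers_to_geojson(cpue, grid, outdir / "cell_cpue.geojson")
    manifest.stage_counts["cpue_cell_years"] = len(cpue)

    # -- terrain ----------------------------------------------------------
    stack = compute_stack(dem, config.bpi_inner, config.bpi_outer,
                          config.terrain_window)
    covars = cell_means(stack, dem, grid)
    covars.to_csv(outdir / "cell_covariates.csv", index=False)
    retained_vars, dropped_vars = screen_collinearity(
        covars, config.collinearity_threshold)
    (outdir / "collinearity.json").write_text(json.dumps(
        {"retained": retained_vars, "dropped": dropped_vars}, indent=1))
    manifest.stage_counts["covariate_cells"] = len(covars)

    # -- spatial statistics (per year, fished cells only) ------------------
    years = sorted(cpue["year"].unique())
    profile_rows = []
    gi_frames = []
    layers = []
    for year in years:
        sub = cpue[cpue["year"] == year]
        cents = grid.centroids(sub["cell_id"].to_numpy())
        values = sub["cpue_kg_per_h"].to_numpy()
        results, errors = morans_profile(values, cents, config.bands,
                                         variance=config.moran_variance)
        pf = profile_to_frame(results)
        pf.insert(0, "year", year)
        profile_rows.append(pf)
        for band, msg in errors.items():
            manifest.warnings.append(f"Moran {year} band {band}: {msg}")
        w = build_weights(cents, config.gi_band, include_self=True)
        gi = local_gi_star(values, w)
        gdf = pd.DataFrame({"year": year, "cell_id": sub["cell_id"].to_numpy(),
                            "gi_star_z": gi.gi_star})
        gi_frames.append(gdf)
        layers.append(binarize(gi, sub["cell_id"].to_numpy(), year,
                               config.z_threshold))
    profile = pd.concat(profile_rows, ignore_index=True)
    profile.to_csv(outdir / "moran_profile.csv", index=False)
    gi_all = pd.concat(gi_frames, ignore_index=True)
    gi_all.to_csv(outdir / "gi_star.csv", index=False)

    # -- hotspots -----------------------------------------------------------
    cum = cumulative_overlay(layers)
    cum_df = cum.to_frame()
    cum_df.to_csv(outdir / "cumulative_hotspots.csv", index=False)
    hot_any = cum.cells_with_class(1)

    fished_cells = set(map(int, cpue["cell_id"].unique()))
    depth_means = covars.set_index("cell_id")["depth_mean"]
    metrics = reef_fraction_fished(fished_cells, reef_mask, grid,
                                   depth_means=depth_means,
                                   depth_band=config.depth_band,
                                   hot_cells=hot_any,
                                   cover_threshold=config.reef_cover_threshold)
    metrics.to_json(outdir / "reef_metrics.json")

    recovery = None
    if truth is not None:
        truth_ids = {int(grid.linear(r, c)) for r, c in truth.all_hotspot_cells()}
        recovery = hotspot_recovery_score(cum, truth_ids, fished_cells)
        (outdir / "hotspot_recovery.json").write_text(json.dumps(
            {"sensitivity": recovery[0], "specificity": recovery[1]}, indent=1))

    # -- additive model -----------------------------------------------------
    frame = build_model_frame(cpue, covars)
    model = CPUEModel(frame)
    fit = model.fit()
    fit.report(outdir / "model_report.json")
    for term in model.smooth_terms:
        fit.partial_effects(term).to_csv(
            outdir / f"partial_{term.removesuffix('_mean')}.csv", index=False)

    # -- report -------------------------------------------------------------
    summary = {
        "moran_profile": profile.to_dict(orient="records"),
        "hotspot_class_counts": {int(k): int(v) for k, v in
                                 zip(*np.unique(cum.klass, return_counts=True))},
        "reef_metrics": metrics.to_json(),
        "model": fit.report(),
        "recovery": None if recovery is None else
            {"sensitivity": recovery[0], "specificity": recovery[1]},
        "collinearity_retained": retained_vars,
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=1))
    manifest.write(outdir / "manifest.json")

    return {
        "grid": grid,
        "cpue": cpue,
        "covariates": covars,
        "profile": profile,
        "gi": gi_all,
        "cumulative": cum,
        "metrics": metrics,
        "recovery": recovery,
        "fit": fit,
        "report": summary,
        "outdir": outdir,
    }
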