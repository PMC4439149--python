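"""Hotspot binarization, cumulative persistence mapping and reef metrics.

Annual Gi* maps are thresholded at z > 1.65 (one-sided 95%) into binary
hot layers; overlaying the annual layers gives each cell a persistence
class equal to the number of years it was a significant hotspot (1..Y).
Reef metrics quantify how much of the mapped reef extent was ever fished,
overall and within the 5-15 m preferred diving depth band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gridding import AnalysisGrid
from .raster import Raster
from .spatial import GiResult

Z_THRESHOLD = 1.65


@dataclass
class HotspotLayer:
    """One year's binary hot/cold classification on the fished cells."""

    year: int
    cell_ids: np.ndarray
    hot: np.ndarray
    cold: np.ndarray
    threshold: float = Z_THRESHOLD

    def hot_cells(self) -> set[int]:
        return set(map(int, self.cell_ids[self.hot]))


@dataclass
class CumulativeHotspotMap:
    """Per-cell count of years with a significant hotspot (0..len(years))."""

    cell_ids: np.ndarray
    klass: np.ndarray
    years: tuple[int, ...]

    def cells_with_class(self, minimum: int = 1) -> set[int]:
        return set(map(int, self.cell_ids[self.klass >= minimum]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "class": self.klass})


def binarize(gi: GiResult, cell_ids: np.ndarray, year: int,
             threshold: float = Z_THRESHOLD) -> HotspotLayer:
    """Binary hot (z > threshold) and cold (z < -threshold) layers.

    Inequalities are strict: a cell at exactly the threshold is neither.
    NaN z-scores (cells without a usable statistic) are neither hot nor cold.
    """
    z = np.asarray(gi.gi_star, dtype=float)
    cell_ids = np.asarray(cell_ids)
    if len(z) != len(cell_ids):
        raise ValueError("z-scores and cell ids differ in length")
    with np.errstate(invalid="ignore"):
        hot = z > threshold
        cold = z < -threshold
    return HotspotLayer(year=year, cell_ids=cell_ids, hot=hot, cold=cold,
                        threshold=threshold)


def cumulative_overlay(layers: list[HotspotLayer]) -> CumulativeHotspotMap:
    """Union overlay of annual hot layers as a per-cell year count.

    A cell's class is the number of years in which it was a significant
    hotspot; years need not be consecutive.  Coldspots do not enter the
    cumulative map.
    """
    if not layers:
        raise ValueError("no layers to overlay")
    years = tuple(sorted(l.year for l in layers))
    if len(set(years)) != len(years):
        raise ValueError("duplicate years in overlay")
    all_ids = sorted(set(int(c) for l in layers for c in l.cell_ids))
    index = {c: k for k, c in enumerate(all_ids)}
    klass = np.zeros(len(all_ids), dtype=int)
    for l in layers:
        for c in l.cell_ids[l.hot]:
            klass[index[int(c)]] += 1
    return CumulativeHotspotMap(cell_ids=np.array(all_ids), klass=klass,
                                years=years)


# ---------------------------------------------------------------------------
# reef metrics
# ---------------------------------------------------------------------------

@dataclass
class ReefMetrics:
    reef_area_cells: int
    fished_cells: int            # reef cells with any-year effort
    hot_cells_any_year: int
    fraction_fished: float
    reef_area_cells_5_15m: int
    fished_cells_5_15m: int
    fraction_fished_5_15m: float
    depth_band: tuple[float, float] = (5.0, 15.0)
    reef_cover_threshold: float = 0.5

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.__dict__.items()}
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc


def reef_cells(reef_mask: Raster, grid: AnalysisGrid,
               cover_threshold: float = 0.5) -> set[int]:
    """Grid cells whose reef pixel coverage is at least ``cover_threshold``."""
    mask = reef_mask.data.astype(bool)
    xs = reef_mask.x0 + (np.arange(reef_mask.n_cols) + 0.5) * reef_mask.resolution
    ys = reef_mask.y0 + (np.arange(reef_mask.n_rows) + 0.5) * reef_mask.resolution
    xg, yg = np.meshgrid(xs, ys)
    row, col, inside = grid.cell_index(xg.ravel(), yg.ravel())
    cell = grid.linear(row, col)
    reef_counts = np.bincount(cell[inside & mask.ravel()], minlength=grid.n_cells)
    all_counts = np.bincount(cell[inside], minlength=grid.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(all_counts > 0, reef_counts / np.maximum(all_counts, 1), 0.0)
    return set(map(int, np.nonzero(frac >= cover_threshold)[0]))


def reef_fraction_fished(cells_with_effort: set[int] | np.ndarray,
                         reef_mask: Raster, grid: AnalysisGrid,
                         depth_means: pd.Series | None = None,
                         depth_band: tuple[float, float] = (5.0, 15.0),
                         hot_cells: set[int] | None = None,
                         cover_threshold: float = 0.5) -> ReefMetrics:
    """Fraction of the mapped reef extent fished in any year.

    Denominators are reef cells (coverage >= ``cover_threshold``);
    numerators are reef cells with any-year effort.  The depth-banded
    variant restricts both sides to cells whose mean depth lies inside
    ``depth_band`` (requires ``depth_means`` indexed by cell_id).
    """
    reef = reef_cells(reef_mask, grid, cover_threshold)
    if not reef:
        raise ValueError("no reef cells at this coverage threshold")
    effort = set(map(int, cells_with_effort))
    fished = reef & effort
    hot = (set(map(int, hot_cells)) & reef) if hot_cells is not None else set()

    if depth_means is not None:
        lo, hi = depth_band
        in_band = set(int(c) for c, d in depth_means.items()
                      if np.isfinite(d) and lo <= d <= hi)
        reef_band = reef & in_band
        fished_band = fished & in_band
        frac_band = (len(fished_band) / len(reef_band)) if reef_band else float("nan")
    else:
        reef_band, fished_band, frac_band = set(), set(), float("nan")

    return ReefMetrics(
        reef_area_cells=len(reef),
        fished_cells=len(fished),
        hot_cells_any_year=len(hot),
        fraction_fished=len(fished) / len(reef),
        reef_area_cells_5_15m=len(reef_band),
        fished_cells_5_15m=len(fished_band),
        fraction_fished_5_15m=frac_band,
        depth_band=depth_band,
        reef_cover_threshold=cover_threshold,
    )


def hotspot_recovery_score(detected: CumulativeHotspotMap,
                           truth_cells: set[int],
                           fished_cells: set[int]) -> tuple[float, float]:
    """Sensitivity/specificity of detected hotspots against planted truth.

    sensitivity: fraction of planted hotspot cells with class >= 1;
    specificity: fraction of fished-but-not-planted cells with class 0.
    """
    if not truth_cells:
        raise ValueError("empty ground truth")
    det = detected.cells_with_class(1)
    tp = len(truth_cells & det)
    sensitivity = tp / len(truth_cells)
    negatives = set(map(int, fished_cells)) - set(map(int, truth_cells))
    if negatives:
        tn = len(negatives - det)
        specificity = tn / len(negatives)
    else:
        specificity = float("nan")
    return sensitivity, specificity
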