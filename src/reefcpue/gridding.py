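"""1-ha analysis grid and per-cell, per-year CPUE aggregation.

CPUE is the ratio of sums: total retained catch weight in a cell divided by
total apportioned hours, per year.  Cells with no effort carry no CPUE value
at all — unfished seafloor is absent from the statistics, not zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AnalysisGrid:
    """A regular rectangular grid of square cells (default 1 ha).

    Cells are half-open: cell (i, j) covers
    [x0 + j s, x0 + (j+1) s) x [y0 + i s, y0 + (i+1) s); a point exactly on
    an interior boundary belongs to the higher-index cell.  Linear cell ids
    are row-major: id = row * n_cols + col.
    """

    x0: float
    y0: float
    cell_size: float
    n_cols: int
    n_rows: int

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_index(self, x, y):
        """(rows, cols, inside) for points; half-open membership."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside

    def linear(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def centroids(self, cell_id=None) -> np.ndarray:
        """(N, 2) centroid coordinates for all cells or the given ids."""
        if cell_id is None:
            cell_id = np.arange(self.n_cells)
        row, col = self.rowcol(cell_id)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (row + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def cell_polygon(self, cell_id) -> list[list[float]]:
        row, col = self.rowcol(np.asarray(cell_id))
        s = self.cell_size
        x, y = self.x0 + col * s, self.y0 + row * s
        return [[x, y], [x + s, y], [x + s, y + s], [x, y + s], [x, y]]


def build_grid(extent: tuple[float, float, float, float],
               cell_size: float = 100.0,
               origin: tuple[float, float] | None = None) -> AnalysisGrid:
    """Grid covering ``extent`` with ceil-rule cell counts.

    ``origin`` (default the extent's lower-left corner) lets the grid snap
    to a DEM origin so terrain zonal means align exactly.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate extent")
    ox, oy = origin if origin is not None else (x0, y0)
    n_cols = int(np.ceil((x1 - ox) / cell_size))
    n_rows = int(np.ceil((y1 - oy) / cell_size))
    return AnalysisGrid(x0=ox, y0=oy, cell_size=cell_size,
                        n_cols=n_cols, n_rows=n_rows)


def assign_to_cells(records: pd.DataFrame, grid: AnalysisGrid
                    ) -> tuple[pd.DataFrame, int]:
    """Tag records with their containing cell; out-of-extent rows dropped.

    Returns (tagged records, n_dropped_outside).
    """
    row, col, inside = grid.cell_index(records["x_m"].to_numpy(),
                                       records["y_m"].to_numpy())
    out = records.loc[inside].copy()
    out["cell_id"] = grid.linear(row[inside], col[inside])
    return out, int((~inside).sum())


def aggregate_cpue(records: pd.DataFrame, grid: AnalysisGrid,
                   year: int | None = None) -> pd.DataFrame:
    """Per-cell, per-year CPUE layer (kg per hour).

    Requires ``weight_kg`` and ``apportioned_hours`` on the records.  CPUE
    is sum(catch)/sum(effort) per cell-year; cells with zero effort are
    simply absent.  Pass ``year`` to restrict to one fishing year.
    """
    for colname in ("weight_kg", "apportioned_hours"):
        if colname not in records.columns:
            raise ValueError(f"records lack required column {colname!r}")
    df = records
    if "cell_id" not in df.columns:
        df, _ = assign_to_cells(df, grid)
    if year is not None:
        df = df[df["year"] == year]
    agg = (df.groupby(["cell_id", "year"])
             .agg(catch_kg=("weight_kg", "sum"),
                  effort_h=("apportioned_hours", "sum"),
                  n_swipes=("weight_kg", "size"))
             .reset_index())
    agg = agg[agg["effort_h"] > 0].copy()
    agg["cpue_kg_per_h"] = agg["catch_kg"] / agg["effort_h"]
    return agg.sort_values(["year", "cell_id"], kind="mergesort").reset_index(drop=True)


def cpue_layers_to_geojson(cpue: pd.DataFrame, grid: AnalysisGrid,
                           path: str | Path | None = None) -> dict:
    """CPUE cells as GeoJSON polygons (one feature per cell-year)."""
    features = []
    for rec in cpue.itertuples(index=False):
        features.append({
            "type": "Feature",
            "properties": {
                "cell_id": int(rec.cell_id),
                "year": int(rec.year),
                "catch_kg": float(rec.catch_kg),
                "effort_h": float(rec.effort_h),
                "cpue_kg_per_h": float(rec.cpue_kg_per_h),
                "n_swipes": int(rec.n_swipes),
            },
            "geometry": {"type": "Polygon",
                         "coordinates": [grid.cell_polygon(rec.cell_id)]},
        })
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc
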