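"""Minimal single-band raster container and plain-text I/O.

The pipeline works entirely in a projected metric plane.  Rasters are stored
row 0 = southmost (y increases with the row index); the ESRI ASCII grid
format on disk is north-up, so readers/writers flip vertically.  Plain-text
formats (ASCII grid, GeoJSON) keep every artefact diffable and portable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    data : ndarray, shape (n_rows, n_cols)
        Cell values; row 0 is the southmost row.
    x0, y0 : float
        Coordinates of the lower-left (south-west) corner, metres.
    resolution : float
        Cell edge length, metres.
    nodata : float
        Sentinel for missing cells.
    """

    data: np.ndarray
    x0: float
    y0: float
    resolution: float
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the covered rectangle."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.n_cols * self.resolution,
            self.y0 + self.n_rows * self.resolution,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of column-centre x and row-centre y coordinates."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.resolution
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.resolution
        return xs, ys

    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata, finite cells."""
        d = self.data
        if d.dtype == bool:
            return np.ones_like(d, dtype=bool)
        return np.isfinite(d) & (d != self.nodata)

    def like(self, data: np.ndarray) -> "Raster":
        """A raster with the same geometry but different values."""
        return replace(self, data=np.asarray(data))

    def pixel_index(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of the pixel containing each point (half-open cells).

        Returns (rows, cols, inside) where ``inside`` flags points within the
        raster extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.resolution).astype(int)
        row = np.floor((y - self.y0) / self.resolution).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside

    def sample(self, x, y) -> np.ndarray:
        """Value of the containing pixel; NaN outside the extent."""
        row, col, inside = self.pixel_index(x, y)
        out = np.full(np.shape(row), np.nan, dtype=float)
        out[inside] = self.data[row[inside], col[inside]].astype(float)
        return out


# -- ESRI ASCII grid I/O ----------------------------------------------------

def write_ascii(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (north-up text raster)."""
    path = Path(path)
    data = np.asarray(raster.data, dtype=float).copy()
    data[~raster.valid()] = raster.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.x0:.6f}\n")
        fh.write(f"yllcorner {raster.y0:.6f}\n")
        fh.write(f"cellsize {raster.resolution:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, data[::-1], fmt="%.6g")


def read_ascii(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii` or any GIS."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(value)
            else:  # optional NODATA line absent
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    nodata = header.get("nodata_value", NODATA)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid dimensions do not match header")
    return Raster(
        data=data,
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        resolution=header["cellsize"],
        nodata=nodata,
    )


# -- GeoJSON helpers --------------------------------------------------------

def mask_to_geojson(mask: Raster, path: str | Path | None = None,
                    simplify: float | None = None) -> dict:
    """Vectorise a binary mask raster into GeoJSON polygons.

    Boundaries are traced with marching squares at the 0.5 level; the result
    approximates pixel edges to sub-pixel accuracy, which is sufficient for
    reef-extent exchange.
    """
    from skimage import measure

    data = mask.data.astype(float)
    padded = np.pad(data, 1, constant_values=0.0)
    contours = measure.find_contours(padded, 0.5)
    res = mask.resolution
    features = []
    for ring in contours:
        # ring is (row, col) in padded pixel coordinates
        ys = mask.y0 + (ring[:, 0] - 1 + 0.5) * res
        xs = mask.x0 + (ring[:, 1] - 1 + 0.5) * res
        coords = [[float(x), float(y)] for x, y in zip(xs, ys)]
        if coords[0] != coords[-1]:
            coords.append(coords[0])
        features.append({
            "type": "Feature",
            "properties": {},
            "geometry": {"type": "Polygon", "coordinates": [coords]},
        })
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc


def mask_from_geojson(doc: dict | str | Path, like: Raster) -> Raster:
    """Rasterise GeoJSON polygons onto the grid of ``like``.

    A pixel is reef if its centre falls inside any polygon.
    """
    from shapely.geometry import MultiPolygon, Point, Polygon, shape
    from shapely.prepared import prep

    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    geoms = []
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    for f in feats:
        g = shape(f["geometry"] if "geometry" in f else f)
        if isinstance(g, (Polygon, MultiPolygon)):
            geoms.append(g)
    xs, ys = like.cell_centers()
    out = np.zeros((like.n_rows, like.n_cols), dtype=bool)
    for g in geoms:
        prepared = prep(g)
        minx, miny, maxx, maxy = g.bounds
        j0 = max(0, int(np.floor((minx - like.x0) / like.resolution)) - 1)
        j1 = min(like.n_cols, int(np.ceil((maxx - like.x0) / like.resolution)) + 1)
        i0 = max(0, int(np.floor((miny - like.y0) / like.resolution)) - 1)
        i1 = min(like.n_rows, int(np.ceil((maxy - like.y0) / like.resolution)) + 1)
        for i in range(i0, i1):
            for j in range(j0, j1):
                if not out[i, j] and prepared.contains(Point(xs[j], ys[i])):
                    out[i, j] = True
    return Raster(out, like.x0, like.y0, like.resolution, nodata=like.nodata)
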