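"""Seafloor terrain derivatives from a bathymetric DEM.

Depth is stored positive-down; derivative operators work on elevation
(= -depth) where sign matters, so crests get positive BPI.  All operators
use full-window semantics: a pixel whose window or annulus extends past the
raster edge, or contains nodata, is nodata in the output.

Layers
------
slope        Horn 3x3 finite-difference slope, degrees.
complexity   slope of the slope surface (rate of change of slope).
bpi          bathymetric position index: focal elevation minus the mean
             elevation in an annulus (inner, outer] around the pixel.
rugosity     triangulated 3-D surface area / planar area in a window; >= 1.
vrm          vector ruggedness measure: 1 - |resultant of unit surface
             normals| / n over a window; in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .gridding import AnalysisGrid
from .raster import Raster


def _padded(z: np.ndarray) -> np.ndarray:
    return np.pad(z.astype(float), 1, constant_values=np.nan)


def _horn_gradients(z: np.ndarray, res: float
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Horn-weighted partial derivatives dz/dx, dz/dy and a validity mask."""
    p = _padded(z)
    c = p[1:-1, 1:-1]
    n = p[2:, 1:-1]; s = p[:-2, 1:-1]
    e = p[1:-1, 2:]; w = p[1:-1, :-2]
    ne = p[2:, 2:]; nw = p[2:, :-2]
    se = p[:-2, 2:]; sw = p[:-2, :-2]
    with np.errstate(invalid="ignore"):
        dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8.0 * res)
        dzdy = ((ne + 2 * n + nw) - (se + 2 * s + sw)) / (8.0 * res)
    valid = np.isfinite(c)
    for a in (n, s, e, w, ne, nw, se, sw):
        valid &= np.isfinite(a)
    return dzdx, dzdy, valid


def _masked(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.where(valid, values, np.nan)
    return out


def slope(dem: Raster) -> Raster:
    """Slope in degrees (Horn 3x3 operator).  Sign-free: uses |gradient|."""
    z = np.where(dem.valid(), dem.data.astype(float), np.nan)
    dzdx, dzdy, valid = _horn_gradients(z, dem.resolution)
    deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.like(_masked(deg, valid))


def complexity(dem: Raster) -> Raster:
    """Rate of change of slope: the slope operator applied to the slope raster.

    Planes of any tilt have constant slope, hence zero complexity.
    Units are degrees of slope change per horizontal metre, expressed as an
    angle (the operator output), matching the slope-of-slope convention.
    """
    s = slope(dem)
    z = np.where(np.isfinite(s.data), s.data, np.nan)
    dzdx, dzdy, valid = _horn_gradients(z, dem.resolution)
    deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.like(_masked(deg, valid))


def _annulus_kernel(inner_m: float, outer_m: float, res: float) -> np.ndarray:
    """Binary annulus: centre-to-centre distance d with inner < d <= outer."""
    r = int(np.floor(outer_m / res))
    ii, jj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1),
                         indexing="ij")
    d = res * np.hypot(ii, jj)
    k = ((d > inner_m) & (d <= outer_m)).astype(float)
    if k.sum() == 0:
        raise ValueError("annulus contains no cells at this resolution")
    return k


def bpi(dem: Raster, inner_radius_m: float = 50.0,
        outer_radius_m: float = 150.0) -> Raster:
    """Bathymetric position index on elevation (= -depth).

    Positive on crests, negative in troughs, ~0 on flats and uniform
    slopes.  The annulus takes pixels whose centre distance d from the
    focal centre satisfies inner < d <= outer; output is nodata wherever
    any annulus pixel is missing or off-raster.
    """
    if not 0 < inner_radius_m < outer_radius_m:
        raise ValueError("need outer_radius > inner_radius > 0")
    elev = -dem.data.astype(float)
    valid = dem.valid()
    k = _annulus_kernel(inner_radius_m, outer_radius_m, dem.resolution)
    filled = np.where(valid, elev, 0.0)
    num = ndimage.convolve(filled, k, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), k, mode="constant", cval=0.0)
    full = den >= k.sum() - 0.5  # every annulus pixel present and valid
    with np.errstate(invalid="ignore", divide="ignore"):
        out = elev - num / den
    return dem.like(_masked(out, full & valid))


def _triangle_areas(ax, ay, az, bx, by, bz, cx, cy, cz):
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = cx - ax, cy - ay, cz - az
    nx = uy * vz - uz * vy
    ny = uz * vx - ux * vz
    nz = ux * vy - uy * vx
    return 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)


def rugosity(dem: Raster, window: int = 3) -> Raster:
    """Surface-area to planar-area ratio over a focal window.

    The 3-D surface over the (window-1) x (window-1) cell patch centred on
    the pixel is triangulated (two triangles per cell, diagonal SW-NE
    consistent) using elevation; flat seafloor gives exactly 1.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    z = np.where(dem.valid(), -dem.data.astype(float), np.nan)
    res = dem.resolution
    half = window // 2
    p = np.pad(z, half, constant_values=np.nan)
    rows, cols = z.shape
    surface = np.zeros_like(z)
    valid = np.ones_like(z, dtype=bool)
    # iterate over the (window-1)^2 unit cells of the patch
    for di in range(-half, half):
        for dj in range(-half, half):
            z00 = p[half + di: half + di + rows, half + dj: half + dj + cols]
            z01 = p[half + di: half + di + rows, half + dj + 1: half + dj + 1 + cols]
            z10 = p[half + di + 1: half + di + 1 + rows, half + dj: half + dj + cols]
            z11 = p[half + di + 1: half + di + 1 + rows, half + dj + 1: half + dj + 1 + cols]
            valid &= (np.isfinite(z00) & np.isfinite(z01)
                      & np.isfinite(z10) & np.isfinite(z11))
            a1 = _triangle_areas(0.0, 0.0, z00, res, 0.0, z01, res, res, z11)
            a2 = _triangle_areas(0.0, 0.0, z00, 0.0, res, z10, res, res, z11)
            surface = surface + a1 + a2
    planar = ((window - 1) * res) ** 2
    return dem.like(_masked(surface / planar, valid))


def vrm(dem: Raster, window: int = 3) -> Raster:
    """Vector ruggedness measure: dispersion of unit surface normals.

    vrm = 1 - |sum of unit normals| / n over the window; 0 for flat or
    uniformly tilted terrain (parallel normals), approaching 1 for
    completely disordered terrain.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    z = np.where(dem.valid(), -dem.data.astype(float), np.nan)
    dzdx, dzdy, ok = _horn_gradients(z, dem.resolution)
    norm = np.sqrt(1.0 + dzdx ** 2 + dzdy ** 2)
    nx = np.where(ok, -dzdx / norm, 0.0)
    ny = np.where(ok, -dzdy / norm, 0.0)
    nz = np.where(ok, 1.0 / norm, 0.0)
    k = np.ones((window, window))
    sx = ndimage.convolve(nx, k, mode="constant", cval=0.0)
    sy = ndimage.convolve(ny, k, mode="constant", cval=0.0)
    sz = ndimage.convolve(nz, k, mode="constant", cval=0.0)
    cnt = ndimage.convolve(ok.astype(float), k, mode="constant", cval=0.0)
    full = cnt >= window * window - 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sqrt(sx ** 2 + sy ** 2 + sz ** 2)
        out = 1.0 - r / cnt
    out = np.clip(out, 0.0, 1.0)
    return dem.like(_masked(out, full))


# ---------------------------------------------------------------------------
# stack, zonal means, collinearity screen
# ---------------------------------------------------------------------------

@dataclass
class TerrainStack:
    """Co-registered derivative rasters plus the parameters that made them."""

    layers: dict[str, Raster]
    params: dict = field(default_factory=dict)


def compute_stack(dem: Raster, bpi_inner_m: float = 50.0,
                  bpi_outer_m: float = 150.0, window: int = 3) -> TerrainStack:
    """All five derivatives with the standard parameterisation."""
    return TerrainStack(
        layers={
            "slope": slope(dem),
            "complexity": complexity(dem),
            "bpi": bpi(dem, bpi_inner_m, bpi_outer_m),
            "rugosity": rugosity(dem, window),
            "vrm": vrm(dem, window),
        },
        params={"bpi_inner_m": bpi_inner_m, "bpi_outer_m": bpi_outer_m,
                "window": window},
    )


def cell_means(stack: TerrainStack, dem: Raster, grid: AnalysisGrid
               ) -> pd.DataFrame:
    """Mean of valid pixels of each layer (and depth) per analysis cell.

    Cells with no valid pixel in any layer get no row; a cell missing one
    layer carries NaN in that column.
    """
    layers = {"depth": dem, **stack.layers}
    xs = dem.x0 + (np.arange(dem.n_cols) + 0.5) * dem.resolution
    ys = dem.y0 + (np.arange(dem.n_rows) + 0.5) * dem.resolution
    xg, yg = np.meshgrid(xs, ys)
    row, col, inside = grid.cell_index(xg.ravel(), yg.ravel())
    cell = grid.linear(row, col)
    out: dict[str, np.ndarray] = {}
    n_cells = grid.n_cells
    for name, ras in layers.items():
        vals = np.where(ras.valid(), ras.data.astype(float), np.nan).ravel()
        ok = inside & np.isfinite(vals)
        sums = np.bincount(cell[ok], weights=vals[ok], minlength=n_cells)
        cnts = np.bincount(cell[ok], minlength=n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"{name}_mean"] = np.where(cnts > 0, sums / np.maximum(cnts, 1),
                                           np.nan)
    df = pd.DataFrame(out)
    df.insert(0, "cell_id", np.arange(n_cells))
    keep = df.drop(columns="cell_id").notna().any(axis=1)
    return df.loc[keep].reset_index(drop=True)


DEFAULT_PRIORITY = ("complexity", "bpi", "depth", "slope", "rugosity", "vrm")


def screen_collinearity(cell_table: pd.DataFrame, threshold: float = 0.7,
                        priority: tuple[str, ...] = DEFAULT_PRIORITY
                        ) -> tuple[list[str], dict[str, str]]:
    """Greedy collinearity screen on per-cell covariate means.

    Variables are visited in priority order (complexity and BPI first,
    mirroring the convention of retaining the structural variables); a
    variable correlated above ``threshold`` (|Pearson r|) with any
    already-retained variable is dropped.  Constant variables are dropped
    with a report entry.  Returns (retained, {dropped: reason}).
    """
    cols = {}
    for name in priority:
        for cand in (name, f"{name}_mean"):
            if cand in cell_table.columns:
                cols[name] = cand
                break
    extras = [c for c in cell_table.columns
              if c not in cols.values() and c != "cell_id"
              and np.issubdtype(cell_table[c].dtype, np.number)]
    for c in extras:
        cols[c.removesuffix("_mean")] = c
    if len(cols) < 2:
        raise ValueError("need at least two variables to screen")
    data = cell_table[list(cols.values())].dropna()
    if len(data) < 3:
        raise ValueError("need at least three complete cells")

    retained: list[str] = []
    dropped: dict[str, str] = {}
    for name, colname in cols.items():
        x = data[colname].to_numpy(dtype=float)
        if np.std(x) == 0:
            dropped[name] = "constant (correlation undefined)"
            continue
        clash = None
        for kept in retained:
            y = data[cols[kept]].to_numpy(dtype=float)
            r = np.corrcoef(x, y)[0, 1]
            if abs(r) > threshold:
                clash = (kept, r)
                break
        if clash is None:
            retained.append(name)
        else:
            dropped[name] = f"|r|={abs(clash[1]):.3f} with {clash[0]}"
    return retained, dropped
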