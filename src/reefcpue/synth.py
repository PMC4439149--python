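"""Synthetic seafloor and dive-fishery generator with planted ground truth.

Emulates the data a GPS-logged abalone dive fishery produces: a reef/sediment
bathymetry mosaic, multi-year streams of geo-located shell "swipe" records
from a handful of divers, and per-diver-day logbook hours.  Hotspot centres,
transit artefacts and reef cells are planted and recorded, so every
downstream stage (outlier filtering, gridding, autocorrelation, hotspot
detection) can be scored against exact truth.

All coordinates are generated directly in a projected metric plane;
distance-band statistics downstream require metres, so no geographic CRS
round-trip happens here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SeafloorConfig:
    """Parameters of the synthetic bathymetry.

    extent : (x0, y0, x1, y1) in projected metres.
    resolution : metres per pixel (5 m, the scale of airborne-LiDAR DEMs).
    depth_range : (shallow, deep) metres positive-down; values are clipped
        into this range after synthesis.
    n_reefs : number of disjoint rugose reef bumps planted on the sediment.
    reef_amplitude : vertical relief of each reef bump, metres.
    reef_radius : footprint radius of a reef bump, metres.
    roughness_scale : correlation length of the regional depth field, metres.
    roughness_amplitude : standard deviation of the regional field, metres;
        zero gives a constant-depth plane (plus any reefs).
    reef_roughness_amplitude / reef_roughness_scale : extra fine-scale
        relief applied on reef tops, making reefs rugose and complex.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 4500.0, 3000.0)
    resolution: float = 5.0
    depth_range: tuple[float, float] = (3.0, 25.0)
    n_reefs: int = 3
    reef_amplitude: float = 8.0
    reef_radius: float = 450.0
    roughness_scale: float = 300.0
    roughness_amplitude: float = 4.0
    reef_roughness_amplitude: float = 0.7
    reef_roughness_scale: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate extent: zero or negative area")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not self.depth_range[0] < self.depth_range[1]:
            raise ValueError("depth_range must be (shallow, deep) with shallow < deep")
        if self.n_reefs < 0:
            raise ValueError("n_reefs must be non-negative")


@dataclass
class HotspotCentre:
    """A planted centre of elevated catch rate.

    years=None means active in every simulated year.  intensity is a
    multiplier on the baseline catch rate (swipes per hour in the water).
    """

    x: float
    y: float
    years: tuple[int, ...] | None = None
    intensity: float = 3.0

    def active_in(self, year: int) -> bool:
        return self.years is None or year in self.years


@dataclass
class FisheryConfig:
    """Parameters of the synthetic dive-fishery stream.

    Scale defaults emulate a small commercial zone: 6 divers over four
    years, ~12 dive-days per diver-year at ~5 h each (≈1400 h total).
    Within a dive the diver random-walks within ``diver_drift_radius`` of the
    anchor (the umbilical constraint); swipes arrive at irregular gaps.
    A ``transit_fraction`` of inter-swipe gaps is replaced by vessel-transit
    excursions whose implied straight-line speed is at least
    ``vessel_speed_transit`` — these are the planted outliers.
    """

    years: tuple[int, ...] = (2008, 2009, 2010, 2011)
    n_divers: int = 6
    dives_per_year: int = 12               # dive-days per diver per year
    swipes_per_dive_mean: float = 60.0     # at baseline intensity 1.0
    hotspot_centres: tuple[HotspotCentre, ...] = ()
    background_intensity: float = 1.0
    background_fraction: float = 0.3       # dives anchored off-hotspot grounds
    n_background_grounds: int = 9          # habitual non-hotspot fishing grounds
    ground_jitter_m: float = 120.0         # anchor scatter around a ground
    shell_length_dist: tuple[float, float, float] = (140.0, 12.0, 120.0)  # mean, sd, legal min (mm)
    transit_fraction: float = 0.02
    vessel_speed_transit: float = 3.0      # m/s, ~6 knots
    diver_drift_radius: float = 100.0
    step_sd_m: float = 5.0                 # within-dive walk step SD
    gap_mean_s: float = 40.0
    gap_min_s: float = 20.0
    effort_hours_dist: tuple[float, float] = (5.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")
        if self.n_divers <= 0 or self.dives_per_year <= 0:
            raise ValueError("n_divers and dives_per_year must be positive")
        if self.diver_drift_radius <= 0:
            raise ValueError("diver_drift_radius must be positive")
        if not 0.0 <= self.transit_fraction < 1.0:
            raise ValueError("transit_fraction must be in [0, 1)")
        for c in self.hotspot_centres:
            if c.intensity <= 0:
                raise ValueError("hotspot intensities must be positive")


# ---------------------------------------------------------------------------
# seafloor
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSeafloor:
    dem: Raster           # depth, metres positive-down
    reef_mask: Raster     # boolean
    reef_centres: list[tuple[float, float]]


def _correlated_field(shape: tuple[int, int], scale_px: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Stationary smooth field: Gaussian-filtered white noise, unit SD."""
    noise = rng.standard_normal(shape)
    if scale_px > 0:
        noise = ndimage.gaussian_filter(noise, sigma=scale_px, mode="reflect")
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def generate_dem(config: SeafloorConfig) -> SyntheticSeafloor:
    """Synthesise a depth raster and reef mask with planted reef bumps.

    The seafloor is a smooth sediment surface (correlated random field)
    on which ``n_reefs`` non-overlapping rugose bumps are raised; the reef
    mask is the union of the bump footprints, so it has exactly ``n_reefs``
    connected components.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    x0, y0, x1, y1 = config.extent
    res = config.resolution
    n_cols = int(np.ceil((x1 - x0) / res))
    n_rows = int(np.ceil((y1 - y0) / res))
    shallow, deep = config.depth_range
    mid = 0.5 * (shallow + deep)

    depth = np.full((n_rows, n_cols), mid)
    if config.roughness_amplitude > 0:
        depth = depth + config.roughness_amplitude * _correlated_field(
            (n_rows, n_cols), config.roughness_scale / res, rng)

    # plant non-overlapping reef bumps away from the boundary; candidates
    # maximise spread (best-candidate sampling) so reefs separate widely
    centres: list[tuple[float, float]] = []
    margin = config.reef_radius + 2 * res
    min_sep = 2.0 * config.reef_radius + 100.0
    for _ in range(config.n_reefs):
        placed = False
        for _attempt in range(50):
            cand = np.column_stack([
                rng.uniform(x0 + margin, x1 - margin, 64),
                rng.uniform(y0 + margin, y1 - margin, 64)])
            if centres:
                prev = np.array(centres)
                dmin = np.min(np.hypot(cand[:, 0:1] - prev[None, :, 0],
                                       cand[:, 1:2] - prev[None, :, 1]), axis=1)
            else:
                dmin = np.full(len(cand), np.inf)
            best = int(np.argmax(dmin))
            if dmin[best] >= min_sep:
                centres.append((float(cand[best, 0]), float(cand[best, 1])))
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place non-overlapping reefs; reduce n_reefs or "
                "reef_radius, or enlarge the extent")

    xs = x0 + (np.arange(n_cols) + 0.5) * res
    ys = y0 + (np.arange(n_rows) + 0.5) * res
    xg, yg = np.meshgrid(xs, ys)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    taper = np.zeros((n_rows, n_cols))
    for cx, cy in centres:
        d = np.hypot(xg - cx, yg - cy)
        foot = d <= config.reef_radius
        mask |= foot
        bump = config.reef_amplitude * np.exp(-0.5 * (d / (config.reef_radius / 2.0)) ** 2)
        depth -= np.where(foot, bump, 0.0)
        taper = np.maximum(taper, np.where(foot, bump / max(config.reef_amplitude, 1e-12), 0.0))

    if config.n_reefs and config.reef_roughness_amplitude > 0:
        fine = _correlated_field((n_rows, n_cols),
                                 config.reef_roughness_scale / res, rng)
        depth += config.reef_roughness_amplitude * fine * taper

    depth = np.clip(depth, shallow, deep)
    dem = Raster(depth, x0, y0, res)
    reef = Raster(mask, x0, y0, res)
    return SyntheticSeafloor(dem=dem, reef_mask=reef, reef_centres=centres)


# ---------------------------------------------------------------------------
# fishery
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted structure of a synthetic fishery run.

    hotspot_cells_by_year maps year -> list of (row, col) cells of the
    reference 1-ha analysis grid (origin at the DEM origin) whose centroid
    lies within the diver drift radius of an active planted centre.
    transit_indices are positional row indices into the emitted swipe table.
    """

    hotspot_cells_by_year: dict[int, list[tuple[int, int]]]
    transit_indices: list[int]
    centres: list[HotspotCentre]
    cell_size: float = 100.0

    def all_hotspot_cells(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for cells in self.hotspot_cells_by_year.values():
            out.update(cells)
        return out

    def to_json(self, path: str | Path) -> None:
        doc = {
            "cell_size": self.cell_size,
            "hotspot_cells_by_year": {
                str(y): [list(c) for c in cells]
                for y, cells in self.hotspot_cells_by_year.items()
            },
            "transit_indices": list(map(int, self.transit_indices)),
            "centres": [
                {"x": c.x, "y": c.y,
                 "years": None if c.years is None else list(c.years),
                 "intensity": c.intensity}
                for c in self.centres
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            hotspot_cells_by_year={
                int(y): [tuple(c) for c in cells]
                for y, cells in doc["hotspot_cells_by_year"].items()
            },
            transit_indices=doc["transit_indices"],
            centres=[
                HotspotCentre(d["x"], d["y"],
                              None if d["years"] is None else tuple(d["years"]),
                              d["intensity"])
                for d in doc["centres"]
            ],
            cell_size=doc["cell_size"],
        )


@dataclass
class SyntheticFishery:
    swipes: pd.DataFrame   # diver_id, timestamp, x_m, y_m, shell_length_mm
    effort: pd.DataFrame   # diver_id, date, hours
    truth: GroundTruth


def _truncated_normal(rng: np.random.Generator, n: int, mean: float,
                      sd: float, lower: float) -> np.ndarray:
    """Normal draws truncated below at ``lower`` (vectorised rejection)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        draw = draw[draw >= lower]
        take = min(draw.size, n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _hotspot_cells(centre: HotspotCentre, radius: float, origin: tuple[float, float],
                   cell_size: float) -> list[tuple[int, int]]:
    """Grid cells (row, col) whose rectangle intersects the drift disc.

    These are exactly the cells that can receive swipes from dives anchored
    at the centre, so they are the planted truth for hotspot recovery.
    """
    ox, oy = origin
    j0 = int(np.floor((centre.x - radius - ox) / cell_size))
    j1 = int(np.floor((centre.x + radius - ox) / cell_size))
    i0 = int(np.floor((centre.y - radius - oy) / cell_size))
    i1 = int(np.floor((centre.y + radius - oy) / cell_size))
    cells = []
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            # nearest point of the cell rectangle to the centre
            nx = min(max(centre.x, ox + j * cell_size), ox + (j + 1) * cell_size)
            ny = min(max(centre.y, oy + i * cell_size), oy + (i + 1) * cell_size)
            if np.hypot(nx - centre.x, ny - centre.y) <= radius:
                cells.append((i, j))
    return cells


def generate_fishery(dem: Raster, reef_mask: Raster,
                     config: FisheryConfig) -> SyntheticFishery:
    """Simulate multi-year swipe and logbook streams over a seafloor.

    Each dive-day anchors either at a planted hotspot centre (probability
    proportional to intensity) or at a background reef location; the number
    of swipes scales with the anchor's intensity while logbook hours do not,
    so planted centres carry genuinely higher CPUE.  Within-dive positions
    follow a bounded random walk (displacement never exceeds the drift
    radius); planted transit excursions break the walk with gaps whose
    implied speed is at least ``vessel_speed_transit``.
    """
    rng = np.random.default_rng(config.seed)
    x0, y0, x1, y1 = dem.extent
    res = dem.resolution
    mask = reef_mask.data.astype(bool)
    if not mask.any():
        raise ValueError("reef mask is empty; nowhere to anchor dives")

    for c in config.hotspot_centres:
        if not (x0 <= c.x < x1 and y0 <= c.y < y1):
            raise ValueError(f"hotspot centre ({c.x}, {c.y}) outside DEM extent")
        if not bool(reef_mask.sample(c.x, c.y)):
            raise ValueError(f"hotspot centre ({c.x}, {c.y}) is not on reef")

    # reef pixels with enough clearance for the drift disc
    rows, cols = np.nonzero(mask)
    px = x0 + (cols + 0.5) * res
    py = y0 + (rows + 0.5) * res
    clear = ((px > x0 + config.diver_drift_radius) &
             (px < x1 - config.diver_drift_radius) &
             (py > y0 + config.diver_drift_radius) &
             (py < y1 - config.diver_drift_radius))
    bg_x, bg_y = px[clear], py[clear]
    if bg_x.size == 0:
        bg_x, bg_y = px, py

    # habitual background grounds: a few reef spots away from the planted
    # hotspots (real fleets revisit known grounds rather than covering the
    # full reef extent uniformly)
    keepout = 2.0 * config.diver_drift_radius + 50.0
    grounds: list[tuple[float, float]] = []
    n_grounds = max(1, int(config.n_background_grounds))
    for _ in range(n_grounds):
        best, best_d = None, -1.0
        for _attempt in range(64):
            i = int(rng.integers(0, bg_x.size))
            gx, gy = float(bg_x[i]), float(bg_y[i])
            d_hot = min((np.hypot(gx - c.x, gy - c.y)
                         for c in config.hotspot_centres), default=np.inf)
            if d_hot < keepout:
                continue
            d_grounds = min((np.hypot(gx - qx, gy - qy)
                             for qx, qy in grounds), default=np.inf)
            if d_grounds > best_d:
                best, best_d = (gx, gy), d_grounds
        if best is not None:
            grounds.append(best)
    if not grounds:
        grounds = [(float(bg_x[0]), float(bg_y[0]))]

    sl_mean, sl_sd, sl_min = config.shell_length_dist
    eff_mean, eff_sd = config.effort_hours_dist
    season_days = 300
    day_stride = max(1, season_days // config.dives_per_year)

    recs: list[tuple] = []
    effort_rows: list[tuple] = []
    transit_idx: list[int] = []

    for year in config.years:
        active = [c for c in config.hotspot_centres if c.active_in(year)]
        weights = np.array([c.intensity for c in active], dtype=float)
        for d in range(config.n_divers):
            diver = f"D{d + 1:02d}"
            for k in range(config.dives_per_year):
                day = min(20 + k * day_stride + int(rng.integers(0, max(day_stride, 2))),
                          360)
                date = datetime(year, 1, 1) + timedelta(days=day)
                # anchor choice
                if active and rng.random() >= config.background_fraction:
                    c = active[rng.choice(len(active), p=weights / weights.sum())]
                    ax, ay, intensity = c.x, c.y, c.intensity
                else:
                    gx, gy = grounds[int(rng.integers(0, len(grounds)))]
                    ax = gx + float(rng.normal(0, config.ground_jitter_m))
                    ay = gy + float(rng.normal(0, config.ground_jitter_m))
                    ax = float(np.clip(ax, x0 + config.diver_drift_radius,
                                       x1 - config.diver_drift_radius))
                    ay = float(np.clip(ay, y0 + config.diver_drift_radius,
                                       y1 - config.diver_drift_radius))
                    intensity = config.background_intensity
                n_swipes = max(1, int(rng.poisson(config.swipes_per_dive_mean
                                                  * intensity)))
                hours = float(np.clip(rng.normal(eff_mean, eff_sd), 0.5, None))
                effort_rows.append((diver, date.date().isoformat(), hours))

                # bounded random walk around the anchor
                t = date + timedelta(hours=8, minutes=int(rng.integers(0, 59)))
                pos = np.array([ax, ay]) + rng.normal(0, config.step_sd_m, 2)
                last_xy = pos.copy()   # position of the last emitted record
                lengths = _truncated_normal(rng, n_swipes, sl_mean, sl_sd, sl_min)
                for s in range(n_swipes):
                    if s > 0:
                        if rng.random() < config.transit_fraction:
                            # planted transit excursion
                            gap = float(rng.uniform(120.0, 400.0))
                            f = float(rng.uniform(1.3, 2.0))
                            want = f * config.vessel_speed_transit * gap
                            target = np.array([rng.uniform(x0 + res, x1 - res),
                                               rng.uniform(y0 + res, y1 - res)])
                            u = target - last_xy
                            norm = np.hypot(*u)
                            if norm < 1e-9:
                                u = np.array([1.0, 0.0]); norm = 1.0
                            u /= norm
                            dist = min(want, norm)
                            if dist < want:  # keep implied speed >= f * v
                                gap = dist / (f * config.vessel_speed_transit)
                            tpt = last_xy + dist * u
                            t += timedelta(seconds=gap)
                            recs.append((diver, t.isoformat(), tpt[0], tpt[1],
                                         lengths[s]))
                            transit_idx.append(len(recs) - 1)
                            last_xy = tpt
                            # the walk itself resumes from the pre-transit
                            # position (pos is untouched)
                            continue
                        gap = config.gap_min_s + rng.exponential(
                            max(config.gap_mean_s - config.gap_min_s, 1.0))
                        t += timedelta(seconds=gap)
                        step = rng.normal(0, config.step_sd_m, 2)
                        cand = pos + step
                        off = cand - np.array([ax, ay])
                        r = np.hypot(*off)
                        if r > config.diver_drift_radius:
                            cand = (np.array([ax, ay])
                                    + off / r * (2 * config.diver_drift_radius - r))
                        pos = cand
                    recs.append((diver, t.isoformat(), pos[0], pos[1], lengths[s]))
                    last_xy = pos.copy()

    swipes = pd.DataFrame(recs, columns=["diver_id", "timestamp", "x_m", "y_m",
                                         "shell_length_mm"])
    effort = (pd.DataFrame(effort_rows, columns=["diver_id", "date", "hours"])
              .groupby(["diver_id", "date"], as_index=False)["hours"].sum())

    cells_by_year: dict[int, list[tuple[int, int]]] = {}
    for year in config.years:
        cells: list[tuple[int, int]] = []
        for c in config.hotspot_centres:
            if c.active_in(year):
                cells.extend(_hotspot_cells(c, config.diver_drift_radius,
                                            (x0, y0), 100.0))
        cells_by_year[year] = sorted(set(cells))
    truth = GroundTruth(hotspot_cells_by_year=cells_by_year,
                        transit_indices=transit_idx,
                        centres=list(config.hotspot_centres))
    return SyntheticFishery(swipes=swipes, effort=effort, truth=truth)


# ---------------------------------------------------------------------------
# canonical scenario
# ---------------------------------------------------------------------------

def default_scenario(seed: int = 0) -> tuple[SyntheticSeafloor, SyntheticFishery,
                                             SeafloorConfig, FisheryConfig]:
    """The reference end-to-end scenario: 3 reefs, 3 persistent hotspots.

    One hotspot centre is planted on each reef, active in all four years,
    with catch intensity 3x the background.  Scale matches a small
    commercial abalone zone (6 divers, ~1400 h over 2008-2011).
    """
    sea_cfg = SeafloorConfig(seed=seed)
    sea = generate_dem(sea_cfg)
    centres = tuple(HotspotCentre(x=cx, y=cy, years=None, intensity=3.0)
                    for cx, cy in sea.reef_centres)
    fish_cfg = FisheryConfig(hotspot_centres=centres, seed=seed + 1)
    fishery = generate_fishery(sea.dem, sea.reef_mask, fish_cfg)
    return sea, fishery, sea_cfg, fish_cfg
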