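"""Shared fixtures: a compact synthetic scenario reused across modules."""

import numpy as np
import pandas as pd
import pytest

from reefcpue.synth import (FisheryConfig, HotspotCentre, SeafloorConfig,
                            generate_dem, generate_fishery)


@pytest.fixture(scope="session")
def small_seafloor():
    """A small reef/sediment mosaic (fast to generate, 2 reefs)."""
    cfg = SeafloorConfig(extent=(0.0, 0.0, 2000.0, 1500.0), n_reefs=2,
                         reef_radius=300.0, seed=7)
    return generate_dem(cfg)


@pytest.fixture(scope="session")
def small_fishery(small_seafloor):
    """A two-year fishery over the small seafloor with one planted hotspot."""
    sea = small_seafloor
    cx, cy = sea.reef_centres[0]
    cfg = FisheryConfig(years=(2008, 2009), n_divers=3, dives_per_year=8,
                        swipes_per_dive_mean=40.0,
                        hotspot_centres=(HotspotCentre(cx, cy, None, 3.0),),
                        n_background_grounds=5, seed=11)
    return generate_fishery(sea.dem, sea.reef_mask, cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def grid_10x10_centroids():
    """Centroids of a 10x10 grid of 100 m cells."""
    xs, ys = np.meshgrid(np.arange(10) * 100.0 + 50.0,
                         np.arange(10) * 100.0 + 50.0)
    return np.column_stack([xs.ravel(), ys.ravel()])
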