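"""Random drifter seeding and bloom/non-bloom attribution.

Drifters are seeded uniformly at random inside the study box (default
13-24°E, 54-60°N, 4000 drifters). Positions whose nearest grid node is land
are redrawn, so every seed starts in water and the requested count is exact.
Each seed is then attributed to the state of its containing grid cell in a
three-state satellite bloom mask: bloom, no-bloom, or inconclusive — the
last meaning the satellite product could not classify the pixel (clouds,
sub-surface blooms), and such drifters are discarded from all contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .fields_io import Grid, MASK_VAR, _normalize_lon
from .tracker import DrifterState, Label

__all__ = [
    "BloomState",
    "BloomMask",
    "SeedingConfig",
    "seed_random",
    "classify_drifters",
    "write_bloom_mask",
    "load_bloom_mask",
]

# integer codes used on disk and in memory
BloomState = Label  # NO_BLOOM=0, BLOOM=1; code 2 = inconclusive on masks
INCONCLUSIVE = 2


@dataclass
class BloomMask:
    """Three-state bloom classification raster for one event.

    ``states`` holds integer codes on the grid nodes (0 = no_bloom,
    1 = bloom, 2 = inconclusive); land cells carry inconclusive by
    convention. ``event_time`` is the satellite detection time in seconds.
    """

    grid: Grid
    states: np.ndarray
    event_time: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.shape != self.grid.shape:
            raise ValueError("states shape must match grid")
        self.states = np.where(self.grid.land_mask, INCONCLUSIVE, self.states)


@dataclass
class SeedingConfig:
    lon_min: float = 13.0
    lon_max: float = 24.0
    lat_min: float = 54.0
    lat_max: float = 60.0
    n_drifters: int = 4000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lon_min >= self.lon_max or self.lat_min >= self.lat_max:
            raise ValueError("empty bounding box")
        if self.n_drifters <= 0:
            raise ValueError("n_drifters must be positive")


def seed_random(config: SeedingConfig, grid: Grid) -> list[DrifterState]:
    """Draw exactly ``n_drifters`` uniform positions on wet cells of the box.

    Land draws (nearest grid node is land) are rejected and redrawn, so the
    returned count is exact. Deterministic for a fixed ``rng_seed``.
    """
    box = (
        (grid.lon >= config.lon_min) & (grid.lon <= config.lon_max),
        (grid.lat >= config.lat_min) & (grid.lat <= config.lat_max),
    )
    sub = grid.land_mask[np.ix_(box[1], box[0])]
    if sub.size == 0 or sub.all():
        raise ValueError("seeding box contains no wet cells")

    rng = np.random.default_rng(config.rng_seed)
    lons = np.empty(config.n_drifters)
    lats = np.empty(config.n_drifters)
    need = np.arange(config.n_drifters)
    while need.size:
        cand_lon = rng.uniform(config.lon_min, config.lon_max, need.size)
        cand_lat = rng.uniform(config.lat_min, config.lat_max, need.size)
        iy, ix = grid.nearest_index(cand_lon, cand_lat)
        wet = ~grid.land_mask[iy, ix]
        lons[need[wet]] = cand_lon[wet]
        lats[need[wet]] = cand_lat[wet]
        need = need[~wet]
    return [
        DrifterState(id=i, lon=float(lons[i]), lat=float(lats[i]))
        for i in range(config.n_drifters)
    ]


def classify_drifters(seeds: list[DrifterState], mask: BloomMask) -> np.ndarray:
    """Label each seed by the bloom state of its containing cell.

    Cell membership is nearest-node assignment. Seeds outside the mask
    domain, and seeds over inconclusive pixels, are discarded. The three
    label counts always sum to the number of seeds, and relabelling is
    idempotent (labels depend only on position).
    """
    lon = np.array([s.lon for s in seeds])
    lat = np.array([s.lat for s in seeds])
    labels = np.full(lon.size, Label.DISCARDED, dtype=np.int8)
    inside = mask.grid.contains(lon, lat)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} seed(s) outside mask domain: discarded",
            stacklevel=2,
        )
    iy, ix = mask.grid.nearest_index(lon[inside], lat[inside])
    st = mask.states[iy, ix]
    lab = np.where(
        st == BloomState.BLOOM,
        Label.BLOOM,
        np.where(st == BloomState.NO_BLOOM, Label.NO_BLOOM, Label.DISCARDED),
    )
    labels[inside] = lab
    return labels


def write_bloom_mask(path, mask: BloomMask) -> None:
    ds = xr.Dataset(
        {
            "bloom_state": xr.DataArray(
                mask.states.astype(np.int8),
                dims=("lat", "lon"),
                attrs={
                    "flag_values": "0 1 2",
                    "flag_meanings": "no_bloom bloom inconclusive",
                },
            ),
            MASK_VAR: xr.DataArray(
                mask.grid.land_mask.astype(np.int8), dims=("lat", "lon")
            ),
        },
        coords={"lat": mask.grid.lat, "lon": mask.grid.lon},
        attrs={"event_time_s": mask.event_time},
    )
    ds.to_netcdf(path, engine="scipy")


def load_bloom_mask(path) -> BloomMask:
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        grid = Grid(
            lon=_normalize_lon(ds["lon"].values),
            lat=ds["lat"].values.astype(float),
            land_mask=ds[MASK_VAR].values.astype(bool),
        )
        return BloomMask(
            grid=grid,
            states=ds["bloom_state"].values.astype(np.int8),
            event_time=float(ds.attrs.get("event_time_s", 0.0)),
        )
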