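"""Synthetic ocean scenarios: basin, flows, forcing, bloom masks, nutrients.

Every input the pipeline consumes can be generated here with controlled
statistical structure, so the full chain — seeding, back-tracing,
environmental sampling, ensemble contrasts, nutrient climatology — is
testable without any external data. The basin is a rectangular wet domain
enclosed by a one-node land rim (solid walls, like the hindcast domain),
optionally with a peninsula to make the distance-to-coast field nontrivial.

Velocity regimes are analytic test flows, not realistic circulation:

* ``uniform`` — constant (U, 0) everywhere; closed-form advection.
* ``solid_rotation`` — rigid rotation about the basin centre in a local
  tangent plane; conserves distance from the centre, the standard oracle
  for integrator convergence.
* ``double_gyre`` — the classic two-cell streamfunction flow
  psi = A sin(pi f(x)) sin(pi y) on the wet interior, optionally
  time-periodic; no-flow walls, closed streamlines.

Bloom masks encode a designed offshore confinement: bloom cells are drawn
only where distance to coast >= D*, with an inconclusive fraction sprinkled
uniformly as a cloud proxy. Nutrient tables encode a designed coastal
enrichment: medians step up by a configured offset on the coastal side of
the excluded 40-60 nm band, with multiplicative lognormal noise (bottle
concentrations are positive and right-skewed), so the climatology's
coastal-offshore median difference has a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import distance_to_coast_field
from .fields_io import FieldSeries, Grid
from .seeding import INCONCLUSIVE, BloomMask, BloomState

__all__ = ["ScenarioConfig", "Scenario", "gen_basin", "gen_velocity",
           "gen_forcing", "gen_bloom_mask", "gen_nutrient_table",
           "generate_scenario"]

DAY = 86400.0
EARTH_RADIUS_M = 6_371_000.0


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic study scenario (defaults = study conditions)."""

    # basin: the central Baltic study box with a one-node land rim
    lon_min: float = 13.0
    lon_max: float = 24.0
    lat_min: float = 54.0
    lat_max: float = 60.0
    n_lon: int = 120
    n_lat: int = 100
    peninsula: bool = False

    # velocity output cadence and archive span (covers a 60-day window)
    cadence: float = 3 * 3600.0
    duration: float = 61 * DAY

    # flow regime
    regime: str = "double_gyre"     # uniform | solid_rotation | double_gyre
    speed: float = 0.005            # m/s: uniform speed or gyre peak speed
    rotation_period: float = 60 * DAY
    gyre_eps: float = 0.0           # 0 = steady gyre
    gyre_period: float = 10 * DAY

    # smooth forcing baselines, meridional gradients (per degree lat), noise sd
    sst_base: float = 16.0          # degC
    sst_grad: float = -0.3
    sst_noise: float = 0.1
    mld_base: float = 10.0          # m
    mld_grad: float = 0.0
    mld_noise: float = 0.5
    swr_base: float = 200.0         # W/m2
    swr_noise: float = 10.0

    # bloom placement: offshore-only beyond D*, cloud proxy fraction
    bloom_dstar_nm: float = 15.0
    bloom_coverage: float = 0.5
    inconclusive_frac: float = 0.1

    # nutrient design: offshore medians + coastal enrichment offsets (umol/L)
    no3_offshore_median: float = 1.0
    no3_coastal_offset: float = 0.5
    po4_offshore_median: float = 0.3
    po4_coastal_offset: float = 0.1
    nutrient_sigma: float = 0.3     # sd of log-concentration
    n_records_per_month: int = 2000

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lon < 8 or self.n_lat < 8:
            raise ValueError("grid must be at least 8x8")
        for frac in (self.bloom_coverage, self.inconclusive_frac):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_records_per_month <= 0:
            raise ValueError("n_records_per_month must be positive")
        if self.regime not in ("uniform", "solid_rotation", "double_gyre"):
            raise ValueError(f"unknown velocity regime {self.regime!r}")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one named sub-stream."""
        return np.random.default_rng([self.rng_seed, stream])


# sub-stream tags
_STREAM_FORCING, _STREAM_BLOOM, _STREAM_NUTRIENT = 1, 2, 3


def gen_basin(config: ScenarioConfig) -> Grid:
    """Rectangular wet basin with a one-node land rim (solid walls)."""
    lon = np.linspace(config.lon_min, config.lon_max, config.n_lon)
    lat = np.linspace(config.lat_min, config.lat_max, config.n_lat)
    land = np.zeros((config.n_lat, config.n_lon), dtype=bool)
    land[0, :] = land[-1, :] = True
    land[:, 0] = land[:, -1] = True
    if config.peninsula:
        # spur from the west wall reaching 1/3 into the basin at mid-latitude
        j0 = config.n_lat // 2
        half = max(1, config.n_lat // 40)
        land[j0 - half : j0 + half + 1, : config.n_lon // 3] = True
    return Grid(lon=lon, lat=lat, land_mask=land)


def _local_xy(grid: Grid) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Tangent-plane metres about the basin centre; (x2d, y2d, Lx, Ly)."""
    lonc = 0.5 * (grid.lon[0] + grid.lon[-1])
    latc = 0.5 * (grid.lat[0] + grid.lat[-1])
    coslc = np.cos(np.deg2rad(latc))
    x = EARTH_RADIUS_M * coslc * np.deg2rad(grid.lon - lonc)
    y = EARTH_RADIUS_M * np.deg2rad(grid.lat - latc)
    x2d, y2d = np.meshgrid(x, y)
    return x2d, y2d, float(x[-1] - x[0]), float(y[-1] - y[0])


def gen_velocity(config: ScenarioConfig, grid: Grid | None = None
                 ) -> tuple[FieldSeries, FieldSeries]:
    """Velocity snapshot stack for the configured regime at 3-h cadence."""
    if grid is None:
        grid = gen_basin(config)
    times = np.arange(0.0, config.duration + 0.5 * config.cadence, config.cadence)
    n_t = times.size
    x2d, y2d, Lx, Ly = _local_xy(grid)

    if config.regime == "uniform":
        u2d = np.full(grid.shape, config.speed)
        v2d = np.zeros(grid.shape)
        u = np.broadcast_to(u2d, (n_t,) + grid.shape).copy()
        v = np.broadcast_to(v2d, (n_t,) + grid.shape).copy()
    elif config.regime == "solid_rotation":
        omega = 2.0 * np.pi / config.rotation_period
        u = np.broadcast_to(-omega * y2d, (n_t,) + grid.shape).copy()
        v = np.broadcast_to(omega * x2d, (n_t,) + grid.shape).copy()
    else:  # double_gyre on the wet interior, walls at the rim
        # normalized coords over the interior node span
        xs = (x2d - x2d[0, 1]) / (x2d[0, -2] - x2d[0, 1])
        ys = (y2d - y2d[1, 0]) / (y2d[-2, 0] - y2d[1, 0])
        Lxi = x2d[0, -2] - x2d[0, 1]
        Lyi = y2d[-2, 0] - y2d[1, 0]
        U0 = config.speed
        omega = 2.0 * np.pi / config.gyre_period
        eps = config.gyre_eps
        u = np.empty((n_t,) + grid.shape)
        v = np.empty((n_t,) + grid.shape)
        for k, t in enumerate(times):
            a = eps * np.sin(omega * t)
            b = 1.0 - 2.0 * a
            f = a * xs**2 + b * xs
            dfdx = 2.0 * a * xs + b
            u[k] = -U0 * np.sin(np.pi * f) * np.cos(np.pi * ys)
            v[k] = U0 * (Lyi / Lxi) * np.cos(np.pi * f) * np.sin(np.pi * ys) * dfdx
    us = FieldSeries(grid=grid, times=times, values=u, name="u", units="m s-1")
    vs = FieldSeries(grid=grid, times=times, values=v, name="v", units="m s-1")
    return us, vs


def gen_forcing(config: ScenarioConfig, grid: Grid | None = None
                ) -> tuple[FieldSeries, FieldSeries, FieldSeries]:
    """SST, MLD and shortwave stacks: baseline + meridional gradient + noise."""
    if grid is None:
        grid = gen_basin(config)
    rng = config.rng(_STREAM_FORCING)
    times = np.arange(0.0, config.duration + 0.5 * config.cadence, config.cadence)
    n_t = times.size
    latc = 0.5 * (grid.lat[0] + grid.lat[-1])
    lat2d = np.broadcast_to(grid.lat[:, None], grid.shape)

    def stack(base, grad, noise, floor=None):
        mean2d = base + grad * (lat2d - latc)
        vals = np.broadcast_to(mean2d, (n_t,) + grid.shape).copy()
        if noise > 0:
            vals += rng.normal(0.0, noise, vals.shape)
        if floor is not None:
            vals = np.maximum(vals, floor)
        return vals

    sst = FieldSeries(grid=grid, times=times, name="sst", units="degC",
                      values=stack(config.sst_base, config.sst_grad,
                                   config.sst_noise))
    mld = FieldSeries(grid=grid, times=times, name="mld", units="m",
                      values=stack(config.mld_base, config.mld_grad,
                                   config.mld_noise, floor=1.0))
    swr = FieldSeries(grid=grid, times=times, name="swr", units="W m-2",
                      values=stack(config.swr_base, 0.0, config.swr_noise,
                                   floor=0.0))
    return sst, mld, swr


def gen_bloom_mask(grid: Grid, dist_field: np.ndarray, config: ScenarioConfig,
                   event_time: float = 0.0) -> BloomMask:
    """Bloom cells only beyond D* from the coast, plus a cloud proxy.

    Bloom cells cover ``bloom_coverage`` of the eligible (wet, dist >= D*)
    cells; ``inconclusive_frac`` of all wet cells are then overwritten as
    inconclusive, emulating cloud gaps that can hit any pixel.
    """
    rng = config.rng(_STREAM_BLOOM)
    wet = grid.wet_mask
    eligible = wet & (dist_field >= config.bloom_dstar_nm)
    if not eligible.any():
        raise ValueError(f"no wet cell lies {config.bloom_dstar_nm} nm offshore")
    states = np.full(grid.shape, BloomState.NO_BLOOM, dtype=np.int8)

    idx = np.flatnonzero(eligible.ravel())
    n_bloom = int(round(config.bloom_coverage * idx.size))
    chosen = rng.choice(idx, size=n_bloom, replace=False)
    states.ravel()[chosen] = BloomState.BLOOM

    wet_idx = np.flatnonzero(wet.ravel())
    cloud = wet_idx[rng.random(wet_idx.size) < config.inconclusive_frac]
    states.ravel()[cloud] = INCONCLUSIVE
    return BloomMask(grid=grid, states=states, event_time=event_time)


def gen_nutrient_table(config: ScenarioConfig, grid: Grid | None = None,
                       dist_field: np.ndarray | None = None) -> pd.DataFrame:
    """Synthetic bottle table with a designed coastal median enrichment.

    Records fall at random wet positions on May-September dates. Each
    concentration is lognormal about a zone median: the offshore median
    plus the coastal offset on the coastal side of the excluded band (the
    step sits at 50 nm, inside the band, so zoned bins see clean medians).
    """
    if grid is None:
        grid = gen_basin(config)
    if dist_field is None:
        dist_field = distance_to_coast_field(grid)
    rng = config.rng(_STREAM_NUTRIENT)
    months = (5, 6, 7, 8, 9)
    n = config.n_records_per_month

    frames = []
    for month in months:
        lon = np.empty(n)
        lat = np.empty(n)
        need = np.arange(n)
        while need.size:
            clon = rng.uniform(grid.lon[0], grid.lon[-1], need.size)
            clat = rng.uniform(grid.lat[0], grid.lat[-1], need.size)
            iy, ix = grid.nearest_index(clon, clat)
            wet = ~grid.land_mask[iy, ix]
            lon[need[wet]] = clon[wet]
            lat[need[wet]] = clat[wet]
            need = need[~wet]
        iy, ix = grid.nearest_index(lon, lat)
        dist = dist_field[iy, ix]
        coastal_side = dist < 50.0
        days = rng.integers(1, 29, n)
        dates = pd.to_datetime(
            {"year": np.full(n, 2000), "month": np.full(n, month), "day": days}
        )

        def draw(median_off, offset):
            med = np.where(coastal_side, median_off + offset, median_off)
            vals = med * np.exp(rng.normal(0.0, config.nutrient_sigma, n))
            return np.maximum(vals, 0.0)

        frames.append(pd.DataFrame({
            "date": dates,
            "lon": lon,
            "lat": lat,
            "no3": np.round(draw(config.no3_offshore_median,
                                 config.no3_coastal_offset), 1),
            "po4": np.round(draw(config.po4_offshore_median,
                                 config.po4_coastal_offset), 2),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class Scenario:
    """One fully generated scenario, ready for the pipeline."""

    config: ScenarioConfig
    grid: Grid
    dist_field: np.ndarray
    u: FieldSeries
    v: FieldSeries
    sst: FieldSeries
    mld: FieldSeries
    swr: FieldSeries
    bloom_mask: BloomMask
    nutrients: pd.DataFrame

    @property
    def t_event(self) -> float:
        return float(self.u.times[-1])


def generate_scenario(config: ScenarioConfig | None = None,
                      with_nutrients: bool = True) -> Scenario:
    """Generate every pipeline input for one scenario configuration."""
    config = config or ScenarioConfig()
    grid = gen_basin(config)
    dist_field = distance_to_coast_field(grid)
    u, v = gen_velocity(config, grid)
    sst, mld, swr = gen_forcing(config, grid)
    mask = gen_bloom_mask(grid, dist_field, config, event_time=float(u.times[-1]))
    nutrients = (gen_nutrient_table(config, grid, dist_field)
                 if with_nutrients else pd.DataFrame())
    return Scenario(config=config, grid=grid, dist_field=dist_field,
                    u=u, v=v, sst=sst, mld=mld, swr=swr,
                    bloom_mask=mask, nutrients=nutrients)
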