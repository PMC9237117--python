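"""Gridded data model and masked space-time interpolation.

The pipeline works on regular rectilinear lon/lat grids carrying a boolean
land mask, with every time-varying quantity (velocity components, sea-surface
temperature, mixed-layer depth, shortwave radiation) stored as a
:class:`FieldSeries` — a time-stamped stack of 2-D node-registered fields.
Values on land are NaN, never zero: zero is a legal field value.

Interpolation is bilinear in space with land-aware weight renormalisation
(nodes on land are dropped from the 4-node stencil and the remaining weights
rescaled to sum to one) and linear in time between bracketing snapshots.
No extrapolation is performed in either dimension; out-of-domain queries
raise so that callers decide policy explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = [
    "Grid",
    "FieldSeries",
    "OutOfDomainError",
    "interp_space",
    "interp_spacetime",
    "load_field_series",
    "load_grid",
    "write_field_series",
]

MASK_VAR = "land_mask"


class OutOfDomainError(ValueError):
    """Query point outside the grid bounding box or time span."""


def _check_monotone(name: str, x: np.ndarray) -> None:
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"{name} must be 1-D with at least 2 points")
    if not np.all(np.diff(x) > 0):
        raise ValueError(f"{name} must be strictly increasing")


def _normalize_lon(lon: np.ndarray) -> np.ndarray:
    """Map longitudes from [-180, 360) to a single increasing branch."""
    lon = np.asarray(lon, dtype=float)
    return np.where(lon < -180.0, lon + 360.0, lon)


@dataclass(frozen=True)
class Grid:
    """Regular rectilinear lon/lat mesh with a land mask.

    Parameters
    ----------
    lon, lat
        Strictly increasing node coordinates in degrees east / north.
    land_mask
        Boolean array of shape ``(len(lat), len(lon))``; True marks land.
    """

    lon: np.ndarray
    lat: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        object.__setattr__(self, "land_mask", np.asarray(self.land_mask, dtype=bool))
        _check_monotone("lon", self.lon)
        _check_monotone("lat", self.lat)
        if self.land_mask.shape != (self.lat.size, self.lon.size):
            raise ValueError(
                f"land_mask shape {self.land_mask.shape} != "
                f"({self.lat.size}, {self.lon.size})"
            )
        if self.land_mask.all():
            raise ValueError("grid has no wet cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_mask.shape

    @property
    def wet_mask(self) -> np.ndarray:
        return ~self.land_mask

    def contains(self, lon, lat) -> np.ndarray:
        """Element-wise test that points lie inside the bounding box."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon[0]) & (lon <= self.lon[-1])
            & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )

    def nearest_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Indices (iy, ix) of the nearest grid node to each point."""
        ix = np.clip(
            np.searchsorted(self.lon, np.asarray(lon, dtype=float)), 1, self.lon.size - 1
        )
        ix = np.where(
            np.abs(np.asarray(lon) - self.lon[ix - 1])
            <= np.abs(self.lon[ix] - np.asarray(lon)),
            ix - 1,
            ix,
        )
        iy = np.clip(
            np.searchsorted(self.lat, np.asarray(lat, dtype=float)), 1, self.lat.size - 1
        )
        iy = np.where(
            np.abs(np.asarray(lat) - self.lat[iy - 1])
            <= np.abs(self.lat[iy] - np.asarray(lat)),
            iy - 1,
            iy,
        )
        return iy, ix


@dataclass
class FieldSeries:
    """Time stack of one scalar field on a :class:`Grid`.

    ``values`` has shape ``(n_time, n_lat, n_lon)``; samples on land cells are
    forced to NaN at construction so land can never masquerade as data.
    ``times`` are seconds since an arbitrary but consistent epoch.
    """

    grid: Grid
    times: np.ndarray
    values: np.ndarray
    name: str
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.array(self.values, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size > 1:
            _check_monotone("times", self.times)
        expected = (self.times.size,) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        self.values[:, self.grid.land_mask] = np.nan

    @property
    def time_span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


# ---------------------------------------------------------------------------
# interpolation


def bilinear_masked(field2d: np.ndarray, grid: Grid, lon, lat) -> np.ndarray:
    """Vectorised masked bilinear interpolation; NaN outside or on all-land.

    Low-level kernel: accepts arrays of query points, returns NaN both for
    points outside the bounding box and for points whose 4-node stencil is
    entirely land. Use :func:`interp_space` for the raising scalar contract.
    """
    lon = _normalize_lon(np.asarray(lon, dtype=float))
    lat = np.asarray(lat, dtype=float)
    glon, glat = grid.lon, grid.lat

    inside = grid.contains(lon, lat)
    ix = np.clip(np.searchsorted(glon, lon, side="right") - 1, 0, glon.size - 2)
    iy = np.clip(np.searchsorted(glat, lat, side="right") - 1, 0, glat.size - 2)
    wx = (lon - glon[ix]) / (glon[ix + 1] - glon[ix])
    wy = (lat - glat[iy]) / (glat[iy + 1] - glat[iy])
    wx = np.clip(wx, 0.0, 1.0)
    wy = np.clip(wy, 0.0, 1.0)

    wet = grid.wet_mask
    out = np.zeros(np.broadcast(lon, lat).shape, dtype=float)
    wsum = np.zeros_like(out)
    for dy, dx, w in (
        (0, 0, (1 - wx) * (1 - wy)),
        (0, 1, wx * (1 - wy)),
        (1, 0, (1 - wx) * wy),
        (1, 1, wx * wy),
    ):
        node_wet = wet[iy + dy, ix + dx]
        v = field2d[iy + dy, ix + dx]
        w_eff = np.where(node_wet, w, 0.0)
        out += w_eff * np.where(node_wet, v, 0.0)
        wsum += w_eff
    with np.errstate(invalid="ignore"):
        out = np.where(wsum > 0, out / np.where(wsum > 0, wsum, 1.0), np.nan)
    return np.where(inside, out, np.nan)


def interp_space(field2d: np.ndarray, grid: Grid, lon, lat):
    """Masked bilinear interpolation of a 2-D field at one or many points.

    Land nodes are dropped from the stencil and the remaining weights
    renormalised; the result is NaN (missing) only when all four surrounding
    nodes are land. Raises :class:`OutOfDomainError` if any query point lies
    outside the grid bounding box.
    """
    scalar = np.isscalar(lon) and np.isscalar(lat)
    if not np.all(grid.contains(lon, lat)):
        raise OutOfDomainError(f"point(s) outside grid bounding box")
    out = bilinear_masked(field2d, grid, lon, lat)
    return float(out) if scalar else out


def _time_bracket(times: np.ndarray, t: float) -> tuple[int, int, float]:
    if t < times[0] or t > times[-1]:
        raise OutOfDomainError(
            f"time {t} outside series span [{times[0]}, {times[-1]}]"
        )
    k = int(np.searchsorted(times, t, side="right") - 1)
    k = min(k, times.size - 2) if times.size > 1 else 0
    if times.size == 1 or t == times[k]:
        return k, k, 0.0
    frac = (t - times[k]) / (times[k + 1] - times[k])
    return k, k + 1, float(frac)


def interp_spacetime(series: FieldSeries, lon, lat, t: float):
    """Bilinear-in-space, linear-in-time sample of a field series.

    When ``t`` coincides with a snapshot time exactly one snapshot is used.
    No temporal extrapolation: ``t`` outside the series span raises.
    """
    k0, k1, frac = _time_bracket(series.times, float(t))
    scalar = np.isscalar(lon) and np.isscalar(lat)
    if not np.all(series.grid.contains(lon, lat)):
        raise OutOfDomainError("point(s) outside grid bounding box")
    v0 = bilinear_masked(series.values[k0], series.grid, lon, lat)
    if k1 == k0 or frac == 0.0:
        out = v0
    else:
        v1 = bilinear_masked(series.values[k1], series.grid, lon, lat)
        out = (1.0 - frac) * v0 + frac * v1
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# NetCDF I/O (classic format via xarray's scipy backend)


def write_field_series(path, series: list[FieldSeries] | FieldSeries) -> None:
    """Write one or more field series sharing a grid to a NetCDF file.

    The file is self-describing: dimensions (time, lat, lon), coordinate
    variables, per-variable units attributes, a ``land_mask`` variable and a
    NaN fill value on every data variable.
    """
    if isinstance(series, FieldSeries):
        series = [series]
    grid = series[0].grid
    times = series[0].times
    for s in series[1:]:
        if s.grid.shape != grid.shape or not np.array_equal(s.times, times):
            raise ValueError("all series in one file must share grid and times")
    data = {
        s.name: xr.DataArray(
            s.values,
            dims=("time", "lat", "lon"),
            attrs={"units": s.units, "_FillValue": np.nan},
        )
        for s in series
    }
    data[MASK_VAR] = xr.DataArray(
        grid.land_mask.astype(np.int8),
        dims=("lat", "lon"),
        attrs={"flag_values": "0 1", "flag_meanings": "wet land"},
    )
    ds = xr.Dataset(
        data,
        coords={
            "time": ("time", times, {"units": "s"}),
            "lat": ("lat", grid.lat, {"units": "degrees_north"}),
            "lon": ("lon", grid.lon, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def load_grid(path) -> Grid:
    """Read the coordinates and land mask from a gridded file."""
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        if MASK_VAR not in ds:
            raise ValueError(f"variable not found: {MASK_VAR!r}")
        return Grid(
            lon=_normalize_lon(ds["lon"].values),
            lat=ds["lat"].values.astype(float),
            land_mask=ds[MASK_VAR].values.astype(bool),
        )


def load_field_series(path, variable: str) -> FieldSeries:
    """Load one variable from a gridded file as a validated FieldSeries.

    Raises ``ValueError`` for a missing variable or a variable without a time
    dimension; CF-style ``_FillValue``/NaN missing values become NaN.
    """
    grid = load_grid(path)
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        if variable not in ds:
            raise ValueError(f"variable not found: {variable!r}")
        da = ds[variable]
        if "time" not in da.dims:
            raise ValueError(f"variable {variable!r} has no time dimension")
        fill = da.attrs.get("_FillValue", None)
        values = da.values.astype(float)
        if fill is not None and not np.isnan(fill):
            values = np.where(values == fill, np.nan, values)
        return FieldSeries(
            grid=grid,
            times=ds["time"].values.astype(float),
            values=values,
            name=variable,
            units=str(da.attrs.get("units", "")),
        )
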