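"""Abiotic histories along trajectories: SST, MLD, mixed-layer PAR, coast distance.

PAR (photosynthetically active radiation) experienced by a cell mixed through
the surface layer is modelled as the depth average of exponentially attenuated
surface irradiance,

    PAR(I0, H) = f * I0 * (1 - exp(-k H)) / (k H),

with f = 0.42 the PAR fraction of incoming shortwave and k = 0.2 m^-1 a
constant attenuation coefficient. As H -> 0 the average tends to f*I0 (a cell
pinned at the surface sees 42% of the incoming shortwave); deeper mixed layers
dilute the light linearly in 1/H once k*H >> 1. Self-shading by the bloom
itself is deliberately not modelled.

Distance to coast is a static per-node field: the minimum great-circle
distance from each wet node to any land node, in nautical miles (1 nm =
1852 m). At ~1 nm grid resolution node-to-node distance is an adequate proxy
for distance to the shoreline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields_io import FieldSeries, Grid, bilinear_masked, interp_spacetime
from .tracker import Status, TrajectoryEnsemble

__all__ = [
    "PARParams",
    "EnvHistory",
    "par_mixed_layer",
    "distance_to_coast_field",
    "sample_environment",
    "NM_PER_M",
]

M_PER_NM = 1852.0
NM_PER_M = 1.0 / M_PER_NM
EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class PARParams:
    """PAR fraction of shortwave (dimensionless) and attenuation (m^-1)."""

    par_fraction: float = 0.42
    attenuation: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.par_fraction <= 1.0):
            raise ValueError("par_fraction must be in (0, 1]")
        if self.attenuation <= 0.0:
            raise ValueError("attenuation must be positive")


@dataclass
class EnvHistory:
    """Per-drifter, per-offset environmental samples.

    Arrays are (n_drifter, n_time); samples are NaN wherever the drifter is
    not active (beached or out of domain) at that offset.
    """

    times_rel: np.ndarray
    sst: np.ndarray
    mld: np.ndarray
    par: np.ndarray
    dist_coast_nm: np.ndarray
    labels: np.ndarray | None = None
    status: np.ndarray | None = None

    def variable(self, name: str) -> np.ndarray:
        table = {
            "sst": self.sst,
            "mld": self.mld,
            "par": self.par,
            "dist": self.dist_coast_nm,
            "dist_coast_nm": self.dist_coast_nm,
        }
        if name not in table:
            raise KeyError(f"unknown environment variable {name!r}")
        return table[name]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (drifter_id, time_rel_s, sst, mld, par, ...)."""
        n_d, n_t = self.sst.shape
        out = pd.DataFrame(
            {
                "drifter_id": np.repeat(np.arange(n_d), n_t),
                "time_rel_s": np.tile(self.times_rel, n_d),
                "sst": self.sst.ravel(),
                "mld": self.mld.ravel(),
                "par": self.par.ravel(),
                "dist_coast_nm": self.dist_coast_nm.ravel(),
            }
        )
        if self.labels is not None:
            out["label"] = np.repeat(self.labels, n_t)
        if self.status is not None:
            out["status"] = self.status.ravel()
        return out


def par_mixed_layer(I0, H, params: PARParams = PARParams()):
    """Mixed-layer average PAR in W m^-2.

    ``I0`` is incoming shortwave (W m^-2, >= 0), ``H`` mixed-layer depth in
    metres (> 0). Uses expm1 so the H -> 0 limit (f * I0) is numerically
    exact down to nanometre-scale mixed layers. NaN inputs propagate.
    """
    I0 = np.asarray(I0, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(H[~np.isnan(H)] <= 0.0):
        raise ValueError("mixed-layer depth must be positive")
    if np.any(I0[~np.isnan(I0)] < 0.0):
        raise ValueError("shortwave radiation must be non-negative")
    kH = params.attenuation * H
    out = params.par_fraction * I0 * (-np.expm1(-kH)) / kH
    return float(out) if out.ndim == 0 else out


def distance_to_coast_field(grid: Grid, chunk: int = 2048) -> np.ndarray:
    """Minimum great-circle distance from each node to land, in nautical miles.

    Land nodes get 0. Raises on an all-wet grid (distance undefined). The
    haversine is evaluated wet-nodes x land-nodes in chunks to bound memory.
    """
    if not grid.land_mask.any():
        raise ValueError("grid has no land: distance to coast undefined")
    lon2d, lat2d = np.meshgrid(np.deg2rad(grid.lon), np.deg2rad(grid.lat))
    land = grid.land_mask
    llon, llat = lon2d[land], lat2d[land]
    wlon, wlat = lon2d[~land], lat2d[~land]

    out = np.zeros(grid.shape, dtype=float)
    dists = np.empty(wlon.size, dtype=float)
    for start in range(0, wlon.size, chunk):
        sl = slice(start, start + chunk)
        dlat = wlat[sl, None] - llat[None, :]
        dlon = wlon[sl, None] - llon[None, :]
        a = (
            np.sin(dlat / 2.0) ** 2
            + np.cos(wlat[sl, None]) * np.cos(llat[None, :]) * np.sin(dlon / 2.0) ** 2
        )
        d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
        dists[sl] = d.min(axis=1)
    out[~land] = dists * NM_PER_M
    return out


def sample_environment(
    traj: TrajectoryEnsemble,
    sst: FieldSeries,
    mld: FieldSeries,
    swr: FieldSeries,
    dist_field: np.ndarray,
    params: PARParams = PARParams(),
) -> EnvHistory:
    """Attach abiotic properties to every active trajectory point.

    SST, MLD and shortwave are interpolated in space and time to each
    drifter position; PAR is the mixed-layer average of the sampled
    shortwave over the sampled MLD; distance to coast is a spatial
    interpolation of the static field. Non-active samples are NaN.
    """
    grid = sst.grid
    lo, hi = traj.times_abs.min(), traj.times_abs.max()
    for s in (sst, mld, swr):
        if lo < s.times[0] or hi > s.times[-1]:
            raise ValueError(f"series {s.name!r} does not cover the trajectory span")

    n_d, n_t = traj.status.shape
    out = {
        k: np.full((n_d, n_t), np.nan)
        for k in ("sst", "mld", "swr", "dist")
    }
    for k_t in range(n_t):
        act = traj.status[:, k_t] == Status.ACTIVE
        if not act.any():
            continue
        lon = traj.positions[act, k_t, 0]
        lat = traj.positions[act, k_t, 1]
        t = traj.times_abs[k_t]
        out["sst"][act, k_t] = interp_spacetime(sst, lon, lat, t)
        out["mld"][act, k_t] = interp_spacetime(mld, lon, lat, t)
        out["swr"][act, k_t] = interp_spacetime(swr, lon, lat, t)
        out["dist"][act, k_t] = bilinear_masked(dist_field, grid, lon, lat)

    with np.errstate(invalid="ignore"):
        par = par_mixed_layer(out["swr"], np.where(out["mld"] > 0, out["mld"], np.nan),
                              params)
    return EnvHistory(
        times_rel=traj.times_rel,
        sst=out["sst"],
        mld=out["mld"],
        par=par,
        dist_coast_nm=out["dist"],
        labels=traj.labels,
        status=traj.status,
    )
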