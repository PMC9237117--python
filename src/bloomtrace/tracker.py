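"""Backward (and forward) Euler advection of virtual drifters.

Water parcels are represented by virtual drifters advected through the
Eulerian surface-velocity series with an explicit first-order Euler scheme:
the velocity is sampled at the drifter's current position and current time
(bilinear in space, linear in time) and the position updated by

    dlon = -u * dt / (R * cos(lat)) * 180/pi
    dlat = -v * dt / R * 180/pi

for a backward step (signs flipped going forward), with a single spherical
Earth radius R. Drifters whose next velocity sample is missing (an all-land
stencil) freeze in place as *beached*; drifters stepped outside the grid
bounding box freeze at their last valid position as *out_of_domain*. Frozen
drifters keep their position for every remaining step so the ensemble stays
countable: n_active + n_beached + n_out_of_domain = n_seeded at all times.

The integrator is deliberately plain — no diffusion, no predictor-corrector —
so trajectories are bit-reproducible given identical inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields_io import FieldSeries, Grid, bilinear_masked, interp_spacetime

__all__ = [
    "Status",
    "DrifterState",
    "TrackerConfig",
    "TrajectoryEnsemble",
    "step_euler_backward",
    "step_euler_forward",
    "advect_backward",
    "advect_forward",
]

EARTH_RADIUS_M = 6_371_000.0
DEG = 180.0 / np.pi


class Status(enum.IntEnum):
    ACTIVE = 0
    BEACHED = 1
    OUT_OF_DOMAIN = 2


class Label(enum.IntEnum):
    """Satellite attribution of a drifter's seed cell."""

    NO_BLOOM = 0
    BLOOM = 1
    DISCARDED = 2


@dataclass
class DrifterState:
    id: int
    lon: float
    lat: float
    status: Status = Status.ACTIVE


@dataclass
class TrackerConfig:
    """Integration settings.

    window
        Total traced duration in seconds (default 60 days).
    dt
        Recording/integration interval in seconds (default 3 h, the cadence
        of the archived velocity output).
    substeps
        Euler sub-steps per recorded interval (>= 1); velocities are
        interpolated to sub-step times.
    """

    window: float = 60 * 86400.0
    dt: float = 3 * 3600.0
    substeps: int = 1
    earth_radius: float = EARTH_RADIUS_M

    def __post_init__(self) -> None:
        if self.window <= 0 or self.dt <= 0:
            raise ValueError("window and dt must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        n = self.window / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.window / self.dt))


@dataclass
class TrajectoryEnsemble:
    """Positions and flags of all drifters at each recorded offset.

    ``times_rel`` are offsets in seconds from the reference time (the bloom
    event for backward runs): 0 first, then -dt, -2dt, ... for backward runs
    and +dt, +2dt, ... for forward runs.
    """

    times_rel: np.ndarray              # (n_time,)
    positions: np.ndarray              # (n_drifter, n_time, 2) lon/lat
    status: np.ndarray                 # (n_drifter, n_time) Status codes
    labels: np.ndarray | None = None   # (n_drifter,) Label codes
    t_ref: float = 0.0

    @property
    def n_drifters(self) -> int:
        return self.positions.shape[0]

    @property
    def times_abs(self) -> np.ndarray:
        return self.t_ref + self.times_rel

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (drifter_id, time_rel_s, lon, lat, status, label)."""
        n_d, n_t = self.status.shape
        labels = (
            np.repeat(self.labels, n_t)
            if self.labels is not None
            else np.full(n_d * n_t, -1)
        )
        return pd.DataFrame(
            {
                "drifter_id": np.repeat(np.arange(n_d), n_t),
                "time_rel_s": np.tile(self.times_rel, n_d),
                "lon": self.positions[:, :, 0].ravel(),
                "lat": self.positions[:, :, 1].ravel(),
                "status": self.status.ravel(),
                "label": labels,
            }
        )


def step_euler_backward(pos, u, v, dt: float, earth_radius: float = EARTH_RADIUS_M):
    """One explicit Euler step backward in time.

    ``pos`` is (lon, lat) in degrees (arrays broadcast); ``u``, ``v`` in
    m s^-1; ``dt`` in seconds. Pure arithmetic — no domain validation.
    """
    lon, lat = pos
    coslat = np.cos(np.deg2rad(lat))
    new_lon = lon - np.asarray(u) * dt / (earth_radius * coslat) * DEG
    new_lat = lat - np.asarray(v) * dt / earth_radius * DEG
    return new_lon, new_lat


def step_euler_forward(pos, u, v, dt: float, earth_radius: float = EARTH_RADIUS_M):
    """One explicit Euler step forward in time (sign-flipped backward step)."""
    return step_euler_backward(pos, u, v, -dt, earth_radius)


def _velocity_at(
    u_series: FieldSeries, v_series: FieldSeries, lon, lat, t: float
) -> tuple[np.ndarray, np.ndarray]:
    u = interp_spacetime(u_series, lon, lat, t)
    v = interp_spacetime(v_series, lon, lat, t)
    return np.asarray(u, dtype=float), np.asarray(v, dtype=float)


def _advect(
    seeds: list[DrifterState],
    u_series: FieldSeries,
    v_series: FieldSeries,
    t_ref: float,
    config: TrackerConfig,
    direction: int,
    labels: np.ndarray | None,
) -> TrajectoryEnsemble:
    grid = u_series.grid
    if v_series.grid.shape != grid.shape or not np.array_equal(
        v_series.times, u_series.times
    ):
        raise ValueError("u and v series must share grid and times")
    t_end = t_ref + direction * config.window
    lo, hi = min(t_ref, t_end), max(t_ref, t_end)
    if lo < u_series.times[0] or hi > u_series.times[-1]:
        raise ValueError(
            "velocity series does not cover the requested tracing window"
        )

    n_steps = config.n_steps
    n_d = len(seeds)
    lon = np.array([s.lon for s in seeds], dtype=float)
    lat = np.array([s.lat for s in seeds], dtype=float)
    status = np.full(n_d, Status.ACTIVE, dtype=np.int8)

    times_rel = direction * config.dt * np.arange(n_steps + 1)
    positions = np.empty((n_d, n_steps + 1, 2), dtype=float)
    status_all = np.empty((n_d, n_steps + 1), dtype=np.int8)

    # seeds on land (all-land stencil) are flagged beached immediately
    probe = bilinear_masked(u_series.values[0], grid, lon, lat)
    inside = grid.contains(lon, lat)
    status[~inside] = Status.OUT_OF_DOMAIN
    status[inside & np.isnan(probe)] = Status.BEACHED

    positions[:, 0, 0], positions[:, 0, 1] = lon, lat
    status_all[:, 0] = status

    sub_dt = config.dt / config.substeps
    for k in range(n_steps):
        for j in range(config.substeps):
            t_now = t_ref + direction * (k * config.dt + j * sub_dt)
            act = status == Status.ACTIVE
            if act.any():
                u, v = _velocity_at(u_series, v_series, lon[act], lat[act], t_now)
                # missing velocity at the current position: beached here
                dead = np.isnan(u) | np.isnan(v)
                idx = np.flatnonzero(act)
                status[idx[dead]] = Status.BEACHED
                live = idx[~dead]
                if live.size:
                    step = step_euler_backward if direction < 0 else step_euler_forward
                    nlon, nlat = step(
                        (lon[live], lat[live]), u[~dead], v[~dead],
                        sub_dt, config.earth_radius,
                    )
                    ok = grid.contains(nlon, nlat)
                    lon[live[ok]] = nlon[ok]
                    lat[live[ok]] = nlat[ok]
                    status[live[~ok]] = Status.OUT_OF_DOMAIN
        positions[:, k + 1, 0], positions[:, k + 1, 1] = lon, lat
        status_all[:, k + 1] = status

    return TrajectoryEnsemble(
        times_rel=times_rel,
        positions=positions,
        status=status_all,
        labels=None if labels is None else np.asarray(labels),
        t_ref=t_ref,
    )


def advect_backward(
    seeds: list[DrifterState],
    u_series: FieldSeries,
    v_series: FieldSeries,
    t_event: float,
    config: TrackerConfig | None = None,
    labels: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Trace drifters backward in time from the event over ``config.window``."""
    return _advect(seeds, u_series, v_series, t_event, config or TrackerConfig(),
                   direction=-1, labels=labels)


def advect_forward(
    seeds: list[DrifterState],
    u_series: FieldSeries,
    v_series: FieldSeries,
    t_start: float,
    config: TrackerConfig | None = None,
    labels: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Forward-time counterpart of :func:`advect_backward` (validation aid)."""
    return _advect(seeds, u_series, v_series, t_start, config or TrackerConfig(),
                   direction=+1, labels=labels)
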