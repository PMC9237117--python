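"""Euler backward advection: closed forms, inversion, beaching, determinism."""

import math

import numpy as np
import pytest

from bloomtrace import (
    DrifterState,
    FieldSeries,
    Grid,
    ScenarioConfig,
    Status,
    TrackerConfig,
    advect_backward,
    advect_forward,
    gen_basin,
    gen_velocity,
    step_euler_backward,
    step_euler_forward,
)

R = 6_371_000.0


def uniform_series(grid, u_val, v_val, t_max=6 * 86400.0, dt=10800.0):
    times = np.arange(0.0, t_max + dt / 2, dt)
    shape = (times.size,) + grid.shape
    u = FieldSeries(grid=grid, times=times, values=np.full(shape, u_val), name="u")
    v = FieldSeries(grid=grid, times=times, values=np.full(shape, v_val), name="v")
    return u, v


@pytest.fixture
def open_grid():
    """All-wet grid, so drifters can leave through the bounding box."""
    lon = np.linspace(10.0, 20.0, 41)
    lat = np.linspace(53.0, 58.0, 21)
    return Grid(lon=lon, lat=lat, land_mask=np.zeros((21, 41), dtype=bool))


class TestEulerStep:
    def test_zero_velocity_is_identity(self):
        lon, lat = step_euler_backward((14.0, 55.0), 0.0, 0.0, 10800.0)
        assert (lon, lat) == (14.0, 55.0)

    def test_closed_form_zonal_step(self):
        # independent hand computation of the degree/metre conversion
        u, dt, lat = 1.0, 10800.0, 55.0
        expected_dlon = -(u * dt) / (R * math.cos(math.radians(lat))) * 180.0 / math.pi
        lon, lat_out = step_euler_backward((14.0, lat), u, 0.0, dt)
        assert lon - 14.0 == pytest.approx(expected_dlon, rel=1e-14)
        assert lat_out == lat

    def test_meridional_step_independent_of_latitude_metric(self):
        v, dt = 0.5, 3600.0
        expected_dlat = -(v * dt) / R * 180.0 / math.pi
        _, lat_out = step_euler_backward((14.0, 55.0), 0.0, v, dt)
        assert lat_out - 55.0 == pytest.approx(expected_dlat, rel=1e-14)

    def test_backward_then_forward_with_frozen_zonal_velocity_inverts(self):
        pos = (14.0, 55.0)
        back = step_euler_backward(pos, 0.7, 0.0, 10800.0)
        fwd = step_euler_forward(back, 0.7, 0.0, 10800.0)
        assert fwd[0] == pytest.approx(pos[0], abs=1e-12)
        assert fwd[1] == pos[1]


class TestAdvection:
    def test_zero_velocity_trajectories_constant_and_active(self, open_grid):
        u, v = uniform_series(open_grid, 0.0, 0.0)
        seeds = [DrifterState(0, 14.0, 55.0), DrifterState(1, 16.0, 56.0)]
        cfg = TrackerConfig(window=5 * 86400.0, dt=10800.0)
        traj = advect_backward(seeds, u, v, 5 * 86400.0, cfg)
        assert (traj.status == Status.ACTIVE).all()
        for i, s in enumerate(seeds):
            assert (traj.positions[i, :, 0] == s.lon).all()
            assert (traj.positions[i, :, 1] == s.lat).all()

    def test_uniform_flow_matches_closed_form_exactly(self, open_grid):
        U, T, phi = 0.1, 2 * 86400.0, 55.0
        u, v = uniform_series(open_grid, U, 0.0)
        cfg = TrackerConfig(window=T, dt=10800.0)
        traj = advect_backward([DrifterState(0, 16.0, phi)], u, v, T, cfg)
        expected = 16.0 - U * T / (R * math.cos(math.radians(phi))) * 180.0 / math.pi
        assert traj.positions[0, -1, 0] == pytest.approx(expected, rel=1e-13)
        assert traj.positions[0, -1, 1] == phi

    def test_forward_then_backward_recovers_seeds_in_steady_zonal_flow(self, open_grid):
        u, v = uniform_series(open_grid, 0.08, 0.0)
        seeds = [DrifterState(i, 13.0 + i * 0.5, 54.0 + i * 0.7) for i in range(5)]
        cfg = TrackerConfig(window=3 * 86400.0, dt=10800.0)
        fwd = advect_forward(seeds, u, v, 0.0, cfg)
        back_seeds = [
            DrifterState(i, fwd.positions[i, -1, 0], fwd.positions[i, -1, 1])
            for i in range(5)
        ]
        back = advect_backward(back_seeds, u, v, 3 * 86400.0, cfg)
        for i, s in enumerate(seeds):
            assert back.positions[i, -1, 0] == pytest.approx(s.lon, abs=1e-10)
            assert back.positions[i, -1, 1] == pytest.approx(s.lat, abs=1e-10)

    def test_forward_backward_misfit_shrinks_with_dt_in_unsteady_flow(self):
        cfg_s = ScenarioConfig(n_lon=40, n_lat=40, duration=10 * 86400.0,
                               regime="double_gyre", speed=0.2,
                               gyre_eps=0.25, gyre_period=2 * 86400.0)
        grid = gen_basin(cfg_s)
        u, v = gen_velocity(cfg_s, grid)
        lonc = 0.5 * (grid.lon[0] + grid.lon[-1])
        latc = 0.5 * (grid.lat[0] + grid.lat[-1])
        seeds = [DrifterState(0, lonc - 2.0, latc), DrifterState(1, lonc + 1.5, latc + 1.0)]

        def misfit(substeps):
            cfg = TrackerConfig(window=6 * 86400.0, dt=10800.0, substeps=substeps)
            fwd = advect_forward(seeds, u, v, 0.0, cfg)
            bseeds = [DrifterState(i, *fwd.positions[i, -1]) for i in range(len(seeds))]
            back = advect_backward(bseeds, u, v, 6 * 86400.0, cfg)
            return np.max(np.hypot(
                back.positions[:, -1, 0] - [s.lon for s in seeds],
                back.positions[:, -1, 1] - [s.lat for s in seeds],
            ))

        m1, m2, m4 = misfit(1), misfit(2), misfit(4)
        assert m2 < m1
        assert m4 < m2

    def test_insufficient_temporal_coverage_is_config_error(self, open_grid):
        u, v = uniform_series(open_grid, 0.0, 0.0, t_max=86400.0)
        cfg = TrackerConfig(window=2 * 86400.0, dt=10800.0)
        with pytest.raises(ValueError, match="does not cover"):
            advect_backward([DrifterState(0, 14.0, 55.0)], u, v, 86400.0, cfg)


class TestBeachingAndStatus:
    def test_seeds_on_land_flag_beached_immediately(self, tiny_scenario):
        sc = tiny_scenario
        # a position whose whole stencil is land: the grid corner
        seeds = [DrifterState(0, float(sc.grid.lon[0]), float(sc.grid.lat[0]))]
        cfg = TrackerConfig(window=86400.0, dt=10800.0)
        traj = advect_backward(seeds, sc.u, sc.v, sc.t_event, cfg)
        assert (traj.status[0] == Status.BEACHED).all()
        assert (traj.positions[0, :, 0] == seeds[0].lon).all()

    def test_out_of_domain_freezes_at_last_valid_position(self, open_grid):
        # steady westward flow pushes the backward trace out the east edge
        u, v = uniform_series(open_grid, -1.0, 0.0)
        cfg = TrackerConfig(window=5 * 86400.0, dt=10800.0)
        traj = advect_backward([DrifterState(0, 19.9, 55.0)], u, v,
                               5 * 86400.0, cfg)
        final = traj.status[0, -1]
        assert final == Status.OUT_OF_DOMAIN
        k = int(np.argmax(traj.status[0] == Status.OUT_OF_DOMAIN))
        assert (traj.positions[0, k:, 0] == traj.positions[0, k, 0]).all()
        assert traj.positions[0, k, 0] <= open_grid.lon[-1]

    def test_status_transitions_one_way_and_conserved(self, tiny_scenario):
        sc = tiny_scenario
        rng = np.random.default_rng(3)
        seeds = [
            DrifterState(i, float(rng.uniform(sc.grid.lon[1], sc.grid.lon[-2])),
                         float(rng.uniform(sc.grid.lat[1], sc.grid.lat[-2])))
            for i in range(50)
        ]
        cfg = TrackerConfig(window=4 * 86400.0, dt=10800.0)
        traj = advect_backward(seeds, sc.u, sc.v, sc.t_event, cfg)
        n_per_time = np.array(
            [np.bincount(traj.status[:, k], minlength=3).sum()
             for k in range(traj.status.shape[1])]
        )
        assert (n_per_time == 50).all()
        # one-way transitions: once non-active, never active again
        for i in range(50):
            nonactive = traj.status[i] != Status.ACTIVE
            assert not (np.diff(nonactive.astype(int)) < 0).any()
        assert np.all(traj.positions[:, :, 0] >= sc.grid.lon[0])
        assert np.all(traj.positions[:, :, 0] <= sc.grid.lon[-1])
        assert np.all(traj.positions[:, :, 1] >= sc.grid.lat[0])
        assert np.all(traj.positions[:, :, 1] <= sc.grid.lat[-1])

    def test_trajectories_bit_reproducible(self, tiny_scenario):
        sc = tiny_scenario
        seeds = [DrifterState(0, 18.0, 57.0), DrifterState(1, 20.0, 56.0)]
        cfg = TrackerConfig(window=3 * 86400.0, dt=10800.0)
        t1 = advect_backward(seeds, sc.u, sc.v, sc.t_event, cfg)
        t2 = advect_backward(seeds, sc.u, sc.v, sc.t_event, cfg)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.status, t2.status)


class TestTrackerConfig:
    @pytest.mark.parametrize(
        "kwargs", [dict(window=-1.0), dict(dt=0.0), dict(substeps=0),
                   dict(window=100000.0, dt=10800.0)]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrackerConfig(**kwargs)
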